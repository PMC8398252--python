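"""Annotated synthetic single-lead wearable ECG.

Each heartbeat is a sum of Gaussian waves (P, Q, R, S, T) with
class-specific parameters:

* N — normal morphology (dominant narrow R, upright P and T);
* S — supraventricular ectopic: normal narrow QRS with an attenuated early
  P wave and a 20-40% shortened preceding RR interval;
* V — ventricular ectopic: no P, wide (>= 120 ms) high-amplitude QRS with a
  discordant T wave, slight prematurity and a compensatory pause;
* F — fusion of ventricular and normal: waves averaged between the N and V
  templates, intermediate QRS width;
* Q — paced: a 2 ms high-amplitude pacing spike preceding a widened,
  low-amplitude QRS.

Beats are placed by an RR process (Gaussian jitter, sigma = 3% of the mean
RR, plus the class-driven prematurity/pauses above) and the clean trace is
contaminated with baseline wander (low-frequency sinusoid), mains
interference (50/60 Hz sinusoid) and band-limited Gaussian EMG noise scaled
to a target SNR.  The output is quantized to the ADC grid (1/200 mV) so
WFDB round trips are bit-exact.  All randomness flows from one seeded
generator; identical configs give bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import BeatAnnotation, EcgRecord, write_wfdb

__all__ = ["SynthConfig", "BeatTemplate", "SyntheticEcg", "generate", "CLASS_SYMBOLS"]

#: WFDB beat mnemonic written for each generated AAMI class.
CLASS_SYMBOLS = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "/"}

_ADC_GAIN = 200.0  # adu/mV quantization grid of written records


@dataclass(frozen=True)
class BeatTemplate:
    """Per-wave Gaussian parameters: (amplitude mV, center s rel. R, width s)."""

    waves: tuple[tuple[float, float, float], ...]
    pacing_spike: bool = False

    def render(self, t: np.ndarray) -> np.ndarray:
        y = np.zeros_like(t)
        for amp, mu, sigma in self.waves:
            y += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        if self.pacing_spike:
            # 2 ms rectangular-ish spike just before the QRS
            y += 1.5 * np.exp(-0.5 * ((t + 0.020) / 0.0009) ** 2)
        return y


_N_WAVES = (
    (0.12, -0.220, 0.025),   # P
    (-0.10, -0.030, 0.010),  # Q
    (1.10, 0.000, 0.013),    # R
    (-0.25, 0.026, 0.012),   # S
    (0.35, 0.220, 0.060),    # T
)
_V_WAVES = (
    (1.35, 0.000, 0.040),    # wide R
    (-0.65, 0.075, 0.035),   # deep slurred S
    (-0.45, 0.300, 0.080),   # discordant T
)


def _fusion_waves() -> tuple[tuple[float, float, float], ...]:
    """F template: per-wave average of the N and V templates (padded with
    zero-amplitude waves where one parent lacks the wave)."""
    n = {"P": _N_WAVES[0], "Q": _N_WAVES[1], "R": _N_WAVES[2],
         "S": _N_WAVES[3], "T": _N_WAVES[4]}
    v = {"R": _V_WAVES[0], "S": _V_WAVES[1], "T": _V_WAVES[2]}
    out = []
    for w in ("P", "Q", "R", "S", "T"):
        a1, m1, s1 = n.get(w, (0.0, 0.0, 0.02))
        a2, m2, s2 = v.get(w, (0.0, m1, s1))
        if w in ("P", "Q"):  # absent in V: halve amplitude, keep N timing
            out.append((a1 / 2, m1, s1))
        else:
            out.append(((a1 + a2) / 2, (m1 + m2) / 2, (s1 + s2) / 2))
    return tuple(out)


TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate(_N_WAVES),
    "S": BeatTemplate(
        (
            (0.05, -0.180, 0.018),   # small early ectopic P
            (-0.10, -0.030, 0.010),
            (1.05, 0.000, 0.013),
            (-0.25, 0.026, 0.012),
            (0.30, 0.210, 0.055),
        )
    ),
    "V": BeatTemplate(_V_WAVES),
    "F": BeatTemplate(_fusion_waves()),
    "Q": BeatTemplate(
        (
            (0.80, 0.000, 0.030),    # widened, lower-amplitude paced QRS
            (-0.30, 0.060, 0.030),
            (0.25, 0.260, 0.070),
        ),
        pacing_spike=True,
    ),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults describe a moderately noisy wearable recording: 0.15 mV
    baseline wander at 0.25 Hz, 0.05 mV mains at 50 Hz and EMG at 20 dB SNR
    relative to the clean trace, with a 72 bpm mean rate and the heavily
    N-dominated class mix typical of ambulatory data.
    """

    fs: float = 360.0
    duration: float = 60.0
    mean_hr: float = 72.0
    class_mix: tuple[float, ...] = (0.90, 0.03, 0.05, 0.01, 0.01)
    baseline_amp: float = 0.15
    baseline_freq: float = 0.25
    mains_amp: float = 0.05
    mains_freq: float = 50.0
    emg_snr_db: float | None = 20.0
    rr_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or len(self.class_mix) != 5:
            raise ValueError("class_mix must be 5 probabilities summing to 1")
        if min(self.class_mix) < 0:
            raise ValueError("class_mix must be nonnegative")
        if self.baseline_amp < 0 or self.mains_amp < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        if self.mains_freq not in (50.0, 60.0):
            raise ValueError("mains_freq must be 50 or 60 Hz")

    @classmethod
    def clean(cls, **kw) -> "SynthConfig":
        """A noise-free configuration (useful for detector ground truth)."""
        kw.setdefault("baseline_amp", 0.0)
        kw.setdefault("mains_amp", 0.0)
        kw.setdefault("emg_snr_db", None)
        return cls(**kw)


@dataclass
class SyntheticEcg:
    """A generated record plus its ground truth."""

    record: EcgRecord
    annotations: list[BeatAnnotation]
    clean: np.ndarray
    rpeaks: np.ndarray
    classes: list[str]

    def write_wfdb(self, path: str | Path) -> None:
        write_wfdb(self.record, self.annotations, path, gain=_ADC_GAIN)

    def truth_dict(self) -> dict:
        return {
            "record_id": self.record.record_id,
            "fs": self.record.fs,
            "rpeaks": [int(r) for r in self.rpeaks],
            "classes": list(self.classes),
        }


def _rr_sequence(
    classes: Sequence[str], mean_rr: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """RR interval preceding each beat, shaped by beat class."""
    n = len(classes)
    rr = mean_rr * (1 + jitter * rng.standard_normal(n))
    rr = np.clip(rr, 0.4 * mean_rr, 1.8 * mean_rr)
    for i in range(n):
        if classes[i] == "S":  # premature atrial beat: RRpre down 20-40%
            rr[i] *= 1 - rng.uniform(0.2, 0.4)
        elif classes[i] == "V":  # premature + compensatory pause after
            rr[i] *= rng.uniform(0.75, 0.90)
            if i + 1 < n:
                rr[i + 1] = max(2 * mean_rr - rr[i], 1.1 * mean_rr)
    return rr


def _emg_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited (20 Hz - 0.45*fs) Gaussian noise."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, 0.45 * fs], btype="band", fs=fs, output="sos")
    emg = sps.sosfiltfilt(sos, white)
    return emg / np.std(emg)


def generate(config: SynthConfig | None = None) -> SyntheticEcg:
    """Generate one annotated synthetic record (reproducible from seed)."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration * fs))
    t_axis = np.arange(n) / fs
    mean_rr = 60.0 / config.mean_hr

    # draw enough beats to cover the record, then trim to those whose full
    # template support lies inside it
    n_draw = int(config.duration / mean_rr * 1.6) + 8
    classes_all = [
        str(c)
        for c in rng.choice(list("NSVFQ"), size=n_draw, p=list(config.class_mix))
    ]
    rr = _rr_sequence(classes_all, mean_rr, config.rr_jitter, rng)
    beat_times = 0.35 + np.cumsum(rr) - rr[0]

    clean = np.zeros(n)
    rpeaks: list[int] = []
    classes: list[str] = []
    for bt, cls in zip(beat_times, classes_all):
        r_idx = int(round(bt * fs))
        if r_idx - int(0.35 * fs) < 0 or r_idx + int(0.5 * fs) >= n:
            continue
        lo = r_idx - int(0.35 * fs)
        hi = r_idx + int(0.5 * fs)
        t_rel = (np.arange(lo, hi) - r_idx) / fs
        clean[lo:hi] += TEMPLATES[cls].render(t_rel)
        rpeaks.append(r_idx)
        classes.append(cls)

    noisy = clean.copy()
    if config.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noisy += config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t_axis + phase
        )
    if config.mains_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noisy += config.mains_amp * np.sin(
            2 * np.pi * config.mains_freq * t_axis + phase
        )
    if config.emg_snr_db is not None:
        emg = _emg_noise(n, fs, rng)
        p_clean = float(np.mean(clean**2))
        target_p = p_clean / 10 ** (config.emg_snr_db / 10)
        noisy += emg * np.sqrt(target_p)

    # quantize to the ADC grid so WFDB round trips are exact
    noisy = np.round(noisy * _ADC_GAIN) / _ADC_GAIN
    record = EcgRecord(
        f"synth-{config.seed}", noisy, fs, lead_name="synthetic-I"
    )
    annotations = [
        BeatAnnotation(r, CLASS_SYMBOLS[c], c) for r, c in zip(rpeaks, classes)
    ]
    return SyntheticEcg(
        record=record,
        annotations=annotations,
        clean=clean,
        rpeaks=np.array(rpeaks, dtype=int),
        classes=classes,
    )


def generate_corpus(
    config: SynthConfig, n_records: int, seed: int | None = None
) -> list[SyntheticEcg]:
    """Several records with per-record derived seeds."""
    base = config.seed if seed is None else seed
    out = []
    for i in range(n_records):
        cfg = replace(config, seed=(base + 7919 * i) % (2**31 - 1))
        rec = generate(cfg)
        rec.record.record_id = f"synth-{base}-{i:03d}"
        out.append(rec)
    return out
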