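"""Heartbeat segmentation and the 56-dimensional beat feature vector.

Each beat is a 151-sample fragment at the 360 Hz reference rate: 50 samples
before the R peak, the R sample, and 100 after.  From each fragment the
pipeline derives

* five morphological features — the previous RR interval, the local
  heart-rate variability (RRpos - RRpre), the left/right area ratio about
  the R peak, the above/below area ratio about the isoelectric line, and
  the peak-to-peak amplitude within a 220 ms window split 3:5 around R; and
* 51 wavelet features — the level-4 approximation (14), level-3 detail (23)
  and level-4 detail (14) coefficients of a 4-level discrete wavelet
  decomposition with a fixed length-6 quadratic-spline analysis pair.

The vector layout is frozen as [morph(5), a4(14), d3(23), d4(14)]; trained
models record a hash of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import logging

import numpy as np
import pandas as pd
import pywt

from .io import EcgRecord

logger = logging.getLogger("ecgbeats")

FRAGMENT_LEN = 151
PRE_SAMPLES = 50   # samples before R; R is the 51st sample (paper index 51)
POST_SAMPLES = 100

#: Analysis filter pair of the quadratic-spline decomposition.
LOD = np.array([0.000, 0.125, 0.375, 0.375, 0.125, 0.000])
HID = np.array([-0.0061, -0.0868, -0.5798, 0.5798, 0.0868, 0.0061])

_WAVELET = pywt.Wavelet(
    "qspline-ecg", filter_bank=[LOD, HID, LOD[::-1], HID[::-1]]
)

_EPS_DENOM = 1e-6  # floor for area-ratio denominators, mV * samples

#: Frozen 56-column layout.
FEATURE_NAMES: tuple[str, ...] = (
    "rr_pre", "hrv_loc", "ratio_lr", "ratio_ud", "dif",
    *[f"a4_{i}" for i in range(1, 15)],
    *[f"d3_{i}" for i in range(1, 24)],
    *[f"d4_{i}" for i in range(1, 15)],
)
MORPH_NAMES = FEATURE_NAMES[:5]
FEATURE_GROUPS: dict[str, tuple[int, int]] = {
    "morphological": (0, 5),
    "a4": (5, 19),
    "d3": (19, 42),
    "d4": (42, 56),
}


@dataclass
class HeartbeatFragment:
    """One segmented heartbeat: 151 mV samples with R at position 50
    (0-based; the 51st sample), plus beat bookkeeping."""

    hb: np.ndarray
    r_index_in_record: int
    record_id: str
    rr_pre: float
    rr_pos: float
    aami_class: str | None = None

    def __post_init__(self) -> None:
        self.hb = np.asarray(self.hb, dtype=float)
        if self.hb.size != FRAGMENT_LEN:
            raise ValueError(
                f"heartbeat fragment must have {FRAGMENT_LEN} samples, "
                f"got {self.hb.size}"
            )


@dataclass(frozen=True)
class MorphFeatures:
    rr_pre: float
    hrv_loc: float
    ratio_lr: float
    ratio_ud: float
    dif: float


@dataclass(frozen=True)
class WaveletFeatures:
    a4: np.ndarray
    d4: np.ndarray
    d3: np.ndarray

    def __post_init__(self) -> None:
        if (len(self.a4), len(self.d4), len(self.d3)) != (14, 14, 23):
            raise ValueError(
                "wavelet feature lengths must be (a4, d4, d3) = (14, 14, 23), "
                f"got ({len(self.a4)}, {len(self.d4)}, {len(self.d3)})"
            )


@dataclass
class FeatureVector:
    """The 56 features of one beat, in the frozen layout."""

    values: np.ndarray
    label: str | None = None
    record_id: str = ""
    sample_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(FEATURE_NAMES):
            raise ValueError(
                f"feature vector must have {len(FEATURE_NAMES)} values, "
                f"got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def segment(
    record: EcgRecord,
    rpeaks: Sequence[int],
    labels: Sequence[str | None] | None = None,
) -> list[HeartbeatFragment]:
    """Cut one 151-sample fragment per eligible R peak.

    A peak is eligible when the record holds >= 50 samples before and
    >= 100 after it AND it has both a previous and a next R peak (the RR
    features need them).  Ineligible peaks are skipped with a logged count.
    """
    rpeaks = sorted(int(r) for r in rpeaks)
    if labels is not None and len(labels) != len(rpeaks):
        raise ValueError("labels must align with rpeaks")
    n = len(record)
    fs = record.fs
    out: list[HeartbeatFragment] = []
    skipped = 0
    for i, r in enumerate(rpeaks):
        if i == 0 or i == len(rpeaks) - 1:
            skipped += 1
            continue
        if r - PRE_SAMPLES < 0 or r + POST_SAMPLES >= n:
            skipped += 1
            continue
        frag = record.samples[r - PRE_SAMPLES : r + POST_SAMPLES + 1]
        out.append(
            HeartbeatFragment(
                hb=frag.copy(),
                r_index_in_record=r,
                record_id=record.record_id,
                rr_pre=(r - rpeaks[i - 1]) / fs,
                rr_pos=(rpeaks[i + 1] - r) / fs,
                aami_class=labels[i] if labels is not None else None,
            )
        )
    if skipped:
        logger.info(
            "record %s: skipped %d of %d peaks during segmentation",
            record.record_id, skipped, len(rpeaks),
        )
    return out


# --------------------------------------------------------------------------
# Morphological features
# --------------------------------------------------------------------------

def _guarded(denom: float) -> float:
    if abs(denom) < _EPS_DENOM:
        return _EPS_DENOM if denom >= 0 else -_EPS_DENOM
    return denom


def morph_features(
    fragment: HeartbeatFragment,
    rr_pre: float | None = None,
    rr_pos: float | None = None,
) -> MorphFeatures:
    """The five morphological features of one fragment.

    Using the 1-based fragment convention hb(1..151) with R at hb(51):
    ratio_lr sums hb(1..50) against hb(52..151); ratio_ud sums the positive
    samples against the magnitude of the negative ones; dif is the
    peak-to-peak amplitude over hb(21..101) — an 81-sample (225 ms at
    360 Hz) window split 30:50 = 3:5 before/after R.  Denominator
    magnitudes are floored at 1e-6 so one-sided fragments stay finite.
    """
    rr_pre = fragment.rr_pre if rr_pre is None else rr_pre
    rr_pos = fragment.rr_pos if rr_pos is None else rr_pos
    if not (rr_pre > 0 and rr_pos > 0):
        raise ValueError("rr_pre and rr_pos must be > 0")
    hb = fragment.hb
    left = float(np.sum(hb[:PRE_SAMPLES]))          # hb(1..50)
    right = float(np.sum(hb[PRE_SAMPLES + 1:]))     # hb(52..151)
    pos_sum = float(np.sum(hb[hb > 0]))
    neg_sum = float(np.sum(hb[hb < 0]))
    window = hb[20:101]                             # hb(21..101)
    return MorphFeatures(
        rr_pre=rr_pre,
        hrv_loc=rr_pos - rr_pre,
        ratio_lr=left / _guarded(right),
        ratio_ud=pos_sum / abs(_guarded(neg_sum)),
        dif=float(np.max(window) - np.min(window)),
    )


# --------------------------------------------------------------------------
# Wavelet features
# --------------------------------------------------------------------------

def dwt_features(fragment: HeartbeatFragment | np.ndarray) -> WaveletFeatures:
    """4-level DWT of the 151-sample fragment with the fixed filter pair.

    Symmetric boundary extension; per-level output length
    floor((n - 1) / 2) + 3, giving levels of 78, 41, 23 and 14 samples and
    the 51 retained coefficients a4(14) + d4(14) + d3(23).
    """
    hb = fragment.hb if isinstance(fragment, HeartbeatFragment) else np.asarray(fragment, float)
    if hb.size != FRAGMENT_LEN:
        raise ValueError(
            f"dwt_features expects {FRAGMENT_LEN} samples, got {hb.size}"
        )
    a4, d4, d3, _d2, _d1 = pywt.wavedec(hb, _WAVELET, mode="symmetric", level=4)
    return WaveletFeatures(a4=a4, d4=d4, d3=d3)


def build_vector(
    m: MorphFeatures,
    w: WaveletFeatures,
    label: str | None = None,
    record_id: str = "",
    sample_index: int = -1,
) -> FeatureVector:
    """Assemble the frozen-layout 56-vector [morph(5), a4, d3, d4]."""
    values = np.concatenate(
        [[m.rr_pre, m.hrv_loc, m.ratio_lr, m.ratio_ud, m.dif], w.a4, w.d3, w.d4]
    )
    return FeatureVector(values, label, record_id, sample_index)


def extract_features(
    record: EcgRecord,
    rpeaks: Sequence[int],
    labels: Sequence[str | None] | None = None,
) -> list[FeatureVector]:
    """Segment + featurize: one FeatureVector per eligible beat."""
    out = []
    for frag in segment(record, rpeaks, labels):
        m = morph_features(frag)
        w = dwt_features(frag)
        out.append(
            build_vector(
                m, w, frag.aami_class, frag.record_id, frag.r_index_in_record
            )
        )
    return out


# --------------------------------------------------------------------------
# Feature matrix I/O
# --------------------------------------------------------------------------

def vectors_to_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """One row per beat: the 56 features plus label / record / index."""
    vectors = list(vectors)
    df = pd.DataFrame(
        [v.values for v in vectors], columns=list(FEATURE_NAMES)
    )
    df["label"] = [v.label for v in vectors]
    df["record_id"] = [v.record_id for v in vectors]
    df["sample_index"] = [v.sample_index for v in vectors]
    return df


def frame_to_vectors(df: pd.DataFrame) -> list[FeatureVector]:
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing[:3]}...")
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                row[list(FEATURE_NAMES)].to_numpy(dtype=float),
                label=row.get("label") if isinstance(row.get("label"), str) else None,
                record_id=str(row.get("record_id", "")),
                sample_index=int(row.get("sample_index", -1)),
            )
        )
    return out


def write_feature_csv(vectors: Iterable[FeatureVector], path) -> None:
    vectors_to_frame(vectors).to_csv(path, index=False)


def read_feature_csv(path) -> list[FeatureVector]:
    return frame_to_vectors(pd.read_csv(path))
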