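"""Wavelet-based R-peak detection.

The detector is a modulus-maxima scheme on an undecimated (a-trous)
quadratic-spline wavelet transform built from the same length-6 analysis
filter pair used for beat features.  A QRS complex appears at each dyadic
scale as a pair of opposite-signed modulus maxima; the zero-crossing between
them localizes the R wave.  Candidate pairs must exceed an adaptive
threshold (a multiple of the windowed RMS of the detail signal, so detection
is invariant to positive rescaling) at every configured scale.  A refractory
period suppresses double-fires and a search-back pass with a halved
threshold recovers beats missed inside abnormally long RR gaps.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .features import HID, LOD
from .io import EcgRecord

__all__ = ["RPeakConfig", "detect_rpeaks", "match_to_annotations", "swt_detail"]


@dataclass(frozen=True)
class RPeakConfig:
    """Detector parameters.

    scales : tuple of int
        Dyadic scales (2**level) of the undecimated transform used for
        modulus-maxima agreement; default (4, 8) = levels 2 and 3.
    threshold_factor : float
        Multiple of the windowed detail RMS a modulus maximum must exceed.
    refractory : float
        Minimum separation between accepted peaks, seconds.
    searchback_factor : float
        RR gaps longer than this multiple of the running median RR trigger a
        search-back with the threshold halved.
    threshold_window : float
        Length of the adaptive-threshold RMS window, seconds.
    pair_window : float
        Maximum separation of the opposite-signed maxima of one QRS, seconds.
    refine_halfwidth : float
        Half-width of the signal-extremum refinement window around the
        wavelet zero-crossing, seconds.
    """

    scales: tuple[int, ...] = (4, 8)
    threshold_factor: float = 4.0
    refractory: float = 0.2
    searchback_factor: float = 1.66
    threshold_window: float = 2.0
    pair_window: float = 0.12
    refine_halfwidth: float = 0.025

    def __post_init__(self) -> None:
        if not self.refractory > 0:
            raise ValueError("refractory must be > 0")
        if not self.threshold_factor > 0:
            raise ValueError("threshold_factor must be > 0")


def swt_detail(x: np.ndarray, level: int) -> np.ndarray:
    """Detail signal of the undecimated quadratic-spline transform.

    A-trous scheme: at each stage the analysis filters are dilated by
    inserting 2**(j-1) - 1 zeros between taps; the cumulative (fractional)
    group delay of the filter chain is compensated so features stay aligned
    with the input.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    a = np.asarray(x, dtype=float)
    n = a.size
    delay = 0.0
    for j in range(1, level + 1):
        hole = 2 ** (j - 1)
        hi = np.zeros((len(HID) - 1) * hole + 1)
        hi[::hole] = HID
        lo = np.zeros((len(LOD) - 1) * hole + 1)
        lo[::hole] = LOD
        stage_delay = (len(hi) - 1) / 2
        if j == level:
            full = np.convolve(a, hi, mode="full")
        else:
            full = np.convolve(a, lo, mode="full")
        d = int(round(delay + stage_delay))
        out = full[d : d + n]
        if out.size < n:  # very short inputs
            out = np.pad(out, (0, n - out.size))
        if j == level:
            return out
        a = out
        # the slice already absorbed the integer part of the delay
        delay = delay + stage_delay - d
    raise AssertionError("unreachable")


def _windowed_rms(w: np.ndarray, win: int) -> np.ndarray:
    """Per-sample robust RMS of w over non-overlapping windows.

    The background RMS is estimated as 1.4826 * median(|w|) per window (the
    Gaussian-consistent MAD estimate), so the sparse large-amplitude QRS
    responses do not inflate their own detection threshold.  A floor of 2%
    of the global maximum keeps near-silent windows from passing numeric
    ripple; being relative, it preserves invariance to positive rescaling.
    """
    n = w.size
    nwin = max(1, n // win)
    out = np.empty(n)
    for i in range(nwin):
        lo = i * win
        hi = n if i == nwin - 1 else (i + 1) * win
        out[lo:hi] = 1.4826 * np.median(np.abs(w[lo:hi]))
    floor = 0.02 * float(np.max(np.abs(w))) if n else 0.0
    return np.maximum(out, floor)


def _local_extrema(w: np.ndarray) -> np.ndarray:
    """Indices of strict sign-consistent local extrema of w."""
    dw = np.diff(w)
    s = np.sign(dw)
    # indices i where slope changes sign across sample i+1
    turn = np.nonzero(s[:-1] * s[1:] < 0)[0] + 1
    return turn


def _candidate_peaks(
    x: np.ndarray,
    details: list[np.ndarray],
    thresholds: list[np.ndarray],
    fs: float,
    config: RPeakConfig,
    lo: int,
    hi: int,
) -> list[tuple[int, float]]:
    """(refined index, pair strength) candidates in x[lo:hi]."""
    w = details[0]
    thr = thresholds[0]
    pair_max = int(round(config.pair_window * fs))
    refine = int(round(config.refine_halfwidth * fs))

    seg = slice(lo, hi)
    extrema = _local_extrema(w[seg]) + lo
    strong = [e for e in extrema if abs(w[e]) > thr[e]]
    out: list[tuple[int, float]] = []
    for a, b in zip(strong[:-1], strong[1:]):
        if b - a > pair_max or w[a] * w[b] >= 0:
            continue
        # zero-crossing of the detail between the opposite-signed pair
        segment = w[a : b + 1]
        zc_rel = np.nonzero(np.diff(np.sign(segment)) != 0)[0]
        zc = a + (int(zc_rel[0]) if zc_rel.size else (b - a) // 2)
        # agreement at the coarser scales
        ok = True
        for wj, thrj in zip(details[1:], thresholds[1:]):
            lo_j = max(0, zc - pair_max)
            hi_j = min(w.size, zc + pair_max + 1)
            if np.max(np.abs(wj[lo_j:hi_j])) <= thrj[zc]:
                ok = False
                break
        if not ok:
            continue
        rlo, rhi = max(0, zc - refine), min(x.size, zc + refine + 1)
        window = np.abs(x[rlo:rhi])
        # ties toward larger amplitude then earlier index: argmax is earliest max
        r = rlo + int(np.argmax(window))
        strength = min(abs(w[a]), abs(w[b]))
        out.append((r, strength))
    return out


def _enforce_refractory(
    candidates: list[tuple[int, float]], refractory_samples: int
) -> list[tuple[int, float]]:
    accepted: list[tuple[int, float]] = []
    for r, s in sorted(candidates):
        if accepted and r - accepted[-1][0] < refractory_samples:
            if s > accepted[-1][1]:
                accepted[-1] = (r, s)
        else:
            accepted.append((r, s))
    return accepted


def detect_rpeaks(record: EcgRecord, config: RPeakConfig | None = None) -> np.ndarray:
    """Detect R peaks in a (denoised) record.

    Returns a strictly increasing array of 0-based sample indices, each at a
    local extremum of the signal near a wavelet zero-crossing, with
    consecutive peaks at least ``refractory`` seconds apart.

    Raises
    ------
    ValueError
        If the record is shorter than 2 s.
    """
    config = config or RPeakConfig()
    fs = record.fs
    x = record.samples
    if x.size < 2 * fs:
        raise ValueError(
            f"record {record.record_id} is {x.size / fs:.2f} s long; "
            "detection needs at least 2 s"
        )
    levels = [int(np.log2(s)) for s in sorted(config.scales)]
    details = [swt_detail(x, lv) for lv in levels]
    win = int(round(config.threshold_window * fs))
    thresholds = [
        config.threshold_factor * _windowed_rms(w, win) for w in details
    ]
    if all(float(np.max(np.abs(w))) == 0.0 for w in details):
        return np.array([], dtype=int)

    candidates = _candidate_peaks(x, details, thresholds, fs, config, 0, x.size)
    refractory_samples = int(round(config.refractory * fs))
    accepted = _enforce_refractory(candidates, refractory_samples)

    # search-back over abnormally long RR gaps, threshold halved
    peaks = [r for r, _ in accepted]
    if len(peaks) >= 3:
        for _ in range(3):  # a recovered beat can split a gap further
            rr = np.diff(peaks)
            med_rr = float(np.median(rr))
            gaps = [
                (peaks[i], peaks[i + 1])
                for i in range(len(peaks) - 1)
                if rr[i] > config.searchback_factor * med_rr
            ]
            if not gaps:
                break
            halved = [0.5 * t for t in thresholds]
            new: list[tuple[int, float]] = []
            for g0, g1 in gaps:
                lo = g0 + refractory_samples
                hi = g1 - refractory_samples
                if hi - lo < 2:
                    continue
                new.extend(
                    _candidate_peaks(x, details, halved, fs, config, lo, hi)
                )
            if not new:
                break
            merged = _enforce_refractory(
                [(r, s) for r, s in accepted] + new, refractory_samples
            )
            if len(merged) == len(peaks):
                break
            accepted = merged
            peaks = [r for r, _ in accepted]

    return np.array([r for r, _ in accepted], dtype=int)


def match_to_annotations(
    detected: np.ndarray,
    annotated: np.ndarray,
    fs: float,
    tolerance: float = 0.05,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one nearest-neighbor matching within a time tolerance.

    Parameters
    ----------
    detected, annotated : sorted index arrays
    fs : sampling rate (Hz) used to convert ``tolerance`` to samples
    tolerance : matching tolerance in seconds (default 50 ms)

    Returns
    -------
    (matches, false_positives, false_negatives)
        ``matches`` is a list of (detected, annotated) index pairs;
        the other two are the unmatched detections / annotations.
    """
    tol = tolerance * fs
    detected = [int(d) for d in detected]
    annotated = [int(a) for a in annotated]
    # candidate pairs ordered by distance -> greedy one-to-one
    pairs: list[tuple[float, int, int]] = []
    for i, d in enumerate(detected):
        j = bisect_left(annotated, d)
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(annotated) and abs(d - annotated[k]) <= tol:
                pairs.append((abs(d - annotated[k]), i, k))
    pairs.sort()
    used_d: set[int] = set()
    used_a: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, k in pairs:
        if i in used_d or k in used_a:
            continue
        used_d.add(i)
        used_a.add(k)
        matches.append((detected[i], annotated[k]))
    fps = [d for i, d in enumerate(detected) if i not in used_d]
    fns = [a for k, a in enumerate(annotated) if k not in used_a]
    return matches, fps, fns


def detection_scores(
    detected: np.ndarray,
    annotated: np.ndarray,
    fs: float,
    tolerance: float = 0.05,
) -> dict[str, float]:
    """Sensitivity and precision of a detection against reference peaks."""
    matches, fps, fns = match_to_annotations(detected, annotated, fs, tolerance)
    tp = len(matches)
    sens = tp / (tp + len(fns)) if tp + len(fns) else float("nan")
    prec = tp / (tp + len(fps)) if tp + len(fps) else float("nan")
    return {
        "tp": tp,
        "fp": len(fps),
        "fn": len(fns),
        "sensitivity": sens,
        "precision": prec,
    }
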