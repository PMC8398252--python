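"""Reading and writing annotated single-lead ECG records.

Records travel as WFDB triplets (``.hea`` header, ``.dat`` format-16 signal,
``.atr`` annotation) so that synthetic records written here are readable by
standard PhysioNet tooling and vice versa.  Only the subset of the WFDB
specification needed for single-/dual-lead beat analysis is supported:
signal format 16 (little-endian 16-bit two's complement, interleaved) and
the MIT annotation format including the SKIP/NUM/SUB/CHN/AUX pseudo-codes.

Voltages are held in millivolts throughout; ADC-unit arithmetic happens only
at the file boundary.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("ecgbeats")

REFERENCE_FS = 360.0
#: AAMI heartbeat super-classes, in the frozen order used everywhere downstream.
CLASS_ORDER = ("N", "S", "V", "F", "Q")


class MappingError(ValueError):
    """An annotation symbol with no AAMI class."""


class ChannelError(ValueError):
    """Requested lead absent from the record."""


@dataclass
class EcgRecord:
    """A sampled single-lead voltage trace.

    Parameters
    ----------
    record_id : str
        Identity of the recording (the WFDB record name).
    samples : numpy.ndarray
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz, > 0.
    lead_name : str
        Name of the lead, e.g. ``"MLII"``.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    lead_name: str = "MLII"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("EcgRecord.samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EcgRecord.samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"EcgRecord.fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat: R-peak sample index plus labels.

    ``sample_index`` is 0-based into the record's sample array.
    ``source_symbol`` is the WFDB beat mnemonic; ``aami_class`` is its
    mapped AAMI super-class.
    """

    sample_index: int
    source_symbol: str
    aami_class: str


@dataclass(frozen=True)
class DatasetSplit:
    """The inter-patient DS1 (train) / DS2 (test) record split."""

    ds1_record_ids: frozenset[str]
    ds2_record_ids: frozenset[str]
    excluded_record_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ds1_record_ids & self.ds2_record_ids:
            raise ValueError("DS1 and DS2 must be disjoint")


# --------------------------------------------------------------------------
# AAMI class mapping
# --------------------------------------------------------------------------

# Long-form mnemonics and the one-letter WFDB beat codes, merged into one
# lookup.  N: normal + bundle-branch block + escape; S: supraventricular
# ectopic; V: ventricular ectopic; F: ventricular/normal fusion; Q: paced,
# paced-fusion, unclassifiable.
_AAMI_MAP: dict[str, str] = {
    # long mnemonics
    "NOR": "N", "LBBB": "N", "RBBB": "N", "AE": "N", "NE": "N",
    "AP": "S", "aAP": "S", "NP": "S", "SP": "S",
    "PVC": "V", "VE": "V",
    "fVN": "F",
    "P": "Q", "fPN": "Q", "U": "Q",
    # one-letter WFDB codes
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}


def map_to_aami(source_symbol: str) -> str:
    """Map a WFDB beat mnemonic to its AAMI class in {N, S, V, F, Q}.

    Raises
    ------
    MappingError
        If the symbol is not a recognized beat mnemonic.
    """
    try:
        return _AAMI_MAP[source_symbol]
    except KeyError:
        raise MappingError(
            f"no AAMI class for beat symbol {source_symbol!r}"
        ) from None


# --------------------------------------------------------------------------
# WFDB file format (subset)
# --------------------------------------------------------------------------

# MIT annotation code <-> symbol, beat codes only plus the common non-beat
# codes we must be able to step over when reading third-party files.
_BEAT_CODE_TO_SYM = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_SYM_TO_BEAT_CODE = {s: c for c, s in _BEAT_CODE_TO_SYM.items()}
_NONBEAT_CODE_TO_SYM = {
    14: "~", 16: "|", 18: "s", 19: "T", 20: "*", 21: "D", 22: '"',
    23: "=", 24: "p", 25: "B", 26: "^", 27: "t", 28: "+", 29: "u",
    30: "?", 31: "!", 32: "[", 33: "]", 35: "n", 36: "x", 37: "@",
    39: "(", 40: ")", 41: "r",
}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

_DEFAULT_GAIN = 200.0  # adu per mV, the MITDB convention


def _read_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip() for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain_spec = f[2] if len(f) > 2 else "200"
        gain_part = gain_spec.split("/")[0]
        if "(" in gain_part:
            gain_s, base_s = gain_part.rstrip(")").split("(")
            gain, baseline = float(gain_s), int(base_s)
        else:
            gain, baseline = float(gain_part), 0
        if gain == 0:
            gain = _DEFAULT_GAIN
        desc = " ".join(f[8:]) if len(f) > 8 else f"ch{len(sigs)}"
        sigs.append(
            {"file": f[0], "fmt": fmt, "gain": gain, "baseline": baseline,
             "desc": desc}
        )
    return record_name, nsig, fs, nsamp, sigs


def _read_signal_fmt16(dat_path: Path, nsig: int) -> np.ndarray:
    raw = np.fromfile(dat_path, dtype="<i2")
    n = raw.size // nsig
    return raw[: n * nsig].reshape(n, nsig)


def _read_annotations(atr_path: Path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file into (sample, symbol) pairs."""
    data = atr_path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:  # EOF
            break
        if code == _SKIP and interval == 0:
            hi = struct.unpack_from("<h", data, i)[0]
            lo = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            t += (hi << 16) | lo
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += interval + (interval & 1)
        else:
            t += interval
            sym = _BEAT_CODE_TO_SYM.get(code) or _NONBEAT_CODE_TO_SYM.get(code)
            out.append((t, sym if sym is not None else f"<{code}>"))
    return out


def read_record(
    path: str | Path,
    channel: int | str = 0,
    *,
    on_unknown_symbol: str = "raise",
) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Read a WFDB header/signal/annotation triplet.

    Parameters
    ----------
    path : path-like
        Record path without extension (``rec`` for ``rec.hea``/``rec.dat``/
        ``rec.atr``).
    channel : int or str
        Lead index or lead name to extract.  Defaults to the first channel
        (lead MLII on the MITDB).
    on_unknown_symbol : {"raise", "drop"}
        Whether a beat symbol outside the AAMI mapping aborts the read or is
        dropped with a logged count.

    Returns
    -------
    (EcgRecord, list of BeatAnnotation)
        One lead's samples in mV and all beat annotations.  Non-beat
        annotations (rhythm labels, noise markers, ...) are dropped with a
        logged count.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    atr = base.with_suffix(".atr")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header file: {hea}")
    if not atr.exists():
        raise FileNotFoundError(f"missing WFDB annotation file: {atr}")
    record_name, nsig, fs, _nsamp, sigs = _read_header(hea)

    if isinstance(channel, str):
        names = [s["desc"] for s in sigs]
        if channel not in names:
            raise ChannelError(
                f"lead {channel!r} not in record {record_name} (has {names})"
            )
        ch = names.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < nsig:
            raise ChannelError(
                f"channel {ch} out of range for record {record_name} "
                f"with {nsig} signal(s)"
            )

    sig = sigs[ch]
    if sig["fmt"] != "16":
        raise IOError(
            f"unsupported WFDB signal format {sig['fmt']!r} in {hea}; "
            "only format 16 is supported"
        )
    dat = base.parent / sig["file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {dat}")
    digital = _read_signal_fmt16(dat, nsig)[:, ch]
    mv = (digital.astype(float) - sig["baseline"]) / sig["gain"]
    record = EcgRecord(record_name, mv, fs, lead_name=sig["desc"])

    annotations: list[BeatAnnotation] = []
    n_nonbeat = 0
    n_unknown = 0
    for sample, sym in _read_annotations(atr):
        if sym not in _SYM_TO_BEAT_CODE:
            n_nonbeat += 1
            continue
        try:
            aami = map_to_aami(sym)
        except MappingError:
            if on_unknown_symbol == "drop":
                n_unknown += 1
                continue
            raise
        if 0 <= sample < len(record):
            annotations.append(BeatAnnotation(sample, sym, aami))
    if n_nonbeat:
        logger.info(
            "record %s: dropped %d non-beat annotations", record_name, n_nonbeat
        )
    if n_unknown:
        logger.info(
            "record %s: dropped %d unmapped beat symbols", record_name, n_unknown
        )
    return record, annotations


def write_wfdb(
    record: EcgRecord,
    annotations: Sequence[BeatAnnotation],
    path: str | Path,
    *,
    gain: float = _DEFAULT_GAIN,
) -> None:
    """Write a record + beat annotations as a WFDB triplet.

    The signal is stored in format 16 at ``gain`` adu/mV; annotations use
    standard beat mnemonics so third-party WFDB tools can read the output.
    Samples already quantized to the 1/gain grid round-trip bit-exactly.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    digital = np.round(record.samples * gain).astype(np.int64)
    if digital.max() > 32767 or digital.min() < -32768:
        raise IOError(
            f"signal exceeds the int16 range at gain {gain} adu/mV"
        )
    digital = digital.astype("<i2")
    checksum = int(np.sum(digital.astype(np.int64)) & 0xFFFF)
    if checksum >= 0x8000:
        checksum -= 0x10000

    name = base.name
    fs_txt = f"{record.fs:g}"
    header = (
        f"{name} 1 {fs_txt} {len(record)}\n"
        f"{name}.dat 16 {gain:g}/mV 16 0 {int(digital[0])} {checksum} 0 "
        f"{record.lead_name}\n"
    )
    base.with_suffix(".hea").write_text(header)
    digital.tofile(base.with_suffix(".dat"))

    words = bytearray()
    prev = 0
    for ann in sorted(annotations, key=lambda a: a.sample_index):
        if ann.source_symbol not in _SYM_TO_BEAT_CODE:
            raise ValueError(
                f"cannot write non-beat symbol {ann.source_symbol!r}"
            )
        code = _SYM_TO_BEAT_CODE[ann.source_symbol]
        delta = ann.sample_index - prev
        if delta < 0:
            raise ValueError("annotation indices must be sorted and unique")
        if delta > 1023:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<h", (delta >> 16) & 0xFFFF)
            words += struct.pack("<H", delta & 0xFFFF)
            delta = 0
            words += struct.pack("<H", (code << 10) | delta)
        else:
            words += struct.pack("<H", (code << 10) | delta)
        prev = ann.sample_index
    words += struct.pack("<H", 0)  # EOF
    base.with_suffix(".atr").write_bytes(bytes(words))


def annotations_to_csv(
    record_id: str, annotations: Iterable[BeatAnnotation], path: str | Path
) -> None:
    """Export annotations as (record_id, sample_index, source_symbol, aami_class)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "record_id": record_id,
                "sample_index": a.sample_index,
                "source_symbol": a.source_symbol,
                "aami_class": a.aami_class,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_to_reference(
    record: EcgRecord,
    annotations: Sequence[BeatAnnotation] = (),
    target_fs: float = REFERENCE_FS,
) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Resample a record to the pipeline's reference rate.

    Uses an anti-aliased polyphase resampler; annotation indices are rescaled
    by ``target_fs / fs`` and rounded half-away-from-zero.  A record already
    at ``target_fs`` is returned unchanged.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if record.fs == target_fs:
        return record, list(annotations)
    ratio = Fraction(target_fs) / Fraction(record.fs)
    ratio = ratio.limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    resampled = sps.resample_poly(record.samples, up, down)
    new_record = EcgRecord(
        record.record_id, resampled, target_fs, record.lead_name
    )
    scale = target_fs / record.fs
    new_annotations = []
    for a in annotations:
        idx = int(_round_half_away(np.array(a.sample_index * scale)))
        idx = min(max(idx, 0), len(new_record) - 1)
        new_annotations.append(
            BeatAnnotation(idx, a.source_symbol, a.aami_class)
        )
    return new_record, new_annotations


# --------------------------------------------------------------------------
# Inter-patient split
# --------------------------------------------------------------------------

_DS1 = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
_DS2 = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)
_EXCLUDED = ("102", "104", "107", "217")  # paced ECGs


def default_split() -> DatasetSplit:
    """The standard inter-patient DS1 (train) / DS2 (test) split of the
    MIT-BIH Arrhythmia Database; the four paced recordings are excluded."""
    return DatasetSplit(
        ds1_record_ids=frozenset(_DS1),
        ds2_record_ids=frozenset(_DS2),
        excluded_record_ids=frozenset(_EXCLUDED),
    )
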