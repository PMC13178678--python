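"""Reading, validating and writing 12-lead ECG waveforms and audit tables.

Two waveform dialects are supported:

* **matrix** — a tab-delimited text file, one column per lead (header row of
  lead names, one row per sample) with a JSON sidecar ``<path>.json`` carrying
  ``sampling_rate_hz``, ``units``, ``record_id``, ``patient_id``, ``age``
  and ``sex``.  This is the package's language-neutral fixture format.
* **wfdb** — single-segment PhysioNet-style ``.hea``/``.dat`` records in
  format 16 (little-endian int16 with per-lead gain/offset).  A minimal
  reader/writer is included so records round-trip without external tooling.

The canonical internal amplitude unit is the millivolt.  Microvolt inputs are
divided by 1000 on read; ``raw`` units pass through untouched (the amplitude
scaling stage of the harmonization pipeline handles them downstream) and are
flagged in the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical 12-lead order; all records are normalized to it on read.
CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_VALID_UNITS = ("mV", "uV", "raw")
_VALID_SEX = ("M", "F", None)


@dataclass
class ECGRecord:
    """One 12-lead ECG waveform with identity metadata.

    ``signal`` has shape ``(n_leads, n_samples)`` in millivolts (unless
    ``units == "raw"``).  Rows follow ``lead_names``.
    """

    record_id: str
    signal: np.ndarray
    sampling_rate_hz: float
    patient_id: str = ""
    lead_names: tuple[str, ...] = CANONICAL_LEADS
    units: str = "mV"
    age_years: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.lead_names = tuple(self.lead_names)
        validate_record(self)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, **changes) -> "ECGRecord":
        """Return a copy with ``changes`` applied (signal copied by default)."""
        if "signal" not in changes:
            changes["signal"] = self.signal.copy()
        return replace(self, **changes)


def validate_record(record: ECGRecord, require_12_leads: bool = True) -> None:
    """Check ECGRecord invariants, raising :class:`ValidationError`."""
    sig = record.signal
    if sig.ndim != 2:
        raise ValidationError(
            f"signal must be 2-D (leads x samples), got shape {sig.shape}"
        )
    if require_12_leads and sig.shape[0] != 12:
        raise ValidationError(f"expected 12 leads, got {sig.shape[0]}")
    if len(record.lead_names) != sig.shape[0]:
        raise ValidationError("lead_names length does not match signal rows")
    if len(set(record.lead_names)) != len(record.lead_names):
        raise ValidationError("duplicate lead names")
    if not np.isfinite(record.sampling_rate_hz) or record.sampling_rate_hz <= 0:
        raise ValidationError("sampling_rate_hz must be positive")
    if sig.shape[1] == 0:
        raise ValidationError("record has zero duration")
    if not np.all(np.isfinite(sig)):
        raise ValidationError("signal contains non-finite samples")
    if record.units not in _VALID_UNITS:
        raise ValidationError(f"units must be one of {_VALID_UNITS}")
    if record.sex not in _VALID_SEX:
        raise ValidationError("sex must be 'M', 'F' or None")
    if record.age_years is not None and record.age_years < 0:
        raise ValidationError("age_years must be nonnegative")


def _normalize_units(record: ECGRecord) -> ECGRecord:
    if record.units == "uV":
        return record.copy_with(signal=record.signal / 1000.0, units="mV")
    if record.units == "raw":
        logger.warning(
            "record %s has 'raw' units; passing through untouched "
            "(amplitude scaling handles unit drift downstream)",
            record.record_id,
        )
    return record


def _reorder_leads(record: ECGRecord, permissive: bool) -> ECGRecord:
    names = record.lead_names
    if names == CANONICAL_LEADS:
        return record
    if set(names) == set(CANONICAL_LEADS):
        order = [names.index(lead) for lead in CANONICAL_LEADS]
        return record.copy_with(signal=record.signal[order], lead_names=CANONICAL_LEADS)
    if permissive:
        return record
    raise ValidationError(
        f"record {record.record_id}: leads {sorted(names)} do not form the "
        "canonical 12-lead set (pass permissive=True to accept)"
    )


# ---------------------------------------------------------------------------
# matrix + JSON sidecar dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_matrix(path: Path, permissive: bool) -> ECGRecord:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate_hz", "units"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    frame = pd.read_csv(path, sep="\t")
    record = ECGRecord(
        record_id=str(meta.get("record_id", path.stem)),
        patient_id=str(meta.get("patient_id", "")),
        signal=frame.to_numpy(dtype=float).T,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        lead_names=tuple(frame.columns),
        units=str(meta["units"]),
        age_years=meta.get("age"),
        sex=meta.get("sex"),
    )
    return record


def _write_matrix(record: ECGRecord, path: Path) -> None:
    frame = pd.DataFrame(record.signal.T, columns=list(record.lead_names))
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "sampling_rate_hz": record.sampling_rate_hz,
        "units": record.units,
        "record_id": record.record_id,
        "patient_id": record.patient_id,
        "age": record.age_years,
        "sex": record.sex,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# minimal single-segment WFDB (format 16)
# ---------------------------------------------------------------------------

def _read_wfdb(path: Path, permissive: bool) -> ECGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing WFDB header {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_id, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    gains, zeros, names = [], [], []
    dat_name = None
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_name = parts[0]
        if parts[1] != "16":
            raise FormatError(f"unsupported WFDB sample format {parts[1]} (only 16)")
        gain_field = parts[2].split("/")[0]  # "gain(zero)" per WFDB convention
        if "(" in gain_field:
            gain_str, zero_str = gain_field.split("(")
            gain = float(gain_str) or 200.0
            zero = float(zero_str.rstrip(")"))
        else:
            gain = float(gain_field) or 200.0
            zero = 0.0
        gains.append(gain)
        zeros.append(zero)
        names.append(parts[-1])
    meta = {}
    for ln in lines[1 + n_sig:]:
        if ":" in ln:
            key, _, value = ln.partition(":")
            meta[key.strip()] = value.strip()
    dat = hea.parent / dat_name
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_sig]
    adc = raw.reshape(-1, n_sig).T.astype(float)
    signal = (adc - np.asarray(zeros)[:, None]) / np.asarray(gains)[:, None]
    age = meta.get("age")
    return ECGRecord(
        record_id=record_id,
        patient_id=meta.get("patient_id", ""),
        signal=signal,
        sampling_rate_hz=fs,
        lead_names=tuple(names),
        units="mV",
        age_years=float(age) if age not in (None, "", "None") else None,
        sex=meta.get("sex") or None,
    )


def _write_wfdb(record: ECGRecord, path: Path) -> None:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    dat = hea.with_suffix(".dat")
    maxabs = float(np.max(np.abs(record.signal))) or 1.0
    # per-record gain: highest ADC resolution that avoids int16 overflow
    gain = min(1000.0, 32000.0 / maxabs)
    adc = np.rint(record.signal * gain).astype("<i2")
    n_sig, n_samples = record.signal.shape
    lines = [f"{record.record_id} {n_sig} {record.sampling_rate_hz:g} {n_samples}"]
    for name in record.lead_names:
        lines.append(f"{dat.name} 16 {gain:.6f}(0)/mV 16 0 0 0 0 {name}")
    lines.append(f"patient_id: {record.patient_id}")
    lines.append(f"age: {record.age_years if record.age_years is not None else ''}")
    lines.append(f"sex: {record.sex or ''}")
    hea.write_text("\n".join(lines) + "\n")
    adc.T.tofile(dat)


def wfdb_adc_precision(record: ECGRecord) -> float:
    """Worst-case quantization error (mV) of :func:`write_record` in WFDB format."""
    maxabs = float(np.max(np.abs(record.signal))) or 1.0
    gain = min(1000.0, 32000.0 / maxabs)
    return 0.5 / gain


# ---------------------------------------------------------------------------
# public waveform API
# ---------------------------------------------------------------------------

def read_record(path, format: str = "auto", permissive: bool = False) -> ECGRecord:
    """Read and validate an ECG record.

    Parameters
    ----------
    path
        Matrix TSV path, or WFDB header (``.hea``) / record basename.
    format
        ``"wfdb"``, ``"matrix"`` or ``"auto"`` (decides from the extension /
        presence of a ``.hea`` file).
    permissive
        Accept non-canonical lead sets (e.g. fewer than 12 leads).
    """
    path = Path(path)
    if format == "auto":
        if path.suffix == ".hea" or path.with_suffix(".hea").exists():
            format = "wfdb"
        else:
            format = "matrix"
    if format == "wfdb":
        record = _read_wfdb(path, permissive)
    elif format == "matrix":
        record = _read_matrix(path, permissive)
    else:
        raise ParameterError(f"unknown format {format!r}")
    validate_record(record, require_12_leads=not permissive)
    record = _reorder_leads(record, permissive)
    return _normalize_units(record)


def write_record(record: ECGRecord, path, format: str = "matrix") -> Path:
    """Write ``record`` so that :func:`read_record` recovers it.

    Matrix round-trips are exact to ~1e-9 mV; WFDB round-trips are exact to
    the ADC precision reported by :func:`wfdb_adc_precision`.
    """
    validate_record(record)
    path = Path(path)
    if format == "matrix":
        _write_matrix(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# prediction / truth tables
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Row-aligned (record x label) probability and ground-truth matrices."""

    record_ids: list[str]
    label_names: list[str]
    scores: np.ndarray
    truths: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truths = np.asarray(self.truths)
        n, L = len(self.record_ids), len(self.label_names)
        if self.scores.shape != (n, L) or self.truths.shape != (n, L):
            raise ValidationError(
                f"shape mismatch: {n} records x {L} labels vs scores "
                f"{self.scores.shape}, truths {self.truths.shape}"
            )
        if len(set(self.record_ids)) != n:
            raise ValidationError("record_ids are not unique")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores contain non-finite values")
        if self.scores.min(initial=0.0) < 0 or self.scores.max(initial=0.0) > 1:
            raise ValidationError("scores must lie in [0, 1]")
        if not np.isin(self.truths, (0, 1)).all():
            raise ValidationError("truths must be binary (0/1)")
        self.truths = self.truths.astype(np.int8)

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def subset(self, indices: Sequence[int]) -> "PredictionSet":
        """Row subset; repeated indices (bootstrap draws) get suffixed ids."""
        idx = np.asarray(indices)
        ids = [self.record_ids[i] for i in idx]
        if len(set(ids)) != len(ids):
            ids = [f"{rid}#{k}" for k, rid in enumerate(ids)]
        return PredictionSet(
            record_ids=ids,
            label_names=list(self.label_names),
            scores=self.scores[idx],
            truths=self.truths[idx],
        )


def _read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=None, engine="python")
    id_col = frame.columns[0]
    frame = frame.rename(columns={id_col: "record_id"})
    frame["record_id"] = frame["record_id"].astype(str)
    return frame


def read_prediction_set(scores_path, truths_path) -> PredictionSet:
    """Load delimited score and truth tables into an aligned PredictionSet.

    Both tables must share the record_id column (first column) and identical
    label headers.  Rows are aligned by sorted record_id, so the result is
    invariant to row permutations of either input.
    """
    scores = _read_table(scores_path)
    truths = _read_table(truths_path)
    s_labels = list(scores.columns[1:])
    t_labels = list(truths.columns[1:])
    if s_labels != t_labels:
        raise SchemaError(
            f"label headers differ between tables: {s_labels} vs {t_labels}"
        )
    s_ids, t_ids = set(scores["record_id"]), set(truths["record_id"])
    if s_ids != t_ids:
        only = sorted((s_ids ^ t_ids))[:5]
        raise SchemaError(f"records present in only one table, e.g. {only}")
    scores = scores.sort_values("record_id").reset_index(drop=True)
    truths = truths.sort_values("record_id").reset_index(drop=True)
    return PredictionSet(
        record_ids=list(scores["record_id"]),
        label_names=s_labels,
        scores=scores[s_labels].to_numpy(dtype=float),
        truths=truths[s_labels].to_numpy(),
    )


def read_group_table(path) -> pd.DataFrame:
    """Read a demographics table with columns record_id, age, sex."""
    frame = _read_table(path)
    missing = {"age", "sex"} - set(frame.columns)
    if missing:
        raise SchemaError(f"group table lacks columns {sorted(missing)}")
    return frame[["record_id", "age", "sex"]]
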