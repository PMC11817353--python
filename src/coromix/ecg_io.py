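"""Reading, writing and validating 12-lead ECG records.

The canonical in-memory container is :class:`ECGRecord`: twelve named lead
waveforms in millivolts at a common sampling rate, an optional occlusion
label, and free-form metadata.  Two on-disk dialects are supported:

* **CSV** — UTF-8, header ``time,I,II,III,aVR,aVL,aVF,V1,...,V6``, one row per
  sample, with a JSON sidecar ``<name>.meta.json`` carrying ``fs``, ``label``
  and ``record_id``.
* **XML** — root ``<ecg fs="500" label="RCA" id="...">`` with one
  ``<lead name="I" unit="mV">`` element per lead holding whitespace-separated
  samples.  A ``unit="uV"`` attribute is honoured by dividing by 1000.

Both dialects are lossless to well under 1e-9 mV per sample.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyarrow as pa
import pyarrow.csv as pacsv

#: Canonical ordering of the 12 standard leads.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The seven culprit-artery classes, in their fixed index order.
CLASS_NAMES: tuple[str, ...] = (
    "CX", "RCA", "LAD", "CX+LAD", "RCA+LAD", "RCA+CX", "RCA+CX+LAD",
)

_CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Sampling rates used by the acquisition hardware this package models.
STANDARD_RATES = (500.0, 1000.0)

#: Amplitude bound (mV) beyond which a sample is considered non-physiological.
MAX_ABS_MV = 25.0


class ECGIOError(ValueError):
    """Base class for record I/O and validation failures."""


class MissingLeadError(ECGIOError):
    def __init__(self, lead: str):
        self.lead = lead
        super().__init__(f"missing-lead: {lead}")


class LengthMismatchError(ECGIOError):
    def __init__(self, detail: str):
        super().__init__(f"length-mismatch: {detail}")


class BadSamplingRateError(ECGIOError):
    def __init__(self, detail: str):
        super().__init__(f"bad-sampling-rate: {detail}")


def class_index(name: str) -> int:
    """Map a class name (e.g. ``"RCA+CX"``) to its fixed index 0-6."""
    try:
        return _CLASS_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown class label {name!r}; expected one of {CLASS_NAMES}")


def class_name(index: int) -> str:
    """Inverse of :func:`class_index`."""
    return CLASS_NAMES[index]


@dataclass
class ECGRecord:
    """A validated 12-lead ECG record.

    Parameters
    ----------
    record_id
        Stable identifier used in manifests and file names.
    fs
        Sampling frequency in Hz.  500 and 1000 Hz are the expected rates;
        other positive values are accepted with a warning.
    leads
        Mapping lead name -> float array (mV).  Stored in canonical order.
    label
        One of the seven class names, or ``None`` for unlabeled records.
    meta
        Free-form string metadata (e.g. age, sex).  Never required.
    """

    record_id: str
    fs: float
    leads: dict[str, np.ndarray]
    label: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise BadSamplingRateError(f"fs={self.fs!r}")
        if self.fs not in STANDARD_RATES:
            warnings.warn(
                f"non-standard sampling rate {self.fs} Hz (expected 500 or 1000)",
                stacklevel=2,
            )
        for name in LEAD_NAMES:
            if name not in self.leads:
                raise MissingLeadError(name)
        ordered: dict[str, np.ndarray] = {}
        n = None
        for name in LEAD_NAMES:
            arr = np.asarray(self.leads[name], dtype=np.float64)
            if arr.ndim != 1 or arr.size < 1:
                raise LengthMismatchError(f"lead {name} must be a 1-d sequence")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise LengthMismatchError(
                    f"lead {name} has {arr.size} samples, expected {n}"
                )
            ordered[name] = arr
        self.leads = ordered
        if self.label is not None and self.label not in _CLASS_INDEX:
            raise ECGIOError(
                f"unknown label {self.label!r}; expected one of {CLASS_NAMES}"
            )

    @property
    def n_samples(self) -> int:
        return next(iter(self.leads.values())).size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def to_array(self) -> np.ndarray:
        """Stack the leads into an (n_samples, 12) array in canonical order."""
        return np.column_stack([self.leads[name] for name in LEAD_NAMES])

    def equals(self, other: "ECGRecord", atol: float = 1e-9) -> bool:
        """Sample-wise equality within ``atol`` mV, ignoring metadata."""
        if self.fs != other.fs or self.label != other.label:
            return False
        if self.n_samples != other.n_samples:
            return False
        return all(
            np.allclose(self.leads[k], other.leads[k], atol=atol, rtol=0)
            for k in LEAD_NAMES
        )


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found by :func:`validate_record`."""

    kind: str  # "nan-sample" | "flat-lead" | "amplitude"
    lead: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}: {self.lead} ({self.detail})"


def validate_record(
    record: ECGRecord,
    flat_fraction: float = 0.5,
    max_abs_mv: float = MAX_ABS_MV,
) -> list[ValidationIssue]:
    """Automated validity screen standing in for manual noise review.

    Reports (per lead): non-finite samples, leads flat for more than
    ``flat_fraction`` of consecutive sample pairs, and amplitudes beyond
    ``max_abs_mv``.  An empty list means the record is kept.
    """
    issues: list[ValidationIssue] = []
    for name in LEAD_NAMES:
        x = record.leads[name]
        bad = ~np.isfinite(x)
        if bad.any():
            issues.append(
                ValidationIssue("nan-sample", name, f"{int(bad.sum())} non-finite samples")
            )
            continue
        if x.size > 1:
            flat = np.mean(np.diff(x) == 0.0)
            if flat > flat_fraction:
                issues.append(
                    ValidationIssue("flat-lead", name, f"flat for {flat:.0%} of samples")
                )
        over = np.abs(x) > max_abs_mv
        if over.any():
            issues.append(
                ValidationIssue(
                    "amplitude", name,
                    f"{int(over.sum())} samples exceed {max_abs_mv} mV",
                )
            )
    return issues


# ---------------------------------------------------------------------------
# CSV dialect


def _sidecar_path(path: Path) -> Path:
    path = Path(path)
    return path.parent / (path.stem + ".meta.json")


def _read_csv(path: Path) -> ECGRecord:
    table = pacsv.read_csv(path)
    cols = set(table.column_names)
    for name in LEAD_NAMES:
        if name not in cols:
            raise MissingLeadError(name)
    leads = {
        name: table.column(name).to_numpy(zero_copy_only=False).astype(np.float64)
        for name in LEAD_NAMES
    }
    sidecar = _sidecar_path(path)
    fs = None
    label = None
    record_id = Path(path).stem
    meta: dict[str, str] = {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        fs = info.get("fs")
        label = info.get("label")
        record_id = info.get("record_id", record_id)
        meta = {k: str(v) for k, v in info.get("meta", {}).items()}
    if fs is None:
        raise BadSamplingRateError(f"no fs in sidecar {sidecar.name}")
    try:
        fs = float(fs)
    except (TypeError, ValueError):
        raise BadSamplingRateError(f"unparsable fs {fs!r}")
    return ECGRecord(record_id=record_id, fs=fs, leads=leads, label=label, meta=meta)


def _write_csv(record: ECGRecord, path: Path) -> None:
    n = record.n_samples
    time = np.arange(n, dtype=np.float64) / record.fs
    arrays = [pa.array(time)] + [pa.array(record.leads[k]) for k in LEAD_NAMES]
    table = pa.table(arrays, names=["time", *LEAD_NAMES])
    # header written by hand: pyarrow quotes header fields unconditionally
    buf = pa.BufferOutputStream()
    pacsv.write_csv(table, buf,
                    write_options=pacsv.WriteOptions(include_header=False))
    with open(path, "wb") as fh:
        fh.write((",".join(["time", *LEAD_NAMES]) + "\n").encode())
        fh.write(buf.getvalue())
    sidecar = _sidecar_path(path)
    info = {
        "fs": record.fs,
        "label": record.label,
        "record_id": record.record_id,
        "meta": record.meta,
    }
    sidecar.write_text(json.dumps(info, indent=1))


# ---------------------------------------------------------------------------
# XML dialect


def _read_xml(path: Path) -> ECGRecord:
    root = ET.parse(path).getroot()
    if root.tag != "ecg":
        raise ECGIOError(f"expected <ecg> root, found <{root.tag}>")
    fs_text = root.get("fs")
    if fs_text is None:
        raise BadSamplingRateError("missing fs attribute")
    try:
        fs = float(fs_text)
    except ValueError:
        raise BadSamplingRateError(f"unparsable fs {fs_text!r}")
    label = root.get("label") or None
    record_id = root.get("id") or Path(path).stem
    leads: dict[str, np.ndarray] = {}
    for el in root.findall("lead"):
        name = el.get("name")
        if name is None:
            raise ECGIOError("<lead> without a name attribute")
        unit = (el.get("unit") or "mV").lower()
        vals = np.array((el.text or "").split(), dtype=np.float64)
        if unit in ("uv", "µv"):
            vals = vals / 1000.0
        elif unit != "mv":
            raise ECGIOError(f"unsupported unit {unit!r} on lead {name}")
        leads[name] = vals
    for name in LEAD_NAMES:
        if name not in leads:
            raise MissingLeadError(name)
    meta = {
        k: v for k, v in root.attrib.items() if k not in ("fs", "label", "id")
    }
    return ECGRecord(record_id=record_id, fs=fs, leads=leads, label=label, meta=meta)


def _write_xml(record: ECGRecord, path: Path) -> None:
    root = ET.Element("ecg", fs=f"{record.fs:g}", id=record.record_id)
    if record.label is not None:
        root.set("label", record.label)
    for k, v in record.meta.items():
        root.set(k, v)
    for name in LEAD_NAMES:
        el = ET.SubElement(root, "lead", name=name, unit="mV")
        el.text = " ".join(f"{v:.12g}" for v in record.leads[name])
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# public entry points


def read_record(path: str | Path, format: str = "auto") -> ECGRecord:
    """Read one record from ``path`` in the CSV or XML dialect.

    ``format="auto"`` dispatches on the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "xml" if path.suffix.lower() == ".xml" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "xml":
        return _read_xml(path)
    raise ValueError(f"unknown format {format!r}; expected csv, xml or auto")


def write_record(record: ECGRecord, path: str | Path, format: str = "auto") -> Path:
    """Write ``record`` to ``path``; returns the path written."""
    path = Path(path)
    if format == "auto":
        format = "xml" if path.suffix.lower() == ".xml" else "csv"
    if format == "csv":
        _write_csv(record, path)
    elif format == "xml":
        _write_xml(record, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected csv or xml")
    return path
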