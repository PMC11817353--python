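"""Synthetic labeled 12-lead ECG datasets with class-dependent ST morphology.

Each of the seven occlusion classes (CX, RCA, LAD and their combinations) is
tied to a set of *territory leads* — the leads in which ischemia of that
artery is conventionally reflected:

* RCA  -> II, III, aVF (inferior)
* LAD  -> V1-V4 (anteroseptal)
* CX   -> I, aVL, V5, V6 (lateral)

A combination class affects the union of its arteries' territories; aVR
carries no class effect.  The class signature written into a record is an
NSTEMI-like ST-segment *depression* (a negative level shift over the 80 ms
window after each QRS offset) plus, with configurable probability, T-wave
inversion, applied only on the territory leads.  Everything else — P-QRS-T
beat templates built from Gaussians and a triangular R spike, baseline
wander, white noise — is shared across classes.

The generator is a pure function of ``(label, config, seed)``; datasets are
reproducible from a single master seed with per-record seeds
``master_seed + record_index``.

The module also provides :func:`make_tabular_benchmark`, a 7-class Gaussian
feature benchmark (a handful of informative columns among many noise
columns) used to exercise the feature-selection and ensemble stages without
the signal front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg_io import CLASS_NAMES, LEAD_NAMES, ECGRecord, write_record

#: Lead territory of each single artery.
TERRITORY_MAP: dict[str, tuple[str, ...]] = {
    "RCA": ("II", "III", "aVF"),
    "LAD": ("V1", "V2", "V3", "V4"),
    "CX": ("I", "aVL", "V5", "V6"),
}


def territory_leads(label: str) -> tuple[str, ...]:
    """Territory leads of a class label (union over its arteries)."""
    leads: list[str] = []
    for artery in label.split("+"):
        leads.extend(TERRITORY_MAP[artery])
    return tuple(leads)


# Per-lead amplitude scaling of the shared beat template.  aVR sees the
# heart from the opposite direction, hence the negative factor; precordial
# leads carry larger QRS complexes.  Values are stylized, not fitted.
_LEAD_SCALE: dict[str, float] = {
    "I": 0.7, "II": 1.0, "III": 0.6, "aVR": -0.8, "aVL": 0.5, "aVF": 0.8,
    "V1": 0.8, "V2": 1.2, "V3": 1.3, "V4": 1.2, "V5": 1.0, "V6": 0.9,
}

#: Default per-class record counts (CX, RCA, LAD, CX+LAD, RCA+LAD, RCA+CX,
#: RCA+CX+LAD) — the class composition of the cohort this generator emulates.
DEFAULT_CLASS_COUNTS: tuple[int, ...] = (180, 185, 252, 183, 173, 156, 192)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``st_shift_mv`` is the magnitude of the ST-segment depression on
    territory leads; ``noise_sd_mv`` the white-noise level; both in mV.
    """

    fs: float = 500.0
    duration: float = 10.0
    heart_rate_bpm: tuple[float, float] = (55.0, 95.0)
    st_shift_mv: float = 0.15
    t_inversion_prob: float = 0.5
    noise_sd_mv: float = 0.02
    baseline_wander_mv: float = 0.05
    per_class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_class_counts) != len(CLASS_NAMES):
            raise ValueError("per_class_counts must list all 7 classes")
        if any(c < 0 for c in self.per_class_counts):
            raise ValueError("per_class_counts must be non-negative")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        if not 0.0 <= self.t_inversion_prob <= 1.0:
            raise ValueError("t_inversion_prob must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _gaussian(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _triangle(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    return np.clip(1.0 - np.abs(t - center) / half_width, 0.0, None)


# Beat geometry relative to the R peak, in seconds.  QRS offset (J point)
# sits ~40 ms after R; the ST window covers the following 80 ms.
_P_CENTER, _P_WIDTH, _P_AMP = -0.17, 0.022, 0.12
_Q_CENTER, _Q_HW, _Q_AMP = -0.025, 0.012, -0.12
_R_HW, _R_AMP = 0.022, 1.0
_S_CENTER, _S_HW, _S_AMP = 0.030, 0.014, -0.20
_T_CENTER, _T_WIDTH, _T_AMP = 0.28, 0.045, 0.30
QRS_OFFSET_S = 0.045
ST_WINDOW_S = 0.080


def generate_record(label: str, config: GeneratorConfig, seed: int) -> ECGRecord:
    """Generate one labeled 12-lead record; deterministic in all arguments."""
    if label not in CLASS_NAMES:
        raise KeyError(f"unknown class label {label!r}")
    rng = np.random.default_rng(seed)
    fs, n = config.fs, config.n_samples
    t = np.arange(n) / fs

    hr = rng.uniform(*config.heart_rate_bpm)
    rr = 60.0 / hr
    r_times = np.arange(0.35, config.duration - 0.25, rr)

    terr = set(territory_leads(label))
    invert_t = {
        lead: (lead in terr) and (rng.random() < config.t_inversion_prob)
        for lead in LEAD_NAMES
    }
    wander_freq = rng.uniform(0.2, 0.5)
    wander_phase = rng.uniform(0.0, 2.0 * np.pi)

    # Shared per-beat template, evaluated once on a window around R.
    beat: dict[str, np.ndarray] = {}
    rel = (np.arange(int(-0.25 * fs), int(0.40 * fs)) / fs)
    base_wave = (
        _P_AMP * _gaussian(rel, _P_CENTER, _P_WIDTH)
        + _Q_AMP * _triangle(rel, _Q_CENTER, _Q_HW)
        + _R_AMP * _triangle(rel, 0.0, _R_HW)
        + _S_AMP * _triangle(rel, _S_CENTER, _S_HW)
    )
    t_wave = _T_AMP * _gaussian(rel, _T_CENTER, _T_WIDTH)
    st_mask = (rel >= QRS_OFFSET_S) & (rel < QRS_OFFSET_S + ST_WINDOW_S)

    leads: dict[str, np.ndarray] = {}
    for lead in LEAD_NAMES:
        scale = _LEAD_SCALE[lead]
        wave = base_wave + (-1.0 if invert_t[lead] else 1.0) * t_wave
        template = scale * wave
        if lead in terr:
            template = template - config.st_shift_mv * st_mask
        x = np.zeros(n)
        for r_time in r_times:
            i0 = int(round(r_time * fs)) + int(-0.25 * fs)
            j0, j1 = max(i0, 0), min(i0 + rel.size, n)
            x[j0:j1] += template[j0 - i0 : j1 - i0]
        x += config.baseline_wander_mv * np.sin(
            2.0 * np.pi * wander_freq * t + wander_phase
        )
        if config.noise_sd_mv > 0:
            x += rng.normal(0.0, config.noise_sd_mv, n)
        leads[lead] = x

    return ECGRecord(
        record_id=f"syn-{label}-{seed}",
        fs=fs,
        leads=leads,
        label=label,
        meta={"generator": "coromix.synthetic", "seed": str(seed), "hr_bpm": f"{hr:.1f}"},
    )


@dataclass(frozen=True)
class DatasetManifest:
    """Index of a generated dataset: one row per record."""

    frame: pd.DataFrame = field(repr=False)
    path: Path | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def class_counts(self) -> dict[str, int]:
        counts = self.frame["label"].value_counts()
        return {name: int(counts.get(name, 0)) for name in CLASS_NAMES}


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> DatasetManifest:
    """Write one CSV record per manifest row plus ``manifest.csv``.

    Per-record seeds are ``config.seed + running_index`` so any record can be
    regenerated in isolation.  The manifest is written last, so its presence
    marks a complete dataset.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for label, count in zip(CLASS_NAMES, config.per_class_counts):
        for _ in range(count):
            seed = config.seed + index
            record = generate_record(label, config, seed)
            record_id = f"rec{index:05d}"
            record.record_id = record_id
            path = out_dir / f"{record_id}.csv"
            write_record(record, path, format="csv")
            rows.append(
                {"record_id": record_id, "label": label, "seed": seed,
                 "path": str(path)}
            )
            index += 1
    frame = pd.DataFrame(rows, columns=["record_id", "label", "seed", "path"])
    manifest_path = out_dir / "manifest.csv"
    frame.to_csv(manifest_path, index=False)
    return DatasetManifest(frame=frame, path=manifest_path)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a ``manifest.csv`` written by :func:`generate_dataset`."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"record_id": str, "label": str, "path": str})
    return DatasetManifest(frame=frame, path=path)


# ---------------------------------------------------------------------------
# tabular benchmark for the feature-selection / ensemble stages


def make_tabular_benchmark(
    n_samples: int = 700,
    n_informative: int = 40,
    n_noise: int = 960,
    n_classes: int = 7,
    class_sep: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """7-class Gaussian features: informative columns first, then pure noise.

    Informative columns have class-dependent means drawn from
    ``N(0, class_sep^2)``; every column has unit noise variance.  Returns
    ``(X, y)`` with balanced classes (remainder spread over the first
    classes).
    """
    rng = np.random.default_rng(seed)
    per = np.full(n_classes, n_samples // n_classes)
    per[: n_samples - per.sum()] += 1
    y = np.repeat(np.arange(n_classes), per)
    means = rng.normal(0.0, class_sep, size=(n_classes, n_informative))
    p = n_informative + n_noise
    X = rng.normal(0.0, 1.0, size=(n_samples, p))
    X[:, :n_informative] += means[y]
    perm = rng.permutation(n_samples)
    return X[perm], y[perm]
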