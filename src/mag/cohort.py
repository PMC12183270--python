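"""Cohort data model, on-disk dialect and pipeline configuration.

A cohort is a set of subjects, each carrying one T×N ROI time-series matrix
per brain atlas plus site, diagnosis and covariate metadata. The on-disk form
is deliberately plain: a tab-delimited manifest (subject_id, site_id, label,
age, sex, is_synthetic) and one tab-delimited numeric file per
(subject, atlas) pair named ``<subject_id>__<atlas>.tsv`` with T rows and
n_rois columns.

Label encoding is fixed project-wide: MDD (patient) = 1 = positive class,
HC (healthy control) = 0.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MDD = 1
HC = 0

#: the paper's four parcellations, in the fixed ensemble order
DEFAULT_ATLASES = (("Dose", 160), ("AAL", 116), ("CK", 200), ("HO", 112))


@dataclass(frozen=True)
class AtlasSpec:
    """A brain parcellation: a name and its number of regions of interest."""

    name: str
    n_rois: int

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError(f"atlas {self.name!r}: n_rois must be >= 2, got {self.n_rois}")


@dataclass
class SubjectRecord:
    """One subject: per-atlas T×n_rois time series plus metadata."""

    subject_id: str
    site_id: str
    label: int  # MDD=1, HC=0
    age: float
    sex: int  # {0, 1}
    series: Dict[str, np.ndarray]
    is_synthetic: bool = False

    def t_points(self) -> int:
        return next(iter(self.series.values())).shape[0]

    def flatten(self, atlas_order: List[str]) -> np.ndarray:
        """All atlases' series concatenated into one flat vector."""
        return np.concatenate([self.series[a].ravel() for a in atlas_order])


@dataclass
class Cohort:
    atlases: List[AtlasSpec]
    subjects: List[SubjectRecord]
    t_points: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [a.name for a in self.atlases]
        if len(set(names)) != len(names):
            raise ValueError("atlas names must be unique")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        for s in self.subjects:
            for a in self.atlases:
                if a.name not in s.series:
                    raise ValueError(f"subject {s.subject_id} missing series for atlas {a.name}")
                m = s.series[a.name]
                if m.shape != (self.t_points, a.n_rois):
                    raise ValueError(
                        f"subject {s.subject_id}, atlas {a.name}: shape {m.shape} "
                        f"!= ({self.t_points}, {a.n_rois})"
                    )
                if not np.all(np.isfinite(m)):
                    raise ValueError(f"subject {s.subject_id}, atlas {a.name}: non-finite values")

    @property
    def atlas_names(self) -> List[str]:
        return [a.name for a in self.atlases]

    def real_subjects(self) -> List[SubjectRecord]:
        return [s for s in self.subjects if not s.is_synthetic]

    def by_id(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subset(self, subject_ids) -> "Cohort":
        wanted = set(subject_ids)
        subs = [s for s in self.subjects if s.subject_id in wanted]
        return Cohort(self.atlases, subs, self.t_points)


@dataclass
class PipelineConfig:
    """Hyperparameters for the full pipeline.

    Defaults follow the reference configuration: batch size 16, learning rate
    1e-3, weight decay 5e-4, dropout 0.5, three GAT layers of 64 hidden units
    with 4 attention heads, SMOTE with k=3 neighbors and doubling, stratified
    10-fold evaluation.
    """

    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    dropout_rate: float = 0.5
    n_layers: int = 3
    hidden_units: int = 64
    n_heads: int = 4
    knn_k: int = 10
    smote_k: int = 3
    smote_multiplier: int = 2
    max_epochs: int = 200
    patience: int = 20
    n_folds: int = 10
    seed: int = 0
    ensemble_method: str = "majority"  # majority | sum | weighted_sum
    harmonize: bool = True
    knn_metric: str = "abs_z"  # abs_z | euclidean
    gap_mode: str = "per_row"  # per_row | per_sample
    leaky_slope: float = 0.2
    head_combine: str = "concat"  # concat | average

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        for name in ("batch_size", "n_layers", "hidden_units", "n_heads", "knn_k",
                     "smote_k", "smote_multiplier", "max_epochs", "patience", "n_folds"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.ensemble_method not in ("majority", "sum", "weighted_sum"):
            raise ValueError(f"unknown ensemble_method {self.ensemble_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


MANIFEST_COLUMNS = ["subject_id", "site_id", "label", "age", "sex", "is_synthetic"]

_LABEL_ALIASES = {"1": 1, "0": 0, "MDD": 1, "HC": 0}


def _series_path(series_dir: Path, subject_id: str, atlas: str) -> Path:
    return Path(series_dir) / f"{subject_id}__{atlas}.tsv"


def write_cohort(cohort: Cohort, manifest_path, series_dir) -> None:
    """Write a cohort in the tab-delimited dialect (ordering: subject_id)."""
    series_dir = Path(series_dir)
    series_dir.mkdir(parents=True, exist_ok=True)
    subjects = sorted(cohort.subjects, key=lambda s: s.subject_id)
    rows = [
        {
            "subject_id": s.subject_id,
            "site_id": s.site_id,
            "label": int(s.label),
            "age": s.age,
            "sex": int(s.sex),
            "is_synthetic": int(s.is_synthetic),
        }
        for s in subjects
    ]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(manifest_path, sep="\t", index=False)
    for s in subjects:
        for a in cohort.atlases:
            np.savetxt(_series_path(series_dir, s.subject_id, a.name),
                       s.series[a.name], delimiter="\t", fmt="%.17g")


def read_cohort(manifest_path, series_dir, atlases: List[AtlasSpec] | None = None) -> Cohort:
    """Read a cohort written in the dialect of :func:`write_cohort`.

    Subjects containing any NaN entry are dropped with a warning (missing ROI
    signals exclude a subject). A declared (subject, atlas) pair without a
    file, or inconsistent T across files, is a hard error.

    If ``atlases`` is omitted, atlas names and sizes are inferred from the
    series files of the first manifest subject.
    """
    series_dir = Path(series_dir)
    df = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str, "site_id": str})
    missing_cols = set(MANIFEST_COLUMNS[:5]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    if "is_synthetic" not in df.columns:
        df["is_synthetic"] = 0

    if atlases is None:
        if df.empty:
            raise ValueError("cannot infer atlases from an empty manifest")
        sid0 = df["subject_id"].iloc[0]
        prefix = f"{sid0}__"
        names = sorted(p.stem[len(prefix):] for p in series_dir.glob(f"{prefix}*.tsv"))
        if not names:
            raise FileNotFoundError(f"no series files for subject {sid0} in {series_dir}")
        atlases = []
        for name in names:
            mat = np.loadtxt(_series_path(series_dir, sid0, name), delimiter="\t", ndmin=2)
            atlases.append(AtlasSpec(name, mat.shape[1]))

    subjects: List[SubjectRecord] = []
    t_points = None
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        series = {}
        has_nan = False
        for a in atlases:
            path = _series_path(series_dir, sid, a.name)
            if not path.exists():
                raise FileNotFoundError(f"missing series file for (subject={sid}, atlas={a.name}): {path}")
            mat = np.loadtxt(path, delimiter="\t", ndmin=2)
            if np.isnan(mat).any():
                has_nan = True
            series[a.name] = mat
        if has_nan:
            logger.warning("subject %s dropped: NaN entries in ROI time series", sid)
            continue
        t_here = {m.shape[0] for m in series.values()}
        if len(t_here) != 1:
            raise ValueError(f"subject {sid}: inconsistent T across atlases: {sorted(t_here)}")
        t = t_here.pop()
        if t_points is None:
            t_points = t
        elif t != t_points:
            raise ValueError(f"subject {sid}: T={t} differs from cohort T={t_points}")
        label_raw = str(row["label"])
        if label_raw not in _LABEL_ALIASES:
            raise ValueError(f"subject {sid}: unrecognized label {label_raw!r}")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                site_id=str(row["site_id"]),
                label=_LABEL_ALIASES[label_raw],
                age=float(row["age"]),
                sex=int(row["sex"]),
                series=series,
                is_synthetic=bool(int(row["is_synthetic"])),
            )
        )
    if t_points is None:
        t_points = 0
    return Cohort(list(atlases), subjects, t_points)
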