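"""Class-wise SMOTE on T×N time-series matrices, interpolated row by row.

Each synthetic subject is built from one real seed sample and one of its k
nearest same-class neighbors (Euclidean distance on the flattened
concatenation of all atlases' matrices, so a single neighbor serves every
atlas). For each time point t a gap ~ Uniform(0,1) is drawn and the synthetic
row is seed_row + (neighbor_row − seed_row)·gap — the same gap across all
ROIs of that row and across atlases, which preserves within-row spatial
correlation structure. Z = X0 + (X − X0)·gap, applied per row.

Synthetic records are flagged ``is_synthetic``, inherit the class label and
the seed sample's site, and receive fresh ``syn:``-prefixed ids; they are
barred from test sets downstream by that flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from ._rng import substream
from .cohort import SubjectRecord


@dataclass
class SmoteSpec:
    k_neighbors: int = 3
    multiplier: int = 2
    gap_mode: str = "per_row"  # per_row | per_sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.gap_mode not in ("per_row", "per_sample"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


def smote_class(samples: Sequence[SubjectRecord], spec: SmoteSpec,
                rng: np.random.Generator | None = None) -> List[SubjectRecord]:
    """Generate (multiplier−1)·n synthetic records for one class.

    Seed samples are visited in sorted subject_id order, cycling until the
    target count is reached; for each, one of its k nearest neighbors is
    chosen uniformly at random.
    """
    labels = {s.label for s in samples}
    if len(labels) > 1:
        raise ValueError("smote_class expects samples from a single class")
    n = len(samples)
    if n < spec.k_neighbors + 1:
        raise ValueError(
            f"class of size {n} too small for k={spec.k_neighbors} neighbors")
    if rng is None:
        rng = substream(spec.seed, "smote")

    ordered = sorted(samples, key=lambda s: s.subject_id)
    atlas_order = sorted(ordered[0].series.keys())
    flat = np.stack([s.flatten(atlas_order) for s in ordered])
    nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(flat)
    _, idx = nn.kneighbors(flat)
    # drop self if present, keep k nearest others
    neighbor_ids = np.empty((n, spec.k_neighbors), dtype=int)
    for i in range(n):
        others = [j for j in idx[i] if j != i][: spec.k_neighbors]
        neighbor_ids[i] = others

    n_synth = (spec.multiplier - 1) * n
    out: List[SubjectRecord] = []
    t_points = ordered[0].t_points()
    i = 0
    while len(out) < n_synth:
        seed_rec = ordered[i % n]
        nbr_rec = ordered[neighbor_ids[i % n][rng.integers(spec.k_neighbors)]]
        if spec.gap_mode == "per_row":
            gap = rng.uniform(0.0, 1.0, size=t_points)
        else:
            gap = np.full(t_points, rng.uniform(0.0, 1.0))
        series = {}
        for a in seed_rec.series:
            x0 = seed_rec.series[a]
            x = nbr_rec.series[a]
            series[a] = x0 + (x - x0) * gap[:, None]
        out.append(SubjectRecord(
            subject_id=f"syn:{seed_rec.subject_id}:{len(out)}",
            site_id=seed_rec.site_id,
            label=seed_rec.label,
            age=seed_rec.age,
            sex=seed_rec.sex,
            series=series,
            is_synthetic=True,
        ))
        i += 1
    return out


def oversample_split(train: Sequence[SubjectRecord], val: Sequence[SubjectRecord],
                     spec: SmoteSpec, rng: np.random.Generator | None = None,
                     ) -> Tuple[List[SubjectRecord], List[SubjectRecord]]:
    """SMOTE each class of the training and validation sets independently.

    At multiplier 2 every class count is exactly doubled; test data is never
    passed through here.
    """
    if rng is None:
        rng = substream(spec.seed, "smote")
    if spec.multiplier == 1:
        return list(train), list(val)
    out = []
    for subset in (train, val):
        classes = sorted({s.label for s in subset})
        if len(classes) < 2:
            raise ValueError("both classes must be present in each oversampled set")
        augmented = list(subset)
        for c in classes:
            members = [s for s in subset if s.label == c]
            augmented.extend(smote_class(members, spec, rng=rng))
        out.append(augmented)
    return out[0], out[1]


def validate_synthetic(real: SubjectRecord, synthetic: SubjectRecord) -> float:
    """Two-sided paired t-test over all flattened (t, roi, atlas) entries.

    Identical samples (zero-variance differences) return p = 1 by convention.
    A non-significant p indicates the synthetic sample is distributionally
    consistent with its real counterpart.
    """
    atlas_order = sorted(real.series.keys())
    a = real.flatten(atlas_order)
    b = synthetic.flatten(atlas_order)
    if a.shape != b.shape:
        raise ValueError("real and synthetic samples must share shapes")
    diff = a - b
    if np.allclose(diff.std(), 0.0):
        # constant difference: |t| unbounded unless the samples are identical
        return 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)
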