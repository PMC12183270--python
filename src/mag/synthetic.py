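"""Synthetic multi-site, two-class ROI time-series cohorts with known ground truth.

The generator emulates the statistical structure the pipeline is built to
handle: additive (γ) and multiplicative (δ) site effects applied per
(time point, ROI) feature stream, age and sex covariate effects, and a
class-dependent latent inter-ROI correlation structure. The diagnostic signal
is injected in *correlation* space — a designated subset of between-module
ROI pairs is shifted in the patient class — because the classifier consumes
functional-connectivity matrices and Pearson centering would erase any mean
shift.

Latent correlation matrices come from a block (community) model and are
repaired to the nearest symmetric positive-definite matrix after the class
perturbation, so sampling is always valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from ._rng import substream
from .cohort import MDD, HC, AtlasSpec, Cohort, SubjectRecord, DEFAULT_ATLASES


@dataclass
class SimulationSpec:
    """Study conditions for the simulated cohort.

    Defaults mirror the multi-site study setup: 16 acquisition sites, T=140
    time points, the four-atlas ensemble (Dose 160, AAL 116, CK 200, HO 112
    ROIs), site effects of the location/scale form, ages ~ Normal(34, 12)
    truncated to [18, 65] and balanced sexes.
    """

    n_sites: int = 16
    subjects_per_site_per_class: int = 25
    t_points: int = 140
    atlases: List[AtlasSpec] = field(
        default_factory=lambda: [AtlasSpec(n, r) for n, r in DEFAULT_ATLASES]
    )
    site_gamma_sd: float = 0.3
    site_delta_range: Tuple[float, float] = (0.7, 1.4)
    beta_age: float = 0.01
    beta_sex: float = 0.1
    n_modules: int = 5
    class_effect: float = 0.3
    perturbed_fraction: float = 0.2
    within_module_corr: float = 0.35
    between_module_corr: float = 0.05
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.site_delta_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"site_delta_range must be a positive interval, got {self.site_delta_range}")
        if not (0 <= self.perturbed_fraction <= 1):
            raise ValueError("perturbed_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually used — the recovery oracle for tests."""

    gamma: Dict[str, np.ndarray]  # site -> (n_features,) additive effect
    delta: Dict[str, np.ndarray]  # site -> (n_features,) multiplicative effect
    latent_corr: Dict[str, Dict[int, np.ndarray]]  # atlas -> label -> (n, n)
    perturbed_pairs: Dict[str, np.ndarray]  # atlas -> (m, 2) upper-tri indices


def nearest_spd_correlation(mat: np.ndarray, min_eig: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped from below and the result renormalized to unit
    diagonal; iterated until the smallest eigenvalue clears ``min_eig``.
    """
    a = (mat + mat.T) / 2.0
    for _ in range(100):
        w, v = np.linalg.eigh(a)
        if w.min() >= min_eig:
            break
        w = np.clip(w, min_eig, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    w = np.linalg.eigvalsh(a)
    if w.min() <= 0:
        raise ValueError("could not repair matrix to positive definite")
    return a


def _block_correlation(n_rois: int, n_modules: int, within: float, between: float) -> Tuple[np.ndarray, np.ndarray]:
    modules = np.arange(n_rois) % n_modules
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, within, between).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr, modules


def _perturbed_pairs(modules: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    iu, ju = np.triu_indices(len(modules), k=1)
    between = modules[iu] != modules[ju]
    cand = np.stack([iu[between], ju[between]], axis=1)
    m = int(round(fraction * len(cand)))
    idx = rng.choice(len(cand), size=m, replace=False)
    return cand[np.sort(idx)]


def class_correlations(spec: SimulationSpec, atlas: AtlasSpec,
                       rng: np.random.Generator) -> Tuple[Dict[int, np.ndarray], np.ndarray]:
    """HC and MDD latent correlation matrices for one atlas plus the perturbed pair set."""
    base, modules = _block_correlation(atlas.n_rois, spec.n_modules,
                                       spec.within_module_corr, spec.between_module_corr)
    pairs = _perturbed_pairs(modules, spec.perturbed_fraction, rng)
    shifted = base.copy()
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        new = base[i, j] + spec.class_effect
        if np.any(np.abs(new) >= 1):
            raise ValueError("class_effect pushes a target correlation outside (-1, 1)")
        shifted[i, j] = new
        shifted[j, i] = new
    return (
        {HC: nearest_spd_correlation(base), MDD: nearest_spd_correlation(shifted)},
        pairs,
    )


def simulate_cohort(spec: SimulationSpec) -> Tuple[Cohort, GroundTruth]:
    """Draw a cohort under ``spec``; labels are balanced per site by construction.

    For each subject and atlas, T rows are drawn from a multivariate normal
    with the class's latent correlation matrix; each (t, roi) feature stream
    is then transformed y → y·δ_site + γ_site + β_age·age + β_sex·sex + noise.
    """
    rng_struct = substream(spec.seed, "sim", "structure")
    rng_site = substream(spec.seed, "sim", "sites")
    rng_subj = substream(spec.seed, "sim", "subjects")

    latent: Dict[str, Dict[int, np.ndarray]] = {}
    chol: Dict[str, Dict[int, np.ndarray]] = {}
    perturbed: Dict[str, np.ndarray] = {}
    for atlas in spec.atlases:
        mats, pairs = class_correlations(spec, atlas, rng_struct)
        latent[atlas.name] = mats
        perturbed[atlas.name] = pairs
        chol[atlas.name] = {lab: np.linalg.cholesky(m) for lab, m in mats.items()}

    n_feat = spec.t_points * sum(a.n_rois for a in spec.atlases)
    sites = [f"site{idx:02d}" for idx in range(spec.n_sites)]
    gamma = {s: rng_site.normal(0.0, spec.site_gamma_sd, size=n_feat) for s in sites}
    lo, hi = spec.site_delta_range
    delta = {s: rng_site.uniform(lo, hi, size=n_feat) for s in sites}

    subjects: List[SubjectRecord] = []
    counter = 0
    for site in sites:
        for label in (MDD, HC):
            for _ in range(spec.subjects_per_site_per_class):
                sid = f"sub{counter:05d}"
                counter += 1
                age = float(np.clip(rng_subj.normal(34.0, 12.0), 18.0, 65.0))
                sex = int(rng_subj.integers(0, 2))
                series: Dict[str, np.ndarray] = {}
                offset = 0
                g, d = gamma[site], delta[site]
                for atlas in spec.atlases:
                    z = rng_subj.standard_normal((spec.t_points, atlas.n_rois))
                    y = z @ chol[atlas.name][label].T
                    block = slice(offset, offset + spec.t_points * atlas.n_rois)
                    gs = g[block].reshape(spec.t_points, atlas.n_rois)
                    ds = d[block].reshape(spec.t_points, atlas.n_rois)
                    y = y * ds + gs + spec.beta_age * age + spec.beta_sex * sex
                    if spec.noise_sd > 0:
                        y = y + rng_subj.normal(0.0, spec.noise_sd, size=y.shape)
                    series[atlas.name] = y
                    offset += spec.t_points * atlas.n_rois
                subjects.append(SubjectRecord(sid, site, label, age, sex, series))
    cohort = Cohort(list(spec.atlases), subjects, spec.t_points)
    truth = GroundTruth(gamma=gamma, delta=delta, latent_corr=latent, perturbed_pairs=perturbed)
    return cohort, truth


@dataclass
class SiteEffectTable:
    """Per-site feature moments and the between-site one-way F statistics."""

    sites: List[str]
    means: np.ndarray  # (n_sites, n_features)
    variances: np.ndarray  # (n_sites, n_features), ddof=1
    f_stat: np.ndarray  # (n_features,)


def empirical_site_effect(cohort: Cohort, atlas: str) -> SiteEffectTable:
    """One-way between-site ANOVA per (t, roi) feature of ``atlas``.

    A harmonization diagnostic: F ≫ 1 on many features indicates residual
    site effects.
    """
    sites = sorted({s.site_id for s in cohort.subjects})
    if len(sites) < 2:
        raise ValueError("empirical_site_effect requires at least 2 sites")
    data = {site: [] for site in sites}
    for s in cohort.subjects:
        data[s.site_id].append(s.series[atlas].ravel())
    mats = [np.asarray(data[site]) for site in sites]
    ns = np.array([m.shape[0] for m in mats])
    if np.any(ns < 2):
        raise ValueError("every site needs >= 2 subjects for variance estimates")
    means = np.stack([m.mean(axis=0) for m in mats])
    variances = np.stack([m.var(axis=0, ddof=1) for m in mats])
    n_total = ns.sum()
    grand = (ns[:, None] * means).sum(axis=0) / n_total
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ms_between = ss_between / (len(sites) - 1)
    ms_within = ((ns - 1)[:, None] * variances).sum(axis=0) / (n_total - len(sites))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_within > 0, ms_between / np.maximum(ms_within, 1e-300), np.inf)
    return SiteEffectTable(sites=sites, means=means, variances=variances, f_stat=f)
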