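"""Parametric empirical-Bayes ComBat harmonization of multi-site time series.

Each (atlas, time point, ROI) entry is treated as one feature observed across
subjects: Y = α + Xβ + γ_site + δ_site·ε, with X the (standardized age, sex)
design. Per feature, α and β are fit by least squares pooled over subjects;
residuals are standardized by the pooled SD; per-site additive (γ̂) and
multiplicative (δ̂²) effects are estimated from the standardized data and
shrunk by parametric empirical Bayes (normal prior on γ, inverse-gamma on δ²,
moment-matched hyperpriors, iterated conditional updates). Harmonized data
remove γ*, δ* and restore the covariate model, so age and sex effects are
preserved.

Zero-variance features are flagged and passed through unharmonized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .cohort import AtlasSpec, Cohort, SubjectRecord

_EB_TOL = 1e-4
_EB_MAX_ITER = 500


@dataclass
class HarmonizationModel:
    sites: List[str]
    atlas_layout: List[Tuple[str, int]]  # (atlas name, n_rois), fixes feature order
    t_points: int
    alpha_hat: np.ndarray  # (n_features,)
    beta_hat: np.ndarray  # (2, n_features): rows = (age_std, sex)
    pooled_sd: np.ndarray  # (n_features,)
    gamma_star: np.ndarray  # (n_sites, n_features)
    delta_star: np.ndarray  # (n_sites, n_features), multiplicative scale (>0)
    age_mean: float
    age_sd: float
    constant_features: np.ndarray  # bool mask of passthrough features

    def site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"site {site!r} was not seen at fit time") from None


def _design(subjects: List[SubjectRecord], age_mean: float, age_sd: float) -> np.ndarray:
    age = np.array([s.age for s in subjects], dtype=float)
    sex = np.array([s.sex for s in subjects], dtype=float)
    age_std = (age - age_mean) / (age_sd if age_sd > 0 else 1.0)
    return np.column_stack([np.ones(len(subjects)), age_std, sex])


def _data_matrix(cohort: Cohort) -> np.ndarray:
    order = cohort.atlas_names
    return np.stack([s.flatten(order) for s in cohort.subjects])


def _eb_shrink(sdata: np.ndarray, site_of: np.ndarray, sites: List[str],
               eb: bool) -> Tuple[np.ndarray, np.ndarray]:
    """γ*, δ*² per site from standardized data (rows subjects, cols features)."""
    n_feat = sdata.shape[1]
    gamma_star = np.zeros((len(sites), n_feat))
    delta2_star = np.ones((len(sites), n_feat))
    for si, _ in enumerate(sites):
        rows = sdata[site_of == si]
        n_i = rows.shape[0]
        gamma_hat = rows.mean(axis=0)
        # ddof=0 keeps the estimator internally consistent with the ddof=0
        # pooled SD: on batch-free data the site scale estimate is exactly 1.
        delta2_hat = rows.var(axis=0, ddof=0)
        if not eb:
            gamma_star[si] = gamma_hat
            delta2_star[si] = delta2_hat
            continue
        # moment-matched hyperpriors
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta2_hat.mean()
        s2 = delta2_hat.var(ddof=1)
        if tau2 <= 0 or s2 <= 0:
            gamma_star[si] = gamma_hat
            delta2_star[si] = delta2_hat
            continue
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g = gamma_hat.copy()
        d2 = delta2_hat.copy()
        sq = rows  # (n_i, n_feat)
        for _ in range(_EB_MAX_ITER):
            g_new = (n_i * tau2 * gamma_hat + d2 * gamma_bar) / (n_i * tau2 + d2)
            ssq = ((sq - g_new) ** 2).sum(axis=0)
            d2_new = (b_prior + 0.5 * ssq) / (n_i / 2.0 + a_prior - 1.0)
            change = max(np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2)))
            g, d2 = g_new, d2_new
            if change < _EB_TOL:
                break
        gamma_star[si] = g
        delta2_star[si] = d2
    return gamma_star, delta2_star


def fit_combat(cohort: Cohort, eb: bool = True) -> HarmonizationModel:
    """Fit the site-effect model on a cohort with >= 2 sites, >= 2 subjects/site.

    ``eb=False`` disables empirical-Bayes shrinkage, leaving plain per-site
    mean/variance estimates (useful as a check; harmonization is then
    location/scale per site without pooling across features).
    """
    sites = sorted({s.site_id for s in cohort.subjects})
    if len(sites) < 2:
        raise ValueError("fit_combat requires at least 2 sites")
    site_of = np.array([sites.index(s.site_id) for s in cohort.subjects])
    counts = np.bincount(site_of, minlength=len(sites))
    if counts.min() < 2:
        small = [sites[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"sites with a single subject (variance undefined): {small}")

    data = _data_matrix(cohort)
    ages = np.array([s.age for s in cohort.subjects], dtype=float)
    age_mean = float(ages.mean())
    age_sd = float(ages.std(ddof=0)) or 1.0
    design = _design(cohort.subjects, age_mean, age_sd)

    coef, *_ = np.linalg.lstsq(design, data, rcond=None)
    resid = data - design @ coef
    # pooled scale from *within-site* residuals: the between-site location
    # spread belongs to gamma, not to the standardization scale
    within = resid.copy()
    for si in range(len(sites)):
        rows = site_of == si
        within[rows] -= resid[rows].mean(axis=0)
    pooled_var = within.var(axis=0, ddof=0)
    constant = pooled_var <= 1e-300
    pooled_sd = np.sqrt(np.where(constant, 1.0, pooled_var))

    sdata = resid / pooled_sd
    gamma_star, delta2_star = _eb_shrink(sdata, site_of, sites, eb=eb)

    return HarmonizationModel(
        sites=sites,
        atlas_layout=[(a.name, a.n_rois) for a in cohort.atlases],
        t_points=cohort.t_points,
        alpha_hat=coef[0],
        beta_hat=coef[1:],
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta_star=np.sqrt(np.maximum(delta2_star, 1e-12)),
        age_mean=age_mean,
        age_sd=age_sd if age_sd > 0 else 1.0,
        constant_features=constant,
    )


def apply_combat(model: HarmonizationModel, cohort: Cohort) -> Cohort:
    """Remove fitted site effects; covariate (age, sex) effects are restored."""
    if [(a.name, a.n_rois) for a in cohort.atlases] != model.atlas_layout:
        raise ValueError("cohort atlases do not match the fitted model")
    if cohort.t_points != model.t_points:
        raise ValueError("cohort T does not match the fitted model")
    data = _data_matrix(cohort)
    design = _design(cohort.subjects, model.age_mean, model.age_sd)
    fitted = design @ np.vstack([model.alpha_hat, model.beta_hat])
    sdata = (data - fitted) / model.pooled_sd
    out = np.empty_like(data)
    for row, subject in enumerate(cohort.subjects):
        si = model.site_index(subject.site_id)
        adj = (sdata[row] - model.gamma_star[si]) / model.delta_star[si]
        out[row] = adj * model.pooled_sd + fitted[row]
    out[:, model.constant_features] = data[:, model.constant_features]

    new_subjects = []
    for row, s in enumerate(cohort.subjects):
        series = {}
        offset = 0
        for name, n_rois in model.atlas_layout:
            block = out[row, offset:offset + model.t_points * n_rois]
            series[name] = block.reshape(model.t_points, n_rois)
            offset += model.t_points * n_rois
        new_subjects.append(SubjectRecord(s.subject_id, s.site_id, s.label,
                                          s.age, s.sex, series, s.is_synthetic))
    return Cohort(list(cohort.atlases), new_subjects, cohort.t_points)


def harmonize(cohort: Cohort, eb: bool = True) -> Tuple[Cohort, HarmonizationModel]:
    """Fit and apply in one step."""
    model = fit_combat(cohort, eb=eb)
    return apply_combat(model, cohort), model
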