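import copy

import numpy as np
import pytest

from mag.cohort import AtlasSpec, Cohort
from mag.harmonization import apply_combat, fit_combat, harmonize
from mag.synthetic import SimulationSpec, empirical_site_effect, simulate_cohort
from conftest import make_subjects


def recovery_cohort(seed=7, gamma_sd=2.0):
    """3 sites × 40 subjects with strong, well-identified site effects."""
    spec = SimulationSpec(n_sites=3, subjects_per_site_per_class=20, t_points=40,
                          atlases=[AtlasSpec("A", 16)], class_effect=0.0,
                          site_gamma_sd=gamma_sd, site_delta_range=(0.6, 1.6),
                          noise_sd=0.1, seed=seed)
    return simulate_cohort(spec)


def duplicated_site_cohort():
    """One site's data duplicated under two site labels: a true null."""
    subjects = make_subjects(12, t=5, rois=(6,), seed=3, sites=("s0",))
    dup = []
    for s in subjects:
        for site in ("siteA", "siteB"):
            c = copy.deepcopy(s)
            c.subject_id = f"{s.subject_id}@{site}"
            c.site_id = site
            dup.append(c)
    return Cohort([AtlasSpec("atl0", 6)], dup, 5)


def test_duplicated_sites_give_null_effects_and_identity():
    cohort = duplicated_site_cohort()
    model = fit_combat(cohort)
    np.testing.assert_allclose(model.gamma_star, 0.0, atol=1e-10)
    np.testing.assert_allclose(model.delta_star, 1.0, atol=1e-10)
    adjusted = apply_combat(model, cohort)
    for a, b in zip(adjusted.subjects, cohort.subjects):
        assert np.max(np.abs(a.series["atl0"] - b.series["atl0"])) < 1e-6


def test_ground_truth_recovery():
    cohort, truth = recovery_cohort()
    model = fit_combat(cohort)
    g_true = np.stack([truth.gamma[s] for s in model.sites])
    g_true -= g_true.mean(axis=0)  # gamma is identifiable up to location
    g_est = model.gamma_star * model.pooled_sd
    assert np.corrcoef(g_true.ravel(), g_est.ravel())[0, 1] > 0.9
    assert np.abs(g_true - g_est).mean() < 0.1 * 2.0  # 0.1 * site_gamma_sd
    d_true = np.stack([truth.delta[s] for s in model.sites])
    d_rel = d_true / np.sqrt((d_true**2).mean(axis=0))  # delta* is pooled-relative
    assert np.corrcoef(d_rel.ravel(), model.delta_star.ravel())[0, 1] > 0.9


def test_disabled_shrinkage_equals_plain_site_moments():
    cohort, _ = recovery_cohort(seed=9)
    model = fit_combat(cohort, eb=False)
    data = np.stack([s.series["A"].ravel() for s in cohort.subjects])
    import mag.harmonization as hz
    design = hz._design(cohort.subjects, model.age_mean, model.age_sd)
    resid = data - design @ np.vstack([model.alpha_hat, model.beta_hat])
    sdata = resid / model.pooled_sd
    site_of = np.array([model.sites.index(s.site_id) for s in cohort.subjects])
    for si in range(len(model.sites)):
        rows = sdata[site_of == si]
        np.testing.assert_allclose(model.gamma_star[si], rows.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(model.delta_star[si]**2, rows.var(axis=0),
                                   rtol=1e-8)


def test_harmonization_reduces_between_site_f_by_80_percent():
    cohort, _ = recovery_cohort(seed=13, gamma_sd=0.5)
    pre = empirical_site_effect(cohort, "A").f_stat
    adjusted, _ = harmonize(cohort)
    post = empirical_site_effect(adjusted, "A").f_stat
    assert post.mean() < 0.2 * pre.mean()
    assert np.median(post) < 0.2 * np.median(pre)


def test_refit_on_harmonized_data_is_near_null():
    # a limit property: EB shrinkage residue decays with per-site n,
    # so probe it on a larger cohort with few features
    spec = SimulationSpec(n_sites=3, subjects_per_site_per_class=80, t_points=20,
                          atlases=[AtlasSpec("A", 10)], class_effect=0.0,
                          site_gamma_sd=1.0, site_delta_range=(0.7, 1.4),
                          noise_sd=0.1, seed=21)
    cohort, _ = simulate_cohort(spec)
    adjusted, _ = harmonize(cohort)
    refit = fit_combat(adjusted)
    assert np.abs(refit.gamma_star).mean() < 1e-2
    assert np.abs(refit.delta_star - 1.0).mean() < 1e-2


def test_covariate_effects_preserved():
    spec = SimulationSpec(n_sites=3, subjects_per_site_per_class=30, t_points=30,
                          atlases=[AtlasSpec("A", 10)], class_effect=0.0,
                          beta_age=0.05, beta_sex=0.5,
                          site_gamma_sd=0.8, site_delta_range=(0.7, 1.4),
                          noise_sd=0.1, seed=17)
    cohort, _ = simulate_cohort(spec)
    adjusted, _ = harmonize(cohort)

    def age_slope(c):
        ages = np.array([s.age for s in c.subjects])
        means = np.array([s.series["A"].mean() for s in c.subjects])
        return np.polyfit(ages, means, 1)[0]

    raw, adj = age_slope(cohort), age_slope(adjusted)
    assert abs(adj - raw) < 0.05 * abs(raw)


def test_twin_subjects_get_closer_after_harmonization():
    # same underlying signal observed under two different site transforms
    cohort, truth = recovery_cohort(seed=31)
    a = cohort.subjects[0]
    other = next(s for s in cohort.subjects if s.site_id != a.site_id)
    t, n = a.series["A"].shape
    g0 = truth.gamma[a.site_id].reshape(t, n)
    d0 = truth.delta[a.site_id].reshape(t, n)
    g1 = truth.gamma[other.site_id].reshape(t, n)
    d1 = truth.delta[other.site_id].reshape(t, n)
    twin = copy.deepcopy(a)
    twin.subject_id = "twin"
    twin.site_id = other.site_id
    twin.series = {"A": (a.series["A"] - g0) / d0 * d1 + g1}
    cohort.subjects.append(twin)
    adjusted, _ = harmonize(cohort)
    raw_d = np.linalg.norm(a.series["A"] - twin.series["A"])
    adj_d = np.linalg.norm(adjusted.by_id(a.subject_id).series["A"]
                           - adjusted.by_id("twin").series["A"])
    assert adj_d < raw_d


def test_error_cases():
    cohort, _ = recovery_cohort(seed=2)
    single = Cohort(cohort.atlases,
                    [s for s in cohort.subjects if s.site_id == "site00"],
                    cohort.t_points)
    with pytest.raises(ValueError, match="2 sites"):
        fit_combat(single)
    lonely = Cohort(cohort.atlases,
                    [s for s in cohort.subjects if s.site_id == "site00"]
                    + [s for s in cohort.subjects if s.site_id == "site01"][:1],
                    cohort.t_points)
    with pytest.raises(ValueError, match="single subject"):
        fit_combat(lonely)
    model = fit_combat(cohort)
    unseen = Cohort(cohort.atlases, cohort.subjects[:2], cohort.t_points)
    unseen.subjects[0].site_id = "siteXX"
    with pytest.raises(KeyError, match="siteXX"):
        apply_combat(model, unseen)
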