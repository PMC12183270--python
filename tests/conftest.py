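import numpy as np
import pytest

from mag.cohort import AtlasSpec, Cohort, SubjectRecord
from mag.synthetic import SimulationSpec, simulate_cohort


def make_subjects(n, t=6, rois=(4,), seed=0, sites=("s0", "s1"), atlas_names=None):
    """Toy subjects with random series, alternating labels across sites."""
    rng = np.random.default_rng(seed)
    atlas_names = atlas_names or [f"atl{i}" for i in range(len(rois))]
    subjects = []
    for i in range(n):
        series = {name: rng.normal(size=(t, r)) for name, r in zip(atlas_names, rois)}
        subjects.append(SubjectRecord(
            subject_id=f"sub{i:03d}", site_id=sites[i % len(sites)],
            label=i % 2, age=30.0 + i, sex=i % 2, series=series))
    return subjects


def make_cohort(n=8, t=6, rois=(4, 3), seed=0, **kw):
    subjects = make_subjects(n, t=t, rois=rois, seed=seed, **kw)
    atlases = [AtlasSpec(name, mat.shape[1])
               for name, mat in subjects[0].series.items()]
    return Cohort(atlases, subjects, t)


@pytest.fixture
def toy_cohort():
    return make_cohort()


@pytest.fixture(scope="session")
def separable_cohort():
    """Two-atlas cohort with a strong class-dependent connectivity shift."""
    spec = SimulationSpec(
        n_sites=2, subjects_per_site_per_class=15, t_points=80,
        atlases=[AtlasSpec("A", 16), AtlasSpec("B", 12)],
        class_effect=0.5, site_gamma_sd=0.3, site_delta_range=(0.8, 1.25),
        noise_sd=0.2, seed=11)
    cohort, truth = simulate_cohort(spec)
    return cohort, truth
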