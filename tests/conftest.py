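import numpy as np
import pytest

from petmbf.cohort import generate_cohort, phase_curves, render_histo_series, rest_config
from petmbf.motion import make_motion_trace
from petmbf.phantom import build_phantom


@pytest.fixture(scope="session")
def geometry():
    return build_phantom()


@pytest.fixture(scope="session")
def patient_one():
    return generate_cohort(1, rng_seed=1)[0]


@pytest.fixture(scope="session")
def rest_noiseless(geometry, patient_one):
    """Motion-free noiseless rest acquisition of one patient."""
    cfg = rest_config(rng_seed=patient_one.rest_seed)
    idif, tissue = phase_curves(geometry, patient_one.ground_truth, cfg)
    trace = make_motion_trace(cfg, "none")
    series = render_histo_series(geometry, idif, tissue, trace, cfg, noise="none")
    return {"config": cfg, "idif": idif, "tissue": tissue, "trace": trace,
            "series": series}


@pytest.fixture(scope="session")
def study_report_n20():
    """The scaled-down synthetic study: 20 patients, mixed motion, all arms.

    Session-scoped because it drives several end-to-end checks; runs once.
    """
    from petmbf.pipeline import StudyConfig, run_study

    return run_study(StudyConfig(n_patients=20, motion_profile="mixed",
                                 master_seed=0))


def small_series(volumes, voxel_size_mm=2.0):
    from petmbf.containers import HistoImageSeries

    volumes = np.asarray(volumes)
    return HistoImageSeries(volumes=volumes,
                            second_index=np.arange(volumes.shape[0]),
                            voxel_size_mm=voxel_size_mm)
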