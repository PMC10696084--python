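"""Shared fixtures: a small simulated acquisition reused across test modules.

The small configuration (64x64 matrix, 2 coils, 200 repetitions) keeps the
suite fast while exercising every stage end to end; tests that need the
full-size protocol build it themselves.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import freewave as fw

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SMALL = dict(n_pe=64, n_fe=64, n_repetitions=200, tr_ms=3.6, n_coils=2)


@pytest.fixture(scope="session")
def small_truth():
    # MCA arrives 200 ms, sinus 600 ms after the trigger: a 400 ms delay
    return fw.make_phantom(
        fw.PhantomConfig(
            n_pe=64,
            n_fe=64,
            n_coils=2,
            arrival_time_ms={"mca_l": 200.0, "sinus": 600.0},
        )
    )


@pytest.fixture(scope="session")
def small_acq():
    return fw.AcquisitionConfig(**SMALL, noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def small_pmu(small_acq):
    return fw.simulate_pmu(
        1000.0, 30.0, small_acq.total_duration_ms, small_acq.tr_ms, seed=5
    )


@pytest.fixture(scope="session")
def small_series(small_truth, small_pmu, small_acq):
    return fw.simulate_kspace(small_truth, small_pmu, small_acq)


@pytest.fixture(scope="session")
def small_gated(small_series, small_pmu):
    """Everything downstream of gating for the small acquisition."""
    series, trace, counts = fw.discard_steady_state(small_series, small_pmu, 10)
    stats = fw.detect_pmu_peaks(trace)
    assignment = fw.assign_phases(trace, stats)
    gated = fw.bin_and_average(series, assignment)
    phases = fw.reconstruct_phase_images(gated, upsample_to=128, cycle_stats=stats)
    filtered = fw.guided_filter_series(phases)
    rep = fw.reconstruct_per_repetition(series, upsample_to=128)
    mask = fw.brain_mask(rep.mean_signal_image)
    return {
        "series": series,
        "trace": trace,
        "counts": counts,
        "stats": stats,
        "assignment": assignment,
        "gated": gated,
        "phases": phases,
        "filtered": filtered,
        "rep": rep,
        "mask": mask,
    }


@pytest.fixture(scope="session")
def static_truth():
    """Zero-modulation phantom: no cardiac signal at all."""
    amps = {name: 0.0 for name in fw.phantom.COMPARTMENTS}
    return fw.make_phantom(
        fw.PhantomConfig(n_pe=64, n_fe=64, n_coils=2, modulation_amplitude=amps)
    )


def single_coil(truth):
    """Copy of a phantom with one unit-sensitivity coil."""
    from dataclasses import replace

    return replace(
        truth, coil_sensitivities=np.ones((1,) + truth.shape)
    )
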