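"""Shared fixtures: the standard phantom and one full pipeline run.

The expensive objects are session-scoped so the whole suite pays for the
phantom generation and the end-to-end segmentation only once.
"""

import numpy as np
import pytest

import pulsevessel as pv
from pulsevessel.cardiac import PhaseAssignment


@pytest.fixture(scope="session")
def phantom() -> pv.PhantomBundle:
    """The standard phantom: 32³ grid, 450 volumes, TR 0.5 s, SNR 2, seed 7."""
    return pv.generate_phantom()


@pytest.fixture(scope="session")
def pipeline_result(phantom) -> pv.PipelineResult:
    """One full segmentation run on the standard phantom, seed 1."""
    return pv.segment_vessels(
        phantom.bold,
        phantom.physio,
        phantom.brain_mask,
        phantom.general_artery_roi,
        phantom.general_sss_roi,
        config=pv.SegmentationConfig(seed=1),
    )


@pytest.fixture(scope="session")
def prepped_bold(phantom) -> pv.Bold4D:
    """The phantom BOLD after the standard trim + high-pass."""
    trimmed = pv.trim_initial_volumes(phantom.bold, 10)
    return pv.highpass_filter(trimmed)


@pytest.fixture(scope="session")
def phantom_phases(phantom, prepped_bold) -> PhaseAssignment:
    peaks = pv.detect_peaks(phantom.physio)
    return pv.assign_phase(prepped_bold.acquisition_times(), peaks)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
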