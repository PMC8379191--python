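import numpy as np
import pytest

from mamspat import segment as sg
from mamspat import stain as stn
from mamspat import synthetic as syn


@pytest.fixture(scope="session")
def young_gt():
    """Default render-scale young field (planted geometry only)."""
    return syn.generate_field(syn.SimulationConfig(seed=1), "young")


@pytest.fixture(scope="session")
def young_render(young_gt):
    """Rendered default field with its planted label maps."""
    field, labels = syn.render_field(young_gt)
    return field, labels


@pytest.fixture(scope="session")
def young_noise_free():
    """Zero-noise render used by exact colour-model checks."""
    cfg = syn.SimulationConfig(seed=1, od_noise_sd=0.0)
    gt = syn.generate_field(cfg, "young")
    field, labels = syn.render_field(gt)
    return gt, field, labels


@pytest.fixture(scope="session")
def segmented_default(young_gt, young_render):
    """Full normalise + segment products on the default field."""
    field, _ = young_render
    source = stn.estimate_stain_matrix(field.rgb)
    reference = stn.StainModel.default_hdab()
    reference.max_concentrations = source.max_concentrations.copy()
    normalized = stn.normalize_to_reference(field.rgb, source, reference)
    masks = sg.segment_field(normalized, reference)
    return masks


@pytest.fixture(scope="session")
def slide_gt():
    """Slide-scale field for count-box / TLS morphometry."""
    return syn.generate_field(syn.slide_scale_config(seed=5), "young")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
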