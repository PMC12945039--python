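import numpy as np
import pytest

from ki67quant import SlideSpec, analyze_image, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """A 400x400 px synthetic slide with 60 nuclei and its ground truth."""
    spec = SlideSpec(width_px=400, height_px=400, n_nuclei=60, seed=1)
    image, truth, roiset = generate_slide(spec)
    return spec, image, truth, roiset


@pytest.fixture(scope="session")
def small_slide_result(small_slide):
    """The analysis pipeline run on the small synthetic slide."""
    _, image, _, roiset = small_slide
    return analyze_image(image, roiset, slide_id="small")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
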