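"""Shared fixtures: small phantom configurations and rendered samples.

Everything is generated programmatically at collection time; no stored
media.  Session scope keeps rendering cost paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

import lusemble as lu
from lusemble.phantom import sample_geometry


@pytest.fixture(scope="session")
def phantom_cfg() -> lu.PhantomConfig:
    """Desk-scale phantom conditions: 64 px frames, short videos, 25 fps."""
    return lu.PhantomConfig(image_size=64, duration_range_s=(3.0, 4.0),
                            fps_choices=(25.0,))


@pytest.fixture(scope="session")
def rendered_sample(phantom_cfg):
    """One deterministic phantom with >=3 B-lines plus its geometry/meta."""
    rng = np.random.default_rng(123)
    labels = lu.LabelVector.from_positives(lu.resolve_label_set("mlS4"),
                                           ["≥3 B-lines"])
    geometry = sample_geometry(phantom_cfg, rng)
    video, meta = lu.render_video(labels, geometry, phantom_cfg, rng)
    return video, geometry, labels, meta


@pytest.fixture(scope="session")
def standardized_sample(rendered_sample):
    video, geometry, labels, _ = rendered_sample
    std, g2 = lu.standardize(lu.apply_fov_mask(video, geometry), geometry,
                             size=32)
    return std, g2, labels
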