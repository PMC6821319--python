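import numpy as np
import pytest

import myelinquant as mq


def channel(pixels, bit_depth=8, role="myelin", source_id="test"):
    """Shorthand for building a ChannelImage from a plain array."""
    return mq.ChannelImage(
        pixels=np.asarray(pixels, dtype=float),
        bit_depth=bit_depth,
        channel_role=role,
        source_id=source_id,
    )


@pytest.fixture
def default_settings():
    return mq.default_settings()


@pytest.fixture
def phantom():
    """One default phantom field with ground truth (fixed seed)."""
    return mq.generate_field(mq.PhantomParams(seed=0))


@pytest.fixture
def small_phantom():
    """A fast 96x96 phantom for pipeline-level tests."""
    params = mq.PhantomParams(
        width=96, height=96, n_neurites=4, n_sheaths=3, n_cellbodies=1, seed=7
    )
    return mq.generate_field(params)
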