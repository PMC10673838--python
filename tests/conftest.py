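from __future__ import annotations

import numpy as np
import pytest

from scarscope.junctionscan import JunctionTemplate


@pytest.fixture
def mh_template() -> JunctionTemplate:
    """Product 'TTTGGATCGATCCAAA' with j=8: a 4-bp GATC repeat flanks the
    junction, so junction-spanning deletions show microhomology."""
    return JunctionTemplate("TTTGGATC", "GATCCAAA", 8, 0)


@pytest.fixture
def long_template() -> JunctionTemplate:
    """120-bp product with generous anchors for generator round trips."""
    rng = np.random.default_rng(20240917)
    a = "".join(rng.choice(list("ACGT"), size=60))
    b = "".join(rng.choice(list("ACGT"), size=60))
    return JunctionTemplate(a, b, 60, 0)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
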