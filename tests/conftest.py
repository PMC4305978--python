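import numpy as np
import pytest

from ihcaudit.marks import Label, Mark, MarkSet, Role


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_markset(rng, n, width=1000, height=1000, role=Role.DD,
                   spot_id="spot", p_pos=0.3):
    """Random marks with unique coordinates (helper shared by tests)."""
    coords = set()
    while len(coords) < n:
        coords.add((int(rng.integers(0, width)), int(rng.integers(0, height))))
    marks = [Mark(x, y, Label.POSITIVE if rng.random() < p_pos else Label.NEGATIVE)
             for x, y in sorted(coords)]
    return MarkSet(spot_id, role, marks)
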