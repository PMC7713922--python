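import numpy as np
import pandas as pd
import pytest

from hostnet.datamodel import LINK_COLUMNS, LinkTable


def make_links(rows):
    """Rows of (site, tree, hsp, hgen, hfam, insect, stage, count)."""
    return LinkTable(pd.DataFrame(rows, columns=list(LINK_COLUMNS)))


@pytest.fixture
def tiny_links():
    """Two insect species over three trees in two host taxa."""
    return make_links(
        [
            ("P", "T1", "hsA", "hgA", "hfA", "i1", "adult_female", 3),
            ("P", "T2", "hsA", "hgA", "hfA", "i1", "second_instar", 1),
            ("P", "T3", "hsB", "hgB", "hfB", "i1", "adult_female", 2),
            ("P", "T1", "hsA", "hgA", "hfA", "i2", "adult_female", 1),
            ("P", "T3", "hsB", "hgB", "hfB", "i2", "first_instar", 4),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
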