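import numpy as np
import pandas as pd
import pytest

from hybridscan.codes import assign_split_codes

INGROUP = ("rerio", "kyathit", "aesculapii", "nigrofasciatus")


def build_sites(rows, ingroup=INGROUP):
    """Hand-built polarized-site table from (chrom, pos, four states) rows."""
    chrom = [r[0] for r in rows]
    pos = [r[1] for r in rows]
    states = np.array([r[2] for r in rows], dtype=np.int8)
    df = pd.DataFrame({"chrom": chrom, "pos": pos})
    for i, t in enumerate(ingroup):
        df[t] = states[:, i]
    df["split"] = assign_split_codes(states, ingroup)
    return df


@pytest.fixture
def ingroup():
    return INGROUP


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
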