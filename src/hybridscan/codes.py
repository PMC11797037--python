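"""Split-code vocabulary for polarized site patterns.

A polarized biallelic site assigns each ingroup taxon an ancestral (A) or
derived (B) state, judged against basal outgroups.  The *split code* of a
site names which subset of the four focal ingroup taxa carries the derived
allele.  Sites where exactly two taxa are derived ("pairwise splits") carry
most of the phylogenetic signal used downstream; singleton, triple and
other configurations are labelled but generally ignored by the windowed
analyses.

States are encoded as small integers: 0 = ancestral, 1 = derived,
-1 = missing.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

STATE_ANCESTRAL = 0
STATE_DERIVED = 1
STATE_MISSING = -1

TRIPLE = "triple"
OTHER = "other"


def pair_code(t1: str, t2: str, ingroup: Sequence[str]) -> str:
    """Canonical code for the unordered pair {t1, t2}, ordered by ingroup rank."""
    order = {t: i for i, t in enumerate(ingroup)}
    if t1 not in order or t2 not in order:
        raise ValueError(f"taxa {t1!r}/{t2!r} not in ingroup {list(ingroup)}")
    if t1 == t2:
        raise ValueError("pair code requires two distinct taxa")
    a, b = sorted((t1, t2), key=order.__getitem__)
    return f"{a}+{b}"


def pair_codes(ingroup: Sequence[str]) -> list[str]:
    """The six pairwise split codes in canonical (combination) order."""
    if len(ingroup) != 4 or len(set(ingroup)) != 4:
        raise ValueError("ingroup must be 4 unique taxa")
    return [f"{a}+{b}" for a, b in combinations(ingroup, 2)]


def singleton_code(taxon: str) -> str:
    return f"single:{taxon}"


def assign_split_codes(states: np.ndarray, ingroup: Sequence[str]) -> np.ndarray:
    """Vectorised split-code assignment for an (n_sites, 4) state matrix.

    Pair, singleton and triple codes require all four ingroup calls to be
    non-missing; any missing call demotes the site to ``other`` so that
    windowed proportions stay comparable across windows.
    """
    states = np.asarray(states)
    if states.ndim != 2 or states.shape[1] != 4:
        raise ValueError("states must be (n_sites, 4)")
    n = states.shape[0]
    out = np.full(n, OTHER, dtype=object)
    complete = (states != STATE_MISSING).all(axis=1)
    derived = states == STATE_DERIVED
    n_b = derived.sum(axis=1)
    # bitmask over the 4 ingroup columns identifies the derived subset
    mask = (derived.astype(np.int8) * (1 << np.arange(4, dtype=np.int8))).sum(axis=1)

    lut = np.full(16, OTHER, dtype=object)
    for i, t in enumerate(ingroup):
        lut[1 << i] = singleton_code(t)
    for i, j in combinations(range(4), 2):
        lut[(1 << i) | (1 << j)] = pair_code(ingroup[i], ingroup[j], ingroup)
    for trip in combinations(range(4), 3):
        lut[sum(1 << i for i in trip)] = TRIPLE

    valid = complete & (n_b >= 1) & (n_b <= 3)
    out[valid] = lut[mask[valid]]
    return out


def is_pair_code(codes: np.ndarray | Sequence[str], ingroup: Sequence[str]) -> np.ndarray:
    pc = set(pair_codes(ingroup))
    return np.asarray([c in pc for c in codes], dtype=bool)
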