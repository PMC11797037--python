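"""Sliding-window analysis of the six pairwise splits and binomial enrichment.

With four focal ingroup taxa there are six unordered species pairs; if all
four taxa were equally related, each pairwise split would appear at
frequency 1/6 (~16.7%).  Windows of a fixed number of pairwise-split sites
(default 500, stepping by 10 sites) are scored for enrichment of each code
by an exact upper-tail binomial test against p = 1/6, and consecutive
windows sharing an identical enriched-code set are merged into regions.
Fixed-count windows (rather than fixed-bp) keep the binomial trial count
constant so one critical count applies genome wide.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .codes import pair_codes

logger = logging.getLogger(__name__)

__all__ = [
    "split_windows",
    "enrichment_call",
    "critical_count",
    "region_segmentation",
    "window_majority",
]


def critical_count(window_n: int, alpha: float, p: float = 1.0 / 6.0) -> int:
    """Smallest count k with P(X >= k | Binomial(window_n, p)) <= alpha."""
    # sf(k-1) = P(X >= k); isf gives the smallest k-1 with sf <= alpha
    k = int(binom.isf(alpha, window_n, p)) + 1
    while k > 0 and binom.sf(k - 2, window_n, p) <= alpha:
        k -= 1
    return k


def enrichment_call(
    counts: Sequence[int] | np.ndarray,
    window_n: int,
    alpha: float = 0.001,
    p: float = 1.0 / 6.0,
    bonferroni: bool = False,
) -> np.ndarray:
    """Boolean enrichment flags for per-code counts in one or many windows.

    A code is enriched iff the exact upper-tail binomial probability
    P(X >= count | n = window_n, p) is <= alpha (optionally Bonferroni-
    corrected across the 6 codes).  Accepts a 1-D (one window) or 2-D
    (windows x codes) count array.
    """
    a = alpha / 6.0 if bonferroni else alpha
    c = np.asarray(counts)
    tail = binom.sf(c - 1, window_n, p)
    return tail <= a


def split_windows(
    sites: pd.DataFrame,
    ingroup: Sequence[str],
    window_n: int = 500,
    step: int = 10,
    alpha: float = 0.001,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Sliding windows of ``window_n`` pairwise-split sites advancing by
    ``step`` sites, per chromosome.

    Tail windows with fewer than ``window_n`` sites are dropped (and logged)
    rather than shrunk, keeping the binomial trial count constant; a
    chromosome with fewer than ``window_n`` pairwise splits contributes no
    windows.  Output: one row per window with chrom, window index, start/end
    bp, per-code counts (``n_<code>``) and proportions (``p_<code>``),
    per-code enrichment flags (``enr_<code>``), majority code and tie flag.
    """
    if window_n < 1 or step < 1:
        raise ValueError("window_n and step must be >= 1")
    codes = pair_codes(ingroup)
    sub = sites[sites["split"].isin(codes)]
    frames = []
    n_skipped_chroms = 0
    for chrom, grp in sub.groupby("chrom", sort=False, observed=True):
        pos = grp["pos"].to_numpy()
        m = len(pos)
        if m < window_n:
            n_skipped_chroms += 1
            logger.info("chromosome %s has %d pairwise splits (< %d): no windows", chrom, m, window_n)
            continue
        code_idx = pd.Categorical(grp["split"], categories=codes).codes
        onehot = np.zeros((m + 1, len(codes)), dtype=np.int64)
        onehot[1:][np.arange(m), code_idx] = 1
        cs = np.cumsum(onehot, axis=0)
        offsets = np.arange(0, m - window_n + 1, step)
        counts = cs[offsets + window_n] - cs[offsets]  # (n_windows, 6)
        props = counts / window_n
        enr = enrichment_call(counts, window_n, alpha=alpha, bonferroni=bonferroni)
        maj = counts.argmax(axis=1)
        tie = (counts == counts.max(axis=1, keepdims=True)).sum(axis=1) > 1
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "window": np.arange(len(offsets)),
                "start_pos": pos[offsets],
                "end_pos": pos[offsets + window_n - 1],
            }
        )
        for j, c in enumerate(codes):
            frame[f"n_{c}"] = counts[:, j]
        for j, c in enumerate(codes):
            frame[f"p_{c}"] = props[:, j]
        for j, c in enumerate(codes):
            frame[f"enr_{c}"] = enr[:, j]
        frame["majority"] = np.array(codes, dtype=object)[maj]
        frame["majority_tie"] = tie
        frames.append(frame)
    if not frames:
        cols = ["chrom", "window", "start_pos", "end_pos"]
        cols += [f"n_{c}" for c in codes] + [f"p_{c}" for c in codes]
        cols += [f"enr_{c}" for c in codes] + ["majority", "majority_tie"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def region_segmentation(
    windows: pd.DataFrame,
    ingroup: Sequence[str],
    min_windows: int = 10,
) -> pd.DataFrame:
    """Merge consecutive windows with identical enriched-code sets into
    regions; runs shorter than ``min_windows`` are demoted to unenriched.

    Output: chrom, start_pos, end_pos, codes (comma-joined, "" when none),
    n_windows.  Adjacent regions with equal code sets (after demotion) are
    merged.
    """
    codes = pair_codes(ingroup)
    enr_cols = [f"enr_{c}" for c in codes]
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("window")
        enr = grp[enr_cols].to_numpy(dtype=bool)
        keys = [frozenset(c for c, f in zip(codes, flags) if f) for flags in enr]
        start = grp["start_pos"].to_numpy()
        end = grp["end_pos"].to_numpy()
        # first pass: maximal runs of identical enriched sets
        runs = []
        i = 0
        while i < len(keys):
            j = i
            while j + 1 < len(keys) and keys[j + 1] == keys[i]:
                j += 1
            runs.append((i, j, keys[i]))
            i = j + 1
        # demote short enriched runs, then merge adjacent equal sets
        demoted = [
            (i, j, key if (j - i + 1 >= min_windows or not key) else frozenset())
            for i, j, key in runs
        ]
        merged: list[list] = []
        for i, j, key in demoted:
            if merged and merged[-1][2] == key:
                merged[-1][1] = j
            else:
                merged.append([i, j, key])
        for i, j, key in merged:
            rows.append(
                {
                    "chrom": chrom,
                    "start_pos": int(start[i]),
                    "end_pos": int(end[j]),
                    "codes": ",".join(sorted(key, key=codes.index)),
                    "n_windows": int(j - i + 1),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos", "codes", "n_windows"])


def window_majority(
    windows: pd.DataFrame, ingroup: Sequence[str]
) -> tuple[pd.Series, dict[str, int]]:
    """Per-window majority code (ties broken by canonical code order, flagged
    upstream in ``split_windows``) and the genome-wide tally."""
    tally = windows["majority"].value_counts().to_dict()
    for c in pair_codes(ingroup):
        tally.setdefault(c, 0)
    return windows["majority"], tally
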