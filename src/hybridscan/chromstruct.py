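"""Chromosome-structure machinery: folded coordinates, jackknife bins,
position profiles and hybrid-ancestry estimation.

Recombination in many fish genomes (zebrafish included) is concentrated near
chromosome ends, so phylogenetic signal is organised by distance to the
nearest telomere rather than by absolute position.  The *folded coordinate*
collapses the two chromosome arms onto [0, 1], with 0 at a telomere and 1 at
the chromosome midpoint.  All positional aggregation here (equal-count
jackknife partitions, folded bins, smoothed split-proportion profiles, and
the per-bin hybrid-ancestry estimator) is built on that coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .codes import pair_code, pair_codes

__all__ = [
    "fold",
    "jackknife_partition",
    "folded_profile",
    "ancestry_by_bin",
    "AncestryBins",
    "interval_jaccard",
]


def fold(position, chrom_length):
    """Fold a 1-based position onto [0, 1]: 0 = nearest telomere, 1 = midpoint.

    r = min(position - 1, chrom_length - position) / (chrom_length / 2),
    clamped to [0, 1].  Symmetric: fold(p, L) == fold(L - p + 1, L).
    Accepts scalars or arrays.
    """
    pos = np.asarray(position)
    L = np.asarray(chrom_length)
    if np.any((pos < 1) | (pos > L)):
        raise ValueError("position out of range [1, chrom_length]")
    r = np.minimum(pos - 1, L - pos) / (L / 2.0)
    r = np.clip(r, 0.0, 1.0)
    if np.isscalar(position) or (isinstance(pos, np.ndarray) and pos.ndim == 0):
        return float(r)
    return r


def _per_chrom_bin_sizes(n: int, n_bins: int) -> np.ndarray:
    """Equal-count partition sizes; the remainder goes to the leftmost bins."""
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    return sizes


def jackknife_partition(sites: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Partition each chromosome into ``n_bins`` contiguous runs of equal site
    counts (the leftmost bins absorb any remainder).

    With the 25-chromosome zebrafish-like map and the default of 10 bins this
    yields the 250 genome windows used for jackknife subsampling.  Returns one
    row per partition: chrom, bin (1-based), start_pos, end_pos, n_sites.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False, observed=True):
        pos = np.asarray(grp["pos"])
        if not np.all(np.diff(pos) >= 0):
            raise ValueError(f"sites on {chrom} are not position-sorted")
        n = len(pos)
        if n < n_bins:
            raise ValueError(
                f"chromosome {chrom} has {n} sites; needs >= {n_bins} to partition"
            )
        sizes = _per_chrom_bin_sizes(n, n_bins)
        edges = np.concatenate([[0], np.cumsum(sizes)])
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            rows.append(
                {
                    "chrom": chrom,
                    "bin": b + 1,
                    "start_pos": int(pos[lo]),
                    "end_pos": int(pos[hi - 1]),
                    "n_sites": int(hi - lo),
                }
            )
    return pd.DataFrame(rows)


def _folded_bin_index(r: np.ndarray, n_bins: int) -> np.ndarray:
    """Bins tile [0, 1]; bin i covers [i/n, (i+1)/n), last bin closed at 1."""
    idx = np.minimum((r * n_bins).astype(int), n_bins - 1)
    return idx


def folded_profile(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    ingroup: Sequence[str],
    n_bins: int = 10,
    smooth_points: int = 101,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool pairwise-split proportions into folded-coordinate bins across all
    chromosomes, plus a smoothed profile.

    Returns ``(bins, smooth)``.  ``bins`` has one row per folded bin with the
    bin range, per-code counts and proportions, and n_sites; empty bins are
    kept with NaN proportions.  ``smooth`` evaluates a monotone-preserving
    (PCHIP) interpolant of the binned proportions on a regular grid of
    ``smooth_points`` folded coordinates; bins with no data are excluded from
    the fit rather than interpolated silently.
    """
    codes = pair_codes(ingroup)
    sub = sites[sites["split"].isin(codes)]
    L = sub["chrom"].map(chrom_lengths).to_numpy(dtype=float)
    r = fold(sub["pos"].to_numpy(), L)
    bidx = _folded_bin_index(np.asarray(r), n_bins)

    counts = np.zeros((n_bins, len(codes)), dtype=int)
    code_idx = pd.Categorical(sub["split"], categories=codes).codes
    np.add.at(counts, (bidx, code_idx), 1)

    n_sites = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(n_sites[:, None] > 0, counts / np.maximum(n_sites, 1)[:, None], np.nan)

    bins = pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "r_low": np.arange(n_bins) / n_bins,
            "r_high": np.arange(1, n_bins + 1) / n_bins,
            "n_sites": n_sites,
        }
    )
    for j, c in enumerate(codes):
        bins[f"n_{c}"] = counts[:, j]
        bins[f"p_{c}"] = props[:, j]

    grid = np.linspace(0.0, 1.0, smooth_points)
    smooth = pd.DataFrame({"r": grid})
    mids = (bins["r_low"].to_numpy() + bins["r_high"].to_numpy()) / 2
    ok = n_sites > 0
    for j, c in enumerate(codes):
        if ok.sum() >= 2:
            f = PchipInterpolator(mids[ok], props[ok, j], extrapolate=True)
            smooth[f"p_{c}"] = f(grid)
        else:
            smooth[f"p_{c}"] = np.nan
    return bins, smooth


@dataclass(frozen=True)
class AncestryBins:
    """Per-folded-bin hybrid ancestry estimates.

    gamma_hat is the estimated fraction of the hybrid genome drawn from the
    parent1 lineage; z is an excess-over-ILS score for the weaker parental
    signal (see ``ancestry_by_bin``).
    """

    table: pd.DataFrame
    hybrid: str
    parent1: str
    parent2: str


def ancestry_by_bin(
    sites: pd.DataFrame,
    hybrid: str,
    parent1: str,
    parent2: str,
    chrom_lengths: Mapping[str, int],
    ingroup: Sequence[str],
    n_bins: int = 10,
) -> AncestryBins:
    """Estimate per-bin hybrid ancestry from pairwise-split counts.

    For each folded bin let c1 = #(hybrid,parent1) splits, c2 =
    #(hybrid,parent2) splits and c0 = #(parent1,parent2) splits.  Under
    balanced incomplete lineage sorting the two minor pairings of a triplet
    are equally frequent, so c0 estimates the ILS background common to c1 and
    c2; the excesses c1 - c0 and c2 - c0 measure genuine shared ancestry.
    The ancestry fraction attributable to parent1 is

        gamma_hat = (c1 - c0) / ((c1 - c0) + (c2 - c0)),  clipped to [0, 1].

    This count-ratio estimator is this package's own replacement for
    likelihood-based hybrid detection (e.g. HyDe); it is unbiased under the
    reduced coalescent model used by the simulator but is NOT numerically
    interchangeable with HyDe's gamma on real data.

    The hybridization z-score asks whether even the weaker parental pairing
    exceeds the ILS background: conditional on N = min(c1, c2) + c0 draws,
    both codes are equally likely under pure ILS, so
    z = (min(c1,c2) - N/2) / sqrt(N/4).  Large positive z in a bin means both
    parents share a derived-allele excess with the hybrid there, the HHS
    signature.
    """
    if len({hybrid, parent1, parent2}) != 3:
        raise ValueError("hybrid and parents must be three distinct taxa")
    c1_code = pair_code(hybrid, parent1, ingroup)
    c2_code = pair_code(hybrid, parent2, ingroup)
    c0_code = pair_code(parent1, parent2, ingroup)

    sub = sites[sites["split"].isin([c1_code, c2_code, c0_code])]
    L = sub["chrom"].map(chrom_lengths).to_numpy(dtype=float)
    r = fold(sub["pos"].to_numpy(), L)
    bidx = _folded_bin_index(np.asarray(r), n_bins)

    counts = np.zeros((n_bins, 3), dtype=int)
    code_idx = pd.Categorical(sub["split"], categories=[c1_code, c2_code, c0_code]).codes
    np.add.at(counts, (bidx, code_idx), 1)
    c1, c2, c0 = counts[:, 0].astype(float), counts[:, 1].astype(float), counts[:, 2].astype(float)

    e1 = c1 - c0
    e2 = c2 - c0
    denom = e1 + e2
    gamma = np.full(n_bins, np.nan)
    ok = denom > 0
    gamma[ok] = np.clip(e1[ok] / denom[ok], 0.0, 1.0)

    cmin = np.minimum(c1, c2)
    ntrial = cmin + c0
    z = np.full(n_bins, np.nan)
    okz = ntrial > 0
    z[okz] = (cmin[okz] - ntrial[okz] / 2.0) / np.sqrt(ntrial[okz] / 4.0)
    p = np.full(n_bins, np.nan)
    p[okz] = norm.sf(z[okz])

    table = pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "r_low": np.arange(n_bins) / n_bins,
            "r_high": np.arange(1, n_bins + 1) / n_bins,
            "n_hybrid_parent1": counts[:, 0],
            "n_hybrid_parent2": counts[:, 1],
            "n_parents": counts[:, 2],
            "gamma_hat": gamma,
            "gamma_defined": ok,
            "z_hybridization": z,
            "p_hybridization": p,
        }
    )
    return AncestryBins(table=table, hybrid=hybrid, parent1=parent1, parent2=parent2)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals if b >= a)
    out: list[tuple[int, int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def interval_jaccard(
    a: Mapping[str, Iterable[tuple[int, int]]],
    b: Mapping[str, Iterable[tuple[int, int]]],
) -> float:
    """Jaccard index (bp of intersection / bp of union) of two interval sets
    keyed by chromosome; intervals are 1-based inclusive."""
    inter = 0
    union = 0
    chroms = set(a) | set(b)
    for c in chroms:
        ia = _merge_intervals(a.get(c, []))
        ib = _merge_intervals(b.get(c, []))
        la = sum(e - s + 1 for s, e in ia)
        lb = sum(e - s + 1 for s, e in ib)
        ov = 0
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e >= s:
                ov += e - s + 1
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        inter += ov
        union += la + lb - ov
    return inter / union if union else float("nan")
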