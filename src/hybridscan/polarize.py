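"""Read genotypes, filter, and polarize sites against basal outgroups.

Polarization converts biallelic genotypes (A/C/G/T) into ancestral (A) vs
derived (B) states: the ancestral allele is the one carried by *all*
non-missing outgroup taxa, sites where outgroups disagree are removed (they
may reflect gene flow involving the outgroup), and only variable sites — at
least one ingroup taxon derived — are kept.  The result is the shared-
derived-character table every downstream scan consumes.

Genotypes here are haploid-style consensus calls (one allele per taxon),
matching a single-individual-per-species design.  Heterozygous diploid
records, if encountered, are resolved by a configurable rule (default:
treated as missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .codes import STATE_MISSING, assign_split_codes

logger = logging.getLogger(__name__)

__all__ = [
    "TaxaConfig",
    "PolarizeResult",
    "read_vcf",
    "polarize_sites",
    "apply_site_filters",
    "sdc_sharing",
    "SdcSharing",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class TaxaConfig:
    """Taxon roles: ordered 4-taxon ingroup plus >= 1 polarizing outgroup."""

    ingroup: tuple[str, str, str, str]
    outgroups: tuple[str, ...]

    def __post_init__(self):
        if len(self.ingroup) != 4 or len(set(self.ingroup)) != 4:
            raise ValueError("ingroup must be 4 unique taxa")
        if not self.outgroups:
            raise ValueError("at least one outgroup is required")
        if set(self.ingroup) & set(self.outgroups):
            raise ValueError("ingroup and outgroup roles must be disjoint")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.ingroup) + tuple(self.outgroups)


def _call_to_allele(gt: tuple, het_rule: str) -> int:
    """Collapse a GT tuple to a haploid allele index (0 ref / 1 alt / -1 missing)."""
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return STATE_MISSING
    if len(set(alleles)) == 1:
        return int(alleles[0])
    if het_rule == "missing":
        return STATE_MISSING
    if het_rule == "ref":
        return 0
    if het_rule == "alt":
        return 1
    raise ValueError(f"unknown heterozygote rule {het_rule!r}")


def read_vcf(path: str, taxa: TaxaConfig, het_rule: str = "missing") -> pd.DataFrame:
    """Load a VCF into a genotype table restricted to biallelic SNVs.

    Returns a DataFrame with columns chrom, pos, ref, alt, one allele-index
    column per configured taxon (0 ref / 1 alt / -1 missing) and, when the
    VCF carries per-sample DP, one ``<taxon>_dp`` column per taxon.  Contig
    lengths from the header are stored in ``.attrs["contig_lengths"]`` and
    drop counters in ``.attrs["filter_counts"]``.  Multi-allelic records and
    indels are dropped and counted.  A configured taxon absent from the VCF
    header is a hard error.
    """
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    missing = [t for t in taxa.taxa if t not in samples]
    if missing:
        raise ValueError(f"taxa absent from VCF header: {missing}")

    contig_lengths = {
        name: rec.length for name, rec in vcf.header.contigs.items() if rec.length
    }

    rows_chrom: list[str] = []
    rows_pos: list[int] = []
    rows_ref: list[str] = []
    rows_alt: list[str] = []
    alleles: dict[str, list[int]] = {t: [] for t in taxa.taxa}
    depths: dict[str, list[int]] = {t: [] for t in taxa.taxa}
    any_depth = False
    n_multi = 0
    n_indel = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        ref, alt = rec.ref.upper(), alts[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _ACGT or alt not in _ACGT:
            n_indel += 1
            continue
        rows_chrom.append(rec.contig)
        rows_pos.append(rec.pos)
        rows_ref.append(ref)
        rows_alt.append(alt)
        for t in taxa.taxa:
            s = rec.samples[t]
            alleles[t].append(_call_to_allele(s.get("GT", (None,)), het_rule))
            dp = s.get("DP")
            if dp is not None:
                any_depth = True
                depths[t].append(int(dp))
            else:
                depths[t].append(-1)
    vcf.close()

    df = pd.DataFrame({"chrom": rows_chrom, "pos": rows_pos, "ref": rows_ref, "alt": rows_alt})
    for t in taxa.taxa:
        df[t] = np.asarray(alleles[t], dtype=np.int8)
    if any_depth:
        for t in taxa.taxa:
            df[f"{t}_dp"] = np.asarray(depths[t], dtype=np.int32)
    df.attrs["contig_lengths"] = contig_lengths
    df.attrs["filter_counts"] = {"multiallelic": n_multi, "non_snv": n_indel}
    if n_multi or n_indel:
        logger.info("read_vcf dropped %d multi-allelic and %d non-SNV records", n_multi, n_indel)
    return df


@dataclass
class PolarizeResult:
    """Polarized sites plus per-rule removal counters.

    Count identity: input rows == len(sites) + sum(removed.values()).
    """

    sites: pd.DataFrame
    removed: dict[str, int] = field(default_factory=dict)


def polarize_sites(
    genotypes: pd.DataFrame,
    ingroup: Sequence[str],
    outgroups: Sequence[str],
) -> PolarizeResult:
    """Polarize a genotype table against the outgroups and assign split codes.

    The ancestral allele at a site is the allele shared by all non-missing
    outgroup taxa.  Removed (and counted): sites where all outgroups are
    missing ("outgroup_missing"), where outgroups disagree
    ("outgroup_polymorphic"), and where no ingroup taxon carries the derived
    allele ("invariant").  Output columns: chrom, pos, one int8 state column
    per ingroup taxon (0 = A, 1 = B, -1 = missing), split, anc_base,
    der_base.
    """
    ingroup = tuple(ingroup)
    outgroups = tuple(outgroups)
    og = genotypes[list(outgroups)].to_numpy(dtype=np.int8)
    og_missing = og == STATE_MISSING
    all_missing = og_missing.all(axis=1)
    og_masked = np.where(og_missing, np.int8(-9), og)
    og_min = np.where(og_missing, np.int8(9), og).min(axis=1)
    og_max = og_masked.max(axis=1)
    polymorphic = (~all_missing) & (og_min != og_max)

    keep = ~(all_missing | polymorphic)
    anc_allele = np.where(og_max == 1, np.int8(1), np.int8(0))  # valid where keep

    ing = genotypes[list(ingroup)].to_numpy(dtype=np.int8)
    states = np.where(
        ing == STATE_MISSING,
        np.int8(STATE_MISSING),
        (ing != anc_allele[:, None]).astype(np.int8),
    )
    has_derived = (states == 1).any(axis=1)
    invariant = keep & ~has_derived
    final = keep & has_derived

    removed = {
        "outgroup_missing": int(all_missing.sum()),
        "outgroup_polymorphic": int(polymorphic.sum()),
        "invariant": int(invariant.sum()),
    }
    if any(removed.values()):
        logger.info("polarize_sites removals: %s", removed)

    sub = genotypes.loc[final]
    st = states[final]
    anc = anc_allele[final]
    out = pd.DataFrame({"chrom": sub["chrom"].to_numpy(), "pos": sub["pos"].to_numpy()})
    for i, t in enumerate(ingroup):
        out[t] = st[:, i]
    out["split"] = assign_split_codes(st, ingroup)
    ref = sub["ref"].to_numpy()
    alt = sub["alt"].to_numpy()
    out["anc_base"] = np.where(anc == 0, ref, alt)
    out["der_base"] = np.where(anc == 0, alt, ref)
    out.reset_index(drop=True, inplace=True)
    return PolarizeResult(sites=out, removed=removed)


def apply_site_filters(
    genotypes: pd.DataFrame,
    taxa: Sequence[str],
    min_depth: int = 5,
    snp_cluster_window: int = 10,
    snp_cluster_count: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Depth and SNP-cluster site filters.

    A site fails depth if any listed taxon has depth < ``min_depth``.  A site
    is part of a SNP cluster if some stretch of ``snp_cluster_count``
    consecutive variant sites containing it spans at most
    ``snp_cluster_window`` bp (inclusive); all member sites of such a run are
    removed.  Defaults mirror a 5x-coverage, 3-SNPs-in-10-bp rule.
    """
    n0 = len(genotypes)
    if min_depth > 0:
        dp_cols = [f"{t}_dp" for t in taxa]
        absent = [c for c in dp_cols if c not in genotypes.columns]
        if absent:
            raise ValueError(f"min_depth > 0 but depth columns missing: {absent}")
        dp = genotypes[dp_cols].to_numpy()
        depth_ok = (dp >= min_depth).all(axis=1)
    else:
        depth_ok = np.ones(n0, dtype=bool)
    kept = genotypes.loc[depth_ok].reset_index(drop=True)
    n_depth = int(n0 - depth_ok.sum())

    cluster_bad = np.zeros(len(kept), dtype=bool)
    if snp_cluster_count > 0 and len(kept):
        for _, grp in kept.groupby("chrom", sort=False, observed=True):
            ipos = grp.index.to_numpy()
            order = np.argsort(grp["pos"].to_numpy(), kind="stable")
            pos = grp["pos"].to_numpy()[order]
            m = len(pos)
            k = snp_cluster_count
            if m >= k:
                span = pos[k - 1 :] - pos[: m - k + 1]
                starts = np.nonzero(span <= snp_cluster_window - 1)[0]
                bad = np.zeros(m, dtype=bool)
                for s in starts:
                    bad[s : s + k] = True
                cluster_bad[ipos[order[bad]]] = True
    out = kept.loc[~cluster_bad].reset_index(drop=True)
    counters = {"low_depth": n_depth, "snp_cluster": int(cluster_bad.sum())}
    if any(counters.values()):
        logger.info("apply_site_filters removals: %s", counters)
    return out, counters


@dataclass(frozen=True)
class SdcSharing:
    n_overlap: int
    fraction_fixed_derived: float | None


def sdc_sharing(
    reference_sdc_sites: pd.DataFrame,
    panel_genotypes: pd.DataFrame,
    samples: Sequence[str],
) -> SdcSharing:
    """How often a panel of individuals is fixed for reference derived alleles.

    ``reference_sdc_sites`` must carry chrom, pos, der_base (the derived
    allele at each shared-derived-character site).  ``panel_genotypes`` must
    carry chrom, pos and one column per sample with a two-character diploid
    genotype string of bases (e.g. "TT", "AT"); any character outside ACGT
    marks a missing call.  Overlap counts positions present in both tables
    and genotyped in *all* panel samples; the fraction is the share of the
    overlap where every sample is homozygous for the derived allele.  An
    empty overlap leaves the fraction undefined (None).
    """
    merged = reference_sdc_sites.merge(
        panel_genotypes, on=["chrom", "pos"], how="inner", suffixes=("", "_panel")
    )
    if not len(merged):
        return SdcSharing(0, None)
    geno = merged[list(samples)].to_numpy(dtype=object)
    called = np.array(
        [[isinstance(g, str) and len(g) == 2 and set(g) <= _ACGT for g in row] for row in geno]
    )
    all_called = called.all(axis=1)
    if not all_called.any():
        return SdcSharing(0, None)
    der = merged["der_base"].to_numpy()
    fixed = np.array(
        [
            all(g == 2 * d for g in row)
            for row, d in zip(geno[all_called], der[all_called])
        ]
    )
    n_overlap = int(all_called.sum())
    return SdcSharing(n_overlap, float(fixed.mean()))
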