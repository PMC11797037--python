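"""Polarization, site filters and panel-sharing checks."""

import numpy as np
import pandas as pd
import pytest

from hybridscan import polarize
from hybridscan.codes import assign_split_codes

ING = ("rerio", "kyathit", "aesculapii", "nigrofasciatus")
OUT = ("devario", "meghalayensis")


def geno_table(rows, outgroups=OUT, with_depth=False, depth=10):
    """rows: (chrom, pos, ref, alt, ingroup alleles 4-tuple, outgroup alleles)"""
    recs = []
    for chrom, pos, ref, alt, ing, out in rows:
        rec = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        rec.update(dict(zip(ING, ing)))
        rec.update(dict(zip(outgroups, out)))
        recs.append(rec)
    df = pd.DataFrame(recs)
    for t in ING + tuple(outgroups):
        df[t] = df[t].astype(np.int8)
        if with_depth:
            df[f"{t}_dp"] = depth
    return df


class TestPolarizeSites:
    def test_outgroup_defines_ancestral_state(self):
        g = geno_table([("chr1", 10, "G", "T", (1, 1, 0, 0), (0, 0))])
        res = polarize.polarize_sites(g, ING, OUT)
        assert list(res.sites["split"]) == ["rerio+kyathit"]
        assert list(res.sites["anc_base"]) == ["G"]
        assert list(res.sites["der_base"]) == ["T"]

    def test_polymorphic_outgroups_removed(self):
        g = geno_table([("chr1", 10, "G", "T", (1, 1, 0, 0), (0, 1))])
        res = polarize.polarize_sites(g, ING, OUT)
        assert len(res.sites) == 0
        assert res.removed["outgroup_polymorphic"] == 1

    def test_invariant_sites_removed(self):
        g = geno_table([("chr1", 10, "G", "T", (0, 0, 0, 0), (0, 0))])
        res = polarize.polarize_sites(g, ING, OUT)
        assert len(res.sites) == 0
        assert res.removed["invariant"] == 1

    def test_all_outgroups_missing_removed_not_error(self):
        g = geno_table([("chr1", 10, "G", "T", (1, 0, 0, 0), (-1, -1))])
        res = polarize.polarize_sites(g, ING, OUT)
        assert len(res.sites) == 0
        assert res.removed["outgroup_missing"] == 1

    def test_outgroups_fixed_for_alt_flip_polarity(self):
        # outgroups carry ALT -> ALT is ancestral, REF-bearing taxa are derived
        g = geno_table([("chr1", 10, "G", "T", (0, 0, 1, 1), (1, 1))])
        res = polarize.polarize_sites(g, ING, OUT)
        assert list(res.sites["split"]) == ["rerio+kyathit"]
        assert list(res.sites["anc_base"]) == ["T"]
        assert list(res.sites["der_base"]) == ["G"]

    def test_ref_alt_swap_leaves_split_codes_unchanged(self, rng):
        n = 300
        ing = rng.integers(0, 2, size=(n, 4))
        ing[(ing.sum(axis=1) == 0), 0] = 1
        rows = [("chr1", 10 + 3 * i, "A", "C", tuple(ing[i]), (0, 0)) for i in range(n)]
        g = geno_table(rows)
        res = polarize.polarize_sites(g, ING, OUT)
        swapped = g.copy()
        swapped["ref"], swapped["alt"] = g["alt"], g["ref"]
        for t in ING + OUT:
            swapped[t] = np.where(g[t] >= 0, 1 - g[t], g[t]).astype(np.int8)
        res2 = polarize.polarize_sites(swapped, ING, OUT)
        pd.testing.assert_series_equal(res.sites["split"], res2.sites["split"])

    def test_missing_ingroup_taxon_demotes_to_other(self):
        g = geno_table([("chr1", 10, "G", "T", (1, 1, -1, 0), (0, 0))])
        res = polarize.polarize_sites(g, ING, OUT)
        assert list(res.sites["split"]) == ["other"]

    def test_count_identity(self, rng):
        n = 500
        rows = []
        for i in range(n):
            ing = tuple(rng.integers(-1, 2, size=4))
            out = tuple(rng.integers(-1, 2, size=2))
            rows.append(("chr1", 5 * i + 1, "A", "G", ing, out))
        g = geno_table(rows)
        res = polarize.polarize_sites(g, ING, OUT)
        assert len(g) == len(res.sites) + sum(res.removed.values())


class TestSiteFilters:
    def test_snp_cluster_removes_all_members(self):
        rows = [("chr1", p, "A", "G", (1, 0, 0, 0), (0, 0)) for p in (100, 105, 109, 200)]
        g = geno_table(rows, with_depth=True)
        out, counters = polarize.apply_site_filters(g, ING + OUT)
        assert list(out["pos"]) == [200]
        assert counters["snp_cluster"] == 3

    def test_two_close_snps_kept(self):
        rows = [("chr1", p, "A", "G", (1, 0, 0, 0), (0, 0)) for p in (100, 104)]
        g = geno_table(rows, with_depth=True)
        out, _ = polarize.apply_site_filters(g, ING + OUT)
        assert list(out["pos"]) == [100, 104]

    def test_low_depth_site_removed(self):
        g = geno_table([("chr1", 10, "A", "G", (1, 0, 0, 0), (0, 0))], with_depth=True)
        g.loc[0, "kyathit_dp"] = 4
        out, counters = polarize.apply_site_filters(g, ING + OUT, min_depth=5)
        assert len(out) == 0 and counters["low_depth"] == 1

    def test_depth_required_when_min_depth_positive(self):
        g = geno_table([("chr1", 10, "A", "G", (1, 0, 0, 0), (0, 0))])
        with pytest.raises(ValueError, match="depth columns"):
            polarize.apply_site_filters(g, ING + OUT, min_depth=5)

    def test_cluster_rule_is_span_based_not_pair_based(self):
        # 3 SNPs spanning 11 bp (100..110) do not form a cluster at window 10
        rows = [("chr1", p, "A", "G", (1, 0, 0, 0), (0, 0)) for p in (100, 105, 110)]
        g = geno_table(rows, with_depth=True)
        out, _ = polarize.apply_site_filters(g, ING + OUT)
        assert len(out) == 3


class TestReadVcf:
    def test_missing_taxon_is_hard_error(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\trerio\n"
        )
        taxa = polarize.TaxaConfig(ingroup=ING, outgroups=("devario",))
        with pytest.raises(ValueError, match="absent"):
            polarize.read_vcf(str(path), taxa)

    def test_multiallelic_dropped_and_counted(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ING + ("devario",))
            + "\n"
        )
        body = (
            "chr1\t5\t.\tA\tC,G\t.\t.\t.\tGT\t1\t1\t0\t0\t0\n"
            "chr1\t9\t.\tA\tAT\t.\t.\t.\tGT\t1\t0\t0\t0\t0\n"
            "chr1\t12\t.\tA\tC\t.\t.\t.\tGT\t1\t1\t0\t0\t0\n"
        )
        path = tmp_path / "t.vcf"
        path.write_text(header + body)
        taxa = polarize.TaxaConfig(ingroup=ING, outgroups=("devario",))
        df = polarize.read_vcf(str(path), taxa)
        assert len(df) == 1 and df.attrs["filter_counts"] == {"multiallelic": 1, "non_snv": 1}
        assert df.attrs["contig_lengths"] == {"chr1": 1000}

    def test_empty_body_gives_empty_table(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ING + ("devario",))
            + "\n"
        )
        taxa = polarize.TaxaConfig(ingroup=ING, outgroups=("devario",))
        df = polarize.read_vcf(str(path), taxa)
        assert len(df) == 0


class TestSdcSharing:
    @staticmethod
    def panel(rows, samples=("s1", "s2")):
        recs = []
        for chrom, pos, genos in rows:
            rec = {"chrom": chrom, "pos": pos}
            rec.update(dict(zip(samples, genos)))
            recs.append(rec)
        return pd.DataFrame(recs)

    @staticmethod
    def reference(rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "der_base"])

    def test_all_fixed_derived(self):
        ref = self.reference([("chr1", 10, "T"), ("chr1", 20, "C")])
        pan = self.panel([("chr1", 10, ("TT", "TT")), ("chr1", 20, ("CC", "CC"))])
        res = polarize.sdc_sharing(ref, pan, ("s1", "s2"))
        assert (res.n_overlap, res.fraction_fixed_derived) == (2, 1.0)

    def test_all_fixed_ancestral(self):
        ref = self.reference([("chr1", 10, "T")])
        pan = self.panel([("chr1", 10, ("AA", "AA"))])
        res = polarize.sdc_sharing(ref, pan, ("s1", "s2"))
        assert (res.n_overlap, res.fraction_fixed_derived) == (1, 0.0)

    def test_nine_of_ten_fixed(self):
        ref = self.reference([("chr1", 10 * i, "T") for i in range(1, 11)])
        genos = [("TT", "TT")] * 9 + [("AT", "TT")]
        pan = self.panel([("chr1", 10 * (i + 1), g) for i, g in enumerate(genos)])
        res = polarize.sdc_sharing(ref, pan, ("s1", "s2"))
        assert res.n_overlap == 10
        assert res.fraction_fixed_derived == pytest.approx(0.9)

    def test_empty_overlap_undefined(self):
        ref = self.reference([("chr1", 10, "T")])
        pan = self.panel([("chr2", 10, ("TT", "TT"))])
        res = polarize.sdc_sharing(ref, pan, ("s1", "s2"))
        assert res.n_overlap == 0 and res.fraction_fixed_derived is None

    def test_missing_calls_excluded_from_overlap(self):
        ref = self.reference([("chr1", 10, "T"), ("chr1", 20, "T")])
        pan = self.panel([("chr1", 10, ("TT", "..")), ("chr1", 20, ("TT", "TT"))])
        res = polarize.sdc_sharing(ref, pan, ("s1", "s2"))
        assert res.n_overlap == 1 and res.fraction_fixed_derived == 1.0


def test_polarization_idempotent_on_sim_schema(rng):
    # re-coding already-polarized states (A/B as ref/alt with outgroup=0) is a no-op
    n = 200
    states = rng.integers(0, 2, size=(n, 4)).astype(np.int8)
    states[states.sum(axis=1) == 0, 1] = 1
    g = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1) * 7, "ref": "A", "alt": "T"})
    for i, t in enumerate(ING):
        g[t] = states[:, i]
    g["devario"] = np.int8(0)
    first = polarize.polarize_sites(g, ING, ("devario",)).sites
    assert (first[list(ING)].to_numpy() == states).all()
    assert list(first["split"]) == list(assign_split_codes(states, ING))
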