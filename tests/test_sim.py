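"""Simulator: closed-form laws, determinism, gene-flow mixtures, VCF output."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridscan import polarize, sim
from hybridscan.codes import pair_codes


def small_scenario(**kw):
    defaults = dict(
        ingroup=("rerio", "kyathit", "aesculapii", "nigrofasciatus"),
        outgroup="devario",
        topology=((("rerio", "kyathit"), "aesculapii"), "nigrofasciatus"),
        t_internal=1.0,
        chromosomes=(sim.Chromosome("chr1", 50_000_000, 20_000),),
        seed=7,
    )
    defaults.update(kw)
    return sim.SimScenario(**defaults)


class TestScenarioValidation:
    def test_hybrid_taxon_equal_to_parent_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            sim.HybridSpec("rerio", "rerio", "aesculapii", 0.5)

    def test_gamma_and_rate_bounds(self):
        with pytest.raises(ValueError):
            sim.HybridSpec("rerio", "kyathit", "aesculapii", 1.2)
        with pytest.raises(ValueError):
            sim.IntrogressionEdge("a", "b", -0.1)

    def test_retention_outside_unit_interval_rejected(self):
        bad = sim.IntrogressionEdge(
            "aesculapii", "kyathit", 0.3, profile=lambda r: np.full_like(r, 1.5)
        )
        sc = small_scenario(introgression=(bad,), chromosomes=(sim.Chromosome("chr1", 1000, 10),))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            sim.simulate_sites(sc)

    def test_balanced_topology_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            small_scenario(topology=(("rerio", "kyathit"), ("aesculapii", "nigrofasciatus")))

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError):
            small_scenario(ingroup=("a", "a", "b", "c"), topology=((("a", "a"), "b"), "c"))


class TestCoalescentLaw:
    def test_infinite_branch_gives_only_concordant_split(self):
        sc = small_scenario(t_internal=math.inf, chromosomes=(sim.Chromosome("chr1", 10**6, 2000),))
        sites, truth = sim.simulate_sites(sc)
        assert set(sites["split"]) == {"rerio+kyathit"}
        assert set(truth["genealogy"]) == {"concordant"}

    def test_zero_branch_star_symmetry(self):
        sc = small_scenario(t_internal=0.0)
        sites, _ = sim.simulate_sites(sc)
        freqs = sites["split"].value_counts(normalize=True)
        assert set(freqs.index) == {"rerio+kyathit", "rerio+aesculapii", "kyathit+aesculapii"}
        se = 3 * math.sqrt((1 / 3) * (2 / 3) / len(sites))
        for f in freqs:
            assert abs(f - 1 / 3) < se

    def test_concordant_fraction_matches_closed_form_at_t1(self):
        sc = small_scenario(t_internal=1.0, chromosomes=(sim.Chromosome("chr1", 10**8, 100_000),))
        _, truth = sim.simulate_sites(sc)
        expect = 1 - (2 / 3) * math.exp(-1)
        assert (truth["genealogy"] == "concordant").mean() == pytest.approx(expect, abs=0.01)

    def test_concordant_frequency_monotone_in_t(self):
        fracs = []
        for t in (0.25, 0.75, 1.5, 3.0):
            _, truth = sim.simulate_sites(small_scenario(t_internal=t, seed=5))
            fracs.append((truth["genealogy"] == "concordant").mean())
        assert fracs == sorted(fracs)


class TestGeneFlow:
    def test_hybrid_half_gamma_balances_parent_splits(self):
        sc = sim.hybrid_scenario(gamma=0.5, total_sites=100_000, seed=11)
        sites, truth = sim.simulate_sites(sc)
        vc = sites["split"].value_counts()
        c1, c2 = vc["rerio+kyathit"], vc["rerio+aesculapii"]
        c0 = vc["kyathit+aesculapii"]
        # balanced within sampling error, each well above the parents-only count
        assert abs(c1 - c2) < 4 * math.sqrt(c1 + c2)
        assert c1 > 1.5 * c0 and c2 > 1.5 * c0
        origins = truth["origin"].value_counts(normalize=True)
        assert origins["hybrid-parent-1"] == pytest.approx(0.5, abs=0.01)

    def test_mixture_property_constant_retention(self):
        f = 0.3
        common = dict(t_internal=1.0, chromosomes=(sim.Chromosome("chr1", 10**8, 300_000),))
        edge = sim.IntrogressionEdge(
            "aesculapii", "kyathit", f, profile=sim.ConstantRetention(f)
        )
        mixed = small_scenario(introgression=(edge,), seed=3, **common)
        sites, _ = sim.simulate_sites(mixed)
        emp = sites["split"].value_counts(normalize=True)
        none = sim.expected_pattern_freqs(small_scenario(**common))
        full_edge = sim.IntrogressionEdge(
            "aesculapii", "kyathit", 1.0, profile=sim.ConstantRetention(1.0)
        )
        full = sim.expected_pattern_freqs(small_scenario(introgression=(full_edge,), **common))
        n = len(sites)
        for code in set(none) | set(full):
            expect = (1 - f) * none.get(code, 0) + f * full.get(code, 0)
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(emp.get(code, 0.0) - expect) < 3 * se + 1e-9

    def test_complete_replacement_matches_reattached_topology(self):
        edge = sim.IntrogressionEdge(
            "aesculapii", "kyathit", 1.0, profile=sim.ConstantRetention(1.0)
        )
        freqs = sim.expected_pattern_freqs(small_scenario(introgression=(edge,), t_internal=1.0))
        # re-attached cherry is (kyathit, aesculapii); rerio becomes the third taxon
        assert freqs["kyathit+aesculapii"] == pytest.approx(1 - (2 / 3) * math.exp(-1))
        assert freqs["rerio+kyathit"] == pytest.approx((1 / 3) * math.exp(-1))


class TestExpectedFreqs:
    def test_no_flow_triplet_law(self):
        t = 0.8
        freqs = sim.expected_pattern_freqs(small_scenario(t_internal=t))
        assert freqs["rerio+kyathit"] == pytest.approx(1 - (2 / 3) * math.exp(-t))
        assert freqs["rerio+aesculapii"] == pytest.approx((1 / 3) * math.exp(-t))
        assert freqs["kyathit+aesculapii"] == pytest.approx((1 / 3) * math.exp(-t))

    def test_probabilities_sum_to_one(self):
        sc = sim.hybrid_scenario(gamma=0.3)
        assert sum(sim.expected_pattern_freqs(sc).values()) == pytest.approx(1.0)
        sc2 = small_scenario(singleton_rate=0.1, triple_rate=0.05)
        assert sum(sim.expected_pattern_freqs(sc2).values()) == pytest.approx(1.0)

    def test_abba_baba_balanced_without_gene_flow(self):
        sc = small_scenario(chromosomes=(sim.Chromosome("chr1", 10**8, 100_000),), seed=9)
        sites, _ = sim.simulate_sites(sc)
        n_abba = (sites["split"] == "kyathit+aesculapii").sum()
        n_baba = (sites["split"] == "rerio+aesculapii").sum()
        d = (n_abba - n_baba) / (n_abba + n_baba)
        assert abs(d) < 3 / math.sqrt(n_abba + n_baba)


class TestDeterminismAndPositions:
    def test_same_seed_identical_output(self):
        a, ta = sim.simulate_sites(small_scenario(seed=42))
        b, tb = sim.simulate_sites(small_scenario(seed=42))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_differs(self):
        a, _ = sim.simulate_sites(small_scenario(seed=1))
        b, _ = sim.simulate_sites(small_scenario(seed=2))
        assert not a["pos"].equals(b["pos"])

    def test_positions_unique_sorted_per_chromosome(self):
        sc = sim.ils_scenario(total_sites=30_000, seed=6)
        sites, _ = sim.simulate_sites(sc)
        for _, grp in sites.groupby("chrom", observed=True):
            pos = grp["pos"].to_numpy()
            assert np.all(np.diff(pos) > 0)
        assert len(sites) == 30_000

    def test_singleton_and_triple_rates(self):
        sc = small_scenario(singleton_rate=0.2, triple_rate=0.1, seed=8)
        sites, _ = sim.simulate_sites(sc)
        frac_single = sites["split"].str.startswith("single:").mean()
        frac_triple = (sites["split"] == "triple").mean()
        assert frac_single == pytest.approx(0.2, abs=0.02)
        assert frac_triple == pytest.approx(0.1, abs=0.02)


class TestWriteVcf:
    def test_header_only_for_zero_sites(self, tmp_path):
        sc = small_scenario(chromosomes=(sim.Chromosome("chr1", 1000, 0),))
        sites, _ = sim.simulate_sites(sc)
        path = tmp_path / "empty.vcf"
        sim.write_vcf(sites, sc.taxa, str(path), sc.chrom_lengths)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert any("##contig=<ID=chr1,length=1000>" in l for l in lines)

    def test_single_site_genotype_encoding(self, tmp_path):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "pos": [500],
                "rerio": [1],
                "kyathit": [1],
                "aesculapii": [0],
                "nigrofasciatus": [0],
                "split": ["rerio+kyathit"],
                "anc_base": ["G"],
                "der_base": ["T"],
            }
        )
        path = tmp_path / "one.vcf"
        taxa = ("rerio", "kyathit", "aesculapii", "nigrofasciatus", "devario")
        sim.write_vcf(sites, taxa, str(path), {"chr1": 1000})
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1
        fields = body[0].split("\t")
        assert fields[:5] == ["chr1", "500", ".", "G", "T"]
        assert fields[9:] == ["1", "1", "0", "0", "0"]

    def test_unsorted_input_refused(self, tmp_path):
        sc = small_scenario(chromosomes=(sim.Chromosome("chr1", 10_000, 50),))
        sites, _ = sim.simulate_sites(sc)
        shuffled = sites.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="unsorted"):
            sim.write_vcf(shuffled, sc.taxa, str(tmp_path / "x.vcf"), sc.chrom_lengths)

    def test_roundtrip_recovers_split_codes(self, tmp_path):
        sc = sim.ils_scenario(total_sites=4000, seed=13)
        sites, _ = sim.simulate_sites(sc)
        path = tmp_path / "rt.vcf"
        sim.write_vcf(sites, sc.taxa, str(path), sc.chrom_lengths)
        taxa = polarize.TaxaConfig(ingroup=sc.ingroup, outgroups=(sc.outgroup,))
        geno = polarize.read_vcf(str(path), taxa)
        back = polarize.polarize_sites(geno, sc.ingroup, (sc.outgroup,)).sites
        cols = ["chrom", "pos", *sc.ingroup, "split"]
        pd.testing.assert_frame_equal(
            back[cols].reset_index(drop=True), sites[cols].reset_index(drop=True)
        )


class TestHelpers:
    def test_default_chromosome_map(self):
        chroms = sim.default_chromosomes(100_000)
        assert len(chroms) == 25
        assert sum(c.n_sites for c in chroms) == 100_000
        assert all(40_000_000 <= c.length <= 80_000_000 for c in chroms)
        # stable across calls
        again = sim.default_chromosomes(100_000)
        assert [c.length for c in chroms] == [c.length for c in again]

    def test_uniform_split_null_is_balanced(self, ingroup):
        sites = sim.uniform_split_null(60_000, seed=2)
        freqs = sites["split"].value_counts(normalize=True)
        assert set(freqs.index) == set(pair_codes(ingroup))
        assert np.allclose(freqs, 1 / 6, atol=0.01)

    def test_truth_intervals_terminal_and_symmetric(self):
        sc = sim.introgression_scenario(total_sites=1000, rate=0.3)
        iv = sim.introgression_truth_intervals(sc, 0.25)
        for chrom in iv:
            L = sc.chrom_lengths[chrom]
            (s1, e1), (s2, e2) = iv[chrom]
            assert s1 == 1 and e2 == L
            assert (e1 - s1) - (e2 - s2) in (-1, 0, 1)  # symmetric arms
            assert e1 < L / 2 < s2
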