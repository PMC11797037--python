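"""Reduced multispecies-coalescent simulator for polarized site patterns.

The generator emulates the site-pattern data underlying a four-taxon
phylogenomic discordance scan: biallelic sites scattered along a
25-chromosome genome, each polarized against an outgroup and carrying a
derived allele in a subset of the four focal ingroup taxa.  Three processes
shape which subset:

* **Incomplete lineage sorting (ILS).**  Per site, the two lineages entering
  the focal internal branch of length ``T`` (coalescent units) coalesce there
  with probability 1 - exp(-T), producing the species-tree ("concordant")
  pairwise split; otherwise the three pairings of the focal triplet are
  equally likely.  Deeper coalescences are collapsed: the model is a
  one-triplet reduction, which is exactly the resolution at which
  topology-frequency and ABBA/BABA inferences operate.

* **Introgression.**  Each introgression edge re-attaches the recipient
  lineage to the donor, per site, with a probability given by a retention
  profile over the *folded* chromosome coordinate.  The default profile is
  logistic and concentrates retention near telomeres, emulating preferential
  retention of introgressed alleles in high-recombination chromosome ends.

* **Homoploid hybrid speciation (HHS).**  A hybrid taxon joins parent-1's
  lineage with probability ``gamma`` and parent-2's otherwise, independently
  per site, producing a genome-wide mosaic of the two parental histories.

Each emitted site carries exactly one mutation on an internal branch
subtending exactly two ingroup taxa (a pairwise split); singleton and
triple-derived sites can be mixed in at configurable rates for realism but
default to zero.  A per-site truth track records the local genealogy class
and the origin of the lineage arrangement for recovery tests.

All randomness flows from a single ``numpy`` Generator seeded by
``SimScenario.seed``.  Draw order (per chromosome, in chromosome order):
positions; hybrid attachment uniforms; one uniform per introgression edge in
edge order; the coalescence uniform; the 3-way topology pick; the
singleton/triple override uniforms and taxon picks; ancestral/derived base
picks.  Identical scenario + seed therefore gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .chromstruct import fold
from .codes import (
    STATE_DERIVED,
    STATE_MISSING,
    TRIPLE,
    assign_split_codes,
    pair_code,
    pair_codes,
    singleton_code,
)

__all__ = [
    "Chromosome",
    "LogisticRetention",
    "ConstantRetention",
    "TabulatedRetention",
    "IntrogressionEdge",
    "HybridSpec",
    "SimScenario",
    "simulate_sites",
    "expected_pattern_freqs",
    "write_vcf",
    "default_chromosomes",
    "ils_scenario",
    "introgression_scenario",
    "hybrid_scenario",
    "uniform_split_null",
    "introgression_truth_intervals",
]

_BASES = np.array(list("ACGT"))

GENEALOGY_CLASSES = ("concordant", "discordant-1", "discordant-2")


# ---------------------------------------------------------------------------
# scenario building blocks


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    n_sites: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.name}: length must be >= 1")
        if self.n_sites < 0:
            raise ValueError(f"{self.name}: n_sites must be >= 0")
        if self.n_sites > self.length:
            raise ValueError(f"{self.name}: more sites than positions")


@dataclass(frozen=True)
class LogisticRetention:
    """Telomere-concentrated retention: rate / (1 + exp((r - r0) / scale)).

    ``r`` is the folded coordinate (0 = telomere, 1 = chromosome middle), so
    retention plateaus near ``rate`` at chromosome ends and decays to ~0 at
    centers.  Defaults r0 = 0.35, scale = 0.08 place the transition about a
    third of the way in from each telomere.
    """

    rate: float
    r0: float = 0.35
    scale: float = 0.08

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return self.rate / (1.0 + np.exp((np.asarray(r, dtype=float) - self.r0) / self.scale))


@dataclass(frozen=True)
class ConstantRetention:
    rate: float

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(r, dtype=float), self.rate)


@dataclass(frozen=True)
class TabulatedRetention:
    """Piecewise-linear retention given as (folded coordinate, retention) knots."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        rs = [p[0] for p in self.points]
        vs = [p[1] for p in self.points]
        if len(self.points) < 2 or sorted(rs) != rs:
            raise ValueError("need >= 2 knots with increasing folded coordinates")
        if any(v < 0 or v > 1 for v in vs):
            raise ValueError("retention values must lie in [0, 1]")

    def __call__(self, r: np.ndarray) -> np.ndarray:
        rs = np.array([p[0] for p in self.points])
        vs = np.array([p[1] for p in self.points])
        return np.interp(np.asarray(r, dtype=float), rs, vs)


@dataclass(frozen=True)
class IntrogressionEdge:
    """Gene flow from ``donor`` into ``recipient`` with base rate ``rate``.

    ``profile`` maps folded coordinate to the per-site re-attachment
    probability; if None, a LogisticRetention with base ``rate`` is used.
    """

    donor: str
    recipient: str
    rate: float
    profile: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("introgression rate must lie in [0, 1]")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")

    def retention(self, r: np.ndarray) -> np.ndarray:
        prof = self.profile if self.profile is not None else LogisticRetention(self.rate)
        return np.asarray(prof(r), dtype=float)


@dataclass(frozen=True)
class HybridSpec:
    hybrid: str
    parent1: str
    parent2: str
    gamma: float

    def __post_init__(self):
        if self.hybrid in (self.parent1, self.parent2):
            raise ValueError("hybrid taxon must differ from both parents")
        if self.parent1 == self.parent2:
            raise ValueError("the two parent lineages must differ")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class SimScenario:
    """Full generative specification for one synthetic data set."""

    ingroup: tuple[str, str, str, str]
    outgroup: str
    topology: tuple
    t_internal: float
    chromosomes: tuple[Chromosome, ...]
    introgression: tuple[IntrogressionEdge, ...] = ()
    hybrid: HybridSpec | None = None
    singleton_rate: float = 0.0
    triple_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.ingroup) != 4 or len(set(self.ingroup)) != 4:
            raise ValueError("ingroup must be 4 unique taxa")
        if self.outgroup in self.ingroup:
            raise ValueError("outgroup must not be an ingroup taxon")
        if self.t_internal < 0:
            raise ValueError("t_internal must be >= 0")
        if set(_leaves(self.topology)) != set(self.ingroup):
            raise ValueError("topology leaves must equal the ingroup")
        _reduce_topology(self.topology)  # raises if not asymmetric
        for e in self.introgression:
            if e.donor not in self.ingroup or e.recipient not in self.ingroup:
                raise ValueError("introgression edges must connect ingroup taxa")
        if self.hybrid is not None:
            for t in (self.hybrid.hybrid, self.hybrid.parent1, self.hybrid.parent2):
                if t not in self.ingroup:
                    raise ValueError("hybrid spec must name ingroup taxa")
        if self.singleton_rate < 0 or self.triple_rate < 0 or (
            self.singleton_rate + self.triple_rate > 1
        ):
            raise ValueError("singleton/triple rates must be >= 0 and sum to <= 1")
        if len({c.name for c in self.chromosomes}) != len(self.chromosomes):
            raise ValueError("chromosome names must be unique")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.ingroup) + (self.outgroup,)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# local-history resolution (one-triplet reduction)


def _leaves(t) -> list[str]:
    if isinstance(t, str):
        return [t]
    if len(t) != 2:
        raise ValueError("topology nodes must be binary")
    return _leaves(t[0]) + _leaves(t[1])


def _reduce_topology(topo) -> tuple[tuple[str, str], str, str]:
    """Reduce a rooted asymmetric quartet (((w,x),y),z) to (cherry, third, fourth)."""
    a, b = topo
    if isinstance(a, str) and not isinstance(b, str):
        a, b = b, a
    if not isinstance(b, str) or isinstance(a, str):
        raise ValueError("topology must be rooted asymmetric: (((w,x),y),z)")
    fourth = b
    c, d = a
    if isinstance(c, str) and not isinstance(d, str):
        c, d = d, c
    if not isinstance(d, str) or isinstance(c, str):
        raise ValueError("topology must be rooted asymmetric: (((w,x),y),z)")
    third = d
    w, x = c
    if not (isinstance(w, str) and isinstance(x, str)):
        raise ValueError("topology must be rooted asymmetric: (((w,x),y),z)")
    return (w, x), third, fourth


@dataclass(frozen=True)
class _LocalHistory:
    cherry: tuple[str, str]
    third: str
    fourth: str
    origin: str


def _reattach(
    hist: _LocalHistory,
    mover: str,
    target: str,
    ingroup: Sequence[str],
    origin: str,
    orig_sister: str | None = None,
) -> _LocalHistory:
    """Re-attach ``mover`` as sister of ``target`` and re-reduce to a triplet.

    If the re-attachment lands on the deepest lineage the local tree would be
    balanced; the third slot is then filled by the mover's original sister if
    still available, else by ingroup order (deterministic tie rule).
    """
    order = {t: i for i, t in enumerate(ingroup)}
    cherry, third, fourth = hist.cherry, hist.third, hist.fourth
    if mover == target:
        raise ValueError("mover and target must differ")
    if target in cherry and mover in cherry:
        return _LocalHistory(cherry, third, fourth, origin)
    # prune mover -> triplet ((x, y), z)
    if mover in cherry:
        other = cherry[0] if cherry[1] == mover else cherry[1]
        x, y, z = other, third, fourth
    elif mover == third:
        x, y, z = cherry[0], cherry[1], fourth
    elif mover == fourth:
        x, y, z = cherry[0], cherry[1], third
    else:
        raise ValueError(f"{mover!r} not in local history")
    # graft mover as sister of target
    if target == x or target == y:
        new_cherry = (target, mover)
        new_third = y if target == x else x
        new_fourth = z
    elif target == z:
        new_cherry = (target, mover)
        if orig_sister is not None and orig_sister in (x, y):
            new_third = orig_sister
        else:
            new_third = min(x, y, key=order.__getitem__)
        new_fourth = y if new_third == x else x
    else:
        raise ValueError(f"{target!r} not in local history after pruning")
    a, b = sorted(new_cherry, key=order.__getitem__)
    return _LocalHistory((a, b), new_third, new_fourth, origin)


def _history_states(scenario: SimScenario) -> list[_LocalHistory]:
    """Enumerate the distinct per-site lineage arrangements.

    Index layout: h * (n_edges + 1) + (1 + edge_index), where h indexes the
    hybrid attachment (0 = parent1 side, or the only state without a hybrid)
    and edge_index -1 means no introgression fired.
    """
    base_cherry, base_third, base_fourth = _reduce_topology(scenario.topology)
    base = _LocalHistory(base_cherry, base_third, base_fourth, "species-tree")

    if scenario.hybrid is None:
        attached = [base]
    else:
        hs = scenario.hybrid
        sister = (
            base_cherry[0]
            if hs.hybrid == base_cherry[1]
            else base_cherry[1]
            if hs.hybrid == base_cherry[0]
            else None
        )
        attached = [
            _reattach(base, hs.hybrid, hs.parent1, scenario.ingroup, "hybrid-parent-1", sister),
            _reattach(base, hs.hybrid, hs.parent2, scenario.ingroup, "hybrid-parent-2", sister),
        ]

    states: list[_LocalHistory] = []
    for h in attached:
        states.append(h)
        for e in scenario.introgression:
            sis = (
                h.cherry[0]
                if e.recipient == h.cherry[1]
                else h.cherry[1]
                if e.recipient == h.cherry[0]
                else None
            )
            states.append(
                _reattach(h, e.recipient, e.donor, scenario.ingroup, "introgressed", sis)
            )
    return states


def _triplet_pairs(hist: _LocalHistory) -> list[tuple[str, str]]:
    return [
        hist.cherry,
        (hist.cherry[0], hist.third),
        (hist.cherry[1], hist.third),
    ]


# ---------------------------------------------------------------------------
# simulation


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions, uniform along the chromosome, sorted."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n > length // 2:
        return np.sort(rng.permutation(length)[:n]) + 1
    pool = np.unique(rng.integers(1, length + 1, size=n + max(16, n // 16)))
    while pool.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pool = np.unique(np.concatenate([pool, extra]))
    if pool.size > n:
        keep = rng.permutation(pool.size)[:n]
        pool = np.sort(pool[keep])
    return pool.astype(np.int64)


def simulate_sites(scenario: SimScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate polarized sites and the per-site truth track.

    Returns ``(sites, truth)``.  ``sites`` has columns chrom, pos, one int8
    state column per ingroup taxon (0 ancestral / 1 derived), split,
    anc_base, der_base; exactly ``n_sites`` rows per chromosome, sorted by
    (chromosome order, position).  ``truth`` has chrom, pos, genealogy
    (concordant / discordant-1 / discordant-2, relative to the local
    post-attachment triplet) and origin (species-tree / introgressed /
    hybrid-parent-1 / hybrid-parent-2).
    """
    rng = np.random.default_rng(scenario.seed)
    states_list = _history_states(scenario)
    ingroup = scenario.ingroup
    idx = {t: i for i, t in enumerate(ingroup)}
    n_eo = len(scenario.introgression) + 1  # edge options incl. "none"

    # per-state, per-choice lookup: derived-set bitmask and split code
    mask_lut = np.zeros((len(states_list), 3), dtype=np.int8)
    code_lut = np.empty((len(states_list), 3), dtype=object)
    origin_lut = np.empty(len(states_list), dtype=object)
    for s, hist in enumerate(states_list):
        origin_lut[s] = hist.origin
        for c, (a, b) in enumerate(_triplet_pairs(hist)):
            mask_lut[s, c] = (1 << idx[a]) | (1 << idx[b])
            code_lut[s, c] = pair_code(a, b, ingroup)

    p_coal = 1.0 - math.exp(-scenario.t_internal) if math.isfinite(scenario.t_internal) else 1.0

    site_frames = []
    truth_frames = []
    for chrom in scenario.chromosomes:
        n = chrom.n_sites
        pos = _draw_positions(rng, chrom.length, n)
        r = fold(pos, chrom.length) if n else np.empty(0)

        state_id = np.zeros(n, dtype=np.int64)
        if scenario.hybrid is not None:
            h = (rng.random(n) >= scenario.hybrid.gamma).astype(np.int64)  # 0 = parent1
            state_id = h * n_eo
        edge_pick = np.full(n, -1, dtype=np.int64)
        taken = np.zeros(n, dtype=bool)
        for i, e in enumerate(scenario.introgression):
            p = e.retention(r)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"retention profile of {e.donor}->{e.recipient} leaves [0, 1]")
            fire = (~taken) & (rng.random(n) < p)
            edge_pick[fire] = i
            taken |= fire
        state_id = state_id + 1 + edge_pick

        coal = rng.random(n) < p_coal
        alt = rng.integers(0, 3, size=n)
        choice = np.where(coal, 0, alt)

        masks = mask_lut[state_id, choice]
        codes = code_lut[state_id, choice]

        # optional singleton / triple-derived sites for realism
        if scenario.singleton_rate > 0 or scenario.triple_rate > 0:
            v = rng.random(n)
            sing = v < scenario.singleton_rate
            trip = (~sing) & (v < scenario.singleton_rate + scenario.triple_rate)
            t_pick = rng.integers(0, 4, size=n)
            if sing.any():
                masks = masks.copy()
                codes = codes.copy()
                masks[sing] = (1 << t_pick[sing]).astype(np.int8)
                codes[sing] = np.array(
                    [singleton_code(ingroup[t]) for t in t_pick[sing]], dtype=object
                )
            if trip.any():
                masks = masks.copy() if not sing.any() else masks
                codes = codes.copy() if not sing.any() else codes
                masks[trip] = (np.int8(15) ^ (1 << t_pick[trip])).astype(np.int8)
                codes[trip] = TRIPLE

        st = ((masks[:, None] >> np.arange(4, dtype=np.int8)) & 1).astype(np.int8)
        anc = rng.integers(0, 4, size=n)
        der = (anc + rng.integers(1, 4, size=n)) % 4

        frame = pd.DataFrame({"chrom": np.repeat(chrom.name, n), "pos": pos})
        for i, t in enumerate(ingroup):
            frame[t] = st[:, i]
        frame["split"] = codes
        frame["anc_base"] = _BASES[anc]
        frame["der_base"] = _BASES[der]
        site_frames.append(frame)

        truth_frames.append(
            pd.DataFrame(
                {
                    "chrom": np.repeat(chrom.name, n),
                    "pos": pos,
                    "genealogy": np.array(GENEALOGY_CLASSES, dtype=object)[choice],
                    "origin": origin_lut[state_id],
                }
            )
        )

    sites = pd.concat(site_frames, ignore_index=True) if site_frames else pd.DataFrame()
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame()
    return sites, truth


# ---------------------------------------------------------------------------
# closed-form oracle


def expected_pattern_freqs(scenario: SimScenario) -> dict[str, float]:
    """Closed-form split-code probabilities for the scenario.

    Mixes the per-arrangement triplet law (concordant pair with probability
    1 - (2/3) exp(-T), each discordant pairing (1/3) exp(-T)) over the hybrid
    attachment (gamma / 1-gamma) and introgression events by total
    probability.  Introgression edges contribute at their *base* rate: the
    closed form matches simulation exactly only for position-independent
    (constant) retention profiles; with the default telomere-logistic profile
    it describes sites at the plateau retention, not the genome-wide average.
    """
    states_list = _history_states(scenario)
    n_eo = len(scenario.introgression) + 1

    if scenario.hybrid is None:
        h_probs = [1.0]
    else:
        h_probs = [scenario.hybrid.gamma, 1.0 - scenario.hybrid.gamma]

    edge_probs = []
    stay = 1.0
    for e in scenario.introgression:
        edge_probs.append(stay * e.rate)
        stay *= 1.0 - e.rate
    state_probs = []
    for hp in h_probs:
        state_probs.append(hp * stay)  # no edge fired
        state_probs.extend(hp * ep for ep in edge_probs)
    assert len(state_probs) == len(states_list) == len(h_probs) * n_eo

    e_t = math.exp(-scenario.t_internal) if math.isfinite(scenario.t_internal) else 0.0
    p_conc = 1.0 - (2.0 / 3.0) * e_t
    p_disc = (1.0 / 3.0) * e_t

    pair_mass = 1.0 - scenario.singleton_rate - scenario.triple_rate
    freqs: dict[str, float] = {}
    for sp, hist in zip(state_probs, states_list):
        for c, (a, b) in enumerate(_triplet_pairs(hist)):
            code = pair_code(a, b, scenario.ingroup)
            p = p_conc if c == 0 else p_disc
            freqs[code] = freqs.get(code, 0.0) + pair_mass * sp * p
    if scenario.singleton_rate > 0:
        for t in scenario.ingroup:
            freqs[singleton_code(t)] = scenario.singleton_rate / 4.0
    if scenario.triple_rate > 0:
        freqs[TRIPLE] = scenario.triple_rate
    return freqs


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    sites: pd.DataFrame,
    taxa: Sequence[str],
    path: str,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write polarized sites as a minimal VCF 4.2.

    One haploid-style sample column per taxon: GT 0 = ancestral allele (REF),
    1 = derived (ALT).  Taxa absent from the sites table (outgroups) are
    written as ancestral.  Contig header lines carry chromosome lengths.
    Input must be sorted by (chromosome block, position); unsorted input is
    refused.
    """
    chroms = list(dict.fromkeys(sites["chrom"])) if len(sites) else []
    for c in chroms:
        if c not in contig_lengths:
            raise ValueError(f"no contig length for {c}")
    pos = sites["pos"].to_numpy() if len(sites) else np.empty(0, dtype=int)
    cseq = sites["chrom"].to_numpy() if len(sites) else np.empty(0, dtype=object)
    seen: set = set()
    last_chrom = None
    last_pos = -1
    for c, p in zip(cseq, pos):
        if c != last_chrom:
            if c in seen:
                raise ValueError("unsorted input refused: chromosome blocks interleaved")
            seen.add(c)
            last_chrom, last_pos = c, -1
        if p <= last_pos:
            raise ValueError("unsorted input refused: positions not increasing")
        last_pos = p

    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={name},length={int(length)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for t in taxa:
        header.add_sample(t)

    in_table = [t for t in taxa if t in sites.columns]
    col_of = {t: j for j, t in enumerate(in_table)}
    state_mat = sites[in_table].to_numpy(dtype=np.int8) if len(sites) else None
    anc = sites["anc_base"].to_numpy() if "anc_base" in sites.columns else None
    der = sites["der_base"].to_numpy() if "der_base" in sites.columns else None

    with pysam.VariantFile(path, "w", header=header) as vf:
        for i in range(len(sites)):
            ref = anc[i] if anc is not None else "A"
            alt = der[i] if der is not None else "T"
            rec = vf.new_record(
                contig=str(cseq[i]), start=int(pos[i]) - 1, alleles=(ref, alt)
            )
            for t in taxa:
                if t in col_of:
                    s = int(state_mat[i, col_of[t]])
                    rec.samples[t]["GT"] = (None,) if s == STATE_MISSING else (s,)
                else:
                    rec.samples[t]["GT"] = (0,)
            vf.write(rec)


# ---------------------------------------------------------------------------
# scenario factories and helpers

DEFAULT_INGROUP = ("rerio", "kyathit", "aesculapii", "nigrofasciatus")
DEFAULT_OUTGROUP = "devario"
DEFAULT_TOPOLOGY = ((("rerio", "kyathit"), "aesculapii"), "nigrofasciatus")
_CHROM_MAP_SEED = 140  # fixed so the default 25-chromosome map is stable


def default_chromosomes(
    total_sites: int, n_chromosomes: int = 25, map_seed: int = _CHROM_MAP_SEED
) -> tuple[Chromosome, ...]:
    """A zebrafish-like chromosome map: 25 chromosomes, 40-80 Mb, with sites
    apportioned proportionally to length (uniform site density)."""
    rng = np.random.default_rng(map_seed)
    lengths = rng.integers(40_000_000, 80_000_001, size=n_chromosomes)
    frac = lengths / lengths.sum()
    counts = np.floor(frac * total_sites).astype(int)
    # largest-remainder top-up to hit the exact total
    rem = total_sites - counts.sum()
    order = np.argsort(-(frac * total_sites - counts))
    counts[order[:rem]] += 1
    return tuple(
        Chromosome(f"chr{i + 1}", int(lengths[i]), int(counts[i]))
        for i in range(n_chromosomes)
    )


def ils_scenario(
    total_sites: int = 100_000,
    t_internal: float = 1.0,
    seed: int = 0,
    n_chromosomes: int = 25,
) -> SimScenario:
    """ILS only: asymmetric species tree, no gene flow, no hybrid."""
    return SimScenario(
        ingroup=DEFAULT_INGROUP,
        outgroup=DEFAULT_OUTGROUP,
        topology=DEFAULT_TOPOLOGY,
        t_internal=t_internal,
        chromosomes=default_chromosomes(total_sites, n_chromosomes),
        seed=seed,
    )


def introgression_scenario(
    total_sites: int = 500_000,
    rate: float = 0.3,
    t_internal: float = 1.0,
    seed: int = 0,
    n_chromosomes: int = 25,
    profile: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SimScenario:
    """Telomere-restricted introgression from the third lineage (aesculapii)
    into a cherry lineage (kyathit), logistic retention by default."""
    return SimScenario(
        ingroup=DEFAULT_INGROUP,
        outgroup=DEFAULT_OUTGROUP,
        topology=DEFAULT_TOPOLOGY,
        t_internal=t_internal,
        chromosomes=default_chromosomes(total_sites, n_chromosomes),
        introgression=(
            IntrogressionEdge("aesculapii", "kyathit", rate, profile=profile),
        ),
        seed=seed,
    )


def hybrid_scenario(
    gamma: float = 0.5,
    total_sites: int = 200_000,
    t_internal: float = 0.5,
    seed: int = 0,
    n_chromosomes: int = 25,
) -> SimScenario:
    """Homoploid hybrid speciation: rerio is a mosaic of the kyathit (gamma)
    and aesculapii (1 - gamma) lineages.

    The default internal branch T = 0.5 puts the model in the regime where
    each hybrid-parent split class is roughly twice as frequent as the
    parents-exclusive class — the diagnostic excess that separates HHS from
    balanced ILS.
    """
    return SimScenario(
        ingroup=DEFAULT_INGROUP,
        outgroup=DEFAULT_OUTGROUP,
        topology=DEFAULT_TOPOLOGY,
        t_internal=t_internal,
        chromosomes=default_chromosomes(total_sites, n_chromosomes),
        hybrid=HybridSpec("rerio", "kyathit", "aesculapii", gamma),
        seed=seed,
    )


def uniform_split_null(
    total_sites: int,
    seed: int = 0,
    ingroup: Sequence[str] = DEFAULT_INGROUP,
    n_chromosomes: int = 25,
) -> pd.DataFrame:
    """Sites whose pairwise-split codes are multinomial(1/6 each): the
    equal-relatedness null for enrichment calibration."""
    chroms = default_chromosomes(total_sites, n_chromosomes)
    rng = np.random.default_rng(seed)
    codes6 = pair_codes(ingroup)
    idx = {t: i for i, t in enumerate(ingroup)}
    pair_masks = np.array(
        [(1 << idx[a]) | (1 << idx[b]) for a, b in
         [tuple(c.split("+")) for c in codes6]],
        dtype=np.int8,
    )
    frames = []
    for ch in chroms:
        pos = _draw_positions(rng, ch.length, ch.n_sites)
        pick = rng.integers(0, 6, size=ch.n_sites)
        masks = pair_masks[pick]
        st = ((masks[:, None] >> np.arange(4, dtype=np.int8)) & 1).astype(np.int8)
        frame = pd.DataFrame({"chrom": np.repeat(ch.name, ch.n_sites), "pos": pos})
        for i, t in enumerate(ingroup):
            frame[t] = st[:, i]
        frame["split"] = np.array(codes6, dtype=object)[pick]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def introgression_truth_intervals(
    scenario: SimScenario, min_pair_prob: float, edge_index: int = 0
) -> dict[str, list[tuple[int, int]]]:
    """Chromosome-end intervals where the introgressed (recipient, donor) pair
    is expected above ``min_pair_prob``.

    Inverts the retention profile numerically: with retention rho(r), the
    expected (recipient, donor)-pair probability is
    rho * (1 - (2/3) e^-T) + (1 - rho) * (1/3) e^-T; the interval is the set
    of folded coordinates where this exceeds the threshold, mapped back to bp
    at both chromosome ends.  Assumes retention non-increasing in the folded
    coordinate (telomere-concentrated).
    """
    edge = scenario.introgression[edge_index]
    e_t = math.exp(-scenario.t_internal) if math.isfinite(scenario.t_internal) else 0.0
    c1 = 1.0 - (2.0 / 3.0) * e_t
    c0 = (1.0 / 3.0) * e_t
    grid = np.linspace(0.0, 1.0, 100_001)
    p = edge.retention(grid) * c1 + (1.0 - edge.retention(grid)) * c0
    above = p >= min_pair_prob
    out: dict[str, list[tuple[int, int]]] = {}
    if not above.any():
        return {c.name: [] for c in scenario.chromosomes}
    r_star = float(grid[above][-1])  # largest folded coordinate still detectable
    for c in scenario.chromosomes:
        half = r_star * c.length / 2.0
        left = (1, int(math.floor(1 + half)))
        right = (int(math.ceil(c.length - half)), c.length)
        if above.all():
            out[c.name] = [(1, c.length)]
        else:
            out[c.name] = [left, right]
    return out
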