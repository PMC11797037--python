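"""Plain-text ``key = value`` configuration for scenarios and pipeline runs.

Two config kinds share one syntax: a *scenario* config describing the
synthetic genome (taxa, newick tree, coalescent branch length, chromosome
map, gene-flow events, seed) and a *run* config describing the analysis
(taxon roles, window sizes, alpha, seed).  Lines starting with ``#`` are
comments; later keys override earlier ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy

from . import sim
from .dstat import TripletSpec


class ConfigError(ValueError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


def parse_kv(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def parse_newick_quartet(s: str) -> tuple:
    """Parse a rooted quartet newick string to the nested-tuple topology."""
    if not s.endswith(";"):
        s = s + ";"
    tree = dendropy.Tree.get(data=s, schema="newick")

    def nest(node):
        if node.is_leaf():
            return node.taxon.label.replace(" ", "_")
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ConfigError("tree must be binary and rooted")
        return (nest(kids[0]), nest(kids[1]))

    return nest(tree.seed_node)


def _parse_profile(spec_parts: list[str], rate: float):
    if not spec_parts or spec_parts[0] == "logistic":
        args = [float(x) for x in spec_parts[1:]]
        if len(args) == 0:
            return sim.LogisticRetention(rate)
        if len(args) == 2:
            return sim.LogisticRetention(rate, r0=args[0], scale=args[1])
        raise ConfigError("logistic profile takes 0 or 2 parameters (r0, scale)")
    if spec_parts[0] == "constant":
        return sim.ConstantRetention(rate)
    raise ConfigError(f"unknown retention profile {spec_parts[0]!r}")


def scenario_from_config(text: str, seed: int | None = None) -> sim.SimScenario:
    kv = parse_kv(text)
    try:
        ingroup = tuple(t.strip() for t in kv["ingroup"].split(","))
        outgroup = kv.get("outgroup", "outgroup").strip()
        topology = parse_newick_quartet(kv["tree"])
        t_internal = float(kv.get("t_internal", "1.0"))
    except KeyError as e:
        raise ConfigError(f"missing required scenario key: {e.args[0]}") from None

    if "chromosomes" in kv:
        chroms = []
        for part in kv["chromosomes"].split(","):
            name, length, n_sites = part.strip().split(":")
            chroms.append(sim.Chromosome(name, int(length), int(n_sites)))
        chromosomes = tuple(chroms)
    else:
        total = int(kv.get("total_sites", "100000"))
        n_chrom = int(kv.get("n_chromosomes", "25"))
        chromosomes = sim.default_chromosomes(total, n_chrom)

    edges = []
    if kv.get("introgression"):
        for part in kv["introgression"].split(","):
            head, *prof = part.strip().split(":")
            rate = float(prof[0]) if prof else 0.0
            if ">" not in head:
                raise ConfigError("introgression syntax: donor>recipient:rate[:profile...]")
            donor, recipient = (x.strip() for x in head.split(">", 1))
            edges.append(
                sim.IntrogressionEdge(donor, recipient, rate, profile=_parse_profile(prof[1:], rate))
            )

    hybrid = None
    if kv.get("hybrid"):
        parts = kv["hybrid"].split(":")
        if len(parts) != 4:
            raise ConfigError("hybrid syntax: hybrid:parent1:parent2:gamma")
        hybrid = sim.HybridSpec(parts[0].strip(), parts[1].strip(), parts[2].strip(), float(parts[3]))

    try:
        return sim.SimScenario(
            ingroup=ingroup,  # type: ignore[arg-type]
            outgroup=outgroup,
            topology=topology,
            t_internal=t_internal,
            chromosomes=chromosomes,
            introgression=tuple(edges),
            hybrid=hybrid,
            singleton_rate=float(kv.get("singleton_rate", "0")),
            triple_rate=float(kv.get("triple_rate", "0")),
            seed=int(kv["seed"]) if seed is None and "seed" in kv else (seed or 0),
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e


def scenario_to_config(scenario: sim.SimScenario) -> str:
    def newick(t):
        return t if isinstance(t, str) else f"({newick(t[0])},{newick(t[1])})"

    lines = [
        f"ingroup = {','.join(scenario.ingroup)}",
        f"outgroup = {scenario.outgroup}",
        f"tree = {newick(scenario.topology)};",
        f"t_internal = {scenario.t_internal}",
        "chromosomes = "
        + ",".join(f"{c.name}:{c.length}:{c.n_sites}" for c in scenario.chromosomes),
    ]
    if scenario.introgression:
        parts = []
        for e in scenario.introgression:
            prof = e.profile if e.profile is not None else sim.LogisticRetention(e.rate)
            if isinstance(prof, sim.LogisticRetention):
                parts.append(f"{e.donor}>{e.recipient}:{e.rate}:logistic:{prof.r0}:{prof.scale}")
            elif isinstance(prof, sim.ConstantRetention):
                parts.append(f"{e.donor}>{e.recipient}:{e.rate}:constant")
            else:
                raise ConfigError("tabulated retention profiles cannot be serialised yet")
        lines.append("introgression = " + ",".join(parts))
    if scenario.hybrid is not None:
        h = scenario.hybrid
        lines.append(f"hybrid = {h.hybrid}:{h.parent1}:{h.parent2}:{h.gamma}")
    if scenario.singleton_rate:
        lines.append(f"singleton_rate = {scenario.singleton_rate}")
    if scenario.triple_rate:
        lines.append(f"triple_rate = {scenario.triple_rate}")
    lines.append(f"seed = {scenario.seed}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration shared by the pipeline stages.

    The windowing defaults (200 ABBA/BABA sites for D, 500 pairwise splits
    stepping by 10, 10 folded bins) are the standard operating point of this
    analysis style.  Site filters default to off here because simulated
    input emulates already-filtered variants; ``polarize.apply_site_filters``
    itself defaults to the conventional 5x / 3-SNPs-in-10-bp rule for real
    call sets.
    """

    ingroup: tuple[str, str, str, str]
    outgroups: tuple[str, ...]
    triplets: tuple[TripletSpec, ...] = ()
    hybrid_roles: tuple[str, str, str] | None = None  # (hybrid, parent1, parent2)
    d_window: int = 200
    split_window: int = 500
    split_step: int = 10
    n_bins: int = 10
    alpha: float = 0.001
    bonferroni: bool = False
    level: float = 0.95
    min_region_windows: int = 10
    min_depth: int = 0
    snp_cluster_window: int = 10
    snp_cluster_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(self.ingroup) != 4 or len(set(self.ingroup)) != 4:
            raise ConfigError("ingroup must be 4 unique taxa")
        if not self.outgroups:
            raise ConfigError("at least one outgroup is required")
        if set(self.ingroup) & set(self.outgroups):
            raise ConfigError("taxon roles must be disjoint")
        for w in (self.d_window, self.split_window, self.split_step, self.n_bins):
            if w < 1:
                raise ConfigError("window sizes must be >= 1")
        for t in self.triplets:
            for x in (t.p1, t.p2, t.p3):
                if x not in self.ingroup:
                    raise ConfigError(f"triplet taxon {x!r} not in ingroup")
        if self.hybrid_roles is not None:
            if len(set(self.hybrid_roles)) != 3 or any(
                x not in self.ingroup for x in self.hybrid_roles
            ):
                raise ConfigError("hybrid roles must be 3 distinct ingroup taxa")


def runconfig_from_config(text: str, seed: int | None = None) -> RunConfig:
    kv = parse_kv(text)
    try:
        ingroup = tuple(t.strip() for t in kv["ingroup"].split(","))
        outgroups = tuple(t.strip() for t in kv["outgroups"].split(","))
    except KeyError as e:
        raise ConfigError(f"missing required run key: {e.args[0]}") from None
    triplets = []
    if kv.get("triplets"):
        for part in kv["triplets"].split(";"):
            p = [x.strip() for x in part.split(":")]
            if len(p) != 3:
                raise ConfigError("triplet syntax: p1:p2:p3[;p1:p2:p3...]")
            triplets.append(TripletSpec(*p))
    hybrid_roles = None
    if kv.get("hybrid_roles"):
        p = [x.strip() for x in kv["hybrid_roles"].split(":")]
        if len(p) != 3:
            raise ConfigError("hybrid_roles syntax: hybrid:parent1:parent2")
        hybrid_roles = (p[0], p[1], p[2])
    try:
        return RunConfig(
            ingroup=ingroup,  # type: ignore[arg-type]
            outgroups=outgroups,
            triplets=tuple(triplets),
            hybrid_roles=hybrid_roles,
            d_window=int(kv.get("d_window", "200")),
            split_window=int(kv.get("split_window", "500")),
            split_step=int(kv.get("split_step", "10")),
            n_bins=int(kv.get("n_bins", "10")),
            alpha=float(kv.get("alpha", "0.001")),
            bonferroni=kv.get("bonferroni", "false").lower() in ("1", "true", "yes"),
            level=float(kv.get("level", "0.95")),
            min_region_windows=int(kv.get("min_region_windows", "10")),
            min_depth=int(kv.get("min_depth", "0")),
            snp_cluster_window=int(kv.get("snp_cluster_window", "10")),
            snp_cluster_count=int(kv.get("snp_cluster_count", "0")),
            seed=int(kv["seed"]) if seed is None and "seed" in kv else (seed or 0),
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]
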