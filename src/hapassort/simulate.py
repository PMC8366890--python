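"""Coalescent synthetic-data generator.

Emulates the study system: two deeply diverged mitochondrial lineages
("northern" and "southern") sampled from Florida-Keys-like sites in
three habitat classes, with a tunable lineage-habitat assortment
strength.  Time is measured in expected substitutions per site
throughout, so the divergence time ``tau`` and the within-lineage
diversity ``theta`` compose additively into expected pairwise
distances: within a lineage E[d] = theta, between lineages
E[d] = 2*tau + theta_anc (before finite-sites saturation).

The generative model, stage by stage:

1. ``draw_lineages`` — each individual is northern with probability
   (1 + alpha)/2 in inshore habitats (inshore reef, grass bed),
   (1 - alpha)/2 offshore, and 1/2 elsewhere.  alpha = 0 is random
   placement (the study's empirical finding); alpha = 1 is complete
   habitat segregation (the ecological-speciation hypothesis).
2. ``simulate_genealogy`` — a Kingman coalescent within each lineage
   (pairwise coalescence rate 2/theta) until ``tau``, when the
   surviving lineages merge into one ancestral pool with rate
   2/theta_anc.
3. ``sprinkle_mutations`` — finite-sites Jukes-Cantor mutations:
   Poisson(L * branch length) mutations per branch, each hitting a
   uniform site and substituting a uniform different base.

All randomness flows from a single seeded generator, so identical
config and seed reproduce the dataset bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import Alignment, Dataset, HABITATS, MetadataTable, make_dataset
from .trees import UltrametricTree, build_tree_from_heights

BASES = np.array(list("ACGT"))

#: habitats in which the northern lineage is favoured when alpha > 0
INSHORE_HABITATS = ("inshore_reef", "grass_bed")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    """One sampling site: name, habitat class, sample size.

    ``n_northern`` forces an exact lineage composition (used for
    benchmark stand-ins built from printed regional frequencies);
    when ``None`` the composition is drawn per ``alpha``.
    """

    name: str
    habitat: str
    n: int
    region: str = "florida_keys"
    n_northern: int | None = None

    def __post_init__(self):
        if self.habitat not in HABITATS:
            raise SimulationError(f"habitat {self.habitat!r} not in {HABITATS}")
        if self.n < 1:
            raise SimulationError("site sample size must be >= 1")
        if self.n_northern is not None and not 0 <= self.n_northern <= self.n:
            raise SimulationError("n_northern must lie in [0, n]")


# Default Keys design: 8 sites in three habitat classes, 78 samples
# total, uneven sizes including a singleton grass-bed site (KML, n=1)
# and a small offshore site (XMuta, n=4) whose 4-vs-1 comparison the
# site-level permutation analysis exercises.
DEFAULT_SITES: tuple[SiteSpec, ...] = (
    SiteSpec("sombrero", "offshore_reef", 14),
    SiteSpec("elevenfoot", "offshore_reef", 9),
    SiteSpec("xmuta", "offshore_reef", 4),
    SiteSpec("tennessee", "offshore_reef", 16),
    SiteSpec("washerwoman", "inshore_reef", 12),
    SiteSpec("turtleshoal", "inshore_reef", 10),
    SiteSpec("longkey", "grass_bed", 12),
    SiteSpec("kml", "grass_bed", 1),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (time in expected substitutions/site).

    Defaults target the study conditions: a 723-bp fragment, ~5% net
    between-lineage divergence via 2*tau + theta = 0.05, modest
    within-lineage diversity, and random habitat assortment.
    """

    sites: tuple[SiteSpec, ...] = DEFAULT_SITES
    tau: float = 0.0225
    theta: float = 0.005
    theta_anc: float | None = None
    alpha: float = 0.0
    L: int = 723
    seed: int = 0

    def __post_init__(self):
        if self.tau < 0:
            raise SimulationError("tau must be >= 0")
        if self.theta <= 0:
            raise SimulationError("theta must be > 0")
        if self.theta_anc is not None and self.theta_anc <= 0:
            raise SimulationError("theta_anc must be > 0")
        if not 0 <= self.alpha <= 1:
            raise SimulationError("alpha must lie in [0, 1]")
        if self.L < 1:
            raise SimulationError("fragment length must be >= 1")
        if self.total_n < 2:
            raise SimulationError("need at least 2 samples in total")
        names = [s.name for s in self.sites]
        if len(names) != len(set(names)):
            raise SimulationError("site names must be unique")

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.sites)

    @property
    def theta_ancestral(self) -> float:
        return self.theta if self.theta_anc is None else self.theta_anc


@dataclass(frozen=True)
class SimResult:
    dataset: Dataset
    genealogy: UltrametricTree
    config: SimConfig = field(repr=False)


def _sample_ids(config: SimConfig) -> list[tuple[str, SiteSpec]]:
    out = []
    for site in config.sites:
        for i in range(site.n):
            out.append((f"{site.name}-{i + 1:02d}", site))
    return out


def draw_lineages(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Per-sample lineage labels under the assortment model."""
    labels: dict[str, str] = {}
    for site in config.sites:
        ids = [f"{site.name}-{i + 1:02d}" for i in range(site.n)]
        if site.n_northern is not None:
            is_north = np.zeros(site.n, dtype=bool)
            is_north[rng.permutation(site.n)[: site.n_northern]] = True
        else:
            if site.habitat in INSHORE_HABITATS:
                p_north = (1 + config.alpha) / 2
            elif site.habitat == "offshore_reef":
                p_north = (1 - config.alpha) / 2
            else:
                p_north = 0.5
            is_north = rng.random(site.n) < p_north
        for sid, north in zip(ids, is_north):
            labels[sid] = "northern" if north else "southern"
    return labels


def _coalesce_pool(
    pool: list[tuple[float, object]],
    theta: float,
    t: float,
    stop: float,
    rng: np.random.Generator,
    merges: list,
) -> tuple[list[tuple[float, object]], float]:
    """Run a Kingman coalescent on ``pool`` from time ``t`` until ``stop``.

    Pool entries are ``(height, node_ref)``; pairwise rate is 2/theta.
    Returns the surviving pool and the current time.
    """
    pool = list(pool)
    while len(pool) > 1:
        k = len(pool)
        rate = k * (k - 1) / theta
        wait = rng.exponential(1.0 / rate)
        if t + wait > stop:
            return pool, stop
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a = pool.pop(j)
        b = pool.pop(i)
        merges.append((t, a[1], b[1]))
        pool.append((t, len(merges) - 1))
    return pool, t


def simulate_genealogy(
    lineage_labels: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> UltrametricTree:
    """Two-population coalescent genealogy for the labelled samples.

    Within-lineage pairwise coalescence rate is 2/theta (so the
    expected within-lineage pairwise tree distance is theta); at time
    ``tau`` the survivors of both lineages merge into one ancestral
    pool with rate 2/theta_anc.
    """
    ids = sorted(lineage_labels)
    if len(ids) < 2:
        raise SimulationError("need at least 2 samples for a genealogy")
    merges: list = []
    pools = {}
    for lineage in ("northern", "southern"):
        members = [s for s in ids if lineage_labels[s] == lineage]
        pools[lineage] = [(0.0, s) for s in members]
    t_n = t_s = 0.0
    if pools["northern"]:
        pools["northern"], t_n = _coalesce_pool(
            pools["northern"], config.theta, 0.0, config.tau, rng, merges
        )
    if pools["southern"]:
        pools["southern"], t_s = _coalesce_pool(
            pools["southern"], config.theta, 0.0, config.tau, rng, merges
        )
    ancestral = pools["northern"] + pools["southern"]
    ancestral, _ = _coalesce_pool(
        ancestral, config.theta_ancestral, config.tau, math.inf, rng, merges
    )
    return build_tree_from_heights(merges, ids)


def sprinkle_mutations(
    tree: UltrametricTree, config: SimConfig, rng: np.random.Generator
) -> Alignment:
    """Finite-sites JC69 mutations along the genealogy -> gap-free alignment."""
    L = config.L
    root = tree.dendropy_tree.seed_node
    root_seq = rng.integers(0, 4, size=L).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {}

    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            blen = float(node.height - child.height)
            child_seq = seq.copy()
            n_mut = rng.poisson(L * blen)
            for _ in range(n_mut):
                site = rng.integers(0, L)
                # uniform different base
                child_seq[site] = (child_seq[site] + rng.integers(1, 4)) % 4
            stack.append((child, child_seq))
        if node.is_leaf():
            seqs[node.taxon.label] = seq

    ids = sorted(seqs)
    matrix = np.array([BASES[seqs[s]] for s in ids], dtype="<U1")
    return Alignment(tuple(ids), matrix)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Compose lineage draw -> genealogy -> mutations into a full dataset."""
    rng = np.random.default_rng(config.seed)
    labels = draw_lineages(config, rng)
    tree = simulate_genealogy(labels, config, rng)
    alignment = sprinkle_mutations(tree, config, rng)
    records = []
    for sid, site in _sample_ids(config):
        records.append(
            {
                "sample_id": sid,
                "site": site.name,
                "habitat": site.habitat,
                "region": site.region,
                "lineage_truth": labels[sid],
            }
        )
    records.sort(key=lambda r: r["sample_id"])
    metadata = MetadataTable.from_records(records)
    return SimResult(make_dataset(alignment, metadata), tree, config)


def synthetic_benchmark_config(seed: int = 0) -> SimConfig:
    """Synthetic stand-in for the deposited study alignment.

    The real benchmark alignment must be supplied by the user (it is
    not redistributed here); this config generates a synthetic dataset
    with the study's regional design so benchmark-shaped analyses can
    be exercised end to end: the 8-site / 78-sample Keys design with
    random lineage-habitat assortment, a 40-sample Bahamas region
    dominated by the southern lineage with exactly one northern
    individual (an archival record without fine-scale locality, hence
    habitat ``other``), two northern-lineage Gulf Coast sites, and one
    southern-lineage Belize site.  Regional lineage compositions are
    simulator inputs; everything downstream (assignment, frequencies,
    divergence, delimitation) is recomputed from the sequences.
    """
    extra = (
        SiteSpec("bahamas-a", "other", 20, region="bahamas", n_northern=1),
        SiteSpec("bahamas-b", "other", 20, region="bahamas", n_northern=0),
        SiteSpec("gulf-a", "other", 5, region="gulf_coast", n_northern=5),
        SiteSpec("gulf-b", "other", 5, region="gulf_coast", n_northern=5),
        SiteSpec("belize", "other", 5, region="belize", n_northern=0),
    )
    return SimConfig(sites=DEFAULT_SITES + extra, seed=seed)


# ----------------------------------------------------------------------
# Calibration harness


def estimate_error_rates(
    config: SimConfig,
    replicates: int,
    nominal_level: float = 0.05,
    n_perm: int = 199,
    include_gmyc: bool = True,
    allele_mode: str = "haplotype",
) -> dict:
    """Rejection-rate summary over simulated replicates.

    For each replicate the habitat-pooled pairwise permutation test
    (and optionally the GMYC likelihood-ratio test) is run on a fresh
    simulated dataset; reported are the fraction of replicates with any
    habitat-pair p <= level (raw and Holm-adjusted), the per-pair
    rejection fraction, and the GMYC rejection fraction, each with a
    binomial standard error.
    """
    from . import gmyc as gmyc_mod
    from . import lineages as lineages_mod
    from . import popgen
    from .distances import distance_matrix

    if replicates < 1:
        raise SimulationError("replicates must be >= 1")

    seeds = np.random.SeedSequence(config.seed).generate_state(replicates)
    any_raw = np.zeros(replicates, dtype=bool)
    any_holm = np.zeros(replicates, dtype=bool)
    pair_flat: list[bool] = []
    gmyc_rej = np.zeros(replicates, dtype=bool)
    for r in range(replicates):
        rep_cfg = replace(config, seed=int(seeds[r] % (2**31)))
        sim = simulate_dataset(rep_cfg)
        grouping = popgen.habitat_grouping(sim.dataset)
        table = popgen.pairwise_analysis(
            sim.dataset,
            grouping,
            allele_mode=allele_mode,
            n_perm=n_perm,
            seed=rep_cfg.seed,
        )
        pvals = table["p_value"].to_numpy()
        any_raw[r] = bool((pvals <= nominal_level).any())
        any_holm[r] = bool((popgen.holm_adjust(pvals) <= nominal_level).any())
        pair_flat.extend(p <= nominal_level for p in pvals)
        if include_gmyc:
            dm = distance_matrix(sim.dataset.alignment, "jc69")
            tree = lineages_mod.upgma(dm)
            fit = gmyc_mod.fit_gmyc(tree)
            gmyc_rej[r] = fit.p_value <= nominal_level

    def rate_se(flags):
        n = len(flags)
        rate = float(np.mean(flags)) if n else float("nan")
        se = math.sqrt(rate * (1 - rate) / n) if n else float("nan")
        return rate, se

    out = {
        "replicates": replicates,
        "nominal_level": nominal_level,
        "n_perm": n_perm,
    }
    for key, flags in (
        ("habitat_any_raw", any_raw),
        ("habitat_any_holm", any_holm),
        ("habitat_per_pair", np.array(pair_flat, dtype=bool)),
    ):
        rate, se = rate_se(flags)
        out[key] = {"rate": rate, "se": se, "n": int(len(flags))}
    if include_gmyc:
        rate, se = rate_se(gmyc_rej)
        out["gmyc"] = {"rate": rate, "se": se, "n": replicates}
    return out
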