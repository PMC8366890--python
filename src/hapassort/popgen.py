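"""Pairwise Nei Fst between groups and the fixed-sample-size permutation null.

The mitochondrial fragment is a single non-recombining locus, so the
alleles are whole haplotypes (default) or the two deep lineage classes.
Differentiation between two groups is measured as Fst = 1 - Hs/Ht with

    h_k  = gene diversity of group k (1 - sum p_ki^2, bias-corrected by
           n_k/(n_k - 1) when every group has n >= 2; with a singleton
           group the plug-in form is used throughout for comparability)
    Hs   = (h_1 + h_2) / 2
    Ht   = 1 - sum(pbar_i^2) + Hs / (2 * ntilde),  ntilde = harmonic
           mean of the two sample sizes
    pbar = per-allele mean of the two group frequencies

Significance comes from the permutation scheme of the study: samples
are reshuffled between the two groups keeping group sizes fixed; when
the number of distinct assignments C(n1+n2, n1) is small the null is
enumerated exhaustively, otherwise Monte-Carlo with the add-one
convention p = (1 + #{perm >= obs}) / (1 + n_perm).  The test is
one-sided (large Fst = differentiation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd

from .lineages import LineageAssignment, collapse_haplotypes
from .seqio import Dataset

log = logging.getLogger(__name__)

ESTIMATOR_VARIANT = "nei-chesser-pairwise;plug-in-when-singleton"
EXHAUSTIVE_CAP = 100_000

_FST_TIE_TOL = 1e-12


class PopgenError(ValueError):
    pass


# ----------------------------------------------------------------------
# Groupings


@dataclass(frozen=True)
class Grouping:
    """Disjoint groups of sample ids, keyed by group label."""

    members: dict[str, tuple[str, ...]]
    kind: str = "custom"

    def __post_init__(self):
        seen: set[str] = set()
        for label, ids in self.members.items():
            overlap = seen & set(ids)
            if overlap:
                raise PopgenError(f"sample(s) {sorted(overlap)} in multiple groups")
            seen |= set(ids)

    @property
    def labels(self) -> list[str]:
        return list(self.members)

    def sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.members.items()}


def habitat_grouping(dataset: Dataset, include_other: bool = False) -> Grouping:
    """Pool sites by habitat class (the study's pooled analysis).

    Samples with habitat ``other`` (e.g. archival records without
    fine-scale locality) are excluded unless ``include_other``.
    """
    df = dataset.metadata.table
    members: dict[str, tuple[str, ...]] = {}
    for habitat, sub in df.groupby("habitat", sort=True):
        if habitat == "other" and not include_other:
            continue
        members[str(habitat)] = tuple(sub["sample_id"])
    return Grouping(members, kind="habitat")


def site_grouping(dataset: Dataset) -> Grouping:
    """One group per sampling site (the study's unpooled analysis)."""
    df = dataset.metadata.table
    members = {
        str(site): tuple(sub["sample_id"])
        for site, sub in df.groupby("site", sort=True)
    }
    return Grouping(members, kind="site")


def region_grouping(dataset: Dataset) -> Grouping:
    df = dataset.metadata.table
    members = {
        str(r): tuple(sub["sample_id"]) for r, sub in df.groupby("region", sort=True)
    }
    return Grouping(members, kind="region")


# ----------------------------------------------------------------------
# Allele counts


def sample_alleles(
    dataset: Dataset,
    allele_mode: str = "haplotype",
    assignment: LineageAssignment | None = None,
) -> dict[str, int]:
    """Integer allele code per sample.

    ``haplotype`` mode treats each distinct sequence as one allele;
    ``lineage`` mode uses the two deep lineage classes, taken from the
    supplied assignment or, failing that, from simulated
    ``lineage_truth`` metadata.
    """
    if allele_mode == "haplotype":
        haps = collapse_haplotypes(dataset.alignment)
        order = {h: i for i, h in enumerate(sorted(haps.sequences, key=lambda x: int(x[1:])))}
        return {s: order[h] for s, h in haps.haplotype_of().items()}
    if allele_mode == "lineage":
        if assignment is not None:
            labels = assignment.labels
        elif dataset.metadata.has_lineage_truth:
            labels = dict(
                zip(
                    dataset.metadata.table["sample_id"],
                    dataset.metadata.table["lineage_truth"],
                )
            )
        else:
            raise PopgenError("lineage allele mode needs an assignment or lineage_truth")
        return {s: (0 if labels[s] == "northern" else 1) for s in dataset.sample_ids}
    raise PopgenError(f"unknown allele_mode {allele_mode!r}")


def allele_counts(
    dataset: Dataset,
    grouping: Grouping,
    allele_mode: str = "haplotype",
    assignment: LineageAssignment | None = None,
) -> dict[str, np.ndarray]:
    """Per-group allele count vectors over the union allele set (zero-padded)."""
    alleles = sample_alleles(dataset, allele_mode, assignment)
    n_alleles = max(alleles.values()) + 1
    out: dict[str, np.ndarray] = {}
    for label, ids in grouping.members.items():
        if not ids:
            log.warning("dropping empty group %r", label)
            continue
        codes = np.array([alleles[s] for s in ids])
        out[label] = np.bincount(codes, minlength=n_alleles)
    return out


# ----------------------------------------------------------------------
# Nei Fst


@dataclass(frozen=True)
class FstResult:
    group1: str
    group2: str
    n1: int
    n2: int
    fst: float
    hs: float
    ht: float
    p_value: float | None = None
    n_perm: int | None = None
    exhaustive: bool | None = None
    degenerate: bool = False


def nei_fst_pair(counts1: np.ndarray, counts2: np.ndarray) -> tuple[float, float, float]:
    """Pairwise Nei Fst from two allele-count vectors -> (fst, hs, ht)."""
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    n1, n2 = c1.sum(), c2.sum()
    if n1 < 1 or n2 < 1:
        raise PopgenError("both groups must be nonempty")
    p1, p2 = c1 / n1, c2 / n2
    h1 = 1.0 - float(p1 @ p1)
    h2 = 1.0 - float(p2 @ p2)
    if min(n1, n2) >= 2:
        h1 *= n1 / (n1 - 1)
        h2 *= n2 / (n2 - 1)
    hs = 0.5 * (h1 + h2)
    pbar = 0.5 * (p1 + p2)
    ntilde = 2.0 / (1.0 / n1 + 1.0 / n2)
    ht = 1.0 - float(pbar @ pbar) + hs / (2.0 * ntilde)
    if ht <= 0.0:
        return 0.0, hs, ht
    return 1.0 - hs / ht, hs, ht


def _fst_of_split(codes: np.ndarray, idx1: np.ndarray, n_alleles: int) -> float:
    mask = np.zeros(len(codes), dtype=bool)
    mask[idx1] = True
    c1 = np.bincount(codes[mask], minlength=n_alleles)
    c2 = np.bincount(codes[~mask], minlength=n_alleles)
    return nei_fst_pair(c1, c2)[0]


# ----------------------------------------------------------------------
# Permutation test


def permutation_test_pair(
    alleles: np.ndarray,
    n1: int,
    n2: int,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> tuple[float, int, bool, bool]:
    """One-sided permutation p-value for the Fst of a two-group split.

    ``alleles`` holds integer allele codes for the pooled sample in
    observed order: the first ``n1`` entries are group 1.  Returns
    ``(p_value, n_used, exhaustive, degenerate)``.
    """
    codes = np.asarray(alleles)
    n = len(codes)
    if n != n1 + n2:
        raise PopgenError("n1 + n2 must equal the pooled sample size")
    if n1 < 1 or n2 < 1:
        raise PopgenError("both group sizes must be >= 1")
    n_alleles = int(codes.max()) + 1
    if n_alleles == 1:
        return 1.0, 0, True, True  # monomorphic pool: nothing to permute

    observed = _fst_of_split(codes, np.arange(n1), n_alleles)
    total = comb(n, n1)
    if total <= exhaustive_cap:
        hits = 0
        for idx in combinations(range(n), n1):
            if _fst_of_split(codes, np.array(idx), n_alleles) >= observed - _FST_TIE_TOL:
                hits += 1
        return hits / total, total, True, False
    if n_perm < 1:
        raise PopgenError("n_perm must be >= 1 for Monte-Carlo mode")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)[:n1]
        if _fst_of_split(codes, perm, n_alleles) >= observed - _FST_TIE_TOL:
            hits += 1
    return (1 + hits) / (1 + n_perm), n_perm, False, False


# ----------------------------------------------------------------------
# All-pairs analysis


def pairwise_analysis(
    dataset: Dataset,
    grouping: Grouping,
    allele_mode: str = "haplotype",
    n_perm: int = 9999,
    seed: int = 0,
    assignment: LineageAssignment | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> pd.DataFrame:
    """Fst estimate + permutation p for every unordered pair of groups."""
    alleles = sample_alleles(dataset, allele_mode, assignment)
    groups = {g: ids for g, ids in grouping.members.items() if ids}
    if len(groups) < 2:
        raise PopgenError("need at least 2 nonempty groups")
    rng = np.random.default_rng(seed)
    rows = []
    labels = sorted(groups)
    for g1, g2 in combinations(labels, 2):
        ids1, ids2 = groups[g1], groups[g2]
        codes = np.array([alleles[s] for s in (*ids1, *ids2)])
        codes = _compress_codes(codes)
        n1, n2 = len(ids1), len(ids2)
        n_alleles = int(codes.max()) + 1
        c1 = np.bincount(codes[:n1], minlength=n_alleles)
        c2 = np.bincount(codes[n1:], minlength=n_alleles)
        fst, hs, ht = nei_fst_pair(c1, c2)
        p, n_used, exhaustive, degenerate = permutation_test_pair(
            codes, n1, n2, n_perm=n_perm, seed=rng, exhaustive_cap=exhaustive_cap
        )
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "n1": n1,
                "n2": n2,
                "fst": fst,
                "hs": hs,
                "ht": ht,
                "p_value": p,
                "n_perm": n_used,
                "exhaustive": exhaustive,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _compress_codes(codes: np.ndarray) -> np.ndarray:
    """Relabel allele codes to a dense 0..K-1 range for the pooled pair."""
    _, inv = np.unique(codes, return_inverse=True)
    return inv


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ----------------------------------------------------------------------
# Frequency tables


def frequency_table(
    dataset: Dataset,
    assignment: LineageAssignment,
    grouping: Grouping,
) -> pd.DataFrame:
    """Per-group lineage counts and proportions (map-figure analogue)."""
    rows = []
    for label, ids in grouping.members.items():
        n = len(ids)
        n_north = sum(1 for s in ids if assignment.labels[s] == "northern")
        rows.append(
            {
                "group": label,
                "n": n,
                "n_northern": n_north,
                "n_southern": n - n_north,
                "prop_northern": n_north / n if n else float("nan"),
                "prop_southern": (n - n_north) / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
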