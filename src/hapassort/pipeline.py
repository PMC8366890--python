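"""End-to-end orchestration: dataset -> machine-readable report.

The report mirrors the study's result structure: lineage frequency
tables per site/habitat/region, pairwise Fst matrices with permutation
p-values (habitat-pooled and site-level), a GMYC summary, the
between-lineage divergence headline (under both p and TN93 distances),
the haplotype-network edge list, and a provenance block sufficient to
regenerate every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distances import between_group_divergence, distance_matrix
from .gmyc import fit_gmyc
from .lineages import assign_lineages, build_network, collapse_haplotypes, upgma
from .popgen import (
    ESTIMATOR_VARIANT,
    frequency_table,
    habitat_grouping,
    holm_adjust,
    pairwise_analysis,
    region_grouping,
    site_grouping,
)
from .seqio import Dataset

log = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    allele_mode: str = "haplotype"
    model: str = "tn93"
    n_perm: int = 9999
    seed: int = 0
    gmyc_df: int = 3
    pooling: bool = True
    site_level: bool = True
    anchors: tuple[frozenset, frozenset] | None = None
    holm: bool = False
    outdir: str | None = None

    def __post_init__(self):
        if self.n_perm < 99:
            raise PipelineError("n_perm must be >= 99 in analyze mode")
        if self.gmyc_df not in (2, 3):
            raise PipelineError("gmyc_df must be 2 or 3")


def _anchors_from_truth(dataset: Dataset):
    """One known-northern and one known-southern sample, if truth exists."""
    if not dataset.metadata.has_lineage_truth:
        return None
    df = dataset.metadata.table
    north = df.loc[df["lineage_truth"] == "northern", "sample_id"]
    south = df.loc[df["lineage_truth"] == "southern", "sample_id"]
    if north.empty or south.empty:
        return None
    return frozenset([north.iloc[0]]), frozenset([south.iloc[0]])


def analyze(dataset: Dataset, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run the full analysis; stage failures are recorded, not fatal."""
    report: dict = {
        "provenance": {
            "package": "hapassort",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "n_samples": dataset.n_samples,
            "alignment_length": dataset.alignment.length,
            "fst_estimator": ESTIMATOR_VARIANT,
            "network_method": "minimum-spanning-tree (Kruskal, mismatch steps)",
        },
        "notices": [],
        "stage_errors": {},
    }

    def stage(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:  # noqa: BLE001 - per-stage error capture
            log.warning("stage %s failed: %s", name, exc)
            report["stage_errors"][name] = f"{type(exc).__name__}: {exc}"

    # --- haplotypes & network (never needs >= 2 samples of anything)
    haps = collapse_haplotypes(dataset.alignment)
    net = build_network(haps)
    report["haplotypes"] = {
        "n_haplotypes": haps.n_haplotypes,
        "counts": haps.counts,
    }
    report["network"] = {
        "nodes": list(net.nodes),
        "edges": [list(e) for e in net.edges],
        "total_weight": net.total_weight,
    }

    if dataset.n_samples < 2:
        report["notices"].append("fewer than 2 samples: tree stages skipped")
        return report

    # --- distances, tree, lineage assignment
    dm = distance_matrix(dataset.alignment, config.model)
    tree = upgma(dm)
    anchors = config.anchors or _anchors_from_truth(dataset)
    assignment = assign_lineages(tree, anchors)
    report["lineages"] = {
        "labels": dict(sorted(assignment.labels.items())),
        "split_depth": assignment.split_depth,
        "anchor_policy": assignment.anchor_policy,
        "n_northern": len(assignment.northern),
        "n_southern": len(assignment.southern),
    }

    # --- divergence headline under p and tn93 (distance model unnamed upstream)
    def divergence():
        out = {}
        north, south = set(assignment.northern), set(assignment.southern)
        if not north or not south:
            raise PipelineError("one lineage is empty; no between-lineage divergence")
        for model in ("p", "tn93"):
            dmx = dm if dm.model == model else distance_matrix(dataset.alignment, model)
            out[model] = between_group_divergence(dmx, north, south)
        return out

    stage("divergence", divergence)

    # --- frequency tables (map-figure analogues)
    freq = {}
    for kind, grouping in (
        ("habitat", habitat_grouping(dataset, include_other=True)),
        ("site", site_grouping(dataset)),
        ("region", region_grouping(dataset)),
    ):
        freq[kind] = frequency_table(dataset, assignment, grouping).to_dict("records")
    report["frequencies"] = freq

    # --- Fst + permutation tests
    def fst_stage(grouping):
        def run():
            table = pairwise_analysis(
                dataset,
                grouping,
                allele_mode=config.allele_mode,
                n_perm=config.n_perm,
                seed=config.seed,
                assignment=assignment,
            )
            if config.holm:
                table["p_holm"] = holm_adjust(table["p_value"].to_numpy())
            sizes = grouping.sizes()
            return {"group_sizes": sizes, "pairs": table.to_dict("records")}

        return run

    if config.pooling:
        stage("fst_habitat", fst_stage(habitat_grouping(dataset)))
    else:
        report["notices"].append("habitat pooling disabled")
    if config.site_level:
        stage("fst_site", fst_stage(site_grouping(dataset)))

    # --- GMYC species delimitation
    # identical sequences produce zero-length branches that degenerate the
    # mixed-model rates, so delimitation runs on one representative per
    # haplotype (standard GMYC practice)
    hap_reps = [members[0] for members in haps.members.values()]
    if len(hap_reps) >= 3:

        def gmyc_stage():
            rep_dm = distance_matrix(dataset.alignment.subset(sorted(hap_reps)),
                                     config.model)
            rep_tree = upgma(rep_dm)
            fit = fit_gmyc(rep_tree, df=config.gmyc_df)
            return {
                "n_haplotypes_used": len(hap_reps),
                "threshold_height": fit.threshold_height,
                "lambda1": fit.lambda1,
                "p1": fit.p1,
                "lambda2": fit.lambda2,
                "p2": fit.p2,
                "loglik": fit.loglik,
                "lambda0": fit.lambda0,
                "p0": fit.p0,
                "null_loglik": fit.null_loglik,
                "lrt_stat": fit.lrt_stat,
                "p_value": fit.p_value,
                "df": fit.df,
                "n_clusters": fit.n_clusters,
                "entities": sorted(sorted(e) for e in fit.entities),
                "likelihood_form": "interval-survival x total-branching-rate",
            }

        stage("gmyc", gmyc_stage)
    else:
        report["notices"].append("fewer than 3 haplotypes: GMYC stage skipped")

    return report


# ----------------------------------------------------------------------
# Serialization


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write report.json plus the TSV tables; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key, fname in (("fst_habitat", "fst_pairs.tsv"), ("fst_site", "fst_pairs_sites.tsv")):
        if key in report:
            df = pd.DataFrame(report[key]["pairs"]).rename(columns={"p_value": "p"})
            cols = ["group1", "group2", "n1", "n2", "fst", "hs", "ht", "p",
                    "n_perm", "exhaustive"]
            extra = [c for c in df.columns if c not in cols]
            df.to_csv(outdir / fname, sep="\t", index=False, columns=cols + extra)
    if "frequencies" in report:
        rows = []
        for kind, recs in report["frequencies"].items():
            for rec in recs:
                rows.append({"grouping": kind, **rec})
        pd.DataFrame(rows).to_csv(
            outdir / "frequencies.tsv", sep="\t", index=False,
            columns=["grouping", "group", "n", "n_northern", "n_southern",
                     "prop_northern", "prop_southern"],
        )
    if "network" in report:
        pd.DataFrame(
            report["network"]["edges"], columns=["hap1", "hap2", "steps"]
        ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    return outdir
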