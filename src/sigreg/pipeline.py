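"""End-to-end orchestration: counts -> contrasts -> statuses -> regulons,
plus recovery evaluation against a simulator truth table."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd

from . import diffexpr, regulon
from .simulate import PlantedRegulonEffect
from .strains import MUTANT_STRAINS

logger = logging.getLogger(__name__)

#: Planted (sigma, direction) -> expected assignment (label, direction).
#: Losing the factor silences activated targets (down) and derepresses
#: repressed ones (up).
TRUTH_LABEL = {
    ("B", "activated"): ("SigB", "down"),
    ("B", "repressed"): ("SigB", "up"),
    ("D", "activated"): ("SigD", "down"),
    ("D", "repressed"): ("SigD", "up"),
    ("CorE", "activated"): ("SigCorE", "down"),
    ("CorE", "repressed"): ("SigCorE", "up"),
}


@dataclass
class AnalysisResult:
    """All pipeline outputs for one count matrix."""

    contrasts: Dict[str, pd.DataFrame]
    statuses: Dict[str, Dict[str, pd.DataFrame]]       # condition -> strain -> table
    assignments: Dict[str, pd.DataFrame]               # condition -> table
    overlap: Optional[pd.DataFrame]
    heatmaps: Dict[str, pd.DataFrame]                  # condition -> genes x strains


def analyze(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr_threshold: float = regulon.DEFAULT_FDR,
    lfc_threshold: float = regulon.DEFAULT_LFC,
    sigma_genes: Optional[Mapping[str, str]] = None,
) -> AnalysisResult:
    """Run the full pipeline on a validated count matrix and design."""
    tables = diffexpr.run_all_contrasts(counts, design)
    conditions = sorted(design["condition"].unique())

    statuses: Dict[str, Dict[str, pd.DataFrame]] = {}
    assignments: Dict[str, pd.DataFrame] = {}
    heatmaps: Dict[str, pd.DataFrame] = {}
    for cond in conditions:
        st = regulon.statuses_for_condition(
            tables, cond, fdr_threshold, lfc_threshold, sigma_genes
        )
        statuses[cond] = st
        assigned = regulon.assign_regulons(st, cond)
        if cond == "standard":
            # the stress-response annotation is defined relative to standard
            assigned["cs_response"] = "na"
        else:
            cs_table = tables.get(diffexpr.cs_stress_name(cond))
            assigned = regulon.annotate_cs_response(assigned, cs_table,
                                                    fdr_threshold)
        assignments[cond] = assigned
        n_labeled = int((assigned["label"] != "none").sum())
        logger.info(
            "%s: %d candidate genes, %d assigned a label", cond,
            len(assigned), n_labeled,
        )
        strain_tables = {
            s: tables[diffexpr.contrast_name(s, cond)] for s in MUTANT_STRAINS
        }
        masked = {
            s: regulon.sigma_mask_for_strain(s, sigma_genes)
            for s in MUTANT_STRAINS
        }
        heatmaps[cond] = regulon.heatmap_matrix(
            strain_tables, list(assigned.index), masked=masked
        )

    overlap = (
        regulon.compare_conditions(assignments) if len(assignments) >= 2 else None
    )
    return AnalysisResult(tables, statuses, assignments, overlap, heatmaps)


def write_analysis(result: AnalysisResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    diffexpr.write_contrasts(result.contrasts, out / "contrasts")
    for cond, assigned in result.assignments.items():
        regulon.write_assignments(assigned, out / f"regulons_{cond}.tsv")
    for cond, st in result.statuses.items():
        for strain, table in st.items():
            table.to_csv(out / f"status_{strain}_{cond}.tsv", sep="\t",
                         index_label="gene_id")
    for cond, hm in result.heatmaps.items():
        regulon.write_heatmap(hm, out / f"heatmap_{cond}.tsv")
    if result.overlap is not None:
        regulon.write_overlap(result.overlap, out / "regulon_overlap.tsv")


LABELED = ("SigB", "SigD", "SigCorE", "shared")


def evaluate_recovery(
    truth: Iterable[PlantedRegulonEffect],
    assignments: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Score assignments against a planted truth.

    Per (condition, sigma, direction) class: sensitivity = fraction of
    planted genes assigned their expected label and direction.  Per
    condition: false_assignment_rate = fraction of unplanted genes carrying
    any label (a gene absent from the candidate set counts as unlabeled).

    Returns a tidy table with columns condition, metric, class, value, n.
    """
    truth = list(truth)
    known = {(e.sigma, e.direction) for e in truth}
    bad = known - set(TRUTH_LABEL)
    if bad:
        raise ValueError(f"unknown truth class(es): {sorted(bad)}")

    rows = []
    for cond, assigned in assignments.items():
        cond_truth = [e for e in truth if e.condition == cond]
        planted_genes = {e.gene_id for e in cond_truth}
        by_class: Dict[tuple, list] = {}
        for e in cond_truth:
            by_class.setdefault((e.sigma, e.direction), []).append(e.gene_id)
        for (sigma, direction), genes in sorted(by_class.items()):
            label, want_dir = TRUTH_LABEL[(sigma, direction)]
            hit = 0
            for g in genes:
                if g in assigned.index and (
                    assigned.at[g, "label"] == label
                    and assigned.at[g, "direction"] == want_dir
                ):
                    hit += 1
            rows.append((cond, "sensitivity", f"{label}_{want_dir}",
                         hit / len(genes), len(genes)))
        # false assignments among genes with no planted effect in this condition
        unplanted = assigned.index.difference(sorted(planted_genes))
        n_false = int(assigned.loc[unplanted, "label"].isin(LABELED).sum())
        rows.append((cond, "false_assignments", "any_label", n_false,
                     len(unplanted)))
    return pd.DataFrame(rows, columns=["condition", "metric", "class",
                                       "value", "n"])


def recovery_summary(
    truth: Iterable[PlantedRegulonEffect],
    assignments: Mapping[str, pd.DataFrame],
    n_genes: int,
) -> Dict[str, float]:
    """Headline numbers: overall planted-label sensitivity and the fraction
    of unplanted genes (out of all ``n_genes`` analysed) that got a label."""
    truth = list(truth)
    total = hit = 0
    false = 0
    unplanted_total = 0
    for cond, assigned in assignments.items():
        cond_truth = [e for e in truth if e.condition == cond]
        planted = {e.gene_id for e in cond_truth}
        for e in cond_truth:
            label, want_dir = TRUTH_LABEL[(e.sigma, e.direction)]
            total += 1
            if e.gene_id in assigned.index and (
                assigned.at[e.gene_id, "label"] == label
                and assigned.at[e.gene_id, "direction"] == want_dir
            ):
                hit += 1
        unplanted = assigned.index.difference(sorted(planted))
        false += int(assigned.loc[unplanted, "label"].isin(LABELED).sum())
        unplanted_total += n_genes - len(planted)
    return {
        "sensitivity": hit / total if total else float("nan"),
        "false_rate": false / unplanted_total if unplanted_total else 0.0,
    }
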