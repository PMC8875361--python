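"""Combinatorial regulon assignment from the four-mutant expression pattern.

The strain panel identifies sigma-factor regulons by where an expression
change co-occurs:

* **SigB** targets change in dsigB and dsigBCE (both lack SigB) but not in
  dsigD, while opposite-direction regulation in dsigCDE is tolerated;
* **SigD** targets mirror this with dsigD/dsigCDE, tolerating
  opposite-direction regulation in dsigBCE;
* **SigCorE** targets change in the same direction in both triple mutants
  (the only strains lacking SigC and SigE) and in neither single mutant —
  the panel cannot separate SigC from SigE;
* any other pattern with at least two regulated strains is reported as
  ``shared``; everything else is ``none``.

A gene enters classification only if it is significantly at-least-two-fold
regulated in at least one strain; inside the rules, sub-two-fold but
significant changes still count as regulated.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .strains import CANONICAL_GENOTYPES, MUTANT_STRAINS

logger = logging.getLogger(__name__)

UP, DOWN, NS, MASKED = "UP", "DOWN", "NS", "MASKED"

LABELS = ("SigB", "SigD", "SigCorE", "shared", "none")

#: Locus tags of the group-2 sigma-factor genes in Synechocystis sp. PCC 6803,
#: used to mask each deleted factor's own gene in its deletion strain.
DEFAULT_SIGMA_GENES = {"B": "sll0306", "C": "sll0184", "D": "sll2012", "E": "sll1689"}

DEFAULT_FDR = 0.05
DEFAULT_LFC = 1.0


def sigma_mask_for_strain(strain: str,
                          sigma_genes: Optional[Mapping[str, str]] = None) -> frozenset:
    """Gene ids to mask in a strain: the genes of its deleted sigma factors."""
    if sigma_genes is None:
        sigma_genes = DEFAULT_SIGMA_GENES
    genotype = CANONICAL_GENOTYPES[strain]
    return frozenset(
        sigma_genes[s] for s in genotype.deleted_sigmas if s in sigma_genes
    )


def call_status(
    results: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    mask_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-gene UP/DOWN/NS call plus the two-fold gate for one contrast table.

    ``status`` is UP (DOWN) when fdr < threshold and log2fc is positive
    (negative), else NS; ``twofold`` additionally requires
    |log2fc| >= lfc_threshold.  Genes in ``mask_genes`` (a deleted sigma
    factor's own gene) get status MASKED and never pass the gate.
    """
    fdr = results["fdr"].to_numpy(dtype=float)
    lfc = results["log2fc"].to_numpy(dtype=float)
    sig = np.nan_to_num(fdr, nan=1.0) < fdr_threshold
    status = np.where(sig & (lfc > 0), UP, np.where(sig & (lfc < 0), DOWN, NS))
    twofold = sig & (np.abs(lfc) >= lfc_threshold)
    out = pd.DataFrame({"status": status, "twofold": twofold}, index=results.index)
    masked = out.index.intersection(list(mask_genes))
    out.loc[masked, "status"] = MASKED
    out.loc[masked, "twofold"] = False
    return out


def statuses_for_condition(
    tables: Mapping[str, pd.DataFrame],
    condition: str,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    sigma_genes: Optional[Mapping[str, str]] = None,
) -> Dict[str, pd.DataFrame]:
    """Status tables for all four mutant strains in one condition, with each
    strain's deleted sigma-factor genes masked."""
    from .diffexpr import contrast_name

    statuses = {}
    for strain in MUTANT_STRAINS:
        name = contrast_name(strain, condition)
        if name not in tables:
            raise ValueError(f"missing contrast table {name!r}")
        statuses[strain] = call_status(
            tables[name], fdr_threshold, lfc_threshold,
            mask_genes=sigma_mask_for_strain(strain, sigma_genes),
        )
    return statuses


def candidate_genes(statuses: Mapping[str, pd.DataFrame]) -> pd.Index:
    """Genes significantly at-least-two-fold regulated in >= 1 mutant strain."""
    missing = [s for s in MUTANT_STRAINS if s not in statuses]
    if missing:
        raise ValueError(f"missing status table(s) for {missing}")
    index = statuses[MUTANT_STRAINS[0]].index
    any_twofold = np.zeros(len(index), dtype=bool)
    for strain in MUTANT_STRAINS:
        any_twofold |= statuses[strain]["twofold"].to_numpy()
    return index[any_twofold]


def assign_pattern(b: str, d: str, bce: str, cde: str):
    """Map one (dsigB, dsigD, dsigBCE, dsigCDE) status pattern to a
    (label, direction) pair.  Inputs are UP/DOWN/NS."""
    if b == DOWN and bce == DOWN and d == NS and cde in (NS, UP):
        return "SigB", "down"
    if b == UP and bce == UP and d == NS and cde in (NS, DOWN):
        return "SigB", "up"
    if d == DOWN and cde == DOWN and b == NS and bce in (NS, UP):
        return "SigD", "down"
    if d == UP and cde == UP and b == NS and bce in (NS, DOWN):
        return "SigD", "up"
    if bce == cde and bce in (UP, DOWN) and b == NS and d == NS:
        return "SigCorE", "up" if bce == UP else "down"
    regulated = [s for s in (b, d, bce, cde) if s in (UP, DOWN)]
    if len(regulated) >= 2:
        if all(s == UP for s in regulated):
            direction = "up"
        elif all(s == DOWN for s in regulated):
            direction = "down"
        else:
            direction = "mixed"
        return "shared", direction
    return "none", "na"


def assign_regulons(
    statuses: Mapping[str, pd.DataFrame],
    condition: str,
    genes: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Classify candidate genes of one condition.

    Returns a table with columns condition, label, direction and
    ``unclassifiable`` — True where a masked status sits in a rule position
    (the gene is kept, never silently dropped).
    """
    if genes is None:
        genes = candidate_genes(statuses)
    rows = []
    for gene in genes:
        pattern = tuple(statuses[s].at[gene, "status"] for s in MUTANT_STRAINS)
        if MASKED in pattern:
            rows.append((gene, condition, "none", "na", True))
            continue
        label, direction = assign_pattern(*pattern)
        rows.append((gene, condition, label, direction, False))
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "label", "direction",
                       "unclassifiable"],
    ).set_index("gene_id")


def compare_conditions(
    assignments: Mapping[str, pd.DataFrame],
    labels: Sequence[str] = ("SigB", "SigD", "SigCorE"),
) -> pd.DataFrame:
    """Cross-condition regulon overlap.

    For each regulon label: the gene set per condition, the intersection
    across all compared conditions, and each condition's private genes
    (``only_<condition>``), as one tidy (label, set_name, gene_id) table.
    """
    if len(assignments) < 2:
        raise ValueError("need assignments for at least two conditions")
    rows = []
    for label in labels:
        sets = {
            cond: set(df.index[df["label"] == label])
            for cond, df in assignments.items()
        }
        common = set.intersection(*sets.values())
        for cond, genes in sets.items():
            rows.extend((label, cond, g) for g in sorted(genes))
            others = set.union(*(s for c, s in sets.items() if c != cond))
            rows.extend((label, f"only_{cond}", g) for g in sorted(genes - others))
        rows.extend((label, "intersection", g) for g in sorted(common))
    return pd.DataFrame(rows, columns=["label", "set_name", "gene_id"])


def annotate_cs_response(
    assignments: pd.DataFrame,
    cs_stress_results: Optional[pd.DataFrame],
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Add how each regulon gene responds in the control strain under stress.

    Uses the significance/sign rule alone (no fold-change gate): up, down or
    ns.  If the control stress-vs-standard table is missing the column is
    filled with "unknown" and a warning is logged.
    """
    out = assignments.copy()
    if cs_stress_results is None:
        logger.warning("control stress-vs-standard table missing; "
                       "cs_response set to 'unknown'")
        out["cs_response"] = "unknown"
        return out
    status = call_status(cs_stress_results, fdr_threshold, lfc_threshold=0.0)
    mapped = status["status"].map({UP: "up", DOWN: "down", NS: "ns"})
    out["cs_response"] = mapped.reindex(out.index).fillna("unknown")
    return out


def heatmap_matrix(
    tables: Mapping[str, pd.DataFrame],
    genes: Sequence[str],
    masked: Optional[Mapping[str, Iterable[str]]] = None,
) -> pd.DataFrame:
    """Genes x strains matrix of log2 fold changes for heat-map export.

    ``tables`` maps strain -> contrast table; row order follows ``genes``;
    entries listed in ``masked`` (strain -> gene ids) become NaN, written as
    the literal "NA" by :func:`write_heatmap`.  Unknown genes are an error.
    """
    masked = masked or {}
    columns = {}
    for strain, table in tables.items():
        unknown = [g for g in genes if g not in table.index]
        if unknown:
            raise KeyError(f"gene(s) not in table for {strain}: {unknown[:5]}")
        col = table["log2fc"].loc[list(genes)].astype(float)
        hide = col.index.intersection(list(masked.get(strain, ())))
        col.loc[hide] = np.nan
        columns[strain] = col
    out = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return out


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index_label="gene_id")


def write_overlap(overlap: pd.DataFrame, path) -> None:
    overlap.to_csv(path, sep="\t", index=False)


def write_heatmap(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")
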