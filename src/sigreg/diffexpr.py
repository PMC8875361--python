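"""Negative-binomial differential expression for mutant-vs-control contrasts.

A deliberately small, fully documented pipeline in the mould of the standard
RNA-seq count model (Var = mu + alpha mu^2):

1. median-of-ratios library-size normalisation,
2. per-gene method-of-moments dispersion pooled across replicate groups,
3. a two-group comparison of size-factor-normalized group means under the
   NB variance model, with a Wald test on the group log2-ratio,
4. Benjamini-Hochberg FDR within each contrast table.

There is deliberately no shrinkage of dispersions or fold changes, no
independent filtering and no outlier refitting: every step has a closed-form
or brute-force oracle and is tested against it.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .strains import CONTROL_STRAIN

logger = logging.getLogger(__name__)

#: Dispersion floor; keeps the Poisson limit numerically stable.
ALPHA_FLOOR = 1e-8

#: Absolute cap on |log2 fold change| when one group has only zero counts.
LFC_CAP = 10.0

LN2 = np.log(2.0)

RESULT_COLUMNS = ["base_mean", "log2fc", "se", "wald", "p", "fdr", "flag"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over reference genes i of
    counts_ij / geomean_i, where geomean_i is the geometric mean of gene i
    across all samples and the reference set is the genes with no zero count.
    """
    values = counts.to_numpy(dtype=float)
    ref = (values > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has all-positive counts across samples; median-of-ratios "
            "normalization needs at least one zero-free reference gene "
            "(pseudo-reference fallback is disabled)"
        )
    ref_values = values[ref]
    geomean = np.exp(np.mean(np.log(ref_values), axis=1))
    sf = np.median(ref_values / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _group_columns(design: pd.DataFrame) -> Dict[Tuple[str, str], list]:
    groups: Dict[Tuple[str, str], list] = {}
    for sample_id, row in design.iterrows():
        groups.setdefault((row["strain"], row["condition"]), []).append(sample_id)
    return groups


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    sf: Optional[pd.Series] = None,
) -> pd.Series:
    """Per-gene method-of-moments dispersion pooled across replicate groups.

    On normalized counts, alpha_i = max(ALPHA_FLOOR,
    (pooled within-group variance - pooled mean) / pooled mean^2), where the
    pooled variance weights each group's sample variance by its degrees of
    freedom and the pooled mean averages over all samples in the design.
    """
    if sf is None:
        sf = size_factors(counts)
    groups = _group_columns(design.loc[design.index.intersection(counts.columns)])
    thin = [f"{s}/{c}" for (s, c), cols in groups.items() if len(cols) < 2]
    if thin:
        raise ValueError(f"group(s) with fewer than 2 replicates: {', '.join(thin)}")

    norm = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()
    col_idx = {s: j for j, s in enumerate(counts.columns)}

    ss = np.zeros(counts.shape[0])
    df_total = 0
    n_samples = 0
    mean_sum = np.zeros(counts.shape[0])
    for cols in groups.values():
        j = [col_idx[c] for c in cols]
        sub = norm[:, j]
        ss += sub.var(axis=1, ddof=1) * (len(j) - 1)
        df_total += len(j) - 1
        mean_sum += sub.sum(axis=1)
        n_samples += len(j)
    pooled_var = ss / df_total
    pooled_mean = mean_sum / n_samples

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(pooled_mean > 0, alpha, ALPHA_FLOOR)
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    return pd.Series(alpha, index=counts.index, name="alpha")


def _fit_group_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene estimate of the group mean on the common (normalized) scale:
    the average of size-factor-normalized counts.

    This solves the unbiased estimating equation sum_j (y_ij / sf_j - mu) = 0
    and coincides with the NB maximum-likelihood solution whenever the
    size factors within the group are equal.  Crucially it depends on the
    data only through normalized counts, which makes the fitted fold change
    exactly invariant under rescaling any sample together with its size
    factor (offset correctness)."""
    return (y / sf[None, :]).mean(axis=1)


def _log_mean_information(mu: np.ndarray, sf: np.ndarray,
                          alpha: np.ndarray) -> np.ndarray:
    """Inverse variance of log(mu-hat) under the NB model Var = mu + alpha mu^2:
    Var(mu-hat) = n^-2 sum_j (mu / sf_j + alpha mu^2), so
    1 / Var(log mu-hat) = n^2 / sum_j (1/(mu sf_j) + alpha).

    Equals the information sum_j mu sf_j / (1 + alpha mu sf_j) of the NB fit
    when the group's size factors are equal."""
    n = sf.size
    with np.errstate(divide="ignore"):
        var_log = (1.0 / (mu[:, None] * sf[None, :]) + alpha[:, None]).sum(axis=1) / n**2
    return 1.0 / var_log


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersions: pd.Series,
    contrast: Tuple[Tuple[str, str], Tuple[str, str]],
    sf: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Two-group NB Wald test for contrast (test group, reference group).

    Groups are (strain, condition) pairs.  The two-group model is saturated
    in group means, so each group's mean on the common scale is estimated
    separately from its size-factor-normalized counts (see
    :func:`_fit_group_mean`); log2fc is the fitted log2 ratio
    test/reference, its standard error comes from the NB variance model
    Var = mu + alpha mu^2, and p is the two-sided normal tail of
    wald = log2fc / se.

    Genes with zero counts in both groups are flagged ``untestable`` with
    log2fc 0 and p 1.  When only one group is all-zero, that group's mean is
    replaced by a half-count pseudo-mean and the log2fc is capped at +-10.
    """
    test_group, ref_group = contrast
    groups = _group_columns(design)
    for grp in (test_group, ref_group):
        if tuple(grp) not in groups:
            raise ValueError(f"contrast group {grp} not present in the design")
    if sf is None:
        sf = size_factors(counts)

    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)
    cols_t = groups[tuple(test_group)]
    cols_r = groups[tuple(ref_group)]
    y_t = counts[cols_t].to_numpy(dtype=float)
    y_r = counts[cols_r].to_numpy(dtype=float)
    sf_t = sf.loc[cols_t].to_numpy(dtype=float)
    sf_r = sf.loc[cols_r].to_numpy(dtype=float)

    mu_t = _fit_group_mean(y_t, sf_t, alpha)
    mu_r = _fit_group_mean(y_r, sf_r, alpha)

    zero_t = y_t.sum(axis=1) == 0
    zero_r = y_r.sum(axis=1) == 0
    untestable = zero_t & zero_r
    # half-count continuity correction for a single all-zero group
    pseudo_t = 0.5 / sf_t.sum()
    pseudo_r = 0.5 / sf_r.sum()
    mu_t = np.where(zero_t & ~untestable, pseudo_t, mu_t)
    mu_r = np.where(zero_r & ~untestable, pseudo_r, mu_r)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mu_t / mu_r)
    log2fc = np.where(untestable, 0.0, np.clip(log2fc, -LFC_CAP, LFC_CAP))

    info_t = _log_mean_information(mu_t, sf_t, alpha)
    info_r = _log_mean_information(mu_r, sf_r, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / info_t + 1.0 / info_r) / LN2
    se = np.where(untestable, np.nan, se)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    wald = np.where(untestable, 0.0, wald)
    p = np.where(untestable, 1.0, 2.0 * stats.norm.sf(np.abs(wald)))

    norm_all = counts[cols_t + cols_r].to_numpy(dtype=float) / np.concatenate(
        [sf_t, sf_r]
    )
    base_mean = norm_all.mean(axis=1)

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "fdr": np.nan,
            "flag": np.where(untestable, "untestable", ""),
        },
        index=counts.index,
    )
    testable = ~untestable
    if testable.any():
        result.loc[testable, "fdr"] = bh_adjust(p[testable])
    return result


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_name(test_strain: str, condition: str) -> str:
    return f"{test_strain}_vs_CS_{condition}"


def cs_stress_name(condition: str) -> str:
    return f"CS_{condition}_vs_CS_standard"


def run_all_contrasts(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    sf: Optional[pd.Series] = None,
) -> Dict[str, pd.DataFrame]:
    """All mutant-vs-control tables plus control stress-vs-standard tables.

    For every condition and every non-control strain present there, tests
    (strain, condition) against (CS, condition); additionally, for every
    non-standard condition with a CS group, tests (CS, condition) against
    (CS, standard) to support the stress-response annotation of regulon
    genes.  FDR is adjusted within each table separately.
    """
    design = design.loc[list(counts.columns)]
    groups = _group_columns(design)
    conditions = sorted({c for (_s, c) in groups})
    strains_by_cond = {
        c: sorted({s for (s, cc) in groups if cc == c}) for c in conditions
    }
    for c, strains in strains_by_cond.items():
        if CONTROL_STRAIN not in strains:
            raise ValueError(f"no {CONTROL_STRAIN} group in condition {c!r}")

    if sf is None:
        sf = size_factors(counts)
    dispersions = estimate_dispersion(counts, design, sf=sf)

    tables: Dict[str, pd.DataFrame] = {}
    for c in conditions:
        for strain in strains_by_cond[c]:
            if strain == CONTROL_STRAIN:
                continue
            tables[contrast_name(strain, c)] = nb_wald_test(
                counts, design, dispersions, ((strain, c), (CONTROL_STRAIN, c)),
                sf=sf,
            )
    if "standard" in conditions:
        for c in conditions:
            if c == "standard":
                continue
            tables[cs_stress_name(c)] = nb_wald_test(
                counts, design, dispersions,
                ((CONTROL_STRAIN, c), (CONTROL_STRAIN, "standard")), sf=sf,
            )
    logger.info("computed %d contrast tables", len(tables))
    return tables


def write_contrasts(tables: Mapping[str, pd.DataFrame], outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index_label="gene_id",
                     na_rep="NA")
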