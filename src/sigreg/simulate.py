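"""Synthetic RNA-seq counts with planted sigma-factor regulon structure.

The generator draws gene-level counts from a negative binomial with the
mean/dispersion parameterisation Var = mu + alpha * mu^2 (the same model the
differential-expression stage fits), multiplies per-sample library-size
factors onto the means, and plants condition-specific regulon effects:

* a gene *activated* by a sigma factor loses expression in every strain
  where that factor is deleted (mean multiplied by ``2**-effect_log2``);
* a *repressed* gene gains expression there (``2**+effect_log2``);
* "CorE" effects fire only when both SigC and SigE are deleted, because the
  strain panel cannot separate the two regulons.

Everything is driven by a single integer seed, so a (config, truth, seed)
triple reproduces the count matrix bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .strains import (
    CANONICAL_CONDITIONS,
    CANONICAL_GENOTYPES,
    Condition,
    GenotypeSpec,
)

SIGMA_CHOICES = ("B", "D", "CorE")
DIRECTION_CHOICES = ("activated", "repressed")


@dataclass(frozen=True)
class PlantedRegulonEffect:
    """One planted dependency of a gene on a sigma factor in one condition.

    ``direction`` encodes what happens when the governing factor is lost:
    activated targets go down, repressed targets go up, both by
    ``effect_log2`` log2 units.
    """

    gene_id: str
    sigma: str
    condition: str
    direction: str
    effect_log2: float

    def __post_init__(self) -> None:
        if self.sigma not in SIGMA_CHOICES:
            raise ValueError(f"sigma must be one of {SIGMA_CHOICES}, got {self.sigma!r}")
        if self.direction not in DIRECTION_CHOICES:
            raise ValueError(
                f"direction must be one of {DIRECTION_CHOICES}, got {self.direction!r}"
            )
        if not self.effect_log2 > 0:
            raise ValueError("effect_log2 must be strictly positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    Parameters
    ----------
    n_genes
        Number of genes simulated.
    n_replicates
        Biological replicates per (strain, condition) cell; the study used 3.
    baseline_median
        Median of the log-normal law for per-gene baseline means.
    baseline_sigma
        Standard deviation of that law on the natural-log scale.
    dispersion
        Negative-binomial dispersion alpha shared by all genes
        (Var = mu + alpha mu^2).
    size_factor_low, size_factor_high
        Per-sample library-size factors are drawn uniformly from this range.
    seed
        Fully determines the output.
    """

    n_genes: int
    n_replicates: int = 3
    baseline_median: float = 200.0
    baseline_sigma: float = 1.0
    dispersion: float = 0.05
    size_factor_low: float = 0.7
    size_factor_high: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        for name in ("baseline_median", "baseline_sigma", "dispersion",
                     "size_factor_low", "size_factor_high"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.size_factor_high < self.size_factor_low:
            raise ValueError("size_factor_high must be >= size_factor_low")


@dataclass(frozen=True)
class SimulationTruth:
    """Everything the generator planted: per-gene means and dispersions,
    per-sample size factors, and the regulon effects."""

    baseline_mean: pd.Series
    dispersion: pd.Series
    size_factors: pd.Series
    effects: frozenset


def gene_id(i: int) -> str:
    return f"g{i:04d}"


def expression_multiplier(
    gene: str,
    genotype: GenotypeSpec,
    condition: str,
    truth: Iterable[PlantedRegulonEffect],
) -> float:
    """Fold multiplier applied to a gene's baseline mean in one sample group.

    Returns 1.0 when no planted effect matches (gene, condition) or when the
    genotype still carries the governing factor(s).  A "B" (resp. "D") effect
    fires iff SigB (resp. SigD) is deleted; a "CorE" effect fires only when
    both SigC and SigE are deleted.
    """
    matching = [e for e in truth if e.gene_id == gene and e.condition == condition]
    if not matching:
        return 1.0
    if len(matching) > 1:
        raise ValueError(
            f"conflicting planted effects for gene {gene!r} in condition {condition!r}"
        )
    eff = matching[0]
    sigmas = genotype.functional_sigmas
    if eff.sigma == "CorE":
        fires = "C" not in sigmas and "E" not in sigmas
    else:
        fires = eff.sigma not in sigmas
    if not fires:
        return 1.0
    sign = -1.0 if eff.direction == "activated" else 1.0
    return 2.0 ** (sign * eff.effect_log2)


def _effects_by_key(truth: Iterable[PlantedRegulonEffect]) -> dict:
    out: dict = {}
    for e in truth:
        key = (e.gene_id, e.condition)
        if key in out:
            raise ValueError(
                f"conflicting planted effects for gene {e.gene_id!r} "
                f"in condition {e.condition!r}"
            )
        out[key] = e
    return out


def simulate_counts(
    config: SimulationConfig,
    genotypes: Sequence[GenotypeSpec] = tuple(CANONICAL_GENOTYPES.values()),
    conditions: Sequence[Condition] = CANONICAL_CONDITIONS,
    truth: Iterable[PlantedRegulonEffect] = frozenset(),
):
    """Draw a count matrix for the full strain x condition x replicate design.

    Returns ``(counts, samples, sim_truth)`` where ``counts`` is a genes x
    samples integer DataFrame, ``samples`` maps each sample to
    (strain, condition, replicate), and ``sim_truth`` records the planted
    parameters.
    """
    truth = frozenset(truth)
    effects = _effects_by_key(truth)

    genes = [gene_id(i) for i in range(config.n_genes)]
    gene_set = set(genes)
    planted_genes = {e.gene_id for e in truth}
    missing = planted_genes - gene_set
    if missing:
        raise ValueError(
            f"truth references gene ids outside the simulated range: {sorted(missing)[:5]}"
        )

    rng = np.random.default_rng(config.seed)
    mu = np.exp(
        math.log(config.baseline_median)
        + config.baseline_sigma * rng.standard_normal(config.n_genes)
    )
    alpha = np.full(config.n_genes, config.dispersion)

    sample_rows = []
    for g in genotypes:
        for c in conditions:
            for r in range(1, config.n_replicates + 1):
                sample_rows.append(
                    (f"{g.strain_name}_{c.condition_name}_r{r}",
                     g.strain_name, c.condition_name, r)
                )
    sample_ids = [row[0] for row in sample_rows]
    size_factors = rng.uniform(
        config.size_factor_low, config.size_factor_high, len(sample_ids)
    )

    gene_index = {g: i for i, g in enumerate(genes)}
    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    col = 0
    for g in genotypes:
        for c in conditions:
            mult = np.ones(config.n_genes)
            for (gid, cond), eff in effects.items():
                if cond != c.condition_name:
                    continue
                mult[gene_index[gid]] = expression_multiplier(
                    gid, g, cond, (eff,)
                )
            for _r in range(config.n_replicates):
                mean = mu * mult * size_factors[col]
                r_param = 1.0 / alpha
                p_param = r_param / (r_param + mean)
                counts[:, col] = rng.negative_binomial(r_param, p_param)
                col += 1

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=sample_ids)
    samples_df = pd.DataFrame(
        [(s, st, cond, rep) for s, st, cond, rep in sample_rows],
        columns=["sample_id", "strain", "condition", "replicate"],
    ).set_index("sample_id")
    sim_truth = SimulationTruth(
        baseline_mean=pd.Series(mu, index=genes, name="baseline_mean"),
        dispersion=pd.Series(alpha, index=genes, name="dispersion"),
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
        effects=truth,
    )
    return counts_df, samples_df, sim_truth


def plant_truth(
    n_per_class: int = 100,
    effect_log2: float = 2.0,
    condition: str = "heat",
    first_gene: int = 0,
) -> frozenset:
    """Plant ``n_per_class`` genes for each of the six regulon classes
    (SigB/SigD/SigCorE x activated/repressed) in one condition, using
    consecutive generator gene ids starting at ``first_gene``."""
    effects = []
    i = first_gene
    for sigma in SIGMA_CHOICES:
        for direction in DIRECTION_CHOICES:
            for _ in range(n_per_class):
                effects.append(
                    PlantedRegulonEffect(gene_id(i), sigma, condition,
                                         direction, effect_log2)
                )
                i += 1
    return frozenset(effects)


# --- on-disk formats -------------------------------------------------------

TRUTH_COLUMNS = ["gene_id", "sigma", "condition", "direction", "effect_log2"]


def write_truth(truth: Iterable[PlantedRegulonEffect], path) -> None:
    rows = sorted(
        ((e.gene_id, e.sigma, e.condition, e.direction, e.effect_log2) for e in truth)
    )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> frozenset:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth file {path} lacks columns {sorted(missing)}")
    return frozenset(
        PlantedRegulonEffect(r.gene_id, r.sigma, r.condition, r.direction,
                             float(r.effect_log2))
        for r in df.itertuples()
    )


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimulationConfig(**raw)


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(config, k) for k in config.__dataclass_fields__},
            fh, sort_keys=False,
        )
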