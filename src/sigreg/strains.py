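"""Strain genotypes and growth conditions of the sigma-factor mutant panel.

The panel compares the glucose-tolerant control strain (CS) of
*Synechocystis* sp. PCC 6803 against four group-2 sigma-factor deletion
strains.  A genotype is summarised by the set of group-2 sigma factors
(B, C, D, E) it still carries: the triple mutants retain exactly one
factor (dsigBCE keeps SigD, dsigCDE keeps SigB), which is what makes the
combinatorial regulon rules identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

GROUP2_SIGMAS = frozenset({"B", "C", "D", "E"})

#: Strain labels in panel order: control first, then single, then triple mutants.
CONTROL_STRAIN = "CS"
MUTANT_STRAINS = ("dsigB", "dsigD", "dsigBCE", "dsigCDE")
ALL_STRAINS = (CONTROL_STRAIN,) + MUTANT_STRAINS


@dataclass(frozen=True)
class GenotypeSpec:
    """A strain and the group-2 sigma factors it still expresses."""

    strain_name: str
    functional_sigmas: frozenset

    def __post_init__(self) -> None:
        extra = set(self.functional_sigmas) - GROUP2_SIGMAS
        if extra:
            raise ValueError(f"unknown sigma factor(s) {sorted(extra)} in {self.strain_name}")
        if not self.functional_sigmas:
            raise ValueError(f"genotype {self.strain_name} retains no group-2 sigma factor")

    @property
    def deleted_sigmas(self) -> frozenset:
        return GROUP2_SIGMAS - self.functional_sigmas


#: The five canonical genotypes of the study.
CANONICAL_GENOTYPES = {
    "CS": GenotypeSpec("CS", frozenset("BCDE")),
    "dsigB": GenotypeSpec("dsigB", frozenset("CDE")),
    "dsigD": GenotypeSpec("dsigD", frozenset("BCE")),
    "dsigBCE": GenotypeSpec("dsigBCE", frozenset("D")),
    "dsigCDE": GenotypeSpec("dsigCDE", frozenset("B")),
}


def get_genotype(strain_name: str) -> GenotypeSpec:
    """Look up a canonical genotype by strain label."""
    try:
        return CANONICAL_GENOTYPES[strain_name]
    except KeyError:
        raise KeyError(
            f"unknown genotype {strain_name!r}; known: {', '.join(CANONICAL_GENOTYPES)}"
        ) from None


CONDITION_NAMES = ("standard", "heat", "highlight")


@dataclass(frozen=True)
class Condition:
    """A growth/treatment condition.

    ``metadata`` is descriptive only (temperature, photon flux) and never
    enters any computation.
    """

    condition_name: str
    metadata: str = ""

    def __post_init__(self) -> None:
        if self.condition_name not in CONDITION_NAMES:
            raise ValueError(
                f"condition {self.condition_name!r} not one of {CONDITION_NAMES}"
            )


#: The study's three conditions: standard growth, 1 h at 42 degC, and
#: 1 h high light at PPFD 750 umol photons m^-2 s^-1.
CANONICAL_CONDITIONS = (
    Condition("standard", "32 degC, PPFD 40 umol m-2 s-1"),
    Condition("heat", "1 h at 42 degC"),
    Condition("highlight", "1 h at PPFD 750 umol m-2 s-1"),
)
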