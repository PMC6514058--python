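"""In-silico genotypes: knockouts and transcription-source ablations.

A knockout is implemented as zeroing the corresponding synthesis (or, for
the p52-processing deficiency, processing) rate constants; all species stay
in the state vector and simply relax to ~0 on re-equilibration.  Ablations
zero individual NF-kB-induced transcription weights of the Relb gene,
leaving everything else intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigurationError
from .parameters import ParameterSet

KNOCKOUT_TOKENS = ("Nfkb2", "Nfkbia", "Relb", "Rela", "p52-processing")
ABLATION_TOKENS = ("RelA-driven-Relb-txn", "RelB-driven-Relb-txn")

#: parameters zeroed by each knockout token
_KNOCKOUT_PARAMS = {
    "Nfkb2": ("txn_nfkb2_const", "txn_nfkb2_a50", "txn_nfkb2_a52",
              "txn_nfkb2_b50", "txn_nfkb2_b52"),
    "Nfkbia": ("txn_ikba_const", "txn_ikba_a50", "txn_ikba_a52",
               "txn_ikba_b50", "txn_ikba_b52"),
    "Relb": ("txn_relb_const", "txn_relb_a50", "txn_relb_a52",
             "txn_relb_b50", "txn_relb_b52"),
    "Rela": ("syn_rela",),
    # p100 is still expressed; only its conversion into p52 is blocked
    "p52-processing": ("proc_p100",),
}

_ABLATION_PARAMS = {
    "RelA-driven-Relb-txn": ("txn_relb_a50", "txn_relb_a52"),
    "RelB-driven-Relb-txn": ("txn_relb_b50", "txn_relb_b52"),
}


@dataclass(frozen=True)
class GenotypeSpec:
    name: str
    knockouts: frozenset = field(default_factory=frozenset)
    txn_source_ablation: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "txn_source_ablation",
                           frozenset(self.txn_source_ablation))
        for token in self.knockouts:
            if token not in KNOCKOUT_TOKENS:
                raise ConfigurationError(
                    f"unknown knockout token {token!r}; expected one of "
                    f"{KNOCKOUT_TOKENS}")
        for token in self.txn_source_ablation:
            if token not in ABLATION_TOKENS:
                raise ConfigurationError(
                    f"unknown ablation token {token!r}; expected one of "
                    f"{ABLATION_TOKENS}")

    @property
    def is_wild_type(self) -> bool:
        return not self.knockouts and not self.txn_source_ablation

    def combined(self, other: "GenotypeSpec", name: str | None = None) -> "GenotypeSpec":
        """Compound genotype: union of interventions."""
        return GenotypeSpec(
            name or f"{self.name}+{other.name}",
            self.knockouts | other.knockouts,
            self.txn_source_ablation | other.txn_source_ablation)

    def zeroed_parameters(self) -> tuple[str, ...]:
        out: list[str] = []
        for token in sorted(self.knockouts):
            out.extend(_KNOCKOUT_PARAMS[token])
        for token in sorted(self.txn_source_ablation):
            out.extend(_ABLATION_PARAMS[token])
        return tuple(dict.fromkeys(out))

    def apply(self, parameters: ParameterSet) -> ParameterSet:
        """Parameter set with this genotype's interventions applied."""
        zeroed = self.zeroed_parameters()
        missing = [p for p in zeroed if p not in parameters]
        if missing:
            raise ConfigurationError(
                f"genotype {self.name!r} refers to parameters absent from the "
                f"parameter set: {missing}")
        if not zeroed:
            return parameters
        return parameters.with_updates({p: 0.0 for p in zeroed})


# -- the named systems used throughout the analysis ------------------------

WT = GenotypeSpec("WT")
NFKB2_NULL = GenotypeSpec("Nfkb2-null", {"Nfkb2"})
NFKBIA_NULL = GenotypeSpec("Nfkbia-null", {"Nfkbia"})
P52_NULL = GenotypeSpec("p52-null", {"p52-processing"})
RELA_NULL = GenotypeSpec("Rela-null", {"Rela"})
RELB_NULL = GenotypeSpec("Relb-null", {"Relb"})
RELB_NFKB2_NULL = GenotypeSpec("Relb-Nfkb2-null", {"Relb", "Nfkb2"})
RELA_NFKB2_NULL = GenotypeSpec("Rela-Nfkb2-null", {"Rela", "Nfkb2"})
#: cRel is not modelled, so loss of all transcription-competent subunits is
#: represented as the Rela/Relb double null
NFKB_DEFICIENT = GenotypeSpec("NF-kB-deficient", {"Rela", "Relb"})

NAMED_GENOTYPES = {
    g.name: g for g in (
        WT, NFKB2_NULL, NFKBIA_NULL, P52_NULL, RELA_NULL, RELB_NULL,
        RELB_NFKB2_NULL, RELA_NFKB2_NULL, NFKB_DEFICIENT)
}


def get_genotype(name: str) -> GenotypeSpec:
    try:
        return NAMED_GENOTYPES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown genotype {name!r}; known: {sorted(NAMED_GENOTYPES)}") from None
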