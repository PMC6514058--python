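"""Species catalog for the integrated NF-kB network.

The model tracks five Rel-family monomers, the four transcription-competent
heterodimers (RelA:p50 = A50, RelA:p52 = A52, RelB:p50 = B50, RelB:p52 = B52)
in cytoplasm and nucleus, the three classical IkB inhibitors, IkB:dimer and
p100:dimer sequestration complexes, and the four NF-kB-inducible mRNAs
(IkBa, IkBe, Nfkb2/p100 and Relb transcripts).

Naming conventions: a leading ``n`` marks a nuclear species (``nA50``,
``nIkBa``); a colon joins the partners of a complex (``IkBa:A50``); a leading
``t`` marks an mRNA (``tRelb``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"

MONOMER = "monomer"
DIMER = "dimer"
INHIBITOR = "inhibitor"
COMPLEX = "inhibitor-dimer complex"
MRNA = "mRNA"

#: dimer short name -> (Rel monomer, partner monomer)
DIMER_COMPOSITION = {
    "A50": ("RelA", "p50"),
    "A52": ("RelA", "p52"),
    "B50": ("RelB", "p50"),
    "B52": ("RelB", "p52"),
}

#: classical IkB inhibitors
IKB_NAMES = ("IkBa", "IkBb", "IkBe")

#: (inhibitor, dimer) pairs that form cytoplasmic complexes.  IkBb/IkBe bind
#: only RelA dimers; IkBa additionally retains a fraction of the RelB dimers
#: (the "less preferred" interactions of the network diagram).
IKB_DIMER_PAIRS = (
    ("IkBa", "A50"),
    ("IkBb", "A50"),
    ("IkBe", "A50"),
    ("IkBa", "A52"),
    ("IkBb", "A52"),
    ("IkBe", "A52"),
    ("IkBa", "B50"),
    ("IkBa", "B52"),
)

#: dimers sequestered by the p100 precursor (dimer-level sequestration)
P100_DIMER_PARTNERS = ("A50", "B50", "B52")

#: gene tag -> (mRNA species, translated protein species)
GENE_PRODUCTS = {
    "ikba": ("tIkBa", "IkBa"),
    "ikbe": ("tIkBe", "IkBe"),
    "nfkb2": ("tNfkb2", "p100"),
    "relb": ("tRelb", "RelB"),
}


@dataclass(frozen=True)
class SpeciesEntry:
    name: str
    compartment: str
    kind: str


@dataclass(frozen=True)
class SpeciesCatalog:
    """Ordered, immutable list of model species."""

    entries: tuple[SpeciesEntry, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[SpeciesEntry]:
        return iter(self.entries)

    def subset(self, kind: str | None = None, compartment: str | None = None):
        out = [e for e in self.entries
               if (kind is None or e.kind == kind)
               and (compartment is None or e.compartment == compartment)]
        return tuple(e.name for e in out)


def nuclear(name: str) -> str:
    """Nuclear counterpart of a cytoplasmic species name."""
    return "n" + name


def complex_name(inhibitor: str, dimer: str) -> str:
    return f"{inhibitor}:{dimer}"


def default_catalog() -> SpeciesCatalog:
    entries: list[SpeciesEntry] = []

    for m in ("RelA", "RelB", "p50", "p100", "p52"):
        entries.append(SpeciesEntry(m, CYTOPLASM, MONOMER))

    for d in DIMER_COMPOSITION:
        entries.append(SpeciesEntry(d, CYTOPLASM, DIMER))
    for d in DIMER_COMPOSITION:
        entries.append(SpeciesEntry(nuclear(d), NUCLEUS, DIMER))

    for i in IKB_NAMES:
        entries.append(SpeciesEntry(i, CYTOPLASM, INHIBITOR))
    for i in IKB_NAMES:
        entries.append(SpeciesEntry(nuclear(i), NUCLEUS, INHIBITOR))

    for i, d in IKB_DIMER_PAIRS:
        entries.append(SpeciesEntry(complex_name(i, d), CYTOPLASM, COMPLEX))
    # nuclear IkBa:dimer complexes exist transiently and are exported
    for d in DIMER_COMPOSITION:
        entries.append(SpeciesEntry(nuclear(complex_name("IkBa", d)), NUCLEUS, COMPLEX))

    for d in P100_DIMER_PARTNERS:
        entries.append(SpeciesEntry(complex_name("p100", d), CYTOPLASM, COMPLEX))

    for mrna, _ in GENE_PRODUCTS.values():
        entries.append(SpeciesEntry(mrna, CYTOPLASM, MRNA))

    catalog = SpeciesCatalog(tuple(entries))
    names = catalog.names
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in catalog")
    return catalog


def rel_content(catalog: SpeciesCatalog, monomer: str) -> dict[str, int]:
    """Stoichiometric content of ``monomer`` in every species.

    Used by the conservation checks: binding, transport and
    inhibitor-degradation reactions must leave the volume-weighted total of
    each monomer unchanged.
    """
    content: dict[str, int] = {}
    for entry in catalog.entries:
        base = entry.name[1:] if entry.name.startswith("n") and entry.kind != MRNA else entry.name
        count = 0
        if base == monomer:
            count = 1
        else:
            parts = base.split(":")
            dimer = parts[-1] if parts[-1] in DIMER_COMPOSITION else None
            if dimer is not None and monomer in DIMER_COMPOSITION[dimer]:
                count += 1
            if parts[0] == monomer:  # e.g. p100:B50 counts p100 content
                count += 1
        if count:
            content[entry.name] = count
    return content
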