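"""Reaction list of the integrated canonical/non-canonical NF-kB model.

The network couples the canonical module (IKK2-responsive IkBa/b/e
degradation releasing RelA dimers, with NF-kB-induced IkBa/IkBe negative
feedback) to the non-canonical components p100 and RelB: NF-kB-induced
synthesis of p100 (which sequesters RelB dimers and a subpopulation of
RelA:p50) and of Relb mRNA (driven by both RelA and RelB heterodimers, the
autoregulatory loop behind the late RelB:p50 response when p100 is absent).
IKK2 enters only as a prescribed activity multiplying the fast degradation
of the classical IkBs, free or complexed; canonical inducers never degrade
p100, whose turnover and basal processing to p52 are IKK2-independent.

Reaction groups instantiated here (per dimer D in {A50, A52, B50, B52} and
inhibitor I in {IkBa, IkBb, IkBe} where applicable):

1. constitutive protein synthesis of RelA, p50 and IkBb;
2. transcription (constitutive + induced by each nuclear dimer) of the
   IkBa, IkBe, Nfkb2 and Relb genes, mRNA decay, and translation;
3. reversible dimerisation of RelA/RelB with p50/p52 in the cytoplasm;
4. basal processing of free p100 into p52;
5. reversible binding of IkBa/b/e to RelA dimers, of IkBa to RelB dimers,
   and of p100 to A50/B50/B52 (dimer-level sequestration);
6. nuclear import of free dimers and free IkBs, IkBa binding to nuclear
   dimers, and export of the nuclear IkBa:dimer complexes;
7. constitutive degradation of free species and mRNAs, slow degradation of
   the inhibitor inside complexes (releasing the intact dimer), and fast
   IKK2-modulated degradation of cytoplasmic IkBs free and in complexes.
"""

from __future__ import annotations

from .network import Reaction
from .species import (DIMER_COMPOSITION, GENE_PRODUCTS, IKB_DIMER_PAIRS,
                      IKB_NAMES, P100_DIMER_PARTNERS, complex_name, nuclear)

DIMERS = tuple(DIMER_COMPOSITION)
GENES = tuple(GENE_PRODUCTS)

#: default cytoplasmic:nuclear volume ratio
NUCLEAR_VOLUME_FACTOR = 3.3


def parameter_names() -> tuple[str, ...]:
    names: list[str] = ["syn_rela", "syn_p50", "syn_ikbb"]
    for g in GENES:
        names.append(f"txn_{g}_const")
        names.extend(f"txn_{g}_{d.lower()}" for d in DIMERS)
        names.append(f"deg_t{g}")
        names.append(f"tl_{g}")
    for d in DIMERS:
        names.append(f"kdim_f_{d.lower()}")
        names.append(f"kdim_r_{d.lower()}")
    names.append("proc_p100")
    for i, d in IKB_DIMER_PAIRS:
        names.append(f"kib_f_{i.lower()}_{d.lower()}")
        names.append(f"kib_r_{i.lower()}_{d.lower()}")
    for d in P100_DIMER_PARTNERS:
        names.append(f"kp100_f_{d.lower()}")
        names.append(f"kp100_r_{d.lower()}")
    names.extend(["k_imp_dimer", "k_imp_ikb", "k_exp_complex"])
    names.extend(["deg_rela", "deg_relb", "deg_p50", "deg_p100", "deg_p52"])
    names.extend(f"deg_{d.lower()}" for d in DIMERS)
    for i in IKB_NAMES:
        names.append(f"deg_{i.lower()}")
        names.append(f"degc_{i.lower()}")
    names.append("degc_p100")
    for i in IKB_NAMES:
        names.append(f"ikk_deg_{i.lower()}")
        names.append(f"ikk_degc_{i.lower()}")
    return tuple(names)


def build_reactions(kv: float = NUCLEAR_VOLUME_FACTOR) -> tuple[Reaction, ...]:
    """Full reaction list; ``kv`` is the cytoplasm:nucleus volume ratio."""
    rxns: list[Reaction] = []
    add = rxns.append

    # 1. constitutive protein synthesis ------------------------------------
    add(Reaction("syn RelA", "syn_rela", (), (("RelA", 1.0),)))
    add(Reaction("syn p50", "syn_p50", (), (("p50", 1.0),)))
    add(Reaction("syn IkBb", "syn_ikbb", (), (("IkBb", 1.0),)))

    # 2. transcription, mRNA decay, translation ----------------------------
    for g in GENES:
        mrna, protein = GENE_PRODUCTS[g]
        add(Reaction(f"txn {g} const", f"txn_{g}_const", (), ((mrna, 1.0),)))
        for d in DIMERS:
            add(Reaction(f"txn {g} by n{d}", f"txn_{g}_{d.lower()}",
                         (nuclear(d),), ((mrna, 1.0),)))
        add(Reaction(f"decay {mrna}", f"deg_t{g}", (mrna,), ((mrna, -1.0),)))
        add(Reaction(f"translate {mrna}", f"tl_{g}", (mrna,), ((protein, 1.0),)))

    # 3. dimerisation ------------------------------------------------------
    for d, (rel, partner) in DIMER_COMPOSITION.items():
        dl = d.lower()
        add(Reaction(f"dimerise {d}", f"kdim_f_{dl}", (rel, partner),
                     ((rel, -1.0), (partner, -1.0), (d, 1.0))))
        add(Reaction(f"dissociate {d}", f"kdim_r_{dl}", (d,),
                     ((d, -1.0), (rel, 1.0), (partner, 1.0))))

    # 4. basal p100 -> p52 processing --------------------------------------
    add(Reaction("process p100", "proc_p100", ("p100",),
                 (("p100", -1.0), ("p52", 1.0))))

    # 5. cytoplasmic sequestration -----------------------------------------
    for i, d in IKB_DIMER_PAIRS:
        c = complex_name(i, d)
        tag = f"{i.lower()}_{d.lower()}"
        add(Reaction(f"bind {c}", f"kib_f_{tag}", (i, d),
                     ((i, -1.0), (d, -1.0), (c, 1.0))))
        add(Reaction(f"unbind {c}", f"kib_r_{tag}", (c,),
                     ((c, -1.0), (i, 1.0), (d, 1.0))))
    for d in P100_DIMER_PARTNERS:
        c = complex_name("p100", d)
        add(Reaction(f"bind {c}", f"kp100_f_{d.lower()}", ("p100", d),
                     (("p100", -1.0), (d, -1.0), (c, 1.0))))
        add(Reaction(f"unbind {c}", f"kp100_r_{d.lower()}", (c,),
                     ((c, -1.0), ("p100", 1.0), (d, 1.0))))

    # 6. nucleocytoplasmic transport ---------------------------------------
    # concentrations, not molecule numbers, are tracked per compartment:
    # a cytoplasmic loss of c nM appears as kv*c nM in the smaller nucleus
    for d in DIMERS:
        add(Reaction(f"import {d}", "k_imp_dimer", (d,),
                     ((d, -1.0), (nuclear(d), kv))))
    for i in IKB_NAMES:
        add(Reaction(f"import {i}", "k_imp_ikb", (i,),
                     ((i, -1.0), (nuclear(i), kv))))
    for d in DIMERS:
        nd, ni = nuclear(d), nuclear("IkBa")
        nc = nuclear(complex_name("IkBa", d))
        tag = f"ikba_{d.lower()}"
        add(Reaction(f"bind {nc}", f"kib_f_{tag}", (ni, nd),
                     ((ni, -1.0), (nd, -1.0), (nc, 1.0))))
        add(Reaction(f"unbind {nc}", f"kib_r_{tag}", (nc,),
                     ((nc, -1.0), (ni, 1.0), (nd, 1.0))))
        add(Reaction(f"export {nc}", "k_exp_complex", (nc,),
                     ((nc, -1.0), (complex_name("IkBa", d), 1.0 / kv))))

    # 7. degradation -------------------------------------------------------
    for m, k in (("RelA", "deg_rela"), ("RelB", "deg_relb"), ("p50", "deg_p50"),
                 ("p100", "deg_p100"), ("p52", "deg_p52")):
        add(Reaction(f"deg {m}", k, (m,), ((m, -1.0),)))
    for d in DIMERS:
        add(Reaction(f"deg {d}", f"deg_{d.lower()}", (d,), ((d, -1.0),)))
        add(Reaction(f"deg n{d}", f"deg_{d.lower()}", (nuclear(d),),
                     ((nuclear(d), -1.0),)))
    for i in IKB_NAMES:
        il = i.lower()
        add(Reaction(f"deg {i}", f"deg_{il}", (i,), ((i, -1.0),)))
        add(Reaction(f"deg n{i}", f"deg_{il}", (nuclear(i),),
                     ((nuclear(i), -1.0),)))
    # inhibitor turnover inside complexes releases the intact dimer
    for i, d in IKB_DIMER_PAIRS:
        c = complex_name(i, d)
        add(Reaction(f"deg {i} in {c}", f"degc_{i.lower()}", (c,),
                     ((c, -1.0), (d, 1.0))))
    for d in DIMERS:
        nc = nuclear(complex_name("IkBa", d))
        add(Reaction(f"deg IkBa in {nc}", "degc_ikba", (nc,),
                     ((nc, -1.0), (nuclear(d), 1.0))))
    for d in P100_DIMER_PARTNERS:
        c = complex_name("p100", d)
        add(Reaction(f"deg p100 in {c}", "degc_p100", (c,),
                     ((c, -1.0), (d, 1.0))))

    # IKK2-responsive degradation: cytoplasmic classical IkBs only ---------
    for i in IKB_NAMES:
        il = i.lower()
        add(Reaction(f"IKK2 deg {i}", f"ikk_deg_{il}", (i,),
                     ((i, -1.0),), ikk_modulated=True))
    for i, d in IKB_DIMER_PAIRS:
        c = complex_name(i, d)
        add(Reaction(f"IKK2 deg {i} in {c}", f"ikk_degc_{i.lower()}", (c,),
                     ((c, -1.0), (d, 1.0)), ikk_modulated=True))

    return tuple(rxns)


def group_assignment() -> dict[str, str]:
    """Functional parameter groups (species x function taxonomy).

    Groups are numbered Gr-I, Gr-II, ... in catalog order; ordering places
    the Relb synthesis group (constitutive transcription, the four induced
    transcription weights, and translation) fifth, i.e. ``Gr-V``.
    """
    from .parameters import roman

    blocks: list[tuple[str, tuple[str, ...]]] = [
        ("RelA synthesis", ("syn_rela",)),
        ("p50 synthesis", ("syn_p50",)),
        ("IkBa synthesis", ("txn_ikba_const", "txn_ikba_a50", "txn_ikba_a52",
                            "txn_ikba_b50", "txn_ikba_b52", "tl_ikba")),
        ("Nfkb2 synthesis", ("txn_nfkb2_const", "txn_nfkb2_a50", "txn_nfkb2_a52",
                             "txn_nfkb2_b50", "txn_nfkb2_b52", "tl_nfkb2")),
        ("Relb synthesis", ("txn_relb_const", "txn_relb_a50", "txn_relb_a52",
                            "txn_relb_b50", "txn_relb_b52", "tl_relb")),
        ("IkBb synthesis", ("syn_ikbb",)),
        ("IkBe synthesis", ("txn_ikbe_const", "txn_ikbe_a50", "txn_ikbe_a52",
                            "txn_ikbe_b50", "txn_ikbe_b52", "tl_ikbe")),
        ("IkBa mRNA decay", ("deg_tikba",)),
        ("IkBe mRNA decay", ("deg_tikbe",)),
        ("Nfkb2 mRNA decay", ("deg_tnfkb2",)),
        ("Relb mRNA decay", ("deg_trelb",)),
        ("A50 dimerisation", ("kdim_f_a50", "kdim_r_a50")),
        ("A52 dimerisation", ("kdim_f_a52", "kdim_r_a52")),
        ("B50 dimerisation", ("kdim_f_b50", "kdim_r_b50")),
        ("B52 dimerisation", ("kdim_f_b52", "kdim_r_b52")),
        ("p100 processing", ("proc_p100",)),
        ("IkBa-dimer binding", ("kib_f_ikba_a50", "kib_r_ikba_a50",
                                "kib_f_ikba_a52", "kib_r_ikba_a52",
                                "kib_f_ikba_b50", "kib_r_ikba_b50",
                                "kib_f_ikba_b52", "kib_r_ikba_b52")),
        ("IkBb-dimer binding", ("kib_f_ikbb_a50", "kib_r_ikbb_a50",
                                "kib_f_ikbb_a52", "kib_r_ikbb_a52")),
        ("IkBe-dimer binding", ("kib_f_ikbe_a50", "kib_r_ikbe_a50",
                                "kib_f_ikbe_a52", "kib_r_ikbe_a52")),
        ("p100-dimer binding", ("kp100_f_a50", "kp100_r_a50",
                                "kp100_f_b50", "kp100_r_b50",
                                "kp100_f_b52", "kp100_r_b52")),
        ("dimer nuclear import", ("k_imp_dimer",)),
        ("IkB nuclear import", ("k_imp_ikb",)),
        ("complex nuclear export", ("k_exp_complex",)),
        ("RelA degradation", ("deg_rela",)),
        ("RelB degradation", ("deg_relb",)),
        ("p50 degradation", ("deg_p50",)),
        ("p100 degradation", ("deg_p100", "degc_p100")),
        ("p52 degradation", ("deg_p52",)),
        ("dimer degradation", ("deg_a50", "deg_a52", "deg_b50", "deg_b52")),
        ("IkBa degradation", ("deg_ikba", "degc_ikba")),
        ("IkBb degradation", ("deg_ikbb", "degc_ikbb")),
        ("IkBe degradation", ("deg_ikbe", "degc_ikbe")),
        ("IKK2-responsive IkBa degradation", ("ikk_deg_ikba", "ikk_degc_ikba")),
        ("IKK2-responsive IkBb degradation", ("ikk_deg_ikbb", "ikk_degc_ikbb")),
        ("IKK2-responsive IkBe degradation", ("ikk_deg_ikbe", "ikk_degc_ikbe")),
    ]
    assignment: dict[str, str] = {}
    for number, (_desc, members) in enumerate(blocks, start=1):
        label = f"Gr-{roman(number)}"
        for name in members:
            assignment[name] = label

    expected = set(parameter_names())
    assigned = set(assignment)
    if assigned != expected:  # defensive: groups must partition the set
        raise AssertionError(
            f"group assignment mismatch: missing={sorted(expected - assigned)} "
            f"extra={sorted(assigned - expected)}")
    return assignment


GROUP_DESCRIPTIONS = {
    "Gr-V": ("Relb synthesis: constitutive and NF-kB-induced transcription "
             "plus translation of Relb mRNA"),
}
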