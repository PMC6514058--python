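"""Generic compiled mass-action reaction network.

Reactions carry a rate law of the form

    rate = k * [X1] * [X2] * IKK2(t)^flag

with zero, one or two rate-law reactants and an optional modulation by the
prescribed IKK2 activity.  Catalytic steps (e.g. transcription induced by a
nuclear dimer that is not consumed) are expressed by listing the catalyst as
a rate-law reactant while leaving it out of the net stoichiometry.
Stoichiometric coefficients may be non-integer: nuclear import/export steps
use the cytoplasmic:nuclear volume ratio so that molecule numbers, not
concentrations, are conserved across compartments.

The network is compiled once into index arrays and a dense stoichiometry
matrix; the right-hand side and its analytic Jacobian are then plain
vectorised numpy, which keeps stiff integration of the ~40-species system
fast enough for Monte Carlo sensitivity sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class Reaction:
    """One elementary step.

    ``rate_reactants`` are the species whose concentrations enter the rate
    law (at most two); ``stoich`` is the net change per firing as
    (species, coefficient) pairs.
    """

    name: str
    rate_param: str
    rate_reactants: tuple[str, ...]
    stoich: tuple[tuple[str, float], ...]
    ikk_modulated: bool = False

    def __post_init__(self):
        if len(self.rate_reactants) > 2:
            raise ConfigurationError(
                f"reaction {self.name!r}: mass action supports at most two "
                "rate-law reactants")


class CompiledNetwork:
    """Index-array representation of a reaction list."""

    def __init__(self, species_names, reactions, param_names):
        self.species_names = tuple(species_names)
        self.reactions = tuple(reactions)
        self.param_names = tuple(param_names)
        sidx = {s: i for i, s in enumerate(self.species_names)}
        pidx = {p: i for i, p in enumerate(self.param_names)}

        nr = len(self.reactions)
        ns = len(self.species_names)
        self.n_species = ns
        self.n_reactions = nr

        self.k_idx = np.empty(nr, dtype=np.intp)
        self.i1 = np.full(nr, -1, dtype=np.intp)
        self.i2 = np.full(nr, -1, dtype=np.intp)
        ikk = np.zeros(nr, dtype=bool)
        S = np.zeros((ns, nr))

        for r, rxn in enumerate(self.reactions):
            if rxn.rate_param not in pidx:
                raise ConfigurationError(
                    f"reaction {rxn.name!r}: unknown rate parameter "
                    f"{rxn.rate_param!r}")
            self.k_idx[r] = pidx[rxn.rate_param]
            for j, sp in enumerate(rxn.rate_reactants):
                if sp not in sidx:
                    raise ConfigurationError(
                        f"reaction {rxn.name!r}: unknown species {sp!r}")
                (self.i1 if j == 0 else self.i2)[r] = sidx[sp]
            ikk[r] = rxn.ikk_modulated
            for sp, coeff in rxn.stoich:
                if sp not in sidx:
                    raise ConfigurationError(
                        f"reaction {rxn.name!r}: unknown species {sp!r}")
                S[sidx[sp], r] += coeff

        self.ikk_flag = ikk
        self.S = S
        # masks precomputed for the vectorised rate evaluation
        self._m1 = self.i1 >= 0
        self._m2 = self.i2 >= 0
        self._j1 = np.where(self._m1, self.i1, 0)
        self._j2 = np.where(self._m2, self.i2, 0)

    # ------------------------------------------------------------- evaluation

    def fluxes(self, p: np.ndarray, x: np.ndarray, ikk_t: float) -> np.ndarray:
        """Per-reaction rates (nM/h in cytoplasmic concentration units)."""
        rate = p[self.k_idx].copy()
        rate[self._m1] *= x[self._j1[self._m1]]
        rate[self._m2] *= x[self._j2[self._m2]]
        rate[self.ikk_flag] *= ikk_t
        return rate

    def rhs(self, p: np.ndarray, x: np.ndarray, ikk_t: float) -> np.ndarray:
        dx = self.S @ self.fluxes(p, x, ikk_t)
        if not np.all(np.isfinite(dx)):
            bad = np.flatnonzero(~np.isfinite(self.S @ self.fluxes(p, x, ikk_t)))
            raise FloatingPointError(
                f"non-finite derivative for species "
                f"{[self.species_names[i] for i in bad[:5]]}")
        return dx

    def jac(self, p: np.ndarray, x: np.ndarray, ikk_t: float) -> np.ndarray:
        """Analytic Jacobian d(rhs)/dx."""
        k = p[self.k_idx].copy()
        k[self.ikk_flag] *= ikk_t
        nr, ns = self.n_reactions, self.n_species
        D = np.zeros((nr, ns))
        rows = np.arange(nr)

        both = self._m1 & self._m2
        only1 = self._m1 & ~self._m2
        # d(k*x1)/dx1 = k ; d(k*x1*x2)/dx1 = k*x2 (and symmetric)
        np.add.at(D, (rows[only1], self.i1[only1]), k[only1])
        np.add.at(D, (rows[both], self.i1[both]), k[both] * x[self.i2[both]])
        np.add.at(D, (rows[both], self.i2[both]), k[both] * x[self.i1[both]])
        return self.S @ D
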