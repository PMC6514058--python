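"""Model assembly, steady-state pre-equilibration and time-course simulation.

A :class:`ModelSystem` combines the species catalog, the compiled reaction
network, a genotype and the effective (post-knockout) parameter values.
Simulations are driven by a prescribed IKK2 activity profile; before any
stimulation the system is relaxed to its own steady state at the profile's
basal IKK2 level, so every genotype is compared against its own basal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root as _root

from . import nfkb_network
from .exceptions import ConfigurationError, ConvergenceError, SimulationError
from .genotypes import GenotypeSpec
from .network import CompiledNetwork
from .parameters import ParameterSet
from .species import SpeciesCatalog, default_catalog, nuclear

#: default integrator tolerances (stiff solver)
RTOL = 1e-8
ATOL = 1e-10
#: pre-equilibration horizon in hours
EQUILIBRATION_HORIZON = 500.0

NUCLEAR_DIMERS = ("nA50", "nA52", "nB50", "nB52")


@dataclass(frozen=True)
class ModelSystem:
    species: SpeciesCatalog
    network: CompiledNetwork
    parameters: ParameterSet          # effective values (genotype applied)
    base_parameters: ParameterSet     # pre-intervention values
    genotype: GenotypeSpec
    nuclear_volume_factor: float = nfkb_network.NUCLEAR_VOLUME_FACTOR
    _pvec: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.nuclear_volume_factor <= 0:
            raise ConfigurationError("nuclear_volume_factor must be positive")
        missing = [p for p in self.network.param_names if p not in self.parameters]
        if missing:
            raise ConfigurationError(
                f"parameter(s) missing from ParameterSet: {missing}")
        vec = np.array([self.parameters[p] for p in self.network.param_names])
        object.__setattr__(self, "_pvec", vec)

    @property
    def species_names(self) -> tuple[str, ...]:
        return self.network.species_names

    @property
    def n_species(self) -> int:
        return self.network.n_species

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def param_vector(self) -> np.ndarray:
        return self._pvec.copy()


def build_system(genotype: GenotypeSpec, parameters: ParameterSet,
                 nuclear_volume_factor: float = nfkb_network.NUCLEAR_VOLUME_FACTOR
                 ) -> ModelSystem:
    """Assemble the full NF-kB reaction system for one genotype."""
    catalog = default_catalog()
    reactions = nfkb_network.build_reactions(kv=nuclear_volume_factor)
    network = CompiledNetwork(catalog.names, reactions,
                              nfkb_network.parameter_names())
    effective = genotype.apply(parameters)
    return ModelSystem(catalog, network, effective, parameters, genotype,
                       nuclear_volume_factor)


def rhs(system: ModelSystem, state: np.ndarray, t: float, ikk) -> np.ndarray:
    """Time derivative of the concentration vector at time ``t``.

    ``ikk`` may be an IKK2 profile object (with ``evaluate``) or a constant.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (system.n_species,):
        raise ValueError(
            f"state must have {system.n_species} entries, got {state.shape}")
    if np.any(state < -1e-6):
        bad = int(np.argmin(state))
        raise FloatingPointError(
            f"state entry {system.species_names[bad]!r} is negative beyond "
            f"tolerance: {state[bad]:.3e}")
    ikk_t = ikk.evaluate(t) if hasattr(ikk, "evaluate") else float(ikk)
    return system.network.rhs(system._pvec, state, ikk_t)


def _constant_field(system: ModelSystem, ikk_value: float):
    net, p = system.network, system._pvec

    def f(x):
        return net.rhs(p, np.maximum(x, 0.0), ikk_value)

    def j(x):
        return net.jac(p, np.maximum(x, 0.0), ikk_value)

    return f, j


def _newton_polish(f, j, x, tol, max_iter=60):
    """Damped Newton iteration projected onto the nonnegative orthant.

    Robust near a physical root where unconstrained solvers can wander to
    negative-concentration solutions of the mass-action equations.
    """
    x = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        r = f(x)
        norm = np.max(np.abs(r))
        if norm < 0.01 * tol:
            break
        try:
            step = np.linalg.solve(j(x), -r)
        except np.linalg.LinAlgError:
            break
        lam, improved = 1.0, False
        for _ in range(12):
            x_new = np.maximum(x + lam * step, 0.0)
            if np.max(np.abs(f(x_new))) < norm:
                x, improved = x_new, True
                break
            lam *= 0.5
        if not improved:
            break
    return x


def steady_state(system: ModelSystem, basal_ikk: float,
                 horizon: float = EQUILIBRATION_HORIZON,
                 initial: np.ndarray | None = None,
                 residual_tol: float = 1e-8) -> np.ndarray:
    """Pre-stimulus steady state under constant basal IKK2 activity.

    Long-horizon stiff integration followed by a Newton polish; the result
    is checked to satisfy max|d[X]/dt| < ``residual_tol`` nM/h.
    """
    if basal_ikk < 0:
        raise ConfigurationError("basal_ikk must be >= 0")
    f, j = _constant_field(system, basal_ikk)
    x0 = np.zeros(system.n_species) if initial is None else np.asarray(initial, float)

    sol = solve_ivp(lambda t, x: f(x), (0.0, horizon), x0, method="LSODA",
                    jac=lambda t, x: j(x), rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise ConvergenceError(f"equilibration failed: {sol.message}")
    x = np.maximum(sol.y[:, -1], 0.0)

    def resid(y):
        return float(np.max(np.abs(f(y))))

    best = _newton_polish(f, j, x, residual_tol)
    if resid(best) >= residual_tol:
        # a physical hybr root is accepted if it beats the current iterate
        res = _root(f, best, jac=j, method="hybr")
        cand = np.maximum(res.x, 0.0)
        if np.min(res.x) > -1e-6 and resid(cand) < resid(best):
            best = cand

    if resid(best) >= residual_tol:
        # last resort: longer relaxation (slow sequestration reservoirs)
        sol = solve_ivp(lambda t, x_: f(x_), (0.0, 10 * horizon), best,
                        method="LSODA", jac=lambda t, x_: j(x_),
                        rtol=RTOL, atol=ATOL)
        if sol.success:
            cand = _newton_polish(f, j, np.maximum(sol.y[:, -1], 0.0),
                                  residual_tol)
            if resid(cand) < resid(best):
                best = cand

    residual = resid(best)
    if residual > residual_tol:
        raise ConvergenceError(
            f"steady state not converged after {horizon} h: max residual "
            f"{residual:.3e} nM/h", residual=residual)
    return best


def steady_state_fast(system: ModelSystem, basal_ikk: float,
                      guess: np.ndarray) -> np.ndarray:
    """Newton-only steady state from a nearby guess (Monte Carlo fast path).

    Falls back to the full integrate-and-polish route when the Newton solve
    leaves the physical (nonnegative) region or does not converge.
    """
    f, j = _constant_field(system, basal_ikk)
    res = _root(f, np.asarray(guess, float), jac=j, method="hybr")
    if res.success and np.all(res.x > -1e-9):
        x = np.maximum(res.x, 0.0)
        if float(np.max(np.abs(f(x)))) < 1e-8:
            return x
    return steady_state(system, basal_ikk)


def simulation_grid(horizon: float, transient_end: float = 2.0,
                    fine_step: float = 0.01, coarse_step: float = 0.05,
                    extra_transients: tuple[float, ...] = ()) -> np.ndarray:
    """Output grid: fine sampling near input transients, coarser elsewhere."""
    pieces = [np.arange(0.0, min(transient_end, horizon), fine_step)]
    for onset in extra_transients:
        if onset < horizon:
            pieces.append(np.arange(onset, min(onset + transient_end, horizon),
                                    fine_step))
    pieces.append(np.arange(0.0, horizon, coarse_step))
    grid = np.concatenate(pieces + [np.array([horizon])])
    return np.unique(np.round(grid, 9))


def simulate(system: ModelSystem, ikk, horizon: float,
             initial: np.ndarray | None = None,
             t_eval: np.ndarray | None = None,
             rtol: float = RTOL, atol: float = ATOL) -> "Trajectory":
    """Stimulated time course from 0 to ``horizon`` hours.

    ``initial`` defaults to the steady state at the profile's basal IKK2
    level, recorded on the trajectory as the basal reference state.
    """
    if horizon <= 0:
        raise ConfigurationError("horizon must be positive")
    basal_ikk = getattr(ikk, "basal", None)
    if initial is None:
        if basal_ikk is None:
            raise ConfigurationError(
                "an explicit initial state is required for inputs without a "
                "basal attribute")
        initial = steady_state(system, basal_ikk)
    initial = np.asarray(initial, dtype=float)

    support_end = getattr(ikk, "support_end", None)
    if support_end is not None and horizon < support_end:
        import warnings
        warnings.warn(
            f"horizon {horizon} h shorter than input support ({support_end} h)",
            stacklevel=2)

    if t_eval is None:
        onsets = tuple(getattr(ikk, "onsets", ()))
        t_eval = simulation_grid(horizon, extra_transients=onsets)

    net, p = system.network, system._pvec
    if hasattr(ikk, "evaluate"):
        ikk_at = ikk.evaluate
    else:
        const = float(ikk)
        ikk_at = lambda t: const  # noqa: E731

    def f(t, x):
        return net.rhs(p, np.maximum(x, 0.0), ikk_at(t))

    def j(t, x):
        return net.jac(p, np.maximum(x, 0.0), ikk_at(t))

    sol = solve_ivp(f, (0.0, float(horizon)), initial, method="LSODA", jac=j,
                    t_eval=np.asarray(t_eval, float), rtol=rtol, atol=atol,
                    max_step=0.25)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(f"integration failed at t={last:.3f} h: "
                              f"{sol.message}", last_time=last)
    states = np.maximum(sol.y.T, 0.0)
    return Trajectory(times=sol.t.copy(), states=states, system=system,
                      basal_state=initial.copy())


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed concentrations plus derived nuclear-activity curves."""

    times: np.ndarray
    states: np.ndarray           # (n_times, n_species)
    system: ModelSystem
    basal_state: np.ndarray | None = None

    def __post_init__(self):
        if self.states.shape != (self.times.size, self.system.n_species):
            raise ValueError("states shape inconsistent with times/species")

    @property
    def species_names(self) -> tuple[str, ...]:
        return self.system.species_names

    def concentration(self, name: str) -> np.ndarray:
        return self.states[:, self.system.species_index(name)]

    def basal_concentration(self, name: str) -> float:
        if self.basal_state is None:
            raise ValueError("trajectory has no basal reference state")
        return float(self.basal_state[self.system.species_index(name)])

    def _sum(self, names) -> np.ndarray:
        idx = [self.system.species_index(n) for n in names]
        return self.states[:, idx].sum(axis=1)

    def _basal_sum(self, names) -> float:
        return float(sum(self.basal_concentration(n) for n in names))

    @property
    def nfkbn(self) -> np.ndarray:
        """Total nuclear NF-kB activity: nA50 + nA52 + nB50 + nB52 (nM)."""
        return self._sum(NUCLEAR_DIMERS)

    @property
    def nrela(self) -> np.ndarray:
        """Nuclear RelA activity: nA50 + nA52 (nM)."""
        return self._sum(("nA50", "nA52"))

    @property
    def nrelb(self) -> np.ndarray:
        """Nuclear RelB activity: nB50 + nB52 (nM)."""
        return self._sum(("nB50", "nB52"))

    def basal_nfkbn(self) -> float:
        return self._basal_sum(NUCLEAR_DIMERS)

    def basal_nrela(self) -> float:
        return self._basal_sum(("nA50", "nA52"))

    def basal_nrelb(self) -> float:
        return self._basal_sum(("nB50", "nB52"))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species_names))
        df.insert(0, "time_h", self.times)
        df["NF-kBn"] = self.nfkbn
        df["nRelA"] = self.nrela
        df["nRelB"] = self.nrelb
        return df

    def rel_totals(self, monomer: str) -> np.ndarray:
        """Volume-weighted total content of a Rel-family monomer over time.

        Nuclear concentrations are down-weighted by the volume ratio so the
        sum is proportional to molecule number; conserved when synthesis,
        degradation and processing are switched off.
        """
        from .species import rel_content
        content = rel_content(self.system.species, monomer)
        kv = self.system.nuclear_volume_factor
        total = np.zeros(self.times.size)
        nuclear_names = {e.name for e in self.system.species.entries
                         if e.compartment == "nucleus"}
        for name, count in content.items():
            weight = count / kv if name in nuclear_names else float(count)
            total += weight * self.concentration(name)
        return total
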