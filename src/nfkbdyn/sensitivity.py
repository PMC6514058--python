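"""Variance-based and local sensitivity analysis over parameter groups.

Each functional parameter group is treated as a single uncertain factor: one
multiplicative scalar per group, drawn uniformly from [1 - r, 1 + r]
(r = 10% by default) and applied to every rate constant in the group.  The
total effect index ST of each group on a scalar model readout is estimated
with the Jansen form of the Sobol total-effect estimator on the classic
two-matrix (radial) design:

    ST_i = E[(f(A) - f(A_B^i))^2] / (2 * V[f])

where A_B^i equals sample matrix A with column i replaced from matrix B.
First-order indices use the companion Jansen estimator
S1_i = (V - E[(f(B) - f(A_B^i))^2] / 2) / V.  Percentile bootstrap over
sample rows supplies error ranges.  The default model readout is the late
(6-8 h) basal-corrected nuclear RelB:p50 AUC of the p100-deficient system
under the brief TNF pulse — the quantity whose control the grouped analysis
is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ConfigurationError, ValidationError
from .genotypes import GenotypeSpec, NFKB2_NULL
from .ikk import DEFAULT_BASAL, make_tnfp_profile
from .metrics import LATE_WINDOW
from .parameters import ParameterSet
from .system import build_system, simulate, steady_state, steady_state_fast

DEFAULT_RANGE = 0.10
DEFAULT_N_SAMPLES = 1000
DEFAULT_N_BOOTSTRAP = 200


@dataclass(frozen=True)
class SensitivityDesign:
    groups: tuple[str, ...]
    range_fraction: float = DEFAULT_RANGE
    n_samples: int = DEFAULT_N_SAMPLES
    output: str = "late-RelB:p50-AUC|Nfkb2-null|TNFp"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if not 0 < self.range_fraction < 1:
            raise ConfigurationError("range_fraction must lie in (0, 1)")
        if self.n_samples < 8:
            raise ConfigurationError("n_samples must be >= 8")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("duplicate group identifiers")


@dataclass(frozen=True)
class TotalEffectResult:
    groups: tuple[str, ...]
    st: np.ndarray
    st_lower: np.ndarray
    st_upper: np.ndarray
    s1: np.ndarray
    n_bootstrap: int
    n_samples: int
    n_discarded: int
    output: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": list(self.groups), "ST": self.st,
                             "ST_lower": self.st_lower,
                             "ST_upper": self.st_upper, "S1": self.s1})

    def top_group(self) -> str:
        return self.groups[int(np.argmax(self.st))]


def _jansen(f_a: np.ndarray, f_b: np.ndarray, f_ab: np.ndarray):
    """Jansen ST and S1 estimators; f_ab has shape (k, n)."""
    allf = np.concatenate([f_a, f_b])
    v = float(np.var(allf, ddof=1))
    if v <= 0:
        return np.zeros(f_ab.shape[0]), np.zeros(f_ab.shape[0])
    st = 0.5 * np.mean((f_a[None, :] - f_ab) ** 2, axis=1) / v
    s1 = (v - 0.5 * np.mean((f_b[None, :] - f_ab) ** 2, axis=1)) / v
    return st, s1


def total_effect_indices(design: SensitivityDesign, evaluate,
                         n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
                         parameters: ParameterSet | None = None
                         ) -> TotalEffectResult:
    """Grouped Sobol total-effect indices of ``evaluate``.

    ``evaluate`` maps a vector of per-group multiplicative factors (aligned
    with ``design.groups``) to a scalar readout; evaluation failures are
    discarded row-wise and more than 5% of failed rows abort the analysis.
    When a ``parameters`` set is supplied, the design's groups are checked
    against its group partition.
    """
    if parameters is not None:
        known = set(parameters.groups)
        unknown = sorted(set(design.groups) - known)
        if unknown:
            raise ConfigurationError(
                f"design groups absent from the parameter partition: {unknown}")
    k = len(design.groups)
    n = design.n_samples
    r = design.range_fraction
    rng = np.random.default_rng(design.seed)
    A = rng.uniform(1 - r, 1 + r, size=(n, k))
    B = rng.uniform(1 - r, 1 + r, size=(n, k))

    def safe(row) -> float:
        try:
            return float(evaluate(row))
        except Exception:
            return float("nan")

    f_a = np.array([safe(A[i]) for i in range(n)])
    f_b = np.array([safe(B[i]) for i in range(n)])
    f_ab = np.empty((k, n))
    for j in range(k):
        AB = A.copy()
        AB[:, j] = B[:, j]
        f_ab[j] = [safe(AB[i]) for i in range(n)]

    bad = np.isnan(f_a) | np.isnan(f_b) | np.isnan(f_ab).any(axis=0)
    n_bad = int(bad.sum())
    if n_bad > 0.05 * n:
        raise AnalysisError(
            f"{n_bad}/{n} Monte Carlo draws failed (> 5%); aborting")
    keep = ~bad
    f_a, f_b, f_ab = f_a[keep], f_b[keep], f_ab[:, keep]
    n_kept = int(keep.sum())

    st, s1 = _jansen(f_a, f_b, f_ab)

    boot = np.empty((n_bootstrap, k))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_kept, size=n_kept)
        boot[b], _ = _jansen(f_a[idx], f_b[idx], f_ab[:, idx])
    lower = np.percentile(boot, 2.5, axis=0)
    upper = np.percentile(boot, 97.5, axis=0)
    # percentile intervals are widened, if needed, to contain the point
    # estimate (tiny-sample bootstrap can otherwise just miss it)
    lower = np.minimum(lower, st)
    upper = np.maximum(upper, st)

    return TotalEffectResult(design.groups, st, lower, upper, s1,
                             n_bootstrap, n_kept, n_bad, design.output,
                             design.seed)


# ---------------------------------------------------------------------------
# model readout used by the grouped analysis


def _late_window_auc(times: np.ndarray, values: np.ndarray, basal: float
                     ) -> float:
    lo, hi = LATE_WINDOW
    y = np.clip(values - basal, 0.0, None)
    tt = np.unique(np.concatenate(([lo], times[(times > lo) & (times < hi)],
                                   [hi])))
    return float(np.trapezoid(np.interp(tt, times, y), tt))


class LateRelBObjective:
    """Late (6-8 h) basal-corrected nuclear RelB:p50 AUC under the brief
    TNF pulse, as a function of per-group parameter factors.

    Each draw rebuilds the system with the scaled parameters,
    re-equilibrates at basal IKK2 (Newton polish seeded from the nominal
    steady state) and simulates the pulse, so basal corrections stay
    consistent draw by draw.
    """

    def __init__(self, parameters: ParameterSet, groups,
                 genotype: GenotypeSpec = NFKB2_NULL,
                 basal: float = DEFAULT_BASAL,
                 species: str = "nB50",
                 rtol: float = 1e-6, atol: float = 1e-9):
        self.parameters = parameters
        self.groups = tuple(groups)
        self.genotype = genotype
        self.basal = basal
        self.species = species
        self.rtol = rtol
        self.atol = atol
        self.profile = make_tnfp_profile(basal)
        ref_system = build_system(genotype, parameters)
        self._ref_ss = steady_state(ref_system, basal)
        self._t_eval = np.unique(np.concatenate(
            [np.arange(0.0, 2.0, 0.02), np.arange(0.0, 8.0, 0.1), [8.0]]))

    def __call__(self, factors) -> float:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (len(self.groups),):
            raise ValidationError(
                f"expected {len(self.groups)} group factors, got "
                f"{factors.shape}")
        scaled = self.parameters.scaled_by_group(
            dict(zip(self.groups, factors)))
        system = build_system(self.genotype, scaled)
        ss = steady_state_fast(system, self.basal, guess=self._ref_ss)
        traj = simulate(system, self.profile, 8.0, initial=ss,
                        t_eval=self._t_eval, rtol=self.rtol, atol=self.atol)
        values = traj.concentration(self.species)
        basal_value = float(ss[system.species_index(self.species)])
        return _late_window_auc(traj.times, values, basal_value)


# ---------------------------------------------------------------------------
# local (+10%) sensitivity


@dataclass(frozen=True)
class LocalPerturbationResult:
    scores: dict[str, float]      # per-parameter normalised effect scores
    reference_value: float
    delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": list(self.scores),
                             "effect_score": list(self.scores.values())})


def local_sensitivity(parameter_names, base_parameters: ParameterSet,
                      objective, delta: float = 0.10
                      ) -> LocalPerturbationResult:
    """Effect of a fractional increase applied to each parameter in turn.

    ``objective`` maps a ParameterSet to the scalar readout (re-equilibrating
    internally); the effect score is the perturbed-minus-unperturbed readout
    normalised to the unperturbed value.
    """
    if delta <= 0:
        raise ConfigurationError("delta must be positive")
    missing = [p for p in parameter_names if p not in base_parameters]
    if missing:
        raise ConfigurationError(f"unknown parameters: {missing}")
    ref = float(objective(base_parameters))
    if ref == 0:
        raise AnalysisError("unperturbed readout is zero; cannot normalise")
    scores: dict[str, float] = {}
    for name in parameter_names:
        perturbed = base_parameters.scaled({name: 1.0 + delta})
        scores[name] = (float(objective(perturbed)) - ref) / ref
    return LocalPerturbationResult(scores, ref, delta)


def make_late_relb_parameter_objective(genotype: GenotypeSpec = NFKB2_NULL,
                                       basal: float = DEFAULT_BASAL,
                                       species: str = "nB50"):
    """Parameter-level objective matching :class:`LateRelBObjective`."""
    profile = make_tnfp_profile(basal)
    t_eval = np.unique(np.concatenate(
        [np.arange(0.0, 2.0, 0.02), np.arange(0.0, 8.0, 0.05), [8.0]]))

    def objective(params: ParameterSet) -> float:
        system = build_system(genotype, params)
        ss = steady_state(system, basal)
        traj = simulate(system, profile, 8.0, initial=ss, t_eval=t_eval)
        values = traj.concentration(species)
        basal_value = float(ss[system.species_index(species)])
        return _late_window_auc(traj.times, values, basal_value)

    return objective


# ---------------------------------------------------------------------------
# Relb transcription-source ablation


ABLATION_VARIANTS = ("both", "RelA-only", "RelB-only", "none")

_RELA_WEIGHTS = ("txn_relb_a50", "txn_relb_a52")
_RELB_WEIGHTS = ("txn_relb_b50", "txn_relb_b52")


def relb_source_ablation(parameters: ParameterSet,
                         genotype: GenotypeSpec = NFKB2_NULL,
                         basal: float = DEFAULT_BASAL,
                         match_basal: bool = True) -> pd.DataFrame:
    """Late nuclear RelB under rewired Relb transcription sources.

    Variants: induced by both RelA and RelB dimers (the unablated model),
    by RelA dimers alone, by RelB dimers alone, or constitutive-only.  With
    ``match_basal`` the constitutive transcription rate absorbs the
    pre-stimulus induced flux of the removed weights (computed at the
    unablated steady state), so variants start from comparable basal RelB
    synthesis and differences reflect inducible wiring.
    """
    base_system = build_system(genotype, parameters)
    ss0 = steady_state(base_system, basal)

    def basal_flux(weight_names) -> float:
        total = 0.0
        for w in weight_names:
            dimer = "n" + w.rsplit("_", 1)[1].upper()
            conc = float(ss0[base_system.species_index(dimer)])
            total += base_system.parameters[w] * conc
        return total

    removed = {"both": (), "RelA-only": _RELB_WEIGHTS,
               "RelB-only": _RELA_WEIGHTS,
               "none": _RELA_WEIGHTS + _RELB_WEIGHTS}

    profile = make_tnfp_profile(basal)
    rows = []
    for variant in ABLATION_VARIANTS:
        weights = removed[variant]
        updates = {w: 0.0 for w in weights}
        if match_basal and weights:
            updates["txn_relb_const"] = (parameters["txn_relb_const"]
                                         + basal_flux(weights))
        params_v = parameters.with_updates(updates) if updates else parameters
        system = build_system(genotype, params_v)
        ss = steady_state(system, basal, initial=ss0)
        traj = simulate(system, profile, 8.0, initial=ss)
        basal_nrelb = float(ss[system.species_index("nB50")]
                            + ss[system.species_index("nB52")])
        late = _late_window_auc(traj.times, traj.nrelb, basal_nrelb)
        rows.append({"variant": variant, "late_nrelb_auc": late})
    return pd.DataFrame(rows)
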