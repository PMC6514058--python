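"""Synthetic IKK2 activity inputs.

The model's sole stimulus interface is a prescribed IKK2 kinase-activity
time course (nM vs h).  This module generates every input the analyses
consume: parametric pulses of requested peak amplitude and threshold-rule
duration, emulations of the kinase profiles seen under brief (TNFp,
0.5 h treatment), chronic (TNFc) TNF and IL-1b stimulation, and pulse-train
compositions for the repeated-stimulation regime.  All profiles are
deterministic, continuous and bounded; before time zero they sit at the
basal activity.

The TNFp/TNFc/IL-1b emulations are piecewise-exponential stand-ins for the
experimentally measured kinase curves, which are not available; only their
qualitative features are constrained (an early peak within 0.25 h, return
to near-basal within 1 h for the brief pulse, a sustained plateau through
at least 8 h for chronic stimulation).  The shape constants live in
:data:`PROFILE_CONSTANTS` and are echoed into run records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import SpecificationError

#: basal IKK2 activity (nM); a small positive constant sustaining the
#: nonzero basal nuclear NF-kB activity seen in unstimulated cells
DEFAULT_BASAL = 0.2

PROFILE_CONSTANTS = {
    "basal_nM": DEFAULT_BASAL,
    "tnfp_peak_nM": 60.0,
    "tnfp_peak_time_h": 0.2,
    "tnfp_decay_tau_h": 0.26,
    "tnfc_peak_nM": 60.0,
    "tnfc_peak_time_h": 0.2,
    "tnfc_decay_tau_h": 0.5,
    "tnfc_plateau_fraction": 0.5,
    "tnfc_support_end_h": 48.0,
    "il1b_peak_nM": 40.0,
    "il1b_peak_time_h": 0.25,
    "il1b_decay_tau_h": 0.25,
}

#: fraction of the basal-corrected peak defining the duration threshold
THRESHOLD_FRACTION = 0.05


@dataclass(frozen=True)
class IKKProfile:
    """A prescribed IKK2 activity input.

    ``corrected`` maps time (h, array) to basal-corrected activity (nM,
    >= 0, and 0 for t < 0); ``evaluate`` adds the basal.  ``onsets`` lists
    stimulation onset times for grid refinement in the integrator.
    """

    basal: float
    support_end: float
    corrected: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    name: str = "profile"
    onsets: tuple[float, ...] = (0.0,)

    def evaluate(self, t):
        t_arr = np.asarray(t, dtype=float)
        value = self.basal + self.corrected(t_arr)
        return float(value) if np.isscalar(t) or t_arr.ndim == 0 else value

    @property
    def peak(self) -> float:
        """Maximum activity located on a fine grid over the support."""
        grid = np.linspace(0.0, max(self.support_end, 1e-6), 20001)
        return float(np.max(self.evaluate(grid)))

    def area_above_basal(self, n: int = 200001) -> float:
        """Fine-grid trapezoid quadrature of the basal-corrected activity."""
        grid = np.linspace(0.0, max(self.support_end, 1e-6), n)
        return float(np.trapezoid(self.corrected(grid), grid))

    def to_frame(self, grid: np.ndarray) -> pd.DataFrame:
        grid = np.asarray(grid, dtype=float)
        return pd.DataFrame({"time_h": grid, "ikk_nM": self.evaluate(grid)})

    def to_tsv(self, path, grid: np.ndarray) -> None:
        self.to_frame(grid).to_csv(path, sep="\t", index=False)


def constant_profile(level: float, name: str = "constant") -> IKKProfile:
    """Flat profile at ``level`` (basal equals the level; no excursion)."""
    return IKKProfile(basal=level, support_end=0.0,
                      corrected=lambda t: np.zeros_like(np.asarray(t, float)),
                      name=name, onsets=())


@dataclass(frozen=True)
class TheoreticalPulseSpec:
    """Parametric pulse: requested peak amplitude and threshold-rule duration.

    ``shape`` selects piecewise-exponential ('exp', default) or piecewise
    linear trapezoid ('linear') rise/fall segments.
    """

    peak_amplitude: float
    duration: float
    rise_time: float = 0.25
    fall_time: float = 0.25
    shape: str = "exp"

    def __post_init__(self):
        if self.duration <= 0:
            raise SpecificationError("duration must be positive")
        if self.rise_time <= 0 or self.fall_time <= 0:
            raise SpecificationError("rise_time and fall_time must be positive")
        if self.duration < self.rise_time + self.fall_time:
            raise SpecificationError(
                f"duration {self.duration} h shorter than rise_time + "
                f"fall_time = {self.rise_time + self.fall_time} h")
        if self.shape not in ("exp", "linear"):
            raise SpecificationError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class PulseTrainSpec:
    n_pulses: int
    separation: float          # onset-to-onset, h
    base_pulse: IKKProfile

    def __post_init__(self):
        if self.n_pulses < 1:
            raise SpecificationError("n_pulses must be >= 1")
        if self.separation < 0:
            raise SpecificationError("separation must be >= 0")


def make_theoretical_profile(spec: TheoreticalPulseSpec,
                             basal: float = DEFAULT_BASAL) -> IKKProfile:
    """Pulse whose 5%-threshold duration equals the requested duration.

    The rise/plateau/fall switch points are placed analytically so that the
    time spent above basal + 5% of the basal-corrected peak matches
    ``spec.duration`` (a flat profile results when the peak equals basal).
    """
    if spec.peak_amplitude < basal:
        raise SpecificationError(
            f"peak_amplitude {spec.peak_amplitude} below basal {basal}")
    amp = spec.peak_amplitude - basal
    if amp == 0.0:
        return constant_profile(basal, name="flat-pulse")

    r, f, d = spec.rise_time, spec.fall_time, spec.duration
    if spec.shape == "exp":
        tau_r = r / 3.0
        norm = 1.0 - math.exp(-r / tau_r)
        tau_f = f / math.log(1.0 / THRESHOLD_FRACTION)
        # threshold crossing on the rising edge
        t_rise_cross = -tau_r * math.log(1.0 - THRESHOLD_FRACTION * norm)
        # fall crosses the threshold exactly fall_time after the plateau ends
        t_off = d + t_rise_cross - f
        t_end = t_off + 5.0 * f

        def corrected(t):
            t = np.asarray(t, dtype=float)
            out = np.zeros_like(t)
            rising = (t >= 0) & (t < r)
            out[rising] = amp * (1.0 - np.exp(-t[rising] / tau_r)) / norm
            plateau = (t >= r) & (t < t_off)
            out[plateau] = amp
            falling = t >= t_off
            out[falling] = amp * np.exp(-(t[falling] - t_off) / tau_f)
            return out
    else:  # linear trapezoid
        t_rise_cross = THRESHOLD_FRACTION * r
        t_off = d + t_rise_cross - (1.0 - THRESHOLD_FRACTION) * f
        t_end = t_off + f

        def corrected(t):
            t = np.asarray(t, dtype=float)
            out = np.zeros_like(t)
            rising = (t >= 0) & (t < r)
            out[rising] = amp * t[rising] / r
            plateau = (t >= r) & (t < t_off)
            out[plateau] = amp
            falling = (t >= t_off) & (t < t_off + f)
            out[falling] = amp * (1.0 - (t[falling] - t_off) / f)
            return out

    if t_off < r:
        raise SpecificationError(
            f"requested duration {d} h leaves no plateau (rise {r} h, "
            f"fall {f} h)")
    return IKKProfile(basal=basal, support_end=t_end, corrected=corrected,
                      name=f"pulse-{spec.peak_amplitude:g}nM-{d:g}h")


def trapezoid_profile(peak_amplitude: float, rise_time: float, plateau: float,
                      fall_time: float, basal: float = DEFAULT_BASAL
                      ) -> IKKProfile:
    """Explicit linear trapezoid (rise r, flat plateau p, fall f).

    Area above basal is analytically A * (p + (r + f) / 2) where A is the
    basal-corrected peak.
    """
    amp = peak_amplitude - basal
    if amp < 0:
        raise SpecificationError("peak_amplitude below basal")
    r, p, f = rise_time, plateau, fall_time

    def corrected(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rising = (t >= 0) & (t < r)
        out[rising] = amp * t[rising] / r
        flat = (t >= r) & (t < r + p)
        out[flat] = amp
        falling = (t >= r + p) & (t < r + p + f)
        out[falling] = amp * (1.0 - (t[falling] - r - p) / f)
        return out

    return IKKProfile(basal=basal, support_end=r + p + f, corrected=corrected,
                      name="trapezoid")


def _peak_decay_profile(peak: float, peak_time: float, decay_tau: float,
                        plateau_fraction: float, support_end: float,
                        basal: float, name: str) -> IKKProfile:
    """Fast saturating rise to the peak, then exponential decay toward a
    plateau (zero plateau fraction gives a transient pulse)."""
    amp = peak - basal
    tau_r = peak_time / 3.0
    norm = 1.0 - math.exp(-peak_time / tau_r)
    tail_tau = 0.5  # h; terminal relaxation beyond the support

    def corrected(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rising = (t >= 0) & (t < peak_time)
        out[rising] = amp * (1.0 - np.exp(-t[rising] / tau_r)) / norm
        after = t >= peak_time
        ta = t[after] - peak_time
        level = amp * ((1.0 - plateau_fraction) * np.exp(-ta / decay_tau)
                       + plateau_fraction)
        over = t[after] > support_end
        level[over] *= np.exp(-(t[after][over] - support_end) / tail_tau)
        out[after] = level
        return out

    return IKKProfile(basal=basal, support_end=support_end + 5.0 * tail_tau,
                      corrected=corrected, name=name)


def make_tnfp_profile(basal: float = DEFAULT_BASAL) -> IKKProfile:
    """IKK2 activity under brief (0.5 h) TNF treatment: sharp early peak,
    back within 5% of the basal-corrected peak by 1 h."""
    c = PROFILE_CONSTANTS
    return _peak_decay_profile(c["tnfp_peak_nM"], c["tnfp_peak_time_h"],
                               c["tnfp_decay_tau_h"], 0.0, 3.0, basal, "TNFp")


def make_tnfc_profile(basal: float = DEFAULT_BASAL) -> IKKProfile:
    """IKK2 activity under chronic TNF treatment: the same early peak
    followed by a sustained plateau through the simulation horizon."""
    c = PROFILE_CONSTANTS
    return _peak_decay_profile(c["tnfc_peak_nM"], c["tnfc_peak_time_h"],
                               c["tnfc_decay_tau_h"], c["tnfc_plateau_fraction"],
                               c["tnfc_support_end_h"], basal, "TNFc")


def make_il1b_profile(basal: float = DEFAULT_BASAL) -> IKKProfile:
    """Transient IL-1b-like IKK2 input (TNFp-like shape, lower peak)."""
    c = PROFILE_CONSTANTS
    return _peak_decay_profile(c["il1b_peak_nM"], c["il1b_peak_time_h"],
                               c["il1b_decay_tau_h"], 0.0, 3.0, basal, "IL-1b")


def get_regime_profile(regime: str, basal: float = DEFAULT_BASAL) -> IKKProfile:
    makers = {"tnfp": make_tnfp_profile, "tnfc": make_tnfc_profile,
              "il1b": make_il1b_profile}
    try:
        return makers[regime.lower()](basal)
    except KeyError:
        raise SpecificationError(
            f"unknown regime {regime!r}; expected one of {sorted(makers)}"
        ) from None


def compose_pulse_train(spec: PulseTrainSpec) -> IKKProfile:
    """Repeated pulses composed by pointwise maximum of the basal-corrected
    single-pulse curves, so overlapping pulses never exceed the single-pulse
    IKK2 peak."""
    base = spec.base_pulse
    if spec.n_pulses == 1:
        return base
    offsets = tuple(i * spec.separation for i in range(spec.n_pulses))

    def corrected(t):
        t = np.asarray(t, dtype=float)
        stacked = np.stack([base.corrected(t - off) for off in offsets])
        return stacked.max(axis=0)

    return IKKProfile(basal=base.basal,
                      support_end=offsets[-1] + base.support_end,
                      corrected=corrected,
                      name=f"{base.name}-x{spec.n_pulses}@{spec.separation:g}h",
                      onsets=offsets)
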