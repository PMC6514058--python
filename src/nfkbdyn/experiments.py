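"""In-silico experiments: production functions, genotype panels, pulse trains
and the calibration acceptance harness.

Every experiment pre-equilibrates each genotype at the input's basal IKK2
level and measures responses against that genotype's own basal activity, so
systems with different basal NF-kB levels remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .genotypes import (GenotypeSpec, NFKB2_NULL, NFKBIA_NULL, NFKB_DEFICIENT,
                        P52_NULL, WT)
from .ikk import (DEFAULT_BASAL, IKKProfile, PulseTrainSpec,
                  TheoreticalPulseSpec, compose_pulse_train, get_regime_profile,
                  make_theoretical_profile, make_tnfp_profile)
from .metrics import ActivityCurve, duration, persistence_time, phase_metrics
from .parameters import ParameterSet
from .system import Trajectory, build_system, simulate

DEFAULT_HORIZON = 16.0

# ---------------------------------------------------------------------------
# trajectory cache: repeated experiments at the reference parameter set reuse
# pre-equilibrated simulations (keyed on genotype, parameter values, profile
# identity and horizon; all inputs are deterministic)

_cache: dict[tuple, Trajectory] = {}


def _fingerprint(params: ParameterSet) -> int:
    return hash(tuple(sorted(params.values.items())))


def run_timecourse(genotype: GenotypeSpec, profile: IKKProfile,
                   parameters: ParameterSet,
                   horizon: float = DEFAULT_HORIZON,
                   use_cache: bool = True) -> Trajectory:
    """Simulate one genotype under one IKK2 input from its own steady state."""
    key = (genotype.name, tuple(sorted(genotype.knockouts)),
           tuple(sorted(genotype.txn_source_ablation)),
           _fingerprint(parameters), profile.name, profile.basal,
           float(horizon))
    if use_cache and key in _cache:
        return _cache[key]
    system = build_system(genotype, parameters)
    traj = simulate(system, profile, horizon)
    if use_cache:
        _cache[key] = traj
    return traj


def clear_cache() -> None:
    _cache.clear()


# ---------------------------------------------------------------------------
# production functions


def production_function(genotype: GenotypeSpec, parameters: ParameterSet,
                        amplitudes=None, durations=None,
                        fixed_duration: float = 8.0,
                        fixed_amplitude: float = 60.0,
                        basal: float = DEFAULT_BASAL) -> pd.DataFrame:
    """NF-kBn response duration versus IKK2 input amplitude or duration.

    Exactly one of ``amplitudes`` (nM, at ``fixed_duration`` h) or
    ``durations`` (h, at ``fixed_amplitude`` nM) must be given.  Each sweep
    point is simulated from the genotype's own steady state; the response
    duration uses the 5%-threshold rule.
    """
    if (amplitudes is None) == (durations is None):
        raise ConfigurationError(
            "provide exactly one of 'amplitudes' or 'durations'")
    sweep = amplitudes if amplitudes is not None else durations
    sweep = list(sweep)
    if not sweep:
        raise ConfigurationError("sweep must be nonempty")

    rows = []
    for value in sweep:
        if amplitudes is not None:
            spec = TheoreticalPulseSpec(peak_amplitude=float(value),
                                        duration=fixed_duration)
            label = {"amplitude_nM": float(value),
                     "input_duration_h": fixed_duration}
        else:
            spec = TheoreticalPulseSpec(peak_amplitude=fixed_amplitude,
                                        duration=float(value))
            label = {"amplitude_nM": fixed_amplitude,
                     "input_duration_h": float(value)}
        profile = make_theoretical_profile(spec, basal=basal)
        horizon = max(DEFAULT_HORIZON, profile.support_end + 8.0)
        try:
            traj = run_timecourse(genotype, profile, parameters, horizon)
            curve = ActivityCurve.from_trajectory(traj, "nfkbn")
            rows.append({**label,
                         "response_duration_h": duration(curve).duration,
                         "error": ""})
        except Exception as exc:  # annotate and propagate per sweep point
            raise type(exc)(f"sweep point {label}: {exc}") from exc
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype x regime panel


@dataclass(frozen=True)
class PanelCell:
    genotype: str
    regime: str
    trajectory: Trajectory | None
    metrics: dict | None
    error: str = ""


def genotype_panel(genotypes, regimes, parameters: ParameterSet,
                   horizon: float = DEFAULT_HORIZON,
                   basal: float = DEFAULT_BASAL) -> list[PanelCell]:
    """Trajectory + phase metrics for every (genotype, regime) combination.

    Per-cell failures are recorded in the cell and the panel continues.
    """
    cells: list[PanelCell] = []
    for genotype in genotypes:
        for regime in regimes:
            profile = get_regime_profile(regime, basal)
            try:
                traj = run_timecourse(genotype, profile, parameters, horizon)
                curve = ActivityCurve.from_trajectory(traj, "nfkbn")
                pm = phase_metrics(curve)
                metrics = {
                    "duration_h": duration(curve).duration,
                    "early_auc": pm.early_auc,
                    "late_auc": pm.late_auc,
                    "first_peak_duration_h": pm.first_peak_duration,
                    "second_phase_onset_h": pm.second_phase_onset,
                    "second_phase_open": pm.second_phase_open,
                    "persistence_h": persistence_time(curve),
                    "peak_nM": curve.peak,
                    "basal_nM": curve.basal,
                }
                cells.append(PanelCell(genotype.name, regime, traj, metrics))
            except Exception as exc:
                cells.append(PanelCell(genotype.name, regime, None, None,
                                       error=f"{type(exc).__name__}: {exc}"))
    return cells


def panel_frame(cells) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {"genotype": c.genotype, "regime": c.regime, "error": c.error}
        if c.metrics:
            row.update(c.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def dimer_auc_table(traj: Trajectory) -> pd.DataFrame:
    """Early/late basal-corrected AUC per nuclear dimer (the dimer
    decomposition of the response)."""
    rows = []
    for dimer in ("nA50", "nA52", "nB50", "nB52"):
        curve = ActivityCurve.from_trajectory(traj, dimer)
        pm = phase_metrics(curve)
        rows.append({"dimer": dimer, "early_auc": pm.early_auc,
                     "late_auc": pm.late_auc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-pulse experiments


EARLY_READOUT_DELAY = 0.5   # h after the last pulse onset
LATE_READOUT_TIME = 8.0     # h after the first pulse onset


def _pulse_readouts(genotype: GenotypeSpec, profile: IKKProfile,
                    parameters: ParameterSet, last_onset: float) -> dict:
    horizon = max(LATE_READOUT_TIME, last_onset + EARLY_READOUT_DELAY) + 0.5
    traj = run_timecourse(genotype, profile, parameters, horizon)
    t_early = last_onset + EARLY_READOUT_DELAY
    nrela = float(np.interp(t_early, traj.times, traj.nrela))
    nrelb = float(np.interp(LATE_READOUT_TIME, traj.times, traj.nrelb))
    trelb = float(np.interp(LATE_READOUT_TIME, traj.times,
                            traj.concentration("tRelb")))
    return {
        "early_nrela": nrela - traj.basal_nrela(),
        "late_nrelb": nrelb - traj.basal_nrelb(),
        "trelb_8h": trelb - traj.basal_concentration("tRelb"),
    }


def pulse_experiment(genotype: GenotypeSpec, separations, n_pulses: int = 2,
                     parameters: ParameterSet | None = None,
                     reference_genotype: GenotypeSpec = NFKB2_NULL,
                     basal: float = DEFAULT_BASAL) -> pd.DataFrame:
    """Repeated-TNFp readouts versus pulse separation.

    Early readout: basal-corrected nuclear RelA 0.5 h after the final pulse
    onset.  Late readout: basal-corrected nuclear RelB 8 h after the first
    onset.  Both are normalised to the single-pulse response of the
    reference system (the p100-deficient system by default), enabling
    cross-genotype comparison.  A basal-corrected Relb mRNA level at 8 h is
    reported alongside.
    """
    if parameters is None:
        raise ConfigurationError("parameters are required")
    separations = [float(s) for s in separations]
    for s in separations:
        if s < 0.5:
            raise ConfigurationError(
                f"separation {s} h too short; minimum 0.5 h (pulse length)")
    base = make_tnfp_profile(basal)

    ref = _pulse_readouts(reference_genotype, base, parameters, last_onset=0.0)
    if ref["early_nrela"] <= 0 or ref["late_nrelb"] <= 0:
        raise ConfigurationError(
            "reference single-pulse responses must be positive for "
            "normalisation")

    rows = []
    for sep in separations:
        train = compose_pulse_train(
            PulseTrainSpec(n_pulses=n_pulses, separation=sep, base_pulse=base))
        last_onset = (n_pulses - 1) * sep
        out = _pulse_readouts(genotype, train, parameters, last_onset)
        rows.append({
            "separation_h": sep,
            "n_pulses": n_pulses,
            **out,
            "early_nrela_norm": out["early_nrela"] / ref["early_nrela"],
            "late_nrelb_norm": out["late_nrelb"] / ref["late_nrelb"],
            "trelb_8h_norm": out["trelb_8h"] / ref["trelb_8h"]
            if ref["trelb_8h"] > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration acceptance harness


def validate_reference_behaviors(parameters: ParameterSet,
                                 basal: float = DEFAULT_BASAL,
                                 horizon: float = DEFAULT_HORIZON) -> list[dict]:
    """Run the calibrated-behavior checklist; failures are results, not errors.

    Each check returns its measured value and the bound it is held to.
    """
    checks: list[dict] = []

    def record(name, value, bound, passed):
        checks.append({"check": name, "value": value, "bound": bound,
                       "passed": bool(passed)})

    try:
        wt_p = run_timecourse(WT, get_regime_profile("tnfp", basal),
                              parameters, horizon)
        wt_c = run_timecourse(WT, get_regime_profile("tnfc", basal),
                              parameters, horizon)
        ko_p = run_timecourse(NFKB2_NULL, get_regime_profile("tnfp", basal),
                              parameters, horizon)
    except Exception as exc:
        record("simulation", float("nan"), "simulations must run", False)
        return checks

    # t1: transient ~1 h NF-kBn response to the brief pulse in WT
    d_wt = duration(ActivityCurve.from_trajectory(wt_p, "nfkbn")).duration
    record("WT TNFp NF-kBn duration", d_wt, "1 h +/- 0.25 h",
           0.75 <= d_wt <= 1.25)

    # t2: p100-deficient late phase persists beyond 8 h (second interval open)
    ko_curve = ActivityCurve.from_trajectory(ko_p, "nfkbn")
    pm_ko = phase_metrics(ko_curve)
    persist = persistence_time(ko_curve)
    record("Nfkb2-null TNFp late-phase persistence", persist,
           ">= 8 h with second phase open",
           persist >= 8.0 and pm_ko.second_phase_open)

    # t3: WT TNFc late RelA:p50 wave persists beyond 8 h
    a50_c = ActivityCurve.from_trajectory(wt_c, "nA50")
    record("WT TNFc nA50 persistence", persistence_time(a50_c), ">= 8 h",
           persistence_time(a50_c) >= 8.0)

    # t4/t5: biphasic WT TNFc response: ~1 h first peak, onset of the second
    # phase near 3 h
    pm_c = phase_metrics(ActivityCurve.from_trajectory(wt_c, "nfkbn"))
    record("WT TNFc first-peak duration", pm_c.first_peak_duration,
           "1 h +/- 0.5 h", 0.5 <= pm_c.first_peak_duration <= 1.5)
    onset = pm_c.second_phase_onset
    record("WT TNFc second-phase onset",
           float("nan") if onset is None else onset, "3 h +/- 1 h",
           onset is not None and 2.0 <= onset <= 4.0)

    # dimer composition: WT TNFc dominated by A50 early and late
    wt_dimers = dimer_auc_table(wt_c).set_index("dimer")
    for window in ("early_auc", "late_auc"):
        a50 = wt_dimers.loc["nA50", window]
        ok = (a50 > wt_dimers.loc["nA52", window]
              and a50 > wt_dimers.loc["nB50", window])
        record(f"WT TNFc {window} A50-dominated", float(a50),
               "A50 AUC > A52 and B50 AUCs", ok)

    # p100-deficient late window dominated by B50
    ko_dimers = dimer_auc_table(ko_p).set_index("dimer")
    record("Nfkb2-null TNFp late window B50 > A50",
           float(ko_dimers.loc["nB50", "late_auc"]),
           "> late A50 AUC",
           ko_dimers.loc["nB50", "late_auc"] > ko_dimers.loc["nA50", "late_auc"])

    # IkBa-deficient system: broadened TNFp response, RelA-dominated
    ia_p = run_timecourse(NFKBIA_NULL, get_regime_profile("tnfp", basal),
                          parameters, horizon)
    d_ia = duration(ActivityCurve.from_trajectory(ia_p, "nfkbn")).duration
    record("Nfkbia-null TNFp duration exceeds WT", d_ia, f"> {d_wt:.2f} h",
           d_ia > d_wt)

    # p52-processing-deficient system: p100 still expressed, late phase absent
    p52_p = run_timecourse(P52_NULL, get_regime_profile("tnfp", basal),
                           parameters, horizon)
    late_p52 = phase_metrics(
        ActivityCurve.from_trajectory(p52_p, "nfkbn")).late_auc
    late_ko = pm_ko.late_auc
    record("p52-null late AUC below 10% of Nfkb2-null", float(late_p52),
           f"< 0.1 * {late_ko:.3f}", late_p52 < 0.1 * late_ko)

    # no transcription-competent dimers -> no nuclear activity at all
    null_c = run_timecourse(NFKB_DEFICIENT, get_regime_profile("tnfc", basal),
                            parameters, horizon)
    peak_null = float(np.max(null_c.nfkbn))
    record("NF-kB-deficient NF-kBn identically zero", peak_null, "< 1e-9 nM",
           peak_null < 1e-9)

    return checks
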