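"""Experiment configuration and reproducible run records.

An :class:`ExperimentConfig` names one experiment kind with its inputs;
unknown keys are rejected so configs cannot silently drift.  Running a
config produces a :class:`RunRecord` — a config echo (defaults filled in),
package version, timestamps, per-step log and the manifest of every file
written — stored as JSON next to the results, so every run is
reconstructible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .exceptions import ConfigurationError

logger = logging.getLogger("nfkbdyn")

EXPERIMENT_KINDS = ("timecourse", "panel", "production_function",
                    "pulse_train", "sensitivity_global", "sensitivity_local",
                    "ablation", "validate")


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    genotypes: tuple[str, ...] = ("WT",)
    regime: str = "tnfp"
    horizon: float = 16.0
    seed: int = 0
    outdir: str = "results"
    basal_ikk: float = 0.2
    # production_function
    amplitudes: tuple[float, ...] | None = None
    durations: tuple[float, ...] | None = None
    fixed_duration: float = 8.0
    fixed_amplitude: float = 60.0
    # pulse_train
    separations: tuple[float, ...] = (1.0, 2.0, 4.0)
    n_pulses: int = 2
    # sensitivity
    n_samples: int = 1000
    n_bootstrap: int = 200
    range_fraction: float = 0.10
    local_parameters: tuple[str, ...] = ()
    # overrides
    parameter_file: str | None = None
    rtol: float | None = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENT_KINDS:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; expected one of "
                f"{EXPERIMENT_KINDS}")
        for fname in ("genotypes", "amplitudes", "durations", "separations",
                      "local_parameters"):
            value = getattr(self, fname)
            if value is not None and not isinstance(value, tuple):
                object.__setattr__(self, fname, tuple(value))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, source=str(path))

    @classmethod
    def from_dict(cls, doc: dict, source: str = "<config>") -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ConfigurationError(f"{source}: unknown config keys {unknown}")
        if "experiment" not in doc:
            raise ConfigurationError(f"{source}: 'experiment' is required")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunRecord:
    config: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    log: list[str] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)

    def note(self, message: str) -> None:
        logger.info(message)
        self.log.append(message)

    def add_file(self, path) -> None:
        self.manifest.append(str(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_experiment(config: ExperimentConfig) -> RunRecord:
    """Dispatch a validated config to its experiment and write artifacts."""
    from . import experiments, io, sensitivity
    from .genotypes import get_genotype
    from .ikk import PROFILE_CONSTANTS, get_regime_profile
    from .parameters import reference_parameters

    record = RunRecord(config=config.to_dict(), started=utcnow())
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = (io.read_parameter_set(config.parameter_file)
              if config.parameter_file else reference_parameters())
    genotypes = [get_genotype(name) for name in config.genotypes]
    record.config["profile_constants"] = dict(PROFILE_CONSTANTS)

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        record.add_file(path)
        return path

    try:
        if config.experiment == "timecourse":
            for genotype in genotypes:
                profile = get_regime_profile(config.regime, config.basal_ikk)
                traj = experiments.run_timecourse(genotype, profile, params,
                                                  config.horizon)
                emit(f"timecourse_{genotype.name}_{config.regime}.tsv",
                     lambda p, tr=traj: io.write_trajectory(tr, p))
                record.note(f"timecourse {genotype.name}/{config.regime} done")

        elif config.experiment == "panel":
            cells = experiments.genotype_panel(
                genotypes, (config.regime,) if isinstance(config.regime, str)
                else config.regime, params, config.horizon, config.basal_ikk)
            frame = experiments.panel_frame(cells)
            emit("panel.tsv", lambda p: frame.to_csv(p, sep="\t", index=False))
            record.note(f"panel with {len(cells)} cells done")

        elif config.experiment == "production_function":
            for genotype in genotypes:
                frame = experiments.production_function(
                    genotype, params, amplitudes=config.amplitudes,
                    durations=config.durations,
                    fixed_duration=config.fixed_duration,
                    fixed_amplitude=config.fixed_amplitude,
                    basal=config.basal_ikk)
                emit(f"production_function_{genotype.name}.tsv",
                     lambda p, fr=frame: fr.to_csv(p, sep="\t", index=False))
                record.note(f"production function {genotype.name} done")

        elif config.experiment == "pulse_train":
            for genotype in genotypes:
                frame = experiments.pulse_experiment(
                    genotype, config.separations, config.n_pulses, params,
                    basal=config.basal_ikk)
                emit(f"pulse_train_{genotype.name}.tsv",
                     lambda p, fr=frame: fr.to_csv(p, sep="\t", index=False))
                record.note(f"pulse train {genotype.name} done")

        elif config.experiment == "sensitivity_global":
            design = sensitivity.SensitivityDesign(
                groups=params.groups, range_fraction=config.range_fraction,
                n_samples=config.n_samples, seed=config.seed)
            objective = sensitivity.LateRelBObjective(
                params, design.groups, basal=config.basal_ikk)
            result = sensitivity.total_effect_indices(
                design, objective, n_bootstrap=config.n_bootstrap,
                parameters=params)
            frame = result.to_frame()
            emit("total_effect_indices.tsv",
                 lambda p: frame.to_csv(p, sep="\t", index=False))
            emit("total_effect_indices.json", lambda p: io.write_json(
                {"design": dataclasses.asdict(design),
                 "result": frame.to_dict(orient="records"),
                 "top_group": result.top_group()}, p))
            record.note(f"global sensitivity done; top group "
                        f"{result.top_group()}")

        elif config.experiment == "sensitivity_local":
            names = config.local_parameters or params.group_members("Gr-V")
            objective = sensitivity.make_late_relb_parameter_objective(
                basal=config.basal_ikk)
            result = sensitivity.local_sensitivity(names, params, objective)
            frame = result.to_frame()
            emit("local_sensitivity.tsv",
                 lambda p: frame.to_csv(p, sep="\t", index=False))
            record.note("local sensitivity done")

        elif config.experiment == "ablation":
            frame = sensitivity.relb_source_ablation(params,
                                                     basal=config.basal_ikk)
            emit("relb_source_ablation.tsv",
                 lambda p: frame.to_csv(p, sep="\t", index=False))
            record.note("Relb transcription-source ablation done")

        elif config.experiment == "validate":
            checks = experiments.validate_reference_behaviors(
                params, basal=config.basal_ikk, horizon=config.horizon)
            emit("validation_checklist.json",
                 lambda p: io.write_checklist(checks, p))
            n_pass = sum(c["passed"] for c in checks)
            record.note(f"validation: {n_pass}/{len(checks)} checks passed")

    except ConfigurationError:
        raise
    except Exception as exc:
        raise type(exc)(f"experiment {config.experiment!r}: {exc}") from exc

    record.finished = utcnow()
    from .io import write_json
    run_path = outdir / "run_record.json"
    write_json(record.to_dict(), run_path)
    return record
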