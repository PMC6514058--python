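"""Kinetic parameter sets with functional group labels.

Rate constants are expressed in nM and hours: zeroth-order synthesis in
nM/h, first-order rates in /h, second-order association rates in /nM/h, and
IKK2-responsive degradation in /nM/h (per nM of IKK2 activity).

Every parameter belongs to exactly one functional group; the groups
partition the parameter set and are the sampling units of the grouped
variance-based sensitivity analysis.  The group holding the Relb synthesis
rates (constitutive transcription, the four NF-kB-induced transcription
weights, and translation) is labelled ``Gr-V``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import yaml

from .exceptions import ValidationError

REFERENCE_RESOURCE = "reference_parameters.yaml"


@dataclass(frozen=True)
class ParameterSet:
    """Immutable mapping parameter name -> rate constant, plus group labels."""

    values: Mapping[str, float]
    group_labels: Mapping[str, str]
    metadata: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "group_labels", dict(self.group_labels))
        self.validate()

    def validate(self) -> None:
        for name, value in self.values.items():
            if not math.isfinite(value):
                raise ValidationError(f"parameter {name!r} is not finite: {value}")
            if value < 0:
                raise ValidationError(f"parameter {name!r} is negative: {value}")
        unassigned = sorted(set(self.values) - set(self.group_labels))
        if unassigned:
            raise ValidationError(
                "parameters without a group label (groups must partition the "
                f"parameter set): {unassigned}")
        orphans = sorted(set(self.group_labels) - set(self.values))
        if orphans:
            raise ValidationError(f"group labels for unknown parameters: {orphans}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def groups(self) -> tuple[str, ...]:
        """Group identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for name in self.values:
            seen.setdefault(self.group_labels[name], None)
        return tuple(seen)

    def group_members(self, group: str) -> tuple[str, ...]:
        return tuple(n for n in self.values if self.group_labels[n] == group)

    def with_updates(self, updates: Mapping[str, float], metadata: str | None = None
                     ) -> "ParameterSet":
        unknown = sorted(set(updates) - set(self.values))
        if unknown:
            raise ValidationError(f"unknown parameters in update: {unknown}")
        values = dict(self.values)
        values.update(updates)
        return ParameterSet(values, self.group_labels,
                            self.metadata if metadata is None else metadata)

    def scaled(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Multiply named parameters by per-parameter factors."""
        updates = {n: self.values[n] * f for n, f in factors.items()}
        return self.with_updates(updates)

    def scaled_by_group(self, group_factors: Mapping[str, float]) -> "ParameterSet":
        """Multiply every member of each named group by one common factor."""
        unknown = sorted(set(group_factors) - set(self.groups))
        if unknown:
            raise ValidationError(f"unknown groups: {unknown}")
        updates = {
            name: self.values[name] * group_factors[self.group_labels[name]]
            for name in self.values
            if self.group_labels[name] in group_factors
        }
        return self.with_updates(updates)

    # ------------------------------------------------------------------ I/O

    def to_yaml(self, path) -> None:
        doc = {
            "metadata": self.metadata,
            "parameters": {
                name: {"value": float(self.values[name]),
                       "group": self.group_labels[name]}
                for name in self.values
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc, source=str(path))

    @classmethod
    def _from_doc(cls, doc, source: str = "<yaml>") -> "ParameterSet":
        if not isinstance(doc, dict) or "parameters" not in doc:
            raise ValidationError(f"{source}: missing top-level 'parameters' mapping")
        values: dict[str, float] = {}
        groups: dict[str, str] = {}
        missing_group: list[str] = []
        for name, spec in doc["parameters"].items():
            if not isinstance(spec, dict) or "value" not in spec:
                raise ValidationError(f"{source}: parameter {name!r} needs a 'value'")
            values[name] = float(spec["value"])
            if "group" in spec:
                groups[name] = str(spec["group"])
            else:
                missing_group.append(name)
        if missing_group:
            raise ValidationError(
                f"{source}: parameters missing a group label: {sorted(missing_group)}")
        return cls(values, groups, metadata=str(doc.get("metadata", "")))


def reference_parameters() -> ParameterSet:
    """The calibrated reference parameter set shipped with the package."""
    text = (resources.files("nfkbdyn.data") / REFERENCE_RESOURCE).read_text()
    return ParameterSet._from_doc(yaml.safe_load(text), source=REFERENCE_RESOURCE)


_ROMAN = (
    (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)
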