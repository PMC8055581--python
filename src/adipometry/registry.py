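"""Loading of the coefficient and Phantom-constant registries.

Both registries are human-readable YAML shipped with the package and
overridable from the CLI (``--registry`` / ``--phantom``), so scientific
provenance lives in versioned data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Mapping

import yaml

from .measurements import SEXES, SKINFOLD_SITES

#: Fold sets each equation requires (fixed by the prediction systems).
REQUIRED_FOLDS = {
    "slaughter": frozenset({"triceps", "medial_calf"}),
    "durnin_rahaman": frozenset({"triceps", "biceps", "subscapular", "suprailiac"}),
    "johnston": frozenset({"triceps", "biceps", "subscapular", "suprailiac"}),
    "lohman": frozenset({"triceps", "suprailiac"}),
}

TRANSFORMS = ("linear_in_sum", "log10_density", "lohman_weight_age")
OUTPUT_KINDS = ("fat_percent", "body_density")


@dataclass(frozen=True)
class EquationSpec:
    """Registry entry for one skinfold prediction system."""

    name: str
    required_folds: frozenset[str]
    transform: str
    output_kind: str
    coefficients: Mapping[str, object]  # sex -> flat mapping or list of age bands
    source: str

    def coeffs_for(self, sex: str, age: float | None = None) -> Mapping[str, float]:
        """Resolve the coefficient vector for a sex and (optionally) age.

        A sex entry is either a flat mapping or a list of age bands
        ``{age_min, age_max, ...}``; the first band containing ``age``
        wins.
        """
        entry = self.coefficients[sex]
        if isinstance(entry, Mapping):
            return entry
        if age is None:
            raise ValueError(f"{self.name}: age required to resolve age-banded coefficients")
        for band in entry:
            if band["age_min"] <= age < band["age_max"]:
                return {k: v for k, v in band.items() if k not in ("age_min", "age_max")}
        raise ValueError(f"{self.name}: no coefficient band covers age {age}")


@dataclass(frozen=True)
class EquationRegistry:
    version: str
    equations: Mapping[str, EquationSpec]

    def __getitem__(self, name: str) -> EquationSpec:
        return self.equations[name]


@dataclass(frozen=True)
class PhantomConstants:
    """Phantom per-variable (p, s, d) constants and the five-way partition."""

    version: str
    stature: float  # phantom stature, cm
    variables: Mapping[str, Mapping[str, float]]  # name -> {p, s, dimension}
    corrections: Mapping[str, Mapping[str, str]]  # corrected var -> {girth, fold}
    components: Mapping[str, Mapping[str, object]]  # name -> {p_mass, s_mass, variables}

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(self.components)


def _data_path(name: str):
    return files("adipometry.data").joinpath(name)


def load_equation_registry(path=None) -> EquationRegistry:
    """Load the skinfold-coefficient registry (packaged default or override)."""
    source = _data_path("skinfold_coefficients.yaml") if path is None else path
    with open(str(source), "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    equations: dict[str, EquationSpec] = {}
    for name, entry in raw["equations"].items():
        folds = frozenset(entry["folds"])
        if name in REQUIRED_FOLDS and folds != REQUIRED_FOLDS[name]:
            raise ValueError(
                f"registry fold set for {name!r} is {sorted(folds)}, "
                f"expected {sorted(REQUIRED_FOLDS[name])}"
            )
        bad = folds - set(SKINFOLD_SITES)
        if bad:
            raise ValueError(f"{name}: unknown skinfold sites {sorted(bad)}")
        if entry["transform"] not in TRANSFORMS:
            raise ValueError(f"{name}: unknown transform {entry['transform']!r}")
        if entry["output"] not in OUTPUT_KINDS:
            raise ValueError(f"{name}: unknown output kind {entry['output']!r}")
        coeffs = entry["coefficients"]
        missing_sex = [s for s in SEXES if s not in coeffs]
        if missing_sex:
            raise ValueError(f"{name}: coefficients missing for sex(es) {missing_sex}")
        equations[name] = EquationSpec(
            name=name,
            required_folds=folds,
            transform=entry["transform"],
            output_kind=entry["output"],
            coefficients=coeffs,
            source=entry.get("source", "").strip(),
        )
    return EquationRegistry(version=str(raw["registry_version"]), equations=equations)


def load_phantom_constants(path=None) -> PhantomConstants:
    """Load Phantom constants (packaged default or override)."""
    source = _data_path("phantom_constants.yaml") if path is None else path
    with open(str(source), "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    variables = raw["variables"]
    for name, entry in variables.items():
        if entry["s"] <= 0:
            raise ValueError(f"phantom variable {name!r}: s must be > 0")
    components = raw["components"]
    for name, comp in components.items():
        if not comp["variables"]:
            raise ValueError(f"component {name!r} has no contributing variables")
        unknown = [v for v in comp["variables"] if v not in variables]
        if unknown:
            raise ValueError(f"component {name!r}: unknown variables {unknown}")
    return PhantomConstants(
        version=str(raw["registry_version"]),
        stature=float(raw["phantom_stature"]),
        variables=variables,
        corrections=raw.get("corrections", {}),
        components=components,
    )
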