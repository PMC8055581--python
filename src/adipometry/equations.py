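"""Skinfold fat-percentage prediction systems and the Siri conversion.

Four prediction systems are implemented, all registry-driven:

* **Slaughter** — fat %% linear in the triceps + medial-calf fold sum,
  sex-specific slope and intercept.
* **Durnin & Rahaman** and **Johnston** — body density as
  ``D = c0 - c1 * log10(sum of four folds)`` (triceps, biceps,
  subscapular, suprailiac), sex-specific, then Siri.
* **Lohman** — fat %% from sex, age, body weight and the triceps +
  suprailiac fold sum.

The Siri two-compartment conversion anchors on assumed tissue densities
of 1.1 g/cm^3 (lean) and 0.9 g/cm^3 (fat):
``FP = (4.95 / D - 4.50) * 100``.

Out-of-range outputs (<0 or >100 %%) are returned raw with a warning —
agreement statistics must see the uncensored value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurements import AthleteRecord, Cohort
from .registry import EquationRegistry, load_equation_registry

#: Skinfold systems in report order (the five-component model is appended
#: by callers that also run the fractionation pipeline).
SKINFOLD_EQUATIONS = ("slaughter", "durnin_rahaman", "lohman", "johnston")
#: Full prediction-system order used in validity reports.
ALL_EQUATIONS = (*SKINFOLD_EQUATIONS, "five_component")


class OutOfRangeFatPercent(UserWarning):
    """A prediction fell outside (0, 100) %; the raw value is kept."""


def siri_fat_percent(density):
    """Convert body density (g/cm^3) to fat percentage via the Siri equation.

    Strictly decreasing in density; equals 0 % at the lean-tissue density
    1.1 and 100 % at the fat-tissue density 0.9.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density <= 0):
        raise ValueError("density must be strictly positive")
    fp = (4.95 / density - 4.50) * 100.0
    return float(fp) if fp.ndim == 0 else fp


def _fold_sum(record: AthleteRecord, folds: frozenset[str], name: str) -> float:
    missing = sorted(folds - set(record.skinfolds))
    if missing:
        raise ValueError(f"{name}: record {record.id!r} missing skinfold(s) {missing}")
    return float(sum(record.skinfolds[f] for f in folds))


def _warn_out_of_range(name: str, fp: float) -> float:
    if not (0.0 < fp < 100.0):
        warnings.warn(
            f"{name} prediction {fp:.3f}% outside (0, 100); returned unclamped",
            OutOfRangeFatPercent,
            stacklevel=3,
        )
    return fp


def _evaluate(spec, sex, age, body_mass, fold_sum):
    """Vectorised core shared by record-level and cohort-level prediction."""
    coeffs = spec.coeffs_for(sex, age if np.isscalar(age) else None) if np.isscalar(sex) else None
    if coeffs is not None:  # scalar path
        if spec.transform == "linear_in_sum":
            return coeffs["slope"] * fold_sum + coeffs["intercept"]
        if spec.transform == "log10_density":
            if fold_sum <= 0:
                raise ValueError(f"{spec.name}: fold sum must be positive for log10")
            density = coeffs["c0"] - coeffs["c1"] * np.log10(fold_sum)
            return siri_fat_percent(density)
        if spec.transform == "lohman_weight_age":
            return (
                coeffs["intercept"]
                + coeffs["fold_sum"] * fold_sum
                + coeffs["weight"] * body_mass
                + coeffs["age"] * age
            )
        raise ValueError(f"unknown transform {spec.transform!r}")
    # array path: dispatch per sex
    fold_sum = np.asarray(fold_sum, dtype=float)
    out = np.full(fold_sum.shape, np.nan)
    for s in ("F", "M"):
        mask = np.asarray(sex) == s
        if not mask.any():
            continue
        c = spec.coeffs_for(s)
        if spec.transform == "linear_in_sum":
            out[mask] = c["slope"] * fold_sum[mask] + c["intercept"]
        elif spec.transform == "log10_density":
            density = c["c0"] - c["c1"] * np.log10(fold_sum[mask])
            out[mask] = (4.95 / density - 4.50) * 100.0
        elif spec.transform == "lohman_weight_age":
            out[mask] = (
                c["intercept"]
                + c["fold_sum"] * fold_sum[mask]
                + c["weight"] * np.asarray(body_mass, dtype=float)[mask]
                + c["age"] * np.asarray(age, dtype=float)[mask]
            )
    return out


def _predict_record(record: AthleteRecord, name: str, registry: EquationRegistry) -> float:
    spec = registry[name]
    fold_sum = _fold_sum(record, spec.required_folds, name)
    fp = float(_evaluate(spec, record.sex, record.age, record.body_mass, fold_sum))
    return _warn_out_of_range(name, fp)


def slaughter_fp(record: AthleteRecord, registry: EquationRegistry | None = None) -> float:
    """Slaughter fat %: sex-specific linear form in triceps + medial-calf folds."""
    return _predict_record(record, "slaughter", registry or default_registry())


def durnin_rahaman_fp(record: AthleteRecord, registry: EquationRegistry | None = None) -> float:
    """Durnin & Rahaman fat %: log10 four-fold density, then Siri."""
    return _predict_record(record, "durnin_rahaman", registry or default_registry())


def johnston_fp(record: AthleteRecord, registry: EquationRegistry | None = None) -> float:
    """Johnston fat %: log10 four-fold density, then Siri."""
    return _predict_record(record, "johnston", registry or default_registry())


def lohman_fp(record: AthleteRecord, registry: EquationRegistry | None = None) -> float:
    """Lohman fat %: sex-dispatched form in age, weight and triceps + suprailiac folds."""
    return _predict_record(record, "lohman", registry or default_registry())


_RECORD_FUNCS = {
    "slaughter": slaughter_fp,
    "durnin_rahaman": durnin_rahaman_fp,
    "johnston": johnston_fp,
    "lohman": lohman_fp,
}

_default_registry: EquationRegistry | None = None


def default_registry() -> EquationRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = load_equation_registry()
    return _default_registry


@dataclass(frozen=True)
class Prediction:
    """Outcome of one equation on one record: a value or an explicit miss."""

    value: float | None
    missing: tuple[str, ...] = ()

    @property
    def available(self) -> bool:
        return self.value is not None


def predict_all(
    record: AthleteRecord,
    which: tuple[str, ...] = SKINFOLD_EQUATIONS,
    registry: EquationRegistry | None = None,
) -> dict[str, Prediction]:
    """Run the selected skinfold equations on one record.

    Equations whose inputs are missing are reported as unavailable
    (:class:`Prediction` with the missing sites listed), never silently
    skipped.
    """
    if not which:
        raise ValueError("empty equation selection")
    registry = registry or default_registry()
    out: dict[str, Prediction] = {}
    for name in which:
        if name not in _RECORD_FUNCS:
            raise KeyError(f"unknown equation {name!r}")
        spec = registry[name]
        missing = tuple(sorted(spec.required_folds - set(record.skinfolds)))
        if missing:
            out[name] = Prediction(value=None, missing=missing)
        else:
            out[name] = Prediction(value=_RECORD_FUNCS[name](record, registry))
    return out


def predict_cohort(
    cohort: Cohort,
    which: tuple[str, ...] = SKINFOLD_EQUATIONS,
    registry: EquationRegistry | None = None,
) -> pd.DataFrame:
    """Vectorised per-athlete fat-percentage table, indexed by athlete id.

    One column per selected skinfold equation; NaN marks records lacking
    that equation's inputs (columns for the five-component model come from
    :func:`adipometry.fractionation.fractionate_cohort`).
    """
    if not which:
        raise ValueError("empty equation selection")
    registry = registry or default_registry()
    frame = cohort.frame
    out = pd.DataFrame(index=pd.Index(frame["id"], name="id"))
    sex = frame["sex"].to_numpy()
    age = frame["age"].to_numpy(dtype=float)
    mass = frame["body_mass"].to_numpy(dtype=float)
    for name in which:
        spec = registry[name]
        cols = [f"skinfold_{f}" for f in sorted(spec.required_folds)]
        folds = frame[cols].to_numpy(dtype=float)
        fold_sum = folds.sum(axis=1)  # NaN propagates -> unavailable
        out[name] = _evaluate(spec, sex, age, mass, fold_sum)
    return out
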