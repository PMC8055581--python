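"""Five-component Phantom fractionation and the adiposity -> fat %% chain.

The fractionation partitions body mass into skin, adipose, muscle, bone
and residual tissue masses by z-scoring each anthropometric variable
against the Phantom reference human (stature 170.18 cm), averaging the
z-scores that feed each component and back-transforming through the
phantom component mass:

    z    = ( value * (170.18 / stature)^d - p ) / s
    mass = ( mean(z) * s_mass + p_mass ) * (stature / 170.18)^3

Adiposity (% of body mass held as adipose tissue) is then converted to a
lipid-based fat percentage through the Martin lipid fraction

    LF = 0.327 + 0.0124 * %Adip

via the explicit five-step chain (adiposity -> fat mass -> lipid fraction
-> lipid mass -> fat %% of weight), which collapses algebraically to
``fat%% = %Adip * LF``.  Both routes are exposed and tested to agree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .measurements import AthleteRecord, Cohort
from .registry import PhantomConstants, load_phantom_constants

#: Martin lipid-fraction coefficients: LF = LF_INTERCEPT + LF_SLOPE * %Adip
LF_INTERCEPT = 0.327
LF_SLOPE = 0.0124

_default_constants: PhantomConstants | None = None


def default_constants() -> PhantomConstants:
    global _default_constants
    if _default_constants is None:
        _default_constants = load_phantom_constants()
    return _default_constants


class NegativeComponentMass(UserWarning):
    """A fractionated tissue mass came out negative; the raw value is kept."""


def phantom_z(
    value: float,
    stature: float,
    var: str,
    constants: PhantomConstants | None = None,
) -> float:
    """Dimension-scaled Phantom z-score of one measurement.

    ``var`` names a registry variable; its dimensional exponent ``d`` is 1
    for lengths/girths/folds and 3 for masses.
    """
    constants = constants or default_constants()
    if var not in constants.variables:
        raise KeyError(f"unknown phantom variable {var!r}")
    if not (value > 0 and stature > 0):
        raise ValueError("value and stature must be strictly positive")
    entry = constants.variables[var]
    d = entry.get("dimension", 1)
    scaled = value * (constants.stature / stature) ** d
    return (scaled - entry["p"]) / entry["s"]


@dataclass(frozen=True)
class FractionationResult:
    """Five tissue masses (kg) plus the adiposity percentage of body mass."""

    masses: Mapping[str, float]  # skin, adipose, muscle, bone, residual
    adiposity_percent: float
    structured_mass_sum: float  # sum of the five component masses


@dataclass(frozen=True)
class LipidChain:
    """Audit trail of the five-step adiposity -> fat-percentage conversion."""

    adiposity_percent: float
    fat_mass: float  # adipose tissue mass, kg
    lipid_fraction: float  # Martin LF, dimensionless
    lipid_mass: float  # kg
    fat_percent_weight: float  # lipid mass as % of body mass


# --- variable assembly -------------------------------------------------------

#: Full declared input set of the five-component method (a record missing
#: any of these is excluded, even where the shipped partition does not
#: consume the variable directly, e.g. sitting height).
FIVE_COMPONENT_COLUMNS = (
    "body_mass",
    "stature",
    "sitting_height",
    "skinfold_triceps",
    "skinfold_subscapular",
    "skinfold_supraspinale",
    "skinfold_abdominal",
    "skinfold_front_thigh",
    "skinfold_medial_calf",
    "girth_head",
    "girth_relaxed_arm",
    "girth_forearm",
    "girth_thigh",
    "girth_calf",
    "girth_chest",
    "girth_waist",
    "breadth_biacromial",
    "breadth_biiliocristal",
    "breadth_humerus",
    "breadth_femur",
    "breadth_ap_chest",
    "breadth_transverse_chest",
)


def _variable_values(frame: pd.DataFrame, constants: PhantomConstants) -> dict[str, np.ndarray]:
    """Resolve every registry variable to a per-row value array.

    Fold-corrected girths are built as girth - pi * fold / 10 (girth in
    cm, fold in mm); all other variables map straight onto canonical
    columns.
    """
    values: dict[str, np.ndarray] = {}
    for var in constants.variables:
        if var in constants.corrections:
            rule = constants.corrections[var]
            girth = frame[rule["girth"]].to_numpy(dtype=float)
            fold = frame[rule["fold"]].to_numpy(dtype=float)
            values[var] = girth - math.pi * fold / 10.0
        else:
            values[var] = frame[var].to_numpy(dtype=float)
    return values


def fractionate_cohort(
    cohort: Cohort,
    constants: PhantomConstants | None = None,
) -> pd.DataFrame:
    """Vectorised five-way fractionation of a whole cohort.

    Returns a frame indexed by athlete id with one mass column per
    component (kg), ``structured_mass_sum``, ``adiposity_percent`` and the
    lipid-converted ``fat_percent``.  Rows missing any required input are
    NaN throughout.
    """
    constants = constants or default_constants()
    frame = cohort.frame
    stature = frame["stature"].to_numpy(dtype=float)
    scale = (stature / constants.stature) ** 3
    values = _variable_values(frame, constants)
    incomplete = frame[list(FIVE_COMPONENT_COLUMNS)].isna().any(axis=1).to_numpy()

    out = pd.DataFrame(index=pd.Index(frame["id"], name="id"))
    total = np.zeros(len(frame))
    for comp, entry in constants.components.items():
        zs = []
        for var in entry["variables"]:
            v = constants.variables[var]
            d = v.get("dimension", 1)
            scaled = values[var] * (constants.stature / stature) ** d
            zs.append((scaled - v["p"]) / v["s"])
        z_bar = np.mean(zs, axis=0)
        mass = (z_bar * entry["s_mass"] + entry["p_mass"]) * scale
        mass = np.where(incomplete, np.nan, mass)
        out[comp] = mass
        total = total + mass
    out["structured_mass_sum"] = total
    body_mass = frame["body_mass"].to_numpy(dtype=float)
    adiposity = 100.0 * out["adipose"].to_numpy() / body_mass
    out["adiposity_percent"] = adiposity
    out["fat_percent"] = fat_percent_from_adiposity(adiposity)
    return out


def fractionate(
    record: AthleteRecord,
    constants: PhantomConstants | None = None,
) -> FractionationResult:
    """Five-way fractionation of a single record.

    Requires mass, stature, sitting height, the six fractionation folds,
    all seven girths and all six breadths; raises naming whatever is
    missing.  Negative component masses are flagged with a warning, never
    clamped.
    """
    constants = constants or default_constants()
    missing = _missing_inputs(record)
    if missing:
        raise ValueError(
            f"five-component fractionation: record {record.id!r} missing {missing}"
        )
    cohort = Cohort((record,), provenance="single-record")
    row = fractionate_cohort(cohort, constants).iloc[0]
    masses = {c: float(row[c]) for c in constants.component_names}
    negative = [c for c, m in masses.items() if m < 0]
    if negative:
        warnings.warn(
            f"negative component mass(es) {negative} for record {record.id!r}",
            NegativeComponentMass,
            stacklevel=2,
        )
    return FractionationResult(
        masses=masses,
        adiposity_percent=float(row["adiposity_percent"]),
        structured_mass_sum=float(row["structured_mass_sum"]),
    )


def _missing_inputs(record: AthleteRecord) -> list[str]:
    missing = []
    if record.sitting_height is None:
        missing.append("sitting_height")
    for site in ("triceps", "subscapular", "supraspinale", "abdominal", "front_thigh", "medial_calf"):
        if site not in record.skinfolds:
            missing.append(f"skinfold_{site}")
    for site in ("head", "relaxed_arm", "forearm", "thigh", "calf", "chest", "waist"):
        if site not in record.girths:
            missing.append(f"girth_{site}")
    for site in ("biacromial", "biiliocristal", "humerus", "femur", "ap_chest", "transverse_chest"):
        if site not in record.breadths:
            missing.append(f"breadth_{site}")
    return missing


def lipid_chain(adiposity_percent: float, body_mass: float) -> LipidChain:
    """Explicit five-step conversion from adiposity %% to fat %% of weight.

    1. adiposity %% (input, from the five-component model);
    2. fat mass = adiposity/100 * body mass;
    3. lipid fraction LF = 0.327 + 0.0124 * adiposity;
    4. lipid mass = fat mass * LF;
    5. fat %% of weight = 100 * lipid mass / body mass.

    The chain is algebraically independent of body mass (it cancels);
    the collapsed identity is :func:`fat_percent_from_adiposity`.
    """
    if adiposity_percent < 0:
        raise ValueError("adiposity_percent must be >= 0")
    if body_mass <= 0:
        raise ValueError("body_mass must be strictly positive")
    fat_mass = (adiposity_percent / 100.0) * body_mass
    lf = LF_INTERCEPT + LF_SLOPE * adiposity_percent
    lipid_mass = fat_mass * lf
    fp = 100.0 * lipid_mass / body_mass
    return LipidChain(
        adiposity_percent=adiposity_percent,
        fat_mass=fat_mass,
        lipid_fraction=lf,
        lipid_mass=lipid_mass,
        fat_percent_weight=fp,
    )


def fat_percent_from_adiposity(adiposity_percent):
    """Collapsed lipid-chain identity: fat%% = %%Adip * (0.327 + 0.0124 * %%Adip)."""
    a = np.asarray(adiposity_percent, dtype=float)
    fp = a * (LF_INTERCEPT + LF_SLOPE * a)
    return float(fp) if fp.ndim == 0 else fp


def phantom_proportional_record(
    stature: float = 170.18,
    record_id: str = "phantom",
    sex: str = "F",
    age: float = 15.0,
    constants: PhantomConstants | None = None,
) -> AthleteRecord:
    """Build a record geometrically similar to the Phantom at a given stature.

    Every registry variable equals its phantom mean scaled by
    ``(stature/170.18)^d`` (fold-corrected girths are inverted so the
    *corrected* value is phantom-proportional), so every component z-score
    is zero and each fractionated mass equals its phantom component mass
    times ``(stature/170.18)^3``.  Mainly a validation fixture.
    """
    constants = constants or default_constants()
    k = stature / constants.stature
    v = constants.variables

    def scaled(name: str) -> float:
        return v[name]["p"] * k ** v[name].get("dimension", 1)

    folds = {
        site: scaled(f"skinfold_{site}")
        for site in ("triceps", "subscapular", "supraspinale", "abdominal", "front_thigh", "medial_calf")
    }
    folds["biceps"] = 8.0 * k  # not a fractionation input; any positive value
    folds["suprailiac"] = 15.0 * k
    girths = {
        "head": scaled("girth_head"),
        "forearm": scaled("girth_forearm"),
        "waist": scaled("girth_waist"),
        # invert the fold correction so corrected girth is phantom-proportional
        "relaxed_arm": v["corrected_arm"]["p"] * k + math.pi * folds["triceps"] / 10.0,
        "thigh": v["corrected_thigh"]["p"] * k + math.pi * folds["front_thigh"] / 10.0,
        "calf": v["corrected_calf"]["p"] * k + math.pi * folds["medial_calf"] / 10.0,
        "chest": v["corrected_chest"]["p"] * k + math.pi * folds["subscapular"] / 10.0,
    }
    breadths = {
        site: scaled(f"breadth_{site}")
        for site in ("biacromial", "biiliocristal", "humerus", "femur", "ap_chest", "transverse_chest")
    }
    return AthleteRecord(
        id=record_id,
        sex=sex,
        age=age,
        body_mass=scaled("body_mass"),
        stature=stature,
        sitting_height=scaled("sitting_height"),
        skinfolds=folds,
        girths=girths,
        breadths=breadths,
    )
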