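"""Method-agreement statistics: ICC, Bland-Altman, and cohort reports.

The concordance battery compares each prediction system against the DEXA
criterion on the same athletes:

* **ICC** — intraclass correlation from the two-way mean-square
  decomposition of the subjects x methods table.  The default variant is
  absolute agreement, single rater (McGraw & Wong ICC(A,1)), which is the
  form that penalises systematic offsets in a criterion-vs-method design;
  a consistency variant is selectable.  Confidence intervals use the
  standard F-based formulas; negative estimates and bounds are reported
  as computed, never truncated.
* **Bland-Altman** — per-subject differences (criterion - prediction)
  summarised by the mean bias, the sample SD of differences, and limits
  of agreement bias +/- 1.96 * SD.
* Reports are sex-stratified (all / F / M) and carry the per-subject
  coordinates needed to redraw the agreement plots.

Validity classification follows the poor (<0.40) / moderate (0.40-0.75) /
good-excellent (>0.75) convention, with both boundaries falling to
moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .equations import ALL_EQUATIONS, SKINFOLD_EQUATIONS, predict_cohort
from .fractionation import fractionate_cohort
from .measurements import Cohort, bmi

STRATA = ("all", "F", "M")

ICC_POOR_BELOW = 0.40
ICC_GOOD_ABOVE = 0.75


@dataclass(frozen=True)
class PairedSeries:
    """Criterion/prediction pairs for one equation in one stratum."""

    criterion: np.ndarray
    predicted: np.ndarray
    stratum: str = "all"
    equation: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.criterion, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if c.shape != p.shape or c.ndim != 1:
            raise ValueError("criterion and predicted must be equal-length 1-d arrays")
        if not (np.isfinite(c).all() and np.isfinite(p).all()):
            raise ValueError("paired series must be complete and finite")
        object.__setattr__(self, "criterion", c)
        object.__setattr__(self, "predicted", p)

    def __len__(self) -> int:
        return len(self.criterion)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    classification: str
    variant: str
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mean(criterion - predicted), percentage points
    sd_diff: float  # sample SD (n-1) of the differences
    loa_low: float  # bias - multiplier * sd_diff
    loa_high: float  # bias + multiplier * sd_diff
    outside_fraction: float
    multiplier: float
    n: int
    means: np.ndarray = field(repr=False)  # per-subject mean of the two methods
    differences: np.ndarray = field(repr=False)


def classify_icc(icc: float) -> str:
    """Map an ICC value to poor / moderate / good_excellent."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc < ICC_POOR_BELOW:
        return "poor"
    if icc <= ICC_GOOD_ABOVE:
        return "moderate"
    return "good_excellent"


def _mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=methods)."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(pairs: PairedSeries, variant: str = "absolute_agreement", alpha: float = 0.05) -> IccResult:
    """Single-rater two-way ICC of a criterion/prediction pairing.

    ``variant`` selects ``"absolute_agreement"`` (ICC(A,1); default) or
    ``"consistency"`` (ICC(C,1)).  The estimate and the F-based
    confidence bounds may be negative; they are reported as computed.
    Raises on fewer than 3 pairs or zero total variance.
    """
    if variant not in ("absolute_agreement", "consistency"):
        raise ValueError(f"unknown ICC variant {variant!r}")
    n = len(pairs)
    if n < 3:
        raise ValueError("ICC requires at least 3 pairs")
    y = np.column_stack([pairs.criterion, pairs.predicted])
    if np.ptp(y) == 0:
        raise ValueError("zero total variance: ICC undefined")
    k = 2
    msr, msc, mse = _mean_squares(y)

    scale = float(np.var(y))
    if mse <= 1e-14 * max(scale, 1.0) and msc <= 1e-14 * max(scale, 1.0):
        # perfect agreement: both methods identical on a non-constant sample
        return IccResult(1.0, 1.0, 1.0, classify_icc(1.0), variant, n)

    if variant == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = f_obs / f_dist.ppf(1 - alpha / 2, n - 1, df2)
        fu = f_obs * f_dist.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        est = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # McGraw & Wong F-based interval for ICC(A,1)
        a = (k * est) / (n * (1 - est))
        b = 1 + (k * est * (n - 1)) / (n * (1 - est))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)

    return IccResult(float(est), float(lo), float(hi), classify_icc(float(est)), variant, n)


def bland_altman(pairs: PairedSeries, multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement summary of criterion - prediction differences.

    ``bias`` keeps the study's sign convention (criterion minus
    prediction): an equation that overestimates fat percentage yields a
    negative bias.  ``outside_fraction`` is the share of differences
    beyond the limits of agreement.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = pairs.criterion - pairs.predicted
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half_width = multiplier * sd
    outside = float(np.mean(np.abs(d - bias) > half_width))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half_width,
        loa_high=bias + half_width,
        outside_fraction=outside,
        multiplier=multiplier,
        n=n,
        means=(pairs.criterion + pairs.predicted) / 2.0,
        differences=d,
    )


@dataclass(frozen=True)
class ValidityReport:
    """Equation x stratum agreement table plus plotting coordinates."""

    table: pd.DataFrame
    coordinates: Mapping[tuple[str, str], pd.DataFrame]
    exclusions: Mapping[str, int]  # per-equation listwise-excluded record count
    notes: tuple[str, ...]


def _prediction_table(cohort: Cohort, equations: Sequence[str], registry, phantom) -> pd.DataFrame:
    skinfold = [e for e in equations if e in SKINFOLD_EQUATIONS]
    preds = predict_cohort(cohort, tuple(skinfold), registry) if skinfold else pd.DataFrame(
        index=pd.Index(cohort.frame["id"], name="id")
    )
    if "five_component" in equations:
        frac = fractionate_cohort(cohort, phantom)
        preds["five_component"] = frac["fat_percent"]
    return preds[list(equations)]


def validity_report(
    cohort: Cohort,
    equations: Sequence[str] = ALL_EQUATIONS,
    strata: Sequence[str] = STRATA,
    icc_variant: str = "absolute_agreement",
    loa_multiplier: float = 1.96,
    registry=None,
    phantom=None,
) -> ValidityReport:
    """Concordance battery of every selected equation in every stratum.

    Records without a DEXA criterion, and records lacking an equation's
    inputs, are excluded listwise per equation with counts recorded on the
    report.  Strata with fewer than 3 complete pairs are reported absent
    with a diagnostic note.  Row order is deterministic: equation, then
    all/F/M.
    """
    if not equations:
        raise ValueError("empty equation selection")
    frame = cohort.frame
    dexa = frame["dexa_fp"].to_numpy(dtype=float)
    if np.isnan(dexa).all():
        raise ValueError("cohort has no DEXA criterion values (dexa_fp)")

    preds = _prediction_table(cohort, equations, registry, phantom)
    sex = frame["sex"].to_numpy()
    notes: list[str] = []
    exclusions: dict[str, int] = {}
    rows: list[dict[str, object]] = []
    coords: dict[tuple[str, str], pd.DataFrame] = {}

    n_missing_dexa = int(np.isnan(dexa).sum())
    if n_missing_dexa:
        notes.append(f"{n_missing_dexa} record(s) without dexa_fp excluded from all pairings")

    for eq in equations:
        p = preds[eq].to_numpy(dtype=float)
        complete = ~np.isnan(p) & ~np.isnan(dexa)
        exclusions[eq] = int(len(p) - complete.sum())
        for stratum in strata:
            mask = complete if stratum == "all" else complete & (sex == stratum)
            n = int(mask.sum())
            if n < 3:
                notes.append(
                    f"{eq}/{stratum}: only {n} complete pair(s); stratum omitted"
                )
                continue
            pairs = PairedSeries(dexa[mask], p[mask], stratum=stratum, equation=eq)
            icc_res = icc(pairs, variant=icc_variant)
            ba = bland_altman(pairs, multiplier=loa_multiplier)
            rows.append(
                {
                    "equation": eq,
                    "stratum": stratum,
                    "n": n,
                    "icc": icc_res.icc,
                    "icc_ci_low": icc_res.ci_low,
                    "icc_ci_high": icc_res.ci_high,
                    "icc_class": icc_res.classification,
                    "icc_variant": icc_res.variant,
                    "bias": ba.bias,
                    "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "outside_fraction": ba.outside_fraction,
                }
            )
            coords[(eq, stratum)] = pd.DataFrame(
                {
                    "id": frame["id"].to_numpy()[mask],
                    "mean": ba.means,
                    "difference": ba.differences,
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                }
            )
    table = pd.DataFrame(rows)
    return ValidityReport(table=table, coordinates=coords, exclusions=exclusions, notes=tuple(notes))


def summarize_cohort(cohort: Cohort, strata: Sequence[str] = STRATA) -> pd.DataFrame:
    """Descriptive summary per variable and stratum.

    Emits both summary families (mean/SD and median/quartiles) for every
    numeric variable plus derived BMI; choosing which family to display
    is left to the caller.  A single-observation cell has NaN SD.
    """
    frame = cohort.to_frame()
    frame["bmi"] = [bmi(m, s) for m, s in zip(frame["body_mass"], frame["stature"])]
    variables = [c for c in frame.columns if c not in ("id", "sex")]
    sex = frame["sex"].to_numpy()
    rows = []
    for stratum in strata:
        mask = np.ones(len(frame), dtype=bool) if stratum == "all" else sex == stratum
        sub = frame.loc[mask, variables]
        for var in variables:
            x = sub[var].dropna()
            rows.append(
                {
                    "variable": var,
                    "stratum": stratum,
                    "n": int(len(x)),
                    "mean": float(x.mean()) if len(x) else np.nan,
                    "sd": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
                    "median": float(x.median()) if len(x) else np.nan,
                    "q1": float(x.quantile(0.25)) if len(x) else np.nan,
                    "q3": float(x.quantile(0.75)) if len(x) else np.nan,
                }
            )
    return pd.DataFrame(rows)
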