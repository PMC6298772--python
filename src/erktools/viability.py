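"""Viability normalization, 4PL dose-response fitting, sensitivity calls,
drug-rescue normalization, ΔΔCt quantification and densitometry ratios.

Dose-response curves are modelled as a four-parameter logistic on linear
dose, v(d) = bottom + (top − bottom) / (1 + (d / ic50)^hill), fit by
unweighted least squares on per-dose replicate means with a multi-start
grid over (ic50, hill). The IC50 reported is the curve midpoint parameter.

Cell lines are then assigned one of three sensitivity tiers:

* sensitive — midpoint IC50 in [1, 3] µM and fitted viability below 10%
  at the 3.2 µM reference dose;
* insensitive — IC50 of at least 5 µM, or no dose effect fit at all while
  viability stays above 50% at the top dose;
* intermediate — everything else.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import PlateReadings, logger

REFERENCE_DOSE = 3.2  # µM; viability here feeds the sensitivity call

#: (lo, hi) IC50 window (µM) and max reference-dose viability for "sensitive";
#: IC50 floor (µM) for "insensitive".
SENSITIVE_IC50_RANGE = (1.0, 3.0)
SENSITIVE_MAX_REF_VIABILITY = 0.10
INSENSITIVE_IC50_MIN = 5.0

_FLAT_SPAN = 0.05  # fitted top-bottom span below this means "no dose effect"


def four_pl(dose, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic viability curve on linear dose."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters and derived quantities for one cell line."""

    cell_line: str
    bottom: float
    top: float
    ic50: float  # NaN when flagged (no dose effect fit)
    hill: float
    rss: float
    ref_dose: float
    viability_at_ref_dose: float
    max_dose: float
    viability_at_max_dose: float
    absolute_ic50: float  # dose where v = 0.5 absolute; NaN if never reached
    extrapolated: bool  # midpoint outside the tested dose range
    flagged: bool  # no resolvable dose effect
    sensitivity: str = ""


def relative_viability(
    readings: PlateReadings,
    control_condition: str | None = None,
    control_dose: float = 0.0,
) -> pd.DataFrame:
    """Replicate-mean viability relative to a control, with SEM.

    The control is either a condition label (e.g. an untreated / no-dox
    condition) or, when ``control_condition`` is None, the wells at
    ``control_dose`` within each (cell_line, condition) group — the vehicle
    wells of a dose series. SEM is the replicate SD/sqrt(n) of the numerator
    divided by the control mean; the control group itself therefore has
    mean_rel exactly 1.
    """
    df = readings.frame.copy()
    if "timepoint" not in df.columns:
        df["timepoint"] = np.nan
    group_keys = ["cell_line", "condition", "dose", "timepoint"]
    agg = (
        df.groupby(group_keys, dropna=False)["signal"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    agg["std"] = agg["std"].fillna(0.0)

    def control_mean(row) -> float:
        if control_condition is not None:
            sel = agg[
                (agg["cell_line"] == row["cell_line"])
                & (agg["condition"] == control_condition)
            ]
        else:
            sel = agg[
                (agg["cell_line"] == row["cell_line"])
                & (agg["condition"] == row["condition"])
                & (agg["dose"] == control_dose)
            ]
        if "timepoint" in agg.columns and not pd.isna(row["timepoint"]):
            tp = sel[sel["timepoint"] == row["timepoint"]]
            sel = tp if len(tp) else sel
        if len(sel) == 0:
            raise ValueError(
                f"no control wells for cell line {row['cell_line']!r}"
            )
        return float(sel["mean"].mean())

    ctrl = agg.apply(control_mean, axis=1)
    if (ctrl <= 0).any():
        raise ValueError("control mean signal must be positive")
    out = agg[group_keys].copy()
    out["mean_rel"] = agg["mean"] / ctrl
    out["sem"] = agg["std"] / np.sqrt(agg["count"]) / ctrl
    out["n"] = agg["count"]
    return out


def fit_4pl(
    doses,
    rel_viability,
    cell_line: str = "",
    ref_dose: float = REFERENCE_DOSE,
) -> DoseResponseFit:
    """Least-squares 4PL fit with a multi-start (ic50, hill) grid.

    Replicate/duplicate dose rows are averaged per dose before fitting, so
    the fit is invariant to row order and replication. A fit whose top and
    bottom plateaus collapse (span < 0.05) is flagged: no dose effect is
    resolvable and the IC50 is reported missing.
    """
    doses = np.asarray(doses, dtype=float)
    rel = np.asarray(rel_viability, dtype=float)
    if len(doses) != len(rel):
        raise ValueError("doses and viabilities must align")
    per_dose = pd.Series(rel).groupby(pd.Series(doses)).mean()
    d = per_dose.index.to_numpy(dtype=float)
    v = per_dose.to_numpy()
    if len(d) < 5 or 0.0 not in d:
        raise ValueError("need >= 5 distinct doses including 0 (vehicle)")

    pos = d[d > 0]
    lo_ic, hi_ic = pos.min() / 100.0, pos.max() * 100.0

    def residuals(theta):
        bottom, top, log_ic50, log_hill = theta
        return four_pl(d, bottom, top, np.exp(log_ic50), np.exp(log_hill)) - v

    bounds = (
        [-0.2, -0.2, np.log(lo_ic), np.log(0.05)],
        [1.5, 1.5, np.log(hi_ic), np.log(50.0)],
    )
    b0, t0 = float(v.min()), float(v.max())
    best = None
    for ic_start, hill_start in itertools.product(
        np.geomspace(max(pos.min(), lo_ic * 10), pos.max(), 5), (0.5, 1.0, 2.0, 4.0)
    ):
        theta0 = [b0, t0, np.log(ic_start), np.log(hill_start)]
        try:
            sol = least_squares(residuals, theta0, bounds=bounds)
        except Exception:  # pragma: no cover - defensive
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
            if best.cost < 1e-14:  # exact fit; further starts cannot improve
                break
    if best is None:
        logger.warning("4PL fit failed to converge for %r", cell_line)
        nan = float("nan")
        return DoseResponseFit(
            cell_line, nan, nan, nan, nan, nan, ref_dose, nan,
            float(d.max()), float(v[-1]), nan, False, True,
        )

    bottom, top, log_ic50, log_hill = best.x
    ic50, hill = float(np.exp(log_ic50)), float(np.exp(log_hill))
    rss = float(2.0 * best.cost)
    flagged = (top - bottom) < _FLAT_SPAN
    max_dose = float(d.max())
    v_ref = float(four_pl(ref_dose, bottom, top, ic50, hill))
    v_max = float(four_pl(max_dose, bottom, top, ic50, hill))
    # dose at 50% absolute viability, if the curve crosses it
    if bottom < 0.5 < top and not flagged:
        frac = (top - bottom) / (0.5 - bottom) - 1.0
        abs_ic50 = float(ic50 * frac ** (1.0 / hill))
    else:
        abs_ic50 = float("nan")
    if flagged:
        logger.info("no dose effect resolvable for %r (span %.3g)", cell_line, top - bottom)
        ic50 = float("nan")
    extrapolated = (not flagged) and not (pos.min() <= ic50 <= max_dose)
    return DoseResponseFit(
        cell_line, float(bottom), float(top), ic50, hill, rss,
        ref_dose, v_ref, max_dose, v_max, abs_ic50, bool(extrapolated), bool(flagged),
    )


def classify_sensitivity(fit: DoseResponseFit) -> str:
    """Three-tier sensitivity call from a dose-response fit.

    Every fit — including a flagged one — maps to exactly one class.
    """
    lo, hi = SENSITIVE_IC50_RANGE
    if fit.flagged or not np.isfinite(fit.ic50):
        return "insensitive" if fit.viability_at_max_dose > 0.5 else "intermediate"
    if lo <= fit.ic50 <= hi and fit.viability_at_ref_dose < SENSITIVE_MAX_REF_VIABILITY:
        return "sensitive"
    if fit.ic50 >= INSENSITIVE_IC50_MIN:
        return "insensitive"
    return "intermediate"


def run_dose_response(
    readings: PlateReadings, ref_dose: float = REFERENCE_DOSE
) -> list[DoseResponseFit]:
    """Normalize to vehicle, fit each cell line, and classify sensitivity."""
    rel = relative_viability(readings)
    fits = []
    for cell_line, grp in rel.groupby("cell_line"):
        fit = fit_4pl(grp["dose"], grp["mean_rel"], str(cell_line), ref_dose)
        fits.append(replace(fit, sensitivity=classify_sensitivity(fit)))
    return fits


def dose_response_table(fits: list[DoseResponseFit]) -> pd.DataFrame:
    return pd.DataFrame([fit.__dict__ for fit in fits])


def rescue_normalize(grid: pd.DataFrame) -> pd.DataFrame:
    """Normalize a (primary drug × rescue drug) viability grid.

    ``grid`` is tidy with columns ``bci`` (primary-drug dose), ``vx``
    (rescue-drug dose) and ``signal`` (replicates averaged if repeated).
    Each well (b, v) is divided by the matching zero-primary-dose well
    (0, v), so the b = 0 row is exactly 1. A missing (0, v) well is a hard
    error naming the rescue dose.
    """
    required = {"bci", "vx", "signal"}
    if not required <= set(grid.columns):
        raise ValueError(f"rescue grid needs columns {sorted(required)}")
    wide = grid.groupby(["bci", "vx"])["signal"].mean().unstack("vx")
    if 0.0 not in wide.index:
        missing = list(wide.columns)
        raise ValueError(f"no zero-BCI wells for rescue doses {missing}")
    base = wide.loc[0.0]
    absent = base.index[base.isna()]
    if len(absent):
        raise ValueError(f"missing (BCI=0) well for rescue dose {absent[0]!r}")
    return wide / base


@dataclass(frozen=True)
class DdCtResult:
    target: str
    reference: str
    condition: str
    calibrator: str
    delta_delta_ct: float
    fold_change: float


def delta_delta_ct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    condition: str,
    calibrator: str,
) -> DdCtResult:
    """Relative expression by the ΔΔCt method on replicate-mean Cts.

    fold = 2^(−ΔΔCt) with
    ΔΔCt = (Ct̄_target − Ct̄_ref)_condition − (Ct̄_target − Ct̄_ref)_calibrator.
    """
    means = ct.groupby(["gene", "condition"])["ct"].mean()

    def cell(gene: str, cond: str) -> float:
        try:
            return float(means.loc[(gene, cond)])
        except KeyError:
            raise ValueError(f"no Ct values for gene {gene!r} in condition {cond!r}")

    ddct = (cell(target, condition) - cell(reference, condition)) - (
        cell(target, calibrator) - cell(reference, calibrator)
    )
    return DdCtResult(target, reference, condition, calibrator, ddct, float(2.0 ** -ddct))


def densitometry_ratio(
    phospho: float, total: float, loading: float, control_ratio: float
) -> float:
    """Relative phospho-protein level from band intensities.

    The loading control cancels from the phospho/total ratio and is accepted
    only so a caller can log per-lane QC; the result is
    (phospho/total) / control_ratio.
    """
    for name, val in (
        ("phospho", phospho), ("total", total),
        ("loading", loading), ("control_ratio", control_ratio),
    ):
        if not val > 0:
            raise ValueError(f"{name} intensity must be positive, got {val}")
    return (phospho / total) / control_ratio
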