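"""Specific activity, product selectivity and pH/temperature optima from assay tables.

Assay records follow the standardized in vitro design for cannabinoid
oxidocyclases: a known mass concentration of enzyme incubated with CBGA for a
fixed time, products (THCA, CBDA, CBCA) quantified in micromolar.  Specific
activity is product formed per unit time per unit enzyme mass
(umol min^-1 g^-1) and is intensive: it does not depend on the reaction
volume.  Replicates (triplicates by default) aggregate as mean +/- sample sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

PRODUCTS = ("thca_uM", "cbda_uM", "cbca_uM")
ASSAY_COLUMNS = ("enzyme", "replicate", "pH", "temp_C", "time_min",
                 "enzyme_ug_per_ml") + PRODUCTS


def read_assay_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_assay_table(df)


def validate_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"assay table missing columns: {sorted(missing)}")
    if (df["time_min"] <= 0).any():
        raise InputError("time_min must be positive")
    if (df[list(PRODUCTS)] < 0).any().any():
        raise InputError("product concentrations must be non-negative")
    if "substrate_uM" in df.columns:
        over = df[list(PRODUCTS)].sum(axis=1) > df["substrate_uM"] + 1e-9
        if over.any():
            raise InputError("total product exceeds initial substrate concentration")
    return df


@dataclass
class CalibrationCurve:
    """Least-squares line mapping peak area to concentration for one analyte."""

    analyte: str
    slope: float  # area per uM
    intercept: float
    r_squared: float
    stderr: float

    def quantify(self, area: float | np.ndarray) -> float | np.ndarray:
        return (area - self.intercept) / self.slope


def calibrate(standards: list[tuple[float, float]], analyte: str = "") -> CalibrationCurve:
    """Fit a calibration line to (concentration, area) standard pairs."""
    if len({c for c, _ in standards}) < 2:
        raise InputError("calibration needs at least two distinct concentrations")
    conc = np.array([c for c, _ in standards], dtype=float)
    area = np.array([a for _, a in standards], dtype=float)
    fit = stats.linregress(conc, area)
    if not np.isfinite(fit.slope) or fit.slope <= 0:
        raise InputError("calibration slope must be positive and finite")
    return CalibrationCurve(analyte=analyte, slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue**2),
                            stderr=float(fit.stderr if fit.stderr is not None else np.nan))


@dataclass
class ActivityResult:
    """Per-enzyme quantification: activity, selectivity, relative activity."""

    enzyme: str
    specific_activity: float  # umol min^-1 g^-1, mean over replicates
    activity_sd: float
    n_replicates: int
    selectivity: dict[str, float] = field(default_factory=dict)  # fractions, sum 1
    relative_activity: float | None = None  # percent of reference enzyme

    @property
    def active(self) -> bool:
        return self.specific_activity > 0


def _per_replicate_activity(group: pd.DataFrame) -> np.ndarray:
    enzyme_g_per_l = group["enzyme_ug_per_ml"].to_numpy(dtype=float) * 1e-3
    if (enzyme_g_per_l <= 0).any():
        raise InputError("enzyme concentration must be positive")
    total_um = group[list(PRODUCTS)].sum(axis=1).to_numpy(dtype=float)  # umol per L
    return total_um / (group["time_min"].to_numpy(dtype=float) * enzyme_g_per_l)


def specific_activity(records: pd.DataFrame) -> dict[str, tuple[float, float, int]]:
    """Mean +/- sample sd (ddof=1) specific activity per enzyme, umol min^-1 g^-1."""
    validate_assay_table(records)
    out = {}
    for enzyme, grp in records.groupby("enzyme", sort=False):
        acts = _per_replicate_activity(grp)
        sd = float(acts.std(ddof=1)) if len(acts) > 1 else 0.0
        out[str(enzyme)] = (float(acts.mean()), sd, len(acts))
    return out


def selectivity(records: pd.DataFrame) -> dict[str, dict[str, float] | None]:
    """Fraction of total product per analyte (THCA/CBDA/CBCA), per enzyme.

    Computed from replicate-summed concentrations; an enzyme with zero total
    product reports ``None`` (no activity).  Unidentified trace products are
    not part of the table and hence excluded from the denominator.
    """
    validate_assay_table(records)
    out: dict[str, dict[str, float] | None] = {}
    for enzyme, grp in records.groupby("enzyme", sort=False):
        totals = grp[list(PRODUCTS)].sum(axis=0)
        total = float(totals.sum())
        if total <= 0:
            out[str(enzyme)] = None
            continue
        out[str(enzyme)] = {
            p.replace("_uM", "").upper(): float(totals[p]) / total for p in PRODUCTS
        }
    return out


def relative_activity(activity: float, reference: float) -> float:
    """Activity as a percentage of a reference enzyme's activity."""
    if reference <= 0:
        raise InputError("reference activity must be positive")
    return 100.0 * activity / reference


def quantify(records: pd.DataFrame, reference: str | None = None) -> list[ActivityResult]:
    """Full quantification of an assay table: activity, selectivity, relative activity."""
    acts = specific_activity(records)
    sels = selectivity(records)
    ref_act = acts[reference][0] if reference is not None else None
    results = []
    for enzyme, (mean, sd, n) in acts.items():
        results.append(ActivityResult(
            enzyme=enzyme, specific_activity=mean, activity_sd=sd, n_replicates=n,
            selectivity=sels[enzyme] or {},
            relative_activity=(relative_activity(mean, ref_act)
                               if ref_act else None)))
    return results


def results_table(results: list[ActivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"enzyme": r.enzyme,
               "specific_activity": r.specific_activity,
               "activity_sd": r.activity_sd,
               "n": r.n_replicates,
               "relative_activity_pct": r.relative_activity}
        for p in ("THCA", "CBDA", "CBCA"):
            row[f"frac_{p}"] = r.selectivity.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ProfileOptimum:
    """Argmax of an activity series over pH or temperature levels."""

    variable: str
    optimum: float
    optimum_range: tuple[float, float]
    at_boundary: bool
    levels: list[float]
    activities: list[float]


def profile_optimum(records: pd.DataFrame, variable: str = "pH",
                    plateau_frac: float = 0.05) -> ProfileOptimum:
    """Optimum level of an activity profile.

    Contiguous levels within ``plateau_frac`` (5 percent) of the maximum are
    reported as a range.  A maximum at either end of the series carries a
    boundary flag (the true optimum may lie outside the tested range).
    """
    validate_assay_table(records)
    if variable not in ("pH", "temp_C"):
        raise InputError("variable must be 'pH' or 'temp_C'")
    acts = []
    for level, grp in records.groupby(variable, sort=True):
        acts.append((float(level), float(np.mean(_per_replicate_activity(grp)))))
    if len(acts) < 3:
        raise InputError("profile needs at least three levels")
    levels = [a[0] for a in acts]
    values = [a[1] for a in acts]
    vmax = max(values)
    if vmax <= 0:
        raise InputError("flat zero activity series: no optimum")
    imax = int(np.argmax(values))
    lo = hi = imax
    while lo > 0 and values[lo - 1] >= (1 - plateau_frac) * vmax:
        lo -= 1
    while hi < len(values) - 1 and values[hi + 1] >= (1 - plateau_frac) * vmax:
        hi += 1
    return ProfileOptimum(
        variable=variable, optimum=levels[imax],
        optimum_range=(levels[lo], levels[hi]),
        at_boundary=imax in (0, len(values) - 1),
        levels=levels, activities=values)
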