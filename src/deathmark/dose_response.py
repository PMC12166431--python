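"""Dose-response curve fitting and sensitivity AUC.

Viability of a cell line across a log10 concentration series is modelled with a
four-parameter logistic whose asymptotes are fixed at 0% and 100% of control:

    v(x) = 100 / (1 + exp(b * (x - e)))

where ``x`` is log10(molar concentration), ``b`` the slope and ``e`` the
log10 EC50 (= IC50 under the fixed asymptotes, since v(e) = 50 exactly).

The vulnerability measure used downstream is the *sensitivity AUC*:
100 minus the range-normalised trapezoidal area of the observed viability
points over log-concentration, so 0 means fully resistant (viability pinned at
100%) and 100 means fully sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DegenerateDataError",
    "FitError",
    "LogisticFit",
    "log_transform_concentration",
    "fit_logistic4",
    "ic50_from_fit",
    "sensitivity_auc",
    "read_dose_response",
    "melt_dose_response",
    "validate_dose_response",
    "auc_table",
    "fit_all",
]


class DegenerateDataError(ValueError):
    """Raised when viability data carry no dose-response information."""


class FitError(RuntimeError):
    """Raised when the logistic fit fails to converge."""


@dataclass(frozen=True)
class LogisticFit:
    """Fixed-asymptote 4PL fit: v(x) = 100 / (1 + exp(slope*(x - ec50_log)))."""

    slope: float
    ec50_log: float
    sse: float
    n_points: int
    lower_asymptote: float = field(default=0.0, init=False)
    upper_asymptote: float = field(default=100.0, init=False)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return 100.0 / (1.0 + np.exp(self.slope * (x - self.ec50_log)))


def log_transform_concentration(concentration):
    """log10 of a molar concentration; scalar or array, must be > 0."""
    conc = np.asarray(concentration, dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
        raise ValueError("concentration must be finite and strictly positive")
    out = np.log10(conc)
    return float(out) if np.isscalar(concentration) else out


def _logistic_residuals(params, x, y):
    b, e = params
    return 100.0 / (1.0 + np.exp(np.clip(b * (x - e), -500, 500))) - y


def fit_logistic4(log_conc, viability, slope0: float = 1.0, ec50_log0: float | None = None) -> LogisticFit:
    """Least-squares fit of the fixed-asymptote logistic.

    Initialiser: slope0 = 1, ec50_log0 = median(log_conc) unless overridden.
    Deterministic; raises :class:`DegenerateDataError` for constant viability
    or fewer than 3 distinct concentrations, :class:`FitError` on
    non-convergence.
    """
    x = np.asarray(log_conc, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log_conc and viability must be 1-D and equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if np.unique(x).size < 3:
        raise DegenerateDataError("need >= 3 distinct log-concentration values")
    if np.allclose(y, y[0]):
        raise DegenerateDataError("viability is constant across doses")
    e0 = float(np.median(x)) if ec50_log0 is None else float(ec50_log0)
    res = least_squares(
        _logistic_residuals,
        x0=[slope0, e0],
        args=(x, y),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10000,
    )
    if not res.success:
        raise FitError(f"logistic fit did not converge: {res.message}")
    b, e = res.x
    return LogisticFit(slope=float(b), ec50_log=float(e), sse=float(np.sum(res.fun**2)), n_points=int(x.size))


def ic50_from_fit(fit: LogisticFit) -> float:
    """Molar IC50 = 10**ec50_log (half-viability point under fixed asymptotes)."""
    return float(10.0 ** fit.ec50_log)


def sensitivity_auc(log_conc, viability) -> float:
    """100 - range-normalised trapezoid of viability over log10 concentration.

    Computed on the observed points (no curve fit), so the value is invariant
    to row order and to affine rescaling of the concentration units. Clipped
    to [0, 100] with a warning if numerically outside.
    """
    x = np.asarray(log_conc, dtype=float)
    y = np.asarray(viability, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct log-concentration values for an AUC")
    order = np.argsort(x)
    x, y = x[order], y[order]
    area = np.trapezoid(y, x) / (x[-1] - x[0])
    auc = 100.0 - area
    if auc < 0.0 or auc > 100.0:
        warnings.warn(f"sensitivity AUC {auc:.3f} outside [0, 100]; clipping", stacklevel=2)
        auc = float(np.clip(auc, 0.0, 100.0))
    return float(auc)


# ---------------------------------------------------------------------------
# Tabular I/O: wide dose-response tables
# (Cell_line, Concentration, logConc, Repeat_1..Repeat_n) and the long form
# used internally (cell_line, concentration, log_conc, replicate, viability).
# ---------------------------------------------------------------------------

def read_dose_response(path) -> pd.DataFrame:
    """Read a wide dose-response CSV and return the validated long form."""
    wide = pd.read_csv(path)
    return melt_dose_response(wide)


def melt_dose_response(wide: pd.DataFrame) -> pd.DataFrame:
    required = {"Cell_line", "Concentration", "logConc"}
    missing = required - set(wide.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    rep_cols = [c for c in wide.columns if c.startswith("Repeat_")]
    if not rep_cols:
        raise ValueError("dose-response table has no Repeat_* columns")
    long = wide.melt(
        id_vars=["Cell_line", "Concentration", "logConc"],
        value_vars=rep_cols,
        var_name="replicate",
        value_name="viability",
    ).rename(columns={"Cell_line": "cell_line", "Concentration": "concentration", "logConc": "log_conc"})
    long = long.dropna(subset=["viability"]).reset_index(drop=True)
    validate_dose_response(long)
    return long


def validate_dose_response(long: pd.DataFrame) -> None:
    """Check the long-form invariants; raise ValueError on violation."""
    if np.any(long["concentration"] <= 0):
        raise ValueError("non-positive concentrations present")
    err = np.abs(long["log_conc"] - np.log10(long["concentration"]))
    if np.any(err >= 1e-4):
        bad = long.loc[err >= 1e-4, "concentration"].iloc[0]
        raise ValueError(f"logConc does not match log10(Concentration) (e.g. at {bad})")
    if np.any(long["viability"] < 0) or np.any(~np.isfinite(long["viability"])):
        raise ValueError("viability must be finite and >= 0")
    counts = long.groupby(["cell_line", "replicate"])["log_conc"].nunique()
    if (counts < 3).any():
        key = counts[counts < 3].index[0]
        raise ValueError(f"fewer than 3 distinct concentrations for {key}")


def fit_all(long: pd.DataFrame) -> pd.DataFrame:
    """Fit the logistic per (cell_line, replicate); one row per fit.

    Columns: cell_line, replicate, slope, ec50_log, ic50, sse, n_points.
    """
    rows = []
    for (cell, rep), grp in long.groupby(["cell_line", "replicate"], sort=True):
        fit = fit_logistic4(grp["log_conc"].to_numpy(), grp["viability"].to_numpy())
        rows.append(
            {
                "cell_line": cell,
                "replicate": rep,
                "slope": fit.slope,
                "ec50_log": fit.ec50_log,
                "ic50": ic50_from_fit(fit),
                "sse": fit.sse,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def auc_table(long: pd.DataFrame, inducer: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sensitivity AUCs for one inducer.

    Returns ``(mean_table, per_replicate)``: the mean table has one row per
    cell line with a column named after the inducer (Table-2 style); the
    per-replicate frame keeps each replicate's AUC computed on its raw points.
    """
    rows = []
    for (cell, rep), grp in long.groupby(["cell_line", "replicate"], sort=True):
        rows.append(
            {
                "cell_line": cell,
                "replicate": rep,
                "auc": sensitivity_auc(grp["log_conc"].to_numpy(), grp["viability"].to_numpy()),
            }
        )
    per_rep = pd.DataFrame(rows)
    mean_tbl = (
        per_rep.groupby("cell_line", sort=True)["auc"].mean().rename(inducer).reset_index().rename(columns={"cell_line": "Cell_line"})
    )
    return mean_tbl, per_rep
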