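"""Differential expression: drug-vs-vehicle RNA-seq contrasts.

Counts are normalised to offset log2 counts-per-million, fitted per gene by
ordinary least squares on a group-means design, and the residual variances are
shrunk toward a common prior by inverse-chi-square empirical-Bayes moderation
(hyperparameters d0 and s0^2 estimated by method of moments on the log
variances, the classic limma-style scheme). The moderated t is

    t_g = logFC_g / (se_g * s_post_g / s_g),    df = d0 + df_residual

where s_post_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df). Precision weights are
deliberately not used; the null-calibration property test in the suite guards
the substitution.

The per-contrast output (gene, logFC, t_stat) is the "drug response
signature" consumed by the enrichment stage. Contrast polarity is always
drug minus vehicle: positive logFC means up in drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

__all__ = [
    "normalize_log_counts",
    "estimate_prior",
    "squeeze_variances",
    "fit_contrasts",
    "default_contrasts",
]


def normalize_log_counts(
    counts: pd.DataFrame,
    min_group_size: int = 3,
    cpm_threshold: float = 1.0,
    offset: float = 0.5,
) -> pd.DataFrame:
    """Offset log2-CPM: log2((count + offset) / (libsize + 2*offset) * 1e6).

    Genes are kept when CPM > *cpm_threshold* in at least *min_group_size*
    samples. Raises on any zero library size.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size in sample(s): {bad}")
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_group_size
    x = counts.to_numpy(dtype=float)[keep]
    logcpm = np.log2((x + offset) / (lib + 2 * offset) * 1e6)
    return pd.DataFrame(logcpm, index=counts.index[keep], columns=counts.columns)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, monotone)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from sample variances with df dof.

    Works on log variances: E[log s^2] and Var[log s^2] under the scaled-F
    model give s0^2 and d0 via digamma/trigamma moments. Returns
    (d0, s0sq); d0 = inf when the observed spread is no larger than the
    chi-square sampling spread alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))) if np.isfinite(d0) else float(np.exp(emean))
    return float(d0), s0sq


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s0sq: float) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df); d0=0 returns s^2,
    d0=inf returns s0^2 for every gene."""
    s2 = np.asarray(s2, dtype=float)
    if d0 == 0:
        return s2.copy()
    if np.isinf(d0):
        return np.full_like(s2, s0sq)
    return (d0 * s0sq + df * s2) / (d0 + df)


@dataclass(frozen=True)
class ModerationInfo:
    d0: float
    s0sq: float
    df_residual: float


def default_contrasts(design: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """One contrast per (cell_line, non-vehicle condition) against that cell
    line's vehicle group, named '<cell_line> treated with <condition>'."""
    out: dict[str, tuple[str, str]] = {}
    for cell, grp in design.groupby("cell_line", sort=True):
        conds = sorted(grp["condition"].unique())
        if "vehicle" not in conds:
            raise ValueError(f"cell line {cell} has no vehicle samples")
        for cond in conds:
            if cond == "vehicle":
                continue
            out[f"{cell} treated with {cond}"] = (f"{cell}|{cond}", f"{cell}|vehicle")
    return out


def fit_contrasts(
    logexpr: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: dict[str, tuple[str, str]] | None = None,
    prior_df: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene OLS on a group-means design plus variance moderation.

    *design* needs columns sample, cell_line, condition (condition 'vehicle'
    is the reference); groups are ``cell_line|condition``. *contrasts* maps a
    contrast name to a (treated_group, reference_group) pair and defaults to
    every drug-vs-vehicle pair within each cell line. *prior_df* overrides the
    estimated d0 (0 gives ordinary t).

    Returns {contrast: DataFrame(gene, logFC, t_stat, p, contrast)}; the
    moderation hyperparameters ride along in ``frame.attrs['moderation']``.
    """
    from scipy import stats as sps

    design = design.set_index("sample").loc[logexpr.columns].reset_index()
    groups = design["cell_line"].astype(str) + "|" + design["condition"].astype(str)
    levels = sorted(groups.unique())
    if contrasts is None:
        contrasts = default_contrasts(design)
    gmat = np.stack([(groups == g).to_numpy(dtype=float) for g in levels], axis=1)
    n_per = gmat.sum(axis=0)
    if np.any(n_per < 1):
        raise ValueError("empty design group")
    n, k = gmat.shape
    df_res = n - k
    if df_res < 1:
        raise ValueError("design leaves no residual degrees of freedom (need replicates)")

    y = logexpr.to_numpy(dtype=float)  # genes x samples
    means = y @ gmat / n_per  # genes x groups
    fitted = means @ gmat.T
    resid = y - fitted
    s2 = (resid**2).sum(axis=1) / df_res

    d0, s0sq = estimate_prior(s2, df_res)
    if prior_df is not None:
        d0 = prior_df
        if np.isinf(d0):
            _, s0sq = estimate_prior(s2, df_res)
    s2_post = squeeze_variances(s2, df_res, d0, s0sq)
    df_total = df_res if d0 == 0 else df_res + (0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        df_total = np.inf

    level_pos = {g: i for i, g in enumerate(levels)}
    out: dict[str, pd.DataFrame] = {}
    for name, (treated, reference) in contrasts.items():
        for g in (treated, reference):
            if g not in level_pos:
                raise ValueError(f"contrast {name!r} names unknown group {g!r}; groups: {levels}")
        i, j = level_pos[treated], level_pos[reference]
        logfc = means[:, i] - means[:, j]
        unscaled = 1.0 / n_per[i] + 1.0 / n_per[j]
        se = np.sqrt(s2_post * unscaled)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = 2.0 * sps.t.sf(np.abs(t), df=df_total)
        frame = pd.DataFrame({"gene": logexpr.index, "logFC": logfc, "t_stat": t, "p": p, "contrast": name})
        frame.attrs["moderation"] = ModerationInfo(d0=float(d0), s0sq=float(s0sq), df_residual=float(df_res))
        out[name] = frame
    return out
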