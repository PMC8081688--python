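"""Two-stage phenotypic analysis for multi-trial breeding data.

Stage 1 fits each trial separately (randomized complete block model),
estimating the trial's repeatability

    h2 = sigma2_G / (sigma2_G + MVD/2)

where MVD is the mean variance of a difference between line BLUEs.  Trials
with h2 > 0.2 feed stage 2: fixed-effects across-trial BLUEs within each
year, then an across-year mixed model with fixed lines and a random year
effect.  A protein-yield index multiplies the across-year BLUEs of protein
content (percent) and grain yield (dt/ha).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .blup import _profile_reml

__all__ = [
    "TrialFit",
    "trial_repeatability",
    "filter_trials",
    "across_trial_blues",
    "across_year_blues",
    "protein_yield",
]


@dataclass
class TrialFit:
    trial_id: str
    blues: pd.Series  # line BLUEs, centered on the trial mean
    sigma2_g: float
    sigma2_e: float
    mvd: float
    h2: float


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Drop-first indicator columns for a categorical factor."""
    levels = list(pd.unique(labels))
    cols = [(labels == lv).to_numpy(dtype=float) for lv in levels[1:]]
    mat = np.column_stack(cols) if cols else np.empty((len(labels), 0))
    return mat, levels


def trial_repeatability(plot_records: pd.DataFrame, trial_id: str | None = None) -> TrialFit:
    """Repeatability and line BLUEs for one trial.

    ``plot_records`` needs columns line_id, replicate, value.  The genetic
    variance comes from a random-line fit (replicates fixed); the BLUEs and
    the mean variance of a difference (MVD) come from a fixed-line fit.
    """
    df = plot_records.reset_index(drop=True)
    if trial_id is None:
        trial_id = str(df["trial_id"].iloc[0]) if "trial_id" in df else "trial"
    if df["replicate"].nunique() < 2:
        raise ValueError("single replicate: genetic variance is confounded")
    y = df["value"].to_numpy(dtype=float)
    rep_x, _ = _dummies(df["replicate"])
    x_fixed = np.column_stack([np.ones(len(df)), rep_x])

    # random-line REML: K = Z Z' with Z the line incidence
    lines = list(pd.unique(df["line_id"]))
    z = (df["line_id"].to_numpy()[:, None] == np.array(lines)[None, :]).astype(float)
    s2g, s2e, *_ = _profile_reml(y, x_fixed, z @ z.T)

    # fixed-line OLS for BLUEs and their contrast covariance
    line_x, line_levels = _dummies(df["line_id"])
    x = np.column_stack([x_fixed, line_x])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = len(df) - x.shape[1]
    if dof < 1:
        raise ValueError("no residual degrees of freedom in the trial model")
    mse = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    p0 = x_fixed.shape[1]
    # effect covariance including the (zero-variance) reference level
    n_lines = len(line_levels)
    cov = np.zeros((n_lines, n_lines))
    cov[1:, 1:] = mse * xtx_inv[p0:, p0:]
    diffs = []
    for i in range(n_lines):
        for j in range(i + 1, n_lines):
            diffs.append(cov[i, i] + cov[j, j] - 2.0 * cov[i, j])
    mvd = float(np.mean(diffs))
    h2 = s2g / (s2g + 0.5 * mvd) if (s2g + 0.5 * mvd) > 0 else 0.0

    effects = np.concatenate([[0.0], beta[p0:]])
    blues = pd.Series(effects, index=line_levels)
    blues = blues - blues.mean() + float(np.mean(y))
    return TrialFit(trial_id, blues.sort_index(), s2g, mse, mvd, float(h2))


def repeatability_from_components(sigma2_g: float, mvd: float) -> float:
    """h2 = sigma2_G / (sigma2_G + MVD/2) from given components."""
    denom = sigma2_g + 0.5 * mvd
    return sigma2_g / denom if denom > 0 else 0.0


def filter_trials(trial_fits: list[TrialFit], min_h2: float = 0.2) -> list[TrialFit]:
    """Keep trials whose repeatability strictly exceeds ``min_h2``."""
    return [t for t in trial_fits if t.h2 > min_h2]


def _check_connected(df: pd.DataFrame, unit_col: str) -> None:
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(("line", row["line_id"]), (unit_col, row[unit_col]))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        summaries = [
            sorted(str(n[1]) for n in comp if n[0] == "line")[:3] for comp in comps
        ]
        raise ValueError(
            f"design is disconnected into {len(comps)} components; "
            f"example lines per component: {summaries}"
        )


def across_trial_blues(trial_blues: pd.DataFrame) -> pd.Series:
    """Across-trial line BLUEs within a year: fixed lines + fixed trials.

    ``trial_blues`` needs columns line_id, trial_id, value (the stage-1
    BLUEs).  Returns line BLUEs centered on the grand mean.
    """
    df = trial_blues.reset_index(drop=True)
    _check_connected(df, "trial_id")
    y = df["value"].to_numpy(dtype=float)
    line_x, line_levels = _dummies(df["line_id"])
    trial_x, _ = _dummies(df["trial_id"])
    x = np.column_stack([np.ones(len(df)), line_x, trial_x])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    effects = np.concatenate([[0.0], beta[1 : len(line_levels)]])
    blues = pd.Series(effects, index=line_levels)
    return (blues - blues.mean() + float(np.mean(y))).sort_index()


def across_year_blues(yearly_blues: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Across-year line BLUEs: fixed lines, random year effect (REML).

    ``yearly_blues`` needs columns line_id, year, value.  Returns the
    centered line BLUEs and the estimated variance components
    ``{"sigma2_year", "sigma2_e"}``.
    """
    df = yearly_blues.reset_index(drop=True)
    years = list(pd.unique(df["year"]))
    if len(years) < 2:
        raise ValueError("across-year analysis needs >= 2 years")
    _check_connected(df, "year")
    y = df["value"].to_numpy(dtype=float)
    line_x, line_levels = _dummies(df["line_id"])
    x = np.column_stack([np.ones(len(df)), line_x])
    zy = (df["year"].to_numpy()[:, None] == np.array(years)[None, :]).astype(float)
    s2j, s2e, beta, *_ = _profile_reml(y, x, zy @ zy.T)
    # note: _profile_reml parameterizes V = s2g*(K + lam I); here K = ZZ'
    # so s2g is the year variance and s2e the residual variance.
    effects = np.concatenate([[0.0], beta[1:]])
    blues = pd.Series(effects, index=line_levels)
    blues = (blues - blues.mean() + float(np.mean(y))).sort_index()
    return blues, {"sigma2_year": s2j, "sigma2_e": s2e}


def protein_yield(protein_content_pct, grain_yield_dt_ha):
    """Protein yield (dt/ha) = protein content (%) / 100 * grain yield."""
    pc = np.asarray(protein_content_pct, dtype=float)
    gy = np.asarray(grain_yield_dt_ha, dtype=float)
    if (pc < 0).any() or (gy < 0).any():
        raise ValueError("protein content and grain yield must be non-negative")
    out = pc / 100.0 * gy
    if isinstance(protein_content_pct, pd.Series):
        return pd.Series(out, index=protein_content_pct.index)
    return out if out.ndim else float(out)
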