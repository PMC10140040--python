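"""Per-interaction cohort statistics: partial correlations and survival.

Two auxiliary analyses interpret validated interactions:

* Spearman partial correlation between a gene's expression and one immune
  cell-type fraction, controlling for the remaining cell-type columns —
  all columns are rank-transformed, the two focal rank vectors are
  residualized against the controls by least squares, and the Pearson
  correlation of the residuals is the partial correlation.  p-values use
  the t approximation with n - 2 - k degrees of freedom (k controls) and
  are Bonferroni-adjusted over the cell types tested per gene.
* Log-rank comparison of survival across the four expression quadrants of
  a pair, plus the two-group test between the winning configuration's
  target and baseline quadrants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from .scoring import CONFIG_BY_ID, Stratification


@dataclass(frozen=True)
class PartialCorrelationResult:
    gene: str
    cell_type: str
    rho: float
    p: float
    p_adj: float
    n: int
    controls: tuple[str, ...]


@dataclass(frozen=True)
class SurvivalComparison:
    pair: tuple[str, str]
    groups: pd.Series           # per-sample quadrant label
    statistic: float            # four-group log-rank chi-square
    p: float
    statistic_pairwise: float | None
    p_pairwise: float | None


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, controls] by least squares."""
    X = np.column_stack([np.ones(len(y)), controls])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _drop_collinear(controls: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that add no rank to the control design matrix."""
    keep: list[str] = []
    X = np.ones((len(controls), 1))
    for c in controls.columns:
        cand = np.column_stack([X, controls[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            keep.append(c)
            X = cand
        else:
            warnings.warn(f"dropping collinear control column {c!r}")
    return controls[keep]


def partial_correlation(
    gene_values: pd.Series,
    fractions: pd.DataFrame,
    cell_type: str,
    gene: str | None = None,
    n_tests: int | None = None,
) -> PartialCorrelationResult:
    """Spearman partial correlation of a gene with one cell-type fraction.

    ``fractions`` holds all cell-type columns; every column other than
    ``cell_type`` serves as a control.  Samples with any missing value are
    excluded.  ``n_tests`` (default: number of cell-type columns) sets the
    Bonferroni multiplier.
    """
    if cell_type not in fractions.columns:
        raise KeyError(f"cell type {cell_type!r} not in fractions table")
    gene = gene if gene is not None else (gene_values.name or "gene")
    df = fractions.copy()
    df["__gene__"] = gene_values.reindex(df.index)
    df = df.dropna()
    n = len(df)
    if n < 10:
        raise ValueError(f"only {n} complete samples; need >= 10")
    controls = _drop_collinear(
        df[[c for c in fractions.columns if c != cell_type]]
    )
    k = controls.shape[1]
    gx = _rank(df["__gene__"].to_numpy(dtype=float))
    cy = _rank(df[cell_type].to_numpy(dtype=float))
    cz = np.column_stack(
        [_rank(controls[c].to_numpy(dtype=float)) for c in controls.columns]
    ) if k else np.empty((n, 0))
    rx = _residualize(gx, cz)
    ry = _residualize(cy, cz)
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    rho = float(np.sum(rx * ry) / denom) if denom > 0 else 0.0
    rho = max(-1.0, min(1.0, rho))
    dof = n - 2 - k
    if dof <= 0:
        raise ValueError("not enough samples for the control set")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    m = n_tests if n_tests is not None else fractions.shape[1]
    return PartialCorrelationResult(
        gene=gene, cell_type=cell_type, rho=rho, p=p,
        p_adj=min(1.0, p * m), n=n, controls=tuple(controls.columns),
    )


def logrank_survival(
    strat: Stratification,
    survival: pd.DataFrame,
    config_id: str | None = None,
    min_group_size: int = 1,
) -> SurvivalComparison:
    """Log-rank tests across expression quadrants.

    ``survival`` is indexed by sample with columns ``time`` (> 0) and
    ``event`` (0/1).  The overall test spans the four quadrants; when a
    winning configuration is given, its target and baseline quadrants are
    additionally compared head-to-head.  Ties are handled with the
    standard hypergeometric-variance form.
    """
    labels = pd.Series(strat.labels, index=list(strat.samples))
    df = survival.copy()
    df["group"] = labels.reindex(df.index)
    df = df.dropna(subset=["time", "event", "group"])
    df = df[df["group"] != ""]
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    counts = df["group"].value_counts()
    if (counts < min_group_size).any() or counts.size < 2:
        raise ValueError("too few samples with survival data per group")
    if df["event"].sum() == 0:
        warnings.warn("no events observed; log-rank test is uninformative")
        return SurvivalComparison(
            pair=strat.pair, groups=df["group"], statistic=0.0, p=1.0,
            statistic_pairwise=None, p_pairwise=None,
        )
    overall = multivariate_logrank_test(
        df["time"], df["group"], df["event"]
    )
    stat_pw = p_pw = None
    if config_id is not None:
        cfg = CONFIG_BY_ID[config_id]
        a = df[df["group"] == cfg.target]
        b = df[df["group"] == cfg.baseline]
        if len(a) and len(b):
            pw = logrank_test(
                a["time"], b["time"],
                event_observed_A=a["event"], event_observed_B=b["event"],
            )
            stat_pw, p_pw = float(pw.test_statistic), float(pw.p_value)
    return SurvivalComparison(
        pair=strat.pair, groups=df["group"],
        statistic=float(overall.test_statistic), p=float(overall.p_value),
        statistic_pairwise=stat_pw, p_pairwise=p_pw,
    )
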