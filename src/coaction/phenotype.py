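"""Immune-associated phenotype (IAP) scoring and rescaling.

An IAP is any per-sample immune-relevant readout: expression of a marker
gene such as *IFNG*, a leukocyte fraction, a deconvolved cell-type
fraction, or a signature score.  Signature-based IAPs are the mean of
per-gene z-scores of log-scaled expression.  Before pair scoring every IAP
is rescaled onto [0, 1] with a branch of a sigmoidal map chosen by the
observed range of the raw values, so combined-action scores are comparable
across phenotypes:

* values already confined to [0, 1] are passed through unchanged;
* values spanning the real line map through ``(tanh(x / sigma) + 1) / 2``;
* nonnegative unbounded values map through ``tanh(x / sigma)``;

where ``sigma`` is the sample standard deviation of the raw values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


class DegeneratePhenotypeError(ValueError):
    """A constant IAP carries no contrast and cannot be scored."""


class SignatureError(ValueError):
    """No signature gene is present in the expression matrix."""


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene set defining a signature-based IAP."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise SignatureError(f"signature {self.name!r} has no genes")


@dataclass(frozen=True)
class ScaledPhenotype:
    """A rescaled IAP column aligned to the cohort's samples.

    ``values`` is a float Series indexed by sample ID with every
    non-missing entry in [0, 1].  ``sigma`` is the standard deviation of
    the raw values (n-1 denominator) and ``branch`` records which case of
    the rescaling map applied.
    """

    name: str
    values: pd.Series
    sigma: float
    branch: str  # identity | real_line | nonnegative

    def aligned(self, samples: list[str]) -> np.ndarray:
        return self.values.reindex(samples).to_numpy(dtype=float)


def compute_signature_score(
    expr: ExpressionMatrix, sig: SignatureDefinition
) -> pd.Series:
    """Mean over signature genes of the per-gene z-score of log2(x + 1).

    Each gene's log-scaled values are standardized across samples (mean 0,
    sd 1, n-1 denominator); a gene constant across samples contributes
    z = 0 everywhere.  Genes absent from the matrix are dropped with a
    warning; at least one must remain.
    """
    present = [g for g in sig.genes if g in expr.data.index]
    absent = [g for g in sig.genes if g not in expr.data.index]
    if absent:
        warnings.warn(
            f"signature {sig.name!r}: genes absent from matrix: {absent}"
        )
    if not present:
        raise SignatureError(
            f"signature {sig.name!r}: no signature gene present in matrix"
        )
    logged = np.log2(expr.data.loc[present].to_numpy(dtype=float) + 1.0)
    mu = np.nanmean(logged, axis=1, keepdims=True)
    sd = np.nanstd(logged, axis=1, ddof=1, keepdims=True)
    z = (logged - mu) / np.where(sd > 0, sd, 1.0)
    # zero-variance genes contribute z = 0 where observed, NaN where missing
    z = np.where(np.broadcast_to(sd == 0, z.shape), 0.0, z)
    z = np.where(np.isnan(logged), np.nan, z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        scores = np.nanmean(z, axis=0)
    return pd.Series(scores, index=expr.samples, name=sig.name)


def scale_iap(raw: pd.Series, name: str | None = None) -> ScaledPhenotype:
    """Rescale a raw IAP column onto [0, 1].

    Branch selection inspects the non-missing raw values: ``identity`` when
    all lie in [0, 1] (takes precedence when the range is exactly filled),
    ``real_line`` when any value is negative, ``nonnegative`` otherwise.
    Missing values are excluded from sigma and stay missing.
    """
    name = name if name is not None else (raw.name or "iap")
    vals = raw.to_numpy(dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size < 2 or np.unique(obs).size < 2:
        raise DegeneratePhenotypeError(
            f"IAP {name!r} is constant or near-empty; cannot be scaled"
        )
    sigma = float(np.std(obs, ddof=1))
    if sigma == 0.0:
        raise DegeneratePhenotypeError(f"IAP {name!r} has zero variance")
    if obs.min() >= 0.0 and obs.max() <= 1.0:
        branch = "identity"
        scaled = vals.copy()
    elif obs.min() < 0.0:
        branch = "real_line"
        scaled = (np.tanh(vals / sigma) + 1.0) / 2.0
    else:
        branch = "nonnegative"
        scaled = np.tanh(vals / sigma)
    return ScaledPhenotype(
        name=name,
        values=pd.Series(scaled, index=raw.index, name=name),
        sigma=sigma,
        branch=branch,
    )
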