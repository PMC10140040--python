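"""Three-part statistical validation of combined-action scores.

Each scored pair is screened in stages:

1. **Robustness** — the score is recomputed on many random sub-cohorts
   (default 70% coverage); R is the root-mean-square deviation of the
   partial scores from the full-cohort score, normalized by |S|.  A pair
   is robust when -log(R) > 0, i.e. R < 1.
2. **Significance** — the phenotype in the winning configuration's target
   quadrant is compared to each of the other three quadrants with a
   two-sided Wilcoxon rank-sum (Mann-Whitney) test; the reported p is the
   maximum of the three, so every comparison must reject.  Benjamini-
   Hochberg correction runs over the robust set.
3. **Specificity** — each focal gene is scored against randomly drawn
   partner genes; the empirical tail probability of the observed score
   under each null is computed and the larger of the two reported, BH-
   corrected over the robust and significant set.

On the choice of rank test: target and comparison quadrants contain
different patients, so the paired signed-rank form is undefined and the
unpaired rank-sum form is used (see docs/methods.md).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .phenotype import ScaledPhenotype
from .scoring import (
    CONFIG_BY_ID,
    DEFAULT_MIN_GROUP_SIZE,
    CombinedActionResult,
    Stratification,
    _stratify_values,
    score_stratification,
    stratify_pair,
)

EXACT_MAX_GROUP = 25  # exact rank-sum null up to this size per group


@dataclass(frozen=True)
class RobustnessResult:
    S_complete: float
    partial_scores: tuple[float, ...]   # valid (non-missing) resample scores
    R: float
    n_boot: int
    coverage: float
    n_valid: int

    @property
    def robust(self) -> bool:
        # -log(R) > 0  <=>  R < 1; additionally require that at least half
        # of the resamples produced a score at all
        return self.R < 1.0 and self.n_valid >= 0.5 * self.n_boot


@dataclass(frozen=True)
class SignificanceResult:
    p_by_group: dict[str, float]
    p: float                       # max of the three comparisons
    Q: float | None = None         # BH-adjusted, filled in by validate_all


@dataclass(frozen=True)
class SpecificityResult:
    p_g1: float | None
    p_g2: float | None
    p_max: float | None
    n_valid_g1: int
    n_valid_g2: int
    n_random: int
    Q: float | None = None

    @property
    def defined(self) -> bool:
        return self.p_max is not None


@dataclass(frozen=True)
class ValidatedInteraction:
    """A scored pair joined with its statistical validation record."""

    result: CombinedActionResult
    robustness: RobustnessResult | None = None
    significance: SignificanceResult | None = None
    specificity: SpecificityResult | None = None
    passed: bool = False
    stage: str = "score"  # furthest stage reached: score|robustness|significance|specificity|passed

    def as_record(self) -> dict:
        r = self.result
        return {
            "tap": r.pair[0],
            "icp": r.pair[1],
            "iap": r.iap,
            "config": r.config if r.config is not None else None,
            "S": r.S if r.S is not None else float("nan"),
            "sign": r.sign if r.sign is not None else None,
            "M_target": r.M_target if r.M_target is not None else float("nan"),
            "M_E": r.M_E if r.M_E is not None else float("nan"),
            "R": self.robustness.R if self.robustness else float("nan"),
            "p_significance": self.significance.p if self.significance else float("nan"),
            "Q_significance": (
                self.significance.Q
                if self.significance and self.significance.Q is not None
                else float("nan")
            ),
            "p_specificity": (
                self.specificity.p_max
                if self.specificity and self.specificity.p_max is not None
                else float("nan")
            ),
            "Q_specificity": (
                self.specificity.Q
                if self.specificity and self.specificity.Q is not None
                else float("nan")
            ),
            "passed": self.passed,
        }


@dataclass(frozen=True)
class ValidationParams:
    model: str = "HSA"
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
    n_boot: int = 1000
    coverage: float = 0.7
    n_random: int = 1000
    q_threshold: float = 0.1
    score_cutoff: float = 0.0
    seed: int = 0
    sem_method: str = "normal"
    min_valid_null: int = 50


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def robustness(
    expr: ExpressionMatrix,
    iap: ScaledPhenotype,
    pair: tuple[str, str],
    model: str = "HSA",
    n_boot: int = 1000,
    coverage: float = 0.7,
    seed: int = 0,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    S_complete: float | None = None,
    sem_method: str = "normal",
) -> RobustnessResult:
    """Normalized RMSD of the score over partial-coverage resamples.

    Each resample draws ``floor(coverage * n)`` samples without
    replacement, re-stratifies at the subsample's own medians and rescores
    the pair from scratch.  Resamples whose score is missing (sign
    conflict or an undersized quadrant) are dropped; if fewer than half
    survive the pair is flagged non-robust regardless of R.
    """
    v1 = expr.gene_values(pair[0])
    v2 = expr.gene_values(pair[1])
    iap_vals = iap.aligned(expr.samples)
    samples = tuple(expr.samples)
    if S_complete is None:
        strat = _stratify_values(v1, v2, pair, samples, min_group_size)
        full = score_stratification(iap_vals, strat, model, iap.name, sem_method)
        S_complete = full.S
    if S_complete is None or S_complete == 0.0:
        raise ValueError(
            "robustness undefined: the full-cohort score is missing or zero"
        )
    n = len(samples)
    k = int(math.floor(coverage * n))
    rng = np.random.default_rng(seed)
    partial: list[float] = []
    for _ in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        strat_p = _stratify_values(
            v1[idx], v2[idx], pair,
            tuple(samples[i] for i in idx), min_group_size,
        )
        res = score_stratification(
            iap_vals[idx], strat_p, model, iap.name, sem_method
        )
        if res.S is not None:
            partial.append(res.S)
    arr = np.asarray(partial, dtype=float)
    if arr.size:
        rmsd = float(np.sqrt(np.mean((S_complete - arr) ** 2)))
        r = rmsd / abs(S_complete)
    else:
        r = float("inf")
    return RobustnessResult(
        S_complete=float(S_complete),
        partial_scores=tuple(partial),
        R=r,
        n_boot=n_boot,
        coverage=coverage,
        n_valid=arr.size,
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact null for small tie-free groups,
    normal approximation with tie correction otherwise."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size <= EXACT_MAX_GROUP and y.size <= EXACT_MAX_GROUP
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def significance_test(
    iap_values: np.ndarray,
    strat: Stratification,
    config_id: str,
) -> SignificanceResult:
    """Rank-sum comparison of the target quadrant against each other quadrant.

    The interaction's p-value is the maximum of the three two-sided
    p-values, so the target must differ from every other quadrant.
    """
    cfg = CONFIG_BY_ID[config_id]
    target_vals = iap_values[strat.mask(cfg.target)]
    target_vals = target_vals[~np.isnan(target_vals)]
    p_by_group: dict[str, float] = {}
    for q in (cfg.baseline, cfg.single1, cfg.single2):
        other = iap_values[strat.mask(q)]
        other = other[~np.isnan(other)]
        p_by_group[q] = _ranksum_p(target_vals, other)
    p = max(p_by_group.values())
    return SignificanceResult(p_by_group=p_by_group, p=p)


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def _gene_seed(seed: int, gene: str, iap_name: str) -> int:
    """Deterministic per-(gene, IAP) stream below 2**31."""
    h = zlib.crc32(f"{gene}\t{iap_name}".encode())
    return (seed * 1_000_003 + h) % (2**31 - 1)


class NullScoreCache:
    """Per-focal-gene null score distributions, shared across pairs.

    The null for a focal gene is the set of combined-action scores of that
    gene against partner genes drawn uniformly without replacement from
    the supplied matrix (the analysis "genome").  The draw is a
    deterministic function of (seed, gene, IAP), so the same null serves
    every pair containing the gene.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        iap: ScaledPhenotype,
        model: str,
        n_random: int,
        seed: int,
        min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
        sem_method: str = "normal",
    ) -> None:
        self.expr = expr
        self.iap = iap
        self.model = model
        self.n_random = n_random
        self.seed = seed
        self.min_group_size = min_group_size
        self.sem_method = sem_method
        self._iap_vals = iap.aligned(expr.samples)
        self._genes = np.asarray(expr.genes)
        self._vectors: dict[str, np.ndarray] = {}
        self._null: dict[str, np.ndarray] = {}

    def _vec(self, gene: str) -> np.ndarray:
        if gene not in self._vectors:
            self._vectors[gene] = self.expr.gene_values(gene)
        return self._vectors[gene]

    def null_scores(self, gene: str, exclude: tuple[str, str]) -> np.ndarray:
        if gene not in self._null:
            candidates = self._genes[~np.isin(self._genes, list(exclude))]
            n_draw = min(self.n_random, candidates.size)
            rng = np.random.default_rng(
                _gene_seed(self.seed, gene, self.iap.name)
            )
            partners = rng.choice(candidates, size=n_draw, replace=False)
            v_focal = self._vec(gene)
            samples = tuple(self.expr.samples)
            scores: list[float] = []
            for partner in partners:
                strat = _stratify_values(
                    v_focal, self._vec(str(partner)), (gene, str(partner)),
                    samples, self.min_group_size,
                )
                res = score_stratification(
                    self._iap_vals, strat, self.model, self.iap.name,
                    self.sem_method,
                )
                if res.S is not None:
                    scores.append(res.S)
            self._null[gene] = np.asarray(scores, dtype=float)
        return self._null[gene]


def _empirical_p(null: np.ndarray, observed: float) -> float:
    """Add-one one-sided tail probability P(null >= observed)."""
    return (1 + int(np.sum(null >= observed))) / (1 + null.size)


def specificity_test(
    expr: ExpressionMatrix,
    iap: ScaledPhenotype,
    pair: tuple[str, str],
    S_observed: float,
    model: str = "HSA",
    n_random: int = 1000,
    seed: int = 0,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    cache: NullScoreCache | None = None,
    min_valid_null: int = 50,
    sem_method: str = "normal",
) -> SpecificityResult:
    """Empirical tail probability of the observed score under per-gene nulls.

    A low ``p_max`` means the pair's score exceeds what either member
    achieves against random partners, i.e. the interaction is specific to
    the pair rather than to one promiscuous gene.
    """
    if cache is None:
        cache = NullScoreCache(
            expr, iap, model, n_random, seed, min_group_size, sem_method
        )
    null1 = cache.null_scores(pair[0], pair)
    null2 = cache.null_scores(pair[1], pair)
    if null1.size < min_valid_null or null2.size < min_valid_null:
        return SpecificityResult(
            p_g1=None, p_g2=None, p_max=None,
            n_valid_g1=null1.size, n_valid_g2=null2.size, n_random=n_random,
        )
    p1 = _empirical_p(null1, S_observed)
    p2 = _empirical_p(null2, S_observed)
    return SpecificityResult(
        p_g1=p1, p_g2=p2, p_max=max(p1, p2),
        n_valid_g1=null1.size, n_valid_g2=null2.size, n_random=n_random,
    )


# ---------------------------------------------------------------------------
# multiple testing and staged filtering
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr <= 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(q) for q in multipletests(arr, method="fdr_bh")[1]]


def validate_all(
    expr: ExpressionMatrix,
    iap: ScaledPhenotype,
    results: list[CombinedActionResult],
    params: ValidationParams = ValidationParams(),
) -> list[ValidatedInteraction]:
    """Staged robustness -> significance -> specificity screen.

    BH correction for significance runs over the pairs that survived
    robustness; BH for specificity over the pairs that additionally
    survived significance.  The ``stage`` field records how far each pair
    got; ``passed`` is true only after all three screens.
    """
    validated: list[ValidatedInteraction] = [
        ValidatedInteraction(result=r) for r in results
    ]

    # stage 0: a usable score
    def scorable(v: ValidatedInteraction) -> bool:
        r = v.result
        return (
            r.S is not None
            and r.S != 0.0
            and abs(r.S) >= params.score_cutoff
        )

    # stage 1: robustness
    strata: dict[int, Stratification] = {}
    iap_vals = iap.aligned(expr.samples)
    for i, v in enumerate(validated):
        if not scorable(v):
            continue
        rob = robustness(
            expr, iap, v.result.pair, params.model,
            n_boot=params.n_boot, coverage=params.coverage,
            seed=(params.seed + i) % (2**31 - 1),
            min_group_size=params.min_group_size,
            S_complete=v.result.S, sem_method=params.sem_method,
        )
        validated[i] = ValidatedInteraction(
            result=v.result, robustness=rob, stage="robustness"
        )
        if rob.robust:
            strata[i] = stratify_pair(
                expr, v.result.pair, params.min_group_size
            )

    # stage 2: significance (BH over the robust set)
    sig_idx: list[int] = []
    sig_p: list[float] = []
    for i, v in enumerate(validated):
        if i not in strata:
            continue
        sig = significance_test(iap_vals, strata[i], v.result.config)
        validated[i] = ValidatedInteraction(
            result=v.result, robustness=v.robustness,
            significance=sig, stage="significance",
        )
        sig_idx.append(i)
        sig_p.append(sig.p)
    if sig_idx:
        qs = bh_adjust(sig_p)
        for i, q in zip(sig_idx, qs):
            v = validated[i]
            validated[i] = ValidatedInteraction(
                result=v.result, robustness=v.robustness,
                significance=SignificanceResult(
                    p_by_group=v.significance.p_by_group,
                    p=v.significance.p, Q=q,
                ),
                stage="significance",
            )

    # stage 3: specificity (BH over robust + significant set)
    cache = NullScoreCache(
        expr, iap, params.model, params.n_random, params.seed,
        params.min_group_size, params.sem_method,
    )
    spec_idx: list[int] = []
    spec_p: list[float] = []
    spec_res: dict[int, SpecificityResult] = {}
    for i, v in enumerate(validated):
        if v.significance is None or v.significance.Q is None:
            continue
        if v.significance.Q >= params.q_threshold:
            continue
        spec = specificity_test(
            expr, iap, v.result.pair, v.result.S, params.model,
            n_random=params.n_random, seed=params.seed,
            min_group_size=params.min_group_size, cache=cache,
            min_valid_null=params.min_valid_null,
            sem_method=params.sem_method,
        )
        spec_res[i] = spec
        if spec.defined:
            spec_idx.append(i)
            spec_p.append(spec.p_max)
    qs = bh_adjust(spec_p)
    q_by_idx = dict(zip(spec_idx, qs))
    for i, spec in spec_res.items():
        v = validated[i]
        q = q_by_idx.get(i)
        spec2 = SpecificityResult(
            p_g1=spec.p_g1, p_g2=spec.p_g2, p_max=spec.p_max,
            n_valid_g1=spec.n_valid_g1, n_valid_g2=spec.n_valid_g2,
            n_random=spec.n_random, Q=q,
        )
        passed = q is not None and q < params.q_threshold
        validated[i] = ValidatedInteraction(
            result=v.result, robustness=v.robustness,
            significance=v.significance, specificity=spec2,
            passed=passed, stage="passed" if passed else "specificity",
        )
    return validated


def stage_counts(
    validated: list[ValidatedInteraction], q_threshold: float = 0.1
) -> dict[str, int]:
    """Counts surviving each stage, for pipeline logging."""
    scored = sum(1 for v in validated if v.result.S not in (None, 0.0))
    robust = sum(
        1 for v in validated if v.robustness is not None and v.robustness.robust
    )
    significant = sum(
        1
        for v in validated
        if v.significance is not None
        and v.significance.Q is not None
        and v.significance.Q < q_threshold
    )
    specific = sum(1 for v in validated if v.passed)
    return {
        "total": len(validated),
        "scored": scored,
        "robust": robust,
        "significant": significant,
        "specific": specific,
    }
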