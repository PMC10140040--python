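"""Combined-action scoring of gene pairs against an immune phenotype.

For a gene pair the cohort is split into four quadrants (LL, LH, HL, HH)
at each gene's median expression.  Under each of four activating /
deactivating configurations a baseline quadrant (presumed least phenotype)
and a target quadrant (presumed most) are fixed, the median deviation of
the scaled phenotype from baseline is computed per quadrant, noisy
deviations below their standard error are zeroed, and the combined-action
score

    S = sign(M) * (M_target - M_E)   when M_target - M_E > 0, else 0

measures the non-additive excess of the target deviation over the additive
expectation M_E from a reference model (Highest Single Agent: max(M1, M2);
Bliss independence: M1 + M2 - M1*M2).  When the nonzero median deviations
disagree in sign the configuration has no consistent direction and yields
a missing score.  The configuration with the highest score wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneListPair
from .phenotype import ScaledPhenotype

QUADRANTS = ("LL", "LH", "HL", "HH")

#: factor converting the standard error of the mean to the asymptotic
#: standard error of the median under normality: sqrt(pi / 2)
MEDIAN_SEM_FACTOR = float(np.sqrt(np.pi / 2.0))

DEFAULT_MIN_GROUP_SIZE = 10


@dataclass(frozen=True)
class Configuration:
    """One activating/deactivating hypothesis for a gene pair.

    The baseline quadrant has both genes on their inactive side, the
    target quadrant both on their active side, and each single quadrant
    flips exactly one gene to its active side.
    """

    id: str
    baseline: str
    target: str
    single1: str
    single2: str


CONFIGURATIONS: tuple[Configuration, ...] = (
    Configuration("act_act", baseline="LL", target="HH",
                  single1="HL", single2="LH"),
    Configuration("deact_deact", baseline="HH", target="LL",
                  single1="LH", single2="HL"),
    Configuration("act_deact", baseline="LH", target="HL",
                  single1="HH", single2="LL"),
    Configuration("deact_act", baseline="HL", target="LH",
                  single1="LL", single2="HH"),
)

CONFIG_BY_ID = {c.id: c for c in CONFIGURATIONS}

#: mirror of each configuration under swapping (gene1, gene2) -> (gene2, gene1)
MIRROR_CONFIG = {
    "act_act": "act_act",
    "deact_deact": "deact_deact",
    "act_deact": "deact_act",
    "deact_act": "act_deact",
}


@dataclass(frozen=True)
class Stratification:
    """Median-split quadrant labels for one gene pair.

    ``labels`` holds one of ``LL``/``LH``/``HL``/``HH`` per sample with
    both genes observed (first letter: gene1 level, second: gene2); other
    samples carry the empty string.  A value at or below the median is
    "L", which keeps the split deterministic under ties.
    """

    pair: tuple[str, str]
    samples: tuple[str, ...]
    labels: np.ndarray  # dtype '<U2', '' for samples missing either gene
    cut1: float
    cut2: float
    min_group_size: int
    quadrant_sizes: dict[str, int]
    scorable: bool

    def mask(self, quadrant: str) -> np.ndarray:
        return self.labels == quadrant


@dataclass(frozen=True)
class MedianDeviation:
    """Median deviation of the phenotype in one quadrant from baseline."""

    quadrant: str
    M: float
    M_raw: float
    sem_quadrant: float
    sem_baseline: float
    sem_M: float


@dataclass(frozen=True)
class CombinedActionResult:
    """Score of one gene pair against one phenotype."""

    pair: tuple[str, str]
    iap: str
    config: str | None          # winning configuration id, None if unscorable
    S: float | None             # missing when every config sign-conflicts
    sign: int | None            # +1 / -1 direction of change from baseline
    M_target: float | None
    M1: float | None
    M2: float | None
    M_E: float | None
    quadrant_sizes: dict[str, int] = field(default_factory=dict)
    additivity_model: str = "HSA"

    @property
    def missing(self) -> bool:
        return self.S is None


def stratify_pair(
    expr: ExpressionMatrix,
    pair: tuple[str, str],
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> Stratification:
    """Median-split the cohort on both genes of ``pair``.

    Medians are taken over samples with both genes observed; those samples
    are then labeled L (at or below the median) or H per gene.  A quadrant
    below ``min_group_size`` flags the pair unscorable rather than raising.
    """
    g1, g2 = pair
    v1 = expr.gene_values(g1)
    v2 = expr.gene_values(g2)
    return _stratify_values(v1, v2, pair, tuple(expr.samples), min_group_size)


def _stratify_values(
    v1: np.ndarray,
    v2: np.ndarray,
    pair: tuple[str, str],
    samples: tuple[str, ...],
    min_group_size: int,
) -> Stratification:
    both = ~np.isnan(v1) & ~np.isnan(v2)
    labels = np.full(v1.shape, "", dtype="<U2")
    if both.sum() == 0:
        cut1 = cut2 = float("nan")
    else:
        cut1 = float(np.median(v1[both]))
        cut2 = float(np.median(v2[both]))
        hi1 = v1 > cut1
        hi2 = v2 > cut2
        lab = np.where(hi1, "H", "L").astype("<U2")
        lab = np.char.add(lab, np.where(hi2, "H", "L"))
        labels[both] = lab[both]
    sizes = {q: int((labels == q).sum()) for q in QUADRANTS}
    scorable = all(sizes[q] >= min_group_size for q in QUADRANTS)
    return Stratification(
        pair=pair,
        samples=samples,
        labels=labels,
        cut1=cut1,
        cut2=cut2,
        min_group_size=min_group_size,
        quadrant_sizes=sizes,
        scorable=scorable,
    )


def _sem_median(values: np.ndarray, method: str, rng=None) -> float:
    """Standard error of the median of ``values`` (no NaNs).

    ``normal`` uses the asymptotic normal-theory estimator
    sqrt(pi/2) * sd / sqrt(n); ``bootstrap`` resamples the median
    (200 draws) for sensitivity checks.
    """
    n = values.size
    if n < 2:
        return float("inf")
    if method == "bootstrap":
        rng = np.random.default_rng(0) if rng is None else rng
        idx = rng.integers(0, n, size=(200, n))
        return float(np.std(np.median(values[idx], axis=1), ddof=1))
    return float(MEDIAN_SEM_FACTOR * np.std(values, ddof=1) / math.sqrt(n))


def median_deviation(
    iap_values: np.ndarray,
    strat: Stratification,
    quadrant: str,
    baseline: str,
    sem_method: str = "normal",
) -> MedianDeviation:
    """Thresholded median deviation of one quadrant from the baseline.

    ``iap_values`` must be aligned to ``strat.samples``.  The raw deviation
    is the difference of quadrant and baseline medians; it is zeroed when
    its magnitude falls below the combined (quadrature) standard error of
    the two medians.
    """
    q_vals = iap_values[strat.mask(quadrant)]
    b_vals = iap_values[strat.mask(baseline)]
    q_vals = q_vals[~np.isnan(q_vals)]
    b_vals = b_vals[~np.isnan(b_vals)]
    if q_vals.size == 0 or b_vals.size == 0:
        raise ValueError(f"empty quadrant {quadrant!r} or baseline {baseline!r}")
    m_raw = float(np.median(q_vals) - np.median(b_vals))
    sem_q = _sem_median(q_vals, sem_method)
    sem_b = _sem_median(b_vals, sem_method)
    sem_m = math.hypot(sem_q, sem_b)
    m = m_raw if abs(m_raw) >= sem_m else 0.0
    return MedianDeviation(
        quadrant=quadrant, M=m, M_raw=m_raw,
        sem_quadrant=sem_q, sem_baseline=sem_b, sem_M=sem_m,
    )


def expected_additive(m1: float, m2: float, model: str) -> float:
    """Additive expectation for the target deviation under a reference model."""
    if model.upper() == "HSA":
        return max(m1, m2)
    if model.lower() == "bliss":
        return m1 + m2 - m1 * m2
    raise ValueError(f"unknown additivity model {model!r}")


def _shared_sign(ms: tuple[float, ...]) -> int | None:
    """Common sign of the nonzero deviations; zeros are neutral.

    Returns +1 when all zero (score will be 0 anyway), None on conflict.
    """
    signs = {1 if m > 0 else -1 for m in ms if m != 0.0}
    if len(signs) > 1:
        return None
    return signs.pop() if signs else 1


def config_score(
    iap_values: np.ndarray,
    strat: Stratification,
    config: Configuration,
    model: str,
    iap_name: str = "",
    sem_method: str = "normal",
) -> CombinedActionResult:
    """Score a single configuration; missing on a sign conflict."""
    devs = {
        q: median_deviation(iap_values, strat, q, config.baseline, sem_method)
        for q in (config.target, config.single1, config.single2)
    }
    m_t = devs[config.target].M
    m_1 = devs[config.single1].M
    m_2 = devs[config.single2].M
    sign = _shared_sign((m_t, m_1, m_2))
    if sign is None:
        return CombinedActionResult(
            pair=strat.pair, iap=iap_name, config=config.id, S=None,
            sign=None, M_target=m_t, M1=m_1, M2=m_2, M_E=None,
            quadrant_sizes=strat.quadrant_sizes, additivity_model=model,
        )
    m_e = expected_additive(m_1, m_2, model)
    excess = m_t - m_e
    s = sign * excess if excess > 0 else 0.0
    return CombinedActionResult(
        pair=strat.pair, iap=iap_name, config=config.id, S=s, sign=sign,
        M_target=m_t, M1=m_1, M2=m_2, M_E=m_e,
        quadrant_sizes=strat.quadrant_sizes, additivity_model=model,
    )


def score_stratification(
    iap_values: np.ndarray,
    strat: Stratification,
    model: str = "HSA",
    iap_name: str = "",
    sem_method: str = "normal",
) -> CombinedActionResult:
    """Evaluate all four configurations on an existing stratification.

    Returns the configuration with maximal (signed) score among those
    yielding a non-missing score; ties resolve to the first configuration
    in the fixed order act_act, deact_deact, act_deact, deact_act.
    """
    if not strat.scorable:
        return CombinedActionResult(
            pair=strat.pair, iap=iap_name, config=None, S=None, sign=None,
            M_target=None, M1=None, M2=None, M_E=None,
            quadrant_sizes=strat.quadrant_sizes, additivity_model=model,
        )
    best: CombinedActionResult | None = None
    first_missing: CombinedActionResult | None = None
    for cfg in CONFIGURATIONS:
        res = config_score(iap_values, strat, cfg, model, iap_name, sem_method)
        if res.S is None:
            if first_missing is None:
                first_missing = res
            continue
        if best is None or res.S > best.S:
            best = res
    if best is not None:
        return best
    assert first_missing is not None
    return first_missing


def combined_action_score(
    expr: ExpressionMatrix,
    iap: ScaledPhenotype,
    pair: tuple[str, str],
    model: str = "HSA",
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    sem_method: str = "normal",
) -> CombinedActionResult:
    """Full combined-action score for one pair: stratify then score."""
    strat = stratify_pair(expr, pair, min_group_size)
    iap_values = iap.aligned(list(strat.samples))
    return score_stratification(
        iap_values, strat, model, iap.name, sem_method
    )


def score_all_pairs(
    expr: ExpressionMatrix,
    iap: ScaledPhenotype,
    lists: GeneListPair,
    model: str = "HSA",
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    sem_method: str = "normal",
) -> list[CombinedActionResult]:
    """Score every (tap, icp) pair, skipping self-pairs, in lexicographic order."""
    results = []
    for tap in sorted(lists.tap_genes):
        for icp in sorted(lists.icp_genes):
            if tap == icp:
                continue
            results.append(
                combined_action_score(
                    expr, iap, (tap, icp), model, min_group_size, sem_method
                )
            )
    return results
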