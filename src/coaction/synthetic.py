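"""Synthetic cohorts with planted gene-pair effects on a phenotype.

The generator emulates the minimal statistical structure the scoring
method assumes: per-gene log-normal expression, independent across genes
and samples, and one phenotype built as a sum of single-gene effects,
quadrant-specific interaction effects, and Gaussian noise.  A planted pair
contributes ``effect_single1`` when gene1 sits on its active side of its
own median, ``effect_single2`` likewise for gene2, and
``effect_interaction`` only for samples in the pair's target quadrant —
exactly the non-additive excess the combined-action score is built to
detect.  "Active side" follows the planted configuration (high for an
activating gene, low for deactivating) and is defined against each gene's
median within the simulated cohort, so the planted quadrant coincides
with what median stratification recovers.

Everything is a deterministic function of the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PhenotypeTable
from .scoring import CONFIG_BY_ID, QUADRANTS
from .validation import ValidatedInteraction


@dataclass(frozen=True)
class PlantedPair:
    gene1: str
    gene2: str
    config: str                  # act_act | deact_deact | act_deact | deact_act
    effect_single1: float = 1.0
    effect_single2: float = 1.0
    effect_interaction: float = 3.0

    def __post_init__(self) -> None:
        if self.config not in CONFIG_BY_ID:
            raise ValueError(f"unknown configuration {self.config!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a mid-sized cancer cohort: 400 patients, unit-variance
    log-expression, unit phenotype noise, planted interaction effects three
    times the noise scale.
    """

    n_samples: int = 400
    n_null_genes: int = 300
    planted: tuple[PlantedPair, ...] = ()
    noise_sd: float = 1.0
    expression_log_sd: float = 1.0
    seed: int = 0
    iap_name: str = "planted_iap"

    def __post_init__(self) -> None:
        if self.n_samples < 40:
            raise ValueError("need at least 40 samples for quadrant scoring")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        planted_names = [g for p in self.planted for g in (p.gene1, p.gene2)]
        null_names = {f"NULL{i:04d}" for i in range(self.n_null_genes)}
        clash = set(planted_names) & null_names
        if clash:
            raise ValueError(f"planted gene names collide with null genes: {clash}")


@dataclass(frozen=True)
class SyntheticCohort:
    expr: ExpressionMatrix
    phenotypes: PhenotypeTable
    config: SimulationConfig
    #: per planted pair: realized mean raw phenotype per quadrant
    quadrant_means: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )

    @property
    def iap_name(self) -> str:
        return self.config.iap_name


def _active_mask(values: np.ndarray, activating: bool) -> np.ndarray:
    """Samples on the gene's active side of its own median (ties are low)."""
    cut = np.median(values)
    return values > cut if activating else values <= cut


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate expression and the planted phenotype for one cohort."""
    rng = np.random.default_rng(config.seed)
    planted_genes: list[str] = []
    for p in config.planted:
        for g in (p.gene1, p.gene2):
            if g not in planted_genes:
                planted_genes.append(g)
    genes = planted_genes + [f"NULL{i:04d}" for i in range(config.n_null_genes)]
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    # per-gene baseline log-level, then i.i.d. log-normal expression
    base = rng.uniform(1.0, 8.0, size=len(genes))
    log_expr = base[:, None] + rng.normal(
        0.0, config.expression_log_sd, size=(len(genes), config.n_samples)
    )
    expr_values = np.exp(log_expr)
    expr = ExpressionMatrix(
        pd.DataFrame(expr_values, index=genes, columns=samples)
    )

    raw = np.zeros(config.n_samples)
    quadrant_means: dict[tuple[str, str], dict[str, float]] = {}
    for p in config.planted:
        cfg = CONFIG_BY_ID[p.config]
        v1 = expr_values[genes.index(p.gene1)]
        v2 = expr_values[genes.index(p.gene2)]
        act1 = _active_mask(v1, cfg.target[0] == "H")
        act2 = _active_mask(v2, cfg.target[1] == "H")
        raw += p.effect_single1 * act1
        raw += p.effect_single2 * act2
        raw += p.effect_interaction * (act1 & act2)
    raw += rng.normal(0.0, config.noise_sd, size=config.n_samples)

    # realized quadrant means of the raw phenotype, recorded as truth
    for p in config.planted:
        v1 = expr_values[genes.index(p.gene1)]
        v2 = expr_values[genes.index(p.gene2)]
        hi1 = v1 > np.median(v1)
        hi2 = v2 > np.median(v2)
        means: dict[str, float] = {}
        for q in QUADRANTS:
            mask = (hi1 == (q[0] == "H")) & (hi2 == (q[1] == "H"))
            means[q] = float(raw[mask].mean()) if mask.any() else float("nan")
        quadrant_means[(p.gene1, p.gene2)] = means

    phen = PhenotypeTable(
        pd.DataFrame({config.iap_name: raw}, index=samples)
    )
    return SyntheticCohort(
        expr=expr, phenotypes=phen, config=config,
        quadrant_means=quadrant_means,
    )


@dataclass(frozen=True)
class PlantedRecovery:
    pair: tuple[str, str]
    rank: int | None          # 1 = highest score among all scored pairs
    passed: bool
    config_match: bool        # winning config equals planted (or its mirror)


@dataclass(frozen=True)
class RecoveryReport:
    planted: tuple[PlantedRecovery, ...]
    n_null_pairs: int
    n_null_passed: int

    @property
    def null_pass_fraction(self) -> float:
        return self.n_null_passed / self.n_null_pairs if self.n_null_pairs else 0.0


def evaluate_recovery(
    cohort: SyntheticCohort, validated: list[ValidatedInteraction]
) -> RecoveryReport:
    """Compare validated interactions to the cohort's planted truth.

    A planted pair matches on its configuration directly or through the
    mirror configuration when the pair was scored in swapped order.
    """
    from .scoring import MIRROR_CONFIG

    planted_keys = {
        (p.gene1, p.gene2): p for p in cohort.config.planted
    }
    scored = [
        v for v in validated if v.result.S is not None
    ]
    order = sorted(scored, key=lambda v: v.result.S, reverse=True)
    rank_of = {v.result.pair: i + 1 for i, v in enumerate(order)}

    recoveries: list[PlantedRecovery] = []
    n_null = n_null_passed = 0
    for v in validated:
        pair = v.result.pair
        swapped = (pair[1], pair[0])
        p = planted_keys.get(pair) or planted_keys.get(swapped)
        if p is None:
            n_null += 1
            n_null_passed += int(v.passed)
            continue
        expected = p.config if pair in planted_keys else MIRROR_CONFIG[p.config]
        recoveries.append(
            PlantedRecovery(
                pair=pair,
                rank=rank_of.get(pair),
                passed=v.passed,
                config_match=v.result.config == expected,
            )
        )
    return RecoveryReport(
        planted=tuple(recoveries),
        n_null_pairs=n_null,
        n_null_passed=n_null_passed,
    )
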