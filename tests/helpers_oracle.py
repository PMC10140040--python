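"""Independent brute-force oracles for the statistical core.

Deliberately written in plain Python (lists, ``statistics.median``, explicit
loops) so they share no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations
from statistics import median


def oracle_median(values):
    return median(values)


def oracle_sd(values):
    n = len(values)
    mu = sum(values) / n
    return math.sqrt(sum((v - mu) ** 2 for v in values) / (n - 1))


def oracle_sem_median(values):
    return math.sqrt(math.pi / 2) * oracle_sd(values) / math.sqrt(len(values))


CONFIGS = {
    "act_act": {"baseline": "LL", "target": "HH", "single1": "HL", "single2": "LH"},
    "deact_deact": {"baseline": "HH", "target": "LL", "single1": "LH", "single2": "HL"},
    "act_deact": {"baseline": "LH", "target": "HL", "single1": "HH", "single2": "LL"},
    "deact_act": {"baseline": "HL", "target": "LH", "single1": "LL", "single2": "HH"},
}


def oracle_stratify(v1, v2):
    """Quadrant label per sample; value at or below the median is low."""
    m1 = median(v1)
    m2 = median(v2)
    labels = []
    for a, b in zip(v1, v2):
        labels.append(("H" if a > m1 else "L") + ("H" if b > m2 else "L"))
    return labels


def oracle_m(iap, labels, quadrant, baseline):
    """Thresholded median deviation of one quadrant from baseline."""
    q = [x for x, l in zip(iap, labels) if l == quadrant]
    b = [x for x, l in zip(iap, labels) if l == baseline]
    m_raw = median(q) - median(b)
    sem = math.sqrt(oracle_sem_median(q) ** 2 + oracle_sem_median(b) ** 2)
    return m_raw if abs(m_raw) >= sem else 0.0


def oracle_config_score(iap, labels, config_id, model):
    """Score of one configuration; None on a sign conflict."""
    cfg = CONFIGS[config_id]
    m_t = oracle_m(iap, labels, cfg["target"], cfg["baseline"])
    m_1 = oracle_m(iap, labels, cfg["single1"], cfg["baseline"])
    m_2 = oracle_m(iap, labels, cfg["single2"], cfg["baseline"])
    signs = set()
    for m in (m_t, m_1, m_2):
        if m > 0:
            signs.add(1)
        elif m < 0:
            signs.add(-1)
    if len(signs) > 1:
        return None
    sign = signs.pop() if signs else 1
    if model.upper() == "HSA":
        m_e = max(m_1, m_2)
    else:
        m_e = m_1 + m_2 - m_1 * m_2
    excess = m_t - m_e
    return sign * excess if excess > 0 else 0.0


def oracle_pair_score(v1, v2, iap, model):
    """Winning (config, S) over the four configurations; S None if all conflict."""
    labels = oracle_stratify(v1, v2)
    best = None
    for cid in ("act_act", "deact_deact", "act_deact", "deact_act"):
        s = oracle_config_score(iap, labels, cid, model)
        if s is None:
            continue
        if best is None or s > best[1]:
            best = (cid, s)
    return best  # None when every configuration sign-conflicts


def oracle_ranksum_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties)."""
    pooled = sorted(x + y)
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mean_u = n1 * len(y) / 2
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    all_ranks = range(1, len(pooled) + 1)
    for combo in combinations(all_ranks, n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-9:
            count += 1
    return count / total


def oracle_bh(pvalues):
    """Benjamini-Hochberg step-up adjusted values by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = q
        prev = q
    return adjusted
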