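"""Secondary pulse/chase classification: local-control normalization,
significance testing, quadrant assignment and the sign-test summary.

In the secondary assay each gene's three test wells sit next to six
local negative and three local positive control wells, so fold-changes
are computed against the local negatives and carry a direction (unlike
the unsigned primary KS Z-scores).  Genes are placed on a quadrant
plot of pulse fold-change vs chase fold-change: quadrant 1 = both up,
3 = both down, 2 = chase down without pulse down (late-acting genes),
4 = the remaining mixed patterns.  A gene enters a quadrant only if at
least one axis is significant at p < alpha (default 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SecondaryPlate

__all__ = [
    "normalize_to_local_controls",
    "test_gene",
    "assign_quadrant",
    "binomial_sign_test",
    "analyze_secondary_plate",
    "crosstab_pathways",
    "SecondaryRecord",
]


@dataclass
class SecondaryRecord:
    gene: str
    pulse_ratio: float
    chase_ratio: float
    p_pulse: float
    p_chase: float
    quadrant: object  # 1|2|3|4|"null"
    significance_class: str  # pulse-only | chase-only | both | none


def normalize_to_local_controls(
    test_values: Sequence[float], negative_values: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Fold ratio of test replicate means over the local negative mean.

    Returns ``(ratio, per_replicate_ratios)``.
    """
    test = np.asarray(test_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if neg.size < 2:
        raise ValueError("need >= 2 local negatives")
    neg_mean = neg.mean()
    if neg_mean == 0:
        raise ValueError("local negative mean is zero")
    per_rep = test / neg_mean
    return float(test.mean() / neg_mean), per_rep


def test_gene(
    test_values: Sequence[float],
    negative_values: Sequence[float],
    *,
    equal_var: bool = False,
) -> float:
    """Two-sided two-sample t-test of test vs local negative well means.

    Welch (unequal-variance) by default.  Identical degenerate groups
    give p = 1.
    """
    test = np.asarray(test_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if test.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 values per group")
    if test.std() == 0 and neg.std() == 0:
        return 1.0 if test.mean() == neg.mean() else 0.0
    p = float(stats.ttest_ind(test, neg, equal_var=equal_var).pvalue)
    return min(max(p, np.nextafter(0, 1)), 1.0)


def assign_quadrant(
    pulse_ratio: float,
    chase_ratio: float,
    p_pulse: float,
    p_chase: float,
    alpha: float = 0.10,
) -> tuple[object, str]:
    """Quadrant and significance class of one gene.

    Axes are dichotomized at ratio 1, but an axis only counts as
    changed when it is significant at ``p < alpha`` -- otherwise its
    measured ratio is treated as "unchanged" (the sign of pure noise
    carries no direction).  Quadrants: 1 = pulse up & chase up; 3 =
    pulse down & chase down; 2 = chase down with pulse not down; 4 =
    any other mixed pattern.  A gene is ``"null"`` when neither axis is
    significant.
    """
    if pulse_ratio <= 0 or chase_ratio <= 0:
        raise ValueError("ratios must be positive")
    sig_p, sig_c = p_pulse < alpha, p_chase < alpha
    if sig_p and sig_c:
        klass = "both"
    elif sig_p:
        klass = "pulse-only"
    elif sig_c:
        klass = "chase-only"
    else:
        return "null", "none"
    up_p, down_p = sig_p and pulse_ratio > 1, sig_p and pulse_ratio < 1
    up_c, down_c = sig_c and chase_ratio > 1, sig_c and chase_ratio < 1
    if up_p and up_c:
        return 1, klass
    if down_p and down_c:
        return 3, klass
    if down_c and not down_p:
        return 2, klass
    return 4, klass


def binomial_sign_test(successes: int, trials: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= successes)."""
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    return float(stats.binom(trials, p0).sf(successes - 1))


def analyze_secondary_plate(
    plate: SecondaryPlate, alpha: float = 0.10, *, equal_var: bool = False
) -> pd.DataFrame:
    """Per-gene normalized ratios, p-values and quadrants for a plate."""
    rows = []
    for group, sub in plate.wells.groupby("group"):
        tests = sub[sub["role"] == "test"]
        negs = sub[sub["role"] == "negative"]
        if tests.empty or len(negs) < 2:
            continue
        gene = tests["gene"].iloc[0]
        p_ratio, p_reps = normalize_to_local_controls(
            tests["pulse"].to_numpy(), negs["pulse"].to_numpy())
        c_ratio, c_reps = normalize_to_local_controls(
            tests["chase"].to_numpy(), negs["chase"].to_numpy())
        p_pulse = test_gene(tests["pulse"].to_numpy(), negs["pulse"].to_numpy(),
                            equal_var=equal_var)
        p_chase = test_gene(tests["chase"].to_numpy(), negs["chase"].to_numpy(),
                            equal_var=equal_var)
        quad, klass = assign_quadrant(p_ratio, c_ratio, p_pulse, p_chase, alpha)
        rows.append((gene, p_ratio, c_ratio, p_pulse, p_chase, quad, klass))
    return pd.DataFrame(
        rows,
        columns=["gene", "pulse_ratio", "chase_ratio", "p_pulse", "p_chase",
                 "quadrant", "significance_class"],
    )


def crosstab_pathways(
    cg_direction: Mapping[str, str], cd_direction: Mapping[str, str]
) -> dict[str, set[str]]:
    """Intersect per-gene directions from two assays.

    Directions are ``"up"``, ``"down"`` or ``"null"``.  Returns sets
    ``both_down``, ``both_up``, ``opposing`` and ``single_pathway``
    (genes with a direction in exactly one assay).
    """
    out = {"both_down": set(), "both_up": set(), "opposing": set(), "single_pathway": set()}
    genes = set(cg_direction) | set(cd_direction)
    for g in genes:
        a = cg_direction.get(g, "null")
        b = cd_direction.get(g, "null")
        if a == "null" and b == "null":
            continue
        if a == "null" or b == "null":
            out["single_pathway"].add(g)
        elif a == b == "down":
            out["both_down"].add(g)
        elif a == b == "up":
            out["both_up"].add(g)
        else:
            out["opposing"].add(g)
    return out
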