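"""Distribution-shape Z-scores from two-sample KS statistics.

The screen's summary statistic compares each test well's single-cell
feature distribution to pooled in-slide negative controls via the
two-sample Kolmogorov-Smirnov statistic D (the sup-deviation between
empirical CDFs).  Because raw D scales like 1/sqrt(n), we work with the
size-adjusted statistic ``T = D * sqrt(n*m/(n+m))`` whose null
distribution is nearly free of the per-well cell count, and standardize
it against a leave-one-out null computed from a *reference* subset of
the slide's negative wells; the remaining negatives are held out to
measure the false-positive rate of the resulting Z-scores.

With ``shape_mode`` on (the default) every sample is affine-normalized
(mean 0, SD 1) before comparison, so pure location/scale changes --
including multiplicative positional artifacts -- do not register; only
changes of distribution *shape* do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import FEATURES

__all__ = [
    "affine_normalize",
    "ks_statistic",
    "scaled_ks_statistic",
    "split_negatives",
    "NullCalibration",
    "calibrate_null",
    "zscore_well",
    "compute_zscore_matrix",
    "evaluate_fp_tp",
]

MIN_CELLS_DEFAULT = 50


class DegenerateSampleError(ValueError):
    """Raised when a sample cannot be normalized (zero spread)."""


def affine_normalize(values: np.ndarray) -> np.ndarray:
    """Center and scale to sample mean 0, SD 1 (population-SD convention).

    Raises :class:`DegenerateSampleError` for constant samples.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateSampleError("need >= 2 values to normalize")
    sd = values.std()
    if sd == 0:
        raise DegenerateSampleError("degenerate sample: zero standard deviation")
    return (values - values.mean()) / sd


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic: sup over x of |F_a(x) - F_b(x)|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def _ks_against_sorted(a: np.ndarray, b_sorted: np.ndarray) -> float:
    """KS statistic where ``b_sorted`` is pre-sorted (hot inner loop)."""
    a = np.sort(a)
    pooled = np.concatenate([a, b_sorted])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b_sorted, pooled, side="right") / b_sorted.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def scaled_ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Size-adjusted statistic ``D * sqrt(n*m/(n+m))``."""
    n, m = len(a), len(b)
    return ks_statistic(a, b) * math.sqrt(n * m / (n + m))


def split_negatives(
    negative_wells: Sequence, fraction_reference: float = 0.5, seed: int = 0
) -> tuple[list, list]:
    """Split a slide's negative wells into reference and evaluation sets.

    The reference set calibrates the null; the evaluation set measures
    the false-positive rate.  Deterministic per seed; disjoint and
    exhaustive.
    """
    wells = list(negative_wells)
    if len(wells) < 4:
        raise ValueError(f"need >= 4 negative wells, got {len(wells)}")
    if not 0.0 < fraction_reference <= 1.0:
        raise ValueError("fraction_reference must be in (0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(wells))
    n_ref = int(round(fraction_reference * len(wells)))
    n_ref = max(2, min(n_ref, len(wells)))
    ref = [wells[i] for i in sorted(order[:n_ref])]
    ev = [wells[i] for i in sorted(order[n_ref:])]
    return ref, ev


@dataclass
class NullCalibration:
    """Null moments of the (scaled) KS statistic among reference negatives."""

    feature: str
    slide: str
    mu_D: float          # raw-D null mean (decreases with cell count)
    sigma_D: float
    mu_T: float          # size-adjusted statistic null mean (used for Z)
    sigma_T: float
    n_null: int
    reference_wells: list = field(default_factory=list)
    null_ts: list = field(default_factory=list)  # raw LOO scaled statistics

    def __post_init__(self) -> None:
        if self.sigma_T <= 0 or self.sigma_D <= 0:
            raise DegenerateSampleError(
                "null spread is zero: reference negatives are identical"
            )


def _prep(values: np.ndarray, shape_mode: bool) -> np.ndarray:
    return affine_normalize(values) if shape_mode else np.asarray(values, dtype=float)


def calibrate_null(
    reference_samples: Sequence[np.ndarray],
    *,
    feature: str = "",
    slide: str = "",
    shape_mode: bool = True,
    reference_wells: Sequence | None = None,
) -> NullCalibration:
    """Leave-one-out null calibration on one slide x feature.

    Each reference negative is compared (KS) against the pool of the
    remaining reference negatives; the mean and SD of those null
    statistics define the calibration.
    """
    samples = [np.asarray(s, dtype=float) for s in reference_samples]
    if len(samples) < 5:
        raise ValueError(f"need >= 5 reference negatives, got {len(samples)}")
    prepped = [_prep(s, shape_mode) for s in samples]
    ds, ts = [], []
    for i, s in enumerate(prepped):
        pool = np.sort(np.concatenate([p for j, p in enumerate(prepped) if j != i]))
        d = _ks_against_sorted(s, pool)
        ds.append(d)
        ts.append(d * math.sqrt(s.size * pool.size / (s.size + pool.size)))
    ds_a, ts_a = np.asarray(ds), np.asarray(ts)
    return NullCalibration(
        feature=feature,
        slide=slide,
        mu_D=float(ds_a.mean()),
        sigma_D=float(ds_a.std(ddof=1)),
        mu_T=float(ts_a.mean()),
        sigma_T=float(ts_a.std(ddof=1)),
        n_null=len(samples),
        reference_wells=list(reference_wells or []),
        null_ts=[float(t) for t in ts],
    )


def zscore_well(
    test_values: np.ndarray,
    calibration: NullCalibration,
    reference_pool: np.ndarray,
    *,
    shape_mode: bool = True,
    min_cells: int = MIN_CELLS_DEFAULT,
    pool_prepped: bool = False,
) -> float:
    """Z-score of one test well against the calibrated slide null.

    Returns NaN for wells below ``min_cells`` (missing, not an error).
    ``reference_pool`` is either a list of per-well reference samples
    (each normalized individually under ``shape_mode``) or, with
    ``pool_prepped=True``, an already-normalized sorted concatenation.
    """
    test_values = np.asarray(test_values, dtype=float)
    if test_values.size < min_cells:
        return float("nan")
    t = _prep(test_values, shape_mode)
    if pool_prepped:
        pool = np.asarray(reference_pool, dtype=float)
    else:
        parts = [_prep(np.asarray(p, dtype=float), shape_mode) for p in reference_pool]
        pool = np.sort(np.concatenate(parts))
    d = _ks_against_sorted(t, pool)
    t_stat = d * math.sqrt(t.size * pool.size / (t.size + pool.size))
    return (t_stat - calibration.mu_T) / calibration.sigma_T


# ---------------------------------------------------------------------------
# screen-level driver


def compute_zscore_matrix(
    wells: Iterable,
    *,
    features: Sequence[str] = FEATURES,
    fraction_reference: float = 0.5,
    shape_mode: bool = True,
    min_cells: int = MIN_CELLS_DEFAULT,
    pool_calibration: bool = True,
    seed: int = 0,
) -> dict:
    """Z-scores for every well of a screen, organized per gene.

    ``wells`` are :class:`~endoscreen.synthetic.WellSample` objects (or
    anything with the same attributes).  Negative wells are split per
    slide into reference/evaluation sets (same seed for every slide of
    a replicate triplet so splits are reproducible).

    Every comparison is slide-local (test well vs the pooled reference
    negatives of its own slide).  With ``pool_calibration`` (default)
    the null *moments* of the size-adjusted statistic are estimated
    from the leave-one-out comparisons of all slides per feature:
    under ``shape_mode`` the null statistic carries no slide-specific
    scale, and pooling stabilizes the SD estimate that a single
    slide's handful of reference wells pins down poorly.  Set
    ``pool_calibration=False`` for strictly slide-local moments.

    Returns a dict with:

    ``z``
        DataFrame indexed by (gene, feature) with columns rep1..repK of
        test-well Z-scores (NaN = unscored well).
    ``negative_z`` / ``positive_z``
        long DataFrames (slide, feature, well_id, z) for
        evaluation-negative and positive-control wells.
    ``calibrations``
        {(slide, feature): NullCalibration} (slide-local moments).
    """
    by_slide: dict[str, list] = {}
    for w in wells:
        by_slide.setdefault(w.slide, []).append(w)

    z_records: dict[tuple[str, str], dict[int, float]] = {}
    neg_rows, pos_rows = [], []
    calibrations: dict[tuple[str, str], NullCalibration] = {}
    null_ts: dict[str, list[float]] = {f: [] for f in features}
    pools: dict[tuple[str, str], np.ndarray] = {}
    pending: list[tuple[str, str, object]] = []  # (slide, feature, well)

    for slide, slide_wells in sorted(by_slide.items()):
        negs = [w for w in slide_wells if w.role == "negative"]
        ref, ev = split_negatives(negs, fraction_reference, seed=seed)
        others = [w for w in slide_wells if w.role != "negative"]
        for f in features:
            ref_samples = [w.cells[f].to_numpy(dtype=float) for w in ref]
            ref_samples = [s for s in ref_samples if s.size >= min_cells]
            if len(ref_samples) < 5:
                continue
            cal = calibrate_null(
                ref_samples, feature=f, slide=slide, shape_mode=shape_mode,
                reference_wells=[w.well_id for w in ref],
            )
            calibrations[(slide, f)] = cal
            null_ts[f].extend(cal.null_ts)
            prepped = [_prep(s, shape_mode) for s in ref_samples]
            pools[(slide, f)] = np.sort(np.concatenate(prepped))
            pending.extend((slide, f, w) for w in ev + others)

    # robust pooled moments: median / scaled MAD resist the occasional
    # aberrant reference well that would otherwise inflate sigma for a
    # whole feature
    pooled_moments: dict[str, tuple[float, float]] = {}
    for f in features:
        ts = np.asarray(null_ts[f])
        if ts.size >= 5:
            med = float(np.median(ts))
            mad = float(np.median(np.abs(ts - med))) * 1.4826
            if mad > 0:
                pooled_moments[f] = (med, mad)

    for slide, f, w in pending:
        cal = calibrations[(slide, f)]
        if pool_calibration and f in pooled_moments:
            mu, sigma = pooled_moments[f]
        else:
            mu, sigma = cal.mu_T, cal.sigma_T
        pool = pools[(slide, f)]
        vals = w.cells[f].to_numpy(dtype=float)
        if vals.size < min_cells:
            z = float("nan")
        else:
            t = _prep(vals, shape_mode)
            d = _ks_against_sorted(t, pool)
            t_stat = d * math.sqrt(t.size * pool.size / (t.size + pool.size))
            z = (t_stat - mu) / sigma
        if w.role == "negative":
            neg_rows.append((slide, f, w.well_id, z))
        elif w.role == "positive":
            pos_rows.append((slide, f, w.well_id, z))
        else:
            z_records.setdefault((w.gene, f), {})[w.replicate] = z

    reps = sorted({r for d in z_records.values() for r in d})
    index = pd.MultiIndex.from_tuples(sorted(z_records), names=["gene", "feature"])
    zmat = pd.DataFrame(
        {f"rep{r}": [z_records[k].get(r, float("nan")) for k in index] for r in reps},
        index=index,
    )
    return {
        "z": zmat,
        "negative_z": pd.DataFrame(neg_rows, columns=["slide", "feature", "well_id", "z"]),
        "positive_z": pd.DataFrame(pos_rows, columns=["slide", "feature", "well_id", "z"]),
        "calibrations": calibrations,
    }


def evaluate_fp_tp(
    negative_z: Sequence[float],
    positive_z: Sequence[float] | None,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """FP/TP curves over a threshold grid.

    ``FP(t)`` is the fraction of evaluation-negative Z-scores >= t (the
    assay's single false-positive rate); ``TP(t)`` the fraction of
    positive-control Z-scores >= t.  ``FP3(t) = 3 f^2 (1-f) + f^3`` is
    the triplicate 2-of-3-rule false-positive rate.
    """
    neg = np.asarray([z for z in negative_z if not math.isnan(z)], dtype=float)
    if neg.size < 10:
        raise ValueError("need >= 10 evaluation-negative Z-scores")
    pos = None
    if positive_z is not None:
        pos = np.asarray([z for z in positive_z if not math.isnan(z)], dtype=float)
        if pos.size == 0:
            pos = None
    rows = []
    for t in thresholds:
        f = float(np.mean(neg >= t))
        fp3 = 3 * f * f * (1 - f) + f ** 3
        tp = float(np.mean(pos >= t)) if pos is not None else float("nan")
        rows.append((t, f, fp3, tp))
    return pd.DataFrame(rows, columns=["threshold", "fp", "fp3", "tp"])
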