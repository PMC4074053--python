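"""Hit calling with the 2-of-3 replicate rule and permutation controls."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "call_hits",
    "HitMatrix",
    "permutation_hit_curve",
    "binarize",
]


@dataclass
class HitMatrix:
    """Per-gene, per-feature boolean hit calls.

    ``hits`` is a genes x features boolean DataFrame.  ``evaluable``
    flags genes with at least two scored replicates for at least one
    feature; unevaluable genes carry all-False rows.
    """

    hits: pd.DataFrame
    threshold: float
    min_reps: int
    evaluable: pd.Series


def _z_cube(z: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    """Reshape a (gene, feature)-indexed replicate frame to a 3-D array."""
    genes = sorted(z.index.get_level_values("gene").unique())
    features = list(z.index.get_level_values("feature").unique())
    # preserve catalog order of features as first-seen order
    seen = dict.fromkeys(z.index.get_level_values("feature"))
    features = list(seen)
    reps = list(z.columns)
    full = z.reindex(pd.MultiIndex.from_product([genes, features], names=["gene", "feature"]))
    cube = full.to_numpy(dtype=float).reshape(len(genes), len(features), len(reps))
    return cube, genes, features, reps


def call_hits(
    z: pd.DataFrame,
    threshold: float = 3.0,
    min_reps: int = 2,
    *,
    strict: bool = False,
) -> HitMatrix:
    """Threshold a replicate Z-score frame into a hit matrix.

    A (gene, feature) bit is set when at least ``min_reps`` replicate
    Z-scores reach ``threshold`` (inclusive ``>=`` by default; pass
    ``strict=True`` for ``>``).  Missing replicates count as failures;
    genes with fewer than two scored replicates everywhere are flagged
    unevaluable.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_reps not in (1, 2, 3):
        raise ValueError("min_reps must be 1, 2 or 3")
    cube, genes, features, _ = _z_cube(z)
    above = (cube > threshold) if strict else (cube >= threshold)
    above &= ~np.isnan(cube)
    hits = above.sum(axis=2) >= min_reps
    scored = (~np.isnan(cube)).sum(axis=2)
    evaluable = (scored >= 2).any(axis=1)
    hits[~evaluable, :] = False
    return HitMatrix(
        hits=pd.DataFrame(hits, index=pd.Index(genes, name="gene"), columns=features),
        threshold=threshold,
        min_reps=min_reps,
        evaluable=pd.Series(evaluable, index=pd.Index(genes, name="gene")),
    )


def permutation_hit_curve(
    z: pd.DataFrame,
    thresholds,
    n_perm: int = 20,
    seed: int = 0,
    *,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Observed vs permuted-gene hit counts across thresholds.

    Permutation shuffles Z-scores across genes independently for every
    (feature, replicate) column, destroying replicate concordance while
    preserving each column's marginal distribution; hit counts are then
    recomputed under the same rule.  Returns per-threshold observed
    counts and the permuted mean/SD.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cube, genes, features, reps = _z_cube(z)
    n_genes = len(genes)
    rng = np.random.Generator(np.random.PCG64(seed))

    def count_hits(c: np.ndarray, t: float) -> int:
        above = (c >= t) & ~np.isnan(c)
        gene_hits = (above.sum(axis=2) >= min_reps).any(axis=1)
        return int(gene_hits.sum())

    thresholds = list(thresholds)
    observed = {t: count_hits(cube, t) for t in thresholds}
    perm_counts = {t: [] for t in thresholds}
    for _ in range(n_perm):
        perm = np.empty_like(cube)
        for j in range(cube.shape[1]):
            for k in range(cube.shape[2]):
                perm[:, j, k] = cube[rng.permutation(n_genes), j, k]
        for t in thresholds:
            perm_counts[t].append(count_hits(perm, t))
    rows = []
    for t in thresholds:
        arr = np.asarray(perm_counts[t], dtype=float)
        rows.append((t, observed[t], arr.mean(), arr.std(ddof=1) if n_perm > 1 else 0.0))
    return pd.DataFrame(rows, columns=["threshold", "observed", "perm_mean", "perm_sd"])


def binarize(hit_matrix: HitMatrix) -> pd.DataFrame:
    """Feature vectors (27-bit binary profiles) of the hit genes.

    One row per evaluable gene with at least one hit feature; genes
    with all-zero profiles are excluded from the hit set.  Column
    ``n_features_hit`` is the popcount.
    """
    hits = hit_matrix.hits.loc[hit_matrix.evaluable]
    fv = hits[hits.any(axis=1)].copy()
    fv["n_features_hit"] = fv.drop(columns=[], errors="ignore").sum(axis=1)
    return fv
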