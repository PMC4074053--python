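"""Hypergeometric and permutation-based enrichment of tree-node gene sets."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_edges",
    "hypergeom_test",
    "correct_pvalues",
    "interaction_enrichment",
    "screen_overlap",
]


def filter_edges(edges: pd.DataFrame, min_conf: float = 0.400) -> pd.DataFrame:
    """Keep interaction edges with confidence >= ``min_conf`` (inclusive)."""
    return edges.loc[edges["confidence"] >= min_conf].reset_index(drop=True)


def hypergeom_test(
    study: Iterable[str], annotated: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p: P(overlap >= observed).

    Probability of drawing at least the observed number of annotated
    genes when a study-set-sized sample is drawn at random from the
    universe.
    """
    study, annotated, uni = set(study), set(annotated), set(universe)
    if not study <= uni:
        raise ValueError("study set must be contained in the universe")
    if not annotated <= uni:
        raise ValueError("annotated set must be contained in the universe")
    obs = len(study & annotated)
    return float(stats.hypergeom(len(uni), len(annotated), len(study)).sf(obs - 1))


def correct_pvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing correction: Benjamini-Hochberg (default) or Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return np.minimum(multipletests(p, method=key)[1], 1.0)


def _draw_random_edges(n_genes: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    """``n_edges`` distinct unordered pairs (no self-edges), uniform."""
    out = np.empty((0, 2), dtype=np.int64)
    while out.shape[0] < n_edges:
        need = n_edges - out.shape[0]
        a = rng.integers(0, n_genes, size=int(need * 1.5) + 8)
        b = rng.integers(0, n_genes, size=a.size)
        ok = a != b
        a, b = a[ok], b[ok]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo * n_genes + hi
        cand = np.stack([lo, hi], axis=1)
        if out.size:
            keys_all = np.concatenate([out[:, 0] * n_genes + out[:, 1], keys])
            _, idx = np.unique(keys_all, return_index=True)
            idx = idx[idx >= out.shape[0]] - out.shape[0]
            idx.sort()
            cand = cand[idx]
        else:
            _, idx = np.unique(keys, return_index=True)
            idx.sort()
            cand = cand[idx]
        out = np.concatenate([out, cand[:need]], axis=0)
    return out


def interaction_enrichment(
    node_gene_sets: Mapping[object, Iterable[str]],
    edges: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    min_conf: float = 0.400,
    degree_preserving: bool = False,
    correction: str = "bh",
) -> pd.DataFrame:
    """Within-node protein-protein interaction enrichment by permutation.

    The observed statistic for a node is the number of
    confidence-filtered edges with both endpoints inside its gene set.
    Each permutation redraws the same number of edges uniformly over
    the network's gene universe (or, with ``degree_preserving=True``,
    rewires by double-edge swaps keeping the degree sequence), and the
    empirical p is ``(1 + #{perm >= obs}) / (n_perm + 1)``, corrected
    across nodes.  Nodes with fewer than two genes get p = 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    kept = filter_edges(edges, min_conf)
    genes = sorted(set(kept["gene_a"]) | set(kept["gene_b"]))
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    ea = kept["gene_a"].map(gidx).to_numpy()
    eb = kept["gene_b"].map(gidx).to_numpy()
    n_edges = len(kept)

    node_ids = list(node_gene_sets)
    members = np.zeros((len(node_ids), n_genes), dtype=bool)
    sizes = []
    for r, nid in enumerate(node_ids):
        gs = [gidx[g] for g in node_gene_sets[nid] if g in gidx]
        members[r, gs] = True
        sizes.append(len(set(node_gene_sets[nid])))
    observed = (members[:, ea] & members[:, eb]).sum(axis=1)

    rng = np.random.Generator(np.random.PCG64(seed))
    geq = np.zeros(len(node_ids), dtype=np.int64)
    if degree_preserving:
        pa, pb = ea.copy(), eb.copy()
        existing = set(zip(np.minimum(pa, pb).tolist(), np.maximum(pa, pb).tolist()))
        for _ in range(n_perm):
            # double-edge swaps; 2*E attempts per permutation step
            for _ in range(2 * n_edges):
                i, j = rng.integers(0, n_edges, size=2)
                if i == j:
                    continue
                a1, b1, a2, b2 = pa[i], pb[i], pa[j], pb[j]
                na1, nb1, na2, nb2 = a1, b2, a2, b1
                if na1 == nb1 or na2 == nb2:
                    continue
                k1 = (min(na1, nb1), max(na1, nb1))
                k2 = (min(na2, nb2), max(na2, nb2))
                if k1 in existing or k2 in existing or k1 == k2:
                    continue
                existing.discard((min(a1, b1), max(a1, b1)))
                existing.discard((min(a2, b2), max(a2, b2)))
                existing.add(k1)
                existing.add(k2)
                pa[i], pb[i] = na1, nb1
                pa[j], pb[j] = na2, nb2
            counts = (members[:, pa] & members[:, pb]).sum(axis=1)
            geq += counts >= observed
    else:
        for _ in range(n_perm):
            pairs = _draw_random_edges(n_genes, n_edges, rng)
            counts = (members[:, pairs[:, 0]] & members[:, pairs[:, 1]]).sum(axis=1)
            geq += counts >= observed
    p_emp = (1.0 + geq) / (n_perm + 1.0)
    p_emp = np.where(np.asarray(sizes) < 2, 1.0, p_emp)
    frame = pd.DataFrame({
        "node": node_ids,
        "n_genes": sizes,
        "observed": observed,
        "p_empirical": p_emp,
    })
    frame["p_corrected"] = correct_pvalues(frame["p_empirical"].to_numpy(), method=correction)
    return frame


def screen_overlap(
    node_gene_sets: Mapping[object, Iterable[str]],
    external_lists: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    *,
    max_unmapped: float = 0.5,
) -> pd.DataFrame:
    """Cross-screen overlap fractions with hypergeometric p per pair.

    Overlap is the fraction of a node's genes also present in the
    external hit list.  External genes absent from the universe are
    dropped; if more than ``max_unmapped`` of a list is unmapped the
    identifier spaces are presumed incompatible and an error is raised.
    """
    uni = set(universe)
    rows = []
    for screen, lst in external_lists.items():
        lst = set(lst)
        mapped = lst & uni
        if lst and len(mapped) / len(lst) < 1.0 - max_unmapped:
            raise ValueError(
                f"screen {screen!r}: {len(lst) - len(mapped)}/{len(lst)} genes unmapped"
            )
        for nid, genes in node_gene_sets.items():
            genes = set(genes) & uni
            if not genes:
                continue
            overlap = len(genes & mapped)
            frac = overlap / len(genes)
            p = hypergeom_test(genes, mapped, uni)
            rows.append((nid, screen, len(genes), len(mapped), overlap, frac, p))
    return pd.DataFrame(
        rows,
        columns=["node", "screen", "n_node", "n_screen", "overlap", "fraction", "p"],
    )
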