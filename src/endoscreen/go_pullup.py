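"""GO-term pull-up on the feature tree.

Replaces gene identifiers at the tree leaves with their cellular
component annotations and lets a term rise to the highest node through
which all of its leaf occurrences are connected: a term carried by all
leaves of one clade rises to that clade's node, a term on a single leaf
stays there, and a term scattered over unrelated leaves gets one home
per maximal fully-covered clade.  A short list of generic terms
(cytoplasm, nucleus, ...) is forced to the root.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .synthetic import AnnotationMap
from .tree import FeatureTree, TreeNode
from . import enrichment as _enrichment

__all__ = ["GENERIC_TERMS", "annotate_leaves", "pull_up", "node_term_enrichment"]

#: Generic cellular-component annotations that converge at the root.
GENERIC_TERMS = frozenset(
    {"cytoplasm", "nucleus", "membrane", "intracellular",
     "extracellular region", "plasma membrane"}
)


def annotate_leaves(
    hit_matrix: pd.DataFrame, annotations: AnnotationMap
) -> tuple[dict[str, set[str]], int]:
    """Terms present at each feature leaf, via the feature's hit genes.

    ``hit_matrix`` is a genes x features boolean frame.  A term is
    present at a leaf iff at least one hit gene for that feature
    carries it (set semantics).  Returns ``(leaf_terms,
    n_unannotated)`` where the count reports hit genes without any
    annotation (they contribute nothing).
    """
    bits = hit_matrix.select_dtypes(include=["bool"])
    leaf_terms: dict[str, set[str]] = {f: set() for f in bits.columns}
    unannotated: set[str] = set()
    for gene, row in bits.iterrows():
        terms = annotations.terms_of(gene)
        if not terms and row.any():
            unannotated.add(gene)
            continue
        for f in bits.columns[row.to_numpy()]:
            leaf_terms[f] |= terms
    return leaf_terms, len(unannotated)


def pull_up(
    tree: FeatureTree,
    leaf_terms: Mapping[str, Iterable[str]],
    generic_terms: Iterable[str] = GENERIC_TERMS,
) -> dict[int, set[str]]:
    """Home node(s) for every term: ``{node_id: set of terms}``.

    A node is *covered* by a term when every leaf below it carries the
    term; homes are the covered nodes whose parent is not covered.
    Every leaf occurrence is therefore covered by exactly one home on
    or above that leaf, and adding occurrences can only move a term's
    home upward.  ``generic_terms`` are placed at the root regardless.
    """
    generic = set(generic_terms)
    terms_by_leaf = {f: set(ts) for f, ts in leaf_terms.items()}
    all_terms = set().union(*terms_by_leaf.values()) if terms_by_leaf else set()
    homes: dict[int, set[str]] = {}

    for term in sorted(all_terms):
        if term in generic:
            homes.setdefault(tree.root.node_id, set()).add(term)
            continue

        def covered(node: TreeNode) -> bool:
            if node.is_leaf:
                return term in terms_by_leaf.get(node.leaf_name, ())
            return all(covered(c) for c in node.children)

        def place(node: TreeNode) -> None:
            if covered(node):
                homes.setdefault(node.node_id, set()).add(term)
                return
            for c in node.children:
                place(c)

        place(tree.root)
    return homes


def node_term_enrichment(
    node_genes: Iterable[str],
    annotations: AnnotationMap,
    universe: Iterable[str],
    *,
    correction: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric term enrichment of one node's gene set.

    Tests every annotated term; returns a frame with raw and corrected
    upper-tail p-values and observed/expected overlap counts.
    """
    study = set(node_genes)
    uni = set(universe)
    if not study:
        return pd.DataFrame(columns=["term", "observed", "expected", "p_raw", "p_corrected"])
    rows = []
    for term, genes in sorted(annotations.term_to_genes.items()):
        annotated = genes & uni
        if not annotated:
            continue
        obs = len(study & annotated)
        p = _enrichment.hypergeom_test(study, annotated, uni)
        expected = len(study) * len(annotated) / len(uni)
        rows.append((term, obs, expected, p))
    frame = pd.DataFrame(rows, columns=["term", "observed", "expected", "p_raw"])
    frame["p_corrected"] = _enrichment.correct_pvalues(frame["p_raw"].to_numpy(), method=correction)
    return frame
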