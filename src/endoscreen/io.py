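"""Tabular and tree file formats plus run manifests.

All tabular interchange is TSV with a header row; well coordinates are
0-based; features use the canonical 27-name catalog.  Trees are Newick
with internal labels ``nodeN`` and jackknife support percentages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
import pandas as pd

from .catalog import FEATURES
from .synthetic import AnnotationMap, WellSample
from .tree import FeatureTree

__all__ = [
    "read_well_table",
    "write_well_table",
    "frame_to_wells",
    "read_annotations",
    "write_zscores",
    "read_zscores",
    "write_tree",
    "node_membership_table",
    "RunManifest",
]

WELL_META_COLUMNS = ["well_id", "row", "col", "role", "gene", "replicate", "slide", "cell_id"]


def write_well_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_well_table(path) -> pd.DataFrame:
    """Read and validate a per-cell well table (TSV).

    Unknown columns are preserved as passthrough; a missing feature
    column or a non-numeric cell value is an error naming the culprit.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in WELL_META_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing metadata column {col!r}")
    for f in FEATURES:
        if f not in frame.columns:
            raise ValueError(f"missing feature {f}")
        coerced = pd.to_numeric(frame[f], errors="coerce")
        bad = coerced.isna() & frame[f].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"non-numeric value for feature {f} at row {row}")
        frame[f] = coerced
    frame["gene"] = frame["gene"].fillna("")
    return frame


def frame_to_wells(frame: pd.DataFrame) -> list[WellSample]:
    """Group a long per-cell table back into WellSample objects."""
    wells = []
    cols = ["cell_id", *FEATURES]
    for (well_id, rep), sub in frame.groupby(["well_id", "replicate"], sort=True):
        first = sub.iloc[0]
        wells.append(WellSample(
            slide=str(first["slide"]),
            row=int(first["row"]),
            col=int(first["col"]),
            role=str(first["role"]),
            gene=str(first["gene"]) or None,
            replicate=int(rep),
            cells=sub[cols].reset_index(drop=True),
        ))
    return wells


def read_annotations(path) -> AnnotationMap:
    """Two-column (gene, term) TSV or GAF 2.x (columns 2 and 5)."""
    pairs = []
    with open(path) as fh:
        first = fh.readline()
        is_gaf = first.startswith("!gaf")
        fh.seek(0)
        for line in fh:
            if line.startswith(("!", "#")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if is_gaf:
                pairs.append((parts[1], parts[4]))
            else:
                if parts[0].lower() in ("gene", "gene_id"):
                    continue
                pairs.append((parts[0], parts[1]))
    return AnnotationMap.from_pairs(pairs)


def write_zscores(z: pd.DataFrame, path) -> None:
    z.reset_index().to_csv(path, sep="\t", index=False)


def read_zscores(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index(["gene", "feature"])


def write_tree(tree: FeatureTree, newick_path=None) -> str:
    """Newick text with internal labels ``nodeN`` and support values.

    Jackknife support (when present) is appended to the internal label
    as ``nodeN_<support>``; polytomies are preserved.  The text parses
    with standard Newick readers.
    """

    def rec(node) -> str:
        if node.is_leaf:
            return node.leaf_name
        inner = ",".join(rec(c) for c in node.children)
        label = f"node{node.node_id}"
        if node.support is not None:
            label += f"_{node.support:g}"
        return f"({inner}){label}"

    text = rec(tree.root) + ";"
    if newick_path is not None:
        Path(newick_path).write_text(text + "\n")
    return text


def node_membership_table(tree: FeatureTree) -> pd.DataFrame:
    """Long (node_id, gene, event) table of gains and losses."""
    rows = []
    for node in tree.nodes():
        for g in node.genes_added:
            rows.append((node.node_id, g, "gain"))
        for g in node.genes_lost:
            rows.append((node.node_id, g, "loss"))
    if tree.singletons:
        for gene, leaf in sorted(tree.singletons.items()):
            leaf_node = next(n for n in tree.leaves() if n.leaf_name == leaf)
            rows.append((leaf_node.node_id, gene, "gain"))
    return pd.DataFrame(rows, columns=["node_id", "gene", "event"])


def write_image_set(channels, cell_mask, nuclear_mask, directory) -> None:
    """Write a field's channels and label masks as 16-bit grayscale TIFFs."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, img in channels.items():
        tifffile.imwrite(directory / f"{ch}.tif", img)
    tifffile.imwrite(directory / "cell_mask.tif", cell_mask.astype("uint16"))
    tifffile.imwrite(directory / "nuclear_mask.tif", nuclear_mask.astype("uint16"))


class RunManifest:
    """Config hash, seed and input digests for reproducible stage runs."""

    def __init__(self, seed: int, config: dict | None = None):
        self.seed = seed
        self.config = config or {}
        self.inputs: dict[str, str] = {}
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.inputs[str(path)] = digest

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": self.config,
            "inputs": self.inputs,
            "timestamp": self.timestamp,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))
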