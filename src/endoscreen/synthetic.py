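"""Seeded synthetic screens with known ground truth.

Emulates the structure of a cell-array RNAi screen: triplicate 10x30
well arrays with 30 negative and 8 positive control wells per slide,
~100-300 cells per well, heavy-tailed per-cell feature distributions,
multiplicative slide-positional artifacts, and gene effects that alter
the location, scale or skew of chosen feature distributions.  Every
generator is a pure function of its configuration and seed.

Baseline per-cell distributions are log-normal for intensities, gamma
for counts and sizes, and beta for bounded fractions -- families chosen
to reproduce the heavy-tailed, bounded shapes of real single-cell data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    COUNT_FEATURES,
    FEATURES,
    FRACTION_FEATURES,
)

__all__ = [
    "ScreenConfig",
    "Effect",
    "GroundTruth",
    "WellSample",
    "SecondaryPlate",
    "AnnotationMap",
    "default_baseline",
    "generate_primary_screen",
    "wells_to_frame",
    "generate_secondary_plate",
    "generate_annotations",
    "generate_interaction_network",
    "generate_images",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its contract."""


# ---------------------------------------------------------------------------
# baseline distributions


def default_baseline() -> dict[str, stats.rv_continuous]:
    """Frozen scipy distributions for the 27 baseline feature families."""
    base: dict[str, object] = {}
    for f in FEATURES:
        if f in FRACTION_FEATURES:
            if f == "NucCirc":
                base[f] = stats.beta(8.0, 2.0)
            elif f in ("Fmph3", "Tmph3"):
                base[f] = stats.beta(5.0, 2.0)
            else:
                base[f] = stats.beta(2.0, 5.0)
        elif f in COUNT_FEATURES:
            base[f] = stats.gamma(4.0, scale=5.0)
        elif f.startswith(("Fint", "Tint")) or f == "Okt":
            base[f] = stats.lognorm(0.6, scale=200.0)
        elif f.startswith("Rto"):
            base[f] = stats.lognorm(0.5, scale=0.8)
        elif f in ("Fmph1", "Tmph1"):
            base[f] = stats.gamma(3.0, scale=2.0)
        elif f == "NucSize":
            base[f] = stats.gamma(9.0, scale=10.0)
        elif f == "CellSize":
            base[f] = stats.gamma(8.0, scale=40.0)
        elif f == "NucDist":
            base[f] = stats.gamma(2.0, scale=3.0)
        elif f == "NucFluct":
            base[f] = stats.gamma(4.0, scale=0.05)
        else:  # pragma: no cover - catalog is closed
            raise KeyError(f)
    return base


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class Effect:
    """A gene's perturbation of one feature distribution.

    kind:
        ``shift``  -- add ``size`` baseline SDs to every cell;
        ``scale``  -- stretch about the mean by factor ``size``;
        ``skew``   -- shift a subpopulation (``subpop_fraction`` of
        cells) by ``size`` baseline SDs, changing shape but only mildly
        the mean.
    """

    kind: str
    size: float
    subpop_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "scale", "skew"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if not 0.0 < self.subpop_fraction <= 1.0:
            raise ConfigurationError("subpop_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ArtifactSpec:
    """Multiplicative slide-positional bias magnitudes (fractions)."""

    row_magnitude: float = 0.15
    col_magnitude: float = 0.15
    edge_magnitude: float = 0.15


@dataclass
class ScreenConfig:
    """Layout and statistical parameters of a synthetic primary screen."""

    n_genes: int = 200
    n_rows: int = 10
    n_cols: int = 30
    n_negative: int = 30
    n_positive: int = 8
    n_replicates: int = 3
    cells_per_well_mean: float = 150.0
    cells_per_well_dispersion: float = 30.0  # negative-binomial shape k
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    #: gene -> {feature -> Effect}; genes absent here have no effect.
    effect_table: Mapping[str, Mapping[str, Effect]] = field(default_factory=dict)
    #: effects applied to every positive-control well (makes positives strong).
    positive_effects: Mapping[str, Effect] | None = None
    baseline_spec: Mapping[str, object] | None = None
    seed: int = 0

    @property
    def wells_per_slide(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def test_wells_per_slide(self) -> int:
        return self.wells_per_slide - self.n_negative - self.n_positive

    @property
    def n_slides_per_replicate(self) -> int:
        return max(1, math.ceil(self.n_genes / self.test_wells_per_slide))

    def validate(self) -> None:
        if self.cells_per_well_mean < 1:
            raise ConfigurationError("cells_per_well_mean must be >= 1")
        if self.n_negative + self.n_positive > self.wells_per_slide:
            raise ConfigurationError("controls exceed wells per slide")
        if self.test_wells_per_slide < 1:
            raise ConfigurationError("no test wells available")
        feats = set(FEATURES)
        for gene, effs in self.effect_table.items():
            unknown = set(effs) - feats
            if unknown:
                raise ConfigurationError(
                    f"effect for gene {gene!r} targets unknown features {sorted(unknown)}"
                )

    def baseline(self) -> Mapping[str, object]:
        return self.baseline_spec if self.baseline_spec is not None else default_baseline()


@dataclass
class WellSample:
    """One well's per-cell feature matrix plus metadata."""

    slide: str
    row: int
    col: int
    role: str  # negative | positive | test
    gene: str | None
    replicate: int
    cells: pd.DataFrame  # columns: cell_id + 27 features

    @property
    def well_id(self) -> str:
        return f"{self.slide}:r{self.row:02d}c{self.col:02d}"

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class GroundTruth:
    """What the generator planted: effects, and per-well artifact factors."""

    true_hits: dict[str, set[str]]
    effect_table: dict[str, dict[str, Effect]]
    artifact_factor: dict[str, float]  # well_id -> multiplicative factor

    def to_json(self) -> str:
        payload = {
            "true_hits": {g: sorted(s) for g, s in self.true_hits.items()},
            "effect_table": {
                g: {f: dataclasses.asdict(e) for f, e in effs.items()}
                for g, effs in self.effect_table.items()
            },
            "artifact_factor": self.artifact_factor,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# primary screen


def _apply_effect(values: np.ndarray, effect: Effect, sd: float, mean: float,
                  rng: np.random.Generator) -> np.ndarray:
    if effect.kind == "shift":
        return values + effect.size * sd
    if effect.kind == "scale":
        return mean + (values - mean) * effect.size
    # skew: shift a random subpopulation
    mask = rng.random(values.shape[0]) < effect.subpop_fraction
    out = values.copy()
    out[mask] += effect.size * sd
    return out


def _clip_feature(feature: str, values: np.ndarray) -> np.ndarray:
    if feature in FRACTION_FEATURES:
        return np.clip(values, 0.0, 1.0)
    return np.maximum(values, 0.0)


def _slide_positions(config: ScreenConfig, rng: np.random.Generator):
    """Assign control/test roles to grid positions, shared across replicates."""
    n_wells = config.wells_per_slide
    order = rng.permutation(n_wells)
    negatives = set(order[: config.n_negative].tolist())
    positives = set(order[config.n_negative: config.n_negative + config.n_positive].tolist())
    roles = []
    for idx in range(n_wells):
        if idx in negatives:
            roles.append("negative")
        elif idx in positives:
            roles.append("positive")
        else:
            roles.append("test")
    return roles


def generate_primary_screen(config: ScreenConfig) -> tuple[list[WellSample], GroundTruth]:
    """Simulate a triplicate cell-array screen.

    Returns the well samples of all slides plus the planted ground
    truth.  Deterministic for a fixed config and seed: negative wells
    are drawn from the baseline families modulated only by positional
    artifacts; test wells are additionally modulated by their gene's
    effects; positive-control wells receive ``config.positive_effects``.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))
    baseline = config.baseline()
    stats_cache = {f: (baseline[f].mean(), baseline[f].std()) for f in FEATURES}

    genes = [f"g{k:04d}" for k in range(config.n_genes)]
    if config.effect_table:
        # allow caller-specified gene names outside the default universe
        extra = [g for g in config.effect_table if g not in set(genes)]
        if extra:
            raise ConfigurationError(
                f"effect_table genes not in universe: {sorted(extra)[:5]}"
            )

    n_slides = config.n_slides_per_replicate
    per_slide = config.test_wells_per_slide
    roles_by_slide = [_slide_positions(config, rng) for _ in range(n_slides)]
    gene_chunks = [genes[i * per_slide:(i + 1) * per_slide] for i in range(n_slides)]

    positive_effects = config.positive_effects
    if positive_effects is None:
        # strong shape-visible perturbation of the core intensity features,
        # emulating dedicated positive-control dsRNAs
        positive_effects = {
            f: Effect("skew", 4.0, subpop_fraction=0.5)
            for f in ("Fint1", "Fint2", "Fint3", "Tint1", "Tint2", "Tint3")
        }

    art = config.artifact_spec
    wells: list[WellSample] = []
    artifact_factor: dict[str, float] = {}

    for rep in range(1, config.n_replicates + 1):
        for s in range(n_slides):
            slide_id = f"S{s:02d}R{rep}"
            roles = roles_by_slide[s]
            chunk = gene_chunks[s]
            # per-slide positional bias fields
            row_bias = rng.uniform(-art.row_magnitude, art.row_magnitude, config.n_rows)
            col_bias = rng.uniform(-art.col_magnitude, art.col_magnitude, config.n_cols)
            edge_bias = rng.uniform(-art.edge_magnitude, art.edge_magnitude)
            gene_iter = iter(chunk)
            for idx, role in enumerate(roles):
                r, c = divmod(idx, config.n_cols)
                gene = None
                if role == "test":
                    gene = next(gene_iter, None)
                    if gene is None:
                        continue  # slide not fully populated
                on_edge = r in (0, config.n_rows - 1) or c in (0, config.n_cols - 1)
                factor = (1.0 + row_bias[r]) * (1.0 + col_bias[c])
                if on_edge:
                    factor *= 1.0 + edge_bias
                n_cells = max(1, int(rng.negative_binomial(
                    config.cells_per_well_dispersion,
                    config.cells_per_well_dispersion
                    / (config.cells_per_well_dispersion + config.cells_per_well_mean))))
                data = {"cell_id": np.arange(n_cells)}
                effects: Mapping[str, Effect] = {}
                if role == "positive":
                    effects = positive_effects
                elif gene is not None:
                    effects = config.effect_table.get(gene, {})
                for f in FEATURES:
                    dist = baseline[f]
                    mean, sd = stats_cache[f]
                    vals = np.asarray(dist.rvs(size=n_cells, random_state=rng), dtype=float)
                    eff = effects.get(f)
                    if eff is not None:
                        vals = _apply_effect(vals, eff, sd, mean, rng)
                    if f not in FRACTION_FEATURES:
                        vals = vals * factor
                    data[f] = _clip_feature(f, vals)
                well = WellSample(slide_id, r, c, role, gene, rep, pd.DataFrame(data))
                artifact_factor[well.well_id] = float(factor)
                wells.append(well)

    def _is_real(e: Effect) -> bool:
        return e.size != 1.0 if e.kind == "scale" else e.size != 0.0

    truth = GroundTruth(
        true_hits={g: {f for f, e in effs.items() if _is_real(e)}
                   for g, effs in config.effect_table.items()},
        effect_table={g: dict(effs) for g, effs in config.effect_table.items()},
        artifact_factor=artifact_factor,
    )
    return wells, truth


def wells_to_frame(wells: Sequence[WellSample]) -> pd.DataFrame:
    """Long per-cell table in the interchange TSV schema."""
    frames = []
    for w in wells:
        df = w.cells.copy()
        df.insert(0, "well_id", w.well_id)
        df.insert(1, "row", w.row)
        df.insert(2, "col", w.col)
        df.insert(3, "role", w.role)
        df.insert(4, "gene", w.gene if w.gene is not None else "")
        df.insert(5, "replicate", w.replicate)
        df.insert(6, "slide", w.slide)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


#: Nested feature groups mirroring the screen's pathway structure:
#: intensity / morphology blocks inside the fluid and transferrin
#: branches, the whole-pathway sets, the combined endocytic set, and
#: the nuclear branch.  Pairwise nested-or-disjoint, so they are
#: realizable as clades of one feature tree.
NESTED_FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "fluid_int_core": ("Fint1", "Fint2"),
    "fluid_int": ("Fint1", "Fint2", "Fint3", "Fint4"),
    "fluid_mph": ("Fmph1", "Fmph2", "Fmph3"),
    "fluid_all": ("Fint1", "Fint2", "Fint3", "Fint4",
                  "Fmph1", "Fmph2", "Fmph3", "Fnum", "Fclc"),
    "tf_int_core": ("Tint1", "Tint2"),
    "tf_int": ("Tint1", "Tint2", "Tint3", "Tint4"),
    "tf_mph": ("Tmph1", "Tmph2", "Tmph3"),
    "tf_rto": ("Rto1", "Rto2", "Rto3"),
    "tf_all": ("Tint1", "Tint2", "Tint3", "Tint4",
               "Tmph1", "Tmph2", "Tmph3", "Tnum", "Okt",
               "Rto1", "Rto2", "Rto3", "Tclc"),
    "endocytic": ("Fint1", "Fint2", "Fint3", "Fint4",
                  "Fmph1", "Fmph2", "Fmph3", "Fnum", "Fclc",
                  "Tint1", "Tint2", "Tint3", "Tint4",
                  "Tmph1", "Tmph2", "Tmph3", "Tnum", "Okt",
                  "Rto1", "Rto2", "Rto3", "Tclc"),
    "nuclear_core": ("NucSize", "NucCirc"),
    "nuclear_all": ("NucSize", "NucCirc", "NucFluct", "NucDist"),
}


def nested_effect_table(
    genes_per_group: int | Mapping[str, int] = 8,
    effect_size: float = 4.0,
    kind: str = "skew",
    groups: Mapping[str, Sequence[str]] | None = None,
    gene_offset: int = 0,
) -> tuple[dict[str, dict[str, Effect]], dict[str, list[str]]]:
    """Effect table planting gene groups on nested feature subsets.

    Returns ``(effect_table, group_members)``; gene names follow the
    primary generator's ``g####`` convention starting at
    ``gene_offset``.  ``genes_per_group`` may be a single count or a
    per-group mapping.  Used to test hierarchical (clade) recovery.
    """
    groups = dict(groups or NESTED_FEATURE_GROUPS)
    table: dict[str, dict[str, Effect]] = {}
    members: dict[str, list[str]] = {}
    k = gene_offset
    for name, feats in groups.items():
        n_genes = (genes_per_group if isinstance(genes_per_group, int)
                   else genes_per_group.get(name, 0))
        members[name] = []
        for _ in range(n_genes):
            gene = f"g{k:04d}"
            table[gene] = {f: Effect(kind, effect_size) for f in feats}
            members[name].append(gene)
            k += 1
    return table, members


# ---------------------------------------------------------------------------
# secondary classification plates


@dataclass
class SecondaryPlate:
    """Per-well pulse/chase means for a local-control classification assay."""

    wells: pd.DataFrame  # columns: well, group, role, gene, pulse, chase
    truth_quadrant: dict[str, object]  # gene -> 1|2|3|4|"null"


def _truth_quadrant(pulse_fold: float, chase_fold: float):
    up_p, down_p = pulse_fold > 1, pulse_fold < 1
    up_c, down_c = chase_fold > 1, chase_fold < 1
    if not (up_p or down_p or up_c or down_c):
        return "null"
    if up_p and up_c:
        return 1
    if down_p and down_c:
        return 3
    if down_c and not down_p:
        return 2
    return 4


def generate_secondary_plate(
    genes: Sequence[str],
    effect_table: Mapping[str, tuple[float, float]],
    *,
    n_test_reps: int = 3,
    n_local_negatives: int = 6,
    n_local_positives: int = 3,
    baseline_pulse: float = 1000.0,
    baseline_chase: float = 800.0,
    well_cv: float = 0.08,
    seed: int = 0,
) -> SecondaryPlate:
    """Simulate the local-control secondary assay.

    Each gene occupies one local group: ``n_test_reps`` test wells with
    (pulse_fold, chase_fold) from ``effect_table`` (default (1, 1)),
    surrounded by local negative wells at baseline and positive wells
    with strongly reduced uptake.  Well means carry log-normal
    measurement noise with coefficient of variation ``well_cv``.
    """
    if n_local_negatives < 2 or n_local_positives < 1:
        raise ConfigurationError("layout must provide >=2 local negatives and >=1 positive")
    rng = np.random.Generator(np.random.PCG64(seed))
    sigma = math.sqrt(math.log(1 + well_cv ** 2))

    def noisy(mean: float, n: int) -> np.ndarray:
        return mean * rng.lognormal(-sigma ** 2 / 2, sigma, n)

    rows = []
    truth: dict[str, object] = {}
    widx = 0
    for group, gene in enumerate(genes):
        pf, cf = effect_table.get(gene, (1.0, 1.0))
        truth[gene] = _truth_quadrant(pf, cf)
        for role, n, pm, cm, g in (
            ("negative", n_local_negatives, baseline_pulse, baseline_chase, ""),
            ("positive", n_local_positives, 0.3 * baseline_pulse, 0.3 * baseline_chase, ""),
            ("test", n_test_reps, pf * baseline_pulse, cf * baseline_chase, gene),
        ):
            pv, cv_ = noisy(pm, n), noisy(cm, n)
            for i in range(n):
                rows.append((f"w{widx:04d}", group, role, g, pv[i], cv_[i]))
                widx += 1
    frame = pd.DataFrame(rows, columns=["well", "group", "role", "gene", "pulse", "chase"])
    return SecondaryPlate(frame, truth)


# ---------------------------------------------------------------------------
# annotations and interaction networks


@dataclass
class AnnotationMap:
    """Gene -> GO-term map plus its consistent inverse."""

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "AnnotationMap":
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        return cls(g2t, t2g)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())


def generate_annotations(
    universe: Sequence[str],
    n_background_terms: int,
    planted: Mapping[str, Sequence[str]] | None = None,
    *,
    genes_per_term_mean: float = 15.0,
    seed: int = 0,
) -> AnnotationMap:
    """Planted terms exactly as given plus random background terms."""
    universe = list(universe)
    if not universe:
        raise ConfigurationError("empty gene universe")
    uset = set(universe)
    planted = dict(planted or {})
    for term, genes in planted.items():
        outside = set(genes) - uset
        if outside:
            raise ConfigurationError(f"planted genes outside universe for {term}: {sorted(outside)[:5]}")
    rng = np.random.Generator(np.random.PCG64(seed))
    pairs: list[tuple[str, str]] = []
    for term, genes in planted.items():
        pairs.extend((g, term) for g in genes)
    for k in range(n_background_terms):
        term = f"GO:BG{k:04d}"
        size = max(1, int(rng.poisson(genes_per_term_mean)))
        members = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        pairs.extend((universe[m], term) for m in members)
    return AnnotationMap.from_pairs(pairs)


def generate_interaction_network(
    universe: Sequence[str],
    planted_modules: Sequence[Sequence[str]] = (),
    n_background_edges: int = 0,
    *,
    module_confidence: tuple[float, float] = (0.6, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Edge list with dense planted modules over a sparse background.

    Returns a DataFrame with columns ``gene_a``, ``gene_b``,
    ``confidence``; undirected duplicate edges are merged keeping the
    highest confidence.
    """
    universe = list(universe)
    uset = set(universe)
    rng = np.random.Generator(np.random.PCG64(seed))
    edges: dict[tuple[str, str], float] = {}

    def put(a: str, b: str, conf: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), conf)

    for module in planted_modules:
        module = list(module)
        if set(module) - uset:
            raise ConfigurationError("planted module gene outside universe")
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                put(module[i], module[j], float(rng.uniform(*module_confidence)))

    n = len(universe)
    target = len(edges) + n_background_edges
    max_possible = n * (n - 1) // 2
    target = min(target, max_possible)
    stall = 0
    while len(edges) < target and stall < 50:
        need = target - len(edges)
        a = rng.integers(0, n, size=2 * need)
        b = rng.integers(0, n, size=2 * need)
        conf = rng.uniform(0.0, 1.0, size=2 * need)
        before = len(edges)
        for i in range(len(a)):
            if len(edges) >= target:
                break
            put(universe[a[i]], universe[b[i]], float(conf[i]))
        stall = stall + 1 if len(edges) == before else 0
    rows = [(a, b, c) for (a, b), c in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])


# ---------------------------------------------------------------------------
# image fixtures


@dataclass
class ImageTruth:
    """Planted spot positions/amplitudes per cell per channel."""

    spots: dict[str, list[dict]]  # channel -> list of {cell, y, x, amplitude, sigma}
    rejected: list[dict]


def _add_gaussian(img: np.ndarray, y: float, x: float, amp: float, sigma: float) -> None:
    r = int(3 * sigma) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    patch = amp * np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma ** 2))
    y0, x0 = int(round(y)), int(round(x))
    ys, ye = max(0, y0 - r), min(img.shape[0], y0 + r + 1)
    xs, xe = max(0, x0 - r), min(img.shape[1], x0 + r + 1)
    img[ys:ye, xs:xe] += patch[ys - (y0 - r): ye - (y0 - r), xs - (x0 - r): xe - (x0 - r)]


def generate_images(
    *,
    shape: tuple[int, int] = (256, 256),
    n_cells: int = 4,
    cell_radius: int = 28,
    nucleus_radius: int = 9,
    spots_per_cell: Mapping[str, int] | None = None,
    spot_amplitude: float = 4000.0,
    spot_sigma: float = 1.5,
    background: float = 200.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, ImageTruth]:
    """Synthetic multi-channel field with masks and spot ground truth.

    Returns ``(channels, cell_mask, nuclear_mask, truth)``.  Channels are
    ``nuclear``, ``fluid``, ``tf``, ``surface`` as uint16 images; masks
    are label images (0 = background, cell ``i`` labeled ``i``).  Spots
    are Gaussian profiles at known positions over a smooth background;
    spots sampled outside their cell mask are rejected and recorded.
    """
    if shape[0] < 128 or shape[1] < 128:
        raise ConfigurationError("image dims must be >= 128x128")
    rng = np.random.Generator(np.random.PCG64(seed))
    spots_per_cell = dict(spots_per_cell or {"fluid": 5, "tf": 5})

    h, w = shape
    cell_mask = np.zeros(shape, dtype=np.int32)
    nuc_mask = np.zeros(shape, dtype=np.int32)
    centers = []
    margin = cell_radius + 4
    grid = max(1, int(math.ceil(math.sqrt(n_cells))))
    for i in range(n_cells):
        gy, gx = divmod(i, grid)
        cy = margin + gy * (2 * cell_radius + 8)
        cx = margin + gx * (2 * cell_radius + 8)
        if cy + cell_radius >= h or cx + cell_radius >= w:
            raise ConfigurationError("too many cells for image size")
        centers.append((cy, cx))
        yy, xx = np.mgrid[0:h, 0:w]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius ** 2
        cell_mask[disk] = i + 1
        ndisk = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius ** 2
        nuc_mask[ndisk] = i + 1

    channels = {}
    truth = ImageTruth({ch: [] for ch in ("fluid", "tf")}, [])
    for ch in ("nuclear", "fluid", "tf", "surface"):
        img = np.full(shape, background, dtype=float)
        if ch == "nuclear":
            for i, (cy, cx) in enumerate(centers):
                _add_gaussian(img, cy, cx, 8000.0, nucleus_radius / 1.5)
        elif ch == "surface":
            img[cell_mask > 0] += 1500.0
        else:
            min_sep = 5.0 * spot_sigma  # keep planted spots resolvable
            for i, (cy, cx) in enumerate(centers):
                placed: list[tuple[float, float]] = []
                for _ in range(spots_per_cell.get(ch, 0)):
                    rec = None
                    for _attempt in range(200):
                        ang = rng.uniform(0, 2 * math.pi)
                        rad = rng.uniform(nucleus_radius + 3, cell_radius - 4)
                        sy, sx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                        if any(math.hypot(sy - py, sx - px) < min_sep for py, px in placed):
                            continue
                        rec = {"cell": i + 1, "y": sy, "x": sx,
                               "amplitude": spot_amplitude, "sigma": spot_sigma}
                        break
                    if rec is None:
                        continue
                    if cell_mask[int(round(rec["y"])), int(round(rec["x"]))] != i + 1:
                        truth.rejected.append(rec)
                        continue
                    placed.append((rec["y"], rec["x"]))
                    _add_gaussian(img, rec["y"], rec["x"], spot_amplitude, spot_sigma)
                    truth.spots[ch].append(rec)
        img += rng.normal(0.0, noise_sd, shape)
        channels[ch] = np.clip(img, 0, 2 ** 16 - 1).astype(np.uint16)
    return channels, cell_mask, nuc_mask, truth
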