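"""Tests for the synthetic-screen generators and their ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endoscreen.catalog import FEATURES
from endoscreen.synthetic import (
    AnnotationMap,
    ConfigurationError,
    Effect,
    ScreenConfig,
    default_baseline,
    generate_annotations,
    generate_images,
    generate_interaction_network,
    generate_primary_screen,
    generate_secondary_plate,
    nested_effect_table,
    wells_to_frame,
)


class TestScreenConfig:
    def test_invalid_effect_feature_rejected(self):
        cfg = ScreenConfig(n_genes=10, effect_table={"g0001": {"NotAFeature": Effect("shift", 1.0)}})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigurationError):
            ScreenConfig(n_genes=10, cells_per_well_mean=0.5).validate()

    def test_controls_must_fit_on_slide(self):
        with pytest.raises(ConfigurationError):
            ScreenConfig(n_genes=1, n_rows=2, n_cols=5, n_negative=8, n_positive=4).validate()


class TestPrimaryScreen:
    def test_deterministic_for_fixed_seed(self):
        cfg = ScreenConfig(n_genes=12, n_rows=3, n_cols=10, n_negative=6,
                           n_positive=2, cells_per_well_mean=60, seed=5)
        f1 = wells_to_frame(generate_primary_screen(cfg)[0])
        f2 = wells_to_frame(generate_primary_screen(cfg)[0])
        pd.testing.assert_frame_equal(f1, f2)
        assert f1.to_csv() == f2.to_csv()  # byte-identical tables

    def test_structure_matches_config(self, null_screen):
        cfg, wells, _ = null_screen
        by_slide = {}
        for w in wells:
            by_slide.setdefault(w.slide, []).append(w)
        assert len(by_slide) == cfg.n_slides_per_replicate * cfg.n_replicates
        for slide_wells in by_slide.values():
            roles = pd.Series([w.role for w in slide_wells]).value_counts()
            assert roles["negative"] == cfg.n_negative
            assert roles["positive"] == cfg.n_positive
        # every gene appears exactly once per replicate
        per_rep = {}
        for w in wells:
            if w.role == "test":
                per_rep.setdefault(w.replicate, []).append(w.gene)
        for genes in per_rep.values():
            assert len(genes) == len(set(genes)) == cfg.n_genes

    def test_cells_carry_all_features(self, null_screen):
        _, wells, _ = null_screen
        assert list(wells[0].cells.columns) == ["cell_id", *FEATURES]

    def test_shift_effect_moves_mean_by_configured_sigmas(self):
        """+2 sigma shift on Fint3 raises the well mean by 2 baseline SDs."""
        base = default_baseline()["Fint3"]
        effects = {"g0000": {"Fint3": Effect("shift", 2.0)}}
        cfg = ScreenConfig(n_genes=5, n_rows=3, n_cols=10, n_negative=6,
                           n_positive=2, cells_per_well_mean=250,
                           effect_table=effects, seed=31)
        wells, truth = generate_primary_screen(cfg)
        factor = truth.artifact_factor
        diffs = []
        for rep in (1, 2, 3):
            test = [w for w in wells if w.gene == "g0000" and w.replicate == rep][0]
            test_mean = test.cells["Fint3"].mean() / factor[test.well_id]
            negs = [w.cells["Fint3"].mean() / factor[w.well_id]
                    for w in wells if w.role == "negative" and w.replicate == rep]
            diffs.append(test_mean - np.mean(negs))
        observed_shift = np.mean(diffs) / base.std()
        assert observed_shift == pytest.approx(2.0, abs=0.3)

    def test_null_gene_wells_match_negative_distribution(self, null_screen):
        """With no effect, test wells are statistically negatives (shape-wise)."""
        _, wells, _ = null_screen
        slide = wells[0].slide
        sw = [w for w in wells if w.slide == slide]
        test = next(w for w in sw if w.role == "test")
        negs = [w for w in sw if w.role == "negative"]
        # normalize out the positional artifact factor before comparing
        pvals = []
        for f in ("Fint3", "Fmph1", "NucSize"):
            a = test.cells[f].to_numpy()
            b = np.concatenate([w.cells[f].to_numpy() for w in negs])
            a = (a - a.mean()) / a.std()
            b = (b - b.mean()) / b.std()
            pvals.append(sps.ks_2samp(a, b).pvalue)
        assert max(pvals) > 0.01

    def test_ground_truth_mirrors_effect_table(self):
        effects = {"g0001": {"Fint1": Effect("shift", 1.0), "Tint1": Effect("shift", 0.0)}}
        cfg = ScreenConfig(n_genes=3, n_rows=3, n_cols=10, n_negative=6,
                           n_positive=2, cells_per_well_mean=40,
                           effect_table=effects, seed=2)
        _, truth = generate_primary_screen(cfg)
        assert truth.true_hits == {"g0001": {"Fint1"}}  # zero-size effect excluded


class TestNestedEffectTable:
    def test_groups_are_nested_or_disjoint(self):
        _, members = nested_effect_table()
        from endoscreen.synthetic import NESTED_FEATURE_GROUPS
        groups = [frozenset(v) for v in NESTED_FEATURE_GROUPS.values()]
        for a in groups:
            for b in groups:
                assert a <= b or b <= a or not (a & b)

    def test_effect_table_covers_group_members(self):
        table, members = nested_effect_table(genes_per_group=3)
        for name, genes in members.items():
            for g in genes:
                assert set(table[g]) == set(
                    dict(__import__("endoscreen.synthetic", fromlist=["x"]).NESTED_FEATURE_GROUPS)[name])


class TestSecondaryPlate:
    @pytest.mark.parametrize(
        "folds, quadrant",
        [((1.0, 1.0), "null"), ((1.5, 1.5), 1), ((1.0, 0.5), 2),
         ((0.5, 0.5), 3), ((0.5, 1.5), 4)],
    )
    def test_ground_truth_quadrants(self, folds, quadrant):
        plate = generate_secondary_plate(["gX"], {"gX": folds}, seed=1)
        assert plate.truth_quadrant["gX"] == quadrant

    def test_layout_counts(self):
        plate = generate_secondary_plate(["gA", "gB"], {}, seed=1)
        for _, sub in plate.wells.groupby("group"):
            counts = sub["role"].value_counts()
            assert counts["test"] == 3
            assert counts["negative"] == 6
            assert counts["positive"] == 3

    def test_bad_layout_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_secondary_plate(["gA"], {}, n_local_negatives=1)


class TestAnnotations:
    def test_planted_terms_exact(self):
        universe = [f"g{i}" for i in range(100)]
        planted = {"GO:X": universe[:10]}
        ann = generate_annotations(universe, 5, planted, seed=3)
        assert ann.term_to_genes["GO:X"] == set(universe[:10])
        # inverse map consistent
        for gene, terms in ann.gene_to_terms.items():
            for t in terms:
                assert gene in ann.term_to_genes[t]

    def test_planted_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_annotations(["g1"], 0, {"GO:X": ["g2"]})

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_annotations([], 1)


class TestInteractionNetwork:
    def test_full_module_edge_count(self):
        universe = [f"g{i}" for i in range(50)]
        edges = generate_interaction_network(universe, [universe[:6]], 0, seed=1)
        assert len(edges) == 15  # C(6,2)
        assert edges["confidence"].between(0, 1).all()

    def test_no_self_or_duplicate_edges(self):
        universe = [f"g{i}" for i in range(30)]
        edges = generate_interaction_network(universe, [], 100, seed=2)
        assert len(edges) == 100
        assert (edges["gene_a"] != edges["gene_b"]).all()
        keys = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert len(keys) == 100

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_interaction_network(["g1"], [["g1", "zz"]], 0)


class TestImages:
    def test_deterministic(self):
        c1, m1, n1, _ = generate_images(seed=9)
        c2, m2, n2, _ = generate_images(seed=9)
        for ch in c1:
            np.testing.assert_array_equal(c1[ch], c2[ch])
        np.testing.assert_array_equal(m1, m2)

    def test_minimum_dimensions_enforced(self):
        with pytest.raises(ConfigurationError):
            generate_images(shape=(64, 64))

    def test_masks_and_channels_consistent(self):
        channels, cmask, nmask, truth = generate_images(n_cells=2, seed=4)
        assert set(channels) == {"nuclear", "fluid", "tf", "surface"}
        assert channels["fluid"].dtype == np.uint16
        assert set(np.unique(cmask)) == {0, 1, 2}
        # every accepted spot lies inside its cell mask
        for ch in ("fluid", "tf"):
            for s in truth.spots[ch]:
                assert cmask[int(round(s["y"])), int(round(s["x"]))] == s["cell"]
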