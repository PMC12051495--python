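"""Pseudobulk construction, entropy/specificity, marker panels, composition."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import hdquant as hq


def small_adata(counts, types, condition="reference"):
    counts = np.asarray(counts)
    return ad.AnnData(
        X=counts,
        obs=pd.DataFrame({"cell_type": types, "condition": [condition] * len(types)},
                         index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(counts.shape[1])]),
    )


class TestBuildPseudobulk:
    def test_hand_arithmetic_with_pseudocount(self):
        # two cells of one type: summed {g0: 5, g1: 3} incl. pseudocount 1
        adata = small_adata([[3, 1], [1, 1]], ["t", "t"])
        pb = hq.build_pseudobulk(adata, {"t": "t", "u": "u"})
        # single-column profile normalises to per-million
        assert pb["reference"].loc["g0", "t"] == pytest.approx(625000.0)
        assert pb["reference"].loc["g1", "t"] == pytest.approx(375000.0)

    def test_empty_type_is_uniform_pseudocount_column(self):
        adata = small_adata([[3, 1]], ["t"])
        adata.obs["cell_type"] = pd.Categorical(["t"], categories=["t", "u"])
        # absent type has no cells; emulate by merging an unused label
        pb = hq.build_pseudobulk(adata, {"t": "t"})
        assert set(pb["reference"].columns) == {"t"}

    def test_merge_additivity(self):
        counts = [[4, 0], [0, 6], [2, 2]]
        adata = small_adata(counts, ["a", "b", "b"])
        merged = hq.build_pseudobulk(adata, {"a": "x", "b": "x"})["reference"]
        fine = hq.build_pseudobulk(adata, {"a": "a", "b": "b"})["reference"]
        # merged counts equal the sum of the fine counts, with the single
        # per-gene pseudocount applied once to the merged column
        raw_merged = np.array([4 + 0 + 2 + 1, 0 + 6 + 2 + 1])
        assert merged["x"].to_numpy() == pytest.approx(raw_merged / raw_merged.sum() * 1e6)
        assert set(fine.columns) == {"a", "b"}

    def test_unknown_label_rejected_by_name(self):
        adata = small_adata([[1, 1]], ["mystery"])
        with pytest.raises(ValueError, match="mystery"):
            hq.build_pseudobulk(adata, {"t": "t"})

    def test_conditions_kept_separate(self):
        counts = np.array([[10, 0], [0, 10]])
        adata = small_adata(counts, ["t", "t"])
        adata.obs["condition"] = ["reference", "disease"]
        pb = hq.build_pseudobulk(adata, {"t": "t"})
        assert pb["reference"].loc["g0", "t"] > pb["reference"].loc["g1", "t"]
        assert pb["disease"].loc["g1", "t"] > pb["disease"].loc["g0", "t"]


class TestSpecificity:
    def test_uniform_is_zero(self):
        profile = pd.DataFrame(np.full((1, 4), 250000.0), index=["g"],
                               columns=list("abcd"))
        out = hq.compute_specificity(profile)
        assert out.loc["g", "H"] == pytest.approx(2.0)
        assert out.loc["g", "s"] == pytest.approx(0.0)

    def test_point_mass_is_one(self):
        profile = pd.DataFrame([[1e6, 0.0, 0.0]], index=["g"], columns=list("abc"))
        out = hq.compute_specificity(profile)
        assert out.loc["g", "H"] == pytest.approx(0.0)
        assert out.loc["g", "s"] == pytest.approx(1.0)

    def test_hand_computed_half_quarter_quarter(self):
        profile = pd.DataFrame([[0.5, 0.25, 0.25]], index=["g"], columns=list("abc"))
        out = hq.compute_specificity(profile)
        assert out.loc["g", "H"] == pytest.approx(1.5, abs=1e-12)
        assert out.loc["g", "s"] == pytest.approx(1 - 1.5 / np.log2(3), abs=1e-12)

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            hq.compute_specificity(pd.DataFrame([[1.0]], columns=["a"]))

    def test_column_rescale_invariance(self):
        rng = np.random.default_rng(1)
        profile = pd.DataFrame(rng.lognormal(0, 1, (20, 4)), columns=list("abcd"))
        scaled = profile.copy()
        scaled["b"] *= 7.3  # a per-million renormalisation absorbs this
        scaled = scaled / scaled.sum(axis=0) * 1e6
        base = profile / profile.sum(axis=0) * 1e6
        # rescaling a single column by a positive constant is absorbed by the
        # per-million normalisation, leaving H and s untouched
        pd.testing.assert_frame_equal(
            hq.compute_specificity(scaled)[["H", "s", "home_type"]],
            hq.compute_specificity(base)[["H", "s", "home_type"]])
        pd.testing.assert_frame_equal(
            hq.compute_specificity(base * 2.0)[["H", "s", "home_type"]],
            hq.compute_specificity(base)[["H", "s", "home_type"]])

    def test_home_type_first_index_tiebreak(self):
        profile = pd.DataFrame([[0.4, 0.4, 0.2]], index=["g"], columns=list("abc"))
        assert hq.compute_specificity(profile).loc["g", "home_type"] == "a"


class TestSelectMarkers:
    spec = pd.DataFrame(
        {"H": [0.0] * 5,
         "s": [1.0, 0.30, 0.45, 0.45, 0.41],
         "home_type": ["A", "A", "A", "A", "B"],
         "home_tpm": [100.0, 500.0, 60.0, 49.0, 50.0]},
        index=["exclusive", "unspecific", "ok", "lowtpm", "edge"],
    )

    def test_gates_and_ranking(self):
        panel = hq.select_markers(self.spec, min_tpm=50, min_specificity=0.40, top_k=20)
        a = panel[panel.cell_type == "A"]
        assert list(a["gene"]) == ["exclusive", "ok"]  # s-descending
        assert "unspecific" not in set(panel["gene"])  # s=0.30 excluded
        assert "lowtpm" not in set(panel["gene"])      # 49 < 50 inclusive gate
        assert "edge" in set(panel["gene"])            # tpm 50 passes, s 0.41 passes

    def test_specificity_gate_is_strict(self):
        spec = self.spec.copy()
        spec.loc["edge", "s"] = 0.40
        panel = hq.select_markers(spec, min_tpm=50, min_specificity=0.40)
        assert "edge" not in set(panel["gene"])

    def test_bulk_detection_filter(self):
        detected = pd.Series(False, index=self.spec.index)
        detected["ok"] = True
        panel = hq.select_markers(self.spec, bulk_detected=detected)
        assert set(panel["gene"]) == {"ok"}

    def test_top_k_truncation_and_determinism(self):
        rng = np.random.default_rng(2)
        n = 50
        spec = pd.DataFrame(
            {"s": rng.uniform(0.41, 1.0, n), "H": 0.0,
             "home_type": "A", "home_tpm": rng.uniform(51, 500, n)},
            index=[f"g{i:02d}" for i in range(n)])
        p1 = hq.select_markers(spec, top_k=20)
        p2 = hq.select_markers(spec.sample(frac=1, random_state=0), top_k=20)
        assert len(p1) == 20
        assert list(p1["gene"]) == list(p2["gene"])  # order-invariant ranking
        assert (p1["s"].diff().dropna() <= 1e-12).all()

    def test_empty_cell_type_warns(self):
        spec = self.spec[self.spec.home_type == "A"].head(2).copy()
        spec["s"] = 0.1  # nothing passes
        with pytest.warns(UserWarning):
            panel = hq.select_markers(spec)
        assert panel.empty

    def test_recovers_planted_markers(self, pseudobulk, sc_reference, marker_panel):
        truth = sc_reference.uns["truth"]["marker_genes"]
        for ct, sub in marker_panel.groupby("cell_type"):
            assert set(sub["gene"]) <= set(truth[ct])


class TestEstimateComposition:
    def panel(self):
        return pd.DataFrame({"cell_type": ["A", "A", "B"], "rank": [1, 2, 1],
                             "gene": ["g0", "g1", "g2"], "s": 1.0, "home_tpm": 100.0})

    def bulk(self, cols):
        return pd.DataFrame(cols, index=["g0", "g1", "g2"])

    def test_reference_self_normalises_to_one(self):
        bulk = self.bulk({"r1": [10.0, 20, 30], "r2": [10.0, 20, 30], "t": [10.0, 20, 30]})
        est = hq.estimate_composition(bulk, self.panel(), ["r1", "r2"])
        assert est.loc["t"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_halved_markers_give_half(self):
        bulk = self.bulk({"r1": [10.0, 20, 30], "t": [5.0, 10, 30]})
        est = hq.estimate_composition(bulk, self.panel(), ["r1"])
        assert est.loc["t", "A"] == pytest.approx(0.5)
        assert est.loc["t", "B"] == pytest.approx(1.0)

    def test_linear_in_mixture_weight(self):
        bulk = self.bulk({"r1": [10.0, 20, 30], "x": [5.0, 10, 30], "y": [20.0, 40, 30]})
        est = hq.estimate_composition(bulk, self.panel(), ["r1"])
        alpha = 0.3
        mixed = self.bulk({"r1": [10.0, 20, 30],
                           "m": list(alpha * np.array([5.0, 10, 30])
                                     + (1 - alpha) * np.array([20.0, 40, 30]))})
        est_m = hq.estimate_composition(mixed, self.panel(), ["r1"])
        assert est_m.loc["m", "A"] == pytest.approx(
            alpha * est.loc["x", "A"] + (1 - alpha) * est.loc["y", "A"])

    def test_zero_reference_marker_dropped_with_warning(self):
        bulk = self.bulk({"r1": [0.0, 20, 30], "t": [5.0, 10, 30]})
        with pytest.warns(UserWarning):
            est = hq.estimate_composition(bulk, self.panel(), ["r1"])
        assert est.loc["t", "A"] == pytest.approx(0.5)  # only g1 remains

    def test_missing_panel_gene_rejected(self):
        bulk = self.bulk({"r1": [1.0, 2, 3]}).drop(index="g2")
        with pytest.raises(ValueError):
            hq.estimate_composition(bulk, self.panel(), ["r1"])

    def test_monotone_recovery_over_depletion_grid(self, pseudobulk, marker_panel):
        from conftest import mixture_proportions

        profiles = pseudobulk["reference"]
        types = profiles.columns
        means = []
        for depl in (1.0, 0.75, 0.5, 0.25):
            vals = []
            for seed in range(10):
                props = pd.DataFrame(
                    [mixture_proportions(1.0, types)] * 3
                    + [mixture_proportions(depl, types)] * 3,
                    columns=types, index=[f"s{i}" for i in range(6)])
                bulk = hq.simulate_bulk(props, profiles, noise_cv=0.1, seed=seed)
                est = hq.estimate_composition(bulk, marker_panel, ["s0", "s1", "s2"])
                vals.append(est.loc[["s3", "s4", "s5"], "type0"].mean())
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestCompareComposition:
    def test_identical_groups_overlap(self):
        comp = pd.DataFrame({"A": [1.0, 1.1, 0.9, 1.0, 1.1, 0.9]},
                            index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=comp.index)
        out = hq.compare_composition(comp, groups, reference_group="x")
        assert out["overlaps_reference"].all()

    def test_degenerate_point_intervals_disjoint(self):
        comp = pd.DataFrame({"A": [1.0, 1.0, 1.0, 0.5, 0.5, 0.5]},
                            index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["ref"] * 3 + ["dis"] * 3, index=comp.index)
        out = hq.compare_composition(comp, groups, reference_group="ref").set_index("group")
        assert not out.loc["dis", "overlaps_reference"]
        assert out.loc["ref", "overlaps_reference"]

    def test_depleted_type_flagged_others_not(self, pseudobulk, marker_panel):
        from conftest import mixture_proportions

        profiles = pseudobulk["reference"]
        types = profiles.columns
        hits, others_ok = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            props = pd.DataFrame(
                [mixture_proportions(1.0, types)] * 3
                + [mixture_proportions(0.5, types)] * 3,
                columns=types, index=[f"s{i}" for i in range(6)])
            bulk = hq.simulate_bulk(props, profiles, noise_cv=0.1, seed=100 + seed)
            est = hq.estimate_composition(bulk, marker_panel, ["s0", "s1", "s2"])
            groups = pd.Series(["ref"] * 3 + ["dis"] * 3, index=est.index)
            out = hq.compare_composition(est, groups, reference_group="ref")
            dis = out[out.group == "dis"].set_index("cell_type")
            hits += int(not dis.loc["type0", "overlaps_reference"])
        assert hits >= 0.9 * n_seeds
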