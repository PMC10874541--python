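import numpy as np
import pandas as pd
import pytest

from peroxiscreen.screen import (
    CutoffPair,
    analyze_screen,
    apply_cytotoxicity_filter,
    build_heatmap_table,
    categorize_compounds,
    compute_cutoffs,
    standardize_to_control,
    summarize_well,
    summarize_wells,
)
from peroxiscreen.synthetic import SceneSpec, make_effect, simulate_screen


def well_df(well_id, counts, dna=100.0, spots=None):
    n = len(counts)
    return pd.DataFrame(
        {
            "well_id": well_id,
            "cell_label": range(1, n + 1),
            "spot_count": counts,
            "spot_total_intensity": spots if spots is not None else [c * 10.0 for c in counts],
            "integrated_dna": dna,
        }
    )


def make_summaries(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "well_id", "compound_id", "replicate", "role", "cell_count",
            "mean_spot_count", "mean_spot_total_intensity", "mean_integrated_dna",
        ],
    )


class TestSummarizeWell:
    def test_arithmetic_means(self):
        s = summarize_well(well_df("w1", [2, 4, 6]))
        assert s.cell_count == 3
        assert s.mean_spot_count == pytest.approx(4.0)

    def test_empty_well(self):
        s = summarize_well(well_df("w", []), well_id="w")
        assert s.cell_count == 0
        assert np.isnan(s.mean_spot_count)

    def test_multiple_wells_rejected(self):
        df = pd.concat([well_df("a", [1]), well_df("b", [2])])
        with pytest.raises(ValueError):
            summarize_well(df)


class TestCytotoxicityFilter:
    def _summaries(self, compound_counts, control_count=2000.0):
        rows = []
        for rep in (1, 2, 3):
            rows.append([f"c{rep}", "control", rep, "control", control_count, 10, 100, 1e4])
            for cid, count in compound_counts.items():
                rows.append([f"{cid}{rep}", cid, rep, "compound", count, 10, 100, 1e4])
        return make_summaries(rows)

    def test_below_quarter_is_cytotoxic(self):
        out = apply_cytotoxicity_filter(self._summaries({"x": 499}))
        assert out[out["compound_id"] == "x"]["cytotoxic"].all()

    def test_exactly_quarter_retained(self):
        out = apply_cytotoxicity_filter(self._summaries({"x": 500}))
        assert not out[out["compound_id"] == "x"]["cytotoxic"].any()

    def test_equal_to_control_retained(self):
        out = apply_cytotoxicity_filter(self._summaries({"x": 2000}))
        assert not out[out["compound_id"] == "x"]["cytotoxic"].any()

    def test_zero_cell_well_always_cytotoxic(self):
        df = self._summaries({"x": 5000})
        df.loc[(df["compound_id"] == "x") & (df["replicate"] == 2), "cell_count"] = 0
        out = apply_cytotoxicity_filter(df)
        assert out[out["compound_id"] == "x"]["cytotoxic"].all()

    def test_no_controls_rejected(self):
        df = self._summaries({"x": 100})
        with pytest.raises(ValueError, match="control"):
            apply_cytotoxicity_filter(df[df["role"] != "control"])

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(0)
        counts = {f"c{i:02d}": float(rng.integers(100, 3000)) for i in range(30)}
        df = apply_cytotoxicity_filter(self._summaries(counts))
        ctrl_avg = 2000.0
        for cid, count in counts.items():
            expected = count < 0.25 * ctrl_avg
            assert df[df["compound_id"] == cid]["cytotoxic"].all() == expected


class TestStandardizeToControl:
    def _summaries(self):
        rows = []
        for rep in (1, 2, 3):
            rows.append([f"c{rep}", "control", rep, "control", 2000, 10.0, 100.0, 1e4])
            rows.append([f"a{rep}", "cmpdA", rep, "compound", 2000, 10.0, 100.0, 1e4])
            rows.append([f"b{rep}", "cmpdB", rep, "compound", 1000, 18.0, 180.0, 2e4])
        return make_summaries(rows)

    def test_identity_compound_is_one(self):
        std = standardize_to_control(self._summaries()).set_index("compound_id")
        for col in ("std_peroxisome", "std_dna", "rel_cell_count", "rel_spot_count"):
            assert std.loc["cmpdA", col] == pytest.approx(1.0)

    def test_fold_changes(self):
        std = standardize_to_control(self._summaries()).set_index("compound_id")
        assert std.loc["cmpdB", "std_peroxisome"] == pytest.approx(1.8)
        assert std.loc["cmpdB", "std_dna"] == pytest.approx(2.0)
        assert std.loc["cmpdB", "rel_cell_count"] == pytest.approx(0.5)

    def test_control_fixed_point(self):
        # standardizing control wells against themselves gives exactly 1
        df = self._summaries()
        ctrl_as_compound = df.copy()
        ctrl_as_compound.loc[ctrl_as_compound["compound_id"] == "control", "role"] = "compound"
        both = pd.concat([df[df["role"] == "control"], ctrl_as_compound])
        std = standardize_to_control(both).set_index("compound_id")
        assert std.loc["control", "std_peroxisome"] == pytest.approx(1.0)

    def test_zero_control_mean_rejected(self):
        df = self._summaries()
        df.loc[df["role"] == "control", "mean_spot_total_intensity"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            standardize_to_control(df)


class TestComputeCutoffs:
    def test_linear_interpolation_values(self):
        cut = compute_cutoffs(np.arange(1.0, 101.0))
        assert cut.low == pytest.approx(5.95)
        assert cut.high == pytest.approx(95.05)

    def test_matches_independent_percentile(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 0.2, size=500)
        cut = compute_cutoffs(vals)
        srt = np.sort(vals)
        # brute-force linear interpolation of the 5th/95th percentiles
        def pctl(q):
            pos = q / 100 * (len(srt) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return srt[lo] * (1 - frac) + srt[min(lo + 1, len(srt) - 1)] * frac

        assert cut.low == pytest.approx(pctl(5), abs=1e-12)
        assert cut.high == pytest.approx(pctl(95), abs=1e-12)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            compute_cutoffs(np.full(50, 1.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            compute_cutoffs(np.arange(10.0))


class TestCategorizeCompounds:
    @pytest.fixture()
    def cutoffs(self):
        return CutoffPair(0.9, 1.1), CutoffPair(0.95, 1.05)  # perox, dna

    def _results(self, perox, dna):
        return pd.DataFrame(
            {
                "compound_id": [f"c{i}" for i in range(len(perox))],
                "std_peroxisome": perox,
                "std_dna": dna,
                "rel_cell_count": 1.0,
                "rel_spot_count": perox,
            }
        )

    def test_center_is_none(self, cutoffs):
        out = categorize_compounds(self._results([1.0], [1.0]), *cutoffs)
        assert out["category"].iloc[0] == "none"

    def test_dna_above_band_is_A(self, cutoffs):
        out = categorize_compounds(self._results([1.5], [1.2]), *cutoffs)
        assert out["category"].iloc[0] == "A"

    def test_perox_up_dna_in_band_is_B(self, cutoffs):
        out = categorize_compounds(self._results([1.5], [1.0]), *cutoffs)
        assert out["category"].iloc[0] == "B"

    def test_perox_down_dna_in_band_is_C(self, cutoffs):
        out = categorize_compounds(self._results([0.5], [1.0]), *cutoffs)
        assert out["category"].iloc[0] == "C"

    def test_dna_below_band_is_none(self, cutoffs):
        out = categorize_compounds(self._results([1.5], [0.5]), *cutoffs)
        assert out["category"].iloc[0] == "none"


class TestHeatmapTable:
    def test_empty_hits(self):
        df = pd.DataFrame(
            {
                "compound_id": ["a"], "category": ["none"], "std_peroxisome": [1.0],
                "std_dna": [1.0], "rel_cell_count": [1.0], "rel_spot_count": [1.0],
            }
        )
        assert len(build_heatmap_table(df)) == 0

    def test_sorted_by_category_then_signal(self):
        df = pd.DataFrame(
            {
                "compound_id": ["a", "b", "c"],
                "category": ["B", "A", "B"],
                "std_peroxisome": [1.5, 1.3, 1.9],
                "std_dna": [1.0, 1.4, 1.0],
                "rel_cell_count": [1.0, 0.7, 1.0],
                "rel_spot_count": [1.4, 1.2, 1.8],
            }
        )
        out = build_heatmap_table(df)
        assert list(out["compound_id"]) == ["b", "c", "a"]


@pytest.fixture(scope="module")
def planted_screen():
    effects = (
            [make_effect(f"A{i}", "A_cell_cycle") for i in range(4)]
        + [make_effect(f"B{i}", "B_perox_up") for i in range(4)]
        + [make_effect(f"C{i}", "C_perox_down") for i in range(4)]
        + [make_effect(f"T{i}", "cytotoxic") for i in range(2)]
        + [make_effect(f"N{i}", "null") for i in range(86)]
    )
    ds = simulate_screen(100, effects, 3, "table", SceneSpec(), seed=17,
                         cells_per_well=1000)
    results, cutoffs = analyze_screen(ds.cells, ds.plate_map)
    return ds, results, cutoffs


class TestEndToEndScreen:
    def test_cytotoxic_excluded_before_categorization(self, planted_screen):
        ds, results, _ = planted_screen
        merged = results.merge(ds.truth, on="compound_id")
        tox = merged[merged["archetype"] == "cytotoxic"]
        assert (tox["category"] == "excluded").all()
        assert tox["cytotoxic"].all()
        assert not merged[merged["category"].isin(["A", "B", "C"])]["cytotoxic"].any()

    def test_planted_archetypes_recovered(self, planted_screen):
        ds, results, _ = planted_screen
        merged = results.merge(ds.truth, on="compound_id")
        for arch, cat in (("A_cell_cycle", "A"), ("B_perox_up", "B"), ("C_perox_down", "C")):
            sub = merged[merged["archetype"] == arch]
            assert (sub["category"] == cat).mean() >= 0.75

    def test_heatmap_rows_match_generative_construction(self, planted_screen):
        ds, results, _ = planted_screen
        merged = results.merge(ds.truth, on="compound_id")
        b_rows = merged[(merged["archetype"] == "B_perox_up") & (merged["category"] == "B")]
        assert (b_rows["rel_spot_count"] > 1).all()
        assert (b_rows["std_peroxisome"] > 1).all()
        a_rows = merged[(merged["archetype"] == "A_cell_cycle") & (merged["category"] == "A")]
        assert (a_rows["std_dna"] > 1).all()

    def test_scale_invariance(self, planted_screen):
        ds, results, _ = planted_screen
        scaled = ds.cells.copy()
        for col in ("integrated_dna", "spot_total_intensity"):
            scaled[col] = scaled[col] * 3.7
        results2, _ = analyze_screen(scaled, ds.plate_map)
        pd.testing.assert_series_equal(results["category"], results2["category"])
        np.testing.assert_allclose(
            results["std_peroxisome"], results2["std_peroxisome"], rtol=1e-12
        )

    def test_percentiles_match_brute_force(self, planted_screen):
        ds, results, cutoffs = planted_screen
        wells = summarize_wells(ds.cells, ds.plate_map)
        wells = apply_cytotoxicity_filter(wells)
        std = standardize_to_control(wells)
        assert cutoffs["peroxisome"].low == pytest.approx(
            np.percentile(std["std_peroxisome"], 5), abs=1e-12
        )
        assert cutoffs["dna"].high == pytest.approx(
            np.percentile(std["std_dna"], 95), abs=1e-12
        )


class TestNullCalibration:
    def test_null_screen_flags_about_10pct_on_perox_axis(self):
        effects = [make_effect(f"N{i}", "null") for i in range(300)]
        ds = simulate_screen(300, effects, 3, "table", SceneSpec(), seed=23,
                             cells_per_well=500)
        results, cutoffs = analyze_screen(ds.cells, ds.plate_map)
        outside = (
            (results["std_peroxisome"] < cutoffs["peroxisome"].low)
            | (results["std_peroxisome"] > cutoffs["peroxisome"].high)
        ).mean()
        assert outside == pytest.approx(0.10, abs=0.03)
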