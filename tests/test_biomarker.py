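"""qPCR arm: geNorm stability, -ddCt, panel validation, clustering."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from sagescope.biomarker import (
    cluster_panel,
    ct_matrix,
    ddct,
    dose_dependence,
    genorm_m,
    group_ttest,
    normalization_factor,
    panel_calls,
    read_ct_csv,
    validate_panel,
    write_ct_csv,
)


def long_table(ct_by_gene_sample, groups=None):
    """Build a long-format Ct table from {gene: {sample: ct}} (1 replicate)."""
    rows = []
    for gene, samples in ct_by_gene_sample.items():
        for sample, ct in samples.items():
            group = (groups or {}).get(sample, "control" if sample.startswith("C") else "treated")
            rows.append({"gene": gene, "sample": sample, "group": group,
                         "replicate": 1, "ct": ct})
    return pd.DataFrame(rows)


class TestGenorm:
    def test_constant_offsets_give_zero_m(self):
        # three genes whose Ct profiles differ by constants across samples
        table = long_table({
            "a": {"C1": 20.0, "C2": 21.0, "C3": 19.5},
            "b": {"C1": 22.0, "C2": 23.0, "C3": 21.5},
            "c": {"C1": 25.0, "C2": 26.0, "C3": 24.5},
        })
        result = genorm_m(table)
        assert np.allclose(result["m_value"], 0.0)

    def test_toy_matrix_matches_pairwise_sd_oracle(self):
        ct = {
            "a": {"S1": 20.0, "S2": 21.0, "S3": 19.0, "S4": 22.0},
            "b": {"S1": 22.5, "S2": 23.0, "S3": 21.0, "S4": 24.5},
            "c": {"S1": 18.0, "S2": 20.0, "S3": 17.5, "S4": 19.0},
        }
        table = long_table(ct)
        result = genorm_m(table)
        genes = list(ct)
        for j in genes:
            sds = []
            for k in genes:
                if k == j:
                    continue
                # log2 ratio j/k across samples is Ct_k - Ct_j
                ratios = [ct[k][s] - ct[j][s] for s in ct[j]]
                mean = sum(ratios) / len(ratios)
                sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1))
                sds.append(sd)
            assert result.loc[j, "m_value"] == pytest.approx(sum(sds) / len(sds))
        assert list(result["rank"]) == sorted(result["rank"])

    def test_per_sample_shift_invariance(self):
        ct = {
            "a": {"S1": 20.0, "S2": 21.0, "S3": 19.0},
            "b": {"S1": 22.5, "S2": 23.0, "S3": 21.0},
            "c": {"S1": 18.0, "S2": 20.0, "S3": 17.5},
        }
        shifted = {g: {s: v + (3.0 if s == "S2" else 0.0) for s, v in d.items()}
                   for g, d in ct.items()}
        m1 = genorm_m(long_table(ct))["m_value"]
        m2 = genorm_m(long_table(shifted))["m_value"]
        assert np.allclose(m1, m2)

    def test_too_few_candidates_rejected(self):
        table = long_table({"a": {"S1": 20.0, "S2": 21.0}, "b": {"S1": 22.0, "S2": 23.0}})
        with pytest.raises(ValueError, match="3 candidate"):
            genorm_m(table)

    def test_missing_cell_names_the_gap(self):
        table = long_table({
            "a": {"S1": 20.0, "S2": 21.0},
            "b": {"S1": 22.0, "S2": 23.0},
            "c": {"S1": 18.0},
        })
        with pytest.raises(ValueError, match="'c'.*'S2'"):
            genorm_m(table)


class TestNormalizationFactor:
    def test_single_reference(self):
        table = long_table({"r1": {"S1": 20.0}})
        nf = normalization_factor(table, ["r1"])
        assert nf["S1"] == pytest.approx(2.0 ** -20)

    def test_geometric_mean_on_log_scale(self):
        table = long_table({"r1": {"S1": 10.0}, "r2": {"S1": 20.0}})
        nf = normalization_factor(table, ["r1", "r2"])
        assert nf["S1"] == pytest.approx(2.0 ** -15)

    def test_three_references_match_brute_force(self):
        cts = {"r1": 18.2, "r2": 21.7, "r3": 19.9}
        table = long_table({g: {"S1": v} for g, v in cts.items()})
        nf = normalization_factor(table, list(cts))
        brute = (2.0 ** -cts["r1"] * 2.0 ** -cts["r2"] * 2.0 ** -cts["r3"]) ** (1 / 3)
        assert nf["S1"] == pytest.approx(brute)

    def test_missing_reference_is_an_error(self):
        table = long_table({"r1": {"S1": 20.0}})
        with pytest.raises(ValueError):
            normalization_factor(table, ["r1", "r2"])


class TestDdct:
    def test_one_cycle_drop_doubles(self):
        table = long_table({
            "tgt": {"C1": 24.0, "C2": 24.0, "S1": 23.0},
            "ref": {"C1": 18.0, "C2": 18.0, "S1": 18.0},
        })
        assert ddct(table, "tgt", ["ref"], "S1") == pytest.approx(1.0)

    def test_global_shift_cancels(self):
        table = long_table({
            "tgt": {"C1": 24.0, "C2": 24.0, "S1": 23.0},
            "ref": {"C1": 18.0, "C2": 18.0, "S1": 17.0},
        })
        assert ddct(table, "tgt", ["ref"], "S1") == pytest.approx(0.0)

    def test_toy_table_matches_arithmetic_oracle(self):
        ct = {
            "tgt": {"C1": 24.1, "C2": 24.6, "C3": 24.3, "S1": 22.0},
            "r1": {"C1": 18.0, "C2": 18.3, "C3": 18.1, "S1": 18.2},
            "r2": {"C1": 20.5, "C2": 20.8, "C3": 20.6, "S1": 20.7},
        }
        table = long_table(ct)
        dct = {s: ct["tgt"][s] - (ct["r1"][s] + ct["r2"][s]) / 2 for s in ct["tgt"]}
        expected = (dct["C1"] + dct["C2"] + dct["C3"]) / 3 - dct["S1"]
        assert ddct(table, "tgt", ["r1", "r2"], "S1") == pytest.approx(expected)

    def test_frozen_fixture_matches_spreadsheet_oracle(self, frozen_ct_fixture):
        """Replicates averaged on the Ct scale, then plain arithmetic."""
        table = frozen_ct_fixture
        avg = {}
        for (gene, sample), grp in table.groupby(["gene", "sample"]):
            avg[(gene, sample)] = sum(grp["ct"]) / len(grp)
        controls = ["C1", "C2", "C3"]
        for target in ("tgt1", "tgt2"):
            for treated in ("S1", "S2", "S3"):
                def dct(sample):
                    ref = (avg[("ref1", sample)] + avg[("ref2", sample)]) / 2
                    return avg[(target, sample)] - ref
                expected = sum(dct(c) for c in controls) / 3 - dct(treated)
                got = ddct(table, target, ["ref1", "ref2"], treated)
                assert got == pytest.approx(expected)

    def test_empty_control_group_rejected(self):
        table = long_table({"tgt": {"S1": 23.0}, "ref": {"S1": 18.0}})
        with pytest.raises(ValueError, match="control"):
            ddct(table, "tgt", ["ref"], "S1")

    def test_panel_calls_shape(self, frozen_ct_fixture):
        calls = panel_calls(frozen_ct_fixture, ["tgt1", "tgt2"], ["ref1", "ref2"])
        assert calls.shape == (2, 3)
        assert list(calls.index) == ["tgt1", "tgt2"]
        # tgt1 drops ~1.7 cycles -> up; tgt2 rises -> down
        assert (calls.loc["tgt1"] > 0).all()
        assert (calls.loc["tgt2"] < 0).all()


class TestPanelValidation:
    def test_all_individuals_qualify(self):
        calls = pd.DataFrame({f"S{i}": [2.0] for i in range(1, 10)}, index=["g1"])
        result = validate_panel(calls)
        assert result.loc["g1", "validated"] and result.loc["g1", "n_qualifying"] == 9

    def test_four_of_nine_fails_min_five(self):
        values = [1.5] * 4 + [0.2] * 5
        calls = pd.DataFrame([values], index=["g1"], columns=[f"S{i}" for i in range(9)])
        result = validate_panel(calls, fold_threshold=2, min_individuals=5)
        assert not result.loc["g1", "validated"]
        assert result.loc["g1", "n_qualifying"] == 4

    def test_random_matrix_matches_brute_recount(self, rng):
        calls = pd.DataFrame(
            rng.normal(1.0, 1.5, size=(20, 9)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"S{i}" for i in range(9)],
        )
        result = validate_panel(calls, fold_threshold=2, min_individuals=5)
        for gene in calls.index:
            n = sum(1 for v in calls.loc[gene] if v >= 1.0)
            assert result.loc[gene, "n_qualifying"] == n
            assert result.loc[gene, "validated"] == (n >= 5)

    def test_thresholds_are_monotone(self, rng):
        calls = pd.DataFrame(rng.normal(1.0, 1.0, size=(15, 9)))
        base = set(validate_panel(calls, 2, 5).query("validated").index)
        assert set(validate_panel(calls, 3, 5).query("validated").index) <= base
        assert set(validate_panel(calls, 2, 7).query("validated").index) <= base


class TestDoseDependence:
    def test_equal_means_are_not_dose_dependent(self):
        low = pd.Series({"g1": 1.0})
        assert not dose_dependence(low, low.copy()).loc["g1"]

    def test_any_increase_counts(self):
        low = pd.Series({"g1": 1.0})
        high = pd.Series({"g1": 1.0 + 1e-9})
        assert dose_dependence(low, high).loc["g1"]

    def test_random_table_matches_elementwise_comparison(self, rng):
        genes = [f"g{i}" for i in range(30)]
        low = pd.Series(rng.normal(1, 1, 30), index=genes)
        high = pd.Series(rng.normal(1.5, 1, 30), index=genes)
        flags = dose_dependence(low, high)
        for g in genes:
            assert flags.loc[g] == (high[g] > low[g])


class TestGroupTtest:
    def test_identical_groups_give_p_one(self):
        assert group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_textbook_examples_match_t_distribution(self):
        # reference p-values computed independently from the t CDF
        assert group_ttest([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.3153335962, abs=1e-8)
        assert group_ttest([5.1, 4.9, 6.0, 5.5, 5.8], [4.2, 4.8, 4.1, 4.5]) == pytest.approx(
            0.0059359770, abs=1e-8
        )

    def test_swapping_groups_preserves_p(self):
        a, b = [1.2, 3.4, 2.2, 4.0], [2.0, 2.5, 1.0]
        assert group_ttest(a, b) == pytest.approx(group_ttest(b, a))

    def test_degenerate_variance_convention(self):
        assert group_ttest([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert group_ttest([2.0, 2.0], [3.0, 3.0]) == 0.0

    def test_single_value_groups_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [1.0, 2.0])


class TestClusterPanel:
    def test_identical_columns_merge_first_at_zero(self, rng):
        base = rng.normal(0, 1, 6)
        matrix = pd.DataFrame(
            {"x1": base, "x2": base, "y": rng.normal(5, 1, 6)},
            index=[f"g{i}" for i in range(6)],
        )
        result = cluster_panel(matrix, distance="euclidean")
        first_merge = result.col_linkage[0]
        assert first_merge[2] == pytest.approx(0.0)
        merged = {int(first_merge[0]), int(first_merge[1])}
        assert merged == {0, 1}  # the two identical columns

    def test_one_dimensional_toy_agglomeration(self):
        # points {0, 1, 10} duplicated into two identical columns so every
        # pairwise Euclidean distance scales by sqrt(2):
        # merge (0,1) at sqrt(2), then with 10 at average distance 9.5*sqrt(2)
        matrix = pd.DataFrame({"c1": [0.0, 1.0, 10.0], "c2": [0.0, 1.0, 10.0]},
                              index=["p0", "p1", "p10"])
        result = cluster_panel(matrix, distance="euclidean", method="average")
        heights = sorted(result.row_linkage[:, 2])
        assert heights[0] == pytest.approx(math.sqrt(2) * 1.0)
        assert heights[1] == pytest.approx(math.sqrt(2) * 9.5)

    def test_outlier_condition_separates_last(self, rng):
        """A strongly up-regulated condition splits off at the root,
        the structure expected when one treatment drives a biomarker
        panel that other treatments leave flat or down."""
        n_genes = 14
        data = {
            "arsenic": rng.normal(3.0, 0.3, n_genes),
            "e2": rng.normal(-0.5, 0.3, n_genes),
            "kt11": rng.normal(-0.3, 0.3, n_genes),
            "tcdd": rng.normal(0.0, 0.3, n_genes),
        }
        matrix = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])
        result = cluster_panel(matrix, distance="euclidean")
        # the root merge joins the arsenic singleton with the rest
        root = result.col_linkage[-1]
        n = matrix.shape[1]
        sizes = {int(root[0]): None, int(root[1]): None}
        singletons = [i for i in sizes if i < n]
        assert singletons == [list(matrix.columns).index("arsenic")]

    def test_newick_trees_are_parseable_with_all_leaves(self, rng):
        matrix = pd.DataFrame(
            rng.normal(0, 1, size=(5, 4)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"cond{i}" for i in range(4)],
        )
        result = cluster_panel(matrix, distance="euclidean")
        tree = Phylo.read(io.StringIO(result.row_newick), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set(matrix.index)

    def test_non_finite_entries_rejected(self):
        matrix = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cluster_panel(matrix)


def test_ct_csv_round_trip(frozen_ct_fixture, tmp_path):
    path = tmp_path / "ct.csv"
    write_ct_csv(frozen_ct_fixture, path)
    loaded = read_ct_csv(path)
    pd.testing.assert_frame_equal(
        loaded.sort_values(["gene", "sample", "replicate"]).reset_index(drop=True),
        frozen_ct_fixture[loaded.columns]
        .sort_values(["gene", "sample", "replicate"])
        .reset_index(drop=True),
    )


def test_ct_matrix_averages_replicates(frozen_ct_fixture):
    mat = ct_matrix(frozen_ct_fixture)
    assert mat.loc["tgt1", "C1"] == pytest.approx((24.1 + 24.3) / 2)
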