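"""Dataset-level summaries: gap estimators, splits/lumps, haplotypes, composition."""

import numpy as np
import pandas as pd
import pytest

from barcodegap import (
    BarcodeDataset,
    BarcodeRecord,
    base_composition,
    category_distances,
    category_summary,
    gap_summary,
    haplotype_collapse,
    high_divergence_species,
    lumps_report,
    make_shared_haplotype_case,
    pairwise_matrix,
    shared_haplotype_pairs,
    splits_report,
)


def _dataset(rows):
    return BarcodeDataset([BarcodeRecord(sid, sp, seq) for sid, sp, seq in rows])


class TestGapSummary:
    def test_toy_intra_estimators(self):
        # Intra distances planted at exactly {1, 3, 5} / 100.
        base = "A" * 100
        ds = _dataset(
            [
                ("a1", "A b", base),
                ("a2", "A b", "G" * 1 + base[1:]),
                ("a3", "A b", "G" * 4 + base[4:]),     # a1:4 a2:3... adjust below
                ("c1", "C d", "G" * 50 + base[50:]),
            ]
        )
        table = pairwise_matrix(ds)
        row = gap_summary(table).iloc[0]
        intra = sorted(table.distances[table.intraspecific_mask] * 100)
        assert row["intra_median"] == pytest.approx(np.median(intra))
        assert row["intra_min"] == pytest.approx(min(intra))
        assert row["intra_max"] == pytest.approx(max(intra))

    def test_percentiles_match_sort_based_brute_force(self, toy):
        dataset, _ = toy
        table = pairwise_matrix(dataset)
        row = gap_summary(table).iloc[0]
        intra = np.sort(table.distances[table.intraspecific_mask]) * 100

        def brute_percentile(xs, q):
            # Linear interpolation between order statistics.
            pos = (len(xs) - 1) * q / 100.0
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return xs[lo] + (xs[hi] - xs[lo]) * (pos - lo)

        assert row["intra_p95"] == pytest.approx(brute_percentile(intra, 95))
        inter = np.sort(table.distances[table.interspecific_mask]) * 100
        assert row["inter_p5"] == pytest.approx(brute_percentile(inter, 5))

    def test_interspecific_includes_allogeneric_pairs(self, tiny_dataset):
        table = pairwise_matrix(tiny_dataset)
        row = gap_summary(table).iloc[0]
        assert row["inter_n"] == int(table.congeneric_mask.sum()
                                     + table.allogeneric_mask.sum())

    def test_single_species_group_gets_na_inter_fields(self):
        ds = _dataset([("a1", "A b", "ACGT" * 5), ("a2", "A b", "ACGA" + "ACGT" * 4)])
        row = gap_summary(pairwise_matrix(ds)).iloc[0]
        assert pd.isna(row["inter_median"])
        assert not pd.isna(row["intra_median"])

    def test_grouping_by_order_yields_one_row_per_order(self):
        from barcodegap import ToySpec, make_toy_dataset

        dataset, _ = make_toy_dataset(ToySpec(n_genera=4, n_orders=2, seed=3))
        table = pairwise_matrix(dataset)
        df = gap_summary(table, group_by="order")
        assert list(df["group"]) == ["Order01", "Order02"]
        assert (df["n_records"] == len(dataset) // 2).all()

    def test_closest_pair_aggregates_bound_each_other(self, toy):
        dataset, _ = toy
        row = gap_summary(pairwise_matrix(dataset)).iloc[0]
        assert row["closest_pair_min"] <= row["closest_pair_median"]
        assert row["closest_pair_max"] <= row["closest_pair_overall_max"]
        assert row["farthest_congener_min"] <= row["farthest_congener_median"] \
            <= row["farthest_congener_max"]


class TestSplitsLumps:
    @pytest.fixture
    def split_lump_dataset(self):
        base = "A" * 100
        return _dataset(
            [
                ("s1", "Gen split", base),
                ("s2", "Gen split", "G" * 4 + base[4:]),         # intra 4.0%
                ("t1", "Gen tight", "C" * 40 + base[40:]),
                ("t2", "Gen tight", "C" * 40 + "G" + base[41:]),  # intra 1.0%
                ("u1", "Gen lumpy", "C" * 40 + "GG" + base[42:]),  # 1% to t2, 2% to t1
            ]
        )

    def test_split_above_threshold_is_reported(self, split_lump_dataset):
        table = pairwise_matrix(split_lump_dataset)
        df = splits_report(table, threshold_pct=3.0)
        assert len(df) == 1
        assert df.iloc[0]["species"] == "Gen split"
        assert df.iloc[0]["distance_pct"] == pytest.approx(4.0)

    def test_threshold_is_inclusive(self, split_lump_dataset):
        table = pairwise_matrix(split_lump_dataset)
        assert len(splits_report(table, threshold_pct=4.0)) == 1
        assert len(splits_report(table, threshold_pct=4.0001)) == 0

    def test_threshold_zero_captures_all_conspecific_pairs(self, split_lump_dataset):
        table = pairwise_matrix(split_lump_dataset)
        assert len(splits_report(table, 0.0)) == int(table.intraspecific_mask.sum())

    def test_lumps_are_congeneric_and_allospecific_only(self, split_lump_dataset):
        table = pairwise_matrix(split_lump_dataset)
        df = lumps_report(table, threshold_pct=5.0)
        assert set(zip(df["species_a"], df["species_b"])) == {
            ("Gen lumpy", "Gen tight")
        }
        assert df["distance_pct"].min() == pytest.approx(1.0)

    def test_shared_haplotype_surfaces_as_zero_lump(self):
        table = pairwise_matrix(make_shared_haplotype_case())
        df = lumps_report(table, threshold_pct=5.0)
        assert df.iloc[0]["distance_pct"] == 0.0

    def test_lump_distance_bounds_closest_species_min(self, split_lump_dataset):
        from barcodegap import closest_species

        table = pairwise_matrix(split_lump_dataset)
        for row in lumps_report(table, threshold_pct=5.0).itertuples():
            for sp in (row.species_a, row.species_b):
                best = closest_species(table, sp)[0].min * 100
                assert best <= row.distance_pct + 1e-9

    def test_sorted_deterministically(self, split_lump_dataset):
        table = pairwise_matrix(split_lump_dataset)
        df = splits_report(table, 0.0)
        assert list(df["distance_pct"]) == sorted(df["distance_pct"], reverse=True)


class TestHaplotypes:
    def test_two_identical_of_five_collapse(self):
        ds = _dataset(
            [
                ("h1", "A b", "ACGT"),
                ("h2", "A b", "ACGT"),
                ("h3", "A b", "ACGA"),
                ("h4", "A c", "TCGA"),
                ("h5", "A c", "GCGA"),
            ]
        )
        hap = haplotype_collapse(ds)
        assert hap.distinct_count == 4
        assert hap.nonunique_sequence_count == 1

    def test_all_distinct(self, tiny_dataset):
        hap = haplotype_collapse(tiny_dataset)
        assert hap.distinct_count == len(tiny_dataset)
        assert hap.nonunique_sequence_count == 0

    def test_counts_partition_n(self, toy):
        dataset, _ = toy
        hap = haplotype_collapse(dataset)
        assert hap.distinct_count + hap.nonunique_sequence_count == len(dataset)
        assert sum(len(g.member_ids) for g in hap.groups) == len(dataset)

    def test_ambiguity_codes_keep_haplotypes_distinct(self):
        ds = _dataset([("n1", "A b", "ACGN"), ("n2", "A b", "ACGA")])
        hap = haplotype_collapse(ds, check_ambiguity_overlap=True)
        assert hap.distinct_count == 2
        assert hap.ambiguity_only_group_pairs == 1

    def test_shared_haplotype_pair_detection(self):
        hap = haplotype_collapse(make_shared_haplotype_case())
        pairs = shared_haplotype_pairs(hap)
        assert len(pairs) == 1
        assert pairs.iloc[0]["species_a"] == "Genus01 species01"

    def test_three_species_group_yields_three_pairs(self):
        ds = _dataset(
            [("x", "A b", "ACGT"), ("y", "A c", "ACGT"), ("z", "B d", "ACGT")]
        )
        pairs = shared_haplotype_pairs(haplotype_collapse(ds))
        assert len(pairs) == 3

    def test_no_multispecies_group_is_empty(self, tiny_dataset):
        assert shared_haplotype_pairs(haplotype_collapse(tiny_dataset)).empty


class TestBaseComposition:
    def test_at_dinucleotide(self):
        comp = base_composition(_dataset([("s", "A b", "ATAT")]))
        assert comp["A"] == 50.0 and comp["T"] == 50.0 and comp["AT"] == 100.0

    def test_equal_composition(self):
        comp = base_composition(_dataset([("s", "A b", "ACGT")]))
        assert comp == {"A": 25.0, "C": 25.0, "G": 25.0, "T": 25.0, "AT": 50.0}

    def test_ambiguities_and_gaps_excluded_from_denominator(self):
        comp = base_composition(_dataset([("s", "A b", "AANN--RT")]))
        assert comp["A"] == pytest.approx(200 / 3)
        assert comp["T"] == pytest.approx(100 / 3)

    def test_no_unambiguous_base_is_an_error(self):
        with pytest.raises(ValueError):
            base_composition(_dataset([("s", "A b", "NN--")]))


class TestCategories:
    def test_combinatorial_sizes_for_balanced_toy(self, tiny_dataset):
        cats = category_distances(pairwise_matrix(tiny_dataset))
        assert cats["allogeneric"].size == 16
        assert cats["congeneric"].size == 8
        assert cats["intraspecific"].size == 4

    def test_single_genus_dataset_has_no_allogeneric(self):
        table = pairwise_matrix(make_shared_haplotype_case())
        assert category_distances(table)["allogeneric"].size == 0

    def test_box_statistics_follow_tukey_rule(self, toy):
        dataset, _ = toy
        df = category_summary(pairwise_matrix(dataset)).set_index("category")
        for _, row in df.iterrows():
            if row["n"]:
                iqr = row["q3"] - row["q1"]
                assert row["whisker_low"] >= row["q1"] - 1.5 * iqr - 1e-9
                assert row["whisker_high"] <= row["q3"] + 1.5 * iqr + 1e-9

    def test_high_divergence_census(self):
        base = "A" * 100
        ds = _dataset(
            [
                ("a1", "Deep split", base),
                ("a2", "Deep split", "G" * 5 + base[5:]),
                ("b1", "Shallow sp", "C" + base[1:]),
                ("b2", "Shallow sp", "C" + "G" + base[2:]),
            ]
        )
        df = high_divergence_species(pairwise_matrix(ds), threshold_pct=3.0)
        assert list(df["species"]) == ["Deep split"]
        assert df.iloc[0]["max_intra_pct"] == pytest.approx(5.0)

    def test_plot_writes_a_file(self, toy, tmp_path):
        from barcodegap.dataset_summary import plot_category_boxes

        dataset, _ = toy
        out = tmp_path / "boxes.svg"
        plot_category_boxes(pairwise_matrix(dataset), str(out))
        assert out.exists() and out.stat().st_size > 0
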