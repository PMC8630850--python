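"""Training-set construction rules: p-value labeling, CpG-based negatives."""

import logging

import numpy as np
import pandas as pd
import pytest

from epidmr import (
    build_dataset,
    generate,
    generate_stats_table,
    label_dmrs,
    max_possible_dmrs,
    select_non_dmrs,
    tile_windows,
)
from epidmr.dataset import read_stats_table
from epidmr.simulate import SyntheticSpec
from epidmr.windows import GenomeWindow


def stats_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "exposure", "p_value"])


def window_with_cpgs(k, chrom="c", start=0, size=1000):
    """A window containing exactly k CpG dinucleotides."""
    seq = "CG" * k + "A" * (size - 2 * k)
    return GenomeWindow(chrom, start, start + size, seq)


class TestLabelDmrs:
    def test_below_threshold_in_one_exposure_is_dmr(self):
        stats = stats_df([("c", 0, 1000, "atrazine", 1e-6)])
        assert label_dmrs(stats) == {("c", 0)}

    def test_threshold_boundary_is_strict(self):
        stats = stats_df([("c", 0, 1000, "atrazine", 1e-5)])
        assert label_dmrs(stats) == set()

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (1e-6, 1e-6, True),
            (1e-6, 0.5, True),   # union: one exposure suffices
            (0.5, 1e-6, True),
            (0.5, 0.5, False),
        ],
    )
    def test_union_over_exposures(self, p1, p2, expected):
        stats = stats_df([
            ("c", 0, 1000, "atrazine", p1),
            ("c", 0, 1000, "DDT", p2),
        ])
        assert (("c", 0) in label_dmrs(stats)) is expected

    def test_duplicates_keep_min_p_with_warning(self, caplog):
        stats = stats_df([
            ("c", 0, 1000, "atrazine", 0.9),
            ("c", 0, 1000, "atrazine", 1e-7),
        ])
        with caplog.at_level(logging.WARNING):
            keys = label_dmrs(stats)
        assert keys == {("c", 0)}
        assert any("duplicate" in r.message for r in caplog.records)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        stats = stats_df([
            ("c", 1000 * i, 1000 * (i + 1), "atrazine", 10.0 ** -rng.uniform(0, 8))
            for i in range(50)
        ])
        thresholds = [1e-7, 1e-6, 1e-5, 1e-3]
        sets = [label_dmrs(stats, t) for t in thresholds]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            label_dmrs(stats_df([("c", 0, 1000, "a", 0.5)]), threshold=0.0)
        with pytest.raises(ValueError):
            label_dmrs(stats_df([("c", 0, 1000, "a", 0.0)]))


class TestSelectNonDmrs:
    def test_zero_cpg_window_selected(self):
        w = GenomeWindow("c", 0, 1000, "A" * 1000)
        assert select_non_dmrs([w]) == {("c", 0)}

    def test_single_cpg_excluded(self):
        w = window_with_cpgs(1)
        assert select_non_dmrs([w]) == set()

    def test_all_n_window_is_negative(self):
        w = GenomeWindow("c", 0, 1000, "N" * 1000)
        assert select_non_dmrs([w]) == {("c", 0)}

    def test_dmr_conflict_excluded_and_logged(self, caplog):
        w = GenomeWindow("c", 0, 1000, "A" * 1000)
        with caplog.at_level(logging.ERROR):
            assert select_non_dmrs([w], dmr_keys={("c", 0)}) == set()
        assert any("no CpGs" in r.message for r in caplog.records)


class TestMaxPossibleDmrs:
    @pytest.mark.parametrize(
        "cpgs,included", [(0, False), (1, True), (200, True), (201, False)]
    )
    def test_cpg_count_bounds(self, cpgs, included):
        w = window_with_cpgs(cpgs)
        assert (w.key in max_possible_dmrs([w])) is included


class TestBuildDataset:
    @pytest.fixture()
    def toy(self):
        # 10 windows on two chromosomes: 6 with one CpG, 3 CpG-free, 1 CpG-free
        seq_cpg = "ACG" + "T" * 997
        seq_free = "AT" * 500
        chrom1 = (seq_cpg * 4) + (seq_free * 2)
        chrom2 = (seq_cpg * 2) + (seq_free * 2)
        return {"chr1": chrom1, "chr2": chrom2}

    def test_toy_counts(self, toy):
        stats = stats_df([
            ("chr1", 0, 1000, "atrazine", 1e-6),
            ("chr2", 0, 1000, "DDT", 1e-7),
        ])
        ds = build_dataset(toy, stats)
        assert ds.n_dmr == 2
        assert ds.n_nondmr == 4  # the CpG-free windows
        assert len(ds.windows) == 6

    def test_empty_stats_gives_only_negatives(self, toy):
        ds = build_dataset(toy, stats_df([]))
        assert ds.n_dmr == 0 and ds.n_nondmr == 4

    def test_per_chromosome_counts_partition_all(self, toy):
        stats = stats_df([
            ("chr1", 0, 1000, "atrazine", 1e-6),
            ("chr2", 0, 1000, "DDT", 1e-7),
        ])
        whole = build_dataset(toy, stats)
        parts = [build_dataset(toy, stats, chrom=c) for c in ("chr1", "chr2")]
        assert sum(p.n_dmr for p in parts) == whole.n_dmr
        assert sum(p.n_nondmr for p in parts) == whole.n_nondmr

    def test_misaligned_stats_raise(self, toy):
        stats = stats_df([("chr1", 500, 1500, "atrazine", 1e-6)])
        with pytest.raises(ValueError, match="chr1:500-1500"):
            build_dataset(toy, stats)

    def test_unlabeled_windows_excluded(self, toy):
        # CpG-bearing windows without a significant p-value stay out
        ds = build_dataset(toy, stats_df([("chr1", 0, 1000, "a", 0.2)]))
        keys = {w.key for w in ds.windows}
        assert ("chr1", 0) not in keys

    def test_optional_island_negatives(self, toy):
        island = {"chr3": "CG" * 500}
        genome = dict(toy, **island)
        ds = build_dataset(genome, stats_df([]), include_island_negatives=True)
        assert ("chr3", 0) in {w.key for w in ds.windows}


class TestSyntheticRoundTrip:
    def test_labels_recovered_exactly_from_stats_table(self):
        ds = generate(SyntheticSpec(n_per_class=30, window_size=120, seed=5))
        stats = generate_stats_table(ds, seed=5)
        dmr_keys = label_dmrs(stats)
        truth = {w.key for w, l in zip(ds.windows, ds.labels) if l == 1}
        assert dmr_keys == truth

    def test_dataset_counts_match_ground_truth(self):
        spec = SyntheticSpec(n_per_class=25, window_size=150, seed=2)
        ds = generate(spec)
        stats = generate_stats_table(ds, seed=2)
        built = build_dataset(ds.windows, stats, window_size=spec.window_size)
        assert built.n_dmr == 25
        assert built.n_nondmr == 25

    def test_stats_table_io_round_trip(self, tmp_path):
        ds = generate(SyntheticSpec(n_per_class=5, window_size=100, seed=3))
        stats = generate_stats_table(ds, seed=3)
        path = tmp_path / "stats.tsv"
        stats.to_csv(path, sep="\t", index=False)
        again = read_stats_table(path)
        assert label_dmrs(again) == label_dmrs(stats)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tstart\n1\t0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_stats_table(path)


def test_dmr_and_negative_sets_disjoint_on_synthetic_genome():
    ds = generate(SyntheticSpec(n_per_class=40, window_size=100, seed=9))
    stats = generate_stats_table(ds, seed=9)
    dmrs = label_dmrs(stats)
    negs = select_non_dmrs(list(ds.windows), dmrs)
    maxp = max_possible_dmrs(list(ds.windows))
    assert dmrs.isdisjoint(negs)
    assert negs.isdisjoint(maxp)
    assert dmrs <= maxp  # every positive carries at least one CpG
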