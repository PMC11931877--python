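"""RPGC coverage, signal matrices, and occupancy clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from glycochrom.intervals import GeneModel, GenomeSpec, GenomicInterval, PeakSet
from glycochrom.signal import (
    CoverageTrack,
    categorize_clusters,
    kmeans_occupancy,
    matrix_around_centers,
    matrix_over_genes,
    read_bedgraph,
    rpgc_coverage,
    write_bedgraph,
)


def _tiling_fragments(n: int, length: int = 150) -> PeakSet:
    return PeakSet(
        [GenomicInterval("c", i * length, (i + 1) * length) for i in range(n)]
    )


class TestRPGC:
    def test_closed_form_ten_fragments_tile_genome(self):
        genome = GenomeSpec({"c": 1500})
        track = rpgc_coverage(_tiling_fragments(10), genome, bin_size=50, extend_to=0)
        assert np.allclose(track.values["c"], 1.0)
        assert track.genome_mean() == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_half_depth_scales_to_one(self):
        genome = GenomeSpec({"c": 1500})
        track = rpgc_coverage(_tiling_fragments(5), genome, bin_size=50, extend_to=0)
        # raw mean 0.5, scale 2.0: covered bins 2.0, empty bins 0, mean 1
        covered = track.values["c"][:15]
        assert np.allclose(covered, 2.0)
        assert track.genome_mean() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            rpgc_coverage(PeakSet([]), GenomeSpec({"c": 1000}))

    @pytest.mark.parametrize("seed", range(4))
    def test_genome_mean_is_one_for_any_fragment_set(self, seed):
        rng = np.random.default_rng(seed)
        genome = GenomeSpec({"c1": 50_000, "c2": 30_000})
        ivs = []
        for _ in range(int(rng.integers(1, 200))):
            chrom = "c1" if rng.random() < 0.6 else "c2"
            start = int(rng.integers(0, genome.chrom_lengths[chrom] - 10))
            ivs.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 400))))
        track = rpgc_coverage(PeakSet(ivs), genome, extend_to=150)
        assert track.genome_mean() == pytest.approx(1.0, abs=1e-9)

    def test_strand_aware_five_prime_extension(self):
        genome = GenomeSpec({"c": 10_000})
        plus = PeakSet([GenomicInterval("c", 1000, 1050, "+")])
        minus = PeakSet([GenomicInterval("c", 1000, 1050, "-")])
        t_plus = rpgc_coverage(plus, genome, bin_size=50, extend_to=150)
        t_minus = rpgc_coverage(minus, genome, bin_size=50, extend_to=150)
        assert (t_plus.values["c"] > 0).nonzero()[0].tolist() == [20, 21, 22]
        assert (t_minus.values["c"] > 0).nonzero()[0].tolist() == [18, 19, 20]

    def test_bedgraph_round_trip(self, tmp_path):
        genome = GenomeSpec({"c": 1500})
        track = rpgc_coverage(_tiling_fragments(5), genome, bin_size=50, extend_to=0)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path, genome, bin_size=50)
        assert np.allclose(back.values["c"], track.values["c"])


def _constant_track(genome: GenomeSpec, value: float, bin_size: int = 50) -> CoverageTrack:
    return CoverageTrack(
        genome,
        bin_size,
        {
            c: np.full(-(-length // bin_size), value)
            for c, length in genome.chrom_lengths.items()
        },
    )


def _step_track(genome: GenomeSpec, boundary: int, bin_size: int = 50) -> CoverageTrack:
    """0 left of `boundary`, 1 at and right of it (boundary on the bin grid)."""
    values = {}
    for c, length in genome.chrom_lengths.items():
        v = np.zeros(-(-length // bin_size))
        v[boundary // bin_size :] = 1.0
        values[c] = v
    return CoverageTrack(genome, bin_size, values)


class TestCenterMatrix:
    GENOME = GenomeSpec({"c": 100_000})

    def test_default_shape_is_40_columns(self):
        regions = PeakSet([GenomicInterval("c", 49_000, 51_000)])
        m = matrix_around_centers(regions, _constant_track(self.GENOME, 3.0))
        assert m.values.shape == (1, 40)
        assert np.allclose(m.values, 3.0)

    def test_flank_must_divide_by_bin(self):
        regions = PeakSet([GenomicInterval("c", 0, 100)])
        with pytest.raises(ValueError, match="divisible"):
            matrix_around_centers(regions, _constant_track(self.GENOME, 1.0), flank=1025)

    def test_step_track_splits_at_center(self):
        center = 50_000
        regions = PeakSet([GenomicInterval("c", center - 500, center + 500)])
        m = matrix_around_centers(regions, _step_track(self.GENOME, center))
        assert np.allclose(m.values[0, :20], 0.0)
        assert np.allclose(m.values[0, 20:], 1.0)

    def test_missing_chromosome_gives_zero_row_and_warns(self):
        regions = PeakSet([GenomicInterval("other", 1000, 2000)])
        with pytest.warns(UserWarning, match="absent"):
            m = matrix_around_centers(regions, _constant_track(self.GENOME, 2.0))
        assert np.allclose(m.values, 0.0)

    def test_extraction_is_linear(self):
        rng = np.random.default_rng(3)
        values = {"c": rng.random(2000)}
        t1 = CoverageTrack(self.GENOME, 50, values)
        t3 = CoverageTrack(self.GENOME, 50, {"c": 3.0 * values["c"]})
        regions = PeakSet([GenomicInterval("c", 10_000, 12_000), GenomicInterval("c", 40_000, 40_100)])
        m1 = matrix_around_centers(regions, t1)
        m3 = matrix_around_centers(regions, t3)
        assert np.allclose(m3.values, 3.0 * m1.values)


class TestGenesMatrix:
    GENOME = GenomeSpec({"c": 100_000})

    def test_default_shape_is_180_columns(self):
        genes = [GeneModel("g", "c", 30_000, 40_000, "+")]
        m = matrix_over_genes(genes, _constant_track(self.GENOME, 2.5))
        assert m.values.shape == (1, 180)
        assert np.allclose(m.values, 2.5)

    def test_constant_track_independent_of_gene_length(self):
        genes = [
            GeneModel("g1", "c", 30_000, 30_050, "+"),  # shorter than body_bins
            GeneModel("g2", "c", 50_000, 80_000, "+"),
        ]
        m = matrix_over_genes(genes, _constant_track(self.GENOME, 1.5))
        assert np.allclose(m.values, 1.5)

    def test_minus_strand_profile_is_mirror_of_plus(self):
        # one step track; two genes symmetric around the step
        step = 50_000
        track = _step_track(self.GENOME, step)
        plus = GeneModel("p", "c", step - 5_000, step + 5_000, "+")
        minus = GeneModel("m", "c", step - 5_000, step + 5_000, "-")
        m = matrix_over_genes([plus, minus], track)
        assert np.allclose(m.values[1], m.values[0][::-1])


def _blob_matrices(seed=0):
    rng = np.random.default_rng(seed)
    low = rng.normal(1.0, 0.05, size=(30, 20))
    high = rng.normal(10.0, 0.05, size=(30, 20))
    values = np.vstack([low, high])
    ids = [f"r{i}" for i in range(60)]
    from glycochrom.signal import SignalMatrix

    return SignalMatrix(ids, values, "center", 500, 50), np.array([0] * 30 + [1] * 30)


class TestKMeans:
    def test_two_separated_blobs_recovered_exactly(self):
        m, truth = _blob_matrices()
        res = kmeans_occupancy([m], k=2, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        # renumbering: cluster 1 has the higher mean signal
        assert set(res.labels[truth == 1]) == {1}

    def test_k1_groups_everything(self):
        m, _ = _blob_matrices()
        res = kmeans_occupancy([m], k=1, seed=0)
        assert res.sizes == {1: 60}
        assert res.inertia == pytest.approx(((m.values - m.values.mean(0)) ** 2).sum())

    def test_k_larger_than_rows_errors(self):
        m, _ = _blob_matrices()
        with pytest.raises(ValueError):
            kmeans_occupancy([m], k=61, seed=0)

    def test_bit_reproducible_for_fixed_seed(self):
        m, _ = _blob_matrices(3)
        r1 = kmeans_occupancy([m], k=3, seed=11)
        r2 = kmeans_occupancy([m], k=3, seed=11)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.inertia == r2.inertia

    def test_row_permutation_invariance_up_to_renumbering(self):
        from glycochrom.signal import SignalMatrix

        m, truth = _blob_matrices(5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(m.region_ids))
        mp = SignalMatrix([m.region_ids[i] for i in perm], m.values[perm], "center", 500, 50)
        r = kmeans_occupancy([m], k=2, seed=2)
        rp = kmeans_occupancy([mp], k=2, seed=2)
        by_id = dict(zip(rp.region_ids, rp.labels))
        assert all(by_id[rid] == lab for rid, lab in zip(r.region_ids, r.labels))

    def test_misaligned_rows_error(self):
        m, _ = _blob_matrices()
        m2, _ = _blob_matrices()
        m2 = type(m2)(["x"] + m2.region_ids[1:], m2.values, "center", 500, 50)
        with pytest.raises(ValueError, match="row-aligned"):
            kmeans_occupancy([m, m2], k=2, seed=0)


class TestCategorize:
    @staticmethod
    def _matrices(factors):
        from glycochrom.signal import SignalMatrix

        rng = np.random.default_rng(0)
        base = np.abs(rng.normal(5.0, 0.2, size=(len(factors) * 20, 10)))
        after = base * np.repeat(factors, 20)[:, None]
        ids = [f"r{i}" for i in range(base.shape[0])]
        return (
            SignalMatrix(ids, base, "center", 250, 50),
            SignalMatrix(ids, after, "center", 250, 50),
        )

    def test_doubling_is_gain_equal_is_unchanged(self):
        before, after = self._matrices([2.0, 1.0, 0.5])
        res = kmeans_occupancy([before, after], k=3, seed=4)
        res = categorize_clusters(res, before, after, tau=0.5)
        assert set(res.categories.values()) == {"gain", "unchanged", "loss"}
        # per-cluster deltas ~ +1, 0, -1
        deltas = sorted(res.cluster_delta.values())
        assert deltas[0] == pytest.approx(-1.0, abs=0.1)
        assert deltas[1] == pytest.approx(0.0, abs=0.1)
        assert deltas[2] == pytest.approx(1.0, abs=0.1)

    def test_planted_three_class_recovery(self):
        before, after = self._matrices([2.0, 1.0, 0.5])
        truth = ["gain"] * 20 + ["unchanged"] * 20 + ["loss"] * 20
        res = kmeans_occupancy([before, after], k=3, seed=4)
        res = categorize_clusters(res, before, after)
        assert res.region_categories() == truth
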