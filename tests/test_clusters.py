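"""Cluster assignment: chaining, center grouping, sub-cluster splitting,
distance bookkeeping, and the bias-decay regression."""
import numpy as np
import pytest

from braim.clusters import assign_clusters, decay_regression, select_representative
from braim.types import BraimFit, GeneCoordinate


def fit(tid, pp_parental, beta=1.0):
    return BraimFit(
        transcript_id=tid,
        pp=np.array([pp_parental, 0.1, 0.1, 0.1]),
        beta_mean=np.array([beta, 0, 0, 0]),
        beta_sd=np.ones(4),
        sigma2_mean=1.0,
        scale_sd=1.0,
        column_labels=("parental", "cross", "sex", "age"),
    )


class TestSelectRepresentative:
    def test_max_pp_wins(self):
        assert select_representative([fit("a", 0.99), fit("b", 0.70)]) == "a"

    def test_single_transcript(self):
        assert select_representative([fit("only", 0.5)]) == "only"

    def test_tie_broken_by_abs_beta_then_id(self):
        assert select_representative([fit("a", 1.0, beta=2.0), fit("b", 1.0, beta=0.5)]) == "a"
        assert select_representative([fit("b", 1.0, beta=1.0), fit("a", 1.0, beta=1.0)]) == "a"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_representative([])


def genes_with_biases(spec):
    """spec: list of (gene_id, start, end, bias[, strand])."""
    genes, biases = [], {}
    for item in spec:
        gid, start, end, bias = item[:4]
        strand = item[4] if len(item) > 4 else "+"
        genes.append(GeneCoordinate(gid, "chr1", start, end, strand))
        biases[gid] = bias
    return genes, biases


class TestAssignClusters:
    def test_one_mb_chain_rule(self):
        genes, biases = genes_with_biases(
            [("g1", 0, 1000, 0.9), ("g2", 500_000, 501_000, 0.6), ("g3", 2_000_000, 2_001_000, 0.9)]
        )
        out = assign_clusters(genes, biases)
        by_gene = {a.gene_id: a for a in out}
        assert by_gene["g1"].cluster_id == by_gene["g2"].cluster_id
        assert by_gene["g3"].cluster_id != by_gene["g1"].cluster_id

    def test_center_threshold_and_distances(self):
        genes, biases = genes_with_biases(
            [("g1", 0, 1000, 0.95), ("g2", 100_000, 101_000, 0.60), ("g3", 300_000, 301_000, 0.55)]
        )
        out = {a.gene_id: a for a in assign_clusters(genes, biases)}
        assert out["g1"].is_center and not out["g2"].is_center
        assert out["g1"].distance_bp == 0.0
        assert out["g2"].distance_bp == pytest.approx(100_000 - 1000)
        assert out["g3"].distance_bp == pytest.approx(300_000 - 1000)

    def test_consecutive_centers_grouped(self):
        genes, biases = genes_with_biases(
            [("c1", 0, 1000, 0.9), ("c2", 10_000, 11_000, 0.9), ("m", 500_000, 501_000, 0.6)]
        )
        out = {a.gene_id: a for a in assign_clusters(genes, biases)}
        assert out["c1"].is_center and out["c2"].is_center
        assert out["c1"].center_interval == out["c2"].center_interval == ("chr1", 0, 11_000)
        assert out["m"].distance_bp == pytest.approx(500_000 - 11_000)

    def test_two_center_groups_split_into_subclusters(self):
        genes, biases = genes_with_biases(
            [
                ("cA", 0, 10_000, 0.95),
                ("m1", 200_000, 201_000, 0.6),   # between the groups, nearer cA
                ("m2", 700_000, 701_000, 0.6),   # nearer cB
                ("cB", 900_000, 910_000, 0.95),
            ]
        )
        out = {a.gene_id: a for a in assign_clusters(genes, biases)}
        # boundary at (10_000 + 900_000) / 2 = 455_000
        assert out["m1"].cluster_id == out["cA"].cluster_id
        assert out["m2"].cluster_id == out["cB"].cluster_id
        assert out["m1"].center_interval == ("chr1", 0, 10_000)
        assert out["m2"].center_interval == ("chr1", 900_000, 910_000)

    def test_gene_beyond_1mb_of_center_removed(self):
        genes, biases = genes_with_biases(
            [
                ("c", 0, 1000, 0.95),
                ("near", 900_000, 901_000, 0.6),
                ("mid", 1_800_000, 1_801_000, 0.6),
                ("far", 2_700_000, 2_701_000, 0.6),
            ]
        )
        out = {a.gene_id: a for a in assign_clusters(genes, biases)}
        assert "near" in out and "far" not in out and "mid" not in out

    def test_centerless_cluster_gets_nan_distance(self):
        genes, biases = genes_with_biases([("g1", 0, 1000, 0.6), ("g2", 5_000, 6_000, 0.7)])
        out = assign_clusters(genes, biases)
        assert len(out) == 2
        assert all(np.isnan(a.distance_bp) for a in out)
        assert all(not a.is_center for a in out)

    def test_antisense_start_site(self):
        # '-' strand gene: start site is the genomic end coordinate
        genes, biases = genes_with_biases(
            [("c", 0, 1000, 0.95), ("anti", 500_000, 800_000, 0.6, "-")]
        )
        out = {a.gene_id: a for a in assign_clusters(genes, biases)}
        assert out["anti"].distance_bp == pytest.approx(800_000 - 1000)

    def test_input_order_invariance(self):
        spec = [("g1", 0, 1000, 0.95), ("g2", 100_000, 101_000, 0.6), ("g3", 300_000, 301_000, 0.9)]
        genes, biases = genes_with_biases(spec)
        a = assign_clusters(genes, biases)
        b = assign_clusters(list(reversed(genes)), biases)
        assert sorted((x.gene_id, x.cluster_id, x.distance_bp) for x in a) == sorted(
            (x.gene_id, x.cluster_id, x.distance_bp) for x in b
        )

    def test_partition_no_duplicates(self):
        genes, biases = genes_with_biases(
            [(f"g{i}", i * 200_000, i * 200_000 + 1000, 0.9 if i % 3 == 0 else 0.6) for i in range(12)]
        )
        out = assign_clusters(genes, biases)
        ids = [a.gene_id for a in out]
        assert len(ids) == len(set(ids))
        assert all(np.isnan(a.distance_bp) or a.distance_bp <= 1_000_000 for a in out)

    def test_removing_noncenter_gene_preserves_other_assignments(self):
        spec = [
            ("c", 0, 1000, 0.95),
            ("m1", 100_000, 101_000, 0.6),
            ("m2", 400_000, 401_000, 0.6),
        ]
        genes, biases = genes_with_biases(spec)
        full = {a.gene_id: a for a in assign_clusters(genes, biases)}
        reduced = {
            a.gene_id: a
            for a in assign_clusters([g for g in genes if g.gene_id != "m1"], biases)
        }
        assert reduced["m2"].distance_bp == full["m2"].distance_bp
        assert reduced["c"].is_center


class TestDecayRegression:
    def _assignments(self, dists, biases):
        return [
            type("A", (), dict(is_center=False, distance_bp=d, bias=b))()
            for d, b in zip(dists, biases)
        ]

    def test_flat_biases_give_zero_slope(self):
        slope, _, _ = decay_regression(self._assignments([0, 1e5, 5e5, 9e5], [0.7] * 4))
        assert slope == pytest.approx(0.0, abs=1e-15)

    def test_exact_line_recovered(self):
        d = np.array([0.0, 2e5, 5e5, 8e5])
        slope, intercept, p = decay_regression(self._assignments(d, 0.9 - 1e-7 * d))
        assert slope == pytest.approx(-1e-7)
        assert intercept == pytest.approx(0.9)
        assert p < 1e-10

    def test_noisy_decay_negative_slope(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1e6, 40)
        b = 0.9 - 2e-7 * d + 0.02 * rng.standard_normal(40)
        slope, _, p = decay_regression(self._assignments(d, b))
        assert slope < 0 and p < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            decay_regression(self._assignments([0, 1], [0.9, 0.8]))
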