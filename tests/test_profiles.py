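"""Quintile stratification and strand-aware metaprofiles."""

import numpy as np
import pytest

from chromaggr.intervals import GeneAnchor, ValidationError
from chromaggr.profiles import (
    anchor_profile,
    assign_quintiles,
    scaled_gene_profile,
    stratified_profiles,
)
from chromaggr.signal import BinnedTrack


def make_track(values, bin_size=100, chrom="chr1"):
    return BinnedTrack(
        bin_size, {chrom: np.asarray(values, dtype=float)}, total_reads=1e6, normalized=True
    )


def gene(tss, strand="+", metric=1.0, length=1000, chrom="chr1", name="."):
    tes = tss + length if strand == "+" else tss - length
    return GeneAnchor(chrom, tss, tes, strand, metric=metric, name=name)


class TestQuintiles:
    def test_equal_split(self):
        anchors = [gene(1000 * (i + 1), metric=float(i + 1)) for i in range(10)]
        q = assign_quintiles(anchors)
        assert [q[i] for i in range(10)] == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_uneven_split_sizes(self):
        anchors = [gene(1000 * (i + 1), metric=float(i)) for i in range(7)]
        q = assign_quintiles(anchors)
        sizes = [list(q.values()).count(lab) for lab in (1, 2, 3, 4, 5)]
        assert sizes == [2, 2, 1, 1, 1]

    def test_labels_ascend_with_metric(self, rng):
        metrics = rng.standard_normal(23)
        anchors = [gene(500 + 1000 * i, metric=float(m)) for i, m in enumerate(metrics)]
        q = assign_quintiles(anchors)
        order = np.argsort(metrics, kind="stable")
        labels = [q[int(i)] for i in order]
        assert labels == sorted(labels)

    def test_ties_resolved_by_stable_genomic_order_deterministically(self):
        anchors = [gene(1000 * (i + 1), metric=2.0) for i in range(10)]
        q1, q2 = assign_quintiles(anchors), assign_quintiles(anchors)
        assert q1 == q2
        # genomic order decides: first two positions land in quintile 1
        assert q1[0] == 1 and q1[9] == 5

    def test_too_few_anchors(self):
        with pytest.raises(ValidationError):
            assign_quintiles([gene(1000)] * 4)


class TestAnchorProfile:
    def test_uniform_track_flat(self):
        t = make_track(np.full(100, 3.0))
        mat = anchor_profile(t, [gene(5000)], flank=1000, bin_size=100)
        np.testing.assert_allclose(mat.mean_profile(), 3.0)

    def test_delta_at_plus_anchor_hits_column_zero(self):
        vals = np.zeros(100)
        vals[50] = 7.0
        t = make_track(vals)
        mat = anchor_profile(t, [gene(5050, "+")], flank=1000, bin_size=100)
        prof = mat.mean_profile()
        mid = len(prof) // 2
        assert prof[mid] == 7.0 and prof.sum() == 7.0

    def test_minus_strand_flips_offset(self):
        vals = np.zeros(100)
        vals[52] = 5.0  # bin of genomic position anchor + 100
        t = make_track(vals)
        mat = anchor_profile(t, [gene(5150, "-")], flank=1000, bin_size=100)
        prof = mat.mean_profile()
        # on the minus strand, +100 genomic is column -100/bin = -1
        col = list(mat.columns).index(-100)
        assert prof[col] == 5.0

    def test_edge_anchors_dropped_and_counted(self):
        t = make_track(np.ones(100))
        mat = anchor_profile(t, [gene(50), gene(5000)], flank=1000, bin_size=100)
        assert mat.dropped == 1 and mat.values.shape[0] == 1

    def test_all_anchors_dropped_errors(self):
        t = make_track(np.ones(10))
        with pytest.raises(ValidationError):
            anchor_profile(t, [gene(50)], flank=5000, bin_size=100)

    def test_unnormalized_track_rejected(self):
        t = BinnedTrack(100, {"chr1": np.ones(100)}, total_reads=100)
        with pytest.raises(ValidationError):
            anchor_profile(t, [gene(5000)], flank=1000, bin_size=100)

    def test_mirror_symmetry(self, rng):
        """Reversing the genome and flipping strands reverses the profile."""
        n = 200
        vals = rng.poisson(4, n).astype(float)
        size = n * 100
        t = make_track(vals)
        anchors = [gene(2_000 + 1500 * i, "+") for i in range(5)]
        fwd = anchor_profile(t, anchors, flank=1000, bin_size=100).mean_profile()
        # mirrored genome: value at bin i moves to bin n-1-i; an anchor at
        # position p maps to size-1-p rounded to the mirrored bin centre
        t_rev = make_track(vals[::-1].copy())
        anchors_rev = [
            GeneAnchor("chr1", size - 100 - a.tss, size - 100 - a.tes, "-")
            for a in anchors
        ]
        rev = anchor_profile(t_rev, anchors_rev, flank=1000, bin_size=100).mean_profile()
        np.testing.assert_allclose(rev, fwd)


class TestStratifiedProfiles:
    def test_identical_signal_gives_coincident_curves(self):
        t = make_track(np.full(200, 2.0))
        anchors = [gene(2000 * (i + 1), metric=float(i)) for i in range(10)]
        strat = stratified_profiles(t, anchors, flank=500, bin_size=100)
        curves = [m.mean_profile() for m in strat.values()]
        for c in curves[1:]:
            np.testing.assert_allclose(c, curves[0])

    def test_order_invariance(self, rng):
        vals = rng.poisson(5, 200).astype(float)
        t = make_track(vals)
        anchors = [gene(1800 * (i + 1), metric=float(rng.random())) for i in range(10)]
        a = stratified_profiles(t, anchors, flank=500, bin_size=100)
        perm = [anchors[i] for i in rng.permutation(10)]
        b = stratified_profiles(t, perm, flank=500, bin_size=100)
        for q in a:
            np.testing.assert_allclose(a[q].mean_profile(), b[q].mean_profile())

    def test_union_mean_is_count_weighted_quintile_mean(self, rng):
        vals = rng.poisson(5, 300).astype(float)
        t = make_track(vals)
        anchors = [gene(2000 * (i + 1), metric=float(rng.random())) for i in range(13)]
        strat = stratified_profiles(t, anchors, flank=500, bin_size=100)
        union = anchor_profile(t, anchors, flank=500, bin_size=100)
        weighted = sum(
            m.values.shape[0] * m.mean_profile() for m in strat.values()
        ) / union.values.shape[0]
        np.testing.assert_allclose(union.mean_profile(), weighted)


class TestScaledGeneProfile:
    def test_uniform_track_flat_composite(self):
        t = make_track(np.full(400, 2.5))
        prof = scaled_gene_profile(
            t, [gene(10_000, length=3000)], flank=1000, n_body_bins=20, bin_size=100
        )
        np.testing.assert_allclose(prof, 2.5)
        assert len(prof) == 10 + 20 + 10

    def test_identity_scaling_when_length_matches(self):
        vals = np.zeros(400)
        vals[100:120] = np.arange(20)
        t = make_track(vals)
        g = gene(10_000, length=2000)  # exactly n_body_bins * bin_size
        prof = scaled_gene_profile(t, [g], flank=1000, n_body_bins=20, bin_size=100)
        np.testing.assert_allclose(prof[10:30], vals[100:120])

    def test_delta_at_tes_lands_in_last_body_bin(self):
        vals = np.zeros(400)
        g = gene(10_000, length=3000)
        vals[(g.tes - 1) // 100] = 9.0
        t = make_track(vals)
        prof = scaled_gene_profile(t, [g], flank=1000, n_body_bins=15, bin_size=100)
        body = prof[10:25]
        assert body[-1] > 0 and body[:-1].sum() == 0

    def test_minus_strand_gene_flipped(self):
        vals = np.zeros(400)
        g = gene(20_000, strand="-", length=3000)  # tes = 17_000
        vals[(g.tes + 100) // 100] = 6.0  # the 3'-most sampled body bin
        t = make_track(vals)
        prof = scaled_gene_profile(t, [g], flank=1000, n_body_bins=15, bin_size=100)
        body = prof[10:25]
        assert body[-1] > 0

    def test_short_gene_single_sample_replicated(self):
        vals = np.zeros(400)
        vals[100] = 3.0
        t = make_track(vals)
        g = gene(10_050, length=40)  # shorter than one native bin
        prof = scaled_gene_profile(t, [g], flank=500, n_body_bins=10, bin_size=100)
        np.testing.assert_allclose(prof[5:15], 3.0)
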