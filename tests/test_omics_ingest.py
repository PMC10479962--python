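"""Gene-level ingestion: log-ratio, copy-number calls, mutation and
methylation summaries, min-max scaling, and wGII."""

import numpy as np
import pandas as pd
import pytest

from omicsimage.omics_ingest import (
    call_cn_channels,
    compute_logR,
    compute_wgii,
    minmax_scale,
    summarize_methylation,
    summarize_mutations,
)
from omicsimage.types import (
    ChannelMatrix,
    CnThresholds,
    GeneAnnotation,
    MutationRecord,
    SampleProfile,
    Segment,
)


class TestLogR:
    @pytest.mark.parametrize(
        "cn,ploidy,expected",
        [
            (2, 2, 0.0),
            (0.5, 2, -2.0),
            (5, 2, 1.3219280948873622),  # log2(2.5), independently evaluated
            (4, 4, 0.0),
        ],
    )
    def test_values(self, cn, ploidy, expected):
        assert compute_logR(cn, ploidy) == pytest.approx(expected, abs=1e-12)

    def test_zero_copy_number_is_negative_infinity(self):
        assert compute_logR(0, 2) == float("-inf")

    def test_invalid_ploidy_rejected(self):
        with pytest.raises(ValueError):
            compute_logR(2, 0)
        with pytest.raises(ValueError):
            compute_logR(2, -1)


def _one_gene_annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {"gene_id": ["G"], "chromosome": ["1"], "start": [100], "end": [200]}
        )
    )


class TestCnCalls:
    """Amplification needs full containment; deletion needs any overlap."""

    @pytest.mark.parametrize(
        "seg_start,seg_end,cn,expect_gain,expect_loss",
        [
            # logR = log2(6/2) = 1.58 > log2(5/2): amplified, gene contained
            (50, 300, 6.0, 1, 0),
            # amplified segment covers the gene only partially: no gain call
            (150, 300, 8.0, 0, 0),
            # deleted segment (cn=0 -> logR=-inf) partial overlap: loss called
            (150, 300, 0.0, 0, 1),
            # neutral segment
            (50, 300, 2.0, 0, 0),
            # exactly at the amplification threshold (logR == tau_amp): no call
            (50, 300, 5.0, 0, 0),
        ],
    )
    def test_containment_vs_overlap_rules(
        self, seg_start, seg_end, cn, expect_gain, expect_loss
    ):
        genes = _one_gene_annotation()
        segs = [Segment("s1", "1", seg_start, seg_end, cn)]
        profiles = {"s1": SampleProfile("s1", ploidy=2.0)}
        gain, loss = call_cn_channels(segs, profiles, genes)
        assert gain.values[0, 0] == expect_gain
        assert loss.values[0, 0] == expect_loss

    def test_no_segments_gives_zeros(self):
        genes = _one_gene_annotation()
        gain, loss = call_cn_channels(
            [], {"s1": SampleProfile("s1", 2.0)}, genes
        )
        assert gain.values.sum() == 0 and loss.values.sum() == 0

    def test_unknown_chromosome_warns_and_zeroes(self):
        genes = _one_gene_annotation()
        segs = [Segment("s1", "9", 1, 1000, 8.0)]
        with pytest.warns(UserWarning):
            gain, _ = call_cn_channels(segs, {"s1": SampleProfile("s1", 2.0)}, genes)
        assert gain.values.sum() == 0

    def test_overlapping_segments_rejected(self):
        genes = _one_gene_annotation()
        segs = [
            Segment("s1", "1", 1, 500, 2.0),
            Segment("s1", "1", 400, 900, 2.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            call_cn_channels(segs, {"s1": SampleProfile("s1", 2.0)}, genes)

    def test_matches_per_base_oracle_on_random_instances(self):
        """Brute-force oracle: mark every base of every gene by its covering
        segment, then apply the containment/overlap rules literally."""
        rng = np.random.default_rng(42)
        thr = CnThresholds()
        for trial in range(200):
            n_genes = rng.integers(1, 11)
            n_segs = rng.integers(0, 9)
            span = 400
            starts = rng.integers(1, span, size=n_genes)
            genes = GeneAnnotation(
                pd.DataFrame(
                    {
                        "gene_id": [f"g{i}" for i in range(n_genes)],
                        "chromosome": ["1"] * n_genes,
                        "start": starts,
                        "end": starts + rng.integers(1, 40, size=n_genes),
                    }
                )
            )
            # non-overlapping random segments: partition from sorted cuts
            cuts = np.sort(rng.choice(np.arange(1, span * 2), size=2 * n_segs, replace=False))
            segs = []
            for i in range(n_segs):
                s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
                cn = float(rng.choice([0, 0.4, 1, 2, 3, 6, 8]))
                segs.append(Segment("s1", "1", s, e, cn))
            ploidy = float(rng.choice([1.8, 2.0, 3.7]))
            profiles = {"s1": SampleProfile("s1", ploidy)}
            gain, loss = call_cn_channels(segs, profiles, genes, thr)

            for gi in range(n_genes):
                g0 = int(genes.table["start"].iat[gi])
                g1 = int(genes.table["end"].iat[gi])
                base_cov = {}
                for seg in segs:
                    for b in range(max(g0, seg.start), min(g1, seg.end) + 1):
                        base_cov[b] = seg
                covering = set(base_cov.values())
                exp_gain = any(
                    compute_logR(seg.total_cn, ploidy) > thr.tau_amp
                    and all(b in base_cov and base_cov[b] is seg for b in range(g0, g1 + 1))
                    for seg in covering
                )
                exp_loss = any(
                    compute_logR(seg.total_cn, ploidy) < thr.tau_del for seg in covering
                )
                assert gain.values[0, gi] == float(exp_gain), f"trial {trial} gene {gi}"
                assert loss.values[0, gi] == float(exp_loss), f"trial {trial} gene {gi}"

    def test_gain_implies_overlap_but_not_conversely(self):
        """Amplification is strictly stronger than overlap."""
        genes = _one_gene_annotation()
        profiles = {"s1": SampleProfile("s1", 2.0)}
        # overlapping amplified segment without containment: no gain
        gain, _ = call_cn_channels([Segment("s1", "1", 150, 300, 8.0)], profiles, genes)
        assert gain.values[0, 0] == 0
        # containment: gain, and containment trivially implies overlap
        gain, _ = call_cn_channels([Segment("s1", "1", 50, 300, 8.0)], profiles, genes)
        assert gain.values[0, 0] == 1


class TestMutationSummary:
    def test_max_polyphen_per_gene(self, toy_genes):
        records = [
            MutationRecord("s1", "A", 0.1),
            MutationRecord("s1", "A", 0.9),
            MutationRecord("s1", "B", 0.42),
        ]
        cm = summarize_mutations(records, toy_genes, ["s1", "s2"])
        assert cm.values[0, toy_genes.index_of("A")] == 0.9
        assert cm.values[0, toy_genes.index_of("B")] == 0.42
        assert cm.values[0, toy_genes.index_of("C")] == 0.0  # no mutation
        assert cm.values[1].sum() == 0.0  # untouched sample

    def test_unknown_gene_warns_and_skips(self, toy_genes):
        with pytest.warns(UserWarning):
            cm = summarize_mutations(
                [MutationRecord("s1", "NOPE", 0.5)], toy_genes, ["s1"]
            )
        assert cm.values.sum() == 0

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            MutationRecord("s1", "A", 1.2)


class TestMethylationSummary:
    def test_mean_over_probes(self, toy_genes):
        scores = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3 + ["s1"],
                "gene_id": ["A", "A", "A", "B"],
                "beta": [0.0, 1.0, 0.5, 0.7],
            }
        )
        cm = summarize_methylation(scores, toy_genes, ["s1"])
        assert cm.values[0, toy_genes.index_of("A")] == pytest.approx(0.5)
        assert cm.values[0, toy_genes.index_of("B")] == pytest.approx(0.7)
        assert cm.values[0, toy_genes.index_of("C")] == 0.0

    def test_empty_input_warns(self, toy_genes):
        with pytest.warns(UserWarning):
            cm = summarize_methylation(
                pd.DataFrame(columns=["sample_id", "gene_id", "beta"]), toy_genes, ["s1"]
            )
        assert cm.values.sum() == 0


class TestMinMaxScale:
    def test_linear_map_endpoints(self):
        cm = ChannelMatrix("expression", ["s1"], ["a", "b", "c"], np.array([[2.0, 4.0, 6.0]]))
        out = minmax_scale(cm)
        assert out.scaled
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_idempotent_on_scaled_data(self):
        cm = ChannelMatrix("expression", ["s1"], ["a", "b"], np.array([[0.0, 1.0]]))
        np.testing.assert_allclose(minmax_scale(minmax_scale(cm)).values, [[0.0, 1.0]])

    def test_constant_channel_maps_to_zero(self):
        cm = ChannelMatrix("expression", ["s1"], ["a", "b", "c"], np.full((1, 3), 3.0))
        np.testing.assert_allclose(minmax_scale(cm).values, 0.0)

    def test_train_only_fit_clips_holdout(self):
        cm = ChannelMatrix(
            "expression", ["s1", "s2"], ["a", "b"], np.array([[0.0, 2.0], [1.0, 4.0]])
        )
        out = minmax_scale(cm, fit_samples=["s1"])
        np.testing.assert_allclose(out.values[0], [0.0, 1.0])
        assert out.values.max() <= 1.0  # holdout clipped into range

    def test_random_matrix_lands_in_unit_interval(self):
        rng = np.random.default_rng(0)
        cm = ChannelMatrix(
            "expression", [f"s{i}" for i in range(5)], [f"g{j}" for j in range(7)],
            rng.normal(3, 10, size=(5, 7)),
        )
        out = minmax_scale(cm)
        assert out.values.min() == 0.0 and out.values.max() == 1.0


class TestWgii:
    def test_half_aberrant_two_chromosomes(self):
        profile = SampleProfile("s1", 2.0)
        segs = [
            Segment("s1", "1", 1, 1000, 4.0),  # fully aberrant
            Segment("s1", "2", 1, 1000, 2.0),  # fully neutral
        ]
        assert compute_wgii(segs, profile) == pytest.approx(0.5)

    def test_all_neutral_is_zero_and_all_aberrant_is_one(self):
        profile = SampleProfile("s1", 2.0)
        neutral = [Segment("s1", c, 1, 500, 2.0) for c in ("1", "2", "3")]
        aberrant = [Segment("s1", c, 1, 500, 5.0) for c in ("1", "2", "3")]
        assert compute_wgii(neutral, profile) == 0.0
        assert compute_wgii(aberrant, profile) == 1.0

    def test_invariant_under_segment_subdivision(self):
        profile = SampleProfile("s1", 2.0)
        whole = [
            Segment("s1", "1", 1, 1000, 3.0),
            Segment("s1", "2", 1, 600, 2.0),
        ]
        split = [
            Segment("s1", "1", 1, 321, 3.0),
            Segment("s1", "1", 322, 1000, 3.0),
            Segment("s1", "2", 1, 100, 2.0),
            Segment("s1", "2", 101, 600, 2.0),
        ]
        assert compute_wgii(whole, profile) == pytest.approx(compute_wgii(split, profile))

    def test_x_chromosome_excluded(self):
        profile = SampleProfile("s1", 2.0)
        segs = [
            Segment("s1", "1", 1, 1000, 2.0),
            Segment("s1", "X", 1, 1000, 8.0),
        ]
        assert compute_wgii(segs, profile) == 0.0

    def test_rounding_against_ploidy(self):
        # ploidy 3.7 rounds to 4; cn 4.2 rounds to 4 -> neutral
        profile = SampleProfile("s1", 3.7)
        assert compute_wgii([Segment("s1", "1", 1, 100, 4.2)], profile) == 0.0

    def test_no_autosome_errors(self):
        with pytest.raises(ValueError):
            compute_wgii([], SampleProfile("s1", 2.0))
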