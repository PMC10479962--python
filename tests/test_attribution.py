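"""Integrated Gradients axioms, gene back-mapping, group scaling, ranking,
channel importance, and the expression-methylation filter."""

import numpy as np
import pandas as pd
import pytest

from omicsimage.attribution import (
    AttributionResult,
    IGConfig,
    attributions_to_genes,
    channel_importance,
    expr_meth_filter,
    integrated_gradients,
    rank_genes,
    scale_by_group,
)
from omicsimage.genome_image import build_layout, image_from_table
from omicsimage.network import ModelConfig, build_model
from omicsimage.types import ChannelMatrix, GeneAnnotation


class LinearProbe:
    """F(x) = sum(w * x) per sample: IG must equal w_i * x_i exactly."""

    def __init__(self, w: np.ndarray) -> None:
        self.w = w

    def output_and_input_grad(self, x, target=None):
        f = (x * self.w).reshape(len(x), -1).sum(axis=1)
        return f, np.broadcast_to(self.w, x.shape).copy()


class QuadraticProbe:
    """F(x) = sum(x^2): nonlinear, completeness holds only as m grows."""

    def output_and_input_grad(self, x, target=None):
        return (x**2).reshape(len(x), -1).sum(axis=1), 2 * x


class TestIntegratedGradients:
    def test_linear_model_exactness_any_step_count(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(2, 4, 4))
        x = rng.random((3, 2, 4, 4))
        for m in (1, 7, 50):
            attr, gap = integrated_gradients(LinearProbe(w), x, IGConfig(steps=m))
            np.testing.assert_allclose(attr, w * x, rtol=1e-10)
            assert gap.max() < 1e-9

    def test_constant_model_gives_zero_attributions(self):
        class Constant:
            def output_and_input_grad(self, x, target=None):
                return np.full(len(x), 3.14), np.zeros_like(x)

        x = np.random.default_rng(1).random((2, 1, 3, 3))
        attr, _ = integrated_gradients(Constant(), x, IGConfig(steps=10))
        np.testing.assert_array_equal(attr, 0.0)

    def test_zero_dependence_pixel_gets_zero_attribution(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(1, 3, 3))
        w[0, 1, 1] = 0.0  # F does not depend on this pixel
        x = rng.random((2, 1, 3, 3))
        attr, _ = integrated_gradients(LinearProbe(w), x, IGConfig(steps=20))
        np.testing.assert_array_equal(attr[:, 0, 1, 1], 0.0)

    def test_completeness_gap_shrinks_with_steps(self):
        """Right-Riemann error decreases monotonically (median over cases)."""
        rng = np.random.default_rng(3)
        xs = rng.random((20, 1, 4, 4))
        medians = []
        for m in (10, 50, 200):
            _, gap = integrated_gradients(QuadraticProbe(), xs, IGConfig(steps=m))
            medians.append(np.median(gap))
        assert medians[0] > medians[1] > medians[2]

    def test_completeness_on_trained_style_network(self):
        """On a real (random-weight) network the completeness axiom holds to
        ~1% of |F(x) - F(baseline)| at m=200."""
        config = ModelConfig(
            image_height=8, image_width=8, image_channels=2,
            encoder_widths=(4, 8), extractor_widths=(4,), head_hidden=8, latent_dim=16,
        )
        model = build_model(config, seed=4)
        x = np.random.default_rng(4).random((4, 2, 8, 8))
        target = np.array([0, 1, 0, 1])
        attr, gap = integrated_gradients(model, x, IGConfig(steps=200), target=target)
        f_x, _ = model.output_and_input_grad(x, target)
        f_0, _ = model.output_and_input_grad(np.zeros_like(x), target)
        denom = np.abs(f_x - f_0)
        assert (gap <= 0.01 * denom + 1e-4).all()

    def test_custom_baseline_shape_checked(self):
        x = np.zeros((1, 1, 2, 2))
        with pytest.raises(ValueError):
            integrated_gradients(
                LinearProbe(np.ones((1, 2, 2))), x, IGConfig(steps=2, baseline=np.zeros((1, 3, 3)))
            )


def small_layout_setup():
    genes = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "chromosome": ["1"] * 4,
                "start": [1, 100, 200, 300],
                "end": [50, 150, 250, 350],
            }
        )
    )
    layout = build_layout(genes, "square", mode="auto")
    return genes, layout


class TestGeneBackMapping:
    def test_single_pixel_maps_to_single_gene(self):
        genes, layout = small_layout_setup()
        attr = np.zeros((1, 2, layout.height, layout.width))
        r, c = layout.gene_to_pixel["c"]
        attr[0, 1, r, c] = 5.0
        res = attributions_to_genes(attr, layout, ["s0"], ["mutation", "expression"], genes.gene_ids)
        assert res.raw[0, 1, genes.index_of("c")] == 5.0
        assert res.raw.sum() == 5.0

    def test_round_trip_with_image_semantics(self):
        genes, layout = small_layout_setup()
        rng = np.random.default_rng(5)
        cm = ChannelMatrix("expression", ["s0", "s1"], genes.gene_ids, rng.random((2, 4)), scaled=True)
        img = image_from_table([cm], layout)
        res = attributions_to_genes(
            img.values, layout, img.sample_ids, img.channel_names, genes.gene_ids
        )
        np.testing.assert_array_equal(res.raw[:, 0, :], cm.values)

    def test_shuffled_layout_is_permutation_equivariant(self):
        """Identical pixel contents permuted by the layout give identical
        per-gene attributions."""
        genes, _ = small_layout_setup()
        square = build_layout(genes, "square", mode="auto")
        shuffled = build_layout(genes, "square_shuffled", mode="auto", seed=7)
        per_gene = {g: i + 1.0 for i, g in enumerate(genes.gene_ids)}
        imgs = {}
        for name, layout in (("square", square), ("shuffled", shuffled)):
            a = np.zeros((1, 1, layout.height, layout.width))
            for g, (r, c) in layout.gene_to_pixel.items():
                a[0, 0, r, c] = per_gene[g]
            imgs[name] = attributions_to_genes(a, layout, ["s0"], ["expression"], genes.gene_ids)
        np.testing.assert_array_equal(imgs["square"].raw, imgs["shuffled"].raw)


def result_from(raw, groups=None):
    s, c, g = raw.shape
    res = AttributionResult(
        raw=raw,
        sample_ids=[f"s{i}" for i in range(s)],
        channel_names=["mutation", "expression", "methylation"][:c],
        gene_ids=[f"g{i}" for i in range(g)],
    )
    return scale_by_group(res, groups or ["all"] * s)


class TestScaleByGroup:
    def test_minmax_within_single_group(self):
        raw = np.array([1.0, 3.0]).reshape(2, 1, 1)
        res = result_from(raw)
        np.testing.assert_allclose(res.group_scaled.reshape(-1), [0.0, 1.0])

    def test_groups_scaled_independently(self):
        raw = np.array([0.0, 10.0, 5.0, 6.0]).reshape(4, 1, 1)
        res = result_from(raw, groups=["A", "A", "B", "B"])
        np.testing.assert_allclose(res.group_scaled.reshape(-1), [0.0, 1.0, 0.0, 1.0])

    def test_constant_group_maps_to_zero(self):
        res = result_from(np.full((3, 1, 2), 7.0))
        np.testing.assert_array_equal(res.group_scaled, 0.0)

    def test_scaled_values_in_unit_interval(self):
        rng = np.random.default_rng(6)
        res = result_from(rng.normal(size=(5, 3, 4)), groups=["A", "B", "A", "B", "A"])
        assert res.group_scaled.min() >= 0 and res.group_scaled.max() <= 1

    def test_missing_group_id_rejected(self):
        raw = np.zeros((2, 1, 1))
        res = AttributionResult(raw, ["s0", "s1"], ["mutation"], ["g0"])
        with pytest.raises(ValueError):
            scale_by_group(res, ["A"])


class TestRankGenes:
    def setup_method(self):
        # gene A: expr 0.9 meth 0.8; gene B: expr 0.7 meth 0.95
        raw = np.zeros((1, 3, 2))
        raw[0, 1] = [0.9, 0.7]
        raw[0, 2] = [0.8, 0.95]
        res = AttributionResult(raw, ["s0"], ["mutation", "expression", "methylation"], ["A", "B"])
        self.res = res
        self.res.group_scaled = raw  # identity scaling for hand-checkable numbers
        self.res.group_ids = ["all"]

    def test_sum_combination(self):
        top = rank_genes(self.res, channels=["expression", "methylation"], k=1, combine="sum")
        assert list(top.gene_id) == ["A"]  # 1.7 > 1.65

    def test_max_combination(self):
        top = rank_genes(self.res, channels=["expression", "methylation"], k=1, combine="max")
        assert list(top.gene_id) == ["B"]  # 0.95 > 0.9

    def test_full_ordering_when_k_is_n(self):
        top = rank_genes(self.res, k=2)
        assert len(top) == 2

    def test_ties_break_by_gene_id(self):
        raw = np.full((1, 1, 3), 0.5)
        res = AttributionResult(raw, ["s0"], ["expression"], ["z", "m", "a"])
        res.group_scaled = raw
        res.group_ids = ["all"]
        top = rank_genes(res, k=3)
        assert list(top.gene_id) == ["a", "m", "z"]

    def test_empty_channel_subset_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(self.res, channels=[], k=1)


class TestChannelImportance:
    def test_shares_normalize_to_one(self):
        raw = np.zeros((2, 2, 3))
        raw[:, 0, :] = 0.2
        raw[:, 1, :] = 0.6
        res = AttributionResult(raw, ["s0", "s1"], ["mutation", "expression"], ["a", "b", "c"])
        res.group_scaled = raw
        res.group_ids = ["all", "all"]
        imp = channel_importance(res)
        np.testing.assert_allclose(sorted(imp["share"]), [0.25, 0.75])

    def test_equal_channels_equal_shares(self):
        raw = np.full((2, 3, 2), 0.4)
        res = AttributionResult(raw, ["s0", "s1"], ["mutation", "expression", "methylation"], ["a", "b"])
        res.group_scaled = raw
        res.group_ids = ["all"] * 2
        imp = channel_importance(res)
        np.testing.assert_allclose(imp["share"], 1 / 3)


class TestExprMethFilter:
    def test_perfect_negative_correlation_kept(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame({"g1": rng.random(30), "g2": rng.random(30)})
        meth = pd.DataFrame({"g1": 1 - expr["g1"], "g2": expr["g2"]})
        kept = expr_meth_filter(expr, meth, alpha=0.05)
        assert kept == ["g1"]

    def test_null_genes_rarely_pass_after_adjustment(self):
        """Under independence, the BH-adjusted pass rate is near zero."""
        rng = np.random.default_rng(8)
        n_genes = 200
        expr = pd.DataFrame(rng.normal(size=(50, n_genes)), columns=[f"g{i}" for i in range(n_genes)])
        meth = pd.DataFrame(rng.normal(size=(50, n_genes)), columns=[f"g{i}" for i in range(n_genes)])
        kept = expr_meth_filter(expr, meth, alpha=0.05)
        assert len(kept) <= 2

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"g": [0.1, 0.2]})
        with pytest.raises(ValueError):
            expr_meth_filter(df, df, 0.05)
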