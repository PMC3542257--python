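import numpy as np
import pandas as pd
import pytest

from tiledep.decay import fit_halflife
from tiledep.expression import aggregate_gene_level
from tiledep.differential import fold_change
from tiledep.model import ArrayInfo
from tiledep.simulate import (
    EffectConfig,
    STABLE,
    default_design,
    generate_annotation,
    generate_probe_layout,
    simulate_decay,
    simulate_expression,
)


class TestGenerateAnnotation:
    def test_empty(self):
        ann = generate_annotation(0, 0, 1000)
        assert len(ann) == 0 and ann.n_coding == 0

    def test_deterministic(self):
        a = generate_annotation(10, 2, 50_000, seed=1)
        b = generate_annotation(10, 2, 50_000, seed=1)
        assert a.to_frame().equals(b.to_frame())
        c = generate_annotation(10, 2, 50_000, seed=2)
        assert not a.to_frame().equals(c.to_frame())

    def test_same_strand_no_overlap(self):
        ann = generate_annotation(40, 10, 80_000, seed=3)
        for strand in "+-":
            feats = sorted(
                (f for f in ann.features if f.strand == strand),
                key=lambda f: f.start,
            )
            for prev, cur in zip(feats, feats[1:]):
                assert prev.end <= cur.start

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_annotation(100, 0, 5_000, seed=0)

    def test_category_shares_multinomial(self):
        # scaled-down coding pool with a 0.9% category share; the mean count
        # over 100 seeds must sit within ~3 standard errors of 0.9
        counts = [
            sum(
                1
                for f in generate_annotation(
                    100, 0, 200_000, category_scheme={"pbsx": 0.009}, seed=s
                ).features
                if "pbsx" in f.categories
            )
            for s in range(100)
        ]
        assert abs(np.mean(counts) - 0.9) < 0.3


class TestGenerateProbeLayout:
    def test_feature_probe_arithmetic(self):
        ann = generate_annotation(0, 0, 440)
        layout = generate_probe_layout(ann, 22)
        plus = layout.probes[layout.probes["strand"] == "+"]
        inside = plus[(plus["position"] >= 0) & (plus["position"] < 220)]
        assert list(inside["position"]) == list(range(0, 220, 22))
        assert len(inside) == 10

    def test_resolution_equal_to_genome(self):
        ann = generate_annotation(0, 0, 1000)
        layout = generate_probe_layout(ann, 1000)
        assert len(layout) == 2  # one probe per strand

    def test_66bp_feature_has_three_probes(self):
        ann = generate_annotation(0, 0, 660)
        layout = generate_probe_layout(ann, 22)
        plus = layout.probes[layout.probes["strand"] == "+"]
        assert ((plus["position"] >= 0) & (plus["position"] < 66)).sum() == 3

    def test_spacing_invariant(self):
        layout = generate_probe_layout(generate_annotation(5, 0, 20_000, seed=1), 22)
        layout.validate_spacing()

    def test_bad_resolution(self):
        with pytest.raises(ValueError, match="resolution"):
            generate_probe_layout(generate_annotation(0, 0, 100), 0)


def _sim(n_genes=20, genome=40_000, seed=0, **effect_kwargs):
    eff = EffectConfig(seed=seed, **effect_kwargs)
    ann = generate_annotation(n_genes, 0, genome, seed=seed)
    layout = generate_probe_layout(ann, 22)
    signals = simulate_expression(ann, layout, default_design(2), eff)
    return ann, signals


class TestSimulateExpression:
    def test_noiseless_null_conditions_identical(self):
        _, sig = _sim()
        assert np.array_equal(
            sig.values[["dep_1", "dep_2"]].to_numpy(),
            sig.values[["ind_1", "ind_2"]].to_numpy(),
        )

    def test_planted_effect_recovered_exactly(self):
        # sds all zero: a planted +1 log2 effect aggregates to fc == 2.0
        ann, sig = _sim(
            frac_direct_up=1.0, up_log2_mean=1.0, up_log2_sd=0.0,
            saturation_ceiling=100.0,
        )
        matrix = aggregate_gene_level(sig, ann)
        fc = fold_change(matrix)
        assert np.allclose(fc["fc"], 2.0)

    def test_saturation_clipping_shrinks_fold_change(self):
        ann, sig = _sim(
            frac_direct_up=1.0, up_log2_mean=1.0, up_log2_sd=0.0,
            baseline_mean=15.5, baseline_sd=0.0, saturation_ceiling=16.0,
        )
        fc = fold_change(aggregate_gene_level(sig, ann))
        assert (fc["fc"] < 2.0).all()
        assert (sig.values.to_numpy() <= 16.0).all()

    def test_empty_design_rejected(self):
        ann = generate_annotation(3, 0, 10_000, seed=0)
        layout = generate_probe_layout(ann, 22)
        with pytest.raises(ValueError, match="design"):
            simulate_expression(ann, layout, [], EffectConfig())

    def test_single_condition_rejected(self):
        ann = generate_annotation(3, 0, 10_000, seed=0)
        layout = generate_probe_layout(ann, 22)
        with pytest.raises(ValueError, match="condition"):
            simulate_expression(
                ann, layout, [ArrayInfo("a", "depleted", 1)], EffectConfig()
            )

    def test_bit_reproducible(self):
        _, s1 = _sim(seed=9, frac_direct_up=0.3, noise_sd_replicate=0.2)
        _, s2 = _sim(seed=9, frac_direct_up=0.3, noise_sd_replicate=0.2)
        pd.testing.assert_frame_equal(s1.values, s2.values)
        pd.testing.assert_series_equal(s1.truth, s2.truth)

    def test_truth_covers_every_feature(self):
        ann, sig = _sim(frac_direct_up=0.2, frac_indirect_down=0.1)
        assert list(sig.truth.index) == ann.ids


class TestEffectConfig:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            EffectConfig(frac_direct_up=0.7, frac_indirect_down=0.5)
        with pytest.raises(ValueError):
            EffectConfig(frac_direct_up=-0.1)

    def test_negative_sd(self):
        with pytest.raises(ValueError, match="noise_sd_replicate"):
            EffectConfig(noise_sd_replicate=-1.0)


class TestSimulateDecay:
    def test_exact_exponential(self):
        series = simulate_decay(5.0, [0, 5, 10], i0=100.0, noise_cv=0.0)
        assert np.allclose(series.intensities, [100.0, 50.0, 25.0])

    def test_stable_sentinel(self):
        series = simulate_decay(STABLE, [0, 5, 10], i0=7.0)
        assert np.allclose(series.intensities, 7.0)
        assert fit_halflife(series).t_half is None

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="times"):
            simulate_decay(5.0, [-1, 0, 5])

    def test_noise_is_mean_preserving(self):
        # E[I(5)]/i0 must be 0.5 within 1% over 200 seeds at CV 5%
        ratios = [
            simulate_decay(5.0, [0, 5, 10], noise_cv=0.05, seed=s).intensities[1]
            / 100.0
            for s in range(200)
        ]
        assert abs(np.mean(ratios) - 0.5) < 0.005

    def test_deterministic_per_seed(self):
        a = simulate_decay(4.0, [0, 2, 4], noise_cv=0.1, seed=3)
        b = simulate_decay(4.0, [0, 2, 4], noise_cv=0.1, seed=3)
        assert np.array_equal(a.intensities, b.intensities)
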