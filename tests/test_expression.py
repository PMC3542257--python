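import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tiledep.differential import fold_change
from tiledep.expression import (
    aggregate_gene_level,
    normalize_lvs,
    select_least_variant_set,
)
from tiledep.model import (
    ArrayInfo,
    ExpressionMatrix,
    Feature,
    GenomeAnnotation,
    ProbeLayout,
    ProbeSignalSet,
)
from tiledep.simulate import (
    EffectConfig,
    default_design,
    generate_annotation,
    generate_probe_layout,
    simulate_expression,
)

from conftest import TWO_VS_TWO, make_matrix


def signal_set(positions, values_per_array, arrays=None, strand="+"):
    arrays = arrays or TWO_VS_TWO
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chrom": "chr1",
            "position": positions,
            "strand": strand,
        }
    )
    layout = ProbeLayout(probes=probes, resolution=22)
    values = pd.DataFrame(
        {a.array_id: values_per_array[a.array_id] for a in arrays},
        index=probes["probe_id"].to_numpy(),
    )
    return ProbeSignalSet(layout=layout, arrays=arrays, values=values)


class TestAggregate:
    def test_odd_count_median(self):
        sig = signal_set(
            [0, 22, 44], {a.array_id: [5.0, 7.0, 6.0] for a in TWO_VS_TWO}
        )
        ann = GenomeAnnotation(features=[Feature("g1", "chr1", 0, 66, "+")])
        m = aggregate_gene_level(sig, ann)
        assert (m.data.loc["g1"] == 6.0).all()

    def test_even_count_median_is_mean_of_middle_two(self):
        sig = signal_set(
            [0, 22, 44, 66],
            {a.array_id: [1.0, 2.0, 3.0, 10.0] for a in TWO_VS_TWO},
        )
        ann = GenomeAnnotation(features=[Feature("g1", "chr1", 0, 88, "+")])
        m = aggregate_gene_level(sig, ann)
        assert (m.data.loc["g1"] == 2.5).all()

    def test_gene_without_probes_masked(self, caplog):
        sig = signal_set([0, 22], {a.array_id: [1.0, 2.0] for a in TWO_VS_TWO})
        ann = GenomeAnnotation(
            features=[
                Feature("g1", "chr1", 0, 44, "+"),
                Feature("g2", "chr1", 1000, 1100, "+"),
            ]
        )
        with caplog.at_level("WARNING"):
            m = aggregate_gene_level(sig, ann)
        assert m.data.loc["g2"].isna().all()
        assert "masked" in caplog.text

    def test_chromosome_mismatch_error(self):
        sig = signal_set([0, 22], {a.array_id: [1.0, 2.0] for a in TWO_VS_TWO})
        ann = GenomeAnnotation(features=[Feature("g1", "chrX", 0, 44, "+")])
        with pytest.raises(ValueError, match="chrX"):
            aggregate_gene_level(sig, ann)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_median_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        n_genes = data.draw(st.integers(1, 5))
        ann = generate_annotation(n_genes, 0, 12_000, seed=rng_seed)
        layout = generate_probe_layout(ann, 22)
        values = pd.DataFrame(
            rng.normal(8, 2, (len(layout), 4)),
            index=layout.probes["probe_id"].to_numpy(),
            columns=[a.array_id for a in TWO_VS_TWO],
        )
        sig = ProbeSignalSet(layout=layout, arrays=list(TWO_VS_TWO), values=values)
        m = aggregate_gene_level(sig, ann)
        # oracle: explicit per-gene probe scan + numpy median
        for f in ann.features:
            mask = [
                (r.chrom == f.chrom and r.strand == f.strand
                 and f.start <= r.position < f.end)
                for r in layout.probes.itertuples()
            ]
            sub = values.loc[np.asarray(mask)]
            for col in values.columns:
                if sub.empty:
                    assert np.isnan(m.data.loc[f.id, col])
                else:
                    assert m.data.loc[f.id, col] == np.median(sub[col])


class TestLeastVariantSet:
    def test_identical_arrays_tie_break_by_id(self):
        m = make_matrix({a.array_id: list(range(10)) for a in TWO_VS_TWO})
        lvs = select_least_variant_set(m, fraction=0.5)
        assert lvs.gene_ids == {f"g{i:03d}" for i in range(5)}
        assert (lvs.variance_statistic == 0).all()

    def test_planted_rank_outlier_excluded(self):
        cols = {a.array_id: list(range(1, 11)) for a in TWO_VS_TWO}
        cols["ind_2"] = [11.0] + list(range(2, 11))  # g000 jumps to top rank
        m = make_matrix(cols)
        lvs = select_least_variant_set(m, fraction=0.5)
        assert "g000" not in lvs.gene_ids

    def test_matches_bruteforce_rank_variance(self):
        rng = np.random.default_rng(42)
        m = make_matrix({a.array_id: rng.normal(10, 2, 20) for a in TWO_VS_TWO})
        lvs = select_least_variant_set(m, fraction=0.4)
        # oracle: explicit rank + variance enumeration
        from scipy.stats import rankdata

        ranks = np.column_stack(
            [rankdata(m.data[c]) for c in m.data.columns]
        )
        variances = ranks.var(axis=1, ddof=1)
        order = sorted(zip(variances, m.data.index))
        expected = {g for _, g in order[:8]}
        assert lvs.gene_ids == expected

    def test_fraction_bounds(self):
        m = make_matrix({a.array_id: [1.0, 2.0] for a in TWO_VS_TWO})
        with pytest.raises(ValueError):
            select_least_variant_set(m, fraction=0.0)

    def test_all_masked_error(self):
        m = make_matrix({a.array_id: [np.nan, np.nan] for a in TWO_VS_TWO})
        with pytest.raises(ValueError, match="masked"):
            select_least_variant_set(m)


class TestNormalizeLvs:
    def _base_matrix(self, distort=None, n=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(10, 1.5, n)
        cols = {}
        for a in TWO_VS_TWO:
            v = base.copy()
            if distort and a.array_id in distort:
                slope, intercept = distort[a.array_id]
                v = slope * v + intercept
            cols[a.array_id] = v
        return make_matrix(cols)

    def test_identity_when_equal_to_baseline(self):
        m = self._base_matrix()
        lvs = select_least_variant_set(m, 0.5)
        out = normalize_lvs(m, lvs)
        assert np.allclose(out.data, m.data, atol=1e-12)

    def test_affine_distortion_removed(self):
        m = self._base_matrix(distort={"ind_2": (0.8, 0.5)})
        lvs = select_least_variant_set(m, 0.5)
        out = normalize_lvs(m, lvs)
        arr = out.data.to_numpy()
        assert np.max(np.abs(arr - arr[:, [0]])) < 1e-6

    def test_shift_removed_and_biology_preserved(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1.5, 40)
        planted = np.zeros(40)
        # plant large effects on mid-ranked genes so their ranks move and
        # the least-variant selection excludes them
        mid = np.argsort(base)[15:25]
        planted[mid] = 5.0
        cols = {
            "dep_1": base + planted,
            "dep_2": base + planted,
            "ind_1": base,
            "ind_2": base + 1.0,  # constant technical shift
        }
        m = make_matrix(cols)
        lvs = select_least_variant_set(m, 0.5)
        assert not ({f"g{i:03d}" for i in mid} & lvs.gene_ids)
        out = normalize_lvs(m, lvs)
        deltas = fold_change(out)["delta"]
        assert np.allclose(deltas, planted, atol=1e-9)

    def test_post_regression_slope_one_intercept_zero(self):
        m = self._base_matrix(distort={"dep_2": (1.2, -0.7), "ind_1": (0.9, 0.2)})
        lvs = select_least_variant_set(m, 0.5)
        out = normalize_lvs(m, lvs)
        genes = sorted(lvs.gene_ids)
        sub = out.data.loc[genes]
        baseline = sub.mean(axis=1)
        for col in sub.columns:
            slope, intercept = np.polyfit(baseline, sub[col], 1)
            assert abs(slope - 1.0) < 1e-9
            assert abs(intercept) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        cols = {a.array_id: rng.normal(10, 2, 50) for a in TWO_VS_TWO}
        m = make_matrix(cols)
        lvs = select_least_variant_set(m, 0.4)
        once = normalize_lvs(m, lvs)
        twice = normalize_lvs(once, select_least_variant_set(once, 0.4))
        assert np.max(np.abs(once.data.to_numpy() - twice.data.to_numpy())) < 1e-9

    def test_too_few_lvs_genes(self):
        m = self._base_matrix(n=5)
        lvs = select_least_variant_set(m, 0.4)  # 2 genes
        with pytest.raises(ValueError, match="under-determined"):
            normalize_lvs(m, lvs)


class TestUpDownBalance:
    def test_sign_preserved_after_normalization(self):
        # planted 20% up-effects plus per-array affine distortions
        eff = EffectConfig(
            frac_direct_up=0.2,
            up_log2_mean=1.5,
            up_log2_sd=0.3,
            noise_sd_replicate=0.1,
            noise_sd_probe_affinity=0.25,
            array_slope_sd=0.05,
            array_offset_sd=0.3,
            saturation_ceiling=100.0,
            seed=7,
        )
        ann = generate_annotation(200, 0, 300_000, seed=7)
        sig = simulate_expression(
            ann, generate_probe_layout(ann, 22), default_design(2), eff
        )
        m = aggregate_gene_level(sig, ann)
        out = normalize_lvs(m, select_least_variant_set(m, 0.4))
        deltas = fold_change(out)["delta"]
        effect = sig.truth[sig.truth != 0]
        preserved = (np.sign(deltas[effect.index]) == np.sign(effect)).mean()
        assert preserved >= 0.99

    def test_planted_effect_bias_small(self):
        # full aggregation -> normalization -> fold-change chain, 100 genes
        eff = EffectConfig(
            frac_direct_up=0.2,
            frac_indirect_down=0.1,
            noise_sd_replicate=0.1,
            noise_sd_probe_affinity=0.25,
            saturation_ceiling=100.0,
            seed=5,
        )
        ann = generate_annotation(100, 0, 150_000, seed=5)
        sig = simulate_expression(
            ann, generate_probe_layout(ann, 22), default_design(2), eff
        )
        m = aggregate_gene_level(sig, ann)
        out = normalize_lvs(m, select_least_variant_set(m, 0.4))
        deltas = fold_change(out)["delta"]
        effect = sig.truth[sig.truth != 0]
        bias = (deltas[effect.index] - effect).mean()
        assert abs(bias) < 0.05
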