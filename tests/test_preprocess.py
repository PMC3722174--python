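"""Normalization and summarization: exact degenerate cases, oracle
comparisons and the model's structural invariants."""

import numpy as np
import pandas as pd
import pytest

from exondys import preprocess
from exondys.formats import IntensityTable
from exondys.preprocess import (
    PreprocessError,
    detect_effective_probesets,
    liwong_summarize,
    lowess_normalize,
    pca_embed,
    summarize_gene_level,
)


def _table(values, samples=None, tissue="muscle"):
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])], columns=samples)
    design = pd.DataFrame({"tissue": tissue, "disease": "control"}, index=samples)
    return IntensityTable(df, design)


class TestLowessNormalize:
    def test_identical_arrays_unchanged(self, rng):
        col = np.exp(rng.normal(8, 1, size=200))
        table = _table(np.column_stack([col] * 4))
        out = lowess_normalize(table)
        np.testing.assert_allclose(out.values.to_numpy(), table.values.to_numpy(), rtol=1e-9)

    def test_constant_bias_removed(self, rng):
        base = np.exp(rng.normal(8, 1, size=300))
        values = np.column_stack([base, base, base * 2.0])
        out = lowess_normalize(_table(values))
        log_ratio = np.log2(out.values.iloc[:, 2] / base)
        assert abs(np.median(log_ratio)) < 0.01

    def test_quadratic_bias_mostly_removed(self, rng):
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

        log_base = rng.normal(8, 1.5, size=800)
        bias = 0.08 * (log_base - 8) ** 2
        values = np.exp2(np.column_stack([log_base, log_base, log_base + bias]))
        out = lowess_normalize(_table(values))
        # oracle: refit lowess to the corrected array's log ratio; the
        # remaining smooth bias curve (central mass, away from sparse
        # tails) must be <10% of the original bias amplitude
        residual = np.log2(out.values.iloc[:, 2].to_numpy()) - log_base
        curve = sm_lowess(residual, log_base, frac=0.3, return_sorted=False, xvals=log_base)
        lo, hi = np.quantile(log_base, [0.02, 0.98])
        central = (log_base > lo) & (log_base < hi)
        assert np.abs(curve[central]).max() < 0.1 * np.abs(bias).max()

    def test_idempotent_on_smooth_bias(self, rng):
        log_base = rng.normal(8, 1.5, size=800)
        bias = 0.2 * (log_base - 8) + 0.5
        values = np.exp2(np.column_stack([log_base, log_base, log_base + bias]))
        once = lowess_normalize(_table(values))
        twice = lowess_normalize(once)
        delta = np.abs(np.log2(twice.values.to_numpy()) - np.log2(once.values.to_numpy()))
        assert delta.max() < 1e-3

    def test_single_sample_rejected(self):
        with pytest.raises(PreprocessError):
            lowess_normalize(_table(np.ones((5, 1))))


class TestLiWong:
    def test_exact_rank_one_recovery(self):
        theta = np.array([1.0, 2.0, 4.0])
        phi = np.array([1.0, 1.0, 1.0, 1.0])
        fit = liwong_summarize(np.outer(phi, theta))
        r = np.corrcoef(fit.theta, theta)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.phi, phi, rtol=1e-6)

    def test_single_probe_degenerate(self):
        row = np.array([[3.0, 1.0, 7.0]])
        fit = liwong_summarize(row)
        np.testing.assert_allclose(fit.theta, row[0])
        np.testing.assert_allclose(fit.phi, [1.0])

    def test_corrupted_cell_flagged_and_recovered(self, rng):
        theta = np.linspace(1, 5, 8)
        phi = np.exp(rng.normal(0, 0.3, size=6))
        y = np.outer(phi, theta)
        y[2, 3] *= 10.0
        fit = liwong_summarize(y)
        assert fit.cell_outliers[2, 3]
        # oracle: the fit with the corrupted cell removed up front
        mask = np.ones_like(y, dtype=bool)
        mask[2, 3] = False
        theta_clean, _, _, _, _ = preprocess._als(y, mask, 1e-6, 50)
        r = np.corrcoef(fit.theta, theta_clean)[0, 1]
        assert r > 0.999

    def test_objective_non_increasing(self, rng):
        y = np.exp(rng.normal(5, 1, size=(6, 10)))
        fit = liwong_summarize(y)
        sse = np.array(fit.sse_path)
        assert np.all(np.diff(sse) <= 1e-8 * np.maximum(sse[:-1], 1))

    def test_scale_identifiability(self, rng):
        y = np.exp(rng.normal(5, 0.5, size=(5, 8)))
        f1 = liwong_summarize(y)
        f2 = liwong_summarize(10.0 * y)
        np.testing.assert_allclose(f2.theta, 10.0 * f1.theta, rtol=1e-4)
        np.testing.assert_allclose(f2.phi, f1.phi, rtol=1e-4)
        assert (f1.phi**2).sum() == pytest.approx(len(f1.phi), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(PreprocessError):
            liwong_summarize(np.zeros((3, 4)))


class TestGeneLevel:
    def test_single_probeset_gene_passthrough(self, rng):
        expr = pd.DataFrame(np.exp(rng.normal(5, 1, size=(1, 6))), index=["ps1"])
        out = summarize_gene_level(expr, {"ps1": "G1"})
        np.testing.assert_allclose(out.loc["G1"], expr.loc["ps1"])

    def test_rank_one_gene(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        expr = pd.DataFrame(np.outer([1.0, 2.0, 0.5], profile), index=["a", "b", "c"])
        out = summarize_gene_level(expr, {"a": "G", "b": "G", "c": "G"})
        r = np.corrcoef(out.loc["G"], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_planted_gene_fold_change_recovered(self, small_dataset):
        """Gene-level summarization recovers planted log2fc within 15%."""
        ds = small_dataset
        pm = ds.probe_map
        probeset_expr = preprocess.summarize_probesets(ds.intensity, pm)
        dedup = pm.drop_duplicates("probeset_id")
        keep = (dedup["region_kind"] != "antisense") & (dedup["gene_id"] != "BACKGROUND")
        mapping = dict(zip(dedup.loc[keep, "probeset_id"], dedup.loc[keep, "gene_id"]))
        gene_expr = summarize_gene_level(probeset_expr, mapping)
        truth = ds.gene_truth.set_index("gene_id")
        t0 = ds.config.tissues[0]
        dis = ds.intensity.samples_where(tissue=t0, disease="RC")
        ctl = ds.intensity.samples_where(tissue=t0, disease="control")
        pure = truth[(truth[f"log2fc_{t0}"] != 0)]
        assert len(pure) >= 3
        for gene in pure.index:
            log2 = np.log2(gene_expr.loc[gene])
            est = log2[dis].mean() - log2[ctl].mean()
            assert est == pytest.approx(truth.loc[gene, f"log2fc_{t0}"], rel=0.15)


class TestEffectiveProbesets:
    def test_background_level_not_effective(self, rng):
        bg = pd.DataFrame(np.exp2(rng.normal(6, 0.3, size=(20, 10))),
                          index=[f"bg{i}" for i in range(20)])
        probe = pd.DataFrame(np.exp2(np.full((1, 10), 6.0)), index=["at_bg"])
        flags = detect_effective_probesets(pd.concat([bg, probe]), bg.index)
        by_id = {f.probeset_id: f for f in flags}
        assert not by_id["at_bg"].effective

    def test_far_above_background_effective(self, rng):
        bg = pd.DataFrame(np.exp2(rng.normal(6, 0.3, size=(20, 10))),
                          index=[f"bg{i}" for i in range(20)])
        probe = pd.DataFrame(np.exp2(np.full((1, 10), 6.0 + 10 * 0.3)), index=["high"])
        flags = detect_effective_probesets(pd.concat([bg, probe]), bg.index)
        by_id = {f.probeset_id: f for f in flags}
        assert by_id["high"].effective
        assert by_id["high"].background_z > 5

    def test_planted_effective_set_recovered(self, small_dataset):
        """Flags recover the generator's effective/ineffective truth for
        antisense probesets with >= 95% accuracy."""
        ds = small_dataset
        expr = preprocess.summarize_probesets(ds.intensity, ds.probe_map)
        flags = detect_effective_probesets(expr, ds.background_ids)
        by_id = {f.probeset_id: f.effective for f in flags}
        truth = ds.probeset_truth.query("region_kind == 'antisense' and not is_background")
        if len(truth) == 0:
            pytest.skip("scenario planted no antisense probesets")
        correct = sum(
            by_id[row.probeset_id] == row.effective_true for row in truth.itertuples()
        )
        assert correct / len(truth) >= 0.95

    def test_empty_background_rejected(self):
        expr = pd.DataFrame(np.ones((2, 4)), index=["a", "b"])
        with pytest.raises(PreprocessError):
            detect_effective_probesets(expr, [])


class TestPca:
    def test_separated_groups_split_on_first_component(self, rng):
        g1 = np.exp2(rng.normal(8, 0.1, size=(50, 6)))
        g2 = np.exp2(rng.normal(8, 0.1, size=(50, 6)) + np.tile([0, 0, 0, 3, 3, 3], (50, 1)))
        expr = pd.DataFrame(g1 * 0 + g2, index=[f"g{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(6)])
        coords, explained = pca_embed(expr)
        a, b = coords.iloc[:3, 0], coords.iloc[3:, 0]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 5 * pooled_sd

    def test_duplicate_samples_identical_coordinates(self, rng):
        base = np.exp2(rng.normal(8, 1, size=(30, 1)))
        expr = pd.DataFrame(np.column_stack([base, base, base * 2, base * 0.5]),
                            columns=list("abcd"))
        coords, _ = pca_embed(expr)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_variance_explained_valid(self, rng):
        expr = pd.DataFrame(np.exp2(rng.normal(8, 1, size=(40, 8))))
        _, explained = pca_embed(expr, n_components=5)
        assert explained.sum() <= 1 + 1e-12
        assert np.all(np.diff(explained) <= 1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(PreprocessError):
            pca_embed(pd.DataFrame(np.ones((5, 4))))
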