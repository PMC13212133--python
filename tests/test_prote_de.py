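"""Per-protein linear models, empirical-Bayes moderation, BH, DEP overlap."""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from circamasld.prote_de import (
    ProteinMatrix,
    bh_adjust,
    fit_per_protein,
    intersect_deps,
    moderate,
    moderated_de,
)


def make_matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    return ProteinMatrix(values=values, protein_ids=ids,
                         participant_ids=[f"S{j}" for j in range(values.shape[1])])


class TestPerProteinFit:
    def test_zero_noise_equal_means(self):
        m = make_matrix(np.ones((5, 8)))
        res = fit_per_protein(m, [0, 0, 0, 0, 1, 1, 1, 1])
        assert np.allclose(res.log_fc, 0.0)

    def test_matches_hand_computed_pooled_t(self):
        # two proteins, groups of 3 and 3
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                         [0.0, 0.0, 1.0, 2.0, 2.0, 2.0]])
        g = [0, 0, 0, 1, 1, 1]
        res = fit_per_protein(make_matrix(vals), g)
        # protein 0: means 2 and 5, pooled var = (2+2)/4 = 1
        assert res.log_fc[0] == pytest.approx(3.0)
        assert res.s2_g[0] == pytest.approx(1.0)
        assert res.t[0] == pytest.approx(3.0 / np.sqrt(1 * (1 / 3 + 1 / 3)))
        from scipy.stats import ttest_ind
        t_ref, p_ref = ttest_ind(vals[1, 3:], vals[1, :3], equal_var=True)
        assert res.t[1] == pytest.approx(t_ref)
        assert res.p_value[1] == pytest.approx(p_ref)

    def test_permutation_null_uniform_p(self, rng):
        vals = rng.normal(size=(200, 40))
        g = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = fit_per_protein(make_matrix(vals), g)
        # under the null, roughly alpha of raw p-values fall below alpha
        assert 0.01 < (res.p_value < 0.05).mean() < 0.10

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fit_per_protein(make_matrix(np.ones((3, 5))), [0, 0, 0, 0, 1])


class TestModeration:
    def test_forced_small_d0_recovers_ordinary_t(self, rng):
        vals = rng.normal(size=(50, 30))
        g = np.r_[np.zeros(15, int), np.ones(15, int)]
        fits = fit_per_protein(make_matrix(vals), g)
        mod = moderate(fits.s2_g, float(fits.df_g[0]), log_fc=fits.log_fc,
                       n1=15, n0=15, d0_override=1e-8)
        assert np.allclose(mod["t_moderated"], fits.t, rtol=1e-4)

    def test_identical_variances_degenerate_prior(self):
        s2 = np.full(50, 2.5)
        mod = moderate(s2, 18.0)
        assert mod["s0_sq"] == pytest.approx(2.5, rel=1e-3)
        assert np.allclose(mod["s2_tilde"], 2.5, rtol=1e-3)

    def test_prior_recovery_from_simulation(self, rng):
        # variances from a scaled inverse-chi-square with known prior
        d0_true, s0_true, df = 6.0, 1.5, 18
        n_prot = 2000
        true_var = d0_true * s0_true / rng.chisquare(d0_true, n_prot)
        s2 = true_var * rng.chisquare(df, n_prot) / df
        mod = moderate(s2, float(df))
        assert mod["d0"] == pytest.approx(d0_true, rel=0.2)
        assert mod["s0_sq"] == pytest.approx(s0_true, rel=0.2)

    def test_shrinkage_largest_for_extreme_variances(self, rng):
        d0_true, s0_true, df = 6.0, 1.0, 10
        true_var = d0_true * s0_true / rng.chisquare(d0_true, 500)
        s2 = true_var * rng.chisquare(df, 500) / df
        lfc = rng.normal(size=500)
        fitsmod = moderate(s2, float(df), log_fc=lfc, n1=6, n0=6)
        t_ord = lfc / np.sqrt(s2 * (1 / 6 + 1 / 6))
        gap = np.abs(fitsmod["t_moderated"] - t_ord)
        # the smallest sample variances get the largest |t| correction
        assert np.corrcoef(np.log(s2), gap)[0, 1] < -0.3
        assert gap[np.argmin(s2)] > np.median(gap)

    def test_matches_r_limma_on_small_matrix(self, tmp_path):
        # independent oracle: Bioconductor limma eBayes on the same data
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(40, 12)) * rng.gamma(2, 1, (40, 1))
        g = np.r_[np.zeros(6, int), np.ones(6, int)]
        fits = fit_per_protein(make_matrix(vals), g)
        mod = moderate(fits.s2_g, float(fits.df_g[0]), log_fc=fits.log_fc,
                       n1=6, n0=6)
        mat = tmp_path / "m.csv"
        pd.DataFrame(vals).to_csv(mat, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{mat}"))
            design <- cbind(1, c(rep(0,6), rep(1,6)))
            fit <- eBayes(lmFit(x, design))
            cat(fit$df.prior, fit$s2.prior, "\\n")
            write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
                      "{tmp_path / 'out.csv'}", row.names=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if r.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {r.stderr[:200]}")
        d0_r, s0_r = map(float, r.stdout.split()[:2])
        ref = pd.read_csv(tmp_path / "out.csv")
        assert mod["d0"] == pytest.approx(d0_r, rel=1e-3)
        assert mod["s0_sq"] == pytest.approx(s0_r, rel=1e-3)
        assert np.allclose(mod["t_moderated"], ref.t, rtol=1e-6)
        assert np.allclose(mod["p_value"], ref.p, rtol=1e-6)


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_order_invariance_and_monotone(self, rng):
        p = rng.random(100)
        adj = bh_adjust(p)
        perm = rng.permutation(100)
        adj_perm = bh_adjust(p[perm])
        assert np.allclose(adj[perm], adj_perm)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDEPIntersection:
    def _results(self, ids, sig):
        return pd.DataFrame({"protein_id": ids,
                             "p_adjusted": [0.01 if p in sig else 0.5 for p in ids]})

    def test_disjoint_sets_empty_common(self):
        ids = list("ABCDEF")
        deps = intersect_deps(self._results(ids, {"A"}),
                              self._results(ids, {"B"}), 0.05)
        assert deps.common == frozenset()

    def test_identical_sets_idempotent(self):
        ids = list("ABCDEF")
        deps = intersect_deps(self._results(ids, {"A", "C"}),
                              self._results(ids, {"A", "C"}), 0.05)
        assert deps.common == frozenset({"A", "C"})

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersect_deps(self._results(list("ABC"), set()),
                           self._results(list("ABD"), set()), 0.05)

    def test_planted_effect_recovery(self, rng):
        # 50 proteins shifted in both contrasts, 950 null, n=400
        n, n_prot, n_sig = 400, 1000, 50
        g1 = rng.integers(0, 2, n)
        g2 = rng.integers(0, 2, n)
        vals = rng.normal(size=(n_prot, n))
        vals[:n_sig] += 0.6 * g1 + 0.6 * g2
        m = make_matrix(vals)
        deps = intersect_deps(moderated_de(m, g1), moderated_de(m, g2), 0.05)
        planted = {f"P{i}" for i in range(n_sig)}
        recall = len(deps.common & planted) / n_sig
        false_frac = len(deps.common - planted) / max(len(deps.common), 1)
        assert recall >= 0.9
        assert false_frac <= 0.05

    def test_null_matrix_dep_counts(self, rng):
        # raw p < alpha near alpha * n; adjusted DEPs near zero
        raw_frac, adj_count = [], []
        for _ in range(30):
            vals = rng.normal(size=(300, 60))
            g = np.r_[np.zeros(30, int), np.ones(30, int)]
            res = moderated_de(make_matrix(vals), g)
            raw_frac.append((res.p_value < 0.05).mean())
            adj_count.append((res.p_adjusted < 0.05).sum())
        assert np.mean(raw_frac) == pytest.approx(0.05, abs=0.015)
        assert np.mean(adj_count) < 1.0


class TestMatrixHygiene:
    def test_missingness_filter_and_imputation(self):
        vals = np.ones((3, 10))
        vals[0, :4] = np.nan          # 40% missing -> dropped
        vals[1, 0] = np.nan           # 10% missing -> mean imputed
        frame = pd.DataFrame(vals, index=["A", "B", "C"],
                             columns=[f"S{j}" for j in range(10)])
        m = ProteinMatrix.from_frame(frame)
        assert m.protein_ids == ["B", "C"]
        assert not np.isnan(m.values).any()
        assert m.values[0, 0] == pytest.approx(1.0)
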