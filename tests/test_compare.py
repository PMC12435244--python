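"""Fold-change calls, repression profiles, correlations and top-k reporting."""
import numpy as np
import pandas as pd
import pytest

from dielphase import (
    InvalidInputError,
    RepressionProfile,
    correlate_profiles,
    fc_correlation,
    gen_correlated_profiles,
    log2fc_test,
    repression_profile,
    top_repressed,
)


def tpm_frame(means, noise_sd, reps, rng, prefix="s"):
    """Genes x replicates TPM table around log2 means."""
    x = np.asarray(means, float)[:, None] + rng.normal(0, noise_sd, (len(means), reps))
    return pd.DataFrame(
        np.clip(np.exp2(x) - 1, 0, None),
        index=pd.Index([f"g{k:04d}" for k in range(len(means))], name="gene_id"),
        columns=[f"{prefix}{j}" for j in range(reps)],
    )


class TestLog2fcTest:
    def test_permuted_replicates_no_calls(self):
        rng = np.random.default_rng(0)
        a = tpm_frame(rng.uniform(2, 10, 200), 0.2, 3, rng)
        b = a[[a.columns[2], a.columns[0], a.columns[1]]]
        res = log2fc_test(a, b)
        assert np.allclose(res.table["log2fc"], 0.0)
        assert res.n_up == 0 and res.n_down == 0

    def test_planted_fourfold_gene_called_up(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(4, 8, 500)
        test_means = base.copy()
        test_means[0] += 2.0  # 4-fold up on the TPM scale
        m_ref = tpm_frame(base, 0.05, 3, rng, "r")
        m_test = tpm_frame(test_means, 0.05, 3, rng, "t")
        res = log2fc_test(m_test, m_ref)
        assert res.table["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.15)
        assert res.table["call"].iloc[0] == "up"

    def test_null_genes_essentially_never_called(self):
        rng = np.random.default_rng(2)
        means = rng.uniform(3, 9, 10000)
        a = tpm_frame(means, 0.25, 3, rng, "a")
        b = tpm_frame(means, 0.25, 3, rng, "b")
        res = log2fc_test(a, b)
        assert (res.n_up + res.n_down) / len(means) <= 1e-4

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = tpm_frame(rng.uniform(2, 10, 50), 0.3, 3, rng, "a")
        b = tpm_frame(rng.uniform(2, 10, 50), 0.3, 3, rng, "b")
        fwd = log2fc_test(a, b).table["log2fc"]
        rev = log2fc_test(b, a).table["log2fc"]
        assert np.allclose(fwd, -rev)

    def test_bh_monotone_in_rank(self):
        rng = np.random.default_rng(4)
        a = tpm_frame(rng.uniform(2, 10, 300), 0.3, 3, rng, "a")
        b = tpm_frame(rng.uniform(2, 10, 300), 0.3, 3, rng, "b")
        tab = log2fc_test(a, b).table.sort_values("p")
        assert (np.diff(tab["padj"]) >= -1e-12).all()
        assert (tab["padj"] >= tab["p"] - 1e-12).all()

    def test_mismatched_gene_sets_rejected(self):
        rng = np.random.default_rng(5)
        a = tpm_frame(np.full(10, 5.0), 0.1, 3, rng)
        with pytest.raises(InvalidInputError):
            log2fc_test(a, a.iloc[:-1])


class TestRepressionProfile:
    def test_direct_formula(self):
        ref = pd.DataFrame({"r1": [1000.0], "r2": [1000.0]}, index=pd.Index(["g"], name="gene_id"))
        test = pd.DataFrame({"t1": [10.0], "t2": [10.0]}, index=ref.index)
        p = repression_profile(ref, test)
        assert p.values["g"] == pytest.approx(np.log10(1001.0 / 11.0), rel=1e-12)

    def test_equal_expression_is_zero_and_zero_tpm_finite(self):
        ref = pd.DataFrame({"r1": [50.0, 200.0]}, index=pd.Index(["a", "b"], name="gene_id"))
        ref["r2"] = ref["r1"]
        test = ref.copy()
        test.loc["b"] = 0.0
        p = repression_profile(ref, test)
        assert p.values["a"] == 0.0
        assert p.values["b"] == pytest.approx(np.log10(201.0))

    def test_floor_excludes_weak_reference_genes(self):
        ref = pd.DataFrame({"r1": [0.2, 10.0], "r2": [0.2, 10.0]},
                           index=pd.Index(["lo", "hi"], name="gene_id"))
        p = repression_profile(ref, ref)
        assert list(p.values.index) == ["hi"]


class TestCorrelations:
    def test_profile_self_correlation(self):
        p, _ = gen_correlated_profiles(100, 0.5, seed=1)
        assert correlate_profiles(p, p).pearson_r == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.25, 0.71, 0.89])
    def test_planted_rho_recovered(self, rho):
        p1, p2 = gen_correlated_profiles(2500, rho, seed=7)
        r = correlate_profiles(p1, p2).pearson_r
        assert abs(r - rho) < 0.03

    def test_too_few_shared_genes_rejected(self):
        idx = pd.Index(["a", "b"], name="gene_id")
        p = RepressionProfile(values=pd.Series([0.1, 0.2], index=idx))
        with pytest.raises(InvalidInputError):
            correlate_profiles(p, p)

    def test_fc_correlation_self_and_locked_transcriptome(self):
        """A strain whose low-light transcriptome mirrors the reference's
        high-light response correlates strongly with the high-light contrast."""
        rng = np.random.default_rng(8)
        n = 2500
        ll_means = rng.uniform(3, 9, n)
        hl_shift = rng.normal(0, 1.0, n)
        wt_ll = tpm_frame(ll_means, 0.1, 3, rng, "a")
        wt_hl = tpm_frame(ll_means + hl_shift, 0.1, 3, rng, "b")
        mut_ll = tpm_frame(ll_means + hl_shift + rng.normal(0, 0.1, n), 0.1, 3, rng, "c")
        c_light = log2fc_test(wt_hl, wt_ll)
        c_strain = log2fc_test(mut_ll, wt_ll)
        assert fc_correlation(c_light, c_light).pearson_r == pytest.approx(1.0)
        assert fc_correlation(c_light, c_strain).pearson_r >= 0.9
        # two independent contrasts decorrelate
        indep = log2fc_test(
            tpm_frame(ll_means + rng.normal(0, 1.0, n), 0.1, 3, rng, "d"), wt_ll
        )
        assert abs(fc_correlation(c_light, indep).pearson_r) < 0.05


class TestTopRepressed:
    @staticmethod
    def profile(values: dict) -> RepressionProfile:
        return RepressionProfile(
            values=pd.Series(values, name="r").rename_axis("gene_id")
        )

    def test_known_ordering_recovered(self):
        rng = np.random.default_rng(9)
        vals = {f"g{k:03d}": v for k, v in enumerate(rng.permutation(np.linspace(0, 3, 50)))}
        top = top_repressed(self.profile(vals), k=20)
        expect = sorted(vals, key=lambda g: -vals[g])[:20]
        assert list(top.table.index) == expect

    def test_tie_break_lexicographic(self):
        top = top_repressed(self.profile({"gb": 1.0, "ga": 1.0, "gc": 2.0}), k=2)
        assert list(top.table.index) == ["gc", "ga"]

    def test_fivefold_check_against_reference(self):
        p = self.profile({f"g{k}": 2.0 - 0.1 * k for k in range(10)})
        check_pass = self.profile({f"g{k}": 1.0 for k in range(10)})    # 10-fold
        check_fail = self.profile({f"g{k}": 0.5 for k in range(10)})    # ~3.2-fold
        assert top_repressed(p, k=5, check_ref=check_pass).all_pass
        report = top_repressed(p, k=5, check_ref=check_fail)
        assert not report.all_pass and not report.table["passes"].any()

    def test_monotone_transform_stability(self):
        rng = np.random.default_rng(10)
        vals = {f"g{k:03d}": float(v) for k, v in enumerate(rng.normal(0, 1, 40))}
        t1 = top_repressed(self.profile(vals), k=10)
        t2 = top_repressed(self.profile({g: 3 * v + 1 for g, v in vals.items()}), k=10)
        assert list(t1.table.index) == list(t2.table.index)

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(InvalidInputError):
            top_repressed(self.profile({"a": 1.0}), k=2)
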