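"""Diel phase classification, the 4-SD amplitude filter and inversion calls."""
import numpy as np
import pandas as pd
import pytest

from dielphase import (
    DielMatrix,
    InvalidInputError,
    SimConfig,
    class_counts,
    classify_phase,
    dawn_dusk_scatter,
    gen_diel_matrix,
    phase_inversion,
    strong_circadian_filter,
)
from dielphase.matrix import TIMEPOINTS


def matrix_from_levels(levels: dict[str, list[float]], reps=3, condition="wt") -> DielMatrix:
    """Matrix with identical replicate values per timepoint (zero variance)."""
    genes = sorted(levels)
    cols = pd.MultiIndex.from_product([TIMEPOINTS, range(1, reps + 1)])
    rows = []
    for g in genes:
        d3, dn, d4 = levels[g]
        rows.append([d3] * reps + [dn] * reps + [d4] * reps)
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=cols)
    return DielMatrix(tpm=df, condition=condition)


class TestClassifyPhase:
    def test_unambiguous_dusk_peak_is_class1(self):
        m = matrix_from_levels({"gA": [100, 10, 100], "gB": [10, 100, 10]})
        with pytest.warns(UserWarning, match="variance floor"):
            calls = classify_phase(m)
        assert calls.loc["gA", "cls"] == "I"
        assert calls.loc["gB", "cls"] == "II"
        assert calls.loc["gA", "amplitude"] > 0 > calls.loc["gB", "amplitude"]

    def test_flat_gene_is_noncircadian(self):
        m = matrix_from_levels({"gA": [50, 50, 50], "gB": [100, 10, 100]})
        with pytest.warns(UserWarning):
            calls = classify_phase(m)
        assert calls.loc["gA", "cls"] == "NC"
        assert calls.loc["gA", "amplitude"] == 0.0

    def test_zero_variance_nonzero_amplitude_retained(self):
        """Degenerate zero replicate variance: floor applies, gene is kept."""
        m = matrix_from_levels({"gA": [400, 5, 400], "gB": [30, 30, 30]})
        with pytest.warns(UserWarning, match="variance floor"):
            calls = classify_phase(m)
        assert calls.loc["gA", "strong"]

    def test_low_expression_forced_noncircadian(self):
        m = matrix_from_levels({"gA": [0.9, 0.0, 0.9], "gB": [100, 10, 100]})
        with pytest.warns(UserWarning):
            calls = classify_phase(m)
        assert calls.loc["gA", "low_expression"]
        assert calls.loc["gA", "cls"] == "NC" and not calls.loc["gA", "strong"]

    def test_planted_recovery_among_high_amplitude_genes(self, small_noisy):
        m, truth = small_noisy
        calls = classify_phase(m)
        confident = truth["true_z"] > 4
        agree = (calls.loc[confident.index[confident], "cls"]
                 == truth.loc[confident, "true_class"]).mean()
        assert agree >= 0.99

    def test_single_replicate_rejected(self):
        cols = pd.MultiIndex.from_product([TIMEPOINTS, [1]])
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=pd.Index(["g"], name="gene_id"), columns=cols)
        with pytest.raises(InvalidInputError):
            DielMatrix(tpm=df)


class TestClassifyProperties:
    def test_partition(self, small_noisy):
        m, _ = small_noisy
        counts = class_counts(classify_phase(m))
        assert sum(counts.values()) == m.n_genes

    def test_replicate_permutation_invariance(self, small_noisy):
        m, _ = small_noisy
        calls = classify_phase(m)
        shuffled = m.tpm.copy()
        for tp in TIMEPOINTS:  # reverse replicate order within each timepoint
            vals = shuffled[tp].to_numpy()[:, ::-1]
            for j, rep in enumerate(sorted(c for c in shuffled[tp].columns)):
                shuffled[(tp, rep)] = vals[:, j]
        calls2 = classify_phase(DielMatrix(tpm=shuffled, condition=m.condition))
        pd.testing.assert_frame_equal(calls, calls2)

    def test_dawn_dusk_swap_antisymmetry(self):
        """Swapping dawn and dusk roles maps Class I to Class II and back."""
        levels = {"g1": [200, 20, 200], "g2": [20, 200, 20], "g3": [50, 50, 50]}
        m = matrix_from_levels(levels)
        swapped = matrix_from_levels({g: [v[1], v[0], v[1]] for g, v in levels.items()})
        with pytest.warns(UserWarning):
            calls = classify_phase(m)
        with pytest.warns(UserWarning):
            calls_sw = classify_phase(swapped)
        mapping = {"I": "II", "II": "I", "NC": "NC"}
        assert (calls_sw["cls"] == calls["cls"].map(mapping)).all()

    def test_amplitude_monotone_in_planted_amplitude(self):
        zs = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            cfg = SimConfig(seed=3, n_genes_per_class={"I": 100, "NC": 20},
                            amplitude_log2=amp, noise_sd_log2=0.25)
            m, truth = gen_diel_matrix(cfg)
            calls = classify_phase(m)
            zs.append(calls.loc[truth["true_class"] == "I", "z_amp"].mean())
        assert all(a < b for a, b in zip(zs, zs[1:]))


class TestStrongFilter:
    def test_threshold_boundary(self):
        calls = pd.DataFrame(
            {
                "cls": ["I", "I"],
                "amplitude": [1.0, 1.0],
                "z_amp": [4.1, 3.9],
                "strong": [True, False],
                "low_expression": [False, False],
            },
            index=pd.Index(["keep", "drop"], name="gene_id"),
        )
        kept = strong_circadian_filter(calls, z_threshold=4)
        assert list(kept.index) == ["keep"]

    def test_null_pass_rate_below_stated_significance(self):
        """Planted-flat genes pass the 4-SD filter at no more than the 0.001 rate."""
        cfg = SimConfig(seed=19, n_genes_per_class={"NC": 20000}, noise_sd_log2=0.25)
        m, _ = gen_diel_matrix(cfg)
        calls = classify_phase(m)
        assert strong_circadian_filter(calls).shape[0] / m.n_genes <= 0.001


class TestPhaseInversion:
    def test_trivial_flip_detected(self):
        ref = matrix_from_levels({"g": [10, 100, 10]})    # dawn-peaked: Class II
        test = matrix_from_levels({"g": [100, 10, 100]})  # dusk-peaked in test
        with pytest.warns(UserWarning):
            calls_ref = classify_phase(ref)
        with pytest.warns(UserWarning):
            calls_test = classify_phase(test)
        inv = phase_inversion(calls_ref, calls_test)
        assert inv.inverted["g"]
        assert inv.fraction_class2_inverted == 1.0

    def test_identical_calls_no_inversions(self, small_noisy):
        m, _ = small_noisy
        calls = classify_phase(m)
        inv = phase_inversion(calls, calls)
        assert not inv.inverted.any()
        assert inv.fraction_class2_inverted == 0.0
        assert inv.transitions.to_numpy().sum() == m.n_genes

    def test_simulated_inversion_fraction_near_one(self):
        cfg = SimConfig(seed=8, n_genes_per_class={"I": 100, "II": 80, "NC": 20},
                        noise_sd_log2=0.1)
        m_wt, _ = gen_diel_matrix(cfg, mode="wt")
        m_inv, _ = gen_diel_matrix(cfg, mode="inverted")
        calls_wt = classify_phase(m_wt)
        calls_inv = classify_phase(m_inv)
        inv = phase_inversion(calls_wt, calls_inv)
        assert inv.fraction_class2_inverted >= 0.98

    def test_gene_universe_mismatch_rejected(self, small_noisy):
        m, _ = small_noisy
        calls = classify_phase(m)
        with pytest.raises(InvalidInputError):
            phase_inversion(calls, calls.iloc[:-1])


class TestDawnDuskScatter:
    def test_diagonal_contract(self):
        m = matrix_from_levels(
            {"c1": [100, 10, 100], "c2": [10, 100, 10], "flat": [40, 40, 40]}
        )
        sc = dawn_dusk_scatter(m)
        assert sc.loc["c1", "dawn_side"] == "below"   # Class I: dawn under diagonal
        assert sc.loc["c2", "dawn_side"] == "above"   # Class II: dawn over diagonal
        assert sc.loc["flat", "dusk_side"] == "on"
        assert sc.loc["c1", "dusk_dev"] == 0.0
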