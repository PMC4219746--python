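"""Preprocessing, differential expression (Welch t + BH), fold-change
classification and tissue-response comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grnbench.data_io import ExpressionMatrix
from grnbench.expression_analysis import (
    Contrast,
    PerturbationCall,
    benjamini_hochberg,
    classify_perturbation_response,
    differential_expression,
    filter_low_signal,
    fold_change_correlation,
    perturbation_consistency_curve,
    perturbation_contrasts,
    replicate_split_correlation,
    select_most_variable,
    tissue_response_comparison,
)


def matrix_from(values: pd.DataFrame, probe_genes=None) -> ExpressionMatrix:
    metadata = pd.DataFrame(
        {
            "condition_class": "time_series",
            "tissue": "m",
            "stage": "E13",
            "perturbed_entity": "",
            "replicate_group": "g",
        },
        index=values.columns,
    )
    return ExpressionMatrix(values, metadata, probe_genes)


class TestLowSignalFilter:
    def test_mean_threshold_removes_dim_probes(self):
        values = pd.DataFrame(
            [[3.0] * 4, [7.0] * 4, [9.0] * 4], index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(4)],
        )
        em = filter_low_signal(matrix_from(values), threshold=5)
        assert list(em.values.index) == ["b", "c"]

    def test_zero_threshold_is_identity_on_positive_data(self):
        values = pd.DataFrame(
            np.full((3, 4), 2.0), index=list("abc"), columns=[f"s{i}" for i in range(4)]
        )
        assert filter_low_signal(matrix_from(values), threshold=0).values.shape == (3, 4)

    def test_removing_everything_is_a_hard_error(self):
        values = pd.DataFrame(
            np.full((3, 4), 2.0), index=list("abc"), columns=[f"s{i}" for i in range(4)]
        )
        with pytest.raises(ValueError, match="every probe"):
            filter_low_signal(matrix_from(values), threshold=100)


class TestMostVariable:
    def _matrix(self, variances, genes=None):
        rng = np.random.default_rng(0)
        rows = [rng.standard_normal(40) * np.sqrt(v) for v in variances]
        values = pd.DataFrame(
            rows, index=[f"p{i}" for i in range(len(variances))],
            columns=[f"s{i}" for i in range(40)],
        )
        pg = None
        if genes is not None:
            pg = pd.Series(genes, index=values.index, name="gene")
        return matrix_from(values, pg)

    def test_top_k_by_variance(self):
        em = select_most_variable(self._matrix([1, 5, 10, 0.1, 7]), k=3)
        assert set(em.values.index) == {"p1", "p2", "p4"}

    def test_anchor_probes_join_the_union(self):
        genes = ["g0", "g1", "g2", "anchor", "g4"]
        em = select_most_variable(self._matrix([1, 5, 10, 0.001, 7], genes), k=3,
                                  anchor_genes={"anchor"})
        assert set(em.values.index) == {"p1", "p2", "p4", "p3"}

    def test_exact_variance_ties_at_boundary_keep_both(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(40)
        values = pd.DataFrame(
            [row * 3, row * 2, row * 2, row], index=list("abcd"),
            columns=[f"s{i}" for i in range(40)],
        )
        em = select_most_variable(matrix_from(values), k=2)
        # rank-2 variance is tied between b and c: superset retained
        assert set(em.values.index) == {"a", "b", "c"}


class TestDifferentialExpression:
    def test_null_contrast_yields_zero_fold_change_and_no_calls(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((20, 4))
        values = pd.DataFrame(
            np.hstack([base, base]),  # identical group profiles
            index=[f"p{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(8)],
        )
        de = differential_expression(
            matrix_from(values), Contrast("c", tuple(f"s{i}" for i in range(4)),
                                          tuple(f"s{i}" for i in range(4, 8))),
        )
        assert np.allclose(de["log2_fold_change"], 0)
        assert (de["bh_adjusted_p"] > 0.99).all()

    def test_constructed_shift_is_recovered_and_significant(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            np.vstack([
                np.concatenate([rng.normal(10, 0.1, 4), rng.normal(8, 0.1, 4)]),
                rng.normal(5, 0.1, 8),
            ]),
            index=["hit", "flat"], columns=[f"s{i}" for i in range(8)],
        )
        de = differential_expression(
            matrix_from(values), Contrast("c", tuple(f"s{i}" for i in range(4)),
                                          tuple(f"s{i}" for i in range(4, 8))),
        ).set_index("probe")
        assert de.loc["hit", "log2_fold_change"] == pytest.approx(2.0, abs=0.3)
        assert de.loc["hit", "bh_adjusted_p"] < 0.05
        assert de.loc["flat", "bh_adjusted_p"] > 0.05

    def test_small_group_is_rejected_by_name(self):
        values = pd.DataFrame(
            np.ones((2, 3)), index=["a", "b"], columns=["s0", "s1", "s2"]
        )
        with pytest.raises(ValueError, match="group B"):
            differential_expression(
                matrix_from(values), Contrast("c", ("s0", "s1"), ("s2",))
            )


class TestBenjaminiHochberg:
    @staticmethod
    def step_up(p):
        """Independent brute-force BH: sort, scale by m/rank, enforce
        monotonicity from the largest p down, clip at 1, unsort."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adjusted, 1.0)
        return out

    def test_hand_worked_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for n in (1, 2, 10, 100, 1000):
            p = rng.uniform(size=n)
            assert np.max(np.abs(benjamini_hochberg(p) - self.step_up(p))) < 1e-12
        # with heavy ties
        p = rng.integers(0, 5, size=200) / 5.0
        assert np.max(np.abs(benjamini_hochberg(p) - self.step_up(p))) < 1e-12

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=300)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()


def _de_table(fcs, bhs, contrast="c"):
    n = len(fcs)
    return pd.DataFrame(
        {
            "probe": [f"p{i}" for i in range(n)],
            "gene": [f"g{i}" for i in range(n)],
            "log2_fold_change": fcs,
            "raw_p": bhs,
            "bh_adjusted_p": bhs,
            "contrast": contrast,
        }
    )


class TestPerturbationCalls:
    def _pairs(self, targets, regulator="R"):
        return pd.DataFrame({"regulator": regulator, "target": list(targets)})

    def _contrast(self, direction):
        return Contrast("c", ("a", "b"), ("c", "d"), perturbed_entity="R",
                        direction=direction)

    def test_stimulation_contrast_above_cutoff_supports_activation(self):
        de = _de_table([1.5], [0.01]).assign(gene=["T"])
        (call,) = classify_perturbation_response(de, self._contrast("gain"),
                                                 self._pairs(["T"]), tau=1.0)
        assert call.observed_sign == +1 and call.log2_fold_change == 1.5

    def test_loss_contrast_flips_sign_orientation(self):
        de = _de_table([-1.5], [0.01]).assign(gene=["T"])
        (call,) = classify_perturbation_response(de, self._contrast("loss"),
                                                 self._pairs(["T"]), tau=1.0)
        assert call.observed_sign == +1  # knockout lowered target => activation

    def test_below_cutoff_is_silent(self):
        de = _de_table([0.4], [0.5]).assign(gene=["T"])
        (call,) = classify_perturbation_response(de, self._contrast("gain"),
                                                 self._pairs(["T"]), tau=1.0)
        assert call.observed_sign == 0

    def test_unmeasured_target_is_skipped_not_fabricated(self):
        de = _de_table([0.4], [0.5]).assign(gene=["other"])
        calls = classify_perturbation_response(de, self._contrast("gain"),
                                               self._pairs(["T"]), tau=1.0)
        assert calls == []

    def test_gene_with_many_probes_uses_largest_magnitude(self):
        de = _de_table([0.2, -1.8, 0.9], [0.5, 0.01, 0.1]).assign(gene=["T", "T", "T"])
        (call,) = classify_perturbation_response(de, self._contrast("gain"),
                                                 self._pairs(["T"]), tau=1.0)
        assert call.log2_fold_change == -1.8


class TestConsistencyCurve:
    def _calls(self, fcs, pairs):
        return [
            PerturbationCall(r, t, int(np.sign(fc)), fc, 0.0, "c")
            for (r, t), fc in zip(pairs, fcs)
        ]

    def _literature(self, modes, pairs):
        return pd.DataFrame(
            {
                "regulator": [r for r, _ in pairs],
                "target": [t for _, t in pairs],
                "mode": modes,
            }
        )

    def test_zero_cutoff_counts_only_sign_concordant_positives(self):
        pairs = [("R", "A"), ("R", "B"), ("R", "C")]
        lit = self._literature(["activating", "inhibiting", "none"], pairs)
        calls = self._calls([0.8, 0.5, 0.3], pairs)  # B discordant (+ for inhibiting)
        curve = perturbation_consistency_curve(calls, lit, [0.0])
        assert curve.loc[0, "tp_rate"] == pytest.approx(0.5)
        assert curve.loc[0, "fp_rate"] == pytest.approx(1.0)  # all negatives fire

    def test_infinite_cutoff_silences_everything(self):
        pairs = [("R", "A"), ("R", "B")]
        lit = self._literature(["activating", "none"], pairs)
        curve = perturbation_consistency_curve(
            self._calls([2.0, 2.0], pairs), lit, [np.inf]
        )
        assert curve.loc[0, "tp_rate"] == 0 and curve.loc[0, "fp_rate"] == 0

    def test_rates_are_monotone_non_increasing_in_tau(self, tooth_benchmark):
        curve = tooth_benchmark["consistency_curve"]
        assert (np.diff(curve["tp_rate"]) <= 1e-12).all()
        assert (np.diff(curve["fp_rate"]) <= 1e-12).all()

    def test_empty_negative_set_reports_missing_not_zero(self):
        pairs = [("R", "A")]
        lit = self._literature(["activating"], pairs)
        curve = perturbation_consistency_curve(self._calls([2.0], pairs), lit, [0.5])
        assert np.isnan(curve.loc[0, "fp_rate"])


class TestTissueResponse:
    def test_identical_tables_flag_nothing_and_correlate_perfectly(self):
        de = _de_table(np.linspace(-2, 2, 30), np.linspace(0.001, 0.9, 30))
        result = tissue_response_comparison(de, de.copy(), fdr=0.05)
        assert len(result.flagged) == 0
        assert result.correlation == pytest.approx(1.0)

    def test_constructed_single_tissue_hits_are_counted_exactly(self):
        n = 200
        bh_a = np.concatenate([np.full(50, 0.001), np.full(n - 50, 0.5)])
        bh_b = np.full(n, 0.5)
        rng = np.random.default_rng(0)
        de_a = _de_table(rng.normal(size=n), bh_a)
        de_b = _de_table(rng.normal(size=n), bh_b)
        result = tissue_response_comparison(de_a, de_b, fdr=0.05)
        assert len(result.flagged) == 50

    def test_independent_fold_changes_correlate_near_zero(self):
        rng = np.random.default_rng(3)
        n = 1000
        de_a = _de_table(rng.normal(size=n), np.full(n, 0.5))
        de_b = _de_table(rng.normal(size=n), np.full(n, 0.5))
        assert abs(fold_change_correlation(de_a, de_b)) < 3 / np.sqrt(n)

    def test_disjoint_probe_sets_are_an_error(self):
        de_a = _de_table([1.0], [0.5])
        de_b = _de_table([1.0], [0.5]).assign(probe=["other"])
        with pytest.raises(ValueError, match="share no probes"):
            tissue_response_comparison(de_a, de_b)


class TestReplicateControls:
    def test_replicate_split_beats_independent_perturbations(self):
        """Positive control (split replicates of one perturbation) correlates
        far above the negative control (two independent perturbations)."""
        from grnbench.synthetic_data import sample_grn, simulate_perturbation

        grn = sample_grn(n_genes=40, density=0.05, seed=11, tissues=("m",), n_no_effect=10)
        regs = sorted(grn.regulators, key=lambda g: -(grn.W[grn.index_of(g)] != 0).sum())
        em1 = simulate_perturbation(grn, regs[0], "loss", replicates=6, seed=1, tissue="m")
        em2 = simulate_perturbation(grn, regs[1], "loss", replicates=6, seed=2, tissue="m")
        (c1,) = perturbation_contrasts(em1)
        (c2,) = perturbation_contrasts(em2)
        positive = replicate_split_correlation(em1, c1, seed=0)
        de1 = differential_expression(em1, c1)
        de2 = differential_expression(em2, c2)
        negative = fold_change_correlation(de1, de2)
        assert positive > negative + 0.2
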