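"""Ground-truth generator: GRN sampling invariants, steady-state expression
against SEM closed forms, clamp-and-resolve perturbations, and the noisy
evidence emitter against its own conditional matrix."""

import numpy as np
import pandas as pd
import pytest

from grnbench.evidence_integration import NoiseModel, SIGNS, integrate_evidence
from grnbench.synthetic_data import (
    GroundTruthGRN,
    emit_evidence,
    evidence_to_records,
    make_benchmark,
    sample_grn,
    simulate_expression,
    simulate_perturbation,
)


def chain_grn(weights, tissues=("m",)) -> GroundTruthGRN:
    """G1 -> G2 -> ... with the given edge weights, active everywhere."""
    n = len(weights) + 1
    genes = [f"G{i}" for i in range(1, n + 1)]
    W = np.zeros((n, n))
    for i, w in enumerate(weights):
        W[i, i + 1] = w
    masks = {t: W != 0 for t in tissues}
    return GroundTruthGRN(genes, W, masks, [])


def ts_metadata(n_samples, tissue="m", stage="E13") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "condition_class": "time_series",
            "tissue": tissue,
            "stage": stage,
            "perturbed_entity": "",
            "replicate_group": "g",
        }
    )


class TestSampleGrn:
    def test_reproducible_and_invariants_hold(self):
        a = sample_grn(n_genes=50, density=0.02, frac_inhibiting=0.25, seed=1)
        b = sample_grn(n_genes=50, density=0.02, frac_inhibiting=0.25, seed=1)
        assert np.array_equal(a.W, b.W)
        assert a.no_effect_pairs == b.no_effect_pairs
        a.validate()  # spectral radius, masks, path-free negatives
        radius = np.max(np.abs(np.linalg.eigvals(np.abs(a.W))))
        assert radius < 1.0

    def test_no_inhibition_fraction_gives_all_positive_weights(self):
        grn = sample_grn(n_genes=30, density=0.05, frac_inhibiting=0.0, seed=2)
        assert (grn.W[grn.W != 0] > 0).all()

    def test_edge_sign_ratio_matches_request_over_many_draws(self):
        frac = 0.25
        signs = []
        for seed in range(40):
            grn = sample_grn(n_genes=30, density=0.05, frac_inhibiting=frac, seed=seed)
            signs.append(grn.W[grn.W != 0] < 0)
        signs = np.concatenate(signs)
        se = np.sqrt(frac * (1 - frac) / len(signs))
        assert abs(signs.mean() - frac) < 3 * se

    def test_impossible_negative_demand_suggests_lower_density(self):
        with pytest.raises(ValueError, match="density"):
            sample_grn(n_genes=10, density=0.5, frac_regulators=1.0,
                       regulator_target_rate=1.0, n_no_effect=80, seed=0)

    def test_every_edge_is_active_somewhere(self):
        grn = sample_grn(n_genes=40, density=0.04, seed=3, tissue_active_rate=0.3)
        union = np.zeros_like(grn.W, dtype=bool)
        for mask in grn.tissue_masks.values():
            union |= mask
        assert np.array_equal(union, grn.W != 0)

    def test_no_effect_pairs_start_at_regulators(self):
        grn = sample_grn(n_genes=40, density=0.04, seed=4)
        regulators = set(grn.regulators)
        assert all(u in regulators for u, _ in grn.no_effect_pairs)


class TestSimulateExpression:
    def test_empty_network_gives_uncorrelated_noise(self):
        n = 6
        genes = [f"G{i}" for i in range(1, n + 1)]
        grn = GroundTruthGRN(genes, np.zeros((n, n)), {"m": np.zeros((n, n), bool)}, [])
        em = simulate_expression(grn, ts_metadata(400), noise_sd=0.5, n_latent=0,
                                 measurement_sd=0.0, seed=0)
        corr = np.corrcoef(em.values.to_numpy())
        off_diag = corr[~np.eye(n, dtype=bool)]
        assert np.abs(off_diag).max() < 4 / np.sqrt(400)

    def test_two_gene_chain_matches_sem_closed_form(self):
        """For u -> v with weight w and equal i.i.d. noise on both genes,
        corr(u, v) = w / sqrt(1 + w^2) (derived from cov = w sigma^2,
        var_v = (1 + w^2) sigma^2)."""
        w = 0.8
        grn = chain_grn([w])
        em = simulate_expression(grn, ts_metadata(3000), noise_sd=0.4, n_latent=0,
                                 measurement_sd=0.0, seed=1)
        observed = np.corrcoef(em.values.to_numpy())[0, 1]
        expected = w / np.sqrt(1 + w**2)
        assert observed == pytest.approx(expected, abs=0.03)

    def test_saturation_attenuates_the_chain_correlation(self):
        w = 0.8
        grn = chain_grn([w])
        kwargs = dict(noise_sd=1.0, n_latent=0, measurement_sd=0.0, seed=1)
        linear = simulate_expression(grn, ts_metadata(2000), **kwargs)
        clipped = simulate_expression(grn, ts_metadata(2000), saturation=0.5, **kwargs)
        r_lin = np.corrcoef(linear.values.to_numpy())[0, 1]
        r_sat = np.corrcoef(clipped.values.to_numpy())[0, 1]
        assert r_sat < r_lin - 0.05

    def test_tissue_mask_silences_the_edge_in_the_other_tissue(self):
        genes = ["G1", "G2"]
        W = np.array([[0.0, 0.8], [0.0, 0.0]])
        masks = {"on": W != 0, "off": np.zeros((2, 2), bool)}
        grn = GroundTruthGRN(genes, W, masks, [])
        meta_on = ts_metadata(1500, tissue="on")
        meta_off = ts_metadata(1500, tissue="off")
        meta_off["sample_id"] = [f"t{i}" for i in range(1500)]
        em_on = simulate_expression(grn, meta_on, n_latent=0, measurement_sd=0.0, seed=2)
        em_off = simulate_expression(grn, meta_off, n_latent=0, measurement_sd=0.0, seed=2)
        r_on = np.corrcoef(em_on.values.to_numpy())[0, 1]
        r_off = np.corrcoef(em_off.values.to_numpy())[0, 1]
        assert r_on > 0.5 and abs(r_off) < 0.1

    def test_background_genes_are_outside_the_network(self):
        grn = chain_grn([0.5])
        em = simulate_expression(grn, ts_metadata(10), n_background=7, seed=0)
        assert em.values.shape[0] == 2 + 7
        assert em.probe_genes.str.startswith("BG").sum() == 7


class TestSimulatePerturbation:
    def test_sink_gene_perturbation_does_not_propagate(self):
        grn = chain_grn([0.6])  # G2 has no outgoing edges
        em = simulate_perturbation(grn, "G2", "loss", replicates=200, noise_sd=0.1,
                                   seed=0, measurement_sd=0.0, n_latent=0)
        meta = em.metadata
        pert = em.values[meta.index[meta["condition_class"] == "genetic_perturbation"]]
        ctrl = em.values[meta.index[meta["condition_class"] == "control"]]
        diff = pert.mean(axis=1) - ctrl.mean(axis=1)
        assert diff["P.G2"] < -2  # the clamp itself
        assert abs(diff["P.G1"]) < 0.05

    def test_sign_propagation_along_a_mixed_chain(self):
        """u -(+)-> v -(-)-> w: loss of u lowers v and raises w."""
        grn = chain_grn([0.7, -0.7])
        em = simulate_perturbation(grn, "G1", "loss", replicates=200, noise_sd=0.1,
                                   seed=1, measurement_sd=0.0, n_latent=0)
        meta = em.metadata
        pert = em.values[meta.index[meta["condition_class"] == "genetic_perturbation"]]
        ctrl = em.values[meta.index[meta["condition_class"] == "control"]]
        diff = pert.mean(axis=1) - ctrl.mean(axis=1)
        assert diff["P.G2"] < -0.5
        assert diff["P.G3"] > 0.3

    def test_gain_raises_direct_targets(self):
        grn = chain_grn([0.7])
        em = simulate_perturbation(grn, "G1", "gain", replicates=200, noise_sd=0.1,
                                   seed=2, measurement_sd=0.0, n_latent=0)
        meta = em.metadata
        pert = em.values[meta.index[meta["condition_class"] == "genetic_perturbation"]]
        ctrl = em.values[meta.index[meta["condition_class"] == "control"]]
        assert (pert.mean(axis=1) - ctrl.mean(axis=1))["P.G2"] > 0.5

    def test_same_seed_is_bitwise_identical(self):
        grn = chain_grn([0.5])
        a = simulate_perturbation(grn, "G1", "loss", replicates=3, seed=5)
        b = simulate_perturbation(grn, "G1", "loss", replicates=3, seed=5)
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_unknown_gene_is_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_perturbation(chain_grn([0.5]), "nope", "loss")


class TestEmitEvidence:
    def test_noiseless_limit_is_sign_consistent(self):
        grn = sample_grn(n_genes=30, density=0.05, seed=0, n_no_effect=20)
        noise = NoiseModel(alpha=1.0 - 1e-12, beta=0.0)
        table = emit_evidence(grn, noise, n_per_pair=2, seed=1)
        truth = {
            (r, t): m
            for r, t, m in grn.evaluated_pairs().itertuples(index=False)
        }
        for _, row in table.iterrows():
            sign = SIGNS[row["perturbation"]] * SIGNS[row["effect"]]
            mode = truth[(row["regulator"], row["target"])]
            assert sign == {"activating": 1, "none": 0, "inhibiting": -1}[mode]

    def test_observed_sign_frequencies_match_the_conditional_matrix(self):
        grn = sample_grn(n_genes=160, density=0.25, frac_inhibiting=0.0,
                         frac_regulators=0.5, regulator_target_rate=0.0,
                         seed=2, n_no_effect=0)
        assert len(grn.positive_pairs()) >= 6000
        noise = NoiseModel(0.9, 0.05)
        table = emit_evidence(grn, noise, n_per_pair=1, include_no_effect=False, seed=3)
        signs = np.array([
            SIGNS[p] * SIGNS[e] for p, e in zip(table["perturbation"], table["effect"])
        ])
        n = len(signs)
        for value, expected in ((1, 0.9), (0, 0.05), (-1, 0.05)):
            freq = (signs == value).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se, (value, freq)

    def test_conflict_rate_matches_closed_form(self):
        """P(conflict | activating, n=3) = 1 - P(no -1) - P(no +1) + P(neither)."""
        grn = sample_grn(n_genes=160, density=0.25, frac_inhibiting=0.0,
                         frac_regulators=0.5, regulator_target_rate=0.0,
                         seed=4, n_no_effect=0)
        noise = NoiseModel(0.9, 0.05)
        table = emit_evidence(grn, noise, n_per_pair=3, include_no_effect=False, seed=5)
        table["sign"] = [
            SIGNS[p] * SIGNS[e] for p, e in zip(table["perturbation"], table["effect"])
        ]
        conflicts = (
            table.groupby(["regulator", "target"])["sign"]
            .apply(lambda s: (s == 1).any() and (s == -1).any())
        )
        expected = 1 - 0.95**3 - 0.10**3 + 0.05**3
        n_pairs = len(conflicts)
        se = np.sqrt(expected * (1 - expected) / n_pairs)
        assert abs(conflicts.mean() - expected) < 3 * se

    def test_record_count_conserves_n_per_pair(self):
        grn = sample_grn(n_genes=30, density=0.05, seed=6, n_no_effect=15)
        table = emit_evidence(grn, n_per_pair=2, seed=7)
        n_pairs = len(grn.positive_pairs()) + len(grn.no_effect_pairs)
        assert len(table) == 2 * n_pairs

    def test_table_round_trips_through_the_evidence_reader(self, tmp_path):
        from grnbench.data_io import read_evidence_table

        grn = sample_grn(n_genes=20, density=0.05, seed=8, n_no_effect=5)
        table = emit_evidence(grn, n_per_pair=(1, 3), seed=9)
        path = tmp_path / "evidence.csv"
        table.to_csv(path, index=False)
        records = read_evidence_table(path)
        assert len(records) == len(table)


class TestMakeBenchmark:
    def test_bundle_passes_its_own_invariants(self, tooth_benchmark):
        study = tooth_benchmark["study"]
        study.validate()
        classes = set(study.expression.metadata["condition_class"])
        assert {"time_series", "genetic_perturbation", "control"} <= classes

    def test_two_seeds_differ_but_share_composition(self):
        a = make_benchmark("heart_like", seed=1)
        b = make_benchmark("heart_like", seed=2)
        assert not np.array_equal(a.grn.W, b.grn.W)
        assert len(a.grn.no_effect_pairs) == len(b.grn.no_effect_pairs)
        assert a.expression.values.shape == b.expression.values.shape

    def test_unknown_preset_is_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            make_benchmark("liver_like", seed=0)

    def test_mode_recovery_from_emitted_evidence(self, tooth_benchmark):
        """Evidence integration applied to the generator's own output
        recovers the true mode for the vast majority of pairs."""
        study = tooth_benchmark["study"]
        records = evidence_to_records(study.evidence)
        inferred, conflicting = integrate_evidence(records)
        truth = {
            (r, t): m for r, t, m in study.grn.evaluated_pairs().itertuples(index=False)
        }
        hits = sum(p.mode == truth[p.key] for p in inferred)
        assert hits / len(inferred) > 0.85
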