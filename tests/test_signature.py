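import dataclasses

import numpy as np
import pandas as pd
import pytest

from muenv import (
    CohortSimConfig,
    SubtypeThresholds,
    assign_subtype,
    bimodal_threshold,
    build_signature,
    classify_muenv,
    mean_center,
    simulate_cohort,
    spearman_rho,
    univariable_cox,
)
from muenv.core_io import ExperimentDesign, ExpressionMatrix
from muenv.signature import MuEnvSignature


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestMeanCenter:
    def test_row_arithmetic(self):
        out = mean_center(_matrix([[1.0, 2.0, 3.0]]))
        assert np.allclose(out.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_all_rows_centered_and_idempotent(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(5, 2, size=(30, 8)))
        out = mean_center(m)
        assert np.abs(out.values.mean(axis=1).to_numpy()).max() < 1e-12
        twice = mean_center(out)
        assert np.allclose(twice.values.to_numpy(), out.values.to_numpy())

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            mean_center(_matrix([[1.0], [2.0]]))


class TestBuildSignature:
    def _design(self):
        rows = [
            ("caf1", "L1", "luminal", "CAF_CM", 1),
            ("caf2", "L1", "luminal", "CAF_CM", 2),
            ("caf3", "L1", "luminal", "CAF_CM", 3),
            ("naf1", "L1", "luminal", "NAF_CM", 1),
        ]
        return ExperimentDesign(
            pd.DataFrame([r[1:] for r in rows], index=[r[0] for r in rows],
                         columns=["cell_line", "subtype", "condition", "replicate"])
        )

    def test_centroid_is_mean_of_caf_replicates(self):
        m = _matrix([[0.9, 1.0, 1.1, -3.0], [1.0, 2.0, 3.0, -6.0]],
                    genes=["a", "b"], samples=["caf1", "caf2", "caf3", "naf1"])
        sig = build_signature({("a", "up"), ("b", "up")}, m, self._design(), "luminal")
        assert sig.centroid["a"] == pytest.approx(1.0)
        assert sig.centroid["b"] == pytest.approx(2.0)

    def test_single_caf_sample_centroid_equals_sample(self):
        design = ExperimentDesign(
            pd.DataFrame(
                [["L1", "luminal", "CAF_CM", 1], ["L1", "luminal", "NAF_CM", 1]],
                index=["caf1", "naf1"],
                columns=["cell_line", "subtype", "condition", "replicate"],
            )
        )
        m = _matrix([[2.5, 0.0]], genes=["a"], samples=["caf1", "naf1"])
        sig = build_signature({("a", "up")}, m, design, "luminal")
        assert sig.centroid["a"] == pytest.approx(2.5)

    def test_empty_de_set_rejected(self):
        with pytest.raises(ValueError, match="no genes pass"):
            build_signature(set(), _matrix([[1.0, 2.0]]), self._design(), "luminal")

    def test_missing_gene_rejected(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0]], genes=["a"],
                    samples=["caf1", "caf2", "caf3", "naf1"])
        with pytest.raises(ValueError, match="absent"):
            build_signature({("zz", "up")}, m, self._design(), "luminal")

    def test_centroid_signs_recover_planted_directions(self, signatures,
                                                       processed_celllines):
        _, _, truth = processed_celllines
        for s, sig in signatures.items():
            agree = [
                (sig.centroid[g] > 0) == (truth.planted_de[g][1] > 0)
                for g, _ in sig.genes if g in truth.planted_de
            ]
            assert np.mean(agree) >= 0.99

    def test_signature_tsv_round_trip(self, signatures, tmp_path):
        sig = signatures["luminal"]
        path = tmp_path / "sig.tsv"
        sig.to_tsv(str(path))
        back = MuEnvSignature.from_tsv(str(path))
        assert back.subtype == "luminal"
        assert back.genes == sig.genes
        assert back.centroid == pytest.approx(sig.centroid)


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3], [10, 100, 1000]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_average_tie_ranks_hand_example(self):
        assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(
            0.9486832980505138, abs=1e-10
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestClassifyMuEnv:
    def _signature(self, k=12):
        genes = [(f"g{i}", "up") for i in range(k)]
        centroid = {f"g{i}": float(i + 1) for i in range(k)}
        return MuEnvSignature("luminal", genes, centroid)

    def test_self_and_reversed_correlation(self):
        sig = self._signature()
        vals = np.column_stack(
            [np.arange(1, 13), np.arange(12, 0, -1), np.zeros(12)]
        ).astype(float)
        vals[:, 2] = [2, 4, 1, 3, 6, 8, 5, 7, 10, 12, 9, 11]  # scrambled
        m = _matrix(vals, genes=[g for g, _ in sig.genes],
                    samples=["same", "rev", "mix"])
        call = classify_muenv(m, sig)
        assert call.table.loc["same", "rho"] == pytest.approx(1.0)
        assert call.table.loc["same", "status"] == "positive"
        assert call.table.loc["rev", "rho"] == pytest.approx(-1.0)
        assert call.table.loc["rev", "status"] == "negative"

    def test_zero_rho_is_negative(self):
        genes = [(f"g{i}", "up") for i in range(4)]
        sig = MuEnvSignature("luminal", genes,
                             {f"g{i}": float(i + 1) for i in range(4)})
        # sample ranks (2,4,1,3) are exactly uncorrelated with (1,2,3,4)
        m = _matrix(np.array([[2.0, 0], [4.0, 0], [1.0, 0], [3.0, 0]]),
                    genes=[g for g, _ in genes], samples=["zero", "pad"])
        call = classify_muenv(m, sig, min_overlap=4)
        assert call.table.loc["zero", "rho"] == pytest.approx(0.0, abs=1e-12)
        assert call.table.loc["zero", "status"] == "negative"

    def test_invariance_to_monotone_transform(self):
        sig = self._signature()
        rng = np.random.default_rng(8)
        raw = rng.normal(size=(12, 5))
        m1 = _matrix(raw, genes=[g for g, _ in sig.genes])
        m2 = _matrix(np.exp(raw) + raw**3, genes=[g for g, _ in sig.genes])
        c1 = classify_muenv(m1, sig)
        c2 = classify_muenv(m2, sig)
        assert np.allclose(c1.table["rho"], c2.table["rho"])
        assert (c1.table["status"] == c2.table["status"]).all()

    def test_constant_sample_warned_negative(self):
        sig = self._signature()
        vals = np.column_stack([np.full(12, 3.0), np.arange(12, dtype=float)])
        m = _matrix(vals, genes=[g for g, _ in sig.genes], samples=["flat", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            call = classify_muenv(m, sig)
        assert call.table.loc["flat", "status"] == "negative"

    def test_overlap_floor_enforced(self):
        sig = self._signature(k=12)
        m = _matrix(np.zeros((5, 2)), genes=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="below minimum"):
            classify_muenv(m, sig, min_overlap=10)


class TestBimodalThreshold:
    def test_two_well_separated_normals(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)])
        fit = bimodal_threshold(vals, seed=1)
        assert 2.5 <= fit.threshold <= 3.5
        assert fit.strength > 4

    def test_perfectly_separated_clusters(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        vals = vals + rng.normal(0, 1e-3, 200)
        fit = bimodal_threshold(vals, seed=0)
        assert 0.0 < fit.threshold < 10.0

    def test_unimodal_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="degenerate|not bimodal"):
            bimodal_threshold(rng.normal(0, 1, 400), seed=1)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 20"):
            bimodal_threshold(np.arange(10.0))


class TestAssignSubtype:
    def _cohort(self, esr1, erbb2):
        return _matrix(np.array([esr1, erbb2], dtype=float),
                       genes=["ESR1", "ERBB2"],
                       samples=[f"p{i}" for i in range(len(esr1))])

    def test_three_way_rules(self):
        m = self._cohort([11.0, 6.0, 11.0, 6.0], [6.0, 11.0, 11.0, 6.0])
        out = assign_subtype(m, SubtypeThresholds(esr1_cut=8.5, erbb2_cut=8.5))
        # ERBB2-high wins regardless of ESR1; ESR1-high else luminal; else basal
        assert list(out) == ["luminal", "her2", "her2", "basal"]

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(4)
        m = self._cohort(rng.normal(8, 3, 50), rng.normal(8, 3, 50))
        out = assign_subtype(m, SubtypeThresholds(esr1_cut=8.0, erbb2_cut=8.0))
        assert len(out) == 50
        assert set(out.unique()) <= {"luminal", "her2", "basal"}

    def test_missing_reporter_rejected(self):
        m = _matrix(np.zeros((1, 3)), genes=["ESR1"])
        with pytest.raises(ValueError, match="ERBB2"):
            assign_subtype(m, SubtypeThresholds())


class TestSubtypeSpecificity:
    def test_cross_subtype_signature_is_uninformative(self, signatures):
        """Scoring a basal cohort with the luminal signature (disjoint planted
        gene sets) gives a ~50% positive rate and no survival association:
        the Cox CI for the cross-signature muENV status covers 1 in at least
        90% of seeds."""
        from muenv import calibrate_baseline_hazard

        covered = 0
        rates = []
        n_seeds = 50
        cfg0 = CohortSimConfig(
            n_patients=300,
            subtype_fracs={"basal": 1.0},
            activated_frac={"basal": 0.79},
            hazard_coefs={"muenv": np.log(2.5)},
            target_events=60,
            n_filler_genes=0,
            seed=0,
        )
        cfg0 = dataclasses.replace(
            cfg0, baseline_hazard=calibrate_baseline_hazard(cfg0),
            target_events=None,
        )
        for seed in range(n_seeds):
            cfg = dataclasses.replace(cfg0, seed=seed)
            matrix, ann, truth = simulate_cohort(cfg, signatures)
            call = classify_muenv(mean_center(matrix), signatures["luminal"])
            rates.append(call.positive_rate())
            status = (call.table["status"] == "positive").astype(int).to_numpy()
            if status.min() == status.max():
                covered += 1  # no split at all: certainly no association
                continue
            fit = univariable_cox(status, ann.table["time_months"].to_numpy(),
                                  ann.table["event"].to_numpy(), name="x")
            lo, hi = fit.table.loc["x", ["ci_low", "ci_high"]]
            covered += int(lo <= 1.0 <= hi)
        assert covered >= 0.9 * n_seeds
        assert 0.35 < np.mean(rates) < 0.65

    def test_matched_signature_tracks_latent_state(self, signatures):
        cfg = CohortSimConfig(n_patients=500, seed=13)
        matrix, _, truth = simulate_cohort(cfg, signatures)
        centered = mean_center(matrix)
        agree = []
        for s, sig in signatures.items():
            ids = [k for k, v in truth.subtype_truth.items() if v == s]
            call = classify_muenv(centered.subset_samples(ids), sig)
            latent = np.array(
                [truth.latent_state[i] == "activated" for i in call.table.index]
            )
            agree.extend(
                (call.table["status"] == "positive").to_numpy() == latent
            )
        assert np.mean(agree) >= 0.90
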