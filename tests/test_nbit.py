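"""Quasi-harmonic entropy, mutual information, and co-information."""

import numpy as np
import pytest

from allocomm import (
    Ensemble,
    GaussianEnsembleSpec,
    RankDeficiencyError,
    SelectionError,
    analytic_pair_mi_nats,
    block_bootstrap_mi,
    coinformation,
    estimate_covariance,
    gaussian_coinformation_nats,
    gaussian_entropy,
    gaussian_mi_nats,
    kcal_per_nat,
    make_gaussian_ensemble,
    mi_bias_bound_nats,
    mutual_information,
    per_residue_profile,
)
from conftest import entropy_sum_coinformation

LN_2PIE = np.log(2 * np.pi * np.e)


def two_body_ensemble(rho, n_frames, seed, sizes=(2, 2)):
    spec = GaussianEnsembleSpec(
        body_sizes=list(sizes), per_pair_correlation=rho, n_frames=n_frames, seed=seed
    )
    return make_gaussian_ensemble(spec)


class TestGaussianEntropy:
    @pytest.mark.parametrize(
        "cov, expected",
        [
            (np.eye(3), 1.5 * LN_2PIE),              # ~4.2568 nats
            (4.0 * np.eye(2), LN_2PIE + np.log(4.0)),  # ~4.2242 nats
            (0.25 * np.eye(6), 3 * LN_2PIE + 3 * np.log(0.25)),
        ],
    )
    def test_closed_forms(self, cov, expected):
        assert gaussian_entropy(cov, eigenvalue_floor=0.0) == pytest.approx(expected, rel=1e-12)

    def test_sampled_isotropic_entropy_near_closed_form(self):
        res = two_body_ensemble(0.0, 50_000, seed=21, sizes=(2,))
        model = estimate_covariance(res.ensemble, res.bodies[0])
        h = gaussian_entropy(model)
        exact = 3 * LN_2PIE + 3 * np.log(0.25)
        assert h == pytest.approx(exact, rel=0.02)

    def test_nonfinite_covariance_rejected(self):
        bad = np.eye(3)
        bad[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            gaussian_entropy(bad)


class TestEstimateCovariance:
    def test_isotropic_variance_recovered(self):
        res = two_body_ensemble(0.0, 50_000, seed=22)
        model = estimate_covariance(res.ensemble, res.bodies[0])
        assert np.allclose(np.diag(model.cov), 0.25, rtol=0.03)
        # off-diagonals are near zero
        off = model.cov[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.01

    def test_frozen_ensemble_gives_zero_covariance(self, helix_topology):
        ens = Ensemble(
            topology=helix_topology,
            coords=np.repeat(helix_topology.coords[None], 200, axis=0),
        )
        from allocomm import ca_selection

        model = estimate_covariance(ens, ca_selection(helix_topology))
        assert np.allclose(model.cov, 0.0)
        # regularization floors the eigenvalues actually consumed
        assert np.all(model.regularized_eigenvalues() >= model.eigenvalue_floor)

    def test_stride_bookkeeping(self):
        res = two_body_ensemble(0.0, 1000, seed=23)
        model = estimate_covariance(res.ensemble, res.bodies[0], stride=7)
        assert model.n_frames == len(range(0, 1000, 7))
        assert model.stride == 7

    def test_rank_deficiency_raises_without_shrinkage(self):
        res = two_body_ensemble(0.0, 5, seed=24)  # 5 frames, 6 dims
        with pytest.raises(RankDeficiencyError):
            estimate_covariance(res.ensemble, res.bodies[0])
        model = estimate_covariance(res.ensemble, res.bodies[0], shrinkage=0.3)
        assert model.shrinkage == 0.3

    def test_superposition_removes_rigid_body_inflation(self):
        """Rigid tumbling inflates apparent covariance; fitting removes it."""
        from scipy.spatial.transform import Rotation

        from allocomm import ca_selection, make_synthetic_topology

        top = make_synthetic_topology(10)
        rng = np.random.default_rng(25)
        frames = []
        for _ in range(300):
            R = Rotation.random(rng=rng).as_matrix()
            frames.append(top.coords @ R.T + rng.uniform(-3, 3, size=3))
        ens = Ensemble(topology=top, coords=np.stack(frames))
        sel = ca_selection(top)
        raw = estimate_covariance(ens, sel)
        fitted = estimate_covariance(ens, sel, fit=sel)
        assert np.trace(fitted.cov) < 1e-6 * np.trace(raw.cov)


class TestMutualInformation:
    def test_determinant_identity_on_constructed_covariance(self):
        res = two_body_ensemble(0.5, 10, seed=26)
        expected = analytic_pair_mi_nats(0.5, 6)  # -(6/2) ln(1 - 0.25)
        assert res.analytic_mi_nats() == pytest.approx(expected, abs=1e-12)
        assert gaussian_mi_nats(res.cov, 6, eigenvalue_floor=0.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_estimate_converges_to_analytic(self):
        res = two_body_ensemble(0.5, 50_000, seed=27)
        est = mutual_information(res.ensemble, res.bodies[0], res.bodies[1])
        assert est.mi_nats == pytest.approx(res.analytic_mi_nats(), rel=0.05)

    def test_entropy_identity_is_exact(self):
        res = two_body_ensemble(0.3, 5000, seed=28)
        est = mutual_information(res.ensemble, res.bodies[0], res.bodies[1])
        assert est.mi_nats == pytest.approx(
            est.h_transmitter + est.h_receiver - est.h_joint, abs=1e-12
        )

    def test_symmetry_under_body_exchange(self):
        res = two_body_ensemble(0.3, 5000, seed=29)
        t, r = res.bodies
        assert mutual_information(res.ensemble, t, r).mi_nats == pytest.approx(
            mutual_information(res.ensemble, r, t).mi_nats, abs=1e-12
        )

    def test_independent_bodies_within_bias_bound_and_bias_shrinks(self):
        for n in (1_000, 10_000, 50_000):
            res = two_body_ensemble(0.0, n, seed=30)
            est = mutual_information(res.ensemble, res.bodies[0], res.bodies[1])
            bound = mi_bias_bound_nats(6, 6, n)
            assert -1e-9 <= est.mi_nats <= bound
        assert mi_bias_bound_nats(6, 6, 50_000) < mi_bias_bound_nats(6, 6, 1_000)

    def test_kcal_conversion_at_310K(self):
        # 1 nat at 310 K is ~0.616 kcal/mol (kB = 0.0019872 kcal/mol/K)
        assert kcal_per_nat(310.0) == pytest.approx(0.616, abs=1e-3)
        res = two_body_ensemble(0.5, 3000, seed=31)
        est = mutual_information(res.ensemble, res.bodies[0], res.bodies[1], temperature=310.0)
        assert est.mi_kcal == pytest.approx(est.mi_nats * kcal_per_nat(310.0), abs=1e-12)

    def test_overlapping_selections_rejected(self):
        res = two_body_ensemble(0.0, 1000, seed=32)
        with pytest.raises(SelectionError, match="disjoint"):
            mutual_information(res.ensemble, res.bodies[0], res.bodies[0])

    def test_replicates_averaged_with_spread(self):
        reps = [two_body_ensemble(0.5, 8000, seed=s).ensemble for s in (40, 41, 42)]
        bodies = two_body_ensemble(0.5, 10, seed=40).bodies
        est = mutual_information(reps, bodies[0], bodies[1])
        assert len(est.per_replica) == 3
        assert est.spread == pytest.approx(np.std(est.per_replica, ddof=1), abs=1e-12)
        assert est.mi_kcal == pytest.approx(np.mean(est.per_replica), abs=1e-12)

    def test_pooled_frames_mode(self):
        reps = [two_body_ensemble(0.5, 4000, seed=s).ensemble for s in (43, 44)]
        bodies = two_body_ensemble(0.5, 10, seed=43).bodies
        pooled = mutual_information(reps, bodies[0], bodies[1], pool_frames=True)
        assert pooled.spread is None
        assert pooled.n_frames == 8000


class TestCoinformation:
    def chain_spec(self, n_frames, seed, rho1=0.6, rho2=0.6):
        # Markov chain T - X - R: bodies ordered (T, R, X)
        rho = np.array(
            [[1.0, rho1 * rho2, rho1], [rho1 * rho2, 1.0, rho2], [rho1, rho2, 1.0]]
        )
        return make_gaussian_ensemble(
            GaussianEnsembleSpec(
                body_sizes=[2, 2, 2], per_pair_correlation=rho, n_frames=n_frames, seed=seed
            )
        )

    def test_markov_chain_ci_equals_mi_on_exact_covariance(self):
        res = self.chain_spec(10, seed=50)
        ci = gaussian_coinformation_nats(res.cov, 6, 6, 6, eigenvalue_floor=0.0)
        assert ci == pytest.approx(res.analytic_mi_nats(0, 1), abs=1e-9)

    def test_mi_difference_form_agrees_with_entropy_sum_expansion(self):
        res = self.chain_spec(10, seed=51, rho1=0.5, rho2=0.7)
        ci = gaussian_coinformation_nats(res.cov, 6, 6, 6, eigenvalue_floor=0.0)
        oracle = entropy_sum_coinformation(res.cov, 6, 6, 6)
        assert ci == pytest.approx(oracle, abs=1e-9)

    def test_all_pairwise_coupled_matches_entropy_sum_oracle(self):
        res = make_gaussian_ensemble(
            GaussianEnsembleSpec(
                body_sizes=[2, 2, 2], per_pair_correlation=0.3, n_frames=10, seed=52
            )
        )
        ci = gaussian_coinformation_nats(res.cov, 6, 6, 6, eigenvalue_floor=0.0)
        assert ci == pytest.approx(entropy_sum_coinformation(res.cov, 6, 6, 6), abs=1e-9)

    def test_sampled_estimate_converges_to_markov_mi(self):
        res = self.chain_spec(50_000, seed=53)
        t, r, x = res.bodies
        ci_kcal = coinformation(res.ensemble, t, r, x)
        assert ci_kcal / kcal_per_nat() == pytest.approx(res.analytic_mi_nats(0, 1), rel=0.05)

    def test_independent_channel_gives_near_zero_ci(self):
        res = make_gaussian_ensemble(
            GaussianEnsembleSpec(
                body_sizes=[2, 2, 2], per_pair_correlation=0.0, n_frames=20_000, seed=54
            )
        )
        t, r, x = res.bodies
        ci_nats = coinformation(res.ensemble, t, r, x) / kcal_per_nat()
        assert abs(ci_nats) < 0.01


class TestPerResidueProfile:
    def mediated_system(self, n_frames=20_000, seed=60):
        """T and R coupled only through body X; two independent decoy residues."""
        k = 5  # T, R, X, decoy1, decoy2 — one residue (CA+CB) each
        rho = np.eye(k)
        rho[0, 2] = rho[2, 0] = 0.6
        rho[1, 2] = rho[2, 1] = 0.6
        rho[0, 1] = rho[1, 0] = 0.36
        res = make_gaussian_ensemble(
            GaussianEnsembleSpec(
                body_sizes=[2] * k, per_pair_correlation=rho, n_frames=n_frames, seed=seed
            )
        )
        res.bodies[0].role = "transmitter"
        res.bodies[1].role = "receiver"
        return res

    def test_unique_mediator_attains_normalized_one(self):
        res = self.mediated_system()
        prof = per_residue_profile(
            res.ensemble, res.bodies[0], res.bodies[1], candidate_residues=[3, 4, 5]
        )
        label = res.ensemble.label
        norm = prof.normalized[label]
        assert prof.residues == [3, 4, 5]
        assert norm[0] == pytest.approx(1.0)  # residue 3 hosts the mediator
        assert np.all(norm[1:] < 0.05)
        # raw CI ordering against per-candidate recomputation
        raw = [
            coinformation(
                res.ensemble,
                res.bodies[0],
                res.bodies[1],
                res.bodies[i],
            )
            for i in (2, 3, 4)
        ]
        assert np.allclose(prof.values[label], raw, atol=1e-12)

    def test_two_identical_ensembles_give_identical_profiles(self):
        res = self.mediated_system(n_frames=5000)
        twin = Ensemble(
            topology=res.ensemble.topology, coords=res.ensemble.coords.copy(), label="twin"
        )
        prof = per_residue_profile(
            [res.ensemble, twin], res.bodies[0], res.bodies[1], candidate_residues=[3, 4, 5]
        )
        assert np.array_equal(prof.values[res.ensemble.label], prof.values["twin"])
        assert prof.normalization_bounds[0] <= prof.normalization_bounds[1]

    def test_single_candidate_degenerate_normalization_warns(self):
        res = self.mediated_system(n_frames=3000)
        with pytest.warns(UserWarning, match="degenerate"):
            prof = per_residue_profile(
                res.ensemble, res.bodies[0], res.bodies[1], candidate_residues=[4]
            )
        assert np.allclose(prof.normalized[res.ensemble.label], 0.0)
        assert np.isfinite(prof.values[res.ensemble.label]).all()

    def test_candidates_overlapping_bodies_rejected(self):
        res = self.mediated_system(n_frames=3000)
        with pytest.raises(SelectionError, match="overlap"):
            per_residue_profile(
                res.ensemble, res.bodies[0], res.bodies[1], candidate_residues=[1, 4]
            )

    def test_body_residues_scannable_on_opt_in(self):
        # transmitter spans residues 1-2; scanning residue 1 removes its atoms
        # from the transmitter rather than double counting them
        res = make_gaussian_ensemble(
            GaussianEnsembleSpec(
                body_sizes=[4, 2, 2], per_pair_correlation=0.3, n_frames=3000, seed=61
            )
        )
        t, r, _ = res.bodies
        t.role, r.role = "transmitter", "receiver"
        prof = per_residue_profile(
            res.ensemble, t, r, candidate_residues=[1, 4], include_body_residues=True
        )
        assert prof.residues == [1, 4]
        assert np.isfinite(prof.values[res.ensemble.label]).all()

    def test_candidate_spanning_whole_body_rejected(self):
        res = self.mediated_system(n_frames=3000)
        with pytest.raises(SelectionError, match="empty"):
            per_residue_profile(
                res.ensemble,
                res.bodies[0],
                res.bodies[1],
                candidate_residues=[1],
                include_body_residues=True,
            )

    def test_empty_candidate_list_rejected(self):
        res = self.mediated_system(n_frames=3000)
        with pytest.raises(ValueError):
            per_residue_profile(res.ensemble, res.bodies[0], res.bodies[1], candidate_residues=[])


class TestBlockBootstrap:
    def test_reproducible_and_positive(self):
        res = two_body_ensemble(0.5, 4000, seed=70)
        se1, samples1 = block_bootstrap_mi(
            res.ensemble, res.bodies[0], res.bodies[1], n_boot=20, seed=5
        )
        se2, samples2 = block_bootstrap_mi(
            res.ensemble, res.bodies[0], res.bodies[1], n_boot=20, seed=5
        )
        assert se1 == se2
        assert np.array_equal(samples1, samples2)
        assert se1 > 0
        assert len(samples1) == 20

    def test_autocorrelated_frames_supported(self):
        spec = GaussianEnsembleSpec(
            body_sizes=[2, 2], per_pair_correlation=0.5, n_frames=4000, seed=71, ar1_phi=0.9
        )
        res = make_gaussian_ensemble(spec)
        se, _ = block_bootstrap_mi(
            res.ensemble, res.bodies[0], res.bodies[1], n_boot=20, block_length=200, seed=6
        )
        assert np.isfinite(se) and se > 0
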