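"""Alignment-tensor algebra, back-calculation oracles, fitting, ranking."""

import numpy as np
import pytest

from anisoverify.saupe import (AlignmentTensor, FitError, RCSARecord, RDCRecord,
                               SaupeModel, d_max_hz, fit_alignment, q_factor,
                               rank_structures, rcsa_back_calculate,
                               rdc_back_calculate)
from anisoverify.synth import (SynthConfig, gen_alignment_tensor,
                               gen_aniso_dataset, gen_shielding_tensors)


def contraction_oracle(S, v):
    """Brute-force element-wise double sum sum_ij S_ij v_i v_j."""
    total = 0.0
    for i in range(3):
        for j in range(3):
            total += S[i, j] * v[i] * v[j]
    return total


class TestAlignmentTensor:
    def test_constructor_enforces_invariants(self):
        with pytest.raises(ValueError):
            AlignmentTensor(np.eye(3))            # not traceless
        with pytest.raises(ValueError):
            AlignmentTensor(np.arange(9.0).reshape(3, 3))  # not symmetric

    def test_params_round_trip(self):
        p = np.array([3e-4, -1e-4, 2e-5, -4e-5, 7e-5])
        t = AlignmentTensor.from_params(p)
        assert np.allclose(t.params, p, atol=1e-18)
        assert abs(np.trace(t.matrix)) < 1e-15

    def test_generated_tensor_properties(self):
        for seed in range(10):
            t = gen_alignment_tensor(seed, 5e-4)
            assert np.allclose(t.matrix, t.matrix.T)
            assert abs(np.trace(t.matrix)) < 1e-12
            assert np.isclose(np.max(np.abs(t.eigenvalues)), 5e-4)

    def test_seed_determinism(self):
        a = gen_alignment_tensor(1, 5e-4)
        b = gen_alignment_tensor(1, 5e-4)
        assert np.array_equal(a.matrix, b.matrix)


class TestBackCalculation:
    def test_zero_tensor_gives_zero(self, caulamidine):
        S = AlignmentTensor(np.zeros((3, 3)))
        recs = [RDCRecord("11", "11", 0.0)]
        assert np.allclose(rdc_back_calculate(caulamidine, S, recs), 0.0)

    def test_axial_symmetry_ratio(self):
        """Bond along z gives D_max*s; bond along x gives -D_max*s/2."""
        from anisoverify.graph import Atom, MoleculeGraph

        s = 1e-3
        S = AlignmentTensor(np.diag([-s / 2, -s / 2, s]))
        r = 1.09
        atoms = [Atom(0, "C", "cz", np.zeros(3)), Atom(1, "H", None, np.array([0, 0, r])),
                 Atom(2, "C", "cx", np.array([3.0, 0, 0])), Atom(3, "H", None, np.array([3.0 + r, 0, 0])),
                 Atom(4, "C", None, np.array([1.5, 0.2, 0]))]
        bonds = [(0, 1, 1.0), (2, 3, 1.0), (0, 4, 1.0), (2, 4, 1.0)]
        g = MoleculeGraph(atoms, bonds, {"cz": 0, "cx": 2})
        dz, dx = rdc_back_calculate(g, S, [RDCRecord("cz", "cz", 0),
                                           RDCRecord("cx", "cx", 0)])
        assert dz == pytest.approx(d_max_hz(r) * s, rel=1e-9)
        assert dx == pytest.approx(-d_max_hz(r) * s / 2, rel=1e-9)
        assert dx / dz == pytest.approx(-0.5, rel=1e-9)

    def test_rdc_matches_contraction_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            S = gen_alignment_tensor(int(rng.integers(1e6)), 5e-4)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            assert S.contract(v) == pytest.approx(
                contraction_oracle(S.matrix, v), abs=1e-12)

    def test_rcsa_matches_contraction_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            S = gen_alignment_tensor(int(rng.integers(1e6)), 5e-4)
            sig = rng.standard_normal((3, 3)) * 50
            sig = 0.5 * (sig + sig.T)
            rec = RCSARecord("x", 0.0, 1.0, sig)
            got = rcsa_back_calculate([rec], S)[0]
            tr = sig - np.eye(3) * np.trace(sig) / 3
            expected = -(2 / 3) * sum(
                S.matrix[i, j] * tr[i, j] for i in range(3) for j in range(3)) * 1e3
            assert got == pytest.approx(expected, abs=1e-9)

    def test_rcsa_isotropic_invariance(self):
        rng = np.random.default_rng(3)
        S = gen_alignment_tensor(9, 5e-4)
        sig = rng.standard_normal((3, 3)) * 30
        sig = 0.5 * (sig + sig.T)
        a = rcsa_back_calculate([RCSARecord("x", 0, 1, sig)], S)[0]
        b = rcsa_back_calculate([RCSARecord("x", 0, 1, sig + 123.4 * np.eye(3))], S)[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_isotropic_shielding_gives_zero(self):
        S = gen_alignment_tensor(5, 5e-4)
        rec = RCSARecord("x", 0, 1, 77.7 * np.eye(3))
        assert rcsa_back_calculate([rec], S)[0] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_covariance(self, caulamidine):
        """Rotating coordinates+tensors while mapping S -> R S R^T leaves
        all back-calculations unchanged."""
        from scipy.spatial.transform import Rotation

        g = caulamidine
        S = gen_alignment_tensor(21, 5e-4)
        cfg = SynthConfig(seed=21, n_rdc=8, n_rcsa=8,
                          rdc_noise_Hz=0.0, rcsa_noise_ppb=0.0)
        rdc, rcsa, _ = gen_aniso_dataset(g, S, cfg)
        R = Rotation.from_euler("zyx", [37, -12, 105], degrees=True).as_matrix()
        g_rot = g.copy()
        for a in g_rot.atoms:
            a.coords = R @ a.coords
        S_rot = AlignmentTensor(R @ S.matrix @ R.T)
        rcsa_rot = [RCSARecord(r.carbon_position, r.rcsa_obs_ppb, r.sigma_ppb,
                               R @ r.shielding_tensor_ppm @ R.T) for r in rcsa]
        assert np.allclose(rdc_back_calculate(g, S, rdc),
                           rdc_back_calculate(g_rot, S_rot, rdc), atol=1e-10)
        assert np.allclose(rcsa_back_calculate(rcsa, S),
                           rcsa_back_calculate(rcsa_rot, S_rot), atol=1e-10)


class TestQFactor:
    def test_identity_is_zero(self):
        assert q_factor([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_null_model_is_one(self):
        assert q_factor([1.0, 2.0], [0.0, 0.0]) == 1.0

    def test_direct_evaluation(self):
        # sqrt(((3-2)^2) / (1+4+9)) = sqrt(1/14)
        assert q_factor([1, 2, 3], [1, 2, 2]) == pytest.approx(
            np.sqrt(1 / 14), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        o, c = rng.standard_normal(9), rng.standard_normal(9)
        assert q_factor(7.7 * o, 7.7 * c) == pytest.approx(q_factor(o, c), rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            q_factor([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            q_factor([0.0, 0.0], [1.0, 1.0])


class TestFitAlignment:
    def test_noiseless_round_trip(self, caulamidine):
        S = gen_alignment_tensor(33, 5e-4)
        cfg = SynthConfig(seed=33, n_rdc=8, n_rcsa=6,
                          rdc_noise_Hz=0.0, rcsa_noise_ppb=0.0)
        rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        res = fit_alignment(caulamidine, rdc, rcsa)
        assert np.abs(res.tensor.matrix - S.matrix).max() < 1e-9
        assert res.q_total < 1e-9

    def test_underdetermined_raises(self, caulamidine):
        S = gen_alignment_tensor(1, 5e-4)
        cfg = SynthConfig(seed=1, n_rdc=4, n_rcsa=0,
                          rdc_noise_Hz=0.0, rcsa_noise_ppb=0.0)
        rdc, _, _ = gen_aniso_dataset(caulamidine, S, cfg)
        with pytest.raises(FitError, match="[Uu]nderdetermined|rank"):
            SaupeModel(caulamidine, rdc, [])

    def test_rcsa_only_fit(self, caulamidine):
        S = gen_alignment_tensor(8, 5e-4)
        cfg = SynthConfig(seed=8, n_rdc=0, n_rcsa=6,
                          rdc_noise_Hz=0.0, rcsa_noise_ppb=0.0)
        _, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        res = fit_alignment(caulamidine, [], rcsa)
        assert res.q_total < 1e-9
        assert res.q_rdc is None and res.q_rcsa is not None

    def test_fitted_residual_is_optimal(self, caulamidine):
        """Perturbing the fitted tensor never lowers the weighted residual."""
        S = gen_alignment_tensor(55, 5e-4)
        cfg = SynthConfig(seed=55, n_rdc=10, n_rcsa=10,
                          rdc_noise_Hz=0.3, rcsa_noise_ppb=1.5)
        rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        model = SaupeModel(caulamidine, rdc, rcsa)
        res = model.fit()
        A, y, w = model._stack()
        best = np.sum((w * (y - A @ res.params)) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(50):
            pert = res.params * (1 + rng.normal(0, 0.05, 5))
            assert np.sum((w * (y - A @ pert)) ** 2) >= best - 1e-18

    def test_parameter_recovery_under_noise(self, caulamidine):
        """Recovered components within 3 SE of truth in >= 95% of trials,
        with noise at ~5% of the RDC rms."""
        inside = total = 0
        for seed in range(150):
            S = gen_alignment_tensor(10_000 + seed, 5e-4)
            cfg = SynthConfig(seed=seed, n_rdc=12, n_rcsa=12,
                              rdc_noise_Hz=0.2, rcsa_noise_ppb=1.0)
            rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
            res = fit_alignment(caulamidine, rdc, rcsa)
            err = np.abs(res.params - S.params)
            inside += int(np.sum(err <= 3 * res.bse))
            total += 5
        assert inside / total >= 0.95

    def test_summary_mentions_q(self, caulamidine):
        S = gen_alignment_tensor(2, 5e-4)
        cfg = SynthConfig(seed=2, n_rdc=8, n_rcsa=6,
                          rdc_noise_Hz=0.1, rcsa_noise_ppb=0.5)
        rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        text = fit_alignment(caulamidine, rdc, rcsa).summary()
        assert "Q(total)" in text and "Szz" in text


class TestRankStructures:
    def test_true_beats_stereo_decoy_noiseless(self, caulamidine, decoy_set):
        S = gen_alignment_tensor(77, 5e-4)
        cfg = SynthConfig(seed=77, n_rdc=12, n_rcsa=12,
                          rdc_noise_Hz=0.0, rcsa_noise_ppb=0.0)
        rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        cands = [decoy_set["epi11"], caulamidine]
        sh = [gen_shielding_tensors(c, cfg.seed,
                                    [r.carbon_position for r in rcsa])
              for c in cands]
        ranked = rank_structures(cands, rdc, rcsa, shieldings=sh)
        assert ranked[0][0] is caulamidine
        assert ranked[0][1].q_total < 1e-9
        assert ranked[1][1].q_total > 0.01

    def test_enantiomer_ties_exactly(self, caulamidine, decoy_set):
        S = gen_alignment_tensor(78, 5e-4)
        cfg = SynthConfig(seed=78, n_rdc=12, n_rcsa=12,
                          rdc_noise_Hz=0.3, rcsa_noise_ppb=1.0)
        rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        ent = decoy_set["enantiomer"]
        sh = [gen_shielding_tensors(c, cfg.seed,
                                    [r.carbon_position for r in rcsa])
              for c in (caulamidine, ent)]
        ranked = rank_structures([caulamidine, ent], rdc, rcsa, shieldings=sh)
        qs = [r.q_total for _, r in ranked]
        assert abs(qs[0] - qs[1]) < 1e-9

    def test_single_candidate(self, caulamidine):
        S = gen_alignment_tensor(5, 5e-4)
        cfg = SynthConfig(seed=5, n_rdc=8, n_rcsa=6,
                          rdc_noise_Hz=0.0, rcsa_noise_ppb=0.0)
        rdc, rcsa, _ = gen_aniso_dataset(caulamidine, S, cfg)
        ranked = rank_structures([caulamidine], rdc, rcsa)
        assert len(ranked) == 1
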