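"""Frame extraction, superposition, discriminability, CoM deviation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from proteox.ensembles import (
    ConformationalEnsemble,
    com_deviation,
    discriminability_profile,
    ensemble_from_pdb,
    ensemble_to_pdb,
    extract_frames,
    kabsch_rotation,
    n_frames_for_span,
    residue_discriminability,
    superpose,
)
from proteox.synth import EnsembleSimConfig, simulate_ensembles


def _pair(n_res=1, n_frames=400, shift=None, sd=0.5, seed=0):
    s = np.zeros((n_res, 3))
    if shift is not None:
        s[:] = shift
    a, b, _ = simulate_ensembles(
        EnsembleSimConfig(n_residues=n_res, n_frames=n_frames, mean_shift=s,
                          coord_sd=sd, seed=seed)
    )
    return a, b


class TestFrameExtraction:
    @pytest.mark.parametrize(
        "span_ps,interval,expected",
        [
            (150_000.0, 50.0, 3001),  # 150 ns at 50 ps, endpoints inclusive
            (100.0, 50.0, 3),
            (0.0, 50.0, 1),
        ],
    )
    def test_inclusive_frame_counts(self, span_ps, interval, expected):
        assert n_frames_for_span(span_ps, interval) == expected

    def test_extract_on_sampling_grid(self):
        times = np.arange(0.0, 1001.0, 10.0)  # 101 frames at 10 ps
        coords = np.zeros((len(times), 2, 3))
        ens = extract_frames(coords, times, interval_ps=50.0)
        assert ens.n_frames == 21  # 0, 50, ..., 1000

    def test_interval_exceeding_span_single_frame(self):
        times = np.array([0.0, 10.0, 20.0])
        coords = np.zeros((3, 1, 3))
        with pytest.warns(UserWarning, match="single frame"):
            ens = extract_frames(coords, times, interval_ps=500.0)
        assert ens.n_frames == 1


class TestSuperposition:
    def test_identity_when_frame_equals_reference(self, rng):
        ref = rng.normal(size=(10, 3))
        ens = ConformationalEnsemble(ref[None], np.arange(10), ref)
        fitted = superpose(ens)
        np.testing.assert_allclose(fitted.coords[0], ref, atol=1e-10)

    def test_exact_rigid_recovery(self, rng):
        ref = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = ref @ rot.T + np.array([5.0, -2.0, 1.0])
        ens = ConformationalEnsemble(moved[None], np.arange(12), ref)
        fitted = superpose(ens)
        np.testing.assert_allclose(fitted.coords[0], ref, atol=1e-8)

    def test_rmsd_matches_scipy_oracle(self, rng):
        """Fitted RMSD equals scipy's independent align_vectors solution."""
        for _ in range(5):
            ref = rng.normal(size=(20, 3))
            frame = rng.normal(size=(20, 3))
            ens = ConformationalEnsemble(frame[None], np.arange(20), ref)
            fitted = superpose(ens)
            ours = np.sqrt(((fitted.coords[0] - ref) ** 2).sum(axis=1).mean())
            rc = ref - ref.mean(0)
            fc = frame - frame.mean(0)
            _, rssd = Rotation.align_vectors(rc, fc)
            oracle = rssd / np.sqrt(len(ref))
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_rotation_proper_and_never_degrades_rmsd(self, rng):
        ref = rng.normal(size=(15, 3))
        frame = ref + rng.normal(scale=0.3, size=(15, 3))
        r, t = kabsch_rotation(frame, ref)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-10)
        before = np.sqrt(((frame - ref) ** 2).sum(1).mean())
        after = np.sqrt((((frame @ r.T + t) - ref) ** 2).sum(1).mean())
        assert after <= before + 1e-12

    def test_collinear_selection_rejected(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        ens = ConformationalEnsemble(ref[None], np.arange(4), ref)
        with pytest.raises(ValueError, match="collinear"):
            superpose(ens)
        with pytest.raises(ValueError, match="at least 3"):
            superpose(ens, selection=np.array([0, 1]))


class TestDiscriminability:
    def test_null_case_near_chance(self):
        a, b = _pair(n_res=1, n_frames=600, seed=1)
        eta = residue_discriminability(a, b, 0, n_repeats=3)
        assert eta == pytest.approx(0.5, abs=0.05)

    def test_disjoint_clouds_full_separation(self):
        a, b = _pair(n_res=1, n_frames=200, shift=(50.0, 0, 0), sd=0.5, seed=2)
        assert residue_discriminability(a, b, 0, n_repeats=2) > 0.99

    def test_matches_bayes_oracle_at_two_sigma(self):
        """d = 2*sigma: eta ~ Phi(1), checked against the Bayes-optimal
        rule (classify by nearest true mean) on the same samples."""
        sd = 0.5
        a, b = _pair(n_res=1, n_frames=3001, shift=(2 * sd, 0, 0), sd=sd, seed=3)
        eta = residue_discriminability(a, b, 0)
        # Monte-Carlo Bayes accuracy with the known generating means
        xa, xb = a.coords[:, 0, 0], b.coords[:, 0, 0]  # discriminant axis
        mid = (xa.mean() + (xb.mean())) / 2.0  # plug-in midpoint
        bayes = 0.5 * ((xa < mid).mean() + (xb >= mid).mean())
        assert eta == pytest.approx(bayes, abs=0.02)
        assert eta == pytest.approx(norm.cdf(1.0), abs=0.02)

    def test_monotone_in_separation(self):
        etas = []
        for i, d in enumerate((0.0, 0.5, 1.0, 2.0, 4.0)):
            a, b = _pair(n_res=1, n_frames=400, shift=(d * 0.5, 0, 0), sd=0.5, seed=10 + i)
            etas.append(residue_discriminability(a, b, 0, n_repeats=3, seed=1))
        assert all(y >= x - 0.02 for x, y in zip(etas, etas[1:]))
        assert etas[-1] > etas[0]

    def test_symmetry_under_swap(self):
        a, b = _pair(n_res=1, n_frames=400, shift=(0.6, 0, 0), seed=5)
        e1 = residue_discriminability(a, b, 0, n_repeats=3, seed=7)
        e2 = residue_discriminability(b, a, 0, n_repeats=3, seed=7)
        assert e1 == pytest.approx(e2, abs=0.03)

    def test_zero_variance_majority_rule(self):
        coords = np.zeros((50, 1, 3))
        ens = ConformationalEnsemble(coords, [0])
        with pytest.warns(UserWarning, match="majority"):
            eta = residue_discriminability(ens, ens, 0, n_repeats=1)
        assert eta == 0.5

    def test_too_few_frames_rejected(self):
        coords = np.zeros((10, 1, 3))
        ens = ConformationalEnsemble(coords, [0])
        with pytest.raises(ValueError, match="20 frames"):
            residue_discriminability(ens, ens, 0)


class TestProfile:
    def test_localized_shift_flags_and_com(self):
        # one residue of 24 shifted 5 sigma: whole-molecule superposition
        # leaks only shift/n_residues (~0.1 A) into the other residues
        n = 24
        shift = np.zeros((n, 3))
        shift[3] = (2.5, 0.0, 0.0)
        a, b, truth = simulate_ensembles(
            EnsembleSimConfig(n_residues=n, n_frames=300, mean_shift=shift,
                              coord_sd=0.5, seed=6)
        )
        prof = discriminability_profile(superpose(a), superpose(b), n_repeats=3)
        t = prof.table.set_index("residue")
        assert t.loc[3, "flagged"]
        # rigid fitting absorbs part of a localized shift; ~15% attenuation
        assert t.loc[3, "com_deviation"] == pytest.approx(2.5, abs=0.45)
        others = t.drop(index=3)
        assert (others.com_deviation < 0.5).all()
        assert not others.flagged.any()

    def test_identical_distributions_no_flags(self):
        a, b, _ = simulate_ensembles(
            EnsembleSimConfig(n_residues=6, n_frames=300, seed=8)
        )
        prof = discriminability_profile(superpose(a), superpose(b), n_repeats=3)
        assert not prof.table.flagged.any()

    def test_profile_invariant_to_global_rigid_transform(self):
        """Rotating+translating both ensembles identically before fitting
        leaves eta and CoM deviations unchanged."""
        a, b, _ = simulate_ensembles(
            EnsembleSimConfig(n_residues=4, n_frames=200,
                              mean_shift=np.tile([0.8, 0, 0], (4, 1)), seed=9)
        )
        rot = Rotation.from_euler("xyz", [30, -20, 45], degrees=True).as_matrix()
        shift = np.array([3.0, -1.0, 2.0])
        move = lambda e: ConformationalEnsemble(
            e.coords @ rot.T + shift, e.residue_ids, e.reference, e.frame_interval_ps
        )
        p1 = discriminability_profile(superpose(a), superpose(b), n_repeats=2)
        p2 = discriminability_profile(superpose(move(a)), superpose(move(b)), n_repeats=2)
        np.testing.assert_allclose(p1.table.eta, p2.table.eta, atol=1e-9)
        np.testing.assert_allclose(p1.table.com_deviation, p2.table.com_deviation, atol=1e-9)

    def test_residue_mismatch_rejected(self):
        a = ConformationalEnsemble(np.zeros((30, 2, 3)), [0, 1])
        b = ConformationalEnsemble(np.zeros((30, 2, 3)), [0, 2])
        with pytest.raises(ValueError, match="residue sets"):
            discriminability_profile(a, b)


class TestCoMDeviation:
    def test_identical_ensembles_zero(self):
        a, _ = _pair(n_res=2, n_frames=50, seed=12)
        assert com_deviation(a, a, 0) == 0.0

    def test_pythagorean_translation(self):
        coords = np.zeros((30, 1, 3))
        a = ConformationalEnsemble(coords, [0])
        b = ConformationalEnsemble(coords + np.array([0.6, 0.8, 0.0]), [0])
        assert com_deviation(a, b, 0) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_clouds_within_3se(self):
        sd, m, d = 0.5, 1500, 1.2
        a, b = _pair(n_res=1, n_frames=m, shift=(d, 0, 0), sd=sd, seed=13)
        se = sd * np.sqrt(2.0 / m)
        assert abs(com_deviation(a, b, 0) - d) < 3 * se


def test_pdb_roundtrip(tmp_path):
    a, _ = _pair(n_res=3, n_frames=25, seed=14)
    path = tmp_path / "ens.pdb"
    ensemble_to_pdb(a, path)
    back = ensemble_from_pdb(path)
    assert back.n_frames == 25
    np.testing.assert_allclose(back.coords, a.coords, atol=1e-2)  # PDB precision
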