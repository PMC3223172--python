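"""Horn fiducial registration and the FRE/TRE accuracy metrics."""

import numpy as np
import pytest

from ctus_fusion.geometry import Point3, make_transform
from ctus_fusion.registration import (
    DegenerateConfigurationError,
    FiducialPair,
    fiducial_registration_error,
    horn_registration,
    read_fiducial_pairs,
    target_registration_error,
    write_fiducial_pairs,
)
from ctus_fusion.synthetic_phantoms import generate_fiducial_pairs, simulate_fusion_tre


def _identical_pairs(n=5, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-40, 40, size=(n, 3))
    return [
        FiducialPair(Point3(*p, space="C"), Point3(*p, space="T")) for p in pts
    ]


class TestHorn:
    def test_identity_for_identical_point_sets(self):
        reg = horn_registration(_identical_pairs())
        assert np.allclose(reg.tracker_from_ct.matrix, np.eye(4), atol=1e-9)
        assert reg.mean_fre == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_of_known_transform(self, true_registration):
        pairs = generate_fiducial_pairs(true_registration, n=12, noise_sd=0.0, seed=0)
        reg = horn_registration(pairs)
        assert np.allclose(
            reg.tracker_from_ct.matrix, true_registration.matrix, atol=1e-9
        )
        assert reg.mean_fre < 1e-9

    def test_exact_recovery_many_configurations(self, true_registration, rng):
        for seed in range(10):
            pairs = generate_fiducial_pairs(
                true_registration, n=int(rng.integers(3, 20)), noise_sd=0.0, seed=seed
            )
            reg = horn_registration(pairs)
            assert np.allclose(
                reg.tracker_from_ct.matrix, true_registration.matrix, atol=1e-9
            )

    def test_noisy_fit_fre_scale_and_translation(self, true_registration):
        sigma = 0.5
        pairs = generate_fiducial_pairs(true_registration, n=12, noise_sd=sigma, seed=0)
        reg = horn_registration(pairs)
        assert sigma / 2 < reg.mean_fre < sigma * 2
        t_err = np.linalg.norm(
            np.array(reg.tracker_from_ct.translation)
            - np.array(true_registration.translation)
        )
        assert t_err < 0.5

    def test_fre_monotone_in_noise(self, true_registration):
        means = []
        for sigma in [0.0, 0.25, 0.5, 1.0]:
            vals = [
                horn_registration(
                    generate_fiducial_pairs(
                        true_registration, n=12, noise_sd=sigma, seed=s
                    )
                ).mean_fre
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_invariant_to_point_ordering(self, true_registration):
        pairs = generate_fiducial_pairs(true_registration, n=12, noise_sd=0.5, seed=1)
        reg_fwd = horn_registration(pairs)
        reg_rev = horn_registration(pairs[::-1])
        assert np.allclose(
            reg_fwd.tracker_from_ct.matrix, reg_rev.tracker_from_ct.matrix, atol=1e-9
        )

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateConfigurationError):
            horn_registration(_identical_pairs(n=2))

    def test_collinear_pairs(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 0.5])
        pairs = [
            FiducialPair(Point3(*p, space="C"), Point3(*p, space="T")) for p in pts
        ]
        with pytest.raises(DegenerateConfigurationError):
            horn_registration(pairs)


class TestFRE:
    def test_fitting_set_matches_stored_mean(self, true_registration):
        pairs = generate_fiducial_pairs(true_registration, n=12, noise_sd=0.5, seed=0)
        reg = horn_registration(pairs)
        mean, sd = fiducial_registration_error(reg, pairs)
        assert mean == pytest.approx(reg.mean_fre, abs=1e-12)
        assert sd >= 0

    def test_pretransformed_pairs_give_zero(self, true_registration):
        pairs = generate_fiducial_pairs(true_registration, n=8, noise_sd=0.0, seed=2)
        reg = horn_registration(pairs)
        mean, _ = fiducial_registration_error(reg, pairs)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_held_out_pairs(self, true_registration):
        fit_pairs = generate_fiducial_pairs(true_registration, n=12, noise_sd=0.5, seed=0)
        held_out = generate_fiducial_pairs(true_registration, n=12, noise_sd=0.5, seed=1)
        reg = horn_registration(fit_pairs)
        mean, sd = fiducial_registration_error(reg, held_out)
        assert mean > 0 and np.isfinite(sd)

    def test_empty_list_rejected(self, true_registration):
        pairs = generate_fiducial_pairs(true_registration, n=5, noise_sd=0.0, seed=0)
        reg = horn_registration(pairs)
        with pytest.raises(ValueError):
            fiducial_registration_error(reg, [])


class TestTRE:
    def test_identical_lists_give_zero(self, rng):
        pts = [Point3(*p) for p in rng.uniform(-10, 10, size=(5, 3))]
        d, mean, sd = target_registration_error(pts, pts)
        assert d == pytest.approx([0.0] * 5)
        assert (mean, sd) == (0.0, 0.0)

    def test_uniform_shift(self, rng):
        pts = rng.uniform(-10, 10, size=(6, 3))
        shifted = pts + [1.0, 0.0, 0.0]
        d, mean, sd = target_registration_error(pts, shifted)
        assert d == pytest.approx([1.0] * 6)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self, rng):
        pts = rng.uniform(-10, 10, size=(5, 3))
        with pytest.raises(ValueError):
            target_registration_error(pts, pts[:4])

    def test_composed_chain_tre_in_millimetre_regime(self):
        """Propagating 0.5 mm noise through calibration + registration +
        target imaging lands the 50-target grid TRE near 1 mm and above
        either single-stage error on average."""
        results = [simulate_fusion_tre(noise_sd=0.5, seed=s) for s in range(5)]
        tre = np.mean([r["tre_mean_mm"] for r in results])
        cal = np.mean([r["calibration_mean_residual_mm"] for r in results])
        fre = np.mean([r["registration_mean_fre_mm"] for r in results])
        assert all(r["n_targets"] == 50 for r in results)
        assert 0.4 < tre < 2.0
        assert tre >= max(cal, fre) * 0.95  # chain error dominates on average


class TestFiducialCSV:
    def test_roundtrip(self, tmp_path, true_registration):
        pairs = generate_fiducial_pairs(true_registration, n=6, noise_sd=0.2, seed=5)
        path = tmp_path / "fiducials.csv"
        write_fiducial_pairs(path, pairs)
        back = read_fiducial_pairs(path)
        assert len(back) == 6
        for a, b in zip(pairs, back):
            assert np.allclose(a.ct_point.as_array(), b.ct_point.as_array())
            assert np.allclose(a.tracked_point.as_array(), b.tracked_point.as_array())
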