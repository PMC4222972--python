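"""Minimum-norm / sLORETA operator and source-space relative power."""

import numpy as np
import pytest

import bandloc as bl
from bandloc import inverse as inv
from bandloc.errors import (
    BaselineInfeasibleError,
    ParameterError,
    ReferenceStateError,
    UndefinedBaselineError,
)

RATE = 1000.0


def car_leadfield(matrix):
    m = np.asarray(matrix, dtype=float)
    return bl.LeadField(m - m.mean(axis=0, keepdims=True),
                        reference="common-average")


class TestMinimumNorm:
    def test_exact_recovery_in_small_lambda_limit(self):
        """Full-column-rank toy (4 sensors → rank 3 after referencing, 2
        patches): T K j returns j as λ → 0."""
        rng = np.random.default_rng(0)
        K = car_leadfield(rng.standard_normal((4, 2)))
        T = inv.compute_mn_operator(K, lambda_rel=1e-12)
        for j in [np.array([1.0, 0.0]), np.array([-2.0, 5.0])]:
            np.testing.assert_allclose(T @ (K.matrix @ j), j, atol=1e-6)

    def test_shrinkage_with_lambda(self):
        rng = np.random.default_rng(1)
        K = car_leadfield(rng.standard_normal((6, 10)))
        norms = [np.linalg.norm(inv.compute_mn_operator(K, lam))
                 for lam in (1e-4, 1e-2, 1.0, 100.0)]
        assert np.all(np.diff(norms) < 0)

    def test_matches_direct_tikhonov_solve(self):
        """Oracle: regularized normal equations solved independently.  For
        average-referenced data y, Kᵀ(KKᵀ+λH)⁺y equals (KᵀK+λI)⁻¹Kᵀy."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            K = rng.standard_normal((6, 10))
            K -= K.mean(axis=0)
            lf = bl.LeadField(K, reference="common-average")
            T = inv.compute_mn_operator(lf, lambda_rel=0.1)
            lam = 0.1 * np.trace(K @ K.T) / 6
            y = K @ rng.standard_normal(10)
            direct = np.linalg.solve(K.T @ K + lam * np.eye(10), K.T @ y)
            np.testing.assert_allclose(
                T @ y, direct, atol=1e-8 * np.linalg.norm(direct)
            )

    def test_reference_and_parameter_guards(self):
        raw = bl.LeadField(np.ones((3, 2)), reference="raw")
        with pytest.raises(ReferenceStateError):
            inv.compute_mn_operator(raw)
        car = car_leadfield(np.random.default_rng(2).standard_normal((3, 2)))
        with pytest.raises(ParameterError):
            inv.compute_mn_operator(car, lambda_rel=-0.1)


class TestSloreta:
    def test_zero_localization_error_exhaustive(self, toy_lead_field_car):
        """Noiseless single sources at every patch localize exactly."""
        op = inv.make_inverse_operator(toy_lead_field_car, lambda_rel=1e-8)
        for j in range(toy_lead_field_car.n_patches):
            est = np.abs(op.apply(toy_lead_field_car.matrix[:, j]))
            assert int(np.argmax(est)) == j

    def test_unstandardized_mn_mislocalizes_deep_sources(self):
        """In the underdetermined regime (12 sensors, 20 patches) plain MN
        drags deep sources toward the surface while sLORETA does not."""
        sensors = bl.geodesic_sensors(12)
        patches = bl.synthetic_patch_model(10, seed=3, radius_range=(15, 60))
        lf = bl.apply_common_average(
            bl.build_spherical_lead_field(sensors, patches)
        )
        T = inv.compute_mn_operator(lf, lambda_rel=1e-8)
        op = inv.make_inverse_operator(lf, lambda_rel=1e-8)
        mn_errs = sum(
            int(np.argmax(np.abs(T @ lf.matrix[:, j]))) != j
            for j in range(patches.n_patches)
        )
        sl_errs = sum(
            int(np.argmax(np.abs(op.apply(lf.matrix[:, j])))) != j
            for j in range(patches.n_patches)
        )
        assert mn_errs >= 1
        assert sl_errs == 0

    def test_identity_leadfield_uniform_standardization(self):
        lf = bl.LeadField(np.eye(5), reference="common-average")
        T = inv.compute_mn_operator(lf, lambda_rel=0.01)
        op = inv.sloreta_standardize(T, lf)
        np.testing.assert_allclose(op.standardization,
                                   op.standardization[0], rtol=1e-9)


class TestApplyInverse:
    def _coeffs(self, values):
        values = np.asarray(values, dtype=np.complex64)
        nt = values.shape[-1]
        return bl.TFCoefficients(
            values=values, times=np.arange(nt) * 10.0,
            frequencies=np.array([20.0]),
            valid=np.ones((1, nt), dtype=bool), space_kind="sensor",
        )

    def _op(self, n_sensors=4, n_patches=3, seed=5):
        rng = np.random.default_rng(seed)
        lf = car_leadfield(rng.standard_normal((n_sensors, n_patches)))
        return inv.make_inverse_operator(lf, lambda_rel=0.01)

    def test_real_input_gives_real_output(self):
        op = self._op()
        vals = np.random.default_rng(6).standard_normal((2, 4, 1, 5))
        src = inv.apply_inverse_tf(op, self._coeffs(vals))
        assert np.max(np.abs(src.values.imag)) == 0

    def test_global_phase_rotation_commutes(self):
        op = self._op()
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((1, 4, 1, 5)) + 1j * rng.standard_normal(
            (1, 4, 1, 5)
        )
        theta = 0.7
        a = inv.apply_inverse_tf(op, self._coeffs(vals * np.exp(1j * theta)))
        b = inv.apply_inverse_tf(op, self._coeffs(vals))
        np.testing.assert_allclose(a.values, b.values * np.exp(1j * theta),
                                   rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(np.abs(a.values) ** 2,
                                   np.abs(b.values) ** 2, rtol=1e-4, atol=1e-6)

    def test_dimension_mismatch(self):
        op = self._op(n_sensors=4)
        with pytest.raises(ParameterError):
            inv.apply_inverse_tf(op, self._coeffs(np.zeros((1, 5, 1, 2))))

    def test_wavelet_and_inverse_commute(self, toy_lead_field_car):
        """Linearity consistency: invert the time series then decompose,
        or decompose then invert — same source power."""
        lf = toy_lead_field_car
        rng = np.random.default_rng(8)
        sensor_ts = rng.standard_normal((1, lf.n_sensors, 2001))
        ep = bl.EpochSet(data=sensor_ts, window=(-1000, 1000), rate=RATE)
        fam = bl.build_morlet_family(RATE, [22.0])
        op = inv.make_inverse_operator(lf, lambda_rel=0.05)

        src_a = inv.apply_inverse_tf(op, bl.wavelet_transform(ep, fam))
        p_a = inv.source_power(src_a)

        w = op.transform / np.sqrt(op.standardization)[:, None]
        src_ts = np.einsum("ps,tsn->tpn", w, sensor_ts)
        ep_src = bl.EpochSet(data=src_ts, window=(-1000, 1000), rate=RATE)
        tc = bl.wavelet_transform(ep_src, fam)
        p_b = np.mean(np.abs(tc.values) ** 2, axis=0)

        np.testing.assert_allclose(p_a, p_b, rtol=1e-4)


class TestSourcePower:
    def _src(self, values):
        values = np.asarray(values, dtype=complex)
        nt = values.shape[-1]
        return bl.SourceTF(values=values, times=np.arange(nt) * 10.0 - 1000.0,
                           frequencies=np.array([30.0]),
                           valid=np.ones((1, nt), dtype=bool))

    def test_single_trial_modulus_squared(self):
        src = self._src(np.full((1, 1, 1, 1), 3 + 4j))
        assert inv.source_power(src)[0, 0, 0] == pytest.approx(25.0)

    def test_opposite_phases_do_not_cancel(self):
        vals = np.stack([np.full((1, 1, 1), 2 + 1j),
                         np.full((1, 1, 1), -2 - 1j)])
        src = self._src(vals)
        assert inv.source_power(src)[0, 0, 0] == pytest.approx(5.0)

    def test_trial_permutation_invariant(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((5, 2, 1, 3)) + 1j * rng.standard_normal(
            (5, 2, 1, 3)
        )
        a = inv.source_power(self._src(vals))
        b = inv.source_power(self._src(vals[::-1]))
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_bootstrap_mean_within_per_trial_range(self):
        rng = np.random.default_rng(10)
        vals = rng.standard_normal((8, 1, 1, 1)) + 1j * rng.standard_normal(
            (8, 1, 1, 1)
        )
        per_trial = np.abs(vals[:, 0, 0, 0]) ** 2
        for _ in range(20):
            pick = rng.integers(0, 8, size=8)
            m = np.mean(per_trial[pick])
            assert per_trial.min() - 1e-12 <= m <= per_trial.max() + 1e-12


class TestBaseline:
    def test_baseline_time_at_120hz_snaps_to_minus_630(self):
        fam = bl.build_morlet_family(RATE, [120.0])
        assert inv.baseline_time(120.0, fam) == pytest.approx(-630.0)

    def test_low_frequency_support_infeasible(self):
        fam = bl.build_morlet_family(RATE, [10.0])
        with pytest.raises(BaselineInfeasibleError):
            inv.baseline_time(10.0, fam)  # 7 σ_t ≈ 780 ms > 400 ms window

    def test_center_placement_option(self):
        fam = bl.build_morlet_family(RATE, [10.0])
        assert inv.baseline_time(10.0, fam, placement="center") == -600.0

    def test_stationary_source_gives_zero_relative_power(self):
        rng = np.random.default_rng(11)
        t = np.arange(-1000, 1001) / RATE
        phases = rng.uniform(0, 2 * np.pi, size=4)
        data = np.stack(
            [np.cos(2 * np.pi * 25.0 * t + p)[None, :] for p in phases]
        )
        ep = bl.EpochSet(data=data, window=(-1000, 1000), rate=RATE)
        fam = bl.build_morlet_family(RATE, [25.0])
        tc = bl.wavelet_transform(ep, fam)
        src = bl.SourceTF(values=tc.values, times=tc.times,
                          frequencies=tc.frequencies, valid=tc.valid)
        B = inv.baseline_power(src, fam)
        pmap = inv.relative_power(inv.source_power(src), B, src.times,
                                  src.frequencies)
        sel = (pmap.times > -500) & (pmap.times < 500)
        assert np.max(np.abs(pmap.values[0, 0, sel])) < 2.0


class TestRelativePower:
    def test_identities(self):
        P = np.ones((2, 1, 3))
        B = np.ones((2, 1))
        pm = inv.relative_power(P, B, np.arange(3.0), [20.0])
        np.testing.assert_allclose(pm.values, 0.0)
        pm2 = inv.relative_power(2 * P, B, np.arange(3.0), [20.0])
        np.testing.assert_allclose(pm2.values, 100.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedBaselineError):
            inv.relative_power(np.ones((1, 1, 1)), np.zeros((1, 1)),
                               [0.0], [20.0])

    def test_invariant_to_global_leadfield_scale(self, toy_lead_field_car):
        """K → 3K yields the same relative power map for the same data."""
        rng = np.random.default_rng(12)
        vals = (rng.standard_normal((2, toy_lead_field_car.n_sensors, 1, 60))
                + 1j * rng.standard_normal(
                    (2, toy_lead_field_car.n_sensors, 1, 60)))
        times = np.arange(60) * 10.0 - 1000.0
        coeffs = bl.TFCoefficients(values=vals.astype(np.complex64),
                                   times=times,
                                   frequencies=np.array([25.0]),
                                   valid=np.ones((1, 60), dtype=bool),
                                   space_kind="sensor")
        fam = bl.build_morlet_family(RATE, [25.0])

        def rel_map(lf):
            op = inv.make_inverse_operator(lf, lambda_rel=0.05)
            src = inv.apply_inverse_tf(op, coeffs)
            B = inv.baseline_power(src, fam)
            return inv.relative_power(inv.source_power(src), B, src.times,
                                      src.frequencies).values

        scaled = bl.LeadField(3.0 * toy_lead_field_car.matrix,
                              reference="common-average")
        a = rel_map(toy_lead_field_car)
        b = rel_map(scaled)
        np.testing.assert_allclose(a, b, rtol=2e-3, atol=1e-4)


class TestOperatorIO:
    def test_hdf5_round_trip(self, toy_lead_field_car, tmp_path):
        op = inv.make_inverse_operator(toy_lead_field_car)
        path = tmp_path / "op.h5"
        inv.save_operator(op, path)
        back = inv.load_operator(path)
        np.testing.assert_array_equal(back.transform, op.transform)
        np.testing.assert_array_equal(back.standardization, op.standardization)
        assert back.lam == op.lam and back.reference == op.reference
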