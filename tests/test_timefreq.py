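"""Morlet family, wavelet transform, relative power, bands, contiguity."""

import numpy as np
import pytest

import bandloc as bl
from bandloc.errors import ParameterError, UndefinedBaselineError

RATE = 1000.0


def sinusoid_epochs(freq, amp=1.0, n_trials=3, envelope=None, rng_phase=None):
    t = np.arange(-1000, 1001) / RATE  # seconds, window (-1000, 1000) ms
    trials = []
    rng = np.random.default_rng(0)
    for _ in range(n_trials):
        ph = rng.uniform(0, 2 * np.pi) if rng_phase else 0.0
        x = amp * np.cos(2 * np.pi * freq * t + ph)
        if envelope is not None:
            x = x * envelope(t * 1000.0)
        trials.append(x[None, :])
    return bl.EpochSet(data=np.stack(trials), window=(-1000.0, 1000.0), rate=RATE)


class TestMorletFamily:
    def test_sigma_t_closed_form(self):
        fam = bl.build_morlet_family(RATE, [10.0])
        assert fam.sigma_t(10.0) == pytest.approx(7.0 / (20.0 * np.pi))
        assert fam.sigma_t(10.0) * 1000 == pytest.approx(111.4, abs=0.1)

    def test_support_halves_when_frequency_doubles(self):
        fam = bl.build_morlet_family(RATE, [10.0, 20.0])
        assert len(fam.wavelet(20.0)) == pytest.approx(len(fam.wavelet(10.0)) / 2,
                                                       abs=1.5)

    def test_unit_energy(self):
        fam = bl.build_morlet_family(RATE, [5.0, 40.0, 120.0])
        for f in fam.frequencies:
            psi = fam.wavelet(f)
            assert np.sum(np.abs(psi) ** 2) / RATE == pytest.approx(1.0, abs=1e-6)

    def test_ratio_guards(self):
        with pytest.warns(UserWarning):
            bl.build_morlet_family(RATE, [10.0], ratio=4.0)
        with pytest.raises(ParameterError):
            bl.build_morlet_family(RATE, [10.0], ratio=-1.0)
        with pytest.raises(ParameterError):
            bl.build_morlet_family(200.0, [120.0])


class TestWaveletTransform:
    def test_stationary_sinusoid_constant_power(self):
        ep = sinusoid_epochs(20.0, amp=2.0)
        fam = bl.build_morlet_family(RATE, [20.0])
        tc = bl.wavelet_transform(ep, fam)
        power = np.abs(tc.values[0, 0, 0]) ** 2
        core = power[tc.valid[0]]
        assert np.ptp(core) / np.mean(core) < 0.02
        # power scales with amplitude squared
        ep4 = sinusoid_epochs(20.0, amp=4.0)
        p4 = np.abs(bl.wavelet_transform(ep4, fam).values[0, 0, 0]) ** 2
        ratio = np.mean(p4[tc.valid[0]]) / np.mean(core)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_spectral_selectivity(self):
        """A 20 Hz tone leaks into the 30 Hz wavelet by less than a tenth of
        its on-frequency power (Gaussian spectral window, σ_f = f/7)."""
        ep = sinusoid_epochs(20.0)
        fam = bl.build_morlet_family(RATE, [20.0, 30.0])
        tc = bl.wavelet_transform(ep, fam)
        valid = tc.valid[0] & tc.valid[1]
        p20 = np.mean(np.abs(tc.values[0, 0, 0, valid]) ** 2)
        p30 = np.mean(np.abs(tc.values[0, 0, 1, valid]) ** 2)
        assert p20 / p30 > 10.0

    def test_zero_in_zero_out(self):
        ep = bl.EpochSet(data=np.zeros((2, 3, 2001)), window=(-1000, 1000),
                         rate=RATE)
        fam = bl.build_morlet_family(RATE, [10.0, 40.0])
        tc = bl.wavelet_transform(ep, fam)
        assert np.all(tc.values == 0)

    def test_ten_ms_grid_and_edge_invalidity(self):
        ep = sinusoid_epochs(10.0)
        fam = bl.build_morlet_family(RATE, [5.0, 40.0])
        tc = bl.wavelet_transform(ep, fam)
        assert np.all(np.diff(tc.times) == pytest.approx(10.0))
        assert tc.times[0] == -1000.0 and tc.times[-1] == 1000.0
        # 5 Hz wavelet: half support 3.5·(7/(10π)) s ≈ 780 ms
        assert not tc.valid[0, 0] and tc.valid[0, len(tc.times) // 2]
        # 40 Hz wavelet: half support ≈ 97 ms, valid from ~-900 ms onward
        assert tc.valid[1, 15] and not tc.valid[1, 0]


class TestRelativePower:
    def test_stationary_signal_near_zero(self):
        ep = sinusoid_epochs(25.0, n_trials=4, rng_phase=True)
        fam = bl.build_morlet_family(RATE, [25.0])
        pm = bl.sensor_relative_power(bl.wavelet_transform(ep, fam))
        core = pm.values[0, 0, pm.valid[0]]
        assert np.max(np.abs(core)) < 5.0

    def test_amplitude_doubling_gives_plus_300(self):
        env = lambda ms: np.where(ms >= 0, 2.0, 1.0)
        ep = sinusoid_epochs(25.0, envelope=env)
        fam = bl.build_morlet_family(RATE, [25.0])
        pm = bl.sensor_relative_power(bl.wavelet_transform(ep, fam))
        sel = (pm.times > 200) & (pm.times < 800)
        assert np.mean(pm.values[0, 0, sel]) == pytest.approx(300.0, abs=10.0)

    def test_full_erd_is_minus_100(self):
        env = lambda ms: np.where(ms >= 0, 0.0, 1.0)
        ep = sinusoid_epochs(25.0, envelope=env)
        fam = bl.build_morlet_family(RATE, [25.0])
        pm = bl.sensor_relative_power(bl.wavelet_transform(ep, fam))
        sel = (pm.times > 200) & (pm.times < 800)
        assert np.mean(pm.values[0, 0, sel]) == pytest.approx(-100.0, abs=5.0)
        assert np.all(pm.values >= -100.0 - 1e-6)

    def test_zero_baseline_raises_naming_frequency(self):
        ep = bl.EpochSet(data=np.zeros((1, 1, 2001)), window=(-1000, 1000),
                         rate=RATE)
        fam = bl.build_morlet_family(RATE, [30.0])
        with pytest.raises(UndefinedBaselineError, match="30"):
            bl.sensor_relative_power(bl.wavelet_transform(ep, fam))


class TestInvariances:
    def _beta_map(self, family_cls_scale=None):
        env = lambda ms: np.where((ms > -500) & (ms < 300), 0.5, 1.0)
        ep = sinusoid_epochs(22.0, n_trials=3, envelope=env, rng_phase=True)
        fam = bl.build_morlet_family(RATE, [20.0, 22.0, 24.0])
        if family_cls_scale:
            orig = fam.wavelet
            fam.wavelet = lambda f: family_cls_scale * orig(f)  # type: ignore
        return bl.sensor_relative_power(
            bl.wavelet_transform(ep, fam, dtype=np.complex128)
        )

    def test_invariant_to_wavelet_rescaling(self):
        a = self._beta_map()
        b = self._beta_map(family_cls_scale=2.7)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-5, atol=1e-6)

    def test_invariant_to_common_channel_gain(self):
        env = lambda ms: np.where(ms >= 0, 0.5, 1.0)
        ep = sinusoid_epochs(22.0, envelope=env)
        fam = bl.build_morlet_family(RATE, [22.0])
        a = bl.sensor_relative_power(
            bl.wavelet_transform(ep, fam, dtype=np.complex128))
        ep2 = bl.EpochSet(data=ep.data * 13.0, window=ep.window, rate=RATE)
        b = bl.sensor_relative_power(
            bl.wavelet_transform(ep2, fam, dtype=np.complex128))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6, atol=1e-9)

    def test_trial_permutation_invariance(self):
        ep = sinusoid_epochs(22.0, n_trials=5, rng_phase=True)
        fam = bl.build_morlet_family(RATE, [22.0])
        a = bl.sensor_relative_power(
            bl.wavelet_transform(ep, fam, dtype=np.complex128))
        ep2 = bl.EpochSet(data=ep.data[::-1], window=ep.window, rate=RATE)
        b = bl.sensor_relative_power(
            bl.wavelet_transform(ep2, fam, dtype=np.complex128))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6, atol=1e-9)


class TestBandAverage:
    def _map(self, values, freqs):
        return bl.RelativePowerMap(
            values=values, times=np.array([0.0]), axis=list(freqs),
            baseline_window=(-1000, -600), axis_kind="frequency",
        )

    def test_beta_is_mean_of_its_bins(self):
        freqs = np.arange(1.0, 121.0)
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(2, 120, 1))
        banded = bl.band_average(self._map(vals, freqs))
        beta = banded.axis.index("beta")
        np.testing.assert_allclose(
            banded.values[:, beta, 0], vals[:, 13:30, 0].mean(axis=1)
        )

    def test_constant_map_preserved_and_notch_excluded(self):
        freqs = np.arange(1.0, 121.0)
        vals = np.full((1, 120, 1), 4.2)
        vals[0, 58:61, 0] = 999.0  # 59-61 Hz poisoned; excluded by default
        banded = bl.band_average(self._map(vals, freqs))
        for bi, name in enumerate(banded.axis):
            assert banded.values[0, bi, 0] == pytest.approx(4.2)

    def test_single_bin_band_is_identity(self):
        freqs = np.arange(1.0, 121.0)
        vals = np.arange(120.0)[None, :, None]
        scheme = bl.BandScheme({"one": (42, 42)})
        banded = bl.band_average(self._map(vals, freqs), scheme)
        assert banded.values[0, 0, 0] == 41.0  # bin for 42 Hz

    def test_band_outside_axis_rejected(self):
        with pytest.raises(ParameterError):
            bl.band_average(self._map(np.zeros((1, 10, 1)), np.arange(1.0, 11.0)),
                            bl.BandScheme({"hg": (61, 120)}))


class TestContiguityScreen:
    def _chain_adjacency(self, n, extra=()):
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        for i, j in extra:
            adj[i, j] = adj[j, i] = True
        return adj

    def test_clique_of_five_retained(self):
        adj = np.ones((5, 5), dtype=bool)
        np.fill_diagonal(adj, False)
        mask = np.ones(5, dtype=bool)
        out = bl.contiguity_screen(mask, adj)
        assert np.all(out)

    def test_isolated_channels_removed(self):
        adj = np.zeros((3, 3), dtype=bool)  # no edges at all
        out = bl.contiguity_screen(np.ones(3, dtype=bool), adj)
        assert not np.any(out)

    def test_chain_of_four_retained_matches_bruteforce(self):
        """Oracle: exhaustive connected-component search on the toy graph."""
        adj = self._chain_adjacency(6)
        mask = np.array([True, True, True, True, False, True])

        # brute force: grow components by repeated neighbor expansion
        def components(on):
            on = set(on)
            comps = []
            while on:
                comp = {on.pop()}
                grew = True
                while grew:
                    grew = False
                    for i in list(comp):
                        for j in range(6):
                            if adj[i, j] and j in on:
                                on.remove(j)
                                comp.add(j)
                                grew = True
                comps.append(comp)
            return comps

        expected = set().union(
            *[c for c in components(np.flatnonzero(mask)) if len(c) >= 4]
        )
        out = bl.contiguity_screen(mask, adj)
        assert set(np.flatnonzero(out)) == expected == {0, 1, 2, 3}

    def test_missing_adjacency_rejected(self):
        with pytest.raises(ParameterError):
            bl.contiguity_screen(np.ones(4, dtype=bool), None)

    def test_top_percent_threshold_sign_preserved(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(10, 2, 20))
        pm = bl.RelativePowerMap(values=vals, times=np.arange(20.0),
                                 axis=["a", "b"], baseline_window=(0, 0),
                                 axis_kind="band")
        mask = bl.threshold_top_percent(pm, top=10.0)
        frac = mask.mean(axis=(0, 2))
        assert np.all(frac >= 0.08) and np.all(frac <= 0.13)
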