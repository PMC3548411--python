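import numpy as np
import pytest

from tremorkit import metrics as mx
from tremorkit import signal_core as sc
from tremorkit import simulator as sim

from conftest import make_tone, random_spectrum


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def oracle_mpf(spec):
    """Scan a fine subdivision of the bins for the 50% power crossing."""
    lo, hi = spec.bin_edges()
    slices = 2000
    freqs, weights = [], []
    for i in range(spec.power.size):
        width = hi[i] - lo[i]
        if width <= 0:
            continue
        edges = np.linspace(lo[i], hi[i], slices + 1)
        freqs.extend((edges[:-1] + edges[1:]) / 2)
        weights.extend([spec.power[i] / slices] * slices)
    freqs = np.asarray(freqs)
    weights = np.asarray(weights)
    cum = np.cumsum(weights)
    k = np.searchsorted(cum, 0.5 * weights.sum())
    return freqs[min(k, freqs.size - 1)]


def oracle_dispersion(spec, center, fraction=0.68, return_contained=False):
    """Replay the alternating symmetric expansion with explicit sets."""
    k = int(np.argmin(np.abs(spec.freqs - center)))
    included = {k}
    total = spec.power.sum()
    side = "low"
    while sum(spec.power[i] for i in included) < fraction * total * (1 - 1e-12):
        lo_next = min(included) - 1
        hi_next = max(included) + 1
        candidates = []
        if lo_next >= 0:
            candidates.append(("low", lo_next))
        if hi_next < spec.power.size:
            candidates.append(("high", hi_next))
        if not candidates:
            break
        pick = next(
            (c for c in candidates if c[0] == side), candidates[0]
        )
        included.add(pick[1])
        side = "high" if side == "low" else "low"
    lo_e, hi_e = spec.bin_edges()
    width = hi_e[max(included)] - lo_e[min(included)]
    if return_contained:
        return width, sum(spec.power[i] for i in included)
    return width


def oracle_hi(spec):
    area = 0.0
    for p in spec.power:
        area += p * spec.df
    rect = max(spec.power) * spec.df * spec.power.size
    return 1.0 - area / rect


def oracle_pow_dist(spec, band=(3.0, 7.0)):
    num = sum(p for f, p in zip(spec.freqs, spec.power) if band[0] <= f <= band[1])
    return 100.0 * num / sum(spec.power)


# ---------------------------------------------------------------------------


class TestRms:
    def test_sinusoid(self):
        x = make_tone(4.0, amplitude=2.0)  # 8.5 s -> 34 cycles
        assert mx.rms_amplitude(sc.demean(x)) == pytest.approx(
            2.0 / np.sqrt(2), rel=0.01
        )

    def test_zeros(self):
        assert mx.rms_amplitude(np.zeros(10)) == 0.0

    def test_square_wave(self):
        assert mx.rms_amplitude([3.0, -3.0, 3.0, -3.0]) == 3.0

    def test_empty(self):
        with pytest.raises(ValueError):
            mx.rms_amplitude([])


class TestRegularity:
    def test_steady_sinusoid_near_zero(self):
        x = make_tone(4.0)  # integer cycles per 1-s epoch
        assert mx.regularity(x, 60.0) < 0.01

    def test_alternating_gain_matches_hand_oracle(self):
        rate = 60.0
        base = make_tone(5.0, rate=rate, n=480, amplitude=1.0)
        gains = np.repeat([1.0, 3.0, 1.0, 3.0, 1.0, 3.0, 1.0, 3.0], int(rate))
        x = base * gains
        # hand-computed: normalize, epoch RMS, SD
        z = (x - x.mean()) / x.std()
        epochs = z.reshape(8, int(rate))
        expected = np.std(
            [np.sqrt(np.mean(e**2)) for e in epochs], ddof=1
        )
        assert mx.regularity(x, rate) == pytest.approx(expected, abs=1e-12)

    def test_510_samples_uses_8_epochs(self):
        # value must be identical whether or not the trailing 30 samples vary
        rng = np.random.default_rng(0)
        x = rng.normal(size=510)
        y = x.copy()
        y[480:] += 100.0  # inside the dropped partial epoch
        zx = (x - x.mean()) / x.std()
        ex = zx.reshape(-1, 60)[:8] if False else zx[:480].reshape(8, 60)
        expected = np.std(np.sqrt(np.mean(ex**2, axis=1)), ddof=1)
        assert mx.regularity(x, 60.0) == pytest.approx(expected)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert mx.regularity(np.full(510, 2.0), 60.0) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            mx.regularity(np.zeros(60), 60.0)


class TestPowerSpectrum:
    def test_tone_dominant_bin(self):
        spec = mx.power_spectrum(sc.demean(make_tone(5.0)), 60.0)
        k = np.argmax(spec.power)
        assert abs(spec.freqs[k] - 5.0) <= spec.df
        assert spec.power[k] > 0.5 * spec.total_power

    def test_tone_power_concentrated(self):
        spec = mx.power_spectrum(sc.demean(make_tone(5.0)), 60.0)
        near = np.abs(spec.freqs - 5.0) <= 3 * spec.df
        assert spec.power[near].sum() > 0.95 * spec.total_power

    def test_white_noise_nonnegative(self, rng):
        spec = mx.power_spectrum(rng.normal(size=510), 60.0)
        assert spec.total_power > 0
        assert np.all(spec.power >= 0)

    def test_two_equal_tones(self):
        x = make_tone(4.0) + make_tone(10.0, phase=1.7)
        spec = mx.power_spectrum(sc.demean(x), 60.0)

        def band_power(f):
            return spec.power[np.abs(spec.freqs - f) <= 6 * spec.df].sum()

        assert band_power(4.0) == pytest.approx(band_power(10.0), rel=0.05)

    def test_band_restriction(self):
        spec = mx.power_spectrum(sc.demean(make_tone(5.0)), 60.0)
        assert spec.freqs[0] >= 1.0
        assert spec.freqs[-1] <= 20.0

    def test_nfft_is_next_power_of_two(self):
        spec = mx.power_spectrum(np.ones(510), 60.0)
        assert spec.df == pytest.approx(60.0 / 512)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            mx.power_spectrum(np.zeros(100), 40.0)


class TestPowerDistribution:
    def test_pure_5hz_tone(self):
        spec = mx.power_spectrum(sc.demean(make_tone(5.0)), 60.0)
        assert mx.power_distribution(spec) >= 95.0

    def test_pure_10hz_tone(self):
        spec = mx.power_spectrum(sc.demean(make_tone(10.0)), 60.0)
        assert mx.power_distribution(spec) <= 5.0

    def test_all_inside_band_is_100(self, rng):
        spec = random_spectrum(rng, n_bins=20, band=(3.0, 7.0))
        assert mx.power_distribution(spec) == pytest.approx(100.0)

    def test_full_band_is_100(self, rng):
        for _ in range(20):
            spec = random_spectrum(rng)
            assert mx.power_distribution(spec, band=(1.0, 20.0)) == pytest.approx(
                100.0
            )

    def test_zero_power_rejected(self):
        spec = mx.PowerSpectrum(
            freqs=np.array([5.0]), power=np.array([0.0]), df=1.0
        )
        with pytest.raises(ValueError):
            mx.power_distribution(spec)


class TestMedianPowerFrequency:
    def test_symmetric_spectrum(self):
        freqs = np.arange(3.0, 7.01, 0.5)
        power = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1.0])
        spec = mx.PowerSpectrum(freqs=freqs, power=power, df=0.5)
        assert mx.median_power_frequency(spec) == pytest.approx(5.0, abs=0.5)

    def test_single_bin(self):
        spec = mx.PowerSpectrum(
            freqs=np.array([6.0]), power=np.array([2.0]), df=0.25
        )
        assert mx.median_power_frequency(spec) == pytest.approx(6.0, abs=0.25)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force(self, rng, trial):
        spec = random_spectrum(rng)
        assert mx.median_power_frequency(spec) == pytest.approx(
            oracle_mpf(spec), abs=spec.df
        )

    def test_inverse_integration_recovers_half(self, rng):
        for _ in range(50):
            spec = random_spectrum(rng)
            mpf = mx.median_power_frequency(spec)
            assert mx.power_below(spec, mpf) == pytest.approx(0.5, abs=1e-9)


class TestPeakPowerFrequency:
    def test_single_tone(self):
        spec = mx.power_spectrum(sc.demean(make_tone(6.0)), 60.0)
        assert abs(mx.peak_power_frequency(spec) - 6.0) <= spec.df

    def test_tie_breaks_low(self):
        freqs = np.array([4.0, 6.0, 9.0])
        power = np.array([5.0, 1.0, 5.0])
        spec = mx.PowerSpectrum(freqs=freqs, power=power, df=1.0)
        assert mx.peak_power_frequency(spec) == 4.0

    @pytest.mark.parametrize("trial", range(10))
    def test_argmax_oracle(self, rng, trial):
        spec = random_spectrum(rng)
        best = max(
            zip(spec.power, -spec.freqs), key=lambda t: (t[0], t[1])
        )
        assert mx.peak_power_frequency(spec) == -best[1]


class TestPowerDispersion:
    def test_single_bin_sufficient(self):
        spec = mx.PowerSpectrum(
            freqs=np.array([5.0, 6.0, 7.0]),
            power=np.array([0.0, 10.0, 0.0]),
            df=1.0,
        )
        assert mx.power_dispersion(spec, 6.0) <= 2.0

    def test_uniform_spectrum(self):
        n = 190
        df = 19.0 / n
        freqs = 1.0 + df / 2 + df * np.arange(n)
        spec = mx.PowerSpectrum(freqs=freqs, power=np.ones(n), df=df)
        width = mx.power_dispersion(spec, 10.5)
        assert width == pytest.approx(0.68 * 19.0, abs=2 * df)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_expansion_oracle(self, rng, trial):
        spec = random_spectrum(rng)
        center = float(rng.uniform(1.5, 19.5))
        assert mx.power_dispersion(spec, center) == pytest.approx(
            oracle_dispersion(spec, center), abs=1e-9
        )

    def test_band_holds_fraction(self, rng):
        for _ in range(50):
            spec = random_spectrum(rng)
            mpf = mx.median_power_frequency(spec)
            width = mx.power_dispersion(spec, mpf)
            o_width, contained = oracle_dispersion(spec, mpf, return_contained=True)
            assert width == pytest.approx(o_width, abs=1e-9)
            assert contained >= 0.68 * spec.total_power * (1 - 1e-9)


class TestHarmonicIndex:
    def test_flat_spectrum_zero(self):
        spec = mx.PowerSpectrum(
            freqs=np.linspace(1.5, 19.5, 19), power=np.ones(19), df=1.0
        )
        assert mx.harmonic_index(spec) == pytest.approx(0.0, abs=1e-12)

    def test_single_line(self):
        n = 20
        power = np.zeros(n)
        power[7] = 4.2
        spec = mx.PowerSpectrum(
            freqs=np.linspace(1.5, 19.5, n), power=power, df=19.0 / n
        )
        assert mx.harmonic_index(spec) == pytest.approx(1.0 - 1.0 / n)

    @pytest.mark.parametrize("trial", range(25))
    def test_area_oracle(self, rng, trial):
        spec = random_spectrum(rng)
        assert mx.harmonic_index(spec) == pytest.approx(oracle_hi(spec), abs=1e-9)

    def test_rescale_invariance(self, rng):
        spec = random_spectrum(rng)
        scaled = mx.PowerSpectrum(
            freqs=spec.freqs, power=spec.power * 17.3, df=spec.df, band=spec.band
        )
        assert mx.harmonic_index(scaled) == pytest.approx(
            mx.harmonic_index(spec), abs=1e-12
        )

    def test_bounds(self, rng):
        for _ in range(50):
            hi = mx.harmonic_index(random_spectrum(rng))
            assert 0.0 <= hi <= 1.0


class TestCharacterize:
    def test_simulated_tremor_recovery(self):
        spec = sim.SimulationSpec(tremor_freq=5.0, displacement_amp=3.0, seed=11)
        rec = sim.synth_trial(spec, sim.ChannelModel(rate=60.0, label="phone"))
        (m,) = mx.characterize(rec, pathway="displacement")
        assert m.rms == pytest.approx(3.0, rel=0.05)
        assert m.mpf == pytest.approx(5.0, abs=0.3)
        assert m.pow_dist > 90.0

    def test_zero_signal_errors(self):
        rec = sc.TremorRecording(np.zeros(600), rate=60.0)
        with pytest.raises(ValueError, match="zero total power"):
            mx.characterize(rec)

    def test_deterministic(self):
        spec = sim.SimulationSpec(tremor_freq=6.0, displacement_amp=2.0, seed=3)
        rec = sim.synth_trial(spec, sim.PHONE_CHANNEL)
        a = mx.characterize(rec)
        b = mx.characterize(rec)
        assert a == b

    def test_acceleration_pathway_units(self):
        spec = sim.SimulationSpec(tremor_freq=5.0, displacement_amp=3.0, seed=11)
        rec = sim.synth_trial(spec, sim.ChannelModel(rate=60.0, label="phone"))
        (m,) = mx.characterize(rec, pathway="acceleration")
        # 3 mm RMS at 5 Hz -> (2 pi 5)^2 * 0.003 m/s² RMS
        assert m.rms == pytest.approx((2 * np.pi * 5) ** 2 * 0.003, rel=0.05)

    def test_metric_invariants_on_simulator_draws(self):
        rng = np.random.default_rng(5)
        n_draws = 250
        for _ in range(n_draws):
            spec = sim.SimulationSpec(
                tremor_freq=float(rng.uniform(3, 10)),
                displacement_amp=float(np.exp(rng.uniform(np.log(0.2), np.log(30)))),
                mod_depth=float(rng.uniform(0, 0.3)),
                mod_rate=float(rng.uniform(0.1, 0.8)),
                harmonic_frac=float(rng.uniform(0, 0.2)),
                noise_sd=float(rng.uniform(0.005, 0.02)),
                seed=int(rng.integers(2**31)),
            )
            rec = sim.synth_trial(spec, sim.PHONE_CHANNEL)
            (m,) = mx.characterize(rec)
            assert 0.0 <= m.pow_dist <= 100.0
            assert 1.0 <= m.mpf <= 20.0
            assert 1.0 <= m.peak <= 20.0
            assert 0.0 <= m.hi <= 1.0
            assert m.disp >= 0.0
            assert m.disp_peak >= 0.0
            assert m.rms >= 0.0
            assert m.regularity >= 0.0

    def test_mpf_tracks_generated_frequency(self):
        trials = sim.synth_battery(n_per_task=30, seed=42, tasks=("rest", "postural"))
        df = sim.analyze_battery(trials)
        lab = df[df.channel == "lab"].set_index("trial_id")
        truth = {t.spec.trial_id: t.spec.tremor_freq for t in trials}
        amps = {t.spec.trial_id: t.spec.displacement_amp for t in trials}
        keep = [tid for tid in lab.index if amps[tid] >= 1.0]
        gen = np.array([truth[tid] for tid in keep])
        meas = lab.loc[keep, "mpf"].to_numpy()
        r = np.corrcoef(gen, meas)[0, 1]
        assert r > 0.95


class TestMetricsIO:
    def test_frame_and_roundtrip(self, tmp_path):
        spec = sim.SimulationSpec(tremor_freq=5.0, displacement_amp=3.0, seed=1)
        rec = sim.synth_trial(spec, sim.PHONE_CHANNEL)
        (m,) = mx.characterize(rec)
        df = mx.metrics_frame([("t0", "rest", "phone", m)])
        path = mx.write_metrics_csv(df, tmp_path / "m.csv")
        back = mx.read_metrics_csv(path)
        assert back.loc[0, "rms"] == pytest.approx(m.rms)
        assert list(back.columns) == list(df.columns)

    def test_reader_validates_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing"):
            mx.read_metrics_csv(p)
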