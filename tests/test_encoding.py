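"""Spike encoding: pulse programs, trains, statistics, closed forms, energy."""

import numpy as np
import pytest

import spikecoder as sc
from spikecoder.device import DeviceParams
from spikecoder.encoding import PulseProgram, SpikeTrain

from conftest import IST, LEVELS


def _train(spikes, t_p=0.010):
    spikes = np.asarray(spikes, dtype=bool)
    n = len(spikes)
    return SpikeTrain(
        spikes=spikes, currents=np.zeros(n), amplitudes=np.zeros(n),
        active_mask=np.ones(n, dtype=bool), t_p=t_p,
    )


# ---------------------------------------------------------------------------
# pulse sampling

def test_degenerate_gaussian_is_constant():
    prog = sc.rate_program(sigma_tg=0.0, seed=1)
    amps = sc.sample_pulse_train(prog, 0)
    assert np.all(amps == prog.mu_tg)


def test_rate_pulse_statistics_match_program():
    """Pooled draws reproduce the programmed mean and spread."""
    prog = sc.rate_program(n_pulses=1000, n_trials=100, seed=9)
    pool = np.concatenate([sc.sample_pulse_train(prog, t) for t in range(100)])
    n = pool.size
    assert pool.mean() == pytest.approx(-2.5, abs=3 * 0.8 / np.sqrt(n))
    assert pool.std() == pytest.approx(0.8, rel=0.02)


def test_noise_free_count_ramp_is_ordered(device):
    prog = sc.count_program(device, IST, sigma_tg=0.0)
    amps = sc.sample_pulse_train(prog, 0)
    assert np.all(np.diff(np.abs(amps)) > 0)


def test_sampling_deterministic_given_seed_and_trial():
    prog = sc.rate_program(seed=5)
    a = sc.sample_pulse_train(prog, 3)
    b = sc.sample_pulse_train(prog, 3)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, sc.sample_pulse_train(prog, 4))


def test_program_validation(device):
    with pytest.raises(ValueError):
        PulseProgram(mode="bogus")
    with pytest.raises(ValueError):
        PulseProgram(mode="rate", sigma_tg=-1)
    with pytest.raises(ValueError):
        PulseProgram(mode="count", ramp_start=-3.0, ramp_end=-1.0)
    with pytest.raises(ValueError):
        PulseProgram(mode="timing", ramp_start=-1.0, ramp_end=-3.0)
    with pytest.raises(ValueError):
        sc.sample_pulse_train(sc.rate_program(), 99)


# ---------------------------------------------------------------------------
# encoding trials

def test_saturated_stimulus_spikes_every_pulse(quiet_device):
    prog = sc.rate_program(sigma_tg=0.0, mu_tg=0.0, seed=0)
    tr = sc.encode_trial(5.0, prog, quiet_device, IST, 0)
    assert tr.spikes.all()


def test_zero_stimulus_rarely_spikes(device):
    prog = sc.rate_program(seed=3, n_trials=64)
    frac = np.mean([
        sc.encode_trial(0.0, prog, device, IST, t).spikes.mean() for t in range(64)
    ])
    assert frac < 0.05


def test_timing_deactivates_after_first_spike(device):
    prog = sc.timing_program(device, IST, seed=5)
    tr = sc.encode_trial(5.0, prog, device, IST, 0)
    assert tr.spikes.sum() == 1
    first = np.flatnonzero(tr.spikes)[0]
    assert not tr.active_mask[first + 1 :].any()
    assert np.all(tr.currents[~tr.active_mask] == 0)
    assert np.all(tr.amplitudes[~tr.active_mask] == 0)


def test_encode_trial_reproducible(device):
    prog = sc.rate_program(seed=12)
    a = sc.encode_trial(2.5, prog, device, IST, 1)
    b = sc.encode_trial(2.5, prog, device, IST, 1)
    assert np.array_equal(a.spikes, b.spikes)
    assert np.array_equal(a.currents, b.currents)


# ---------------------------------------------------------------------------
# statistics

@pytest.mark.parametrize(
    "spikes,expected",
    [
        (np.ones(32), 100.0),                      # every 10 ms pulse spikes
        (np.zeros(32), 0.0),                       # silent trial
        (np.arange(32) % 2 == 0, 50.0),            # every other pulse
        ([0] * 31 + [1], 1 / 0.32),                # single spike: count fallback
    ],
)
def test_rate_estimator(spikes, expected):
    assert sc.rate_from_spikes(_train(spikes)) == pytest.approx(expected)


def test_count_statistic():
    assert sc.count_from_spikes(_train(np.ones(32))) == 32
    assert sc.count_from_spikes(_train(np.zeros(32))) == 0


def test_noise_free_count_crossing_is_exact(quiet_device):
    """Without noise the count equals the number of ramp thresholds below v."""
    prog = sc.count_program(quiet_device, IST, sigma_tg=0.0)
    ramp = np.linspace(prog.ramp_start, prog.ramp_end, prog.n_pulses)
    thresholds = sc.spiking_threshold(ramp, IST, quiet_device)
    for v in (1.0, 2.5, 4.0):
        tr = sc.encode_trial(v, prog, quiet_device, IST, 0)
        assert sc.count_from_spikes(tr) == int(np.sum(thresholds < v))


def test_timing_statistic_and_sentinel():
    assert sc.timing_from_spikes(_train([1] + [0] * 31)) == 1
    assert sc.timing_from_spikes(_train(np.zeros(32))) == 33


def test_noise_free_timing_decreases_with_stimulus(quiet_device):
    prog = sc.timing_program(quiet_device, IST, sigma_tg=0.0)
    t_first = [
        sc.timing_from_spikes(sc.encode_trial(v, prog, quiet_device, IST, 0))
        for v in (1.0, 2.5, 4.0)
    ]
    assert t_first[0] > t_first[1] > t_first[2]


# ---------------------------------------------------------------------------
# closed-form transfer function

def test_probability_half_at_threshold(quiet_device):
    prog = sc.rate_program()
    v_half = sc.spiking_threshold(prog.mu_tg, IST, quiet_device)
    assert sc.spike_probability(v_half, prog, quiet_device, IST) == pytest.approx(0.5)


def test_probability_degenerates_to_step(quiet_device):
    prog = sc.rate_program(sigma_tg=0.0)
    v_half = sc.spiking_threshold(prog.mu_tg, IST, quiet_device)
    assert sc.spike_probability(v_half - 0.1, prog, quiet_device, IST) == 0.0
    assert sc.spike_probability(v_half + 0.1, prog, quiet_device, IST) == 1.0


def test_monte_carlo_matches_gaussian_cdf(quiet_device):
    """Noise-free spike fractions sit within 3 binomial SE of the closed form."""
    n_pulses = 10_000
    prog = sc.rate_program(n_pulses=n_pulses, n_trials=1, seed=21)
    for v in LEVELS:
        p = sc.spike_probability(v, prog, quiet_device, IST)
        frac = sc.encode_trial(v, prog, quiet_device, IST, 0).spikes.mean()
        se = np.sqrt(max(p * (1 - p), 1e-9) / n_pulses)
        assert abs(frac - p) <= 3 * se + 1e-12


def test_pulse_probabilities_cover_all_modes(quiet_device):
    prog = sc.count_program(quiet_device, IST)
    p = sc.pulse_spike_probabilities(2.5, prog, quiet_device, IST)
    assert p.shape == (32,)
    # the count ramp raises the threshold over the trial: early pulses spike
    assert np.all(np.diff(p) <= 0)
    assert p[0] > 0.99 and p[-1] < 0.01


# ---------------------------------------------------------------------------
# energy

def test_energy_hand_oracle():
    """Single pulse at -2.5 V, 500 pA: 0.5*1fF*6.25 + 5e-10*1*0.01 = 5.003 pJ."""
    dev = DeviceParams(
        cap_ratio=2.2, v_on=-2.3, ss=0.3, i_ref=1e-10, i_floor=1e-13, i_sat=2e-9,
        c_tg=1e-15, v_ds=1.0, readout_noise_frac=0.0,
    )
    tr = SpikeTrain(
        spikes=np.array([True]), currents=np.array([5e-10]),
        amplitudes=np.array([-2.5]), active_mask=np.array([True]), t_p=0.010,
    )
    assert sc.encoding_energy([tr], dev) == pytest.approx(5.003125e-12, rel=1e-9)


def test_energy_floor(device):
    """Zero-amplitude pulses at the leakage floor average to i_floor*v_ds*t_p."""
    n = 32
    tr = SpikeTrain(
        spikes=np.zeros(n, dtype=bool), currents=np.full(n, device.i_floor),
        amplitudes=np.zeros(n), active_mask=np.ones(n, dtype=bool), t_p=0.010,
    )
    assert sc.encoding_energy([tr], device) == pytest.approx(
        device.i_floor * device.v_ds * 0.010
    )


def test_per_spike_normalization(device):
    n = 4
    tr = SpikeTrain(
        spikes=np.array([True, False, False, False]),
        currents=np.full(n, 1e-9), amplitudes=np.zeros(n),
        active_mask=np.ones(n, dtype=bool), t_p=0.010,
    )
    per_window = sc.encoding_energy([tr], device)
    per_spike = sc.encoding_energy([tr], device, per_spike=True)
    assert per_spike == pytest.approx(per_window * n)
    silent = _train(np.zeros(n))
    assert np.isnan(sc.encoding_energy([silent], device, per_spike=True))


# ---------------------------------------------------------------------------
# sweeps

def test_sweep_deterministic_and_shaped(device):
    prog = sc.rate_program(seed=8)
    r1 = sc.run_encoding_sweep(LEVELS, prog, device, IST)
    r2 = sc.run_encoding_sweep(LEVELS, prog, device, IST)
    assert len(r1) == len(LEVELS)
    for a, b in zip(r1, r2):
        assert a.statistic == b.statistic
        assert a.energy_per_spike == b.energy_per_spike
        assert a.statistic_std >= 0
    tab = sc.sweep_table(r1)
    assert list(tab.columns) == ["level", "statistic", "statistic_std", "energy_per_spike"]


def test_half_preset_halves_the_count_range(quiet_device):
    """The half-range ramp caps the noise-free count near n_pulses/2."""
    full = sc.count_program(quiet_device, IST, sigma_tg=0.0, preset="full")
    half = sc.count_program(quiet_device, IST, sigma_tg=0.0, preset="half")
    c_full = sc.count_from_spikes(sc.encode_trial(5.0, full, quiet_device, IST, 0))
    c_half = sc.count_from_spikes(sc.encode_trial(5.0, half, quiet_device, IST, 0))
    assert c_half <= 17
    assert c_full >= 2 * c_half - 4
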