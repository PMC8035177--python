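"""Stochastic spike encoding: pulse programs, spike trains, statistics, energy.

The encoder converts an analog stimulus ``v_psv`` into a binary spike train by
applying a sequence of sampling-gate pulses and thresholding the resulting
drain current against ``i_st``. Three neural coding schemes are implemented:

``rate``
    Pulse amplitudes are i.i.d. Gaussian ``N(mu_tg, sigma_tg^2)``; the
    statistic is the mean firing rate (inverse mean interspike interval).
    Because a pulse spikes exactly when its amplitude exceeds the
    stimulus-dependent sampling-gate threshold, the transfer function is the
    Gaussian CDF (:func:`spike_probability`).
``count``
    Amplitudes ramp to larger magnitudes over the trial with additive
    Gaussian noise; the statistic is the spike count in the window.
``timing``
    Mirror-image ramp (magnitudes shrink over the trial); the first spike
    deactivates sampling for the rest of the trial, and the statistic is the
    1-based index of that first spike (time to first spike).

Energy accounting per trial averages, over the ``N`` pulses of the window,
the sampling-gate charging energy plus the drain dissipation of each active
pulse:

    E_en = (1/N) * sum_i ( 1/2 * C_TG * V_TG,i^2  +  I_PSC,i * V_DS * t_p ).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .device import DeviceParams, psc_current, sampling_gate_threshold, spiking_threshold
from .workbench import substream

__all__ = [
    "MODES",
    "PulseProgram",
    "SpikeTrain",
    "EncodingResult",
    "rate_program",
    "count_program",
    "timing_program",
    "ramp_for_stimulus_range",
    "sample_pulse_train",
    "encode_trial",
    "encode_level",
    "rate_from_spikes",
    "count_from_spikes",
    "timing_from_spikes",
    "spike_probability",
    "pulse_spike_probabilities",
    "encoding_energy",
    "run_encoding_sweep",
    "sweep_table",
]

MODES = ("rate", "count", "timing")

#: sentinel energy reported when a per-spike normalization finds no spikes
NO_SPIKE_ENERGY = float("nan")


@dataclass(frozen=True)
class PulseProgram:
    """Sampling-gate waveform specification.

    ``mu_tg``/``sigma_tg`` parameterize the Gaussian of rate mode;
    ``ramp_start``/``ramp_end`` the deterministic ramp of count/timing modes
    (with ``sigma_tg`` the added zero-mean noise). Defaults follow the
    reference experiment: 32 pulses of 10 ms, 16 trials.
    """

    mode: str = "rate"
    mu_tg: float = -2.5
    sigma_tg: float = 0.8
    ramp_start: float = 0.0
    ramp_end: float = 0.0
    n_pulses: int = 32
    t_p: float = 0.010
    n_trials: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.sigma_tg < 0:
            raise ValueError("sigma_tg must be >= 0")
        if self.n_pulses < 1 or self.n_trials < 1:
            raise ValueError("n_pulses and n_trials must be >= 1")
        if self.t_p <= 0:
            raise ValueError("t_p must be positive")
        if self.mode == "count" and abs(self.ramp_end) < abs(self.ramp_start):
            raise ValueError("count mode requires |ramp_end| >= |ramp_start|")
        if self.mode == "timing" and abs(self.ramp_end) > abs(self.ramp_start):
            raise ValueError("timing mode requires |ramp_end| <= |ramp_start|")


@dataclass(frozen=True)
class SpikeTrain:
    """One trial's binary spike record with per-pulse currents/amplitudes.

    Inactive pulses (after the first spike in timing mode) carry zero current
    and zero amplitude so they contribute nothing to the energy sum.
    """

    spikes: np.ndarray        # bool, length n_pulses
    currents: np.ndarray      # amperes per pulse (0 where inactive)
    amplitudes: np.ndarray    # volts per pulse actually applied (0 where inactive)
    active_mask: np.ndarray   # bool per pulse
    t_p: float

    def __post_init__(self):
        n = len(self.spikes)
        if not (len(self.currents) == len(self.amplitudes) == len(self.active_mask) == n):
            raise ValueError("all per-pulse sequences must have equal length")

    @property
    def n_pulses(self) -> int:
        return len(self.spikes)


@dataclass
class EncodingResult:
    """Per-level summary over trials."""

    level: float
    trains: list
    statistic: float
    statistic_std: float
    energy_per_spike: float   # Eq.-style window-normalized energy, joules


# ---------------------------------------------------------------------------
# pulse programs

def rate_program(mu_tg: float = -2.5, sigma_tg: float = 0.8, **kw) -> PulseProgram:
    """Rate-encoding program at the reference operating point."""
    return PulseProgram(mode="rate", mu_tg=mu_tg, sigma_tg=sigma_tg, **kw)


def ramp_for_stimulus_range(
    device: DeviceParams,
    i_st: float,
    v_lo: float = 0.0,
    v_hi: float = 5.0,
    sigma_tg: float = 0.2,
    preset: str = "full",
    margin_sigma: tuple = (1.0, 1.0),
):
    """Sampling-gate ramp endpoints whose thresholds sweep a stimulus range.

    ``full`` spans [v_lo, v_hi] plus ``margin_sigma`` multiples of the pulse
    noise at the (low, high) ends, so a count trial can accumulate up to all
    ``n_pulses`` spikes. ``half`` spans [v_lo, 2*v_hi - v_lo], so only half
    the pulses can cross within the stimulus window — the calibration implied
    by the reference experiment's statement that the maximum count is half
    the pulse budget.
    """
    if preset not in ("full", "half"):
        raise ValueError("preset must be 'full' or 'half'")
    if preset == "half":
        v_hi = 2 * v_hi - v_lo
    m_lo, m_hi = margin_sigma
    start = float(sampling_gate_threshold(v_lo, i_st, device)) + m_lo * sigma_tg
    end = float(sampling_gate_threshold(v_hi, i_st, device)) - m_hi * sigma_tg
    return start, end


def count_program(
    device: DeviceParams, i_st: float, sigma_tg: float = 0.2, preset: str = "full", **kw
) -> PulseProgram:
    start, end = ramp_for_stimulus_range(device, i_st, sigma_tg=sigma_tg, preset=preset)
    return PulseProgram(mode="count", sigma_tg=sigma_tg, ramp_start=start, ramp_end=end, **kw)


def timing_program(
    device: DeviceParams, i_st: float, sigma_tg: float = 0.2, preset: str = "full", **kw
) -> PulseProgram:
    """Mirror image of the count ramp: magnitudes shrink over the trial.

    The bottom of the window gets a deeper (3 sigma) margin so that even the
    weakest stimulus reliably elicits a spike late in the trial and
    deactivates the encoder, as in the reference experiment where the mean
    first-spike index at zero stimulus sits near the end of the window.
    """
    start, end = ramp_for_stimulus_range(
        device, i_st, sigma_tg=sigma_tg, preset=preset, margin_sigma=(3.0, 1.0)
    )
    return PulseProgram(mode="timing", sigma_tg=sigma_tg, ramp_start=end, ramp_end=start, **kw)


# ---------------------------------------------------------------------------
# sampling and encoding

def _ramp(program: PulseProgram) -> np.ndarray:
    return np.linspace(program.ramp_start, program.ramp_end, program.n_pulses)


def sample_pulse_train(program: PulseProgram, trial_index: int, key: tuple = ()) -> np.ndarray:
    """Sampling-gate amplitudes for one trial; deterministic given (seed, key, trial)."""
    if not (0 <= trial_index < program.n_trials):
        raise ValueError(f"trial_index {trial_index} outside 0..{program.n_trials - 1}")
    rng = substream(program.seed, "pulses", *key, trial_index)
    if program.mode == "rate":
        return rng.normal(program.mu_tg, program.sigma_tg, program.n_pulses)
    base = _ramp(program)
    if program.sigma_tg == 0:
        return base
    return base + rng.normal(0.0, program.sigma_tg, program.n_pulses)


def encode_trial(
    v_psv: float,
    program: PulseProgram,
    device: DeviceParams,
    i_st: float,
    trial_index: int,
    key: tuple = (),
) -> SpikeTrain:
    """Encode one stimulus level for one trial.

    Each active pulse evaluates the (noisy) drain current; a spike is
    registered iff the current strictly exceeds ``i_st``. In timing mode the
    first spike deactivates the remaining pulses, which then carry zero
    current and amplitude.
    """
    if not np.isfinite(v_psv):
        raise ValueError("v_psv must be finite")
    amps = sample_pulse_train(program, trial_index, key=key)
    noise_rng = (
        substream(program.seed, "readout", *key, trial_index)
        if device.readout_noise_frac > 0
        else None
    )
    currents = np.asarray(
        psc_current(v_psv, amps, device, rng=noise_rng), dtype=float
    ).reshape(program.n_pulses)
    spikes = currents > i_st
    active = np.ones(program.n_pulses, dtype=bool)
    if program.mode == "timing":
        hits = np.flatnonzero(spikes)
        if hits.size:
            first = hits[0]
            active[first + 1 :] = False
            spikes = spikes & active
    amps = np.where(active, amps, 0.0)
    currents = np.where(active, currents, 0.0)
    return SpikeTrain(
        spikes=spikes, currents=currents, amplitudes=amps, active_mask=active, t_p=program.t_p
    )


# ---------------------------------------------------------------------------
# summary statistics

def rate_from_spikes(train: SpikeTrain) -> float:
    """Mean firing rate in Hz: inverse mean interspike interval.

    Intervals are measured center-to-center between consecutive spike slots.
    Trials with fewer than two spikes fall back to
    ``spike_count / (n_pulses * t_p)`` so the estimator stays defined (0 Hz
    for silent trials).
    """
    idx = np.flatnonzero(train.spikes)
    if idx.size >= 2:
        return 1.0 / (np.diff(idx).mean() * train.t_p)
    return idx.size / (train.n_pulses * train.t_p)


def count_from_spikes(train: SpikeTrain) -> int:
    return int(np.count_nonzero(train.spikes))


def timing_from_spikes(train: SpikeTrain) -> int:
    """1-based index of the first spike; ``n_pulses + 1`` if none occurred."""
    idx = np.flatnonzero(train.spikes)
    if idx.size:
        return int(idx[0]) + 1
    return train.n_pulses + 1


_STATISTICS = {
    "rate": rate_from_spikes,
    "count": count_from_spikes,
    "timing": timing_from_spikes,
}


# ---------------------------------------------------------------------------
# closed forms

def spike_probability(v_psv, program: PulseProgram, device: DeviceParams, i_st: float):
    """Closed-form per-pulse spike probability for rate mode.

    A pulse spikes exactly when its amplitude exceeds the sampling-gate
    threshold v_tg* for this stimulus, so the noise-free transfer function is
    the Gaussian CDF ``Phi((mu_tg - v_tg*) / sigma_tg)``. With
    ``sigma_tg = 0`` the degenerate step function is returned (0.5 exactly at
    threshold).
    """
    if program.mode != "rate":
        raise ValueError("spike_probability is defined for rate mode")
    v_star = sampling_gate_threshold(v_psv, i_st, device)
    v_star = np.asarray(v_star, dtype=float)
    if program.sigma_tg == 0:
        out = np.where(
            program.mu_tg > v_star, 1.0, np.where(program.mu_tg < v_star, 0.0, 0.5)
        )
    else:
        out = ndtr((program.mu_tg - v_star) / program.sigma_tg)
    if out.ndim == 0:
        return float(out)
    return out


def pulse_spike_probabilities(
    v_psv: float, program: PulseProgram, device: DeviceParams, i_st: float
) -> np.ndarray:
    """Noise-free per-pulse spike probabilities for any mode (length n_pulses).

    In timing mode these are marginal probabilities ignoring deactivation
    (i.e. the probability that pulse j would cross threshold if reached).
    """
    v_star = float(sampling_gate_threshold(v_psv, i_st, device))
    means = (
        np.full(program.n_pulses, program.mu_tg) if program.mode == "rate" else _ramp(program)
    )
    if program.sigma_tg == 0:
        return np.where(means > v_star, 1.0, np.where(means < v_star, 0.0, 0.5))
    return ndtr((means - v_star) / program.sigma_tg)


# ---------------------------------------------------------------------------
# energy

def encoding_energy(trains, device: DeviceParams, per_spike: bool = False) -> float:
    """Mean encoding energy per trial (joules) following the window average.

    Sums ``1/2 * C_TG * V_TG,i^2 + I_PSC,i * V_DS * t_p`` over active pulses
    and divides by the number of pulses in the window (the normalization the
    energy expression prints). With ``per_spike=True`` the sum is divided by
    the spike count instead; trials without spikes yield NaN and are excluded
    from the mean (all-silent input returns NaN).
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    if not trains:
        raise ValueError("need at least one spike train")
    vals = []
    for tr in trains:
        if tr.n_pulses < 1:
            raise ValueError("spike train must contain at least one pulse")
        e = np.sum(
            np.where(
                tr.active_mask,
                0.5 * device.c_tg * tr.amplitudes**2 + tr.currents * device.v_ds * tr.t_p,
                0.0,
            )
        )
        if per_spike:
            n_spk = np.count_nonzero(tr.spikes)
            vals.append(e / n_spk if n_spk else NO_SPIKE_ENERGY)
        else:
            vals.append(e / tr.n_pulses)
    vals = np.asarray(vals, dtype=float)
    if np.all(np.isnan(vals)):
        return NO_SPIKE_ENERGY
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# sweeps

def encode_level(
    v_psv: float,
    program: PulseProgram,
    device: DeviceParams,
    i_st: float,
    key: tuple = (),
    per_spike_energy: bool = False,
) -> EncodingResult:
    """Encode all trials of one stimulus level and summarize."""
    stat_fn = _STATISTICS[program.mode]
    trains = [
        encode_trial(v_psv, program, device, i_st, t, key=key)
        for t in range(program.n_trials)
    ]
    stats = np.array([stat_fn(tr) for tr in trains], dtype=float)
    return EncodingResult(
        level=float(v_psv),
        trains=trains,
        statistic=float(stats.mean()),
        statistic_std=float(stats.std(ddof=0)),
        energy_per_spike=encoding_energy(trains, device, per_spike=per_spike_energy),
    )


def run_encoding_sweep(
    levels,
    program: PulseProgram,
    device: DeviceParams,
    i_st: float,
    per_spike_energy: bool = False,
):
    """One :class:`EncodingResult` per stimulus level; deterministic given seed.

    Each level uses level-indexed substreams so that adding or removing
    levels never perturbs the others.
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if levels.size == 0:
        raise ValueError("levels must be nonempty")
    return [
        encode_level(
            v, program, device, i_st, key=("level", j), per_spike_energy=per_spike_energy
        )
        for j, v in enumerate(levels)
    ]


def sweep_table(results) -> pd.DataFrame:
    """Tabulate a sweep: level, mean statistic, across-trial std, energy."""
    return pd.DataFrame(
        {
            "level": [r.level for r in results],
            "statistic": [r.statistic for r in results],
            "statistic_std": [r.statistic_std for r in results],
            "energy_per_spike": [r.energy_per_spike for r in results],
        }
    )
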