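"""Generative model of closed-loop intermittent-stimulation EEG sessions.

A session is a continuous multi-channel recording containing 10 alternating
eyes-open / eyes-closed blocks of 50 trials each (pre / stimulation / post
intervals plus a jittered inter-trial interval), with a single alpha-band
source projected through a posterior spatial pattern on top of 1/f^beta
background noise.  An optional transient post-stimulation suppression of the
alpha envelope provides a ground-truth effect with a closed-form expected
percent modulation (:func:`expected_post_modulation`) against which the
analysis chain can be validated.

Conventions: EEG in microvolts, sample indices 0-based, stimulation interval
half-open ``[stim_onset, stim_offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .montage import ChannelLayout, build_montage

__all__ = [
    "SimulationConfig",
    "EEGRecording",
    "GroundTruth",
    "SubjectSession",
    "draw_itis",
    "sample_schedule",
    "validate_events",
    "simulate_subject",
    "simulate_cohort",
    "inject_stim_artifact",
    "expected_post_modulation",
]

EVENT_COLUMNS = ("trial_id", "block", "stim_onset", "stim_offset", "state", "stimulation")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated cohort; defaults mirror the experimental design."""

    n_subjects: int = 20
    srate: float = 500.0
    n_blocks: int = 10
    trials_per_block: int = 50
    pre_dur: float = 1.0
    stim_dur: float = 1.0
    post_dur: float = 1.0
    iti_range: tuple[float, float] = (333.0, 666.0)  # ms
    iaf_range: tuple[float, float] = (8.0, 13.0)  # Hz
    alpha_amp_ec: float = 20.0  # uV
    alpha_amp_eo: float = 8.0  # uV
    suppression_depth: float = 0.0  # fraction of envelope removed at offset
    suppression_tau: float = 150.0  # ms
    noise_exponent: float = 1.0  # 1/f^beta
    noise_amp: float = 5.0  # uV RMS per channel
    noise_spatial_r: float = 0.4  # spatial correlation radius (0 = independent)
    env_sigma: float = 0.2  # log-normal envelope fluctuation
    artifact_gain: float = 0.0
    break_dur: float = 2.0  # s between blocks
    rest_dur: float = 60.0  # s per resting-state segment
    start_pad: float = 1.0  # s before the first trial
    first_state: str = "EO"
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.pre_dur, self.stim_dur, self.post_dur) <= 0:
            raise ValueError("pre/stim/post durations must be positive")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one block and one trial")
        if self.trials_per_block % 2:
            raise ValueError(
                "trials_per_block must be even to split in-/anti-phase 50/50"
            )
        if not 0 <= self.suppression_depth < 1:
            raise ValueError("suppression_depth must be in [0, 1)")
        if self.suppression_tau <= 0:
            raise ValueError("suppression_tau must be positive")
        if not self.alpha_amp_ec > self.alpha_amp_eo > 0:
            raise ValueError("require alpha_amp_ec > alpha_amp_eo > 0")
        lo, hi = self.iti_range
        if not 0 < lo <= hi:
            raise ValueError("iti_range must satisfy 0 < lo <= hi")
        flo, fhi = self.iaf_range
        if not 0 < flo <= fhi < self.srate / 2:
            raise ValueError("iaf_range must lie in (0, Nyquist)")
        if self.first_state not in ("EO", "EC"):
            raise ValueError("first_state must be 'EO' or 'EC'")
        if self.noise_amp < 0 or self.env_sigma < 0 or self.artifact_gain < 0:
            raise ValueError("noise_amp, env_sigma, artifact_gain must be >= 0")
        if self.noise_spatial_r < 0:
            raise ValueError("noise_spatial_r must be >= 0")


@dataclass
class EEGRecording:
    """Continuous multi-channel voltage data (uV)."""

    data: np.ndarray  # (n_channels, n_samples)
    srate: float
    layout: ChannelLayout

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.layout):
            raise ValueError("data must be (n_channels, n_samples) matching layout")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.layout.index(label)]


@dataclass
class GroundTruth:
    """Hidden parameters of one simulated subject, for recovery tests."""

    iaf: float
    source_pattern: np.ndarray  # (n_channels,), unit norm
    suppression_depth: float
    suppression_tau: float  # ms
    itis_ms: np.ndarray
    phase0: float  # cosine phase of the alpha source at sample 0

    def source_phase_at(self, sample: int, srate: float) -> float:
        """Instantaneous cosine phase of the alpha source at *sample*."""
        return float(
            np.angle(np.exp(1j * (self.phase0 + 2 * np.pi * self.iaf * sample / srate)))
        )


@dataclass
class SubjectSession:
    """One simulated subject: session recording, schedule, truth and rest data."""

    recording: EEGRecording
    events: pd.DataFrame
    ground_truth: GroundTruth
    rest_ec: EEGRecording | None = None
    rest_eo: EEGRecording | None = None
    subject_id: int = 0

    def __iter__(self) -> Iterator:
        return iter((self.recording, self.events, self.ground_truth))


def draw_itis(n: int, iti_range: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Draw *n* inter-trial intervals (ms), continuous uniform on ``iti_range``."""
    lo, hi = iti_range
    return rng.uniform(lo, hi, size=n)


def sample_schedule(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample a full session schedule as an event table.

    Blocks alternate EO/EC starting with ``config.first_state``; within each
    block, half the trials are in-phase and half anti-phase in shuffled order.
    Returns a data frame with columns ``trial_id, block, stim_onset,
    stim_offset, state, stimulation`` (sample indices, half-open intervals)
    plus the realized ITIs in a ``iti_ms`` column.
    """
    srate = config.srate
    pre = int(round(config.pre_dur * srate))
    stim = int(round(config.stim_dur * srate))
    post = int(round(config.post_dur * srate))
    brk = int(round(config.break_dur * srate))
    n_trials = config.n_blocks * config.trials_per_block

    itis_ms = draw_itis(n_trials, config.iti_range, rng)
    iti_samples = np.round(itis_ms / 1000.0 * srate).astype(int)

    states = ("EO", "EC") if config.first_state == "EO" else ("EC", "EO")
    rows = []
    cursor = int(round(config.start_pad * srate))
    trial_id = 0
    for block in range(config.n_blocks):
        state = states[block % 2]
        half = config.trials_per_block // 2
        stim_labels = np.array(["in"] * half + ["anti"] * half, dtype=object)
        rng.shuffle(stim_labels)
        for lab in stim_labels:
            onset = cursor + pre
            offset = onset + stim
            rows.append((trial_id, block, onset, offset, state, lab,
                         itis_ms[trial_id]))
            cursor = offset + post + iti_samples[trial_id]
            trial_id += 1
        cursor += brk
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS) + ["iti_ms"])


def validate_events(events: pd.DataFrame, n_samples: int | None = None) -> None:
    """Check event-table invariants; raise ``ValueError`` on violation."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    onsets = events["stim_onset"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("stim onsets must be strictly increasing")
    if np.any(events["stim_offset"].to_numpy() <= onsets):
        raise ValueError("stim_offset must exceed stim_onset")
    bad_state = set(events["state"]) - {"EO", "EC"}
    bad_stim = set(events["stimulation"]) - {"in", "anti"}
    if bad_state or bad_stim:
        raise ValueError(f"unknown labels: {bad_state | bad_stim}")
    for block, grp in events.groupby("block"):
        n_in = (grp["stimulation"] == "in").sum()
        if n_in * 2 != len(grp):
            raise ValueError(f"block {block}: in/anti counts unbalanced")
    if n_samples is not None and events["stim_offset"].max() > n_samples:
        raise ValueError("event beyond end of recording")


def _pink_noise(n_channels: int, n_samples: int, beta: float,
                rng: np.random.Generator) -> np.ndarray:
    """Independent per-channel 1/f^beta noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    if beta == 0:
        return white.astype(float)
    n_fast = sp_fft.next_fast_len(n_samples)  # pad: FFT cost, not statistics
    spec = sp_fft.rfft(white, n=n_fast, axis=1)
    freqs = sp_fft.rfftfreq(n_fast).astype(np.float32)
    scale = np.empty_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    scale[0] = 0.0  # no DC
    out = sp_fft.irfft(spec * scale, n=n_fast, axis=1)[:, :n_samples]
    out = out.astype(float)
    out /= out.std(axis=1, keepdims=True)
    return out


def _spatial_mixer(layout: ChannelLayout, radius: float) -> np.ndarray | None:
    """Row-unit-norm Gaussian spatial mixing kernel (volume-conduction stand-in).

    Correlated background noise makes the channel covariance effectively
    low-rank, as in real EEG; ``radius = 0`` disables mixing.
    """
    if radius == 0:
        return None
    pos = layout.positions
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    G = np.exp(-d2 / (2 * radius**2))
    return G / np.linalg.norm(G, axis=1, keepdims=True)


def _background_noise(layout: ChannelLayout, n_samples: int,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    noise = _pink_noise(len(layout), n_samples, config.noise_exponent, rng)
    G = _spatial_mixer(layout, config.noise_spatial_r)
    return noise if G is None else G @ noise


def _slow_envelope(n_samples: int, srate: float, sigma: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Log-normal slowly fluctuating amplitude envelope with mean ~1."""
    if sigma == 0:
        return np.ones(n_samples)
    z = rng.standard_normal(n_samples)
    sos = signal.butter(2, 0.5, btype="low", fs=srate, output="sos")
    z = signal.sosfiltfilt(sos, z)
    z /= z.std() or 1.0
    return np.exp(sigma * z - sigma**2 / 2.0)


def _source_pattern(layout: ChannelLayout, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm mixing pattern: posterior Gaussian bump with subject jitter."""
    pos = layout.positions
    center = np.array([rng.normal(0.0, 0.12), -0.85 + rng.normal(0.0, 0.05)])
    d2 = np.sum((pos - center) ** 2, axis=1)
    pattern = np.exp(-d2 / (2 * 0.35**2))
    pattern += rng.normal(0.0, 0.02, size=pattern.shape)
    return pattern / np.linalg.norm(pattern)


def _alpha_source(n_samples: int, config: SimulationConfig, iaf: float,
                  phase0: float, amp: np.ndarray | float,
                  rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_samples) / config.srate
    env = _slow_envelope(n_samples, config.srate, config.env_sigma, rng)
    return amp * env * np.cos(2 * np.pi * iaf * t + phase0)


def _suppression_multiplier(n_samples: int, offsets: np.ndarray,
                            config: SimulationConfig) -> np.ndarray:
    """Envelope factor (1 - depth*exp(-t/tau)) applied after each stimulation."""
    m = np.ones(n_samples)
    depth, tau_s = config.suppression_depth, config.suppression_tau / 1000.0
    if depth == 0:
        return m
    horizon = min(n_samples, int(round(10 * tau_s * config.srate)))
    decay = 1.0 - depth * np.exp(-np.arange(horizon) / (tau_s * config.srate))
    for off in offsets:
        stop = min(n_samples, off + horizon)
        m[off:stop] *= decay[: stop - off]
    return m


def simulate_subject(config: SimulationConfig, subject_id: int,
                     rng: np.random.Generator) -> SubjectSession:
    """Simulate one subject's full session plus resting-state segments.

    The recording is ``source_pattern x alpha_source + noise`` where the alpha
    amplitude is state-dependent (EC > EO) and transiently suppressed after
    every stimulation offset, identically for in- and anti-phase trials.
    """
    layout = build_montage()
    iaf = float(rng.uniform(*config.iaf_range))
    phase0 = float(rng.uniform(-np.pi, np.pi))
    pattern = _source_pattern(layout, rng)
    events = sample_schedule(config, rng)

    srate = config.srate
    n_samples = int(events["stim_offset"].max()
                    + round((config.post_dur + 1.0) * srate))

    # per-sample state amplitude (block-wise step function, EO outside blocks)
    amp = np.full(n_samples, config.alpha_amp_eo)
    pre = int(round(config.pre_dur * srate))
    post = int(round(config.post_dur * srate))
    for _, grp in events.groupby("block"):
        if grp["state"].iloc[0] == "EC":
            b0 = int(grp["stim_onset"].iloc[0]) - pre
            b1 = int(grp["stim_offset"].iloc[-1]) + post
            amp[b0:b1] = config.alpha_amp_ec

    source = _alpha_source(n_samples, config, iaf, phase0, amp, rng)
    source *= _suppression_multiplier(
        n_samples, events["stim_offset"].to_numpy(int), config)

    data = pattern[:, None] * source
    if config.noise_amp > 0:
        data = data + config.noise_amp * _background_noise(
            layout, n_samples, config, rng)
    recording = EEGRecording(data=data, srate=srate, layout=layout)

    rest_ec = rest_eo = None
    if config.rest_dur > 0:
        n_rest = int(round(config.rest_dur * srate))
        for state in ("EC", "EO"):
            a = config.alpha_amp_ec if state == "EC" else config.alpha_amp_eo
            src = _alpha_source(n_rest, config, iaf,
                                float(rng.uniform(-np.pi, np.pi)), a, rng)
            d = pattern[:, None] * src
            if config.noise_amp > 0:
                d = d + config.noise_amp * _background_noise(
                    layout, n_rest, config, rng)
            seg = EEGRecording(data=d, srate=srate, layout=layout)
            if state == "EC":
                rest_ec = seg
            else:
                rest_eo = seg

    truth = GroundTruth(
        iaf=iaf,
        source_pattern=pattern,
        suppression_depth=config.suppression_depth,
        suppression_tau=config.suppression_tau,
        itis_ms=events["iti_ms"].to_numpy(),
        phase0=phase0,
    )
    return SubjectSession(recording=recording, events=events, ground_truth=truth,
                          rest_ec=rest_ec, rest_eo=rest_eo, subject_id=subject_id)


def simulate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> list[SubjectSession]:
    """Simulate ``config.n_subjects`` independent subjects."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [simulate_subject(config, sid, sub_rng)
            for sid, sub_rng in enumerate(rng.spawn(config.n_subjects))]


def inject_stim_artifact(recording: EEGRecording, events: pd.DataFrame,
                         waveforms: np.ndarray, artifact_gain: float) -> EEGRecording:
    """Add a huge stimulation artifact strictly inside each stimulation interval.

    ``waveforms`` is (n_trials, stim_samples) in mA.  ``artifact_gain`` is the
    amplitude of the artifact relative to the neural signal: the artifact
    added to channel c is ``artifact_gain * rms(recording) * weight_c *
    waveform``, with weights increasing linearly toward posterior channels as
    a stand-in for the stimulation electrodes' field.  Samples outside every
    ``[stim_onset, stim_offset)`` interval are bit-identical to the input.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if len(waveforms) != len(events):
        raise ValueError("need exactly one waveform per trial")
    out = recording.data.copy()
    y = recording.layout.positions[:, 1]
    weight = 0.2 + 0.8 * (y.max() - y) / (y.max() - y.min())
    scale = artifact_gain * np.sqrt(np.mean(recording.data**2))
    for wave, (_, row) in zip(waveforms, events.iterrows()):
        on, off = int(row["stim_onset"]), int(row["stim_offset"])
        if len(wave) != off - on:
            raise ValueError(
                f"trial {row['trial_id']}: waveform length {len(wave)} != "
                f"stimulation interval {off - on}")
        out[:, on:off] += scale * weight[:, None] * wave[None, :]
    return replace(recording, data=out)


def expected_post_modulation(depth: float, tau_ms: float,
                             window_ms: tuple[float, float] = (100.0, 600.0)) -> float:
    """Closed-form expected percent power modulation in a post window.

    Integrates the squared suppression envelope ``(1 - depth*exp(-t/tau))^2``
    over ``window_ms`` (relative to stimulation offset) and returns
    ``100 * (mean - 1)``; the independent oracle for the simulator's effect.
    """
    t0, t1 = (w / 1000.0 for w in window_ms)
    tau = tau_ms / 1000.0
    span = t1 - t0
    m1 = tau / span * (np.exp(-t0 / tau) - np.exp(-t1 / tau))
    m2 = tau / (2 * span) * (np.exp(-2 * t0 / tau) - np.exp(-2 * t1 / tau))
    return 100.0 * ((1.0 - 2 * depth * m1 + depth**2 * m2) - 1.0)
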