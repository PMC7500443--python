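"""Online side of the experiment, simulated offline.

Covers individual-alpha-frequency (IAF) estimation from resting EEG,
instantaneous phase estimation of a short alpha segment, latency-compensated
phase forecasting, and synthesis of the 1-s in-/anti-phase sinusoidal
stimulation waveform.

Phase convention: cosine phase, 0 rad at the signal maximum; all returned
phases are wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import EEGRecording, GroundTruth

__all__ = [
    "IAFEstimate",
    "StimWaveform",
    "wrap_phase",
    "estimate_iaf",
    "estimate_phase",
    "forecast_phase",
    "make_stim_waveform",
    "run_closed_loop_session",
]

SEGMENT_DUR = 0.25  # s of data used for phase estimation


@dataclass(frozen=True)
class IAFEstimate:
    iaf: float
    ec_peak_power: float
    eo_peak_power: float
    search_band: tuple[float, float]


@dataclass
class StimWaveform:
    """Sinusoidal stimulation current (mA)."""

    samples: np.ndarray
    freq: float
    onset_phase: float
    relation: str  # "in" | "anti"
    amplitude_pp: float = 1.0
    duration: float = 1.0


def wrap_phase(phi):
    """Wrap angle(s) to (-pi, pi]."""
    w = np.asarray(phi, dtype=float)
    w = -((-w + np.pi) % (2 * np.pi) - np.pi)
    if w.ndim == 0:
        return float(w)
    return w


def _mean_segment_spectrum(x: np.ndarray, srate: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean power spectrum over non-overlapping 1-s segments (1 Hz bins)."""
    seg = int(round(srate))
    n_seg = len(x) // seg
    if n_seg < 1:
        raise ValueError("need at least 1 s of data")
    chunks = x[: n_seg * seg].reshape(n_seg, seg)
    chunks = signal.detrend(chunks, axis=1)
    spec = np.abs(np.fft.rfft(chunks, axis=1)) ** 2 / seg
    return np.fft.rfftfreq(seg, 1.0 / srate), spec.mean(axis=0)


def estimate_iaf(rest_ec: EEGRecording, rest_eo: EEGRecording,
                 channel: str = "POz",
                 band: tuple[float, float] = (7.0, 13.0)) -> IAFEstimate:
    """Estimate the individual alpha frequency by contrasting EC vs EO spectra.

    Mean 1-s-segment FFT spectra are computed for both resting states at
    *channel*; the IAF is the in-band frequency maximizing the EC - EO
    difference.  Raises ``ValueError`` when no positive difference exists
    anywhere in the band (no detectable alpha peak).
    """
    for rec in (rest_ec, rest_eo):
        if rec.n_samples < 10 * rec.srate:
            raise ValueError("resting segments must be at least 10 s long")
    freqs, p_ec = _mean_segment_spectrum(rest_ec.channel(channel), rest_ec.srate)
    _, p_eo = _mean_segment_spectrum(rest_eo.channel(channel), rest_eo.srate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    diff = p_ec[mask] - p_eo[mask]
    if np.all(diff <= 0):
        raise ValueError("no alpha peak: EC spectrum never exceeds EO in band")
    k = int(np.argmax(diff))
    iaf = float(freqs[mask][k])
    return IAFEstimate(iaf=iaf, ec_peak_power=float(p_ec[mask][k]),
                       eo_peak_power=float(p_eo[mask][k]), search_band=band)


def estimate_phase(segment: np.ndarray, iaf: float, srate: float) -> float:
    """Cosine phase at the final sample of a 250-ms single-channel segment.

    The segment is extended by one segment length on both sides with a
    least-squares sinusoid fitted at ``iaf`` (phase-consistent padding), then
    band-pass filtered (4th-order Butterworth, IAF +/- 2 Hz,
    forward-backward) and Hilbert-transformed; the analytic phase at the
    last original sample - now an interior sample - is returned.  Naive
    mirror padding reverses the direction of travel of the oscillation at
    the junction and biases the phase at exactly the sample we care about;
    the sinusoidal extension is exact for a noise-free oscillation.
    """
    segment = np.asarray(segment, dtype=float)
    n_expected = int(round(SEGMENT_DUR * srate))
    if segment.ndim != 1 or len(segment) != n_expected:
        raise ValueError(
            f"segment must be 1-D with {n_expected} samples, got {segment.shape}")
    n = len(segment)
    pad = 3 * n  # enough cycles that analytic-signal leakage is < 1 degree
    t = np.arange(-pad, pad + n) / srate
    tt = t[pad:pad + n]
    basis = np.column_stack([np.cos(2 * np.pi * iaf * tt),
                             np.sin(2 * np.pi * iaf * tt),
                             np.ones(n)])
    coef, *_ = np.linalg.lstsq(basis, segment, rcond=None)
    padded = coef[0] * np.cos(2 * np.pi * iaf * t) \
        + coef[1] * np.sin(2 * np.pi * iaf * t) + coef[2]
    padded[pad:pad + n] = segment
    taper = np.hanning(2 * n)  # soften the circular-FFT wrap discontinuity
    padded[:n] *= taper[:n]
    padded[-n:] *= taper[n:]
    sos = signal.butter(4, (iaf - 2.0, iaf + 2.0), btype="band", fs=srate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, padded)
    analytic = signal.hilbert(filtered)
    return wrap_phase(float(np.angle(analytic[pad + n - 1])))


def forecast_phase(phase_end: float, iaf: float, lead_time: float) -> float:
    """Extrapolate a phase forward by ``lead_time`` seconds at frequency ``iaf``."""
    if lead_time < 0:
        raise ValueError("lead_time must be >= 0")
    return wrap_phase(phase_end + 2 * np.pi * iaf * lead_time)


def make_stim_waveform(iaf: float, forecast: float, relation: str,
                       duration: float = 1.0, amplitude_pp: float = 1.0,
                       srate: float = 500.0) -> StimWaveform:
    """Synthesize the stimulation sinusoid locked to the forecast phase.

    ``s(t) = (amplitude_pp / 2) * cos(2*pi*iaf*t + phi)`` with ``phi`` equal
    to the forecast phase for in-phase stimulation and shifted by pi for
    anti-phase.
    """
    if iaf <= 0:
        raise ValueError("iaf must be positive")
    if relation not in ("in", "anti"):
        raise ValueError(f"unknown relation {relation!r}")
    phi = forecast if relation == "in" else forecast + np.pi
    t = np.arange(int(round(duration * srate))) / srate
    samples = amplitude_pp / 2.0 * np.cos(2 * np.pi * iaf * t + phi)
    return StimWaveform(samples=samples, freq=iaf, onset_phase=wrap_phase(phi),
                        relation=relation, amplitude_pp=amplitude_pp,
                        duration=duration)


def run_closed_loop_session(recording: EEGRecording, events: pd.DataFrame,
                            iaf: float, latency: float = 0.0,
                            channel: str = "POz",
                            amplitude_pp: float = 1.0,
                            ground_truth: GroundTruth | None = None,
                            ) -> tuple[list[StimWaveform], pd.DataFrame]:
    """Replay the closed loop over every trial of a session.

    For each trial the final 250 ms of pre-stimulation data at *channel*
    (ending ``latency`` seconds before stimulation onset) are phase-estimated,
    the phase is forecast to the onset sample, and the trial's waveform is
    synthesized per its in/anti label.  When a :class:`GroundTruth` is given,
    the achieved phase lag (waveform onset phase minus true source phase at
    onset) is logged per trial.
    """
    srate = recording.srate
    try:
        x = recording.channel(channel)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    n_seg = int(round(SEGMENT_DUR * srate))
    lat_samples = int(round(latency * srate))
    stim_dur = float((events["stim_offset"] - events["stim_onset"]).iloc[0] / srate)

    waveforms: list[StimWaveform] = []
    log_rows = []
    for _, row in events.iterrows():
        onset = int(row["stim_onset"])
        end = onset - lat_samples
        if end - n_seg < 0:
            raise ValueError(f"trial {row['trial_id']}: not enough pre data")
        phase_end = estimate_phase(x[end - n_seg:end], iaf, srate)
        # last segment sample sits at onset - lat_samples - 1; forecast to onset
        lead = (lat_samples + 1) / srate
        phase_onset = forecast_phase(phase_end, iaf, lead)
        wf = make_stim_waveform(iaf, phase_onset, row["stimulation"],
                                duration=stim_dur, amplitude_pp=amplitude_pp,
                                srate=srate)
        waveforms.append(wf)
        lag = np.nan
        if ground_truth is not None:
            true_phase = ground_truth.source_phase_at(onset, srate)
            lag = wrap_phase(wf.onset_phase - true_phase)
        log_rows.append((row["trial_id"], row["stimulation"], phase_end,
                         phase_onset, lag))
    log = pd.DataFrame(log_rows, columns=["trial_id", "relation",
                                          "phase_estimate", "phase_forecast",
                                          "achieved_lag"])
    return waveforms, log
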