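"""Offline pre-/post-stimulation window extraction and alpha-power analysis.

The 1-s intervals flanking each stimulation are extracted and band-pass
filtered (5-40 Hz, 4th-order zero-phase Butterworth); 500-ms analysis
windows are then cut with 100-ms guard trims against filter edge effects and
residual stimulation artifacts: pre = [-600, -100) ms relative to
stimulation onset, post = [+100, +600) ms relative to stimulation offset,
plus four overlapping post bins stepped by 100 ms.

Window power is computed from the linearly detrended, zero-padded (512
samples by default) FFT as ``|X_k|^2 / nfft`` (one-sided, no doubling - all
downstream comparisons are scale-invariant), averaged over bins whose center
frequency lies in [IAF - 1, IAF + 1] Hz inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .montage import ChannelLayout, POC_CHANNELS
from .simulate import EEGRecording

__all__ = [
    "TrialEpochs",
    "extract_intervals",
    "bandpass_5_40",
    "epoch_windows",
    "timebin_windows",
    "window_alpha_power",
    "detrended_power_spectrum",
    "aggregate_sources",
    "percent_modulation",
    "modulation_table",
    "mean_spectra",
    "PRE_WINDOW_MS",
    "POST_WINDOW_MS",
    "POST_BINS_MS",
]

PRE_WINDOW_MS = (-600.0, -100.0)  # relative to stimulation onset
POST_WINDOW_MS = (100.0, 600.0)  # relative to stimulation offset
POST_BINS_MS = ((100.0, 600.0), (200.0, 700.0), (300.0, 800.0), (400.0, 900.0))


@dataclass
class TrialEpochs:
    """Per-trial windowed data, shape (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    srate: float
    window_name: str
    window_def: tuple[float, float]  # ms relative to anchor
    anchor: str  # "onset" | "offset"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def extract_intervals(recording: EEGRecording, events: pd.DataFrame,
                      interval_dur: float = 1.0) -> dict[str, TrialEpochs]:
    """Extract the full 1-s pre- and post-stimulation intervals of every trial.

    pre = ``[onset - interval_dur, onset)``; post = ``[offset,
    offset + interval_dur)``.  No sample from ``[onset, offset)`` is included.
    """
    n = int(round(interval_dur * recording.srate))
    pre_list, post_list = [], []
    for _, row in events.iterrows():
        on, off = int(row["stim_onset"]), int(row["stim_offset"])
        if on - n < 0 or off + n > recording.n_samples:
            raise ValueError(
                f"trial {row['trial_id']}: interval outside recording bounds")
        pre_list.append(recording.data[:, on - n:on])
        post_list.append(recording.data[:, off:off + n])
    ms = interval_dur * 1000.0
    return {
        "pre": TrialEpochs(np.stack(pre_list), recording.srate, "pre_interval",
                           (-ms, 0.0), "onset"),
        "post": TrialEpochs(np.stack(post_list), recording.srate,
                            "post_interval", (0.0, ms), "offset"),
    }


def bandpass_5_40(epochs: TrialEpochs, order: int = 4,
                  band: tuple[float, float] = (5.0, 40.0)) -> TrialEpochs:
    """Zero-phase (forward-backward) Butterworth band-pass along time."""
    if epochs.srate <= 2 * band[1]:
        raise ValueError("sampling rate too low for the requested passband")
    sos = signal.butter(order, band, btype="band", fs=epochs.srate, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return TrialEpochs(filtered, epochs.srate, epochs.window_name,
                       epochs.window_def, epochs.anchor)


def _cut(epochs: TrialEpochs, window_ms: tuple[float, float], name: str,
         anchor: str) -> TrialEpochs:
    """Cut a sub-window (ms, half-open) out of a full interval epoch."""
    srate = epochs.srate
    t0_ms, _ = epochs.window_def
    i0 = int(round((window_ms[0] - t0_ms) / 1000.0 * srate))
    i1 = int(round((window_ms[1] - t0_ms) / 1000.0 * srate))
    if i0 < 0 or i1 > epochs.data.shape[-1]:
        raise ValueError(f"window {window_ms} outside extracted interval")
    return TrialEpochs(epochs.data[..., i0:i1], srate, name, window_ms, anchor)


def epoch_windows(recording: EEGRecording, events: pd.DataFrame,
                  filter_intervals: bool = True) -> dict[str, TrialEpochs]:
    """Return the trimmed 500-ms pre/post analysis windows of every trial.

    The full 1-s intervals are (optionally but by default) band-pass filtered
    before the guard-trimmed windows are cut.
    """
    intervals = extract_intervals(recording, events)
    if filter_intervals:
        intervals = {k: bandpass_5_40(v) for k, v in intervals.items()}
    return {
        "pre": _cut(intervals["pre"], PRE_WINDOW_MS, "pre", "onset"),
        "post": _cut(intervals["post"], POST_WINDOW_MS, "post", "offset"),
    }


def timebin_windows(recording: EEGRecording, events: pd.DataFrame,
                    filter_intervals: bool = True) -> dict[str, TrialEpochs]:
    """Return the pre window plus the four overlapping 500-ms post bins.

    Bins start +100, +200, +300 and +400 ms after stimulation offset;
    ``post_bin1`` coincides with the standard post window.
    """
    intervals = extract_intervals(recording, events)
    if filter_intervals:
        intervals = {k: bandpass_5_40(v) for k, v in intervals.items()}
    out = {"pre": _cut(intervals["pre"], PRE_WINDOW_MS, "pre", "onset")}
    for i, bin_ms in enumerate(POST_BINS_MS, start=1):
        out[f"post_bin{i}"] = _cut(intervals["post"], bin_ms,
                                   f"post_bin{i}", "offset")
    return out


def detrended_power_spectrum(x: np.ndarray, srate: float,
                             nfft: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum ``|X_k|^2 / nfft`` of the detrended window.

    Works on the last axis; the window is linearly detrended then
    zero-padded to ``nfft`` samples.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] > nfft:
        raise ValueError(f"window length {x.shape[-1]} exceeds nfft={nfft}")
    x = signal.detrend(x, axis=-1, type="linear")
    spec = np.fft.rfft(x, n=nfft, axis=-1)
    power = np.abs(spec) ** 2 / nfft
    return np.fft.rfftfreq(nfft, 1.0 / srate), power


def window_alpha_power(window: np.ndarray, iaf: float, srate: float,
                       nfft: int = 512) -> np.ndarray | float:
    """Mean detrended-FFT power over bins within [IAF - 1, IAF + 1] Hz.

    Accepts any array whose last axis is time; returns the matching leading
    shape (a scalar for 1-D input).
    """
    freqs, power = detrended_power_spectrum(window, srate, nfft)
    mask = (freqs >= iaf - 1.0) & (freqs <= iaf + 1.0)
    if not mask.any():
        raise ValueError("no FFT bin falls inside the IAF band")
    out = power[..., mask].mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def aggregate_sources(windows: dict[str, TrialEpochs], layout: ChannelLayout,
                      iaf: float, events: pd.DataFrame,
                      subject: int = 0, nfft: int = 512) -> pd.DataFrame:
    """Per-trial alpha power for the POz and POC sources in long format.

    POz is the single-channel window power; POC is the mean of the nine
    per-channel cluster powers (power of each channel, then mean - robust to
    phase cancellation).
    """
    for ch in POC_CHANNELS:
        if ch not in layout.labels:
            raise ValueError(f"POC channel {ch} missing from layout")
    poz = layout.index("POz")
    poc = layout.indices(POC_CHANNELS)
    frames = []
    for name, ep in windows.items():
        p_all = window_alpha_power(ep.data, iaf, ep.srate, nfft)  # (trials, ch)
        for source, values in (("POz", p_all[:, poz]),
                               ("POC", p_all[:, poc].mean(axis=1))):
            frames.append(pd.DataFrame({
                "subject": subject,
                "block": events["block"].to_numpy(),
                "trial": events["trial_id"].to_numpy(),
                "state": events["state"].to_numpy(),
                "stimulation": events["stimulation"].to_numpy(),
                "window": name,
                "source": source,
                "alpha_power": values,
            }))
    return pd.concat(frames, ignore_index=True)


def percent_modulation(pre_power, post_power):
    """Percent change (post - pre) / pre * 100; pre must be positive."""
    pre = np.asarray(pre_power, dtype=float)
    post = np.asarray(post_power, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("pre-stimulation power must be positive")
    out = (post - pre) / pre * 100.0
    return float(out) if out.ndim == 0 else out


def modulation_table(power_table: pd.DataFrame, pre_window: str = "pre",
                     post_windows: tuple[str, ...] = ("post",)) -> pd.DataFrame:
    """Long-format per-trial percent modulation, one row per post window."""
    keys = ["subject", "block", "trial", "state", "stimulation", "source"]
    wide = power_table.pivot_table(index=keys, columns="window",
                                   values="alpha_power", sort=False)
    rows = []
    for post_w in post_windows:
        mod = percent_modulation(wide[pre_window].to_numpy(),
                                 wide[post_w].to_numpy())
        frame = wide.index.to_frame(index=False)
        frame["window"] = post_w
        frame["modulation"] = mod
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def mean_spectra(source_windows: dict[str, np.ndarray], events: pd.DataFrame,
                 srate: float, nfft: int = 512) -> pd.DataFrame:
    """Trial-averaged power spectra per condition and window, plus post/pre ratio.

    ``source_windows`` maps window names (must include ``pre`` and ``post``)
    to per-trial single-source series (n_trials, n_samples).  Returns a tidy
    frame with columns freq, state, stimulation, window, power; ratio rows
    carry window ``"ratio"`` and the post/pre power quotient.
    """
    if "pre" not in source_windows or "post" not in source_windows:
        raise ValueError("source_windows must contain 'pre' and 'post'")
    rows = []
    cond = list(zip(events["state"], events["stimulation"]))
    conditions = sorted(set(cond))
    spectra: dict[tuple, dict[str, np.ndarray]] = {}
    freqs = None
    for name, data in source_windows.items():
        data = np.asarray(data, dtype=float)
        if data.shape[0] != len(events):
            raise ValueError(f"window {name}: trial count mismatch")
        freqs, power = detrended_power_spectrum(data, srate, nfft)
        for c in conditions:
            sel = np.array([cc == c for cc in cond])
            if not sel.any():
                raise ValueError(f"condition {c} has no trials")
            spectra.setdefault(c, {})[name] = power[sel].mean(axis=0)
    for c, by_window in spectra.items():
        for name, spec in by_window.items():
            for f, p in zip(freqs, spec):
                rows.append((f, c[0], c[1], name, p))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = by_window["post"] / by_window["pre"]
        for f, p in zip(freqs, ratio):
            rows.append((f, c[0], c[1], "ratio", p))
    return pd.DataFrame(rows, columns=["freq", "state", "stimulation",
                                       "window", "power"])
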