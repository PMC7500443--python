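"""End-to-end orchestration: simulate -> closed loop -> power -> CSP -> stats.

A run is fully determined by a :class:`RunConfig` (simulation parameters
plus analysis options) and a seed; rerunning with the same config and seed
reproduces byte-identical result tables.  Every written table carries the
config hash in its header comments.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .closedloop import estimate_iaf, run_closed_loop_session
from .csp import average_pattern, component_alpha_power, loto_components
from .io import (read_brainvision, read_events, write_brainvision,
                 write_events, write_ground_truth, write_table)
from .montage import build_montage
from .power import (POST_BINS_MS, TrialEpochs, aggregate_sources, mean_spectra,
                    modulation_table, timebin_windows)
from .simulate import (EEGRecording, SimulationConfig, SubjectSession,
                       expected_post_modulation, inject_stim_artifact,
                       simulate_cohort)
from .stats import fit_rm_anova, linear_contrast, marginal_means

__all__ = ["RunConfig", "RunManifest", "read_recording", "analyze_subject",
           "run_pipeline", "SOURCES", "TIMEBIN_WINDOWS"]

SOURCES = ("POz", "POC", "CSPpre", "CSPpost")
#: window names of the four overlapping post bins ("post" doubles as bin 1)
TIMEBIN_WINDOWS = ("post", "post_bin2", "post_bin3", "post_bin4")


@dataclass(frozen=True)
class RunConfig:
    """Simulation parameters plus analysis options for one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    nfft: int = 512
    filter_band: tuple[float, float] = (5.0, 40.0)
    filter_order: int = 4
    csp_gamma: float = 1e-6
    latency: float = 0.0
    use_true_iaf: bool = False
    write_recordings: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nfft < 1 or self.filter_order < 1 or self.csp_gamma < 0:
            raise ValueError("invalid analysis options")
        if self.filter_band[0] <= 0 or self.filter_band[0] >= self.filter_band[1]:
            raise ValueError("invalid filter band")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        sim_fields = {f.name for f in fields(SimulationConfig)}
        run_fields = {f.name for f in fields(cls)} - {"simulation"}
        unknown = set(mapping) - sim_fields - run_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_kwargs = {k: v for k, v in mapping.items() if k in sim_fields}
        run_kwargs = {k: v for k, v in mapping.items() if k in run_fields}
        for key in ("iti_range", "iaf_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        if "filter_band" in run_kwargs:
            run_kwargs["filter_band"] = tuple(run_kwargs["filter_band"])
        return cls(simulation=SimulationConfig(**sim_kwargs), **run_kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(mapping)

    def to_flat_dict(self) -> dict:
        out = asdict(self.simulation)
        for f in fields(self):
            if f.name != "simulation":
                out[f.name] = getattr(self, f.name)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    stage_seconds: dict[str, float]
    files: list[str]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


def read_recording(vhdr_path: str | Path,
                   events_path: str | Path | None = None
                   ) -> tuple[EEGRecording, pd.DataFrame]:
    """Load a BrainVision triplet plus its companion events TSV."""
    vhdr_path = Path(vhdr_path)
    recording = read_brainvision(vhdr_path)
    if events_path is None:
        events_path = vhdr_path.with_name(vhdr_path.stem + "_events.tsv")
    events = read_events(events_path, n_samples=recording.n_samples)
    return recording, events


def analyze_subject(session: SubjectSession, config: RunConfig,
                    iaf: float | None = None) -> dict:
    """Run the offline analysis chain for one subject.

    Returns the per-trial power table (all four sources), the modulation
    table (standard post window plus the overlapping bins for the CSP
    sources), CSP patterns, and the IAF actually used.
    """
    if iaf is None:
        if config.use_true_iaf or session.rest_ec is None:
            iaf = session.ground_truth.iaf
        else:
            iaf = estimate_iaf(session.rest_ec, session.rest_eo).iaf
    rec, events = session.recording, session.events
    windows = timebin_windows(rec, events)
    pre = windows["pre"]
    post = TrialEpochs(windows["post_bin1"].data, pre.srate, "post",
                       windows["post_bin1"].window_def, "offset")

    sensor_power = aggregate_sources({"pre": pre, "post": post}, rec.layout,
                                     iaf, events, subject=session.subject_id,
                                     nfft=config.nfft)
    extra = {f"post_bin{i}": windows[f"post_bin{i}"] for i in (2, 3, 4)}
    loto = loto_components(pre, post, extra_windows=extra, gamma=config.csp_gamma)
    csp_power = component_alpha_power(loto, events, iaf, rec.srate,
                                      subject=session.subject_id, nfft=config.nfft)
    power = pd.concat([sensor_power, csp_power], ignore_index=True)
    modulation = pd.concat(
        [modulation_table(power[power["source"].isin(("POz", "POC"))]),
         modulation_table(power[power["source"].isin(("CSPpre", "CSPpost"))],
                          post_windows=TIMEBIN_WINDOWS)],
        ignore_index=True)
    return {
        "iaf": iaf,
        "power": power,
        "modulation": modulation,
        "patterns": {k: v for k, v in loto.patterns.items()},
        "loto": loto,
    }


def _group_stats(power: pd.DataFrame, modulation: pd.DataFrame) -> dict:
    """Fit the three repeated-measures models and the time-bin contrast."""
    anova_main = []
    for source in SOURCES:
        sub = power[(power["source"] == source)
                    & (power["window"].isin(("pre", "post")))].copy()
        sub = sub.rename(columns={"window": "time"})
        res = fit_rm_anova(sub, "alpha_power", ["time", "state", "stimulation"])
        res.table.insert(0, "source", source)
        anova_main.append(res.table)
    anova_main = pd.concat(anova_main, ignore_index=True)

    mod_csp = modulation[(modulation["source"] == "CSPpre")
                         & (modulation["window"] == "post")].copy()
    # block position within each state sequence (blocks alternate states)
    mod_csp["block_pos"] = mod_csp["block"] // 2
    block_factors = [f for f in ("block_pos", "state", "stimulation")
                     if mod_csp[f].nunique() > 1]
    anova_block = fit_rm_anova(mod_csp, "modulation", block_factors).table

    bins = modulation[(modulation["source"] == "CSPpre")
                      & (modulation["window"].isin(TIMEBIN_WINDOWS))].copy()
    bins["timebin"] = bins["window"].map(
        {w: i + 1 for i, w in enumerate(TIMEBIN_WINDOWS)})
    bin_factors = [f for f in ("timebin", "state", "stimulation")
                   if bins[f].nunique() > 1]
    anova_bins = fit_rm_anova(bins, "modulation", bin_factors).table

    cell = bins.groupby(["subject", "timebin"])["modulation"].mean().unstack()
    contrast = {
        model: linear_contrast(cell.to_numpy(), error_model=model)
        for model in ("subject", "pooled")
    }
    mm_time = marginal_means(
        power[(power["source"] == "CSPpre")
              & (power["window"].isin(("pre", "post")))],
        "alpha_power", "window")
    mm_state = marginal_means(mod_csp, "modulation", "state")
    return {
        "anova_main": anova_main,
        "anova_block": anova_block,
        "anova_timebin": anova_bins,
        "linear_contrast": contrast,
        "marginal_time": mm_time,
        "marginal_state": mm_state,
        "timebin_cell_means": cell,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 rng: np.random.Generator | None = None) -> RunManifest:
    """Execute the full pipeline and write all result tables to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    if rng is None:
        rng = np.random.default_rng(seed)
    chash = config.config_hash()
    header = {"config_hash": chash, "seed": seed, "version": __version__}
    stage_seconds: dict[str, float] = {}
    files: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        write_table(df, out / name, header=header)
        files.append(name)

    def _stage(name):
        return _StageTimer(name, stage_seconds)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=True)
    files.append("config.yaml")

    with _stage("simulate"):
        sessions = simulate_cohort(config.simulation, rng)

    with _stage("closed_loop"):
        logs = []
        for s in sessions:
            iaf = s.ground_truth.iaf
            waveforms, log = run_closed_loop_session(
                s.recording, s.events, iaf, latency=config.latency,
                ground_truth=s.ground_truth)
            log.insert(0, "subject", s.subject_id)
            logs.append(log)
            if config.simulation.artifact_gain > 0:
                s.recording = inject_stim_artifact(
                    s.recording, s.events, np.array([w.samples for w in waveforms]),
                    config.simulation.artifact_gain)
        _write(pd.concat(logs, ignore_index=True), "trial_log.tsv")

    with _stage("write_recordings"):
        if config.write_recordings:
            for s in sessions:
                base = out / f"subj{s.subject_id:02d}"
                write_brainvision(s.recording, base, events=s.events)
                write_events(s.events, out / f"subj{s.subject_id:02d}_events.tsv")
                write_ground_truth(s.ground_truth,
                                   out / f"subj{s.subject_id:02d}_truth.json")
                files += [f"subj{s.subject_id:02d}{ext}" for ext in
                          (".vhdr", ".vmrk", ".eeg", "_events.tsv", "_truth.json")]

    with _stage("analysis"):
        per_subject = [analyze_subject(s, config) for s in sessions]
        power = pd.concat([a["power"] for a in per_subject], ignore_index=True)
        modulation = pd.concat([a["modulation"] for a in per_subject],
                               ignore_index=True)
        _write(power, "power_table.tsv")
        _write(modulation, "modulation_table.tsv")
        layout = build_montage()
        topo = average_pattern([a["patterns"]["CSPpre"] for a in per_subject],
                               layout)
        _write(topo, "csp_pre_topography.tsv")
        iafs = pd.DataFrame({
            "subject": [s.subject_id for s in sessions],
            "iaf_used": [a["iaf"] for a in per_subject],
            "iaf_true": [s.ground_truth.iaf for s in sessions],
        })
        _write(iafs, "iaf_table.tsv")

    with _stage("spectra"):
        spec_frames = []
        for s, a in zip(sessions, per_subject):
            comp = a["loto"].components["CSPpre"]
            spec = mean_spectra({"pre": comp["pre"], "post": comp["post"]},
                                s.events, s.recording.srate, nfft=config.nfft)
            spec.insert(0, "subject", s.subject_id)
            spec_frames.append(spec)
        spectra = pd.concat(spec_frames, ignore_index=True)
        group_spec = spectra.groupby(["freq", "state", "stimulation", "window"],
                                     as_index=False)["power"].mean()
        _write(group_spec, "csp_pre_spectra.tsv")

    with _stage("stats"):
        stats = _group_stats(power, modulation)
        _write(stats["anova_main"], "anova_main.tsv")
        _write(stats["anova_block"], "anova_block.tsv")
        _write(stats["anova_timebin"], "anova_timebin.tsv")
        _write(stats["marginal_time"], "marginal_means_time.tsv")
        _write(stats["marginal_state"], "marginal_means_state.tsv")
        rows = []
        for model, c in stats["linear_contrast"].items():
            rows.append((model, c.estimate, c.se, c.t, c.df, c.p, c.degenerate))
        _write(pd.DataFrame(rows, columns=["error_model", "estimate", "se", "t",
                                           "df", "p", "degenerate"]),
               "timebin_linear_contrast.tsv")

    with _stage("recovery"):
        sim = config.simulation
        rows = []
        for i, w in enumerate(TIMEBIN_WINDOWS, start=1):
            sel = modulation[(modulation["source"] == "CSPpre")
                             & (modulation["window"] == w)]
            rows.append((i, w, sel["modulation"].mean(),
                         expected_post_modulation(sim.suppression_depth,
                                                  sim.suppression_tau,
                                                  POST_BINS_MS[i - 1])))
        _write(pd.DataFrame(rows, columns=["timebin", "window",
                                           "observed_modulation",
                                           "expected_modulation"]),
               "ground_truth_recovery.tsv")

    manifest = RunManifest(config_hash=chash, seed=seed, version=__version__,
                           stage_seconds=stage_seconds, files=files)
    manifest.write(out / "manifest.json")
    return manifest


class _StageTimer:
    def __init__(self, name: str, sink: dict):
        self.name, self.sink = name, sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.sink[self.name] = round(time.perf_counter() - self.t0, 3)
        if exc is not None:
            raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
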