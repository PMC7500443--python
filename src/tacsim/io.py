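"""File I/O: BrainVision triplet, events TSV, ground-truth JSON, result tables.

The BrainVision writer emits the classic triplet - text ``.vhdr`` header,
text ``.vmrk`` marker file, binary ``.eeg`` data (IEEE float32,
multiplexed, little-endian, microvolts).  Only that profile is read back;
EDF export is intentionally not provided (no EDF library in the target
environment and the BrainVision path covers round-tripping).

Result tables are TSV with ``#``-prefixed header comments carrying
provenance (config hash, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import _POSITIONS, ChannelLayout
from .simulate import EVENT_COLUMNS, EEGRecording, GroundTruth, validate_events

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_events",
    "read_events",
    "write_ground_truth",
    "read_ground_truth",
    "write_waveform",
    "write_table",
    "read_table",
]


def write_brainvision(recording: EEGRecording, base: str | Path,
                      events: pd.DataFrame | None = None) -> Path:
    """Write ``base.vhdr`` / ``base.vmrk`` / ``base.eeg``; returns the vhdr path."""
    base = Path(base)
    name = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    n_ch = len(recording.layout)
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "; Written by tacsim",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / recording.srate:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(recording.layout.labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    if events is not None:
        for k, (_, row) in enumerate(events.iterrows(), start=2):
            desc = f"{row['stimulation']}/{row['state']}"
            length = int(row["stim_offset"]) - int(row["stim_onset"])
            mlines.append(
                f"Mk{k}=Stimulus,{desc},{int(row['stim_onset']) + 1},{length},0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr


def _parse_vhdr(vhdr: Path) -> dict:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for raw in vhdr.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, val = line.split("=", 1)
            sections[current][key.strip()] = val.strip()
    if "Common Infos" not in sections:
        raise ValueError(f"{vhdr}: malformed header (no [Common Infos])")
    return sections


def read_brainvision(vhdr: str | Path) -> EEGRecording:
    """Read a BrainVision triplet written by :func:`write_brainvision`."""
    vhdr = Path(vhdr)
    if not vhdr.exists():
        raise FileNotFoundError(vhdr)
    sec = _parse_vhdr(vhdr)
    common = sec["Common Infos"]
    binary = sec.get("Binary Infos", {})
    if common.get("DataFormat") != "BINARY" or \
            common.get("DataOrientation") != "MULTIPLEXED":
        raise ValueError("only BINARY/MULTIPLEXED BrainVision data is supported")
    if binary.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError("only IEEE_FLOAT_32 BrainVision data is supported")
    marker = vhdr.parent / common["MarkerFile"]
    if not marker.exists():
        raise FileNotFoundError(f"marker file missing: {marker}")
    eeg = vhdr.parent / common["DataFile"]
    if not eeg.exists():
        raise FileNotFoundError(f"data file missing: {eeg}")

    n_ch = int(common["NumberOfChannels"])
    srate = 1e6 / float(common["SamplingInterval"])
    chans = sec.get("Channel Infos", {})
    labels = []
    for i in range(1, n_ch + 1):
        entry = chans.get(f"Ch{i}")
        if entry is None:
            raise ValueError(f"missing channel entry Ch{i}")
        labels.append(entry.split(",")[0])
    raw = np.fromfile(eeg, dtype="<f4")
    if raw.size % n_ch:
        raise ValueError("data file size is not a multiple of channel count")
    data = raw.reshape(-1, n_ch).T.astype(float)
    positions = np.array([_POSITIONS.get(lab, (0.0, 0.0)) for lab in labels])
    layout = ChannelLayout(labels=tuple(labels), positions=positions)
    return EEGRecording(data=data, srate=srate, layout=layout)


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in ("trial_id", "block", "stim_onset", "stim_offset",
                        "state", "stimulation", "iti_ms") if c in events.columns]
    out = events[cols].rename(columns={"stim_onset": "onset_sample",
                                       "stim_offset": "offset_sample"})
    out.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path, n_samples: int | None = None) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    events = events.rename(columns={"onset_sample": "stim_onset",
                                    "offset_sample": "stim_offset"})
    validate_events(events, n_samples=n_samples)
    return events[[c for c in list(EVENT_COLUMNS) + ["iti_ms"]
                   if c in events.columns]]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "iaf": truth.iaf,
        "source_pattern": truth.source_pattern.tolist(),
        "suppression_depth": truth.suppression_depth,
        "suppression_tau": truth.suppression_tau,
        "itis_ms": truth.itis_ms.tolist(),
        "phase0": truth.phase0,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        iaf=payload["iaf"],
        source_pattern=np.array(payload["source_pattern"]),
        suppression_depth=payload["suppression_depth"],
        suppression_tau=payload["suppression_tau"],
        itis_ms=np.array(payload["itis_ms"]),
        phase0=payload["phase0"],
    )


def write_waveform(waveform, path: str | Path, srate: float = 500.0) -> Path:
    """Export a stimulation waveform as a two-column (time, mA) TSV."""
    t = np.arange(len(waveform.samples)) / srate
    df = pd.DataFrame({"time_s": t, "current_ma": waveform.samples})
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_table(df: pd.DataFrame, path: str | Path,
                header: dict | None = None) -> Path:
    """Write a TSV with ``#``-prefixed provenance comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
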