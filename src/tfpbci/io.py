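"""Delimited-text serialization: recordings, epoch directories, matrices.

Everything here is plain TSV/JSON so artifacts stay diffable and portable:

* a recording = one TSV (columns = channels, ``# key=value`` header lines
  for metadata) plus an ``.events.tsv`` sidecar (trial_id, sample_index,
  label);
* an epochs directory = ``manifest.json`` plus one TSV per trial;
* a feature matrix = TSV whose ``# col`` header lines carry per-column
  provenance (channel, band, feature type, window index) and whose first
  data column is the trial label;
* a selection result = TSV of (step, column index, provenance, J score).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import ColumnMeta, FeatureMatrix
from .preprocess import TrialEpoch
from .selection import SelectionResult
from .sim_eeg import Event, Recording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "save_epochs",
    "load_epochs",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_selection",
]


def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.tsv")


def write_recording_text(rec: Recording, path) -> None:
    """Write a recording as TSV (+ events sidecar)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs_hz!r}\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, delimiter="\t", fmt="%.6f")
    with open(_events_path(path), "w") as fh:
        fh.write("trial_id\tsample_index\tlabel\n")
        for ev in rec.events:
            fh.write(f"{ev.trial_id}\t{ev.sample_index}\t{ev.label}\n")


def read_recording_text(path) -> Recording:
    """Read a recording written by :func:`write_recording_text`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs_hz="):
            raise ConfigError(f"{path} lacks the '# fs_hz=' header line")
        fs = float(first.split("=", 1)[1])
        labels = tuple(fh.readline().strip().split("\t"))
        samples = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    events: list[Event] = []
    ev_path = _events_path(path)
    if ev_path.exists():
        df = pd.read_csv(ev_path, sep="\t")
        for row in df.itertuples(index=False):
            events.append(Event(int(row.sample_index), str(row.label),
                                int(row.trial_id)))
        events.sort(key=lambda e: e.sample_index)
    return Recording(samples, fs, labels, tuple(events))


def save_epochs(epochs, dirpath) -> None:
    """Write epochs as one TSV per trial plus a manifest.json."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fs_hz": epochs[0].fs_hz,
        "channel_labels": list(epochs[0].channel_labels),
        "epochs": [],
    }
    for i, ep in enumerate(epochs):
        name = f"epoch_{i:04d}.tsv"
        np.savetxt(dirpath / name, ep.samples.T, delimiter="\t", fmt="%.6f")
        manifest["epochs"].append(
            {
                "file": name,
                "t0_index": int(ep.t0_index),
                "label": int(ep.label),
                "label_name": ep.label_name,
                "trial_id": int(ep.trial_id),
            }
        )
    with open(dirpath / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_epochs(dirpath) -> list[TrialEpoch]:
    """Read an epochs directory written by :func:`save_epochs`."""
    dirpath = Path(dirpath)
    with open(dirpath / "manifest.json") as fh:
        manifest = json.load(fh)
    labels = tuple(manifest["channel_labels"])
    out = []
    for entry in manifest["epochs"]:
        samples = np.loadtxt(dirpath / entry["file"], delimiter="\t", ndmin=2).T
        out.append(
            TrialEpoch(
                samples=samples,
                fs_hz=manifest["fs_hz"],
                channel_labels=labels,
                t0_index=entry["t0_index"],
                label=entry["label"],
                label_name=entry["label_name"],
                trial_id=entry["trial_id"],
            )
        )
    return out


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV with provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# scaled={int(fm.scaled)}\n")
        for i, m in enumerate(fm.column_meta):
            fh.write(
                f"# col\t{i}\t{m.channel}\t{m.band}\t{m.feature_type}\t{m.window_index}\n"
            )
        cols = [f"f{i}" for i in range(fm.n_features)]
        fh.write("label\t" + "\t".join(cols) + "\n")
        for r in range(fm.n_trials):
            vals = "\t".join(f"{v:.8g}" for v in fm.values[r])
            fh.write(f"{fm.labels[r]}\t{vals}\n")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    meta: list[ColumnMeta] = []
    scaled = False
    rows = []
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# scaled="):
                scaled = bool(int(line.split("=", 1)[1]))
            elif line.startswith("# col\t"):
                _, _, ch, band, ftype, widx = line.split("\t")
                meta.append(ColumnMeta(ch, band, ftype, int(widx)))
            elif line.startswith("label\t"):
                continue
            elif line:
                parts = line.split("\t")
                labels.append(int(parts[0]))
                rows.append([float(v) for v in parts[1:]])
    if not rows:
        raise ConfigError(f"no feature rows in {path}")
    return FeatureMatrix(np.array(rows), tuple(meta), np.array(labels), scaled)


def write_selection(sel: SelectionResult, fm: FeatureMatrix, path) -> None:
    """Write a ranking as TSV: step, column, provenance, criterion score."""
    with open(path, "w") as fh:
        beta = "" if sel.beta is None else repr(sel.beta)
        fh.write(f"# criterion={sel.criterion}\tbeta={beta}\tchosen_k={sel.chosen_k}\n")
        fh.write("step\tcolumn\tchannel\tband\tfeature_type\twindow_index\tJ\n")
        for step, (col, score) in enumerate(zip(sel.order, sel.scores)):
            m = fm.column_meta[col]
            fh.write(
                f"{step}\t{col}\t{m.channel}\t{m.band}\t{m.feature_type}\t"
                f"{m.window_index}\t{score:.6g}\n"
            )
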