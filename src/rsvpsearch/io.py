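"""Readers, writers, and run configuration.

On-disk conventions are all plain text: recordings as a CSV signal matrix
(header = channel names) plus a CSV event table (``onset_sample,
image_id``); image databases as one CSV feature matrix per space plus a
label table; fitted models as JSON; run logs as JSON-lines with one record
per iteration.  EDF recordings can be read through MNE when it is
installed; a minimal EDF writer is included so synthetic recordings can be
exported for interoperability (16-bit, one data record per second).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import Recording
from .synthetic import ImageDatabase

__all__ = [
    "RunConfig",
    "load_recording",
    "save_recording",
    "load_database",
    "save_database",
    "write_run_log",
    "read_run_log",
    "write_metrics_table",
    "write_edf",
    "save_graph",
    "load_graph",
]


# -- recordings -------------------------------------------------------------

def save_recording(rec: Recording, signal_path: str | Path,
                   events_path: str | Path | None = None) -> None:
    """Write the signal matrix (CSV, header = channel names) and events."""
    df = pd.DataFrame(rec.data, columns=rec.channel_names)
    df.to_csv(signal_path, index=False, float_format="%.10g")
    if events_path is not None:
        ev = pd.DataFrame(rec.events, columns=["onset_sample", "image_id"])
        ev.to_csv(events_path, index=False)


def _load_events(events_path: str | Path, n_samples: int) -> np.ndarray:
    ev = pd.read_csv(events_path)
    expected = ["onset_sample", "image_id"]
    if list(ev.columns) != expected:
        raise ValueError(
            f"event table must have columns {expected}, got {list(ev.columns)}"
        )
    for col in expected:
        if not np.issubdtype(ev[col].dtype, np.integer):
            raise ValueError(f"event column {col!r} must be integer")
    events = ev.to_numpy(dtype=np.int64)
    if events.size and (events[:, 0].min() < 0 or events[:, 0].max() >= n_samples):
        raise ValueError("event onset beyond recording end")
    return events


def load_recording(signal_path: str | Path, sample_rate: float | None = None,
                   events_path: str | Path | None = None,
                   dialect: str = "matrix") -> Recording:
    """Load a recording from CSV (``matrix`` dialect) or EDF.

    The matrix dialect requires ``sample_rate``; EDF carries its own rate
    (and needs MNE installed).
    """
    if dialect == "matrix":
        if sample_rate is None:
            raise ValueError("matrix dialect requires sample_rate")
        df = pd.read_csv(signal_path)
        data = df.to_numpy(dtype=np.float64)
        events = (np.empty((0, 2), dtype=np.int64) if events_path is None
                  else _load_events(events_path, len(df)))
        return Recording(data=data, sample_rate=float(sample_rate),
                         channel_names=[str(c) for c in df.columns],
                         events=events)
    if dialect == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(signal_path), preload=True, verbose="error")
        try:
            data = raw.get_data(units="uV").T  # undo MNE's conversion to volts
        except ValueError:  # non-voltage channel types present
            data = raw.get_data().T
        events = (np.empty((0, 2), dtype=np.int64) if events_path is None
                  else _load_events(events_path, data.shape[0]))
        return Recording(data=data, sample_rate=float(raw.info["sfreq"]),
                         channel_names=list(raw.ch_names), events=events)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_edf(rec: Recording, path: str | Path,
              physical_range: tuple[float, float] | None = None) -> None:
    """Minimal EDF export: 16-bit samples, one data record per second.

    The recording is truncated to a whole number of seconds.  Intended for
    interoperability of synthetic recordings with standard EEG tooling;
    events are not embedded (keep the CSV event table alongside).
    """
    fs = rec.sample_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[: n_records * spr]
    nch = rec.n_channels
    if physical_range is None:
        amax = float(np.abs(data).max()) or 1.0
        physical_range = (-amax, amax)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.rint((data - pmin) * scale + dmin), dmin, dmax
                      ).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (nch + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(nch), 4),
    ])
    sig = b"".join([
        b"".join(pad(n, 16) for n in rec.channel_names),
        b"".join(pad("EEG", 80) for _ in range(nch)),
        b"".join(pad("uV", 8) for _ in range(nch)),
        b"".join(pad(f"{pmin:.6g}", 8) for _ in range(nch)),
        b"".join(pad(f"{pmax:.6g}", 8) for _ in range(nch)),
        b"".join(pad(str(dmin), 8) for _ in range(nch)),
        b"".join(pad(str(dmax), 8) for _ in range(nch)),
        b"".join(pad("", 80) for _ in range(nch)),
        b"".join(pad(str(spr), 8) for _ in range(nch)),
        b"".join(pad("", 32) for _ in range(nch)),
    ])
    records = digital.reshape(n_records, spr, nch).transpose(0, 2, 1)
    Path(path).write_bytes(header + sig + records.tobytes())


# -- image databases --------------------------------------------------------

def save_database(db: ImageDatabase, directory: str | Path) -> None:
    """One CSV per feature space plus an ``id,label`` table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, feat in db.features.items():
        pd.DataFrame(feat).to_csv(directory / f"features_{name}.csv",
                                  index=False, float_format="%.10g")
    pd.DataFrame({"id": db.ids, "label": db.labels}).to_csv(
        directory / "labels.csv", index=False)


def load_database(directory: str | Path) -> ImageDatabase:
    directory = Path(directory)
    lab = pd.read_csv(directory / "labels.csv")
    features = {}
    for f in sorted(directory.glob("features_*.csv")):
        name = f.stem[len("features_"):]
        features[name] = pd.read_csv(f).to_numpy(dtype=np.float64)
    if not features:
        raise FileNotFoundError(f"no features_*.csv under {directory}")
    return ImageDatabase(ids=lab["id"].to_numpy(),
                         features=features,
                         labels=lab["label"].to_numpy())


# -- run logs ---------------------------------------------------------------

def write_run_log(state, path: str | Path, seed: int | None = None,
                  extra_per_iteration: list[dict] | None = None) -> None:
    """JSON-lines log, one record per completed iteration."""
    with open(path, "w") as fh:
        for it in range(state.n_iterations_done):
            rec = {
                "iteration": it,
                "presented": state.presented[it].tolist(),
                "eeg_hard": state.eeg_hard[it].tolist(),
                "eeg_soft": [round(float(s), 8) for s in state.eeg_soft[it]],
                "seed": seed,
            }
            if extra_per_iteration is not None:
                rec.update(extra_per_iteration[it])
            fh.write(json.dumps(rec) + "\n")


def read_run_log(path: str | Path) -> list[dict]:
    """Parse a run log; a malformed line raises with its line number."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                if "iteration" not in rec:
                    raise ValueError("missing 'iteration' key")
            except (json.JSONDecodeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed log line: {exc}"
                                 ) from exc
            records.append(rec)
    return records


def write_metrics_table(rows: list[dict], path: str | Path) -> None:
    """Flat delimited metric table: run, iteration, metric, value."""
    pd.DataFrame(rows, columns=["run", "iteration", "metric", "value"]).to_csv(
        path, index=False)


# -- run configuration ------------------------------------------------------

_KNOWN_KEYS = {
    "database_dir", "recording", "events", "eog_recording",
    "channels", "eog_correction", "target_class",
    "n_prototypes", "covariance", "dp_threshold", "n_folds",
    "k_neighbors", "n_iterations", "sequence_size", "top_n_next",
    "top_n_retrieved", "initial_target_fraction", "variant",
    "labeler_auc", "output_dir", "seed",
}

_PATH_KEYS = ("database_dir", "recording", "events", "eog_recording")


@dataclass
class RunConfig:
    """One YAML/JSON file drives a whole run; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).parent
        for key in _PATH_KEYS:
            if key in raw and raw[key] is not None:
                p = Path(raw[key])
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"config key {key!r}: {p} not found")
                raw[key] = str(p)
        return cls(values=raw)

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    def digest(self) -> str:
        """Stable hash of the configuration, logged for provenance."""
        blob = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# -- graphs -----------------------------------------------------------------

def save_graph(graph, edges_path: str | Path, labels_path: str | Path) -> None:
    """Edge-list export: ``i, j, weight, space`` plus an ``id,label`` table.

    Each undirected arc is written once (i < j by node index order).
    """
    from scipy import sparse as _sparse

    W = _sparse.triu(graph.weights, k=1).tocoo()
    ids = graph.node_ids
    df = pd.DataFrame({
        "i": ids[W.row], "j": ids[W.col],
        "weight": W.data, "space": graph.space,
    })
    df.to_csv(edges_path, index=False, float_format="%.12g")
    lab = pd.DataFrame(
        {"id": ids, "label": [graph.labels.get(int(i), "") for i in ids]})
    lab.to_csv(labels_path, index=False)


def load_graph(edges_path: str | Path, labels_path: str | Path):
    """Read a graph written by :func:`save_graph`."""
    from scipy import sparse as _sparse

    from .propagation import LabeledGraph

    lab = pd.read_csv(labels_path)
    ids = lab["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    edges = pd.read_csv(edges_path)
    rows = [pos[int(i)] for i in edges["i"]]
    cols = [pos[int(j)] for j in edges["j"]]
    w = edges["weight"].to_numpy(dtype=float)
    n = len(ids)
    W = _sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)
    labels = {int(i): int(v) for i, v in zip(lab["id"], lab["label"])
              if str(v) not in ("", "nan")}
    space = str(edges["space"].iloc[0]) if len(edges) else "joint"
    return LabeledGraph(node_ids=ids, weights=W, labels=labels, space=space)
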