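"""Readers and writers: CSV/TSV multichannel files with a JSON/YAML sidecar.

Format contract
---------------
Signals are stored as delimited text, one column per channel, mandatory
header row, ``.`` decimal.  A sidecar (JSON or YAML) declares the sampling
rate and the kind of every column::

    {"rate": 1000, "start_time": 0.0,
     "channels": {"LegL": "emg", "LegR": "emg", "EKG": "ekg", "Resp": "resp"}}

Every writer output is re-parseable by the readers in this module.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .config import get_logger
from .recording import ChannelKind, Recording

__all__ = [
    "read_recording",
    "write_recordings",
    "read_sidecar",
    "coupling_matrix_to_csv",
    "coupling_matrix_from_csv",
    "write_outputs",
]

log = get_logger(__name__)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_sidecar(path: str | Path) -> dict:
    """Read a JSON or YAML metadata sidecar into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _find_sidecar(data_path: Path) -> Path:
    for suffix in (".json", ".yaml", ".yml"):
        cand = data_path.with_suffix(suffix)
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"no metadata sidecar (.json/.yaml) found next to {data_path}"
    )


def read_recording(path: str | Path, meta: str | Path | dict | None = None) -> list[Recording]:
    """Read a delimited multichannel file into one :class:`Recording` per column.

    Parameters
    ----------
    path : path
        CSV (or TSV, by extension) file with a header row.
    meta : path, dict or None
        Sidecar path or inline metadata dict.  When None, a sidecar with the
        same stem and a ``.json``/``.yaml`` suffix is looked up next to the file.

    Raises
    ------
    ValueError
        If a column contains missing/NaN cells or is not declared in the
        metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if meta is None:
        meta = _find_sidecar(path)
    if not isinstance(meta, dict):
        meta = read_sidecar(meta)
    if "rate" not in meta or "channels" not in meta:
        raise ValueError("metadata must declare 'rate' and per-column 'channels'")
    rate = float(meta["rate"])
    channels: dict[str, str] = dict(meta["channels"])
    start_time = float(meta.get("start_time", 0.0))

    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")

    recs: list[Recording] = []
    for col in frame.columns:
        if col not in channels:
            raise ValueError(f"column {col!r} in {path.name} is not declared in the metadata")
        values = frame[col].to_numpy(dtype=float)
        if np.isnan(values).any():
            row = int(np.flatnonzero(np.isnan(values))[0])
            raise ValueError(f"missing/NaN sample in column {col!r} at row {row}")
        recs.append(Recording(channel_id=col, kind=ChannelKind(channels[col]),
                              samples=values, rate=rate, start_time=start_time))
    missing = set(channels) - set(frame.columns)
    if missing:
        raise ValueError(f"declared channels absent from {path.name}: {sorted(missing)}")
    return recs


def write_recordings(recs: list[Recording], path: str | Path) -> Path:
    """Write recordings (equal length and rate) as CSV + JSON sidecar.

    Returns the data-file path; the sidecar is written next to it.
    """
    path = Path(path)
    if not recs:
        raise ValueError("nothing to write")
    rate = recs[0].rate
    n = recs[0].n_samples
    for r in recs:
        if r.rate != rate or r.n_samples != n:
            raise ValueError("all channels of one file must share rate and length")
    frame = pd.DataFrame({r.channel_id: r.samples for r in recs})
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "rate": rate,
        "start_time": recs[0].start_time,
        "channels": {r.channel_id: r.kind.value for r in recs},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def coupling_matrix_to_csv(matrix, path: str | Path) -> Path:
    """Write a CouplingMatrix as labelled CSV (band labels as row/col headers)."""
    path = Path(path)
    frame = pd.DataFrame(matrix.values, index=matrix.row_labels, columns=matrix.col_labels)
    frame.to_csv(path, float_format="%.17g")
    return path


def coupling_matrix_from_csv(path: str | Path):
    """Read a labelled matrix CSV back into (row_labels, col_labels, values)."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return list(frame.index), list(frame.columns), frame.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# result bundles
# ---------------------------------------------------------------------------

def _network_to_json(network, path: Path) -> None:
    payload = {
        "nodes": [{"system": s, "band": b} for s, b in network.nodes],
        "links": [
            {
                "source_system": l.source[0], "source_band": l.source[1],
                "target_system": l.target[0], "target_band": l.target[1],
                "strength": l.strength, "class": l.class_label,
                "significant": l.significant,
            }
            for l in network.links
        ],
        "class_thresholds": list(network.class_thresholds),
    }
    path.write_text(json.dumps(payload, indent=1))


def write_outputs(bundle: dict, out_dir: str | Path, overwrite: bool = False) -> list[dict]:
    """Write an analysis bundle to ``out_dir`` and return the file manifest.

    ``bundle`` maps stage names to results; recognised value types are
    CouplingMatrix, NetworkMap, pandas DataFrames (tidy stats/series) and
    plain dicts (written as JSON).  The manifest (also written as
    ``manifest.json``) lists every file with its stage provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def _target(name: str) -> Path:
        p = out_dir / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        return p

    for stage, obj in bundle.items():
        # avoid importing coupling module at import time: duck-type on attributes
        if hasattr(obj, "row_labels") and hasattr(obj, "values"):
            p = coupling_matrix_to_csv(obj, _target(f"{stage}.csv"))
            manifest.append({"file": p.name, "stage": stage, "kind": "coupling_matrix"})
        elif hasattr(obj, "links") and hasattr(obj, "nodes"):
            gml = _target(f"{stage}.graphml")
            nx.write_graphml(obj.to_networkx(), gml)
            manifest.append({"file": gml.name, "stage": stage, "kind": "network_graphml"})
            js = _target(f"{stage}.json")
            _network_to_json(obj, js)
            manifest.append({"file": js.name, "stage": stage, "kind": "network_json"})
        elif isinstance(obj, pd.DataFrame):
            p = _target(f"{stage}.csv")
            obj.to_csv(p, index=False, float_format="%.17g")
            manifest.append({"file": p.name, "stage": stage, "kind": "table"})
        elif isinstance(obj, dict):
            p = _target(f"{stage}.json")
            p.write_text(json.dumps(obj, indent=1, default=float))
            manifest.append({"file": p.name, "stage": stage, "kind": "json"})
        else:
            raise TypeError(f"stage {stage!r}: unsupported bundle value type {type(obj)!r}")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("wrote %d files to %s", len(manifest), out_dir)
    return manifest
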