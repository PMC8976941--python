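"""Dataset container I/O.

Datasets are stored as a single HDF5 file: one group per recording holding
the sample array plus its metadata as attributes, with the index table and
optional ground-truth table embedded as CSV strings.  A per-recording
SHA-256 over samples-plus-metadata, verified on read, guards against silent
corruption, and a format-version attribute guards against reading files
written by an incompatible layout.  A human-auditable CSV sidecar index
(`<path>.index.csv`) is written next to the container.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DatasetVersionError, IntegrityError
from .protocols import StimulusSpec
from .synthetic_data import ERGDataset, Recording, TreatmentCondition

__all__ = ["write_dataset", "read_dataset", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _recording_digest(samples: np.ndarray, meta: dict) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(samples, dtype=np.float64).tobytes())
    h.update(json.dumps(meta, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _meta_dict(r: Recording) -> dict:
    return {
        "fs": r.fs,
        "crab_id": r.crab_id,
        "sex": r.sex,
        "carapace_width": r.carapace_width,
        "adaptation": r.condition.adaptation,
        "time_of_day": r.condition.time_of_day,
        "probe_time": None if r.probe_time is None else float(r.probe_time),
        "seed_used": r.seed_used,
        "stim_on_intensity": r.stimulus.on_intensity,
        "stim_frequency": r.stimulus.frequency,
        "stim_duty": r.stimulus.duty,
        "stim_duration": r.stimulus.duration,
        "stim_nd_layers": r.stimulus.nd_layers,
        "stim_label": r.stimulus.label,
    }


def write_dataset(dataset: ERGDataset, path: str | Path) -> Path:
    """Write a dataset container (and its CSV sidecar index); returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_recordings"] = len(dataset)
        f.attrs["dataset_attrs"] = json.dumps(dataset.attrs, default=str)
        grp = f.create_group("recordings")
        for i, r in enumerate(dataset.recordings):
            rid = r.recording_id or f"rec{i:04d}"
            g = grp.create_group(rid)
            g.create_dataset("samples", data=np.asarray(r.samples, dtype=np.float64))
            meta = _meta_dict(r)
            g.attrs["meta"] = json.dumps(meta, default=str)
            g.attrs["sha256"] = _recording_digest(r.samples, meta)
        f.attrs["index_csv"] = dataset.meta.to_csv(index=False)
        if dataset.truth is not None:
            f.attrs["truth_csv"] = dataset.truth.to_csv(index=False)
    dataset.meta.to_csv(path.with_suffix(path.suffix + ".index.csv"), index=False)
    return path


def read_dataset(path: str | Path) -> ERGDataset:
    """Read a dataset container, verifying format version and checksums.

    Raises `DatasetVersionError` on a version mismatch and `IntegrityError`
    on checksum failure or a structurally damaged file; nothing is partially
    loaded on failure.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise DatasetVersionError(
                    f"file format version {version}; this build reads {FORMAT_VERSION}"
                )
            recordings = []
            for rid in sorted(f["recordings"].keys()):
                g = f["recordings"][rid]
                samples = np.asarray(g["samples"][...], dtype=np.float64)
                meta = json.loads(g.attrs["meta"])
                if _recording_digest(samples, meta) != g.attrs["sha256"]:
                    raise IntegrityError(f"checksum mismatch for recording {rid!r}")
                stim = StimulusSpec(
                    on_intensity=meta["stim_on_intensity"],
                    frequency=meta["stim_frequency"],
                    duty=meta["stim_duty"],
                    duration=meta["stim_duration"],
                    nd_layers=meta["stim_nd_layers"],
                    label=meta["stim_label"],
                )
                recordings.append(
                    Recording(
                        samples=samples,
                        fs=meta["fs"],
                        stimulus=stim,
                        crab_id=meta["crab_id"],
                        sex=meta["sex"],
                        carapace_width=meta["carapace_width"],
                        condition=TreatmentCondition(
                            meta["adaptation"], meta["time_of_day"]
                        ),
                        probe_time=meta["probe_time"],
                        seed_used=meta["seed_used"],
                        recording_id=rid,
                    )
                )
            try:
                meta_df = pd.read_csv(_io.StringIO(str(f.attrs["index_csv"])))
            except pd.errors.EmptyDataError:
                meta_df = pd.DataFrame()
            truth = None
            if "truth_csv" in f.attrs:
                truth = pd.read_csv(_io.StringIO(str(f.attrs["truth_csv"])))
            attrs = json.loads(str(f.attrs.get("dataset_attrs", "{}")))
    except (DatasetVersionError, IntegrityError):
        raise
    except (OSError, KeyError) as e:
        raise IntegrityError(f"cannot read dataset {path}: {e}") from e
    return ERGDataset(recordings=recordings, meta=meta_df, truth=truth, attrs=attrs)
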