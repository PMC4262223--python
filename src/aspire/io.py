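"""Reading, writing and preprocessing of event data.

Samples arrive as delimited text (CSV/TSV with a header row of channel
names) or FCS files.  Preprocessing follows cytometry convention: selected
fluorescence channels are log-transformed (scatter channels usually stay
linear) and every channel is standardized to unit variance, by default
pooled across the whole batch so that between-sample location differences
survive standardization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._fcs import read_fcs, write_fcs
from .data import EventMatrix, check_batch


@dataclass(eq=False)
class ManifestEntry:
    sample_id: str
    path: str
    format: str = "csv"
    label: str = "unknown"            # normal | anomalous | unknown
    subject: str = ""
    tube: str = ""


@dataclass(eq=False)
class BatchManifest:
    """List of samples with file locations and optional labels."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in manifest")

    @classmethod
    def read(cls, path: str | Path) -> "BatchManifest":
        df = pd.read_csv(path, dtype=str).fillna("")
        if "sample_id" not in df.columns or "path" not in df.columns:
            raise ValueError("manifest needs 'sample_id' and 'path' columns")
        entries = [ManifestEntry(
            sample_id=row["sample_id"], path=row["path"],
            format=row.get("format", "") or _infer_format(row["path"]),
            label=row.get("label", "") or "unknown",
            subject=row.get("subject", ""), tube=row.get("tube", ""),
        ) for _, row in df.iterrows()]
        return cls(entries)

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "path", "format", "label",
                        "subject", "tube"])
            for e in self.entries:
                w.writerow([e.sample_id, e.path, e.format, e.label,
                            e.subject, e.tube])

    def load_batch(self, channel_selection=None,
                   base_dir: str | Path | None = None) -> list[EventMatrix]:
        batch = []
        for e in self.entries:
            p = Path(e.path)
            if base_dir is not None and not p.is_absolute():
                p = Path(base_dir) / p
            batch.append(read_sample(p, e.format, channel_selection,
                                     sample_id=e.sample_id))
        check_batch(batch)
        return batch


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".fcs": "fcs"}.get(
        suffix, "csv")


def read_sample(path: str | Path, format: str | None = None,
                channel_selection=None,
                sample_id: str | None = None) -> EventMatrix:
    """Read one sample from CSV, TSV or FCS into an :class:`EventMatrix`.

    ``channel_selection`` restricts (and orders) the columns by channel
    name.  Raises distinct errors for a missing file, an empty file, a
    missing channel and non-numeric cells.
    """
    path = Path(path)
    fmt = (format or _infer_format(path)).lower()
    if not path.exists():
        raise FileNotFoundError(f"sample file not found: {path}")
    sid = sample_id if sample_id is not None else path.stem
    if fmt == "fcs":
        data, channels = read_fcs(str(path))
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{path}: file is empty") from exc
        if df.shape[0] == 0:
            raise ValueError(f"{path}: file contains no events")
        channels = [str(c) for c in df.columns]
        try:
            data = df.to_numpy(dtype=np.float64)
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"{path}: non-numeric cell in event data ({exc})") from exc
    else:
        raise ValueError(f"unknown sample format {fmt!r}")
    if channel_selection is not None:
        missing = [c for c in channel_selection if c not in channels]
        if missing:
            raise KeyError(
                f"{path}: channel(s) {missing} not present; available: "
                f"{channels}")
        idx = [channels.index(c) for c in channel_selection]
        data = data[:, idx]
        channels = list(channel_selection)
    return EventMatrix(sample_id=sid, data=data, channels=channels)


def write_sample(sample: EventMatrix, path: str | Path,
                 format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or _infer_format(path)).lower()
    if fmt == "fcs":
        write_fcs(str(path), sample.data, sample.channels)
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(sample.data, columns=sample.channels).to_csv(
            path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown sample format {fmt!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class PreprocessSpec:
    """What to do to a batch before clustering.

    ``log_transform_channels`` lists channels mapped ``x -> log(x + shift)``
    with a per-channel nonnegativity shift (0 for an all-positive channel,
    otherwise ``1 - min(x)`` so the minimum maps to ``log(1) = 0``).
    ``standardize`` divides each channel by its standard deviation, pooled
    across the batch by default or per sample with ``per_sample``.
    ``subsample`` takes a fraction in (0, 1] or an event count per sample.
    """

    log_transform_channels: tuple[str, ...] = ()
    standardize: bool = True
    per_sample: bool = False
    subsample: float | int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsample is not None:
            if isinstance(self.subsample, float) and not 0 < self.subsample <= 1:
                raise ValueError("subsample fraction must lie in (0, 1]")
            if isinstance(self.subsample, int) and self.subsample < 1:
                raise ValueError("subsample count must be >= 1")


@dataclass(eq=False)
class PreprocessParams:
    """Fitted transformation parameters, reusable on new data."""

    shifts: dict[str, float]
    scales: dict[str, float]
    log_channels: tuple[str, ...]


def preprocess(batch: list[EventMatrix], spec: PreprocessSpec,
               params: PreprocessParams | None = None
               ) -> tuple[list[EventMatrix], PreprocessParams]:
    """Log-transform and standardize a batch.

    Returns the transformed batch and the fitted parameters; passing the
    parameters back in reproduces the same transform on new data.
    Raises if a requested channel is missing or has zero variance.
    """
    check_batch(batch)
    channels = batch[0].channels
    for ch in spec.log_transform_channels:
        if ch not in channels:
            raise KeyError(f"log-transform channel {ch!r} not in batch "
                           f"channels {channels}")
    if params is None:
        shifts = {}
        for ch in spec.log_transform_channels:
            col = np.concatenate([s.data[:, channels.index(ch)]
                                  for s in batch])
            mn = float(col.min())
            shifts[ch] = 0.0 if mn > 0 else 1.0 - mn
    else:
        shifts = dict(params.shifts)
    logged = []
    for s in batch:
        data = s.data.copy()
        for ch in spec.log_transform_channels:
            ci = channels.index(ch)
            data[:, ci] = np.log(data[:, ci] + shifts[ch])
        logged.append(EventMatrix(s.sample_id, data, list(channels)))
    if spec.standardize:
        if params is None:
            scales = {}
            pooled = np.concatenate([s.data for s in logged])
            for ci, ch in enumerate(channels):
                sd = float(pooled[:, ci].std())
                if sd == 0:
                    raise ValueError(f"channel {ch!r} has zero variance")
                scales[ch] = sd
        else:
            scales = dict(params.scales)
        out = []
        for s in logged:
            data = s.data.copy()
            if spec.per_sample and params is None:
                for ci, ch in enumerate(channels):
                    sd = float(data[:, ci].std())
                    if sd == 0:
                        raise ValueError(
                            f"channel {ch!r} has zero variance in sample "
                            f"{s.sample_id!r}")
                    data[:, ci] /= sd
            else:
                for ci, ch in enumerate(channels):
                    data[:, ci] /= scales[ch]
            out.append(EventMatrix(s.sample_id, data, list(channels)))
    else:
        scales = {ch: 1.0 for ch in channels}
        out = logged
    return out, PreprocessParams(shifts=shifts, scales=scales,
                                 log_channels=tuple(spec.log_transform_channels))


def subsample(batch: list[EventMatrix], spec: PreprocessSpec
              ) -> list[EventMatrix]:
    """Uniform per-sample subsample without replacement, seeded.

    A float ``spec.subsample`` is a fraction of each sample's events, an
    int an absolute count (error if it exceeds a sample's size).
    """
    if spec.subsample is None:
        return list(batch)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(batch))
    out = []
    for child, s in zip(children, batch):
        rng = np.random.default_rng(child)
        if isinstance(spec.subsample, float):
            k = int(round(spec.subsample * s.n_events))
            k = max(k, 1)
        else:
            k = int(spec.subsample)
            if k > s.n_events:
                raise ValueError(
                    f"cannot draw {k} events from sample {s.sample_id!r} "
                    f"holding {s.n_events}")
        idx = np.sort(rng.choice(s.n_events, size=k, replace=False))
        out.append(EventMatrix(s.sample_id, s.data[idx], list(s.channels)))
    return out
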