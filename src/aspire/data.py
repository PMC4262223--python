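"""Event-matrix container shared by every stage of the pipeline.

A flow-cytometry *sample* is a matrix of events (cells) by channels
(fluorescence / scatter measurements).  A *batch* is simply a list of
:class:`EventMatrix` objects sharing the same channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EventMatrix:
    """One sample's cells-by-channels real matrix.

    Parameters
    ----------
    sample_id
        Unique identifier of the sample within its batch.
    data
        Array of shape ``(n_events, n_channels)``; coerced to float64.
    channels
        Channel names, one per column.  Defaults to ``ch0, ch1, ...``.
    """

    sample_id: str
    data: np.ndarray
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(np.asarray(self.data, dtype=np.float64))
        if self.data.ndim != 2:
            raise ValueError(
                f"sample {self.sample_id!r}: event data must be 2-D, "
                f"got shape {self.data.shape}"
            )
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"sample {self.sample_id!r}: {len(self.channels)} channel names "
                f"for {self.data.shape[1]} columns"
            )

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]


def check_batch(batch: list[EventMatrix]) -> int:
    """Validate a batch and return its common dimensionality."""
    if not batch:
        raise ValueError("batch is empty")
    d = batch[0].dim
    for s in batch[1:]:
        if s.dim != d:
            raise ValueError(
                f"mismatched dimensions across samples: {batch[0].sample_id!r} "
                f"has {d} channels but {s.sample_id!r} has {s.dim}"
            )
    ids = [s.sample_id for s in batch]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in batch")
    return d


def pooled_data(batch: list[EventMatrix]) -> np.ndarray:
    """Concatenate all samples' events into one array."""
    check_batch(batch)
    return np.concatenate([s.data for s in batch], axis=0)
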