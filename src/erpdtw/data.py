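"""In-memory container for labelled multichannel ERP epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS = ("Related", "Unrelated")

#: 10-20-system channel ordering used for full-montage datasets (30 scalp
#: electrodes plus raw and corrected EOG derivations).
CHANNELS_35 = [
    "FP1", "F3", "F7", "FC3", "C3", "C5", "P3", "P7", "PO7", "PO3", "O1",
    "Oz", "Pz", "CPz", "FP2", "Fz", "F4", "F8", "FC4", "FCz", "Cz", "C4",
    "C6", "P4", "P8", "PO8", "PO4", "O2", "HEOG_left", "HEOG_right",
    "VEOG_lower", "(corr)HEOG", "(corr)VEOG", "(uncorr)HEOG", "(uncorr)VEOG",
]


class SchemaError(ValueError):
    """Raised when stored or supplied epoch data violates the schema."""


@dataclass
class EpochDataset:
    """Ordered collection of fixed-length epochs with per-trial metadata.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_samples, n_channels)
        Trial matrices; each row of a trial is one time sample.
    subject_ids : ndarray of str, shape (n_trials,)
    labels : ndarray of str, shape (n_trials,)
        Each entry one of ``{"Related", "Unrelated"}``.
    trial_ids : ndarray of int, shape (n_trials,)
    channel_names : list of str, length n_channels
    sfreq : float
        Sampling rate in Hz; sample ``s`` is at time ``s / sfreq`` seconds
        post-stimulus (0-based, no pre-stimulus baseline).
    """

    data: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    channel_names: list = field(default_factory=list)
    sfreq: float = 256.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=str)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        if self.data.ndim != 3:
            raise SchemaError(
                f"data must be (n_trials, n_samples, n_channels), got {self.data.shape}"
            )
        n = self.data.shape[0]
        for name, arr in (("subject_ids", self.subject_ids),
                          ("labels", self.labels),
                          ("trial_ids", self.trial_ids)):
            if arr.shape != (n,):
                raise SchemaError(f"{name} must have length {n}, got {arr.shape}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[2])]
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[2]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[2]}-channel data"
            )
        bad = set(np.unique(self.labels)) - set(LABELS) if n else set()
        if bad:
            raise SchemaError(f"unknown labels {sorted(bad)}; expected {LABELS}")
        if n and not np.all(np.isfinite(self.data)):
            raise SchemaError("epoch data contains non-finite values")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "EpochDataset":
        """Subset by boolean mask or index array (metadata carried along)."""
        idx = np.asarray(mask)
        if idx.size == 0:
            idx = idx.astype(np.int64)
        return EpochDataset(
            data=self.data[idx],
            subject_ids=self.subject_ids[idx],
            labels=self.labels[idx],
            trial_ids=self.trial_ids[idx],
            channel_names=list(self.channel_names),
            sfreq=self.sfreq,
        )

    def copy(self) -> "EpochDataset":
        return EpochDataset(
            data=self.data.copy(),
            subject_ids=self.subject_ids.copy(),
            labels=self.labels.copy(),
            trial_ids=self.trial_ids.copy(),
            channel_names=list(self.channel_names),
            sfreq=self.sfreq,
        )

    def equals(self, other: "EpochDataset", rtol=0.0, atol=0.0) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.data, other.data, rtol=rtol, atol=atol)
            and np.array_equal(self.subject_ids, other.subject_ids)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.trial_ids, other.trial_ids)
            and self.channel_names == other.channel_names
            and self.sfreq == other.sfreq
        )
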