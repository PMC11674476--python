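"""Core in-memory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialSet", "SampleBatch"]


@dataclass
class TrialSet:
    """Labelled multichannel EEG trials.

    trials   : list of (n_channels, n_time) float arrays (lengths may differ)
    labels   : (n_trials,) int array, or (n_trials, 3) in VAD-triple mode
               (valence / arousal / dominance, each already 0-based)
    subject_id : (n_trials,) int array
    clip_id  : (n_trials,) int array; (subject_id, clip_id) pairs are unique
    """

    trials: list
    labels: np.ndarray
    subject_id: np.ndarray
    clip_id: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.subject_id = np.asarray(self.subject_id)
        self.clip_id = np.asarray(self.clip_id)
        n = len(self.trials)
        if not (len(self.labels) == len(self.subject_id) == len(self.clip_id) == n):
            raise ValueError("trials, labels, subject_id, clip_id must align")
        if n:
            c0 = self.trials[0].shape[0]
            if any(t.shape[0] != c0 for t in self.trials):
                raise ValueError("all trials must share the same channel count")
        pairs = set(zip(self.subject_id.tolist(), self.clip_id.tolist()))
        if len(pairs) != n:
            raise ValueError("(subject_id, clip_id) pairs must be unique")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0] if self.trials else 0

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_id)

    def select(self, mask) -> "TrialSet":
        """Sub-TrialSet for a boolean mask or index array over trials."""
        idx = np.arange(self.n_trials)[mask]
        return TrialSet(
            trials=[self.trials[i] for i in idx],
            labels=self.labels[idx],
            subject_id=self.subject_id[idx],
            clip_id=self.clip_id[idx],
        )


@dataclass
class SampleBatch:
    """Model-ready samples.

    x : (n_samples, seq_len, n_features) float array; the default
        per-timepoint sampling gives seq_len = n_channels, n_features = 1.
    y : (n_samples,) int class labels
    subject_id : (n_samples,) int array
    """

    x: np.ndarray
    y: np.ndarray
    subject_id: np.ndarray = field(default=None)

    def __post_init__(self):
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y)
        if self.x.ndim != 3:
            raise ValueError("x must be (n_samples, seq_len, n_features)")
        if self.subject_id is None:
            self.subject_id = np.zeros(len(self.y), dtype=int)
        self.subject_id = np.asarray(self.subject_id)
        if not (len(self.x) == len(self.y) == len(self.subject_id)):
            raise ValueError("x, y, subject_id must align")
        if not np.isfinite(self.x).all():
            raise ValueError("x contains non-finite values")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_classes_seen(self) -> int:
        return int(self.y.max()) + 1 if len(self.y) else 0

    def take(self, idx) -> "SampleBatch":
        idx = np.asarray(idx)
        return SampleBatch(self.x[idx], self.y[idx], self.subject_id[idx])
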