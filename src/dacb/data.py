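"""Loading, sampling, normalization and splitting of EEG trials.

The sampling convention follows the per-timepoint reading of the corpora:
a 1000-column middle segment of every trial is cut out, and **each column**
(one instantaneous channel vector) becomes one training sample of shape
``(n_channels, 1)``.  SEED-IV-shaped data therefore yields
15 x 24 x 1000 = 360,000 samples.  An optional sliding-window sample shape
(``window_length`` > 1) is provided for sanity experiments.

Splits come in two flavours: a subject-wise hold-out (whole subjects on one
side, preventing identity leakage) and seeded k-fold over samples.  K-fold
can shuffle raw samples (adjacent timepoints of one trial may then straddle
the train/test boundary) or keep trials grouped; both are exposed because
the two protocols answer different questions about generalization.
"""

from __future__ import annotations

import pathlib
import re
from dataclasses import dataclass

import h5py
import numpy as np

from .containers import SampleBatch, TrialSet

__all__ = [
    "read_trials",
    "extract_middle_segment",
    "slice_timepoint_samples",
    "normalize",
    "NormStats",
    "encode_labels",
    "SEEDIV_CLASS_TO_INT",
    "subject_split",
    "SubjectSplitPlan",
    "kfold_indices",
    "KFoldPlan",
]

SEEDIV_CLASS_TO_INT = {"neutral": 0, "sad": 1, "fear": 2, "happy": 3}


# ---------------------------------------------------------------------------
# readers


def read_trials(path, layout: str) -> TrialSet:
    """Load a :class:`TrialSet` from disk.

    layout:
      * ``synthetic_h5`` — directory of ``subject_XX.h5`` files written by
        :func:`dacb.synthetic.save_trialset_h5`
      * ``seediv_mat``   — directory of per-subject MAT files, each holding
        trial variables named ``<prefix>_eeg<k>`` (62 x time), plus a
        ``label.mat`` with variable ``label`` (one class per clip)
      * ``dreamer_mat``  — directory containing ``DREAMER.mat`` with the
        published ``DREAMER.Data{i}.EEG.stimuli`` struct; labels are the raw
        1-5 valence/arousal/dominance ratings, one triple per trial
    """
    path = pathlib.Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    if layout == "synthetic_h5":
        return _read_synthetic_h5(path)
    if layout == "seediv_mat":
        return _read_seediv_mat(path)
    if layout == "dreamer_mat":
        return _read_dreamer_mat(path)
    raise ValueError(f"unknown layout {layout!r}")


def _read_synthetic_h5(path) -> TrialSet:
    files = sorted(path.glob("subject_*.h5"))
    if not files:
        raise FileNotFoundError(
            f"no 'subject_*.h5' files found in {path}; expected the layout "
            "written by dacb.synthetic.save_trialset_h5"
        )
    trials, labels, subj, clip = [], [], [], []
    n_channels = None
    for f in files:
        with h5py.File(f, "r") as h:
            for key in ("eeg", "labels", "clip_id"):
                if key not in h:
                    raise OSError(f"{f}: missing dataset {key!r}")
            eeg = h["eeg"][...]
            if n_channels is None:
                n_channels = eeg.shape[1]
            elif eeg.shape[1] != n_channels:
                raise ValueError(
                    f"{f}: channel count {eeg.shape[1]} != {n_channels} seen earlier"
                )
            sid = int(h.attrs["subject_id"])
            lab = h["labels"][...]
            cid = h["clip_id"][...]
        trials.extend(list(eeg))
        labels.extend(list(lab))
        subj.extend([sid] * len(eeg))
        clip.extend(list(cid))
    return TrialSet(trials, np.asarray(labels), np.asarray(subj), np.asarray(clip))


_EEG_VAR = re.compile(r"^(?P<prefix>.+)_eeg(?P<num>\d+)$")


def _read_seediv_mat(path) -> TrialSet:
    from scipy.io import loadmat

    files = sorted(p for p in path.glob("*.mat") if p.name != "label.mat")
    if not files:
        raise FileNotFoundError(
            f"no subject '*.mat' files in {path}; expected per-subject files "
            "with '<prefix>_eeg<k>' variables and a 'label.mat'"
        )
    label_file = path / "label.mat"
    if not label_file.exists():
        raise FileNotFoundError(f"missing {label_file} (variable 'label', one class per clip)")
    labels_per_clip = np.ravel(_load_mat_any(label_file)["label"]).astype(int)

    trials, labels, subj, clip = [], [], [], []
    n_channels = None
    for si, f in enumerate(files):
        mat = _load_mat_any(f)
        keyed = {}
        for name, val in mat.items():
            m = _EEG_VAR.match(name)
            if m:
                keyed[int(m.group("num"))] = np.asarray(val)
        if not keyed:
            raise OSError(f"{f}: no '<prefix>_eeg<k>' trial variables found")
        for k in sorted(keyed):
            arr = keyed[k]
            if n_channels is None:
                n_channels = arr.shape[0]
            elif arr.shape[0] != n_channels:
                raise ValueError(f"{f}: trial eeg{k} has {arr.shape[0]} channels, expected {n_channels}")
            if k - 1 >= len(labels_per_clip):
                raise ValueError(f"{f}: clip index {k} exceeds label list length {len(labels_per_clip)}")
            trials.append(arr.astype(float))
            labels.append(labels_per_clip[k - 1])
            subj.append(si)
            clip.append(k - 1)
    return TrialSet(trials, np.asarray(labels), np.asarray(subj), np.asarray(clip))


def _load_mat_any(f):
    """MAT reader accepting both classic (v7) and HDF5-based (v7.3) files."""
    from scipy.io import loadmat

    try:
        return loadmat(f, squeeze_me=True)
    except NotImplementedError:
        out = {}
        with h5py.File(f, "r") as h:
            for k in h:
                v = h[k]
                if isinstance(v, h5py.Dataset):
                    # MATLAB v7.3 stores arrays transposed
                    out[k] = np.asarray(v[...]).T
        return out
    except Exception as e:  # unreadable container
        raise OSError(f"cannot read MAT file {f}: {e}") from e


def _read_dreamer_mat(path) -> TrialSet:
    from scipy.io import loadmat

    f = path / "DREAMER.mat"
    if not f.exists():
        raise FileNotFoundError(f"missing {f} (the published DREAMER bundle)")
    try:
        mat = loadmat(f, squeeze_me=True, struct_as_record=False)
    except Exception as e:
        raise OSError(f"cannot read MAT file {f}: {e}") from e
    if "DREAMER" not in mat:
        raise OSError(f"{f}: missing top-level 'DREAMER' struct")
    root = mat["DREAMER"]
    data = np.atleast_1d(root.Data)
    trials, labels, subj, clip = [], [], [], []
    for si, rec in enumerate(data):
        stimuli = np.atleast_1d(rec.EEG.stimuli)
        val = np.ravel(rec.ScoreValence).astype(int)
        aro = np.ravel(rec.ScoreArousal).astype(int)
        dom = np.ravel(rec.ScoreDominance).astype(int)
        for ti, arr in enumerate(stimuli):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"{f}: subject {si} stimulus {ti} is not 2-D")
            if arr.shape[0] > arr.shape[1]:  # stored time x channels
                arr = arr.T
            trials.append(arr)
            labels.append([val[ti], aro[ti], dom[ti]])
            subj.append(si)
            clip.append(ti)
    return TrialSet(trials, np.asarray(labels), np.asarray(subj), np.asarray(clip))


# ---------------------------------------------------------------------------
# sampling


def extract_middle_segment(trial: np.ndarray, n: int = 1000) -> np.ndarray:
    """Central ``n`` columns of a (channels x time) trial (floor centering)."""
    trial = np.asarray(trial)
    L = trial.shape[1]
    if L < n:
        raise ValueError(f"trial length {L} < segment length {n}")
    start = (L - n) // 2
    return trial[:, start : start + n]


def slice_timepoint_samples(
    ts: TrialSet,
    label_dim: int = None,
    window_length: int = 1,
) -> SampleBatch:
    """Turn equal-length segments into model samples.

    Default (``window_length=1``): every timepoint is one sample of shape
    ``(n_channels, 1)`` inheriting its trial's label and subject; total
    sample count is ``n_trials * segment_length``.  With
    ``window_length=w>1``, non-overlapping windows of ``w`` consecutive
    timepoints become samples of shape ``(w, n_channels)``.

    ``label_dim`` selects the rating dimension (0=valence, 1=arousal,
    2=dominance) when the TrialSet carries label triples.
    """
    if ts.n_trials == 0:
        raise ValueError("empty TrialSet")
    lengths = {t.shape[1] for t in ts.trials}
    if len(lengths) != 1:
        raise ValueError(f"segments have ragged lengths {sorted(lengths)}; slice requires equal length")
    n = lengths.pop()
    labels = ts.labels
    if labels.ndim == 2:
        if label_dim is None:
            raise ValueError("TrialSet has label triples; pass label_dim (0, 1 or 2)")
        labels = labels[:, label_dim]
    elif label_dim not in (None, 0):
        raise ValueError("label_dim given but TrialSet has scalar labels")

    arr = np.stack(ts.trials)  # (n_trials, C, n)
    if window_length == 1:
        # (n_trials, C, n) -> (n_trials, n, C, 1) -> (n_trials*n, C, 1)
        x = np.ascontiguousarray(arr.transpose(0, 2, 1)[..., None])
        x = x.reshape(ts.n_trials * n, ts.n_channels, 1)
        reps = n
    else:
        w = int(window_length)
        if w < 1:
            raise ValueError("window_length must be >= 1")
        n_win = n // w
        if n_win == 0:
            raise ValueError(f"segment length {n} shorter than window {w}")
        x = arr[:, :, : n_win * w].transpose(0, 2, 1).reshape(ts.n_trials, n_win, w, ts.n_channels)
        x = x.reshape(ts.n_trials * n_win, w, ts.n_channels)
        reps = n_win
    y = np.repeat(labels, reps)
    sid = np.repeat(ts.subject_id, reps)
    return SampleBatch(x, y, sid)


# ---------------------------------------------------------------------------
# normalization


@dataclass(frozen=True)
class NormStats:
    mean: np.ndarray  # (seq_len, n_features)
    std: np.ndarray  # (seq_len, n_features), epsilon-guarded

    def transform(self, batch: SampleBatch) -> SampleBatch:
        return SampleBatch((batch.x - self.mean) / self.std, batch.y, batch.subject_id)


def normalize(train: SampleBatch, *others: SampleBatch, eps: float = 1e-8):
    """Per-channel z-scoring with statistics from the training batch only.

    Returns ``(train_n, *others_n, stats)``.  Constant channels map to ~0
    via the epsilon guard.
    """
    if len(train) == 0:
        raise ValueError("training batch is empty")
    mean = train.x.mean(axis=0)
    std = train.x.std(axis=0)
    stats = NormStats(mean=mean, std=np.maximum(std, eps))
    out = [stats.transform(b) for b in (train, *others)]
    return (*out, stats)


# ---------------------------------------------------------------------------
# label encoding


def encode_labels(raw_labels, mode: str) -> np.ndarray:
    """Map raw labels to contiguous integer classes.

    ``seediv4``: {'neutral':0,'sad':1,'fear':2,'happy':3} (names or
    already-encoded ints 0-3 pass through); ``dreamer_dim``: 1-5 rating ->
    0-4 class.
    """
    raw = np.asarray(raw_labels)
    if mode == "seediv4":
        if raw.dtype.kind in "iu":
            if raw.size and (raw.min() < 0 or raw.max() > 3):
                bad = raw[(raw < 0) | (raw > 3)][0]
                raise ValueError(f"SEED-IV integer label out of range 0-3: {bad}")
            return raw.astype(int)
        out = np.empty(raw.shape, dtype=int)
        for idx, name in np.ndenumerate(raw):
            key = str(name).strip().lower()
            if key not in SEEDIV_CLASS_TO_INT:
                raise ValueError(
                    f"unknown SEED-IV label {name!r}; expected one of {sorted(SEEDIV_CLASS_TO_INT)}"
                )
            out[idx] = SEEDIV_CLASS_TO_INT[key]
        return out
    if mode == "dreamer_dim":
        ratings = raw.astype(int)
        if ratings.size and (ratings.min() < 1 or ratings.max() > 5):
            bad = ratings[(ratings < 1) | (ratings > 5)][0]
            raise ValueError(f"DREAMER rating out of range 1-5: {bad}")
        return ratings - 1
    raise ValueError(f"unknown label mode {mode!r}")


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SubjectSplitPlan:
    train_subjects: np.ndarray
    test_subjects: np.ndarray
    seed: int

    def indices(self, subject_id: np.ndarray):
        """(train_idx, test_idx) for a per-sample subject vector."""
        subject_id = np.asarray(subject_id)
        test_mask = np.isin(subject_id, self.test_subjects)
        idx = np.arange(len(subject_id))
        return idx[~test_mask], idx[test_mask]


def subject_split(subjects, n_test: int, seed: int) -> SubjectSplitPlan:
    """Seeded choice of ``n_test`` held-out subjects (identity-safe split)."""
    subjects = np.unique(np.asarray(subjects))
    if n_test >= len(subjects):
        raise ValueError(f"n_test={n_test} must be < n_subjects={len(subjects)}")
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    rng = np.random.default_rng(seed)
    test = rng.choice(subjects, size=n_test, replace=False)
    test = np.sort(test)
    train = subjects[~np.isin(subjects, test)]
    return SubjectSplitPlan(train_subjects=train, test_subjects=test, seed=seed)


@dataclass(frozen=True)
class KFoldPlan:
    fold_of: np.ndarray  # sample index -> fold id in [0, k)
    k: int
    seed: int

    def split(self, fold: int):
        """(train_idx, test_idx) with ``fold`` held out."""
        idx = np.arange(len(self.fold_of))
        test = self.fold_of == fold
        return idx[~test], idx[test]

    def folds(self):
        for f in range(self.k):
            yield self.split(f)


def kfold_indices(n_samples: int, k: int = 10, seed: int = 42, groups=None) -> KFoldPlan:
    """Seeded shuffle then k near-equal folds (sizes differ by <= 1).

    With ``groups`` (e.g. trial ids per sample) whole groups are assigned to
    folds, balancing fold sizes greedily — the trial-grouped CV mode.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < k:
        raise ValueError(f"n_samples={n_samples} < k={k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n_samples, dtype=int)
    if groups is None:
        perm = rng.permutation(n_samples)
        # first (n % k) folds get the extra sample
        sizes = np.full(k, n_samples // k)
        sizes[: n_samples % k] += 1
        stop = np.cumsum(sizes)
        start = stop - sizes
        for f in range(k):
            fold_of[perm[start[f] : stop[f]]] = f
    else:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        load = np.zeros(k, dtype=int)
        for g in uniq:
            mask = groups == g
            f = int(np.argmin(load))
            fold_of[mask] = f
            load[f] += int(mask.sum())
    return KFoldPlan(fold_of=fold_of, k=k, seed=seed)
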