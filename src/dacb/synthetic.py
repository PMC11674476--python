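"""Synthetic multichannel EEG-like trials with class-dependent structure.

Every emotion class is given a *signature*: a unit-norm channel-gain vector
(the spatial fingerprint — which electrodes light up) and a small set of
oscillatory components with a strictly positive DC baseline (the temporal
fingerprint — how the envelope evolves).  A trial of class ``c`` is

    X(ch, t) = g_c[ch] * s_c(t) + noise,
    s_c(t)   = b_c + sum_k a_k sin(2*pi*f_k*t/fs + phi_k),

with ``b_c > sum_k a_k`` so the envelope never changes sign.  The positive
baseline is deliberate: downstream sampling treats every timepoint as one
training example (a single channel vector), and a sign-flipping envelope
would make classes non-separable at the sample level (x and -x would share
a label).  Mild per-subject gain jitter and per-trial amplitude jitter make
unseen subjects/trials genuinely harder than unseen timepoints, as in real
recordings.

The generator emulates the *shape* of the SEED-IV (15 subjects x 24 clips,
62 channels, 4 classes) and DREAMER (23 subjects x 18 clips, 14 channels,
three 5-class ratings) corpora; it makes no claim to physiological realism
(no 1/f spectrum, artifacts, or volume conduction).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .containers import TrialSet

__all__ = [
    "SynthSpec",
    "ClassSignature",
    "make_class_signature",
    "make_class_signatures",
    "generate_trialset",
    "generate_crossed_trialset",
    "save_trialset_h5",
    "seediv_preset",
    "dreamer_preset",
]

_MAX_COS = 0.9  # signatures of distinct classes stay below this similarity


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic corpus; generation is a pure
    function of this object (identical spec => bit-identical arrays)."""

    n_subjects: int = 15
    n_trials_per_subject: int = 24
    n_channels: int = 62
    trial_length: int = 3000
    segment_length: int = 1000
    n_classes: int = 4
    label_mode: str = "single"  # "single" | "vad_triple"
    snr: float = 10.0  # RMS(signal)/RMS(noise) amplitude ratio
    seed: int = 42
    fs: float = 200.0  # nominal sampling rate, Hz
    n_oscillations: int = 3
    freq_band: tuple = (4.0, 45.0)  # Hz; theta through low gamma
    subject_gain_jitter: float = 0.05
    trial_amp_jitter: float = 0.1

    def __post_init__(self):
        if self.trial_length < self.segment_length:
            raise ValueError("trial_length must be >= segment_length")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.label_mode not in ("single", "vad_triple"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def seediv_preset(**overrides) -> SynthSpec:
    """SEED-IV-shaped corpus: 15 subjects x 24 clips, 62 ch, 4 classes."""
    kw = dict(
        n_subjects=15,
        n_trials_per_subject=24,
        n_channels=62,
        trial_length=3000,
        segment_length=1000,
        n_classes=4,
        label_mode="single",
    )
    kw.update(overrides)
    return SynthSpec(**kw)


def dreamer_preset(**overrides) -> SynthSpec:
    """DREAMER-shaped corpus: 23 subjects x 18 clips, 14 ch, 128 Hz,
    three independent 5-class valence/arousal/dominance labels."""
    kw = dict(
        n_subjects=23,
        n_trials_per_subject=18,
        n_channels=14,
        trial_length=3000,
        segment_length=1000,
        n_classes=5,
        label_mode="vad_triple",
        fs=128.0,
    )
    kw.update(overrides)
    return SynthSpec(**kw)


@dataclass(frozen=True)
class ClassSignature:
    gain: np.ndarray  # (n_channels,), unit Euclidean norm
    freqs: np.ndarray  # (n_osc,) Hz
    amps: np.ndarray  # (n_osc,)
    phases: np.ndarray  # (n_osc,) rad
    baseline: float  # > sum(amps): envelope stays positive

    def envelope(self, t: np.ndarray, fs: float) -> np.ndarray:
        """s_c(t) for integer sample indices ``t``."""
        arg = 2.0 * np.pi * self.freqs[:, None] * t[None, :] / fs
        return self.baseline + (self.amps[:, None] * np.sin(arg + self.phases[:, None])).sum(axis=0)

    def template(self, t: np.ndarray, fs: float) -> np.ndarray:
        """Noise-free class template g_c x s_c(t), shape (C, len(t))."""
        return np.outer(self.gain, self.envelope(t, fs))


def make_class_signatures(
    n_classes: int,
    n_channels: int,
    seed,
    n_oscillations: int = 3,
    freq_band=(4.0, 45.0),
) -> list:
    """Deterministic signatures for classes ``0..n_classes-1``.

    Gain vectors are drawn sequentially; a candidate too similar to an
    earlier class (cosine >= 0.9) is redrawn, falling back to deflation
    against the most similar earlier gain, so the pairwise-similarity
    bound holds by construction.
    """
    sigs = []
    gains = []
    for c in range(n_classes):
        rng = _class_rng(seed, c)
        g = _draw_separated_gain(rng, n_channels, gains)
        gains.append(g)
        lo, hi = freq_band
        freqs = np.sort(rng.uniform(lo, hi, size=n_oscillations))
        amps = rng.uniform(0.5, 1.0, size=n_oscillations)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_oscillations)
        baseline = 1.25 * float(amps.sum())
        sigs.append(ClassSignature(g, freqs, amps, phases, baseline))
    return sigs


def make_class_signature(class_id: int, n_channels: int, rng) -> ClassSignature:
    """Signature of one class under base seed ``rng`` (int or Generator seed).

    Depends only on ``(class_id, n_channels, seed)``; repeated calls agree
    with the corresponding entry of :func:`make_class_signatures`.
    """
    seed = _as_seed(rng)
    if class_id < 0:
        raise ValueError(f"class_id must be >= 0, got {class_id}")
    return make_class_signatures(class_id + 1, n_channels, seed)[class_id]


def _as_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    if isinstance(rng, np.random.Generator):
        # derive a stable seed from the generator's own state
        return int(rng.integers(0, 2**31 - 1))
    raise TypeError("rng must be an integer seed or numpy Generator")


def _class_rng(seed: int, class_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(class_id),)))


def _draw_separated_gain(rng, n_channels, previous, max_tries=100):
    for _ in range(max_tries):
        g = rng.standard_normal(n_channels)
        g /= np.linalg.norm(g)
        if not previous or max(float(g @ p) for p in previous) < _MAX_COS:
            return g
    # deflate against the closest earlier gain (guaranteed when the number
    # of earlier classes is below the channel count)
    sims = np.array([float(g @ p) for p in previous])
    g = g - previous[int(np.argmax(sims))] * sims.max()
    nrm = np.linalg.norm(g)
    if nrm < 1e-12:  # pragma: no cover - measure-zero draw
        raise RuntimeError("could not construct a separated gain vector")
    return g / nrm


def generate_trialset(spec: SynthSpec) -> TrialSet:
    """Generate the full labelled corpus described by ``spec``."""
    n_label_dims = 3 if spec.label_mode == "vad_triple" else 1
    signatures = [
        make_class_signatures(
            spec.n_classes,
            spec.n_channels,
            # distinct signature families per VAD dimension
            spec.seed + 104729 * d,
            spec.n_oscillations,
            spec.freq_band,
        )
        for d in range(n_label_dims)
    ]

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(9001,)))
    t = np.arange(spec.trial_length, dtype=float)
    trials, labels, subj_ids, clip_ids = [], [], [], []

    for s in range(spec.n_subjects):
        # per-subject spatial jitter: the same class looks slightly
        # different on different heads
        subj_gain_noise = rng.standard_normal((n_label_dims, spec.n_classes, spec.n_channels))
        subj_labels = _balanced_labels(spec.n_trials_per_subject, spec.n_classes, n_label_dims, rng)
        for k in range(spec.n_trials_per_subject):
            clean = np.zeros((spec.n_channels, spec.trial_length))
            for d in range(n_label_dims):
                c = int(subj_labels[k, d])
                sig = signatures[d][c]
                g = sig.gain + spec.subject_gain_jitter * subj_gain_noise[d, c]
                g = g / np.linalg.norm(g)
                amps = sig.amps * (1.0 + spec.trial_amp_jitter * rng.standard_normal(len(sig.amps)))
                arg = 2.0 * np.pi * sig.freqs[:, None] * t[None, :] / spec.fs
                env = sig.baseline + (amps[:, None] * np.sin(arg + sig.phases[:, None])).sum(axis=0)
                clean += np.outer(g, env) / n_label_dims
            sigma = np.sqrt(np.mean(clean**2)) / spec.snr
            trial = clean + sigma * rng.standard_normal(clean.shape)
            trials.append(trial)
            labels.append(subj_labels[k, 0] if n_label_dims == 1 else subj_labels[k])
            subj_ids.append(s)
            clip_ids.append(k)

    return TrialSet(
        trials=trials,
        labels=np.asarray(labels),
        subject_id=np.asarray(subj_ids),
        clip_id=np.asarray(clip_ids),
    )


def generate_crossed_trialset(
    seed: int,
    n_channels: int = 14,
    trial_length: int = 192,
    n_trials: int = 240,
    snr: float = 3.0,
    freqs: tuple = (4.0, 12.0),
    fs: float = 200.0,
    max_gain_cos: float = 0.5,
) -> TrialSet:
    """Corpus whose class information is *split* between spatial and
    temporal signatures: 4 classes = 2 channel-gain patterns x 2
    oscillation frequencies (crossed design).

    Classes sharing a gain pattern differ only in oscillation frequency
    (with a random phase per trial, so no single timepoint reveals it) and
    classes sharing a frequency differ only in their gain pattern.  This
    is the corpus for spatial-vs-temporal ablation studies; it is only
    meaningful with time-spanning windowed samples
    (``slice_timepoint_samples(..., window_length=w)`` with ``w`` covering
    a good fraction of the slower period), because a single timepoint
    carries no frequency information at all.
    """
    rng = np.random.default_rng(seed)
    gains = []
    while len(gains) < 2:
        g = rng.standard_normal(n_channels)
        g /= np.linalg.norm(g)
        if not gains or abs(float(g @ gains[0])) < max_gain_cos:
            gains.append(g)
    t = np.arange(trial_length)
    trials, labels = [], []
    for k in range(n_trials):
        c = k % 4
        gi, fi = c // 2, c % 2
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = 2.0 + np.sin(2.0 * np.pi * freqs[fi] * t / fs + phase)
        clean = np.outer(gains[gi], env)
        sigma = np.sqrt(np.mean(clean**2)) / snr
        trials.append(clean + sigma * rng.standard_normal(clean.shape))
        labels.append(c)
    return TrialSet(
        trials=trials,
        labels=np.asarray(labels),
        subject_id=np.zeros(n_trials, dtype=int),
        clip_id=np.arange(n_trials),
    )


def _balanced_labels(n_trials, n_classes, n_dims, rng):
    """(n_trials, n_dims) labels, each dimension balanced up to rounding."""
    out = np.empty((n_trials, n_dims), dtype=int)
    base = np.resize(np.arange(n_classes), n_trials)
    for d in range(n_dims):
        out[:, d] = rng.permutation(base)
    return out


def save_trialset_h5(ts: TrialSet, out_dir, spec: SynthSpec = None) -> pathlib.Path:
    """Write one HDF5 file per subject plus a JSON manifest; returns out_dir.

    Each ``subject_XX.h5`` holds datasets ``eeg`` (n_trials x C x T),
    ``labels`` and ``clip_id`` and attributes ``subject_id``/``n_channels``.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for s in np.unique(ts.subject_id):
        sub = ts.select(ts.subject_id == s)
        lengths = {t.shape[1] for t in sub.trials}
        if len(lengths) != 1:
            raise ValueError("HDF5 export requires equal-length trials per subject")
        fname = f"subject_{int(s):02d}.h5"
        with h5py.File(out_dir / fname, "w") as f:
            f.create_dataset("eeg", data=np.stack(sub.trials))
            f.create_dataset("labels", data=sub.labels)
            f.create_dataset("clip_id", data=sub.clip_id)
            f.attrs["subject_id"] = int(s)
            f.attrs["n_channels"] = sub.n_channels
        files.append(fname)
    manifest = {"format": "dacb-synthetic-h5", "files": files}
    if spec is not None:
        manifest["spec"] = asdict(spec)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return out_dir


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (tuple, np.ndarray)):
        return list(o)
    raise TypeError(type(o))
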