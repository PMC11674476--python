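"""Training and evaluation protocols.

Three designs are provided, mirroring common EEG-decoding practice:

* **single subject-split** — whole subjects held out (~80/20), so the test
  set contains only unseen identities;
* **10-fold cross-validation** — seeded shuffle of samples into ten folds;
  either raw per-timepoint samples are shuffled (``sample_shuffled``,
  adjacent timepoints of one trial may then straddle the train/test
  boundary) or whole trials are kept together (``trial_grouped``);
* **ablation** — the two single-branch variants and the full model run
  under identical fold manifests.

Training minimizes categorical cross-entropy with Adam.  All shuffling,
initialization and splitting derive from explicit integer seeds, so every
run is bit-reproducible from its manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from .containers import SampleBatch, TrialSet
from .data import (
    extract_middle_segment,
    kfold_indices,
    normalize,
    slice_timepoint_samples,
    subject_split,
)
from .metrics import MetricReport, evaluate_predictions
from .model import DACBModel, ModelConfig, VARIANTS

__all__ = [
    "TrainConfig",
    "RunResult",
    "AdamOptimizer",
    "train",
    "evaluate",
    "prepare_samples",
    "run_single_split",
    "run_kfold",
    "run_ablation",
    "channel_contributions",
    "derive_seed",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    learning_rate: float = 0.001
    batch_size: int = 1024
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    grad_clip: float = 5.0  # global gradient-norm ceiling; None disables
    seed: int = 42

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class RunResult:
    reports: list  # one MetricReport per evaluation (fold or split)
    history: list  # per-training history dicts
    manifest: dict  # seeds + split assignment; reproduces the run
    config: dict  # ModelConfig + TrainConfig snapshot
    model: object = None  # trained model (single-split runs only)

    @property
    def mean_metrics(self) -> dict:
        keys = ("accuracy", "precision", "recall", "f1", "mcc")
        return {k: float(np.mean([getattr(r, k) for r in self.reports])) for k in keys}

    @property
    def std_metrics(self) -> dict:
        keys = ("accuracy", "precision", "recall", "f1", "mcc")
        return {k: float(np.std([getattr(r, k) for r in self.reports])) for k in keys}


def derive_seed(master: int, *key) -> int:
    """Stable child seed < 2**31 from a master seed and a key tuple."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


class AdamOptimizer:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8) and
    optional global gradient-norm clipping (stabilizes the recurrent
    branch against occasional exploding updates)."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8, grad_clip=None):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.grad_clip = grad_clip
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def _clip(self):
        total = np.sqrt(
            sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
        )
        if total > self.grad_clip:
            scale = self.grad_clip / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self):
        if self.grad_clip is not None:
            self._clip()
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train(model: DACBModel, train_batch: SampleBatch, cfg: TrainConfig):
    """Fit ``model`` in place; returns (model, history).

    history is a list of ``{"epoch", "loss", "accuracy"}`` dicts (means over
    the epoch's minibatches, computed from the training forward passes).
    """
    if len(train_batch) == 0:
        raise ValueError("training batch is empty")
    if train_batch.y.max() >= model.cfg.n_classes or train_batch.y.min() < 0:
        raise ValueError(
            f"labels span [{train_batch.y.min()}, {train_batch.y.max()}] but model "
            f"has {model.cfg.n_classes} classes"
        )
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(model.params.tensors(), lr=cfg.learning_rate, grad_clip=cfg.grad_clip)
    x = np.asarray(train_batch.x, dtype=np.dtype(model.cfg.dtype))
    y = train_batch.y
    n = len(y)
    history = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            logits, _, _ = model.logits_graph(x[idx])
            loss, probs = ad.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.sum(losses) / n),
                "accuracy": correct / n,
            }
        )
    return model, history


def evaluate(model: DACBModel, batch: SampleBatch, multiclass_mcc: str = "macro_ovr") -> MetricReport:
    """Argmax predictions (ties -> lowest class index), then the metric suite."""
    if len(batch) == 0:
        raise ValueError("evaluation batch is empty")
    y_pred = model.predict(batch.x)
    return evaluate_predictions(batch.y, y_pred, model.cfg.n_classes, multiclass_mcc)


# ---------------------------------------------------------------------------
# protocol orchestration


def prepare_samples(
    data: TrialSet,
    segment_length: int = 1000,
    label_dim: int = None,
    window_length: int = 1,
) -> SampleBatch:
    """Middle-segment extraction followed by per-timepoint (or windowed)
    slicing."""
    segments = TrialSet(
        trials=[extract_middle_segment(t, segment_length) for t in data.trials],
        labels=data.labels,
        subject_id=data.subject_id,
        clip_id=data.clip_id,
    )
    return slice_timepoint_samples(segments, label_dim=label_dim, window_length=window_length)


def run_single_split(
    data: TrialSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_test_subjects: int,
    segment_length: int = 1000,
    label_dim: int = None,
    variant: str = "full",
) -> RunResult:
    """Subject-wise hold-out: split -> normalize (train stats) -> train -> test."""
    subjects = np.unique(data.subject_id)
    if len(subjects) < 2:
        raise ValueError("subject split requires at least 2 subjects")
    samples = prepare_samples(data, segment_length, label_dim)
    plan = subject_split(subjects, n_test_subjects, seed=train_cfg.seed)
    tr_idx, te_idx = plan.indices(samples.subject_id)
    train_b, test_b = samples.take(tr_idx), samples.take(te_idx)
    train_n, test_n, _ = normalize(train_b, test_b)
    model = DACBModel(model_cfg, variant=variant)
    model, history = train(model, train_n, train_cfg)
    report = evaluate(model, test_n)
    manifest = {
        "protocol": "single_subject_split",
        "seed": train_cfg.seed,
        "train_subjects": plan.train_subjects.tolist(),
        "test_subjects": plan.test_subjects.tolist(),
        "segment_length": segment_length,
        "label_dim": label_dim,
        "variant": variant,
    }
    return RunResult(
        reports=[report],
        history=[history],
        manifest=manifest,
        config={"model": asdict(model_cfg), "train": asdict(train_cfg)},
        model=model,
    )


def run_kfold(
    data: TrialSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k: int = 10,
    mode: str = "sample_shuffled",
    segment_length: int = 1000,
    label_dim: int = None,
    variant: str = "full",
    fold_plan=None,
) -> RunResult:
    """k train/test cycles with a fresh model and fresh normalization per
    fold; aggregates per-metric mean and sd.

    ``mode='sample_shuffled'`` shuffles raw timepoint samples into folds;
    ``mode='trial_grouped'`` assigns whole trials to folds.  A precomputed
    ``fold_plan`` may be passed to share the manifest across runs.
    """
    if mode not in ("sample_shuffled", "trial_grouped"):
        raise ValueError(f"unknown CV mode {mode!r}")
    samples = prepare_samples(data, segment_length, label_dim)
    if fold_plan is None:
        if mode == "sample_shuffled":
            fold_plan = kfold_indices(len(samples), k=k, seed=train_cfg.seed)
        else:
            seg = segment_length
            trial_of = np.repeat(np.arange(data.n_trials), seg)
            fold_plan = kfold_indices(len(samples), k=k, seed=train_cfg.seed, groups=trial_of)
    reports, histories = [], []
    for fold, (tr_idx, te_idx) in enumerate(fold_plan.folds()):
        train_b, test_b = samples.take(tr_idx), samples.take(te_idx)
        train_n, test_n, _ = normalize(train_b, test_b)
        fold_cfg = ModelConfig(
            **{**asdict(model_cfg), "seed": derive_seed(model_cfg.seed, fold)}
        )
        model = DACBModel(fold_cfg, variant=variant)
        model, history = train(model, train_n, train_cfg)
        reports.append(evaluate(model, test_n))
        histories.append(history)
    manifest = {
        "protocol": "kfold_cv",
        "mode": mode,
        "k": fold_plan.k,
        "seed": fold_plan.seed,
        "fold_of": fold_plan.fold_of.tolist(),
        "segment_length": segment_length,
        "label_dim": label_dim,
        "variant": variant,
    }
    return RunResult(
        reports=reports,
        history=histories,
        manifest=manifest,
        config={"model": asdict(model_cfg), "train": asdict(train_cfg)},
    )


def run_ablation(
    data: TrialSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k: int = 10,
    mode: str = "sample_shuffled",
    segment_length: int = 1000,
    label_dim: int = None,
    dataset_name: str = "synthetic",
) -> pd.DataFrame:
    """Run block1 (spatial-only), block2 (temporal-only) and the full model
    under identical fold manifests; returns a tidy table of mean metrics.

    Columns: dataset, variant, accuracy, precision, recall, f1, mcc (means
    over folds) plus accuracy_sd.
    """
    samples_n = data.n_trials * segment_length
    if mode == "sample_shuffled":
        plan = kfold_indices(samples_n, k=k, seed=train_cfg.seed)
    else:
        trial_of = np.repeat(np.arange(data.n_trials), segment_length)
        plan = kfold_indices(samples_n, k=k, seed=train_cfg.seed, groups=trial_of)
    rows = []
    results = {}
    for variant, label in (
        ("block1_spatial_only", "Block1"),
        ("block2_temporal_only", "Block2"),
        ("full", "DACB"),
    ):
        res = run_kfold(
            data,
            model_cfg,
            train_cfg,
            k=k,
            mode=mode,
            segment_length=segment_length,
            label_dim=label_dim,
            variant=variant,
            fold_plan=plan,
        )
        results[variant] = res
        row = {"dataset": dataset_name, "variant": label}
        row.update({k_: 100.0 * v for k_, v in res.mean_metrics.items()})
        row["accuracy_sd"] = 100.0 * res.std_metrics["accuracy"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["results"] = results
    return table


def channel_contributions(model: DACBModel, batch: SampleBatch) -> dict:
    """Per-unit SE scores and per-electrode occlusion scores.

    Returns a dict with
      * ``se_logits``      — batch-averaged pre-sigmoid excitations of the
        64 conv feature maps (may be negative),
      * ``se_weights``     — their sigmoids, all in (0, 1),
      * ``occlusion``      — accuracy drop when zeroing each input
        electrode (length n_channels; positive = electrode helps),
      * ``baseline_accuracy``.
    """
    if len(batch) == 0:
        raise ValueError("attribution batch is empty")
    out = {}
    se = model.se_excitation_logits(batch.x)
    if se is not None:
        out["se_logits"], out["se_weights"] = se
    else:
        out["se_logits"] = out["se_weights"] = None
    base_pred = model.predict(batch.x)
    base_acc = float((base_pred == batch.y).mean())
    n_ch = model.cfg.n_channels
    drops = np.empty(n_ch)
    for ch in range(n_ch):
        x_occ = np.array(batch.x, copy=True)
        if model.cfg.n_features == 1:  # per-timepoint layout: channel = position
            x_occ[:, ch, :] = 0.0
        else:  # windowed layout: channel = feature
            x_occ[:, :, ch] = 0.0
        acc = float((model.predict(x_occ) == batch.y).mean())
        drops[ch] = base_acc - acc
    out["occlusion"] = drops
    out["baseline_accuracy"] = base_acc
    return out
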