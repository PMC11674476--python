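"""The DACB network: dual-branch spatio-temporal EEG classifier.

Architecture (per input sample, a ``seq_len x n_features`` array — by
default one instantaneous channel vector, ``n_channels x 1``):

* **spatial branch** — 1-D convolution (64 filters, kernel 3, same
  padding) + ReLU, max pooling (2), then a 1-D squeeze-and-excitation
  block that reweights the 64 feature maps, then flatten;
* **temporal branch** — bidirectional LSTM (32 units per direction) run
  along the sequence axis, then flatten;
* **fusion** — both branch vectors are linearly projected to a common
  width and stacked as a 2-row value matrix ``V``; tanh-keyed dot-product
  attention (``K = tanh(V W_a)``, ``d = softmax(q K^T)``) scores the two
  branches.  By default the attention-scaled branch vectors are
  concatenated (``[d_1 v_1, d_2 v_2]``) so the head keeps both views;
  ``fusion_mode="pool"`` instead forms the convex combination ``a = d V``;
* **head** — Dense 64 (ReLU) -> Dense 32 (ReLU) -> softmax over classes.

Every building block is exposed as a standalone NumPy-in/NumPy-out
function (:func:`conv1d_forward`, :func:`lstm_step`, :func:`dot_attention`,
...) so each can be verified against brute-force oracles; the trainable
model composes exactly the same graph code, so the whole forward pass is
the composition of its individually tested parts.

Single-branch ablations keep one branch; fusion attention over the
resulting one-row ``V`` degenerates to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "ConvParams",
    "SEParams",
    "LSTMParams",
    "AttentionParams",
    "DenseParams",
    "DACBParams",
    "init_params",
    "DACBModel",
    "build_ablation_variant",
    "conv1d_forward",
    "maxpool1d",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "lstm_step",
    "bilstm_forward",
    "dot_attention",
    "dacb_forward",
]

VARIANTS = ("full", "block1_spatial_only", "block2_temporal_only")


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int
    n_classes: int
    n_features: int = 1  # input features per sequence position
    seq_len: int = None  # defaults to n_channels (per-timepoint samples)
    conv_filters: int = 64
    conv_kernel: int = 3
    pool_size: int = 2
    se_reduction: int = 8
    lstm_units: int = 32
    fc1_units: int = 64
    fc2_units: int = 32
    fusion_width: int = 64  # common width both branches are projected to
    attention_mode: str = "branch"  # "branch" | "position"
    fusion_mode: str = "weighted_concat"  # "weighted_concat" | "pool"
    bilstm_merge: str = "concat"  # "concat" | "gated"
    seed: int = 42
    dtype: str = "float32"

    def __post_init__(self):
        if self.conv_filters % self.se_reduction:
            raise ValueError("conv_filters must be divisible by se_reduction")
        for name in (
            "n_channels",
            "n_classes",
            "n_features",
            "conv_filters",
            "conv_kernel",
            "pool_size",
            "se_reduction",
            "lstm_units",
            "fc1_units",
            "fc2_units",
            "fusion_width",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd (symmetric same-padding)")
        if self.attention_mode not in ("branch", "position"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        if self.fusion_mode not in ("weighted_concat", "pool"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.bilstm_merge not in ("concat", "gated"):
            raise ValueError(f"unknown bilstm_merge {self.bilstm_merge!r}")

    @property
    def sequence_length(self) -> int:
        return self.n_channels if self.seq_len is None else self.seq_len

    @property
    def pooled_length(self) -> int:
        return self.sequence_length // self.pool_size

    @property
    def bilstm_width(self) -> int:
        return self.lstm_units if self.bilstm_merge == "gated" else 2 * self.lstm_units


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ConvParams:
    w: object  # (kernel, in_features, filters)
    b: object  # (filters,)


@dataclass
class SEParams:
    W1: object  # (c/r, c): reduction layer
    W2: object  # (c, c/r): expansion layer


@dataclass
class LSTMParams:
    """One direction's gate parameters; weight rows act on [h_prev, x_t]."""

    w_f: object
    w_i: object
    w_o: object
    w_c: object
    b_f: object
    b_i: object
    b_o: object
    b_c: object


@dataclass
class AttentionParams:
    W_a: object  # (d, d) key projection
    q: object  # (d,) learned query


@dataclass
class DenseParams:
    W: object
    b: object


@dataclass
class DACBParams:
    conv: ConvParams = None
    se: SEParams = None
    lstm_forward: LSTMParams = None
    lstm_backward: LSTMParams = None
    merge: DenseParams = None  # gated Bi-LSTM merge only
    proj_spatial: DenseParams = None
    proj_temporal: DenseParams = None
    attention: AttentionParams = None
    fc1: DenseParams = None
    fc2: DenseParams = None
    fc_out: DenseParams = None

    def tensors(self):
        """All parameter Tensors, in a stable traversal order."""
        out = []
        for group in (
            self.conv,
            self.se,
            self.lstm_forward,
            self.lstm_backward,
            self.merge,
            self.proj_spatial,
            self.proj_temporal,
            self.attention,
            self.fc1,
            self.fc2,
            self.fc_out,
        ):
            if group is None:
                continue
            for f in vars(group).values():
                if isinstance(f, Tensor):
                    out.append(f)
        return out

    def component_names(self):
        return [k for k, v in vars(self).items() if v is not None]


def _data(x):
    """ndarray view of a Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _pt(x):
    """Coerce a params field (Tensor or array) to a graph Tensor."""
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# initialization


def init_params(cfg: ModelConfig, variant: str = "full") -> DACBParams:
    """Seeded uniform fan-in initialization of all weights for ``variant``.

    Each weight W of shape (fan_in, fan_out) is drawn from
    U(-1/sqrt(fan_in), 1/sqrt(fan_in)); biases start at zero.  Streams are
    spawned per component from ``cfg.seed`` so components are independent
    yet fully reproducible.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    dt = np.dtype(cfg.dtype)
    streams = iter(np.random.SeedSequence(entropy=int(cfg.seed)).spawn(12))

    def uni(rng, shape, fan_in):
        bound = 1.0 / np.sqrt(max(fan_in, 1))
        return Tensor(rng.uniform(-bound, bound, size=shape).astype(dt), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape, dtype=dt), requires_grad=True)

    p = DACBParams()
    spatial = variant in ("full", "block1_spatial_only")
    temporal = variant in ("full", "block2_temporal_only")
    T = cfg.sequence_length
    d = cfg.fusion_width

    if spatial:
        rng = np.random.default_rng(next(streams))
        K, F = cfg.conv_kernel, cfg.conv_filters
        p.conv = ConvParams(
            w=uni(rng, (K, cfg.n_features, F), K * cfg.n_features),
            b=zeros(F),
        )
        rng = np.random.default_rng(next(streams))
        c, r = cfg.conv_filters, cfg.se_reduction
        p.se = SEParams(
            W1=uni(rng, (c // r, c), c),
            W2=uni(rng, (c, c // r), c // r),
        )
        rng = np.random.default_rng(next(streams))
        if cfg.attention_mode == "branch":
            sp_flat = cfg.pooled_length * cfg.conv_filters
            p.proj_spatial = DenseParams(W=uni(rng, (sp_flat, d), sp_flat), b=zeros(d))
        else:  # position mode: position-wise projection of feature maps
            p.proj_spatial = DenseParams(W=uni(rng, (cfg.conv_filters, d), cfg.conv_filters), b=zeros(d))

    if temporal:
        H, F = cfg.lstm_units, cfg.n_features
        for attr in ("lstm_forward", "lstm_backward"):
            rng = np.random.default_rng(next(streams))
            setattr(
                p,
                attr,
                LSTMParams(
                    w_f=uni(rng, (H + F, H), H + F),
                    w_i=uni(rng, (H + F, H), H + F),
                    w_o=uni(rng, (H + F, H), H + F),
                    w_c=uni(rng, (H + F, H), H + F),
                    b_f=zeros(H),
                    b_i=zeros(H),
                    b_o=zeros(H),
                    b_c=zeros(H),
                ),
            )
        if cfg.bilstm_merge == "gated":
            rng = np.random.default_rng(next(streams))
            p.merge = DenseParams(W=uni(rng, (2 * H, H), 2 * H), b=zeros(H))
        rng = np.random.default_rng(next(streams))
        W = cfg.bilstm_width
        if cfg.attention_mode == "branch":
            tp_flat = T * W
            p.proj_temporal = DenseParams(W=uni(rng, (tp_flat, d), tp_flat), b=zeros(d))
        else:
            p.proj_temporal = DenseParams(W=uni(rng, (W, d), W), b=zeros(d))

    rng = np.random.default_rng(next(streams))
    p.attention = AttentionParams(W_a=uni(rng, (d, d), d), q=uni(rng, (d,), d))
    rng = np.random.default_rng(next(streams))
    n_branches = int(spatial) + int(temporal)
    if cfg.attention_mode == "branch" and cfg.fusion_mode == "weighted_concat":
        head_in = n_branches * d
    else:  # pooled fusion (always used in position mode)
        head_in = d
    p.fc1 = DenseParams(W=uni(rng, (head_in, cfg.fc1_units), head_in), b=zeros(cfg.fc1_units))
    rng = np.random.default_rng(next(streams))
    p.fc2 = DenseParams(W=uni(rng, (cfg.fc1_units, cfg.fc2_units), cfg.fc1_units), b=zeros(cfg.fc2_units))
    rng = np.random.default_rng(next(streams))
    p.fc_out = DenseParams(W=uni(rng, (cfg.fc2_units, cfg.n_classes), cfg.fc2_units), b=zeros(cfg.n_classes))
    return p


# ---------------------------------------------------------------------------
# graph builders (Tensor in / Tensor out); shared by the public functional
# operations and by the trainable model


def _graph_conv_relu(x: Tensor, p: ConvParams) -> Tensor:
    return ad.conv1d_same(x, _pt(p.w), _pt(p.b)).relu()


def _graph_se(u: Tensor, p: SEParams):
    """(scaled u, excitation s, squeezed z) for u of shape (B, W, c)."""
    z = u.mean(axis=1)  # (B, c)
    h = (z @ _pt(p.W1).T2).elu()
    s = (h @ _pt(p.W2).T2).sigmoid()  # (B, c)
    B, _, c = u.shape
    scaled = u * s.reshape(B, 1, c)
    return scaled, s, z

def _graph_lstm_dir(x: Tensor, p: LSTMParams, reverse: bool) -> Tensor:
    """One LSTM direction over (B, T, F) via the fused sequence op; the
    four per-gate weight matrices are joined with a differentiable concat
    so gradients route back to the individual gate parameters."""
    w_all = ad.concat([_pt(p.w_f), _pt(p.w_i), _pt(p.w_o), _pt(p.w_c)], axis=1)
    b_all = ad.concat([_pt(p.b_f), _pt(p.b_i), _pt(p.b_o), _pt(p.b_c)], axis=0)
    return ad.lstm_sequence(x, w_all, b_all, reverse=reverse)


def _graph_bilstm(x: Tensor, p_fw: LSTMParams, p_bw: LSTMParams, merge: str, merge_p=None) -> Tensor:
    """(B, T, F) -> (B, T, 2H) [concat] or (B, T, H) [gated]."""
    h_fw = _graph_lstm_dir(x, p_fw, reverse=False)
    h_bw = _graph_lstm_dir(x, p_bw, reverse=True)
    seq = ad.concat([h_fw, h_bw], axis=2)
    if merge == "concat":
        return seq
    if merge == "gated":
        return (seq @ _pt(merge_p.W) + _pt(merge_p.b)).sigmoid()
    raise ValueError(f"unknown merge {merge!r}")


def _graph_attention(V: Tensor, p: AttentionParams, fusion: str = "pool"):
    """Tanh-keyed dot-product attention over the rows of V (B, n, d).

    Weights: K = tanh(V W_a); w = softmax(q K^T).  ``fusion="pool"``
    returns the convex combination w.V (B, d); ``fusion="weighted_concat"``
    returns the attention-scaled rows side by side (B, n*d), so the head
    retains every row's information.
    """
    B, n, d = V.shape
    K = (V @ _pt(p.W_a)).tanh()  # (B, n, d)
    scores = (K @ _pt(p.q).reshape(d, 1)).reshape(B, n)
    w = ad.softmax(scores, axis=1)  # (B, n)
    weighted = V * w.reshape(B, n, 1)
    if fusion == "pool":
        return weighted.sum(axis=1), w
    if fusion == "weighted_concat":
        return weighted.reshape(B, n * d), w
    raise ValueError(f"unknown fusion {fusion!r}")


def _graph_dense(x: Tensor, p: DenseParams, relu=True) -> Tensor:
    out = x @ _pt(p.W) + _pt(p.b)
    return out.relu() if relu else out


def _graph_spatial_branch(x: Tensor, params: DACBParams, cfg: ModelConfig):
    """Returns (per-position features (B, Lp, d or F), flat projection)."""
    u = _graph_conv_relu(x, params.conv)
    u = ad.maxpool1d(u, cfg.pool_size)
    scaled, s, _ = _graph_se(u, params.se)
    if cfg.attention_mode == "branch":
        B = x.shape[0]
        flat = scaled.reshape(B, scaled.shape[1] * scaled.shape[2])
        return _graph_dense(flat, params.proj_spatial, relu=False), s
    return _graph_dense(scaled, params.proj_spatial, relu=False), s


def _graph_temporal_branch(x: Tensor, params: DACBParams, cfg: ModelConfig):
    seq = _graph_bilstm(x, params.lstm_forward, params.lstm_backward, cfg.bilstm_merge, params.merge)
    if cfg.attention_mode == "branch":
        B = x.shape[0]
        flat = seq.reshape(B, seq.shape[1] * seq.shape[2])
        return _graph_dense(flat, params.proj_temporal, relu=False)
    return _graph_dense(seq, params.proj_temporal, relu=False)


def _graph_logits(x: Tensor, params: DACBParams, cfg: ModelConfig, variant: str = "full"):
    """Full forward pass to pre-softmax logits; also returns attention
    weights and SE excitations for attribution."""
    B = x.shape[0]
    rows = []
    se_weights = None
    if params.conv is not None and variant in ("full", "block1_spatial_only"):
        vs, se_weights = _graph_spatial_branch(x, params, cfg)
        rows.append(vs)
    if params.lstm_forward is not None and variant in ("full", "block2_temporal_only"):
        rows.append(_graph_temporal_branch(x, params, cfg))
    if not rows:
        raise ValueError("variant/params leave no active branch")
    if cfg.attention_mode == "branch":
        V = ad.stack(rows, axis=1)  # (B, n_branches, d)
        fusion = cfg.fusion_mode
    else:
        V = rows[0] if len(rows) == 1 else ad.concat(rows, axis=1)  # (B, n_pos, d)
        fusion = "pool"  # many positions: concatenation would be huge
    fused, attn = _graph_attention(V, params.attention, fusion)
    h = _graph_dense(fused, params.fc1, relu=True)
    h = _graph_dense(h, params.fc2, relu=True)
    logits = _graph_dense(h, params.fc_out, relu=False)
    return logits, attn, se_weights


# ---------------------------------------------------------------------------
# public functional operations (NumPy in / NumPy out)


def conv1d_forward(x, p: ConvParams):
    """Single-instance 1-D conv + ReLU: (seq_len, in_features) -> (seq_len, filters).

    Cross-correlation with stride 1 and zero same-padding.
    """
    x = np.asarray(x, dtype=float)
    K = _data(p.w).shape[0]
    if x.shape[0] < K:
        raise ValueError(f"sequence length {x.shape[0]} < kernel size {K}")
    cp = ConvParams(w=Tensor(_data(p.w).astype(float)), b=Tensor(_data(p.b).astype(float)))
    return _graph_conv_relu(Tensor(x[None]), cp).data[0]


def maxpool1d(x, pool: int):
    """Non-overlapping max pooling: (seq_len, c) -> (seq_len // pool, c)."""
    x = np.asarray(x, dtype=float)
    if pool < 1:
        raise ValueError("pool size must be >= 1")
    if x.shape[0] < pool:
        raise ValueError(f"sequence length {x.shape[0]} < pool size {pool}")
    return ad.maxpool1d(Tensor(x[None]), pool).data[0]


def se_squeeze(u):
    """Global average pool per feature map: (W, c) -> (c,)."""
    u = np.asarray(u, dtype=float)
    if u.shape[0] < 1:
        raise ValueError("feature maps must have length >= 1")
    return u.mean(axis=0)


def se_excite(z, p: SEParams):
    """Excitation s = sigmoid(W2 . ELU(W1 . z)); all entries in (0, 1)."""
    z = np.asarray(z, dtype=float)
    W1, W2 = _data(p.W1).astype(float), _data(p.W2).astype(float)
    if W1.shape[1] != z.shape[-1] or W2.shape[1] != W1.shape[0]:
        raise ValueError(
            f"shape mismatch: z {z.shape}, W1 {W1.shape}, W2 {W2.shape}"
        )
    h = W1 @ z
    h = np.where(h > 0, h, np.expm1(h))  # ELU, alpha=1
    out = W2 @ h
    return 1.0 / (1.0 + np.exp(-out))


def se_scale(u, s):
    """Reweight feature maps: (W, c) * (c,) -> (W, c)."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape[1] != s.shape[0]:
        raise ValueError(f"channel mismatch: u has {u.shape[1]}, s has {s.shape[0]}")
    return u * s[None, :]


def lstm_step(x_t, h_prev, C_prev, p: LSTMParams):
    """One LSTM cell update; returns (h_t, C_t).

    f = sig(w_f.[h,x]+b_f); i = sig(w_i.[h,x]+b_i); o = sig(w_o.[h,x]+b_o);
    c~ = tanh(w_c.[h,x]+b_c); C = f*C_prev + i*c~; h = o*tanh(C).
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    C_prev = np.atleast_1d(np.asarray(C_prev, dtype=float))
    hx = np.concatenate([h_prev, x_t])
    w_f, w_i, w_o, w_c = (_data(p.w_f), _data(p.w_i), _data(p.w_o), _data(p.w_c))
    if w_f.shape[0] != hx.shape[0]:
        raise ValueError(f"gate weights expect input dim {w_f.shape[0]}, got {hx.shape[0]}")
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    f = sig(hx @ w_f + _data(p.b_f))
    i = sig(hx @ w_i + _data(p.b_i))
    o = sig(hx @ w_o + _data(p.b_o))
    c_tilde = np.tanh(hx @ w_c + _data(p.b_c))
    C_t = f * C_prev + i * c_tilde
    h_t = o * np.tanh(C_t)
    return h_t, C_t


def bilstm_forward(x, p_fw: LSTMParams, p_bw: LSTMParams, merge: str = "concat", merge_p: DenseParams = None):
    """Single-instance Bi-LSTM: (T, F) -> (T, 2H) [concat] or (T, H) [gated]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("x must be (seq_len >= 1, features)")
    if merge == "gated" and merge_p is None:
        raise ValueError("gated merge requires merge parameters")
    pf = LSTMParams(**{k: Tensor(_data(v).astype(float)) for k, v in vars(p_fw).items()})
    pb = LSTMParams(**{k: Tensor(_data(v).astype(float)) for k, v in vars(p_bw).items()})
    mp = None
    if merge_p is not None:
        mp = DenseParams(W=Tensor(_data(merge_p.W).astype(float)), b=Tensor(_data(merge_p.b).astype(float)))
    return _graph_bilstm(Tensor(x[None]), pf, pb, merge, mp).data[0]


def dot_attention(V, p: AttentionParams):
    """Tanh-keyed dot-product attention over value rows.

    V (n_positions, d_v) -> (a (d_v,), d (n_positions,)) with
    K = tanh(V W_a), d = softmax(q K^T), a = d V.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1:
        raise ValueError("V must be (n_positions >= 1, d_v)")
    W_a, q = _data(p.W_a).astype(float), _data(p.q).astype(float)
    if W_a.shape[0] != V.shape[1] or q.shape[0] != W_a.shape[1]:
        raise ValueError(f"shape mismatch: V {V.shape}, W_a {W_a.shape}, q {q.shape}")
    K = np.tanh(V @ W_a)
    scores = K @ q
    e = np.exp(scores - scores.max())
    d = e / e.sum()
    a = d @ V
    return a, d


def dacb_forward(x, params: DACBParams, cfg: ModelConfig, variant: str = "full"):
    """Batched forward pass to class probabilities (rows sum to 1).

    x: (n, seq_len, n_features) or (n, seq_len) with n_features == 1.
    """
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[..., None]
    if x.ndim != 3 or x.shape[1] != cfg.sequence_length or x.shape[2] != cfg.n_features:
        raise ValueError(
            f"x shape {x.shape} incompatible with (n, {cfg.sequence_length}, {cfg.n_features})"
        )
    logits, _, _ = _graph_logits(Tensor(x.astype(np.dtype(cfg.dtype))), params, cfg, variant)
    return ad.softmax(logits, axis=-1).data


# ---------------------------------------------------------------------------
# trainable model


class DACBModel:
    """Configuration + parameters + variant, with forward/predict methods."""

    def __init__(self, cfg: ModelConfig, variant: str = "full", params: DACBParams = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        self.params = params if params is not None else init_params(cfg, variant)

    def logits_graph(self, x: np.ndarray):
        """Build the autodiff graph; returns (logits Tensor, attn, se)."""
        xt = Tensor(np.asarray(x, dtype=np.dtype(self.cfg.dtype)))
        return _graph_logits(xt, self.params, self.cfg, self.variant)

    def predict_proba(self, x, batch_size: int = 1024) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            logits, _, _ = self.logits_graph(x[i : i + batch_size])
            outs.append(ad.softmax(logits, axis=-1).data)
        return np.concatenate(outs, axis=0)

    def predict(self, x, batch_size: int = 1024) -> np.ndarray:
        # np.argmax resolves ties toward the lowest class index
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    def se_excitation_logits(self, x, batch_size: int = 1024):
        """Batch-averaged pre-sigmoid SE excitations (may be negative) and
        their sigmoids; None for the temporal-only ablation."""
        if self.params.se is None:
            return None
        W1 = _data(self.params.se.W1)
        W2 = _data(self.params.se.W2)
        zs = []
        for i in range(0, len(x), batch_size):
            xt = Tensor(np.asarray(x[i : i + batch_size], dtype=np.dtype(self.cfg.dtype)))
            u = _graph_conv_relu(xt, self.params.conv)
            u = ad.maxpool1d(u, self.cfg.pool_size)
            zs.append(u.data.mean(axis=1))
        z = np.concatenate(zs, axis=0)  # (n, c)
        h = z @ W1.T
        h = np.where(h > 0, h, np.expm1(h))
        logits = (h @ W2.T).mean(axis=0)
        return logits, 1.0 / (1.0 + np.exp(-logits))


def save_checkpoint(model: DACBModel, path) -> None:
    """Write weights to ``<path>.npz`` with a ``<path>.json`` sidecar
    recording the ModelConfig, variant and seed."""
    import json
    import pathlib
    from dataclasses import asdict

    path = pathlib.Path(path)
    arrays = {}
    for comp, group in vars(model.params).items():
        if group is None:
            continue
        for fname, val in vars(group).items():
            if isinstance(val, Tensor):
                arrays[f"{comp}.{fname}"] = val.data
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": asdict(model.cfg), "variant": model.variant, "format": "dacb-checkpoint-v1"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> DACBModel:
    """Rebuild a model from :func:`save_checkpoint` output."""
    import json
    import pathlib

    path = pathlib.Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**sidecar["config"])
    model = DACBModel(cfg, variant=sidecar["variant"])
    with np.load(path.with_suffix(".npz")) as npz:
        for key in npz.files:
            comp, fname = key.split(".", 1)
            group = getattr(model.params, comp)
            tensor = getattr(group, fname)
            if tensor.data.shape != npz[key].shape:
                raise ValueError(f"checkpoint field {key} has shape {npz[key].shape}, expected {tensor.data.shape}")
            tensor.data = npz[key].astype(tensor.data.dtype)
    return model


def build_ablation_variant(cfg: ModelConfig, variant: str) -> DACBModel:
    """Construct the full model or a single-branch ablation.

    ``block1_spatial_only`` keeps conv + SE (no LSTM weights exist);
    ``block2_temporal_only`` keeps the Bi-LSTM (no conv/SE weights exist).
    """
    return DACBModel(cfg, variant=variant)
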