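"""The DACB building blocks as standalone NumPy operations.

Each layer is a plain function you can probe with hand-sized inputs; the
printed values follow directly from the layer formulas.
"""

import numpy as np

from dacb import conv1d_forward, dot_attention, lstm_step, se_excite, se_squeeze
from dacb.model import AttentionParams, ConvParams, LSTMParams, SEParams

# 1-D convolution with an identity kernel reproduces its input
w = np.zeros((3, 1, 1))
w[1, 0, 0] = 1.0
out = conv1d_forward(np.array([[1.0], [2.0], [3.0], [4.0]]), ConvParams(w=w, b=np.zeros(1)))
print("identity conv of [1,2,3,4]:", out[:, 0])  # -> [1, 2, 3, 4]

# SE attention: squeeze = per-map mean, excitation = two-layer bottleneck
u = np.array([[1.0, 4.0], [3.0, 0.0]])  # 2 timesteps x 2 feature maps
z = se_squeeze(u)
print("squeezed map means:", z)  # -> [2, 2]
s = se_excite(z, SEParams(W1=np.zeros((1, 2)), W2=np.zeros((2, 1))))
print("excitation with zero weights (sigmoid(0)):", s)  # -> [0.5, 0.5]

# one LSTM cell update with unit weights: gates all sigmoid(1)
p = LSTMParams(*[np.ones((2, 1)) for _ in range(4)], *[np.zeros(1) for _ in range(4)])
h, C = lstm_step([1.0], [0.0], [0.0], p)
print(f"scalar LSTM step: h={h[0]:.4f} (~0.3696), C={C[0]:.4f} (~0.5568)")

# dot-product attention over a 2-row value matrix
a, d = dot_attention(np.eye(2), AttentionParams(W_a=np.eye(2), q=np.array([1.0, 0.0])))
print(f"attention weights over the two rows: {np.round(d, 3)} (sum {d.sum():.6f})")
print("fused vector a = d @ V:", np.round(a, 3))
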