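"""Binary cross entropy on sigmoid probabilities."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def bce_loss(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE and its gradient w.r.t. the probabilities.

    The gradient composed with the upstream sigmoid backward reduces to the
    numerically benign (p - y) / n.
    """
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    y = targets.astype(p.dtype)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    grad = ((p - y) / (p * (1.0 - p))) / p.size
    return loss, grad.astype(np.float32)
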