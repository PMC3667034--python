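"""Small numerical helpers."""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["numeric_hessian"]


def numeric_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    Step per coordinate is ``rel_step * max(1, |x_j|)``; cost is
    2k^2 + 2k evaluations for k parameters.
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    steps = [np.eye(k)[i] * h[i] for i in range(k)]
    for i in range(k):
        H[i, i] = (f(x + steps[i]) - 2.0 * f0 + f(x - steps[i])) / h[i] ** 2
        for j in range(i + 1, k):
            H[i, j] = H[j, i] = (
                f(x + steps[i] + steps[j])
                - f(x + steps[i] - steps[j])
                - f(x - steps[i] + steps[j])
                + f(x - steps[i] - steps[j])
            ) / (4.0 * h[i] * h[j])
    return H
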