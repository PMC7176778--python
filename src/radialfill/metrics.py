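"""Error metrics used to score estimated sinograms and reconstructions."""

from __future__ import annotations

import numpy as np

__all__ = ["max_abs_error", "sum_abs_error", "rmse"]


def _diff(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def max_abs_error(a, b) -> float:
    """max |a − b| over all elements."""
    return float(np.abs(_diff(a, b)).max())


def sum_abs_error(a, b) -> float:
    """Σ |a − b| over all elements."""
    return float(np.abs(_diff(a, b)).sum())


def rmse(a, b) -> float:
    """Root mean square error √(mean (a − b)²)."""
    return float(np.sqrt(np.mean(_diff(a, b) ** 2)))
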