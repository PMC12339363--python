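"""Polyline helpers shared by rasterization, scoring and selection."""

from __future__ import annotations

import numpy as np

__all__ = ["resample_polyline", "arc_length"]


def arc_length(points: np.ndarray) -> float:
    """Total length of a polyline in mm."""
    points = np.asarray(points, dtype=np.float64)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Returns points at distances ``linspace(0, L, n)`` along the curve with
    ``n = max(2, ceil(L / step) + 1)``, so the spacing never exceeds ``step``
    and both endpoints are always included.  A degenerate polyline (all points
    coincident) returns its two endpoints unchanged.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        raise ValueError(f"expected an (n>=2, 3) polyline, got shape {points.shape}")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return points[[0, -1]].copy()
    n = max(2, int(np.ceil(total / step)) + 1)
    target = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for ax in range(3):
        out[:, ax] = np.interp(target, cum, points[:, ax])
    return out
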