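"""Fit-quality and smoothness metrics for curve repair diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["FitReport", "r_squared", "maep", "smoothness", "mae_mre"]


@dataclass
class FitReport:
    r_squared: float
    maep: float  # percent
    smoothness_pre: Optional[float] = None
    smoothness_post: Optional[float] = None


def r_squared(observed, predicted, printed_variant: bool = False) -> float:
    """Coefficient of determination, 1 − SSE/SST.

    ``printed_variant=True`` uses the explained-sum-of-squares numerator
    Σ(ŷ−ȳ)²/Σ(y−ȳ)² instead; the two agree only under OLS orthogonality.
    """
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed series has zero variance")
    if printed_variant:
        return float(1.0 - np.sum((yh - y.mean()) ** 2) / sst)
    return float(1.0 - np.sum((y - yh) ** 2) / sst)


def maep(observed, predicted) -> float:
    """Mean absolute error percentage: (1/N)·Σ|y−ŷ|/y × 100."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(y == 0):
        raise ValueError("observed values must be non-zero")
    return float(np.mean(np.abs(y - yh) / np.abs(y)) * 100.0)


def smoothness(series) -> float:
    """Mean absolute first difference; 0 for a constant series."""
    y = np.asarray(series, dtype=float).reshape(-1)
    if y.size < 2:
        raise ValueError("series must have length >= 2")
    return float(np.mean(np.abs(np.diff(y))))


def mae_mre(reference, measured) -> tuple:
    """(MAE, MRE %) of measured against reference, paired."""
    ref = np.asarray(reference, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if ref.shape != mea.shape:
        raise ValueError("reference and measured must have equal length")
    if np.any(ref == 0):
        raise ValueError("reference values must be non-zero")
    err = np.abs(mea - ref)
    return float(err.mean()), float(np.mean(err / np.abs(ref)) * 100.0)
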