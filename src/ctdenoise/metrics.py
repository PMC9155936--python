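"""Objective image-quality indicators: RMSE, MAE, MSE and PSNR.

PSNR uses the fixed peak value 255 of the canonical intensity scale,
``PSNR = 10 * log10(255**2 / MSE)`` in decibels, regardless of the actual
image maximum.  Identical images have MSE 0 and PSNR ``+inf`` (serialized
as the string ``"inf"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics"]

PEAK = 255.0


@dataclass(frozen=True)
class MetricsReport:
    """Error metrics between a reference image and a test image."""

    rmse: float
    mae: float
    mse: float
    psnr: float

    def as_dict(self) -> dict[str, float | str]:
        """Plain-dict form; infinite PSNR becomes the string ``"inf"``."""
        psnr: float | str = "inf" if math.isinf(self.psnr) else self.psnr
        return {"rmse": self.rmse, "mae": self.mae, "mse": self.mse, "psnr": psnr}


def compute_metrics(reference: np.ndarray, test: np.ndarray) -> MetricsReport:
    """RMSE/MAE/MSE/PSNR of ``test`` against ``reference`` (symmetric in its inputs)."""
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if ref.size == 0:
        raise ValueError("empty image")
    diff = ref - tst
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    rmse = math.sqrt(mse)
    psnr = math.inf if mse == 0 else 10.0 * math.log10(PEAK * PEAK / mse)
    return MetricsReport(rmse=rmse, mae=mae, mse=mse, psnr=psnr)
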