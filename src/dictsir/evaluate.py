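"""Image-quality metrics and display windowing.

NMAD is the normalized mean absolute deviation in percent,

    NMAD% = 100 * sum_ij |mu_ij - truth_ij| / sum_ij truth_ij

(the denominator is the plain sum of the reference image), and SNR is

    SNR = 10 log10( sum_ij truth_ij^2 / sum_ij (mu_ij - truth_ij)^2 )   [dB].

Display export follows CT practice: a linear window [lo, hi] (Hounsfield
units for clinical-style images, raw attenuation for dimensionless
phantoms) clipped and scaled to 8 bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["QualityReport", "nmad", "snr", "hu_window", "quality_report"]


def nmad(mu: np.ndarray, mu_truth: np.ndarray) -> float:
    """Normalized mean absolute deviation against the reference, percent."""
    mu = np.asarray(mu, float)
    truth = np.asarray(mu_truth, float)
    if mu.shape != truth.shape:
        raise ValueError("shape mismatch")
    denom = float(truth.sum())
    if denom <= 0:
        raise ValueError("reference image must have positive sum")
    return 100.0 * float(np.abs(mu - truth).sum()) / denom


def snr(mu: np.ndarray, mu_truth: np.ndarray) -> float:
    """Signal-to-noise ratio against the reference in dB.

    Identical images have no noise energy; the sentinel ``math.inf`` is
    returned in that case.
    """
    mu = np.asarray(mu, float)
    truth = np.asarray(mu_truth, float)
    if mu.shape != truth.shape:
        raise ValueError("shape mismatch")
    noise = float(((mu - truth) ** 2).sum())
    if noise == 0.0:
        return math.inf
    return 10.0 * math.log10(float((truth ** 2).sum()) / noise)


def hu_window(image: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip-and-scale an image to an 8-bit display raster.

    Values ``<= lo`` map to 0, ``>= hi`` to 255, linearly in between.
    Rounding is round-half-to-even, so an exact window midpoint maps to
    128 (or 127 when floating point puts the scaled value a hair under
    the .5 boundary).
    """
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    img = np.asarray(image, float)
    scaled = (np.clip(img, lo, hi) - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


@dataclass
class QualityReport:
    """NMAD/SNR summary for one reconstruction."""

    nmad_percent: float
    snr_db: float
    n_pixels: int
    window: tuple[float, float] | None = None

    def to_json(self) -> str:
        d = asdict(self)
        if math.isinf(self.snr_db):
            d["snr_db"] = "inf"
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "QualityReport":
        d = json.loads(text)
        if d.get("snr_db") == "inf":
            d["snr_db"] = math.inf
        if d.get("window") is not None:
            d["window"] = tuple(d["window"])
        return cls(**d)


def quality_report(mu: np.ndarray, mu_truth: np.ndarray,
                   window: tuple[float, float] | None = None) -> QualityReport:
    """Bundle NMAD and SNR for a reconstruction/reference pair."""
    return QualityReport(nmad_percent=nmad(mu, mu_truth),
                         snr_db=snr(mu, mu_truth),
                         n_pixels=int(np.asarray(mu).size), window=window)
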