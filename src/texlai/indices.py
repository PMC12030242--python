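"""Vegetation indices from plot-mean band reflectance.

Ten classic multispectral indices built from the blue (B), green (G), red (R)
and near-infrared (NIR) plot means.  An index whose denominator vanishes for
a given record is returned as NaN (an invalid marker for that index only);
callers decide how to treat it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .imagery import ReflectanceRecord

__all__ = ["VI_NAMES", "VegetationIndexSet", "compute_vis"]

VI_NAMES: tuple[str, ...] = (
    "SAVI",
    "EVI",
    "MSR",
    "DVI",
    "CIgreen",
    "RDVI",
    "TVI",
    "GNDVI",
    "VDVI",
    "CVI",
)


@dataclass
class VegetationIndexSet:
    """The ten vegetation indices of one plot."""

    plot_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(VI_NAMES):
            raise ValueError("expected exactly the 10 canonical VI names")


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0.0 else math.nan


def compute_vis(record: ReflectanceRecord) -> VegetationIndexSet:
    """Evaluate the ten index formulas on one reflectance record.

    SAVI    = 1.5·(NIR−R)/(NIR+R+0.5)
    EVI     = 2.5·(NIR−R)/((NIR+6R−7.5B)+1)   (signed even if denominator < 0)
    MSR     = (NIR/R−1)/√(NIR/R+1)
    DVI     = NIR−R
    CIgreen = NIR/G−1
    RDVI    = (NIR−R)/√(NIR+R)
    TVI     = √((NIR−R)/(NIR+R)+0.5)
    GNDVI   = (NIR−G)/(NIR+G)
    VDVI    = (2G−R−B)/(2G+R+B)
    CVI     = (2NIR−R−G)/(2NIR+R+G)
    """
    b, g, r, nir = record.R_B, record.R_G, record.R_RED, record.R_NIR
    savi = _safe_div(1.5 * (nir - r), nir + r + 0.5)
    evi = _safe_div(2.5 * (nir - r), (nir + 6.0 * r - 7.5 * b) + 1.0)
    if r > 0:
        ratio = nir / r
        msr = (ratio - 1.0) / math.sqrt(ratio + 1.0) if ratio + 1.0 > 0 else math.nan
    else:
        msr = math.nan
    dvi = nir - r
    cigreen = _safe_div(nir, g) - 1.0 if g != 0 else math.nan
    rdvi = (nir - r) / math.sqrt(nir + r) if nir + r > 0 else math.nan
    ndvi = _safe_div(nir - r, nir + r)
    tvi = math.sqrt(ndvi + 0.5) if not math.isnan(ndvi) and ndvi + 0.5 >= 0 else math.nan
    gndvi = _safe_div(nir - g, nir + g)
    vdvi = _safe_div(2.0 * g - r - b, 2.0 * g + r + b)
    cvi = _safe_div(2.0 * nir - r - g, 2.0 * nir + r + g)
    return VegetationIndexSet(
        record.plot_id,
        {
            "SAVI": savi,
            "EVI": evi,
            "MSR": msr,
            "DVI": dvi,
            "CIgreen": cigreen,
            "RDVI": rdvi,
            "TVI": tvi,
            "GNDVI": gndvi,
            "VDVI": vdvi,
            "CVI": cvi,
        },
    )
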