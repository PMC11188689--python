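"""Plate-based validation assay arithmetic: CFU/ml from serial dilutions
and promoter activity from GFP/OD readings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PLATED_VOLUME_ML = 0.1
CFU_MIN_COLONIES = 100
CFU_MAX_COLONIES = 500


@dataclass
class PlateCount:
    """One plate of a 10-fold serial dilution (0.1 ml plated).

    Counts below 100 or above 500 colonies are flagged unreliable — too few
    colonies are dominated by sampling error, too many merge.
    """

    n_colonies: float
    dilution: int

    @property
    def reliable(self) -> bool:
        return CFU_MIN_COLONIES <= self.n_colonies <= CFU_MAX_COLONIES


def cfu_per_ml(n_colonies, dilution: int) -> tuple[float, bool]:
    """CFU/ml = N · 10^d / 0.1 for N colonies at 10-fold dilution step d.

    ``n_colonies`` may be a list of replicate plates at the same dilution;
    they are averaged before conversion. Returns (CFU/ml, reliable flag).
    """
    if np.ndim(n_colonies) > 0:
        arr = np.asarray(n_colonies, dtype=float)
        if (arr < 0).any():
            raise ValueError("colony counts must be non-negative")
        n = float(arr.mean())
    else:
        n = float(n_colonies)
        if n < 0:
            raise ValueError("colony counts must be non-negative")
    if dilution < 0 or int(dilution) != dilution:
        raise ValueError("dilution must be a non-negative integer exponent")
    cfu = n * 10.0 ** int(dilution) / PLATED_VOLUME_ML
    return cfu, PlateCount(n, int(dilution)).reliable


def promoter_activity(gfp: float, od600: float, gfp_blank: float = 0.0, od_blank: float = 0.0) -> float:
    """Promoter activity in AU = GFP / (1000 × OD600).

    Blank corrections (no-GFP and no-growth controls) are optional explicit
    arguments so the formula stays a pure function of its inputs.
    """
    gfp = gfp - gfp_blank
    od = od600 - od_blank
    if od <= 0:
        raise ValueError("OD600 must be positive after blank correction")
    return gfp / (1000.0 * od)
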