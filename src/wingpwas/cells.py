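"""Cell geometry from trichome counts and per-cell protein levels.

Whole-proteome normalization (median centering) reports protein amount per
unit of total protein, so a protein kept at constant copies per cell looks
less abundant in bigger cells. Converting back with an estimate of relative
cell volume undoes this artifact:

    cell area  = 10^4 um^2 / trichome count in the 100 um x 100 um square
    cell count = wing area / cell area
    volume     ~ area^(3/2)
    per-cell level = 2^(log2 level) x relative volume

With the worked two-cell example (big cell volume 2X holding amount Y/2,
small cell volume X holding Y) both convert to the same per-cell value XY.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cell_metrics", "cell_volume", "per_cell_level"]

DEFINED_AREA_UM2 = 1.0e4  # the counting square, 100 um x 100 um


def cell_metrics(trichome_count, wing_area) -> pd.DataFrame:
    """Single-cell area, total cell number and relative volume per row.

    ``trichome_count`` is the cell count inside the fixed 10^4 um^2 square
    (mean over flies if pre-averaged); ``wing_area`` the whole-wing area in
    um^2. Both must be positive.
    """
    count = np.asarray(trichome_count, dtype=float)
    area = np.asarray(wing_area, dtype=float)
    if (count <= 0).any() or (area <= 0).any():
        raise ValueError("trichome counts and wing areas must be positive")
    cell_area = DEFINED_AREA_UM2 / count
    return pd.DataFrame(
        {
            "trichome_count": count,
            "wing_area": area,
            "cell_area": cell_area,
            "cell_number": area / cell_area,
            "cell_volume": cell_volume(cell_area),
        }
    )


def cell_volume(cell_area) -> np.ndarray:
    """Relative cell volume: (cell area)^(3/2)."""
    area = np.asarray(cell_area, dtype=float)
    if (area <= 0).any():
        raise ValueError("cell area must be positive")
    return np.power(area, 1.5)


def per_cell_level(log2_level, volume, normalize_volumes: bool = True):
    """Linear-scale per-cell protein level: 2^(log2 level) x relative volume.

    Volumes are divided by their mean first (a pure rescaling that keeps
    per-cell levels on a comparable scale and leaves correlations intact);
    pass ``normalize_volumes=False`` for the raw identity.
    """
    lv = np.asarray(log2_level, dtype=float)
    vol = np.asarray(volume, dtype=float)
    if (vol <= 0).any():
        raise ValueError("cell volumes must be positive")
    if normalize_volumes:
        vol = vol / vol.mean()
    return np.power(2.0, lv) * vol
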