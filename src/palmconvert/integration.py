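"""Integration of the 2019 plantation base maps into one class grid.

The 2019 class map combines four boolean layers with fixed precedence:
the industrial-plantation map wins everywhere it is set; pulp plantations
(optional) come next; pixels flagged oil palm by the smallholder base map
or by the radar update become smallholder unless the coconut exclusion
mask removes them; everything else is "other". The coconut mask only ever
removes would-be smallholder pixels — the misclassification it corrects
lives in the smallholder base map, never in the industrial layer.
"""

from __future__ import annotations

import numpy as np

from .grids import INDUSTRIAL, OTHER, PULP, SMALLHOLDER, check_aligned


def integrate_basemaps(industrial: np.ndarray,
                       base_oilpalm: np.ndarray,
                       radar_oilpalm: np.ndarray | None = None,
                       coconut_mask: np.ndarray | None = None,
                       pulp: np.ndarray | None = None) -> np.ndarray:
    """Merge boolean base maps into a class grid (codes 0/1/2/3).

    Precedence: industrial > pulp > coconut removal > smallholder > other.
    A pixel is industrial iff the industrial layer is set; otherwise pulp
    iff the pulp layer is set; otherwise smallholder iff
    ``(base_oilpalm | radar_oilpalm) & ~coconut_mask``; otherwise other.
    """
    industrial = np.asarray(industrial, dtype=bool)
    base_oilpalm = np.asarray(base_oilpalm, dtype=bool)
    shape = check_aligned(industrial, base_oilpalm)
    if radar_oilpalm is None:
        radar_oilpalm = np.zeros(shape, dtype=bool)
    if coconut_mask is None:
        coconut_mask = np.zeros(shape, dtype=bool)
    if pulp is None:
        pulp = np.zeros(shape, dtype=bool)
    radar_oilpalm = np.asarray(radar_oilpalm, dtype=bool)
    coconut_mask = np.asarray(coconut_mask, dtype=bool)
    pulp = np.asarray(pulp, dtype=bool)
    check_aligned(industrial, radar_oilpalm, coconut_mask, pulp)

    out = np.full(shape, OTHER, dtype=np.int16)
    smallholder = (base_oilpalm | radar_oilpalm) & ~coconut_mask
    out[smallholder] = SMALLHOLDER
    out[pulp] = PULP
    out[industrial] = INDUSTRIAL
    return out
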