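"""Annual cloud-free composites and the normalized burn ratio (NBR).

Two compositing criteria are supported, both operating on the cloud-masked
observations of one calendar year:

* **median** — per-pixel, per-band median; clean mosaics, but clearings
  late in the year can be averaged away.
* **minimum NBR** — per pixel, the single observation with the lowest NBR
  is selected and all of its bands copied jointly; noisier, but captures
  clearings whenever they occur within the year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import ObservationStack

log = logging.getLogger(__name__)


def nbr(nir, swir):
    """Normalized burn ratio, ``(NIR - SWIR) / (NIR + SWIR)`` in [-1, 1].

    Where ``nir + swir`` is zero the ratio is undefined and NaN is
    returned (never an exception); scalars in, scalar out.
    """
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    denom = nir + swir
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - swir) / np.where(denom == 0, 1, denom),
                       np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class Composite:
    """An annual composite: 3 bands plus a validity mask."""

    year: int
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    valid: np.ndarray
    criterion: str  # "median" or "min_nbr"

    @property
    def nbr(self) -> np.ndarray:
        return nbr(self.nir, self.swir)


def _masked_bands(stack: ObservationStack, year: int):
    """Cloud-masked band cubes (K, H, W) for one year; NaN where cloudy."""
    obs = sorted(stack.for_year(year), key=lambda o: o.date)
    if not obs:
        return None
    shape = obs[0].red.shape
    k = len(obs)
    cubes = {b: np.empty((k, *shape), dtype=float) for b in ("red", "nir", "swir")}
    for i, o in enumerate(obs):
        for b in cubes:
            band = getattr(o, b).astype(float).copy()
            band[o.cloud] = np.nan
            cubes[b][i] = band
    return cubes


def median_composite(stack: ObservationStack, year: int) -> Composite:
    """Per-band median over a year's cloud-free observations.

    Bands are treated independently; a pixel with no cloud-free
    observation is flagged invalid and holds NaN.
    """
    cubes = _masked_bands(stack, year)
    if cubes is None:
        log.warning("no observations in %d; composite entirely invalid", year)
        raise_shape = _infer_shape(stack)
        nanband = np.full(raise_shape, np.nan)
        return Composite(year, nanband.copy(), nanband.copy(), nanband.copy(),
                         np.zeros(raise_shape, dtype=bool), "median")
    valid = np.isfinite(cubes["nir"]).any(axis=0)
    with warnings.catch_warnings():
        # all-observations-cloudy pixels legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        bands = {b: np.nanmedian(c, axis=0) for b, c in cubes.items()}
    return Composite(year, bands["red"], bands["nir"], bands["swir"],
                     valid, "median")


def min_nbr_composite(stack: ObservationStack, year: int) -> Composite:
    """Select, per pixel, the cloud-free observation with minimum NBR.

    All bands of the winning observation are copied jointly. Ties on NBR
    go to the earliest acquisition date; an undefined NBR (``nir+swir=0``)
    never wins.
    """
    cubes = _masked_bands(stack, year)
    if cubes is None:
        log.warning("no observations in %d; composite entirely invalid", year)
        shape = _infer_shape(stack)
        nanband = np.full(shape, np.nan)
        return Composite(year, nanband.copy(), nanband.copy(), nanband.copy(),
                         np.zeros(shape, dtype=bool), "min_nbr")
    nbr_cube = nbr(cubes["nir"], cubes["swir"])
    valid = np.isfinite(nbr_cube).any(axis=0)
    # nanargmin returns the first (earliest, observations are date-sorted)
    # occurrence of the minimum; guard all-NaN columns
    safe = np.where(np.isfinite(nbr_cube), nbr_cube, np.inf)
    idx = np.argmin(safe, axis=0)
    bands = {}
    for b, c in cubes.items():
        chosen = np.take_along_axis(c, idx[None], axis=0)[0]
        chosen[~valid] = np.nan
        bands[b] = chosen
    return Composite(year, bands["red"], bands["nir"], bands["swir"],
                     valid, "min_nbr")


def _infer_shape(stack: ObservationStack):
    if len(stack) == 0:
        raise ValueError("cannot composite an empty observation stack")
    return stack.observations[0].red.shape
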