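"""Synthetic landscape, observation, price and degraded-map generators.

Every downstream stage of the pipeline (compositing, change accounting,
accuracy assessment, disturbance-year detection, elasticity estimation) is
exercised against landscapes produced here, for which the complete ground
truth is known. The generator emulates the statistical structure of the
Indonesian oil-palm setting: a year-2000 old-growth forest mask with
spatially clustered clearing, industrial plantations as large rectilinear
blocks and smallholders as small irregular patches, a stated split of
rapid (same-year) versus delayed conversion versus expansion onto long-
cleared land, annual clearing intensity log-log coupled to a crude-palm-oil
price series with a known elasticity, multi-date 3-band observations whose
NBR drops at clearing, and a classification-error model with configurable
omission and commission rates.

Randomness: one top-level seed; each generator draws from its own child of
``numpy.random.SeedSequence(seed)`` (fixed spawn order: landscape,
observations, prices, degradation, sampling), so generators are individually
and jointly reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import grids
from .grids import INDUSTRIAL, OTHER, SMALLHOLDER, YEAR_NONE, YEAR_PRE2000

_STREAMS = {"landscape": 0, "observations": 1, "prices": 2,
            "degrade": 3, "sampling": 4}


def _rng(config: "SyntheticConfig", stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Fractions of the landscape under each plantation type, the composition
    of plantation expansion (rapid / delayed / on pre-2000 non-forest), the
    pre-2000 plantation stock, background forest cover and loss, the price
    process and its coupling to expansion, the observation model, and the
    map-degradation error rates. Defaults reproduce the study conditions:
    expansion composition 34% rapid / 3% delayed / 63% on old non-forest,
    48% of the 2019 plantation area already standing in 2000, total forest
    loss ~3.16x the forest area converted to plantations, omission 8.3%
    (industrial) and 36.1% (smallholder), commission 4.7% and 12.6%.
    """

    grid_rows: int = 200
    grid_cols: int = 200
    pixel_area_ha: float = 0.09          # 30 m Landsat cell
    year_start: int = 2001
    year_end: int = 2019
    frac_industrial: float = 0.12        # share of landscape
    frac_smallholder: float = 0.08
    frac_rapid: float = 0.34             # composition of 2001-2019 expansion
    frac_delayed: float = 0.03
    frac_old_nonforest: float = 0.63
    frac_pre2000: float = 0.48           # plantation stock already in place
    frac_forest: float = 0.55            # year-2000 old-growth cover
    loss_multiplier: float = 3.16        # total loss / conversion loss
    n_regions: int = 3
    zone_fraction: float = 0.20          # prohibited-zone share of landscape
    elasticity_true: float = 1.08
    price_base: float = 600.0            # USD per tonne
    price_walk_sd: float = 0.04          # monthly log-price random-walk step
    price_noise_sd: float = 0.10         # sd of log-area disturbance
    obs_per_year: int = 8
    cloud_fraction: float = 0.30
    nbr_pre: float = 0.65
    nbr_post: float = 0.05
    nbr_noise_sd: float = 0.05
    omission_rate: dict = field(default_factory=lambda: {
        "industrial": 0.083, "smallholder": 0.361})
    commission_rate: dict = field(default_factory=lambda: {
        "industrial": 0.047, "smallholder": 0.126})
    seed: int = 0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_pixels(self) -> int:
        return self.grid_rows * self.grid_cols

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_area_ha <= 0:
            raise ValueError("pixel_area_ha must be positive")
        for name in ("frac_industrial", "frac_smallholder", "frac_pre2000",
                     "frac_forest", "cloud_fraction", "zone_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_industrial + self.frac_smallholder > 1.0:
            raise ValueError("plantation fractions exceed the landscape")
        comp = self.frac_rapid + self.frac_delayed + self.frac_old_nonforest
        if abs(comp - 1.0) > 1e-9:
            raise ValueError(
                f"expansion composition fractions sum to {comp}, not 1")
        if not self.nbr_pre > self.nbr_post:
            raise ValueError("nbr_pre must exceed nbr_post (clearing lowers NBR)")
        for name in ("nbr_pre", "nbr_post"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [-1, 1]")
        if self.price_base <= 0:
            raise ValueError("price_base must be positive")
        if not np.isfinite(self.elasticity_true):
            raise ValueError("elasticity_true must be finite")
        for d in (self.omission_rate, self.commission_rate):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"error rate {k}={v} outside [0, 1]")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class LandscapeTruth:
    """Complete ground truth of one generated landscape."""

    forest_2000: np.ndarray          # bool: old-growth forest in 2000
    tree_loss_year: np.ndarray       # int: 0 or 2001..2019
    plantation_class: np.ndarray     # int: 0/1/2 codes
    establishment_year: np.ndarray   # int: 0, 2000, or 2001..2019
    region_id: np.ndarray            # int: 1..n_regions, contiguous bands
    zone_mask: np.ndarray            # bool: prohibited (state forest) zone
    year_start: int = 2001
    year_end: int = 2019

    def validate(self) -> None:
        grids.check_aligned(self.forest_2000, self.tree_loss_year,
                            self.plantation_class, self.establishment_year,
                            self.region_id, self.zone_mask)
        if np.any((self.tree_loss_year > 0) & ~self.forest_2000):
            raise ValueError("tree loss recorded outside the 2000 forest mask")
        planted = self.plantation_class != OTHER
        if np.any((self.establishment_year > 0) & ~planted):
            raise ValueError("establishment year set outside plantations")
        if np.any(planted & (self.establishment_year == YEAR_NONE)):
            raise ValueError("plantation pixel without an establishment year")
        est, loss = self.establishment_year, self.tree_loss_year
        bad = planted & (loss > 0) & (est > YEAR_PRE2000) & (est < loss)
        if np.any(bad):
            raise ValueError("plantation established before its forest was lost")


def _place_industrial(rng, cls, target, rows, cols):
    """Paint rectangular blocks with code 1 until ~target pixels covered."""
    guard = 0
    while np.count_nonzero(cls == INDUSTRIAL) < target and guard < 10_000:
        guard += 1
        h = int(rng.integers(8, 26))
        w = int(rng.integers(8, 26))
        r = int(rng.integers(0, max(rows - h, 1)))
        c = int(rng.integers(0, max(cols - w, 1)))
        block = cls[r:r + h, c:c + w]
        block[block == OTHER] = INDUSTRIAL


def _place_smallholder(rng, cls, target, rows, cols):
    """Grow small irregular patches (random BFS blobs) with code 2."""
    guard = 0
    offsets = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
    while np.count_nonzero(cls == SMALLHOLDER) < target and guard < 50_000:
        guard += 1
        r0 = int(rng.integers(0, rows))
        c0 = int(rng.integers(0, cols))
        if cls[r0, c0] != OTHER:
            continue
        size = int(rng.integers(5, 41))
        frontier = [(r0, c0)]
        grown = 0
        while frontier and grown < size:
            idx = int(rng.integers(0, len(frontier)))
            r, c = frontier.pop(idx)
            if cls[r, c] != OTHER:
                continue
            cls[r, c] = SMALLHOLDER
            grown += 1
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and cls[rr, cc] == OTHER:
                    frontier.append((rr, cc))


def generate_landscape(config: SyntheticConfig) -> LandscapeTruth:
    """Generate a landscape with known classes, years and masks.

    Industrial estates are large rectilinear blocks, smallholdings small
    irregular patches. Plantation pixels are partitioned into a pre-2000
    stock and 2001-2019 expansion; expansion pixels split into rapid
    (cleared and planted the same year), delayed (cleared first, planted
    later) and on-old-non-forest fates per the configured composition.
    Establishment years are drawn with probabilities proportional to the
    price-coupled annual expansion areas from :func:`generate_price_series`,
    so the configured elasticity is recoverable downstream. Background
    forest loss (clearing never followed by plantation) is added so total
    loss is ``loss_multiplier`` times the conversion loss.
    """
    config.validate()
    rng = _rng(config, "landscape")
    rows, cols = config.grid_rows, config.grid_cols
    years = config.years

    cls = np.zeros((rows, cols), dtype=np.int16)
    _place_industrial(rng, cls, round(config.frac_industrial * config.n_pixels),
                      rows, cols)
    _place_smallholder(rng, cls,
                       round(config.frac_smallholder * config.n_pixels),
                       rows, cols)

    # annual expansion weights from the price-coupled series
    _, annual = generate_price_series(config)
    weights = annual["area_ha"].to_numpy()
    weights = weights / weights.sum()

    planted_idx = np.flatnonzero(cls.ravel() != OTHER)
    rng.shuffle(planted_idx)
    n_planted = planted_idx.size
    n_pre = round(config.frac_pre2000 * n_planted)
    pre_idx = planted_idx[:n_pre]
    expansion = planted_idx[n_pre:]
    n_exp = expansion.size
    n_rapid = round(config.frac_rapid * n_exp)
    n_delayed = round(config.frac_delayed * n_exp)
    rapid_idx = expansion[:n_rapid]
    delayed_idx = expansion[n_rapid:n_rapid + n_delayed]
    oldnf_idx = expansion[n_rapid + n_delayed:]

    est = np.zeros(rows * cols, dtype=np.int16)
    loss = np.zeros(rows * cols, dtype=np.int16)
    est[pre_idx] = YEAR_PRE2000
    est[expansion] = rng.choice(years, size=n_exp, p=weights)
    # delayed pixels need room for an earlier loss year
    est[delayed_idx] = np.maximum(est[delayed_idx], config.year_start + 1)
    loss[rapid_idx] = est[rapid_idx]
    loss[delayed_idx] = (config.year_start + (
        rng.random(delayed_idx.size)
        * (est[delayed_idx] - config.year_start)).astype(np.int16))

    # clustered year-2000 forest: smoothed noise thresholded at the target
    # cover, then forced consistent with the plantation fates
    noise = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 6.0)
    thresh = np.quantile(noise, 1.0 - config.frac_forest)
    forest = (noise >= thresh).ravel()
    forest[rapid_idx] = True
    forest[delayed_idx] = True
    forest[oldnf_idx] = False
    forest[pre_idx] = False

    # background clearing (forest loss never converted to plantation)
    n_conv_loss = n_rapid + n_delayed
    n_extra = round((config.loss_multiplier - 1.0) * n_conv_loss)
    candidates = np.flatnonzero(forest & (cls.ravel() == OTHER))
    rng.shuffle(candidates)
    extra_idx = candidates[:n_extra]
    loss[extra_idx] = rng.choice(years, size=extra_idx.size, p=weights)

    region = np.zeros((rows, cols), dtype=np.int16)
    bands = np.array_split(np.arange(cols), max(config.n_regions, 1))
    for i, band in enumerate(bands, start=1):
        region[:, band] = i

    zone = np.zeros((rows, cols), dtype=bool)
    zr = max(int(round(rows * np.sqrt(config.zone_fraction))), 1)
    zc = max(int(round(cols * np.sqrt(config.zone_fraction))), 1)
    r0 = int(rng.integers(0, rows - zr + 1))
    c0 = int(rng.integers(0, cols - zc + 1))
    zone[r0:r0 + zr, c0:c0 + zc] = True

    truth = LandscapeTruth(
        forest_2000=forest.reshape(rows, cols),
        tree_loss_year=loss.reshape(rows, cols),
        plantation_class=cls,
        establishment_year=est.reshape(rows, cols),
        region_id=region, zone_mask=zone,
        year_start=config.year_start, year_end=config.year_end)
    truth.validate()
    return truth


def generate_price_series(config: SyntheticConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly CPO prices and a price-coupled annual expansion series.

    Monthly log prices follow a random walk (step sd ``price_walk_sd``)
    around ``price_base``; annual prices are calendar-year means. Annual
    expansion areas obey ``ln(area_t) = alpha + beta*ln(price_t) + eps_t``
    with ``beta = elasticity_true`` and ``eps ~ N(0, price_noise_sd)``;
    ``alpha`` is set so the expected total expansion matches the configured
    plantation growth. Returns ``(monthly, annual)`` frames with columns
    ``(year, month, price)`` and ``(year, price, area_ha)``.
    """
    config.validate()
    rng = _rng(config, "prices")
    years = config.years
    n_months = 12 * years.size
    steps = rng.normal(0.0, config.price_walk_sd, size=n_months)
    log_price = np.log(config.price_base) + np.cumsum(steps) - steps[0]
    monthly = pd.DataFrame({
        "year": np.repeat(years, 12),
        "month": np.tile(np.arange(1, 13), years.size),
        "price": np.exp(log_price),
    })
    annual_price = monthly.groupby("year")["price"].mean()

    expansion_frac = ((config.frac_industrial + config.frac_smallholder)
                      * (1.0 - config.frac_pre2000))
    target_total_ha = max(
        expansion_frac * config.n_pixels * config.pixel_area_ha, 1e-6)
    beta = config.elasticity_true
    log_p = np.log(annual_price.to_numpy())
    alpha = np.log(target_total_ha) - np.log(np.sum(np.exp(beta * log_p)))
    eps = rng.normal(0.0, config.price_noise_sd, size=years.size) \
        if config.price_noise_sd > 0 else np.zeros(years.size)
    area = np.exp(alpha + beta * log_p + eps)
    annual = pd.DataFrame({"year": years,
                           "price": annual_price.to_numpy(),
                           "area_ha": area})
    return monthly, annual


def degrade_to_map(truth: LandscapeTruth, config: SyntheticConfig
                   ) -> np.ndarray:
    """Corrupt the true class grid with configured omission and commission.

    Omission: a true plantation pixel of class ``c`` is mapped "other" with
    probability ``omission_rate[c]`` (e.g. young smallholdings missed by the
    base map). Commission: enough true-"other" pixels are mapped as class
    ``c`` that the realized commission rate of the mapped class approaches
    ``commission_rate[c]``. Deterministic given the configured seed.
    """
    config.validate()
    rng = _rng(config, "degrade")
    cls = truth.plantation_class
    mapped = cls.ravel().copy()

    for name, code in (("industrial", INDUSTRIAL), ("smallholder", SMALLHOLDER)):
        om = config.omission_rate.get(name, 0.0)
        idx = np.flatnonzero(cls.ravel() == code)
        if om > 0 and idx.size:
            drop = rng.random(idx.size) < om
            mapped[idx[drop]] = OTHER

    # commit only truly-"other" pixels, sized so the mapped class's
    # commission proportion approaches the configured rate
    other_pool = np.flatnonzero((mapped == OTHER) & (cls.ravel() == OTHER))
    rng.shuffle(other_pool)
    used = 0
    for name, code in (("industrial", INDUSTRIAL), ("smallholder", SMALLHOLDER)):
        q = config.commission_rate.get(name, 0.0)
        if q <= 0:
            continue
        kept = np.count_nonzero(mapped == code)
        n_extra = int(round(kept * q / (1.0 - q)))
        mapped[other_pool[used:used + n_extra]] = code
        used += n_extra
    return mapped.reshape(cls.shape)


# ---------------------------------------------------------------------------
# observation model


@dataclass
class Observation:
    """One dated 3-band scene with a per-pixel cloud flag."""

    date: "np.datetime64"
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    cloud: np.ndarray

    @property
    def year(self) -> int:
        return int(str(self.date)[:4])


@dataclass
class ObservationStack:
    """A date-ordered collection of observations over one grid."""

    observations: list[Observation]

    def __iter__(self):
        return iter(self.observations)

    def __len__(self):
        return len(self.observations)

    def for_year(self, year: int) -> "ObservationStack":
        return ObservationStack(
            [o for o in self.observations if o.year == year])

    def nbr_series(self, row: int, col: int) -> pd.DataFrame:
        """Cloud-free (date, nbr) series at one pixel."""
        recs = []
        for o in self.observations:
            if o.cloud[row, col]:
                continue
            denom = o.nir[row, col] + o.swir[row, col]
            if denom <= 0:
                continue
            recs.append((o.date, (o.nir[row, col] - o.swir[row, col]) / denom))
        return pd.DataFrame(recs, columns=["date", "nbr"])


def _dates_for_year(year: int, fracs: np.ndarray) -> list[np.datetime64]:
    start = np.datetime64(f"{year}-01-01")
    return [start + np.timedelta64(int(f * 364), "D") for f in fracs]


def generate_observations(truth: LandscapeTruth, config: SyntheticConfig,
                          years: list[int] | None = None) -> ObservationStack:
    """Simulate multi-date reflectance observations over the landscape.

    Each year carries ``obs_per_year`` scenes at evenly spaced dates with
    small jitter. A pixel's NBR sits at ``nbr_pre`` until its clearing and
    at ``nbr_post`` afterwards, plus Gaussian noise; the clearing falls
    early (first third) in its labelled loss year, so the cleared state
    dominates that year's record — pixels cleared near a year boundary
    would otherwise be ambiguous to date annually at all.
    Cloud flags are i.i.d. Bernoulli(``cloud_fraction``). Bands are derived
    from the NBR target at fixed total brightness, so these are statistical
    stand-ins, not radiometrically realistic spectra.
    """
    config.validate()
    rng = _rng(config, "observations")
    rows, cols = truth.forest_2000.shape
    if years is None:
        years = list(config.years)

    # per-pixel within-year clearing time, early enough in the year that
    # the annual record of the labelled loss year reflects the cleared
    # state (the annual dating convention of the loss product)
    clear_frac = rng.random((rows, cols)) * 0.35
    loss = truth.tree_loss_year
    obs: list[Observation] = []
    for year in years:
        base = (np.arange(config.obs_per_year) + 0.5) / config.obs_per_year
        jitter = rng.uniform(-0.4, 0.4, size=config.obs_per_year) \
            / config.obs_per_year
        fracs = np.clip(base + jitter, 0.0, 1.0)
        fracs.sort()
        for d, frac in zip(_dates_for_year(year, fracs), fracs):
            cleared = (loss > 0) & ((year > loss) |
                                    ((year == loss) & (frac >= clear_frac)))
            nbr = np.where(cleared, config.nbr_post, config.nbr_pre)
            nbr = nbr + rng.normal(0.0, config.nbr_noise_sd, size=(rows, cols))
            nbr = np.clip(nbr, -0.98, 0.98)
            s = 0.6  # nir + swir total brightness
            nir = (s * (1.0 + nbr) / 2.0).astype(np.float32)
            swir = (s * (1.0 - nbr) / 2.0).astype(np.float32)
            red = np.where(cleared, 0.28, 0.08) + rng.normal(
                0.0, 0.02, size=(rows, cols))
            red = np.clip(red, 0.0, 1.0).astype(np.float32)
            cloud = rng.random((rows, cols)) < config.cloud_fraction
            obs.append(Observation(date=d, red=red, nir=nir, swir=swir,
                                   cloud=cloud))
    return ObservationStack(obs)
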