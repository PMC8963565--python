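"""Annual change accounting: forest loss, establishment years, conversion.

The central bookkeeping of the pipeline. Forest loss is the annual
tree-loss grid intersected with the year-2000 old-growth mask. Plantation
establishment years are either mapped directly (industrial) or dated from
the tree-loss grid (smallholder). Each plantation pixel established in
2001-2019 takes exactly one of three fates:

* **rapid conversion** — it was forest in 2000 and lost its cover in the
  same calendar year it was established (the criterion for attributing the
  deforestation to the plantation);
* **delayed conversion** — forest in 2000, cleared in an earlier year,
  planted later;
* **on old non-forest** — established on land that was not old-growth
  forest in 2000 (or shows no recorded loss).

Pixels with establishment year 2000 form the pre-2000 stock and are not
part of the 2001-2019 expansion. All areas are summed in hectares from a
per-pixel area grid; "same calendar year" is integer equality of the two
annual year grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (CLASS_NAMES, OIL_PALM_CODES, OTHER, YEAR_NONE,
                    YEAR_PRE2000, check_aligned)

FATE_COLUMNS = ["expansion_ha", "rapid_ha", "delayed_ha", "old_nonforest_ha"]


@dataclass
class AccountingTable:
    """Per-(year, class) expansion areas plus annual forest loss.

    ``table`` is indexed by (year, class-name) with columns
    ``expansion_ha, rapid_ha, delayed_ha, old_nonforest_ha``;
    ``forest_loss`` is a per-year Series (hectares);
    ``pre2000_ha`` holds the pre-2000 plantation stock per class.
    """

    table: pd.DataFrame
    forest_loss: pd.Series
    pre2000_ha: pd.Series

    def validate(self) -> None:
        t = self.table
        if (t[FATE_COLUMNS] < -1e-9).any().any():
            raise ValueError("negative area in accounting table")
        parts = t["rapid_ha"] + t["delayed_ha"] + t["old_nonforest_ha"]
        if not np.allclose(t["expansion_ha"], parts, rtol=1e-12, atol=1e-6):
            raise ValueError("expansion_ha != rapid + delayed + old_nonforest")

    def national(self) -> pd.DataFrame:
        """Totals over years, per class."""
        return self.table.groupby(level="class").sum()

    def annual_expansion(self, class_name: str | None = None) -> pd.Series:
        """Per-year expansion area, optionally for one class."""
        t = self.table
        if class_name is not None:
            t = t.xs(class_name, level="class")
            return t["expansion_ha"]
        return t.groupby(level="year")["expansion_ha"].sum()

    def __add__(self, other: "AccountingTable") -> "AccountingTable":
        return AccountingTable(
            table=self.table.add(other.table, fill_value=0.0),
            forest_loss=self.forest_loss.add(other.forest_loss, fill_value=0.0),
            pre2000_ha=self.pre2000_ha.add(other.pre2000_ha, fill_value=0.0))


def forest_loss_series(tree_loss: np.ndarray, forest_2000: np.ndarray,
                       areas: np.ndarray,
                       years: np.ndarray | None = None) -> pd.Series:
    """Hectares of old-growth forest lost per year.

    Tree-loss pixels outside the year-2000 forest mask contribute nothing.
    """
    check_aligned(tree_loss, forest_2000, areas)
    loss = np.asarray(tree_loss)
    mask = np.asarray(forest_2000, dtype=bool)
    if years is None:
        vals = np.unique(loss[(loss > YEAR_PRE2000)])
        years = vals if vals.size else np.array([], dtype=int)
    out = {}
    for y in years:
        sel = mask & (loss == y)
        out[int(y)] = float(np.asarray(areas)[sel].sum())
    return pd.Series(out, name="forest_loss_ha", dtype=float)


def assign_establishment_year(plantation_2019: np.ndarray,
                              tree_loss: np.ndarray,
                              year_start: int = 2001,
                              year_end: int = 2019) -> np.ndarray:
    """Date plantation pixels from the tree-loss grid.

    Pixels inside the 2019 plantation map take their tree-loss year if one
    falls within the study period; plantation pixels with no recorded loss
    are classed as already existing in 2000 (sentinel 2000); pixels outside
    the map get 0. Assumes plantations are permanent once established, so
    the 2019 extent bounds all expansion.
    """
    check_aligned(plantation_2019, tree_loss)
    inmap = np.asarray(plantation_2019, dtype=bool)
    loss = np.asarray(tree_loss)
    est = np.zeros(loss.shape, dtype=np.int16)
    in_period = (loss >= year_start) & (loss <= year_end)
    est[inmap & in_period] = loss[inmap & in_period]
    est[inmap & ~in_period] = YEAR_PRE2000
    return est


def conversion_accounting(forest_2000: np.ndarray, tree_loss: np.ndarray,
                          plantation_class: np.ndarray,
                          establishment: np.ndarray, areas: np.ndarray,
                          years: np.ndarray | None = None) -> AccountingTable:
    """Classify every plantation pixel's fate and sum areas.

    Raises on the impossible state of a forest pixel whose establishment
    year precedes its loss year.
    """
    check_aligned(forest_2000, tree_loss, plantation_class, establishment,
                  areas)
    forest = np.asarray(forest_2000, dtype=bool)
    loss = np.asarray(tree_loss)
    cls = np.asarray(plantation_class)
    est = np.asarray(establishment)
    area = np.asarray(areas, dtype=float)

    bad = forest & (loss > 0) & (est > YEAR_PRE2000) & (est < loss)
    if np.any(bad):
        raise ValueError(
            f"{np.count_nonzero(bad)} pixels established before their forest "
            "was lost — inconsistent inputs")

    if years is None:
        cand = np.unique(np.concatenate([loss.ravel(), est.ravel()]))
        cand = cand[cand > YEAR_PRE2000]
        years = cand if cand.size else np.array([], dtype=int)
    years = np.asarray(years)

    class_codes = [c for c in np.unique(cls) if c != OTHER]
    rows = []
    for code in class_codes:
        name = CLASS_NAMES.get(int(code), str(int(code)))
        inclass = cls == code
        for y in years:
            estd = inclass & (est == y)
            rapid = estd & forest & (loss == y)
            delayed = estd & forest & (loss > 0) & (loss < y)
            old_nf = estd & ~(rapid | delayed)
            rows.append({
                "year": int(y), "class": name,
                "rapid_ha": float(area[rapid].sum()),
                "delayed_ha": float(area[delayed].sum()),
                "old_nonforest_ha": float(area[old_nf].sum()),
            })
    if rows:
        table = pd.DataFrame(rows).set_index(["year", "class"])
    else:
        table = pd.DataFrame(
            columns=["rapid_ha", "delayed_ha", "old_nonforest_ha"],
            index=pd.MultiIndex.from_arrays([[], []], names=["year", "class"]),
            dtype=float)
    table["expansion_ha"] = (table["rapid_ha"] + table["delayed_ha"]
                             + table["old_nonforest_ha"])
    table = table[FATE_COLUMNS]

    pre = {}
    for code in class_codes:
        name = CLASS_NAMES.get(int(code), str(int(code)))
        pre[name] = float(area[(cls == code) & (est == YEAR_PRE2000)].sum())
    out = AccountingTable(
        table=table,
        forest_loss=forest_loss_series(loss, forest, area, years),
        pre2000_ha=pd.Series(pre, name="pre2000_ha", dtype=float))
    out.validate()
    return out


def regional_summary(forest_2000, tree_loss, plantation_class, establishment,
                     areas, region_id,
                     years: np.ndarray | None = None
                     ) -> dict[int, AccountingTable]:
    """Per-region accounting tables; regions sum exactly to the national."""
    check_aligned(forest_2000, region_id)
    out = {}
    for rid in np.unique(np.asarray(region_id)):
        m = np.asarray(region_id) == rid
        out[int(rid)] = conversion_accounting(
            np.asarray(forest_2000) & m,
            np.where(m, tree_loss, YEAR_NONE),
            np.where(m, plantation_class, OTHER),
            np.where(m, establishment, YEAR_NONE),
            areas, years=years)
    return out


def zone_overlap(plantation_class: np.ndarray, zone: np.ndarray,
                 areas: np.ndarray) -> tuple[float, float]:
    """Oil-palm area inside a (prohibited) zone and its share of all oil palm.

    Returns ``(hectares_inside, percent_of_total_oil_palm)``; the percent is
    NaN when the map holds no oil palm at all.
    """
    check_aligned(plantation_class, zone, areas)
    cls = np.asarray(plantation_class)
    palm = np.isin(cls, OIL_PALM_CODES)
    area = np.asarray(areas, dtype=float)
    inside = float(area[palm & np.asarray(zone, dtype=bool)].sum())
    total = float(area[palm].sum())
    if total == 0.0:
        return inside, float("nan")
    return inside, 100.0 * inside / total
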