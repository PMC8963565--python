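"""Stratified accuracy assessment and error-adjusted area estimation.

Design-based ("good practices") estimation from a stratified random
reference sample, with the map classes as strata. With mapped-area weights
``W_i = A_i / A_total`` and cell proportions ``p_ij = W_i * n_ij / n_i.``:

* overall accuracy ``OA = sum_j p_jj``;
* user's accuracy ``UA_i = p_ii / sum_j p_ij`` (1 - commission error);
* producer's accuracy ``PA_j = p_jj / sum_i p_ij`` (1 - omission error);
* adjusted area ``A^_j = A_total * sum_i W_i * n_ij / n_i.``, the
  stratified expansion of the reference proportions, which also equals
  ``A_j * UA_j / PA_j``.

Variances follow the stratified estimators (UA: binomial within stratum;
OA: stratum-weighted; PA: delta method over strata); confidence intervals
are ``estimate +- 1.96 * SE`` with no finite-population correction. Cohen's
kappa is computed from the raw sample counts, not area-weighted
proportions. Reference sites labelled "unknown" are excluded before any
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CLASS_NAMES, check_aligned

Z95 = 1.96
UNKNOWN = "unknown"


def draw_stratified_sample(class_grid: np.ndarray, sizes: dict[str, int],
                           seed: int | np.random.Generator = 0,
                           reference_grid: np.ndarray | None = None
                           ) -> pd.DataFrame:
    """Simple random sample without replacement within each map stratum.

    ``sizes`` maps class names to per-stratum sample counts. Returns a
    frame with columns ``row, col, map_label`` (plus ``reference_label``
    drawn from ``reference_grid`` when given). Deterministic given seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    grid = np.asarray(class_grid)
    if reference_grid is not None:
        check_aligned(class_grid, reference_grid)
    name_to_code = {v: k for k, v in CLASS_NAMES.items()}
    recs = []
    for name, n in sizes.items():
        if n == 0:
            continue
        code = name_to_code[name]
        idx = np.flatnonzero(grid.ravel() == code)
        if idx.size < n:
            raise ValueError(
                f"stratum '{name}' has only {idx.size} pixels, "
                f"cannot draw {n} sites")
        pick = rng.choice(idx, size=n, replace=False)
        rows, cols = np.unravel_index(pick, grid.shape)
        for r, c in zip(rows, cols):
            rec = {"row": int(r), "col": int(c), "map_label": name}
            if reference_grid is not None:
                rec["reference_label"] = CLASS_NAMES[
                    int(np.asarray(reference_grid)[r, c])]
            recs.append(rec)
    cols_out = ["row", "col", "map_label"] + (
        ["reference_label"] if reference_grid is not None else [])
    return pd.DataFrame(recs, columns=cols_out)


@dataclass
class ErrorMatrix:
    """Sample counts cross-tabulating map (rows) vs reference (columns).

    ``counts`` is a square DataFrame over the map classes; ``areas`` holds
    the mapped area of each class (same units throughout, conventionally
    hectares); ``n_excluded`` counts unknown-labelled sites removed before
    tabulation.
    """

    counts: pd.DataFrame
    areas: pd.Series
    n_excluded: int = 0

    def validate(self) -> None:
        if list(self.counts.index) != list(self.counts.columns):
            raise ValueError("error matrix must be square over one class set")
        if (self.row_totals() == 0).any():
            empty = self.row_totals()[self.row_totals() == 0].index.tolist()
            raise ValueError(f"stratum with zero retained sites: {empty}")
        sampled = self.counts.index[self.row_totals() > 0]
        if (self.areas.reindex(sampled) <= 0).any():
            raise ValueError("sampled stratum with non-positive mapped area")

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def weights(self) -> pd.Series:
        """Area weights W_i = A_i / A_total."""
        return self.areas / self.total_area

    def proportions(self) -> pd.DataFrame:
        """Estimated area proportions p_ij = W_i * n_ij / n_i."""
        return self.counts.div(self.row_totals(), axis=0).mul(
            self.weights(), axis=0)


def build_error_matrix(sites: pd.DataFrame,
                       mapped_areas: dict[str, float] | pd.Series
                       ) -> ErrorMatrix:
    """Cross-tabulate reference sites, excluding unknown-labelled ones."""
    required = {"map_label", "reference_label"}
    if not required.issubset(sites.columns):
        raise ValueError(f"sites frame must have columns {sorted(required)}")
    known = sites[sites["reference_label"] != UNKNOWN]
    n_excluded = len(sites) - len(known)
    areas = pd.Series(mapped_areas, dtype=float)
    classes = list(areas.index)
    bad_ref = set(known["reference_label"]) - set(classes)
    if bad_ref:
        raise ValueError(f"reference labels outside the class set: {bad_ref}")
    counts = pd.crosstab(known["map_label"], known["reference_label"])
    counts = counts.reindex(index=classes, columns=classes, fill_value=0)
    counts.index.name = "map"
    counts.columns.name = "reference"
    m = ErrorMatrix(counts=counts, areas=areas, n_excluded=n_excluded)
    m.validate()
    return m


def cohen_kappa(counts: pd.DataFrame) -> float:
    """Cohen's kappa from raw sample counts."""
    c = counts.to_numpy(dtype=float)
    n = c.sum()
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n ** 2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


@dataclass
class AccuracyReport:
    """OA, per-class UA and PA (proportions with 95% CIs), and kappa."""

    oa: float
    oa_ci: tuple[float, float]
    ua: pd.Series
    ua_ci: pd.DataFrame     # columns low, high
    pa: pd.Series
    pa_ci: pd.DataFrame
    kappa: float


def _ci(est, se):
    lo = np.clip(est - Z95 * se, 0.0, 1.0)
    hi = np.clip(est + Z95 * se, 0.0, 1.0)
    return lo, hi


def accuracy_metrics(m: ErrorMatrix) -> AccuracyReport:
    """Design-based OA / UA / PA with 95% CIs, plus Cohen's kappa."""
    m.validate()
    n_row = m.row_totals()
    if (n_row < 2).any():
        small = n_row[n_row < 2].index.tolist()
        raise ValueError(f"stratum sample below 2, variance undefined: {small}")
    W = m.weights()
    p = m.proportions()
    classes = m.classes
    diag = pd.Series(np.diag(p.to_numpy()), index=classes)

    ua = diag / p.sum(axis=1)
    pa = diag / p.sum(axis=0)
    oa = float(diag.sum())

    var_ua = ua * (1 - ua) / (n_row - 1)
    var_oa = float((W ** 2 * var_ua).sum())

    # PA by the stratified delta formula, in mapped-area units
    A = m.areas
    ahat = (m.counts.div(n_row, axis=0).mul(A, axis=0)).sum(axis=0)
    var_pa = pd.Series(0.0, index=classes)
    frac = m.counts.div(n_row, axis=0)  # n_ij / n_i.
    for j in classes:
        term_j = (A[j] ** 2 * (1 - pa[j]) ** 2 * ua[j] * (1 - ua[j])
                  / (n_row[j] - 1))
        others = [i for i in classes if i != j]
        term_i = sum(A[i] ** 2 * frac.loc[i, j] * (1 - frac.loc[i, j])
                     / (n_row[i] - 1) for i in others)
        var_pa[j] = (term_j + pa[j] ** 2 * term_i) / ahat[j] ** 2 \
            if ahat[j] > 0 else np.nan

    oa_lo, oa_hi = _ci(oa, np.sqrt(var_oa))
    ua_lo, ua_hi = _ci(ua, np.sqrt(var_ua))
    pa_lo, pa_hi = _ci(pa, np.sqrt(var_pa))
    return AccuracyReport(
        oa=oa, oa_ci=(float(oa_lo), float(oa_hi)),
        ua=ua, ua_ci=pd.DataFrame({"low": ua_lo, "high": ua_hi}),
        pa=pa, pa_ci=pd.DataFrame({"low": pa_lo, "high": pa_hi}),
        kappa=cohen_kappa(m.counts))


def adjusted_areas(m: ErrorMatrix) -> pd.DataFrame:
    """Stratified error-adjusted area per class with SE and 95% CI.

    ``A^_j = sum_i A_i * n_ij / n_i.`` — the mapped areas redistributed by
    the reference proportions; the total is conserved exactly. The
    algebraic identity ``A^_j = A_j * UA_j / PA_j`` is asserted.
    """
    m.validate()
    n_row = m.row_totals()
    if (n_row < 2).any():
        small = n_row[n_row < 2].index.tolist()
        raise ValueError(f"stratum sample below 2, variance undefined: {small}")
    A = m.areas
    A_total = m.total_area
    frac = m.counts.div(n_row, axis=0)          # n_ij / n_i.
    ahat = frac.mul(A, axis=0).sum(axis=0)      # sum_i A_i n_ij / n_i.
    W = m.weights()
    # SE(A^_j) = A_total * sqrt(sum_i W_i^2 (n_ij/n_i.)(1-n_ij/n_i.)/(n_i.-1))
    inner = (frac * (1 - frac)).div(n_row - 1, axis=0).mul(W ** 2, axis=0)
    se = A_total * np.sqrt(inner.sum(axis=0))

    rep = accuracy_metrics(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        identity = A * rep.ua / rep.pa
    ok = rep.pa > 0
    if not np.allclose(ahat[ok], identity[ok], rtol=1e-9):
        raise RuntimeError("adjusted-area identity A*UA/PA violated")
    if not np.isclose(ahat.sum(), A_total, rtol=1e-9):
        raise RuntimeError("adjusted areas do not close to the total area")

    out = pd.DataFrame({
        "mapped_ha": A,
        "adjusted_ha": ahat,
        "se_ha": se,
        "ci_low_ha": ahat - Z95 * se,
        "ci_high_ha": ahat + Z95 * se,
    })
    out.index.name = "class"
    return out


def adjusted_area_from_accuracies(mapped_area: float, ua: float,
                                  pa: float) -> float:
    """Adjusted area via the ratio identity ``A^ = A * UA / PA``.

    Useful when only the published summary metrics, not the full error
    matrix, are available. ``ua`` and ``pa`` are proportions in (0, 1].
    """
    if not 0 < pa <= 1 or not 0 < ua <= 1:
        raise ValueError("UA and PA must be proportions in (0, 1]")
    return mapped_area * ua / pa
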