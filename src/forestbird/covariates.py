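"""Environmental covariates: productivity index, habitat classes, standardization.

Productivity is proxied by the principal component of annual precipitation
(sum of monthly means, mm) and temperature (mean of monthly means, °C) that
loads positively on both — warm and wet years score high.  Site-years whose
within-radius grid cells disagree too much (monthly precipitation range
> 50 mm or temperature range > 11 °C) are screened out as unrepresentative
of the actual sampling points.  Habitats are grouped into main classes by
structural group and Shannon–Wiener diversity (H′, nats).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DataError

__all__ = [
    "screen_climate_cells",
    "annual_climate",
    "productivity_index",
    "shannon_index",
    "assign_habitat_classes",
    "standardize",
    "climate_covariate_table",
]

logger = logging.getLogger(__name__)

PRECIP_RANGE_MAX_MM = 50.0
TEMP_RANGE_MAX_C = 11.0


def screen_climate_cells(
    monthly_cells: pd.DataFrame,
    precip_range_max: float = PRECIP_RANGE_MAX_MM,
    temp_range_max: float = TEMP_RANGE_MAX_C,
) -> pd.DataFrame | None:
    """Monthly cell values → per-month means, or None if the site-year is excluded.

    ``monthly_cells`` has columns (month, precip_mm, temp_c), one row per grid
    cell per month.  Exclusion is strict: a site-year is dropped only if some
    month's cell range exceeds a threshold (boundary values are retained).
    """
    if monthly_cells.empty:
        raise DataError("empty climate cell table")
    if monthly_cells[["precip_mm", "temp_c"]].isna().any().any():
        raise DataError("missing climate cell values")
    g = monthly_cells.groupby("month")
    rng = g.agg(
        precip_range=("precip_mm", lambda v: v.max() - v.min()),
        temp_range=("temp_c", lambda v: v.max() - v.min()),
    )
    if (rng["precip_range"] > precip_range_max).any() or (
        rng["temp_range"] > temp_range_max
    ).any():
        return None
    means = g.agg(precip_mm=("precip_mm", "mean"), temp_c=("temp_c", "mean"))
    return means.reset_index()


def annual_climate(monthly_means: pd.DataFrame) -> tuple[float, float]:
    """(total precipitation mm, mean temperature °C) from 12 monthly means."""
    months = set(monthly_means["month"])
    if months != set(range(1, 13)):
        raise DataError(f"need months 1-12, got {sorted(months)}")
    return (
        float(monthly_means["precip_mm"].sum()),
        float(monthly_means["temp_c"].mean()),
    )


def productivity_index(annual: pd.DataFrame) -> pd.DataFrame:
    """PCA productivity score per site-year.

    ``annual`` has columns (site_id, year, precip_total, temp_mean).  A PCA
    on the standardized two-column matrix is computed and the component with
    positive loadings on both variables is selected (a component whose
    loadings are both negative is sign-flipped first).  Returns
    (site_id, year, PC, component_index) plus the loadings as attrs.
    """
    if len(annual) < 3:
        raise DataError("productivity PCA needs at least 3 site-years")
    mat = np.column_stack([
        standardize(annual["precip_total"].to_numpy(float)),
        standardize(annual["temp_mean"].to_numpy(float)),
    ])
    pca = PCA(n_components=2)
    scores = pca.fit_transform(mat)
    chosen = None
    for idx in range(2):
        load = pca.components_[idx]
        if np.all(load < 0):
            load, scores_i = -load, -scores[:, idx]
        else:
            scores_i = scores[:, idx]
        if np.all(load > 0):
            chosen = (idx, load, scores_i)
            break
    if chosen is None:
        # ties at exactly zero correlation: fall back to component 1 flipped positive
        load = pca.components_[0]
        signs = np.where(load >= 0, 1.0, -1.0)
        chosen = (0, load * signs, scores[:, 0] * signs[0])
        logger.warning("no PCA component loads positively on both variables; using PC1")
    idx, load, sc = chosen
    if pca.explained_variance_[idx] <= 1e-12:
        warnings.warn("selected productivity component has (near-)zero variance",
                      stacklevel=2)
    out = annual[["site_id", "year"]].copy()
    out["PC"] = sc
    out["component_index"] = idx + 1
    out.attrs["loadings"] = (float(load[0]), float(load[1]))
    return out


def shannon_index(abundances) -> float:
    """Shannon–Wiener diversity H′ = −Σ pₖ ln pₖ (nats) of an abundance vector."""
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or np.any(a < 0):
        raise DataError("abundances must be a non-empty, non-negative vector")
    total = a.sum()
    if total <= 0:
        raise DataError("total abundance must be positive")
    return float(_scipy_entropy(a / total))


def assign_habitat_classes(
    h_prime: dict[str, float],
    structural_groups: dict[str, str],
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Merge habitats with similar Shannon entropy inside each structural group.

    Within a structural group, habitats are sorted by H′ and chained into one
    class while consecutive values differ by less than ``tolerance`` (nats).
    Labels are ``"<group>_<k>"``, deterministic given the input.
    """
    missing = set(h_prime) - set(structural_groups)
    if missing:
        raise ConfigurationError(f"habitats missing from structural_groups: {sorted(missing)}")
    rows = []
    for group in sorted(set(structural_groups[h] for h in h_prime)):
        habs = sorted(
            (h for h in h_prime if structural_groups[h] == group),
            key=lambda h: (h_prime[h], h),
        )
        k = 0
        prev = None
        for h in habs:
            if prev is not None:
                gap = h_prime[h] - prev
                if (gap >= tolerance) if tolerance > 0 else (gap > 0):
                    k += 1
            rows.append({"habitat_code": h, "H_prime": h_prime[h],
                         "class_label": f"{group}_{k}"})
            prev = h_prime[h]
    return pd.DataFrame(rows)


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (denominator n−1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("standardize needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def climate_covariate_table(
    cells: pd.DataFrame,
    precip_range_max: float = PRECIP_RANGE_MAX_MM,
    temp_range_max: float = TEMP_RANGE_MAX_C,
) -> pd.DataFrame:
    """Screen, summarize and score climate for every site-year in one pass.

    ``cells`` columns: site_id, year, month, precip_mm, temp_c (one row per
    grid cell per month, or per month if already aggregated).  Returns the
    productivity scores of the retained site-years.
    """
    annual_rows = []
    n_excluded = 0
    for (site, year), sub in cells.groupby(["site_id", "year"]):
        means = screen_climate_cells(sub, precip_range_max, temp_range_max)
        if means is None:
            n_excluded += 1
            continue
        precip, temp = annual_climate(means)
        annual_rows.append({"site_id": site, "year": year,
                            "precip_total": precip, "temp_mean": temp})
    if n_excluded:
        logger.info("climate screening excluded %d site-years", n_excluded)
    if not annual_rows:
        raise DataError("no site-years survived climate screening")
    return productivity_index(pd.DataFrame(annual_rows))
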