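"""Batch-level granulometry: classification, yield, mean size, distributions.

After a wet-granulation run the dried granulate is characterised as a batch:
the liquid-to-solid ratio from wet/dry masses, sieve-style classification
into fine (< 0.4 mm), yield/product (0.4 up to 3 mm, boundaries inclusive)
and coarse (> 3 mm) fractions, the class-histogram mean size

    d_mean = sum(percent_in_class * mid_class_size) / 100,

distribution percentiles d10/d50/d90 with span (d90 - d10)/d50, the Sauter
volume/surface diameter d32 = sum(n d^3) / sum(n d^2), box-chart summary
statistics per impeller-speed group, and the compressibility percentage
CPS = 100 (V_initial - V_final) / V_initial of a powder bed under load.

Sieve mass fractions are emulated from image-analysis diameters by weighting
each granule by d^3 (volumetric evaluation at constant granule density);
every weighted statistic also accepts explicit weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from granmorph.errors import MeasurementError, ValidationError

__all__ = [
    "SizeClassHistogram",
    "BatchRecord",
    "DistributionStats",
    "CompressibilityResult",
    "liquid_to_solid_ratio",
    "classify_granules",
    "build_histogram",
    "mean_granule_size",
    "distribution_stats",
    "span",
    "sauter_diameter",
    "box_summary",
    "compressibility",
    "DEFAULT_CLASS_THRESHOLDS",
]

#: Sieve thresholds (mm) separating fine / yield / coarse fractions.
DEFAULT_CLASS_THRESHOLDS = (0.4, 3.0)


@dataclass(frozen=True)
class SizeClassHistogram:
    """Volume-weighted size-class histogram (edges in mm, percentages)."""

    class_edges: np.ndarray
    percent_in_class: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.class_edges, dtype=float)
        pct = np.asarray(self.percent_in_class, dtype=float)
        object.__setattr__(self, "class_edges", edges)
        object.__setattr__(self, "percent_in_class", pct)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValidationError("class_edges must be strictly increasing")
        if len(pct) != len(edges) - 1:
            raise ValidationError("need one percentage per class")
        if np.any(pct < 0):
            raise ValidationError("percentages must be >= 0")
        if abs(pct.sum() - 100.0) > 1e-6:
            raise ValidationError(
                f"percent_in_class must sum to 100, got {pct.sum():.8f}"
            )

    @property
    def mid_class_sizes(self) -> np.ndarray:
        """Arithmetic midpoints of the class edges (mm)."""
        return 0.5 * (self.class_edges[:-1] + self.class_edges[1:])


@dataclass(frozen=True)
class BatchRecord:
    """One granulation run's batch-level summary."""

    batch_id: str
    ls_ratio: float
    impeller_rpm: float
    mass_wet_g: float
    mass_dry_g: float
    fine_pct: float
    yield_pct: float
    coarse_pct: float
    d_mean_mm: float
    mean_sphericity: float = float("nan")
    mean_roundness: float = float("nan")
    mean_aspect_ratio: float = float("nan")
    mean_concavity: float = float("nan")

    def __post_init__(self) -> None:
        if self.ls_ratio < 0:
            raise ValidationError("L/S ratio must be >= 0")
        if self.d_mean_mm <= 0:
            raise ValidationError("d_mean must be > 0")
        total = self.fine_pct + self.yield_pct + self.coarse_pct
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(
                f"fine + yield + coarse must sum to 100, got {total:.8f}"
            )


@dataclass(frozen=True)
class DistributionStats:
    """Summary of a granule-size sample (lengths in mm)."""

    mean: float
    stdev: float
    p5: float
    p25: float
    median: float
    p75: float
    p95: float
    d10: float
    d50: float
    d90: float
    span: float
    d32: float
    stdev_degenerate: bool = False

    def __post_init__(self) -> None:
        q = (self.p5, self.p25, self.median, self.p75, self.p95)
        if any(a > b + 1e-12 for a, b in zip(q, q[1:])):
            raise ValidationError(f"percentiles must be non-decreasing: {q}")


@dataclass(frozen=True)
class CompressibilityResult:
    """Percent bed-volume reduction under a normal stress."""

    cps_pct: float
    applied_stress_kpa: float
    volume_initial_ml: float
    volume_final_ml: float

    def __post_init__(self) -> None:
        if not 0 < self.volume_final_ml <= self.volume_initial_ml:
            raise ValidationError("need 0 < final volume <= initial volume")
        if not 0 <= self.cps_pct < 100:
            raise ValidationError("CPS must lie in [0, 100)")


def liquid_to_solid_ratio(mass_wet_g: float, mass_dry_g: float) -> float:
    """L/S ratio = (wet mass - dry mass) / dry mass of the granulate."""
    if mass_dry_g <= 0:
        raise ValidationError("dry mass must be > 0")
    if mass_wet_g < mass_dry_g:
        raise MeasurementError(
            f"wet mass {mass_wet_g} g below dry mass {mass_dry_g} g"
        )
    return (mass_wet_g - mass_dry_g) / mass_dry_g


def _resolve_weights(diameters: np.ndarray, weights) -> np.ndarray:
    if weights is None:
        return diameters**3  # volumetric evaluation at constant density
    w = np.asarray(weights, dtype=float)
    if w.shape != diameters.shape:
        raise ValidationError("weights must match diameters in length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValidationError("weights must be >= 0 and not all zero")
    return w


def classify_granules(
    diameters,
    weights=None,
    thresholds: tuple[float, float] = DEFAULT_CLASS_THRESHOLDS,
) -> tuple[float, float, float]:
    """Weight fractions (%) of fine / yield / coarse granules.

    ``fine`` is strictly below the lower threshold, ``coarse`` strictly
    above the upper one, and the yield (product) class is the closed
    interval between them.  Default weights are d^3 (volumetric).
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise MeasurementError("cannot classify an empty granule sample")
    if np.any(d <= 0):
        raise ValidationError("diameters must be > 0")
    lo, hi = thresholds
    if not lo < hi:
        raise ValidationError("thresholds must be increasing")
    w = _resolve_weights(d, weights)
    total = w.sum()
    fine = 100.0 * w[d < lo].sum() / total
    coarse = 100.0 * w[d > hi].sum() / total
    yield_pct = 100.0 - fine - coarse
    return fine, yield_pct, coarse


def build_histogram(
    diameters,
    weights=None,
    bin_width: float = 0.1,
    edges=None,
) -> SizeClassHistogram:
    """Volume-weighted size-class histogram over linear bins.

    Default bins of ``bin_width`` mm span the observed diameter range
    (aligned to multiples of the width); explicit ``edges`` override.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise MeasurementError("cannot histogram an empty sample")
    w = _resolve_weights(d, weights)
    if edges is None:
        if bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        lo = np.floor(d.min() / bin_width) * bin_width
        hi = np.ceil(d.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(d, bins=edges, weights=w)
    missed = w.sum() - counts.sum()
    if missed > 1e-9 * w.sum():
        raise MeasurementError("histogram edges do not cover the sample")
    pct = 100.0 * counts / counts.sum()
    return SizeClassHistogram(edges, pct)


def mean_granule_size(hist: SizeClassHistogram) -> float:
    """Class-histogram mean size: sum(percent * mid-class size) / 100 (mm)."""
    return float(np.dot(hist.percent_in_class, hist.mid_class_sizes) / 100.0)


def _weighted_quantile(d_sorted: np.ndarray, cum_frac: np.ndarray, q: float) -> float:
    return float(np.interp(q, cum_frac, d_sorted))


def span(d10: float, d50: float, d90: float) -> float:
    """Distribution span (d90 - d10) / d50 (dimensionless)."""
    if d50 <= 0:
        raise ValidationError("d50 must be > 0")
    return (d90 - d10) / d50


def sauter_diameter(diameters, counts=None) -> float:
    """Sauter volume/surface mean diameter d32 = sum(n d^3) / sum(n d^2)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise MeasurementError("cannot compute d32 of an empty sample")
    n = np.ones_like(d) if counts is None else np.asarray(counts, dtype=float)
    return float(np.sum(n * d**3) / np.sum(n * d**2))


def distribution_stats(diameters, weights=None) -> DistributionStats:
    """Full distribution summary of a granule-size sample.

    d10/d50/d90 are read off the weighted cumulative distribution by linear
    interpolation (default weights d^3, the volumetric convention of sieve
    and laser-diffraction reporting); the box-chart statistics (mean, sample
    stdev, 5/25/50/75/95th percentiles) are unweighted over the raw values;
    d32 is computed on the number-weighted diameters.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise MeasurementError("cannot summarise an empty sample")
    if np.any(d <= 0):
        raise ValidationError("diameters must be > 0")
    w = _resolve_weights(d, weights)

    order = np.argsort(d)
    d_sorted, w_sorted = d[order], w[order]
    cum = np.cumsum(w_sorted)
    cum_frac = (cum - 0.5 * w_sorted) / cum[-1]  # midpoint cumulative rule
    d10 = _weighted_quantile(d_sorted, cum_frac, 0.10)
    d50 = _weighted_quantile(d_sorted, cum_frac, 0.50)
    d90 = _weighted_quantile(d_sorted, cum_frac, 0.90)

    degenerate = d.size < 2
    stdev = 0.0 if degenerate else float(np.std(d, ddof=1))
    p5, p25, p50, p75, p95 = np.percentile(d, [5, 25, 50, 75, 95])
    return DistributionStats(
        mean=float(np.mean(d)),
        stdev=stdev,
        p5=float(p5),
        p25=float(p25),
        median=float(p50),
        p75=float(p75),
        p95=float(p95),
        d10=d10,
        d50=d50,
        d90=d90,
        span=span(d10, d50, d90),
        d32=sauter_diameter(d),
        stdev_degenerate=degenerate,
    )


def box_summary(groups: dict | pd.DataFrame, value_col: str | None = None,
                group_col: str = "impeller_rpm") -> pd.DataFrame:
    """Box-chart statistics (mean, stdev, 5/25/50/75/95th percentiles) per group.

    ``groups`` is either a mapping {group key: values} or a DataFrame with
    ``group_col`` and ``value_col``.  Percentiles use linear interpolation
    between order statistics; a singleton group reports stdev 0 with the
    ``stdev_degenerate`` flag set.
    """
    if isinstance(groups, pd.DataFrame):
        if value_col is None:
            raise ValidationError("value_col is required with a DataFrame input")
        groups = {k: g[value_col].to_numpy() for k, g in groups.groupby(group_col)}
    rows = []
    for key, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise MeasurementError(f"group {key!r} is empty")
        degenerate = v.size < 2
        p5, p25, p50, p75, p95 = np.percentile(v, [5, 25, 50, 75, 95])
        rows.append(
            {
                group_col: key,
                "mean": float(np.mean(v)),
                "stdev": 0.0 if degenerate else float(np.std(v, ddof=1)),
                "p5": float(p5),
                "p25": float(p25),
                "median": float(p50),
                "p75": float(p75),
                "p95": float(p95),
                "n": int(v.size),
                "stdev_degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def compressibility(
    volume_initial_ml: float,
    volume_final_ml: float,
    applied_stress_kpa: float = 15.0,
) -> CompressibilityResult:
    """CPS = 100 (V_initial - V_final) / V_initial, the percent bed compaction."""
    if volume_initial_ml <= 0:
        raise ValidationError("initial volume must be > 0")
    if volume_final_ml > volume_initial_ml:
        raise MeasurementError("final volume exceeds initial volume")
    if volume_final_ml <= 0:
        raise ValidationError("final volume must be > 0")
    cps = 100.0 * (volume_initial_ml - volume_final_ml) / volume_initial_ml
    return CompressibilityResult(
        cps_pct=cps,
        applied_stress_kpa=applied_stress_kpa,
        volume_initial_ml=volume_initial_ml,
        volume_final_ml=volume_final_ml,
    )
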