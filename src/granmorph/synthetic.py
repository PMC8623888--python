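"""Synthetic granule images and simulated granulation experiments.

No raw data from the granulation campaign are publicly deposited, so every
downstream stage of the pipeline is exercised on synthetic inputs with known
ground truth:

* star-convex 3D particles (triaxial ellipsoid plus a smooth, seeded angular
  roughness term) rendered as binary silhouette stacks under uniformly random
  orientations — emulating a dynamic-image-analysis instrument stream of
  tumbling particles photographed at high frame rate;
* batch experiment tables whose mean-granule-size and process-yield columns
  follow the published quadratic response surfaces plus Gaussian noise;
* per-granule diameter samples drawn from a lognormal whose arithmetic mean
  is anchored to the published size surface (the lognormal family is a
  stand-in: the source study reports only batch-level summaries, not
  per-granule distributions).

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev
from scipy.spatial.transform import Rotation

from granmorph import rsm
from granmorph.errors import DesignError, RenderError, ValidationError

__all__ = [
    "ParticleShapeSpec",
    "ProjectionSequenceSpec",
    "ExperimentDesign",
    "StarConvexSurface",
    "make_particle_surface",
    "render_projection_sequence",
    "simulate_experiment_table",
    "simulate_granule_size_sample",
]


@dataclass(frozen=True)
class ParticleShapeSpec:
    """Star-convex particle: triaxial ellipsoid with optional surface roughness.

    ``semi_axes`` are the ellipsoid semi-axes a >= b >= c in mm;
    ``roughness_amplitude`` is the maximum relative radial perturbation
    (must stay < 0.5 so the shape remains star-convex about its centroid)
    and ``roughness_wavenumber`` sets the angular frequency of the bumps.
    """

    semi_axes: tuple[float, float, float]
    roughness_amplitude: float = 0.0
    roughness_wavenumber: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValidationError(
                f"semi_axes must satisfy a >= b >= c > 0, got {self.semi_axes}"
            )
        if self.roughness_amplitude < 0:
            raise ValidationError("roughness_amplitude must be >= 0")
        if self.roughness_amplitude >= 0.5:
            raise ValidationError(
                "roughness_amplitude must be < 0.5 to keep the shape star-convex"
            )
        if self.roughness_wavenumber < 1:
            raise ValidationError("roughness_wavenumber must be a positive integer")


@dataclass(frozen=True)
class ProjectionSequenceSpec:
    """Rendering parameters for one particle's silhouette stack."""

    n_frames: int = 10
    pixel_size: float = 0.01  # mm per pixel
    image_extent: int = 256  # pixels per side
    orientation_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.image_extent < 8:
            raise ValidationError("image_extent must be >= 8 pixels")


@dataclass(frozen=True)
class ExperimentDesign:
    """Full-factorial granulation design: L/S levels x impeller speeds x replicates.

    Response noise is additive Gaussian, with separate standard deviations
    for the two responses (mm for mean granule size, percentage points for
    process yield) since the responses live on incommensurate scales.
    """

    ls_levels: tuple[float, ...] = (0.70, 0.85, 1.00, 1.15, 1.27)
    is_levels: tuple[float, ...] = (300.0, 500.0, 700.0)
    replicates: int = 2
    noise_sd_d_mm: float = 0.077
    noise_sd_yield_pct: float = 9.6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ls_levels) == 0 or len(self.is_levels) == 0:
            raise DesignError("ls_levels and is_levels must be non-empty")
        if not all(0.6 <= x <= 1.4 for x in self.ls_levels):
            raise ValidationError(f"L/S levels must lie in [0.6, 1.4]: {self.ls_levels}")
        if not all(x > 0 for x in self.is_levels):
            raise ValidationError("impeller speeds must be positive")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_sd_d_mm < 0 or self.noise_sd_yield_pct < 0:
            raise ValidationError("noise standard deviations must be >= 0")

    @property
    def n_runs(self) -> int:
        return len(self.ls_levels) * len(self.is_levels) * self.replicates


class StarConvexSurface:
    """Radial surface model r(u) = ellipsoid radius * (1 + roughness(u)).

    The roughness term is a seeded sum of Chebyshev ridges
    sum_j c_j * T_k(u . v_j) over random unit vectors v_j, normalised by
    sum_j |c_j| so that |roughness(u)| <= roughness_amplitude everywhere
    (|T_k| <= 1 on [-1, 1]).  This keeps the relative perturbation bound
    exact, not just empirical.
    """

    _N_RIDGES = 6

    def __init__(self, spec: ParticleShapeSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        v = rng.standard_normal((self._N_RIDGES, 3))
        self._ridge_dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        c = rng.standard_normal(self._N_RIDGES)
        self._ridge_coefs = c / np.sum(np.abs(c))
        k = spec.roughness_wavenumber
        self._cheb = chebyshev.Chebyshev([0] * k + [1])

    def ellipsoid_radius(self, directions: np.ndarray) -> np.ndarray:
        u = np.asarray(directions, dtype=float)
        a, b, c = self.spec.semi_axes
        denom = (u[..., 0] / a) ** 2 + (u[..., 1] / b) ** 2 + (u[..., 2] / c) ** 2
        return 1.0 / np.sqrt(denom)

    def roughness(self, directions: np.ndarray) -> np.ndarray:
        """Relative radial perturbation, bounded by roughness_amplitude."""
        u = np.asarray(directions, dtype=float)
        if self.spec.roughness_amplitude == 0:
            return np.zeros(u.shape[:-1])
        t = u @ self._ridge_dirs.T  # cosines with ridge axes, in [-1, 1]
        return self.spec.roughness_amplitude * (self._cheb(t) @ self._ridge_coefs)

    def radius(self, directions: np.ndarray) -> np.ndarray:
        """Radial distance from centroid to surface along unit ``directions``."""
        return self.ellipsoid_radius(directions) * (1.0 + self.roughness(directions))

    @property
    def max_radius_bound(self) -> float:
        a = self.spec.semi_axes[0]
        return a * (1.0 + self.spec.roughness_amplitude)


def make_particle_surface(spec: ParticleShapeSpec) -> StarConvexSurface:
    """Build the deterministic star-convex radial surface for ``spec``."""
    return StarConvexSurface(spec)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _silhouette_radial_profile(
    points: np.ndarray, rotation: Rotation, n_bins: int = 1440
) -> np.ndarray:
    """Max projected radius per azimuth bin for one rotated point cloud.

    Projection along the camera axis (z) of a star-convex body is star-convex
    about the centroid's projection, so the silhouette is fully described by
    a periodic radial profile g(psi).
    """
    xy = rotation.apply(points)[:, :2]
    rho = np.hypot(xy[:, 0], xy[:, 1])
    psi = np.arctan2(xy[:, 1], xy[:, 0])
    bins = ((psi + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    profile = np.zeros(n_bins)
    np.maximum.at(profile, bins, rho)
    if np.any(profile == 0):  # fill rare empty bins from neighbours
        idx = np.flatnonzero(profile > 0)
        all_idx = np.arange(n_bins)
        profile = np.interp(all_idx, idx, profile[idx], period=n_bins)
    return profile


def render_projection_sequence(
    surface: StarConvexSurface,
    seq: ProjectionSequenceSpec,
    n_surface_samples: int = 60000,
) -> np.ndarray:
    """Render a particle as a stack of binary silhouette masks.

    Each frame views the particle under an independent uniformly random 3D
    orientation (seeded unit quaternions).  A pixel is foreground when its
    centre lies inside the silhouette.  Returns a bool array of shape
    ``(n_frames, image_extent, image_extent)``.
    """
    half_extent_mm = (seq.image_extent / 2.0 - 2.0) * seq.pixel_size
    if surface.max_radius_bound > half_extent_mm:
        raise RenderError(
            f"particle radius bound {surface.max_radius_bound:.4g} mm exceeds the "
            f"usable image half-extent {half_extent_mm:.4g} mm "
            f"(extent {seq.image_extent} px at {seq.pixel_size} mm/px with 2 px margin)"
        )

    dirs = fibonacci_sphere(n_surface_samples)
    points = dirs * surface.radius(dirs)[:, None]

    rng = np.random.default_rng(seq.orientation_seed)
    quats = rng.standard_normal((seq.n_frames, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)

    coords = (np.arange(seq.image_extent) - (seq.image_extent - 1) / 2.0) * seq.pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    rho_pix = np.hypot(xx, yy)
    psi_pix = np.arctan2(yy, xx)

    from skimage.measure import label

    n_bins = 1440
    bin_centers = (np.arange(n_bins) + 0.5) / n_bins * 2 * np.pi - np.pi
    frames = np.empty((seq.n_frames, seq.image_extent, seq.image_extent), dtype=bool)
    for k in range(seq.n_frames):
        profile = _silhouette_radial_profile(points, Rotation.from_quat(quats[k]), n_bins)
        g = np.interp(psi_pix.ravel(), bin_centers, profile, period=2 * np.pi)
        mask = (rho_pix.ravel() <= g).reshape(rho_pix.shape)
        # Pixel-centre rasterisation of a star-convex silhouette can leave a
        # stray pixel where the radial profile is steep; keep the main body.
        labels = label(mask, connectivity=2)
        if labels.max() > 1:
            sizes = np.bincount(labels.ravel())[1:]
            mask = labels == (np.argmax(sizes) + 1)
        frames[k] = mask
    return frames


def simulate_experiment_table(
    design: ExperimentDesign,
    d_mean_model: rsm.QuadraticModel | None = None,
    yield_model: rsm.QuadraticModel | None = None,
):
    """Simulate one granulation campaign as a tidy batch table.

    One row per (L/S level, impeller speed, replicate); responses are the
    reference-surface predictions plus seeded Gaussian noise; yields are
    clamped to [0, 100] %.  Columns: ``batch_id, ls_ratio, impeller_rpm,
    replicate, d_mean_mm, yield_pct``.
    """
    import pandas as pd

    if d_mean_model is None or yield_model is None:
        ref = rsm.reference_models()
        d_mean_model = d_mean_model or ref["d_mean"]
        yield_model = yield_model or ref["yield"]

    rng = np.random.default_rng(design.seed)
    rows = []
    batch = 0
    for ls in design.ls_levels:
        for is_rpm in design.is_levels:
            for rep in range(1, design.replicates + 1):
                d = float(d_mean_model.predict(ls, is_rpm))
                y = float(yield_model.predict(ls, is_rpm))
                if design.noise_sd_d_mm > 0:
                    d += rng.normal(0.0, design.noise_sd_d_mm)
                if design.noise_sd_yield_pct > 0:
                    y += rng.normal(0.0, design.noise_sd_yield_pct)
                rows.append(
                    {
                        "batch_id": f"B{batch:03d}",
                        "ls_ratio": ls,
                        "impeller_rpm": is_rpm,
                        "replicate": rep,
                        "d_mean_mm": d,
                        "yield_pct": float(np.clip(y, 0.0, 100.0)),
                    }
                )
                batch += 1
    return pd.DataFrame(rows)


def simulate_granule_size_sample(
    ls: float,
    is_rpm: float,
    n: int,
    dispersion: float = 1.5,
    seed: int = 0,
    d_mean_model: rsm.QuadraticModel | None = None,
) -> np.ndarray:
    """Lognormal granule-diameter sample anchored to the size surface.

    ``dispersion`` is the geometric standard deviation (>= 1); the lognormal
    parameters are chosen so the *arithmetic* mean equals the reference
    surface's prediction at (ls, is_rpm).  ``dispersion == 1`` degenerates to
    all diameters equal to the prediction.
    """
    if n < 1:
        raise ValidationError("sample size n must be >= 1")
    if dispersion < 1:
        raise ValidationError("dispersion (geometric sd) must be >= 1")
    if d_mean_model is None:
        d_mean_model = rsm.reference_models()["d_mean"]
    mean = float(d_mean_model.predict(ls, is_rpm))
    if mean <= 0:
        raise ValidationError(
            f"size surface predicts non-positive mean {mean:.4g} mm at "
            f"L/S={ls}, IS={is_rpm}"
        )
    sigma = np.log(dispersion)
    if sigma == 0:
        return np.full(n, mean)
    mu = np.log(mean) - sigma**2 / 2.0
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, size=n)
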