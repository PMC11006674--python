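"""Synthetic acquisition physics for en face RPE imaging.

The retinal pigment epithelium appears in averaged adaptive-optics OCT en face
images as a quasi-hexagonal mosaic of dark cell centers with bright cell
surroundings.  A single coherent acquisition of the same tissue is dominated by
fully developed speckle: interference between light scattered from many points
within each cell multiplies the underlying reflectance by an exponential random
field of unit contrast.  This module generates that world from first
principles:

* :func:`generate_mosaic` — a jittered triangular lattice of cell centers,
  rendered to a noiseless reflectance map (cosine dip at each center, bright
  rim near the Voronoi boundary).
* :func:`simulate_speckle_frame` — circular complex Gaussian field with
  per-pixel variance proportional to reflectance, low-passed by a Gaussian PSF
  and squared (fully developed speckle; ``n_looks`` independent looks averaged
  incoherently give contrast ``1/sqrt(M)``).
* :func:`simulate_motion_trace` / :func:`apply_raster_distortion` — per-row
  random-walk drift plus rare saccadic steps, applied row-by-row the way a
  point-scanning system accumulates them (bulk inter-frame displacement and
  unique intra-frame raster shear).
* :func:`simulate_acquisition` — the composed forward model, returning the
  frames together with the ground-truth mosaic and motion trace.

Conventions: (row, col) coordinates, 0-based, row 0 at top; subpixel positions
are continuous; all interpolation is bilinear; mirror padding at edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MosaicSpec",
    "CellMosaic",
    "EyeMotionTrace",
    "SpeckleFrame",
    "SpeckleStack",
    "generate_mosaic",
    "simulate_speckle_frame",
    "simulate_motion_trace",
    "apply_raster_distortion",
    "simulate_acquisition",
]

MIN_SPACING_PX = 3.0


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of a synthetic RPE mosaic.

    Parameters
    ----------
    image_height_px, image_width_px : int
        Canvas size in pixels.
    pixel_scale_um : float
        Micrometres per pixel (> 0).
    cell_spacing_um : float
        Target center-to-center spacing in micrometres.
    position_jitter_frac : float
        Center jitter as a fraction of the spacing, in [0, 0.5).
    center_dip_depth : float
        Reflectance contrast of the dark center versus the bright surround,
        in [0, 1].
    rng_seed : int
        Seed; the mosaic is deterministic given the spec.
    """

    image_height_px: int
    image_width_px: int
    pixel_scale_um: float = 1.0
    cell_spacing_um: float = 14.0
    position_jitter_frac: float = 0.1
    center_dip_depth: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be > 0")
        if self.cell_spacing_um <= 0:
            raise ValueError("cell_spacing_um must be > 0")
        if not (0.0 <= self.position_jitter_frac < 0.5):
            raise ValueError("position_jitter_frac must lie in [0, 0.5)")
        if not (0.0 <= self.center_dip_depth <= 1.0):
            raise ValueError("center_dip_depth must lie in [0, 1]")
        if self.cell_spacing_px < MIN_SPACING_PX:
            raise ValueError(
                f"unresolvable mosaic: spacing {self.cell_spacing_px:.2f} px < "
                f"{MIN_SPACING_PX} px"
            )

    @property
    def cell_spacing_px(self) -> float:
        return self.cell_spacing_um / self.pixel_scale_um


@dataclass
class CellMosaic:
    """Ground-truth mosaic: cell centers plus a noiseless reflectance map."""

    centers: np.ndarray  # (n, 2) float, (row, col) subpixel
    reflectance: np.ndarray  # (H, W) float in [0, 1]
    spec: MosaicSpec

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape


@dataclass
class EyeMotionTrace:
    """Row-resolved eye-motion displacements for a multi-frame acquisition.

    ``row_shifts`` has shape (n_frames, n_rows, 2) with (dy, dx) per scan row.
    The per-frame bulk displacement is the trace value at the frame's first
    row.
    """

    row_shifts: np.ndarray
    drift_sd_px_per_row: float
    saccade_rate_per_frame: float
    saccade_amp_px: float

    @property
    def n_frames(self) -> int:
        return self.row_shifts.shape[0]

    @property
    def n_rows(self) -> int:
        return self.row_shifts.shape[1]

    def bulk_displacement(self, frame_index: int) -> np.ndarray:
        return self.row_shifts[frame_index, 0]


@dataclass
class SpeckleFrame:
    intensity: np.ndarray
    n_looks: int
    frame_index: int
    valid_mask: np.ndarray | None = None


@dataclass
class SpeckleStack:
    """A sequence of speckled, motion-distorted frames of one retinal patch."""

    frames: list[SpeckleFrame]
    mosaic: CellMosaic
    trace: EyeMotionTrace
    inter_frame_decorrelated: bool = True

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].intensity.shape

    def as_array(self) -> np.ndarray:
        return np.stack([f.intensity for f in self.frames])


def _lattice_centers(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered triangular lattice clipped to the canvas, (row, col)."""
    s = spec.cell_spacing_px
    row_pitch = s * np.sqrt(3.0) / 2.0
    h, w = spec.image_height_px, spec.image_width_px
    # overscan one spacing so boundary cells render correctly
    rows = np.arange(-1, int(np.ceil(h / row_pitch)) + 2)
    cols = np.arange(-1, int(np.ceil(w / s)) + 2)
    pts = []
    for i in rows:
        offset = (s / 2.0) if (i % 2) else 0.0
        y = i * row_pitch
        for j in cols:
            pts.append((y, j * s + offset))
    pts = np.asarray(pts, dtype=float)
    if spec.position_jitter_frac > 0:
        jitter = rng.uniform(
            -spec.position_jitter_frac * s,
            spec.position_jitter_frac * s,
            size=pts.shape,
        )
        pts = pts + jitter
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    )
    return pts[inside]


def generate_mosaic(spec: MosaicSpec) -> CellMosaic:
    """Render a jittered triangular-lattice cell mosaic.

    Each pixel is assigned to its nearest center (the Voronoi cell) and given a
    smooth radial reflectance profile: a cosine dip of depth
    ``center_dip_depth`` at the center rising to a bright rim at half the cell
    spacing.  The map is normalised to [0, 1] and is deterministic given
    ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    centers = _lattice_centers(spec, rng)
    if len(centers) < 1:
        raise ValueError("canvas too small: no lattice centers inside")
    h, w = spec.image_height_px, spec.image_width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    tree = cKDTree(centers)
    dist, _ = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    dist = dist.reshape(h, w)
    r_cell = spec.cell_spacing_px / 2.0
    t = np.minimum(dist / r_cell, 1.0)
    # cosine dip: depth at the center, bright (1.0) at the cell rim
    reflectance = 1.0 - spec.center_dip_depth * 0.5 * (1.0 + np.cos(np.pi * t))
    reflectance = np.clip(reflectance, 0.0, 1.0)
    return CellMosaic(centers=centers, reflectance=reflectance, spec=spec)


def _look_rng(seed: int, frame_index: int, look: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(frame_index, look))
    return np.random.default_rng(ss)


def simulate_speckle_frame(
    mosaic_or_reflectance,
    psf_sigma_px: float = 1.0,
    n_looks: int = 1,
    frame_index: int = 0,
    seed: int = 0,
) -> SpeckleFrame:
    """Simulate one fully developed speckle frame.

    For each look a zero-mean circular complex Gaussian field with per-pixel
    variance proportional to the reflectance is low-passed by an isotropic
    Gaussian of width ``psf_sigma_px`` (which sets the speckle grain size) and
    squared; the ``n_looks`` looks are averaged incoherently.  The result is
    rescaled so the expected intensity equals the reflectance exactly, hence a
    single look over uniform reflectance has speckle contrast (SD/mean) of 1
    and M looks have contrast ``1/sqrt(M)``.
    """
    reflectance = (
        mosaic_or_reflectance.reflectance
        if isinstance(mosaic_or_reflectance, CellMosaic)
        else np.asarray(mosaic_or_reflectance, dtype=float)
    )
    if not np.all(np.isfinite(reflectance)):
        raise ValueError("reflectance must be finite")
    if np.any(reflectance < 0):
        raise ValueError("reflectance must be nonnegative")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    if n_looks < 1:
        raise ValueError("n_looks must be >= 1")

    amp = np.sqrt(reflectance)
    acc = np.zeros_like(reflectance)
    for look in range(n_looks):
        rng = _look_rng(seed, frame_index, look)
        re = rng.standard_normal(reflectance.shape) * amp
        im = rng.standard_normal(reflectance.shape) * amp
        re = ndimage.gaussian_filter(re, psf_sigma_px, mode="mirror")
        im = ndimage.gaussian_filter(im, psf_sigma_px, mode="mirror")
        acc += re * re + im * im
    intensity = acc / n_looks
    # the PSF redistributes variance; renormalise so E[I] == reflectance
    expected = _expected_filtered_intensity(reflectance, psf_sigma_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(expected > 0, reflectance / expected, 0.0)
    intensity = intensity * gain
    return SpeckleFrame(intensity=intensity, n_looks=n_looks, frame_index=frame_index)


def _gaussian_kernel1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    # same kernel construction as scipy.ndimage.gaussian_filter (order 0)
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _expected_filtered_intensity(var_map: np.ndarray, sigma: float) -> np.ndarray:
    """E[|h * a|^2] for white complex noise of per-pixel variance 2*var_map.

    Filtering white noise with kernel h gives variance (h^2) conv var, so the
    expected intensity is the variance map correlated with the squared discrete
    kernel, separably per axis.
    """
    k2 = _gaussian_kernel1d(sigma) ** 2
    out = ndimage.correlate1d(2.0 * var_map, k2, axis=0, mode="mirror")
    out = ndimage.correlate1d(out, k2, axis=1, mode="mirror")
    return out


def simulate_motion_trace(
    drift_sd_px_per_row: float,
    saccade_rate_per_frame: float,
    saccade_amp_px: float,
    n_rows: int,
    n_frames: int,
    seed: int = 0,
) -> EyeMotionTrace:
    """Sample an eye-motion trace: per-row random-walk drift plus saccades.

    The drift is a 2D random walk sampled once per scan row across the whole
    acquisition (``n_rows * n_frames`` steps), so displacement accumulates
    both within a frame (raster distortion) and across frames (bulk shifts).
    Saccades are rare instantaneous steps of amplitude ``saccade_amp_px`` in a
    random direction, occurring at ``saccade_rate_per_frame`` expected events
    per frame.
    """
    for name, v in (
        ("drift_sd_px_per_row", drift_sd_px_per_row),
        ("saccade_rate_per_frame", saccade_rate_per_frame),
        ("saccade_amp_px", saccade_amp_px),
    ):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0")
    if n_rows < 1 or n_frames < 1:
        raise ValueError("n_rows and n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_rows * n_frames
    steps = rng.standard_normal((total, 2)) * drift_sd_px_per_row
    if saccade_rate_per_frame > 0 and saccade_amp_px > 0:
        p_row = saccade_rate_per_frame / n_rows
        hits = rng.random(total) < p_row
        angles = rng.uniform(0, 2 * np.pi, size=total)
        steps[hits, 0] += saccade_amp_px * np.sin(angles[hits])
        steps[hits, 1] += saccade_amp_px * np.cos(angles[hits])
    walk = np.cumsum(steps, axis=0)
    if drift_sd_px_per_row == 0 and (
        saccade_rate_per_frame == 0 or saccade_amp_px == 0
    ):
        walk = np.zeros((total, 2))
    row_shifts = walk.reshape(n_frames, n_rows, 2)
    return EyeMotionTrace(
        row_shifts=row_shifts,
        drift_sd_px_per_row=drift_sd_px_per_row,
        saccade_rate_per_frame=saccade_rate_per_frame,
        saccade_amp_px=saccade_amp_px,
    )


def apply_raster_distortion(
    mosaic: CellMosaic | np.ndarray,
    trace: EyeMotionTrace,
    frame_index: int,
    return_mask: bool = False,
):
    """Resample the reflectance as a raster scanner under eye motion would.

    Row ``r`` of the output samples the input at ``(r + dy[r], c + dx[r])``
    with bilinear interpolation; out-of-canvas samples are filled by mirroring
    and flagged in the validity mask.
    """
    reflectance = (
        mosaic.reflectance if isinstance(mosaic, CellMosaic) else np.asarray(mosaic)
    )
    if not (0 <= frame_index < trace.n_frames):
        raise IndexError(f"frame_index {frame_index} out of range")
    h, w = reflectance.shape
    if trace.n_rows != h:
        raise ValueError("trace row count does not match image height")
    dy = trace.row_shifts[frame_index, :, 0]
    dx = trace.row_shifts[frame_index, :, 1]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    sample_y = yy + dy[:, None]
    sample_x = xx + dx[:, None]
    out = ndimage.map_coordinates(
        reflectance, [sample_y, sample_x], order=1, mode="mirror"
    )
    if return_mask:
        mask = (
            (sample_y >= 0) & (sample_y <= h - 1)
            & (sample_x >= 0) & (sample_x <= w - 1)
        )
        return out, mask
    return out


def simulate_acquisition(
    spec: MosaicSpec,
    n_frames: int = 120,
    psf_sigma_px: float = 1.0,
    n_looks: int = 1,
    drift_sd_px_per_row: float = 0.0,
    saccade_rate_per_frame: float = 0.0,
    saccade_amp_px: float = 0.0,
    seed: int = 0,
) -> SpeckleStack:
    """Simulate a repeated acquisition of one retinal patch.

    Composes :func:`generate_mosaic`, per-frame :func:`apply_raster_distortion`
    and :func:`simulate_speckle_frame` with speckle independent between frames
    (the decorrelated regime that makes incoherent averaging work).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    mosaic = generate_mosaic(spec)
    trace = simulate_motion_trace(
        drift_sd_px_per_row,
        saccade_rate_per_frame,
        saccade_amp_px,
        n_rows=spec.image_height_px,
        n_frames=n_frames,
        seed=seed + 1,
    )
    frames = []
    for k in range(n_frames):
        warped, mask = apply_raster_distortion(mosaic, trace, k, return_mask=True)
        frame = simulate_speckle_frame(
            warped, psf_sigma_px=psf_sigma_px, n_looks=n_looks,
            frame_index=k, seed=seed,
        )
        frame.valid_mask = mask
        frames.append(frame)
    return SpeckleStack(frames=frames, mosaic=mosaic, trace=trace)
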