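"""Quantification of the RPE cell mosaic.

A regularly repeating cell mosaic produces a ring in the 2D power spectrum at
the mosaic's fundamental spatial frequency.  Averaging the spectrum over
annuli of constant frequency magnitude collapses the ring to a peak whose
position estimates the cell spacing and whose height above the local minimum
to its left — the *peak distinctiveness* (PD) — measures cellular contrast.
Pixel spacings are converted to retinal micrometres by a paraxial chief-ray
trace through a three-surface schematic eye whose axial length, corneal
radius and anterior chamber depth can be replaced by per-eye biometry.
Voronoi tessellation of marked cell centers provides the complementary
packing statistics (neighbor counts, neighbor distances, density, fraction of
hexagonally packed cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "RadialPSD", "PeakResult", "EyeBiometry", "VoronoiStats", "CellMetrics",
    "radial_psd", "detect_peak", "retinal_scale", "retinal_microns_per_degree",
    "cell_spacing_from_psd", "voronoi_stats", "compare_to_reference",
    "compare_batches", "default_band_cyc_per_px", "HEX_LATTICE_FACTOR",
]

# For a triangular (hexagonal) mosaic the spectral ring sits at the reciprocal
# of the lattice *row* spacing s*sqrt(3)/2, so the center-to-center spacing is
# (2/sqrt(3)) / f_peak.
HEX_LATTICE_FACTOR = 2.0 / np.sqrt(3.0)


# --------------------------------------------------------------------------
# radial power spectrum
# --------------------------------------------------------------------------

@dataclass
class RadialPSD:
    """Circumferentially averaged log power spectrum.

    ``freq`` ascends from 0 to the Nyquist frequency in cycles/pixel;
    ``log_psd`` is log10 mean power per annulus.  ``annulus_power`` and
    ``total_ac_power`` keep the full power bookkeeping (all annuli including
    the spectral corners beyond Nyquist) so that the annulus sums account for
    the whole non-DC spectrum exactly.
    """

    freq: np.ndarray
    log_psd: np.ndarray
    window: str
    roi_px: int
    annulus_power: np.ndarray = field(repr=False, default=None)
    total_ac_power: float = 0.0
    is_flat: bool = False


def _raised_cosine_window(n: int) -> np.ndarray:
    w = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)
    return np.outer(w, w)


def radial_psd(image: np.ndarray, roi_px: int = 200, window: str = "hann") -> RadialPSD:
    """Circumferentially averaged power spectrum of a centred square ROI.

    The ROI is mean-subtracted, tapered by a 2D raised-cosine window (or left
    untapered with ``window='none'``), Fourier transformed, and the squared
    magnitude is averaged over annuli of one frequency-sample width (annulus
    membership by rounded radial frequency index).
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    h, w = img.shape
    if roi_px > h or roi_px > w:
        raise ValueError(f"roi {roi_px} does not fit in image {img.shape}")
    oy, ox = (h - roi_px) // 2, (w - roi_px) // 2
    roi = img[oy : oy + roi_px, ox : ox + roi_px]
    flat = roi.std() == 0
    roi = roi - roi.mean()
    if window == "hann":
        roi = roi * _raised_cosine_window(roi_px)
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.fft2(roi)
    power = np.abs(spec) ** 2
    k = np.fft.fftfreq(roi_px) * roi_px  # signed integer frequency index
    kr = np.sqrt(k[:, None] ** 2 + k[None, :] ** 2)
    rbin = np.rint(kr).astype(int)
    nbins = rbin.max() + 1
    sums = np.bincount(rbin.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(rbin.ravel(), minlength=nbins)
    mean_power = sums / np.maximum(counts, 1)
    nyq = roi_px // 2
    with np.errstate(divide="ignore"):
        log_psd = np.log10(np.where(mean_power > 0, mean_power, np.nan))
    freq = np.arange(nyq + 1) / roi_px
    return RadialPSD(
        freq=freq,
        log_psd=log_psd[: nyq + 1],
        window=window,
        roi_px=roi_px,
        annulus_power=sums,
        total_ac_power=float(power.sum() - power[0, 0]),
        is_flat=flat,
    )


@dataclass
class PeakResult:
    """Spectral peak of the cell mosaic."""

    found: bool
    f_peak: float = np.nan            # cycles/px, sub-bin refined
    f_peak_bin: float = np.nan        # cycles/px at the raw arg-max bin
    spacing_px: float = np.nan
    spacing_um: float = np.nan
    peak_distinctiveness: float = np.nan
    left_min_freq: float = np.nan

    def with_scale(self, scale_um_per_px: float) -> "PeakResult":
        if not self.found:
            return self
        return replace(self, spacing_um=self.spacing_px * scale_um_per_px)


def default_band_cyc_per_px(
    scale_um_per_px: float, spacing_um_range: tuple[float, float] = (6.0, 40.0)
) -> tuple[float, float]:
    """Search band bracketing plausible RPE spacings (default 6-40 um)."""
    lo_um, hi_um = spacing_um_range
    return (
        HEX_LATTICE_FACTOR * scale_um_per_px / hi_um,
        HEX_LATTICE_FACTOR * scale_um_per_px / lo_um,
    )


def detect_peak(rpsd: RadialPSD, band: tuple[float, float]) -> PeakResult:
    """Locate the mosaic's fundamental-frequency peak and measure its height.

    The peak is the highest strict local maximum of the log PSD inside
    ``band``; peak distinctiveness is the log10 power difference between the
    peak and the nearest strict local minimum at lower frequency (falling back
    to the global minimum in (0, f_peak) when none exists).  The peak
    frequency is refined by a quadratic fit through the three bins around the
    maximum.  A spectrum with no interior local maximum yields
    ``PeakResult(found=False)``.
    """
    f_lo, f_hi = band
    nyquist = rpsd.freq[-1]
    if not (0 < f_lo < f_hi <= nyquist):
        raise ValueError(f"band {band} not within (0, Nyquist={nyquist}]")
    y = rpsd.log_psd
    f = rpsd.freq
    in_band = np.where((f >= f_lo) & (f <= f_hi))[0]
    in_band = in_band[(in_band > 0) & (in_band < len(y) - 1)]
    if len(in_band) == 0:
        raise ValueError("band contains no frequency bins")
    local_max = in_band[
        (y[in_band] > y[in_band - 1]) & (y[in_band] > y[in_band + 1])
    ]
    if len(local_max) == 0:
        return PeakResult(found=False)
    p = int(local_max[np.argmax(y[local_max])])

    # nearest strict local minimum to the left of the peak
    left_min = None
    for i in range(p - 1, 0, -1):
        if y[i] < y[i - 1] and y[i] < y[i + 1]:
            left_min = i
            break
    if left_min is None:
        left_min = int(np.argmin(y[1:p]) + 1) if p > 1 else p
    pd_value = float(y[p] - y[left_min])

    # sub-bin refinement: quadratic through the three bins around the max
    ym, y0, yp = y[p - 1], y[p], y[p + 1]
    denom = ym - 2 * y0 + yp
    delta = 0.5 * (ym - yp) / denom if denom < 0 else 0.0
    f_peak = (p + delta) / rpsd.roi_px

    return PeakResult(
        found=True,
        f_peak=float(f_peak),
        f_peak_bin=float(f[p]),
        spacing_px=float(HEX_LATTICE_FACTOR / f_peak),
        peak_distinctiveness=pd_value,
        left_min_freq=float(f[left_min]),
    )


def cell_spacing_from_psd(
    image: np.ndarray,
    scale_um_per_px: float | None = None,
    band: tuple[float, float] | None = None,
    roi_px: int = 200,
    window: str = "hann",
) -> PeakResult:
    """Estimate cell spacing from the radial power spectrum of an image."""
    rpsd = radial_psd(image, roi_px=roi_px, window=window)
    if band is None:
        if scale_um_per_px is None:
            raise ValueError("need either an explicit band or a scale")
        band = default_band_cyc_per_px(scale_um_per_px)
    result = detect_peak(rpsd, band)
    if scale_um_per_px is not None and result.found:
        result = result.with_scale(scale_um_per_px)
    return result


# --------------------------------------------------------------------------
# model-eye scaling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeBiometry:
    """Three-surface schematic eye (cornea + two lens surfaces).

    Defaults are a standard simplified schematic of the emmetropic adult eye;
    the three clinically measured quantities (axial length, corneal radius,
    anterior chamber depth) override the schematic values per eye, while the
    lens geometry and the refractive indices stay at their schematic values.
    All lengths in millimetres; radii signed with the convention that a
    surface convex toward incoming light has a positive radius.
    """

    axial_length_mm: float = 24.0
    corneal_radius_mm: float = 7.8
    anterior_chamber_depth_mm: float = 3.6
    lens_thickness_mm: float = 3.6
    lens_front_radius_mm: float = 10.0
    lens_back_radius_mm: float = -6.0
    n_aqueous: float = 1.336
    n_lens: float = 1.413
    n_vitreous: float = 1.336

    def __post_init__(self):
        if min(self.axial_length_mm, self.corneal_radius_mm,
               self.anterior_chamber_depth_mm, self.lens_thickness_mm) <= 0:
            raise ValueError("lengths must be > 0")
        if self.axial_length_mm <= self.anterior_chamber_depth_mm + self.lens_thickness_mm:
            raise ValueError("axial length must exceed chamber depth plus lens")
        if min(self.n_aqueous, self.n_lens, self.n_vitreous) <= 1.0:
            raise ValueError("refractive indices must exceed 1")


def retinal_microns_per_degree(biometry: EyeBiometry = EyeBiometry()) -> float:
    """Retinal image size per degree of visual angle via a paraxial ray trace.

    A chief ray entering the cornea vertex at 1 degree is propagated through
    the three refracting surfaces with 2x2 refraction/translation matrices in
    the reduced-angle (y, n*u) convention; the ray height at the retina gives
    micrometres per degree.
    """
    b = biometry
    surfaces = [  # (radius_mm, n_before, n_after)
        (b.corneal_radius_mm, 1.0, b.n_aqueous),
        (b.lens_front_radius_mm, b.n_aqueous, b.n_lens),
        (b.lens_back_radius_mm, b.n_lens, b.n_vitreous),
    ]
    gaps = [  # distance to next plane and its index
        (b.anterior_chamber_depth_mm, b.n_aqueous),
        (b.lens_thickness_mm, b.n_lens),
        (b.axial_length_mm - b.anterior_chamber_depth_mm - b.lens_thickness_mm,
         b.n_vitreous),
    ]
    theta = np.deg2rad(1.0)
    ray = np.array([0.0, 1.0 * theta])  # (y, n*u) at the cornea, n=1
    total_power = 0.0
    for (radius, n0, n1), (d, n_gap) in zip(surfaces, gaps):
        power = (n1 - n0) / (radius * 1e-3)  # dioptres; radius in metres
        total_power += power
        refract = np.array([[1.0, 0.0], [-(n1 - n0) / radius, 1.0]])
        translate = np.array([[1.0, d / n_gap], [0.0, 1.0]])
        ray = translate @ (refract @ ray)
    if total_power <= 0:
        raise ValueError("nonphysical biometry: non-positive power chain")
    return float(ray[0] * 1000.0)  # mm -> um


def retinal_scale(
    biometry: EyeBiometry = EyeBiometry(), fov_deg: float = 1.5, n_px: int = 300
) -> float:
    """Micrometres per pixel for a field of ``fov_deg`` sampled by ``n_px``."""
    if fov_deg <= 0 or n_px <= 1:
        raise ValueError("fov_deg must be > 0 and n_px > 1")
    return retinal_microns_per_degree(biometry) * fov_deg / n_px


# --------------------------------------------------------------------------
# Voronoi packing analysis
# --------------------------------------------------------------------------

@dataclass
class VoronoiStats:
    """Packing statistics of the cell mosaic from marked centers."""

    n_cells: int
    n_cells_interior: int
    neighbor_count_hist: dict[int, int]
    mean_neighbor_distance_px: float
    sd_neighbor_distance_px: float
    mean_neighbor_distance_um: float
    fraction_hexagonal: float
    density_cells_per_mm2: float
    interior_indices: np.ndarray = field(repr=False, default=None)
    adjacency: set = field(repr=False, default=None)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def voronoi_stats(
    centers: np.ndarray,
    image_bounds: tuple[float, float],
    scale_um_per_px: float | None = None,
) -> VoronoiStats:
    """Voronoi tessellation statistics of cell centers.

    Cells whose Voronoi region is unbounded or touches the image bounds are
    excluded from the interior statistics; neighbor distances are
    center-to-center distances over Voronoi-adjacent interior pairs; the
    density is the interior cell count divided by the summed interior region
    area.  ``fraction_hexagonal`` is the fraction of interior cells with
    exactly six Voronoi neighbors.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need at least 4 (row, col) centers")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate input: centers are collinear")
    hmax, wmax = image_bounds
    vor = Voronoi(pts)

    def region_ok(i: int) -> bool:
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            return False
        verts = vor.vertices[region]
        return bool(
            np.all(verts[:, 0] >= 0) and np.all(verts[:, 0] <= hmax)
            and np.all(verts[:, 1] >= 0) and np.all(verts[:, 1] <= wmax)
        )

    interior = np.array([i for i in range(len(pts)) if region_ok(i)], dtype=int)
    interior_set = set(interior.tolist())

    adjacency = {tuple(sorted(rp)) for rp in vor.ridge_points.tolist()}
    neighbor_counts: dict[int, int] = {i: 0 for i in range(len(pts))}
    for a, b in adjacency:
        neighbor_counts[a] += 1
        neighbor_counts[b] += 1

    hist: dict[int, int] = {}
    for i in interior:
        hist[neighbor_counts[i]] = hist.get(neighbor_counts[i], 0) + 1

    pair_d = [
        float(np.linalg.norm(pts[a] - pts[b]))
        for a, b in adjacency
        if a in interior_set and b in interior_set
    ]
    mean_d = float(np.mean(pair_d)) if pair_d else np.nan
    sd_d = float(np.std(pair_d)) if pair_d else np.nan

    area_px2 = sum(
        _polygon_area(vor.vertices[vor.regions[vor.point_region[i]]])
        for i in interior
    )
    if scale_um_per_px is not None and area_px2 > 0:
        density = len(interior) / (area_px2 * (scale_um_per_px * 1e-3) ** 2)
        mean_d_um = mean_d * scale_um_per_px
    else:
        density = len(interior) / area_px2 * 1e6 if area_px2 > 0 else np.nan
        mean_d_um = np.nan if scale_um_per_px is None else mean_d * scale_um_per_px
    frac_hex = (
        float(np.mean([neighbor_counts[i] == 6 for i in interior]))
        if len(interior) else np.nan
    )
    return VoronoiStats(
        n_cells=len(pts),
        n_cells_interior=len(interior),
        neighbor_count_hist=hist,
        mean_neighbor_distance_px=mean_d,
        sd_neighbor_distance_px=sd_d,
        mean_neighbor_distance_um=mean_d_um,
        fraction_hexagonal=frac_hex,
        density_cells_per_mm2=float(density),
        interior_indices=interior,
        adjacency=adjacency,
    )


# --------------------------------------------------------------------------
# comparison reports
# --------------------------------------------------------------------------

@dataclass
class CellMetrics:
    """Joint spacing/contrast/packing summary for one image."""

    peak: PeakResult
    voronoi: VoronoiStats | None = None


def compare_to_reference(metrics_a: CellMetrics, metrics_b: CellMetrics) -> dict:
    """Signed errors a - b between two metric summaries."""
    pa, pb = metrics_a.peak, metrics_b.peak
    if pa is None or pb is None:
        raise ValueError("both inputs need a peak result")
    out = {
        "spacing_error_px": pa.spacing_px - pb.spacing_px,
        "spacing_error_um": pa.spacing_um - pb.spacing_um,
        "pd_difference": pa.peak_distinctiveness - pb.peak_distinctiveness,
    }
    if metrics_a.voronoi is not None and metrics_b.voronoi is not None:
        out["voronoi_spacing_error_px"] = (
            metrics_a.voronoi.mean_neighbor_distance_px
            - metrics_b.voronoi.mean_neighbor_distance_px
        )
    return out


def compare_batches(list_a: list[CellMetrics], list_b: list[CellMetrics]) -> dict:
    """Mean +- SD of the signed errors over paired ROI lists."""
    if len(list_a) != len(list_b) or not list_a:
        raise ValueError("need equal-length nonempty lists")
    reports = [compare_to_reference(a, b) for a, b in zip(list_a, list_b)]
    keys = reports[0].keys()
    return {
        k: {
            "mean": float(np.mean([r[k] for r in reports])),
            "sd": float(np.std([r[k] for r in reports], ddof=1)) if len(reports) > 1 else 0.0,
        }
        for k in keys
    }
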