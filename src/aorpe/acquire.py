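"""Ground-truth construction: registration, averaging, and training pairs.

Repeated acquisitions of the same retinal patch carry decorrelated speckle, so
registering them to a reference frame and averaging suppresses speckle by
``1/sqrt(N)`` and reveals the cell mosaic.  Because eye motion gives every
frame a different bulk shift and a unique intra-frame raster distortion, each
choice of reference frame yields a slightly different averaged image of the
same tissue — which is exactly what makes multi-reference augmentation work:
one stack provides many distinct (speckled reference, averaged) training
pairs, doubled again by horizontal flipping.

Registration here is whole-frame rigid translation by normalised
cross-correlation with subpixel refinement (a quadratic fit to the correlation
peak); strip-wise nonrigid correction used in full AO-OCT processing chains is
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .sim import SpeckleStack

__all__ = [
    "RegisteredStack",
    "TrainingPair",
    "TrainingPairSet",
    "register_to_reference",
    "average_stack",
    "crop_scanner_artifact",
    "rank_references",
    "build_training_pairs",
]

DEFAULT_MIN_SCORE = 0.2


@dataclass
class RegisteredStack:
    """Frames resampled onto a reference frame's grid."""

    reference_index: int
    shifts: np.ndarray          # (n_frames, 2) estimated (dy, dx), subpixel
    frames: np.ndarray          # (n_frames, H, W) resampled
    masks: np.ndarray           # (n_frames, H, W) bool validity after shift
    scores: np.ndarray          # (n_frames,) peak normalised correlation

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class TrainingPair:
    speckled: np.ndarray
    averaged: np.ndarray
    stack_id: int
    reference_index: int
    offset: tuple[int, int]
    flipped: bool
    averaged_alt: np.ndarray | None = None  # same patch from another reference


@dataclass
class TrainingPairSet:
    """Co-registered (speckled, averaged) patch pairs with provenance."""

    pairs: list[TrainingPair] = field(default_factory=list)
    patch_px: int = 150

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.stack([p.speckled for p in self.pairs])
        y = np.stack([p.averaged for p in self.pairs])
        return x, y

    def alt_arrays(self) -> np.ndarray:
        """Alternative averaged renditions (fall back to the primary)."""
        return np.stack(
            [p.averaged_alt if p.averaged_alt is not None else p.averaged
             for p in self.pairs]
        )

    def extend(self, other: "TrainingPairSet") -> None:
        self.pairs.extend(other.pairs)


def _ncc_shift(
    ref: np.ndarray, frame: np.ndarray, smooth_sigma_px: float = 2.0
) -> tuple[np.ndarray, float]:
    """Estimate the (dy, dx) shifting `frame` onto `ref` plus peak NCC.

    Both images are first smoothed by a small Gaussian so that the cell-scale
    structure, not the decorrelated speckle grain, drives the correlation (the
    symmetric kernel does not bias the peak position).  Cross-correlation of
    the zero-mean images via FFT, normalised by the global norms; the integer
    peak is refined per axis by a quadratic fit through the three correlation
    samples around it.
    """
    if smooth_sigma_px > 0:
        ref = ndimage.gaussian_filter(ref, smooth_sigma_px, mode="mirror")
        frame = ndimage.gaussian_filter(frame, smooth_sigma_px, mode="mirror")
    a = ref - ref.mean()
    b = frame - frame.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("degenerate frame: zero variance")
    corr = fftconvolve(a, b[::-1, ::-1], mode="full") / (na * nb)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    score = float(corr[peak])
    h, w = ref.shape
    # full-mode correlation lag; the sampling shift that maps frame onto ref
    # is its negation (sample frame at x + shift to read off ref at x)
    refined = [float(peak[0] - (h - 1)), float(peak[1] - (w - 1))]
    for axis, p in enumerate(peak):
        if 0 < p < corr.shape[axis] - 1:
            idx = list(peak)
            idx[axis] = p - 1
            ym = corr[tuple(idx)]
            idx[axis] = p + 1
            yp = corr[tuple(idx)]
            y0 = corr[peak]
            denom = ym - 2.0 * y0 + yp
            if denom < 0:  # proper maximum
                refined[axis] += 0.5 * (ym - yp) / denom
    return -np.array(refined), score


def register_to_reference(
    stack: SpeckleStack | np.ndarray, reference_index: int, n_passes: int = 2
) -> RegisteredStack:
    """Register every frame of a stack to the chosen reference frame.

    Shifts are estimated by normalised cross-correlation with subpixel
    quadratic refinement and frames are resampled onto the reference grid by
    bilinear interpolation (mirror fill, with a validity mask excluding the
    filled border).  The reference frame's shift is (0, 0) and its score 1.

    Because a quasi-periodic cell mosaic correlates with itself at lattice
    displacements, single-frame NCC against a speckled reference can lock onto
    a lattice alias.  With ``n_passes`` > 1 the first pass's better half of
    frames is averaged into a low-speckle template on the reference grid and
    all frames are re-registered against it, which suppresses both the speckle
    noise and the alias peaks.
    """
    frames = stack.as_array() if isinstance(stack, SpeckleStack) else np.asarray(stack)
    n = frames.shape[0]
    if not (0 <= reference_index < n):
        raise IndexError("reference_index out of range")
    ref = frames[reference_index]
    h, w = ref.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    def one_pass(template: np.ndarray) -> RegisteredStack:
        shifts = np.zeros((n, 2))
        scores = np.zeros(n)
        out = np.empty_like(frames, dtype=float)
        masks = np.zeros(frames.shape, dtype=bool)
        for k in range(n):
            if k == reference_index:
                shifts[k] = 0.0
                scores[k] = 1.0
                out[k] = ref
                masks[k] = True
                continue
            shifts[k], scores[k] = _ncc_shift(template, frames[k])
            sy, sx = yy + shifts[k, 0], xx + shifts[k, 1]
            out[k] = ndimage.map_coordinates(frames[k], [sy, sx], order=1, mode="mirror")
            masks[k] = (sy >= 0) & (sy <= h - 1) & (sx >= 0) & (sx <= w - 1)
        return RegisteredStack(
            reference_index=reference_index, shifts=shifts,
            frames=out, masks=masks, scores=scores,
        )

    reg = one_pass(ref)
    for _ in range(n_passes - 1):
        keep = reg.scores >= np.median(reg.scores)
        counts = np.maximum(reg.masks[keep].sum(axis=0), 1)
        template = np.where(reg.masks[keep], reg.frames[keep], 0.0).sum(axis=0) / counts
        reg = one_pass(template)
    return reg


def average_stack(
    reg: RegisteredStack, min_score: float = DEFAULT_MIN_SCORE
) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise mean over contributing frames.

    Frames whose peak correlation falls below ``min_score`` are excluded;
    the count map records how many frames contributed at each pixel (edges
    lose frames to registration shifts).
    """
    keep = reg.scores >= min_score
    if not keep.any():
        raise ValueError("no frame passes min_score")
    frames = reg.frames[keep]
    masks = reg.masks[keep]
    count = masks.sum(axis=0)
    total = np.where(masks, frames, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return avg, count


def crop_scanner_artifact(image: np.ndarray, margin_px: int = 50) -> np.ndarray:
    """Crop the scanner-turnaround artifact columns from both sides.

    The raster scanner distorts the image near the line turnaround, so
    ``margin_px`` columns are removed from the left and the right; height is
    unchanged (e.g. 300x300 -> 300x200 with the default margin).
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    if image.shape[-1] <= 2 * margin_px:
        raise ValueError(
            f"image width {image.shape[-1]} too narrow for margin {margin_px}"
        )
    if margin_px == 0:
        return image
    return image[..., :, margin_px:-margin_px]


def rank_references(stack: SpeckleStack | np.ndarray) -> np.ndarray:
    """Rank frames as reference candidates.

    Each frame is scored by its mean peak normalised correlation against every
    other frame; the ranking (best first) automates the manual reference
    selection an operator would otherwise perform.
    """
    frames = stack.as_array() if isinstance(stack, SpeckleStack) else np.asarray(stack)
    n = frames.shape[0]
    if n == 1:
        return np.array([0])
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, s = _ncc_shift(frames[i], frames[j])
            scores[i, j] = scores[j, i] = s
    mean_scores = scores.sum(axis=1) / (n - 1)
    return np.argsort(-mean_scores, kind="stable")


def _tile_offsets(size: int, patch: int, stride: int) -> list[int]:
    return list(range(0, size - patch + 1, stride))


def build_training_pairs(
    stack: SpeckleStack | np.ndarray,
    n_references: int,
    patch_px: int = 150,
    stride_px: int = 50,
    horizontal_flip: bool = True,
    crop_margin_px: int = 50,
    min_score: float = DEFAULT_MIN_SCORE,
    stack_id: int = 0,
    references: list[int] | None = None,
) -> TrainingPairSet:
    """Build co-registered (speckled, averaged) patch pairs from one stack.

    For each of the top-``n_references`` frames (ranked by
    :func:`rank_references`, unless ``references`` is given): register all
    frames to it, average, crop the scanner margin from both the reference
    and the average, and tile both into ``patch_px`` patches at ``stride_px``.
    With flipping the pair count is
    ``n_references * patches_per_image * 2``.

    Each pair also carries, when at least two references are used, the same
    patch window from the *next* reference's averaged image — a second
    rendition of the same tissue used as the similar-pair input of the twin
    discriminator.
    """
    frames = stack.as_array() if isinstance(stack, SpeckleStack) else np.asarray(stack)
    n = frames.shape[0]
    if n_references > n:
        raise ValueError("n_references exceeds number of frames")
    if references is None:
        references = list(rank_references(frames)[:n_references])
    else:
        references = list(references[:n_references])

    averaged = {}
    for r in references:
        reg = register_to_reference(frames, r)
        avg, _ = average_stack(reg, min_score=min_score)
        averaged[r] = crop_scanner_artifact(avg, crop_margin_px)

    out = TrainingPairSet(patch_px=patch_px)
    for i, r in enumerate(references):
        spk = crop_scanner_artifact(frames[r], crop_margin_px)
        avg = averaged[r]
        h, w = spk.shape
        if patch_px > h or patch_px > w:
            raise ValueError("patch larger than cropped image")
        alt_ref = references[(i + 1) % len(references)] if len(references) > 1 else None
        alt_full = None
        if alt_ref is not None:
            # renditions from different references sit on different grids;
            # bring the alternative one onto this reference's grid first
            shift, _ = _ncc_shift(avg, averaged[alt_ref])
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            alt_full = ndimage.map_coordinates(
                averaged[alt_ref], [yy + shift[0], xx + shift[1]],
                order=1, mode="mirror",
            )
        for oy in _tile_offsets(h, patch_px, stride_px):
            for ox in _tile_offsets(w, patch_px, stride_px):
                sl = (slice(oy, oy + patch_px), slice(ox, ox + patch_px))
                alt = alt_full[sl].copy() if alt_full is not None else None
                out.pairs.append(
                    TrainingPair(
                        speckled=spk[sl].copy(),
                        averaged=avg[sl].copy(),
                        stack_id=stack_id,
                        reference_index=r,
                        offset=(oy, ox),
                        flipped=False,
                        averaged_alt=alt,
                    )
                )
    if horizontal_flip:
        flipped = [
            TrainingPair(
                speckled=p.speckled[:, ::-1].copy(),
                averaged=p.averaged[:, ::-1].copy(),
                stack_id=p.stack_id,
                reference_index=p.reference_index,
                offset=p.offset,
                flipped=True,
                averaged_alt=(
                    p.averaged_alt[:, ::-1].copy()
                    if p.averaged_alt is not None else None
                ),
            )
            for p in out.pairs
        ]
        out.pairs.extend(flipped)
    return out
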