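"""Frame ingestion, segmentation, skeleton extraction and intensity sampling.

This stage turns a bright-field time-lapse of a tubular organism into the
skeleton-pixel x time intensity matrix on which the mode decomposition
operates. The organism keeps a stable morphology over an analysis segment,
so a single reference skeleton — computed from the pixelwise temporal-median
mask — is used for the whole segment.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_holes, skeletonize

from .containers import (
    FormatError,
    FrameStack,
    InputError,
    IntensityMatrix,
    MorphologyError,
    OrganismMask,
    ParameterError,
    SegmentationError,
    SkeletonMap,
    TubeAxis,
)

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _numeric_key(path: Path) -> tuple:
    """Sort key that orders frame_2 before frame_10."""
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def load_frames(path: str | Path, dt: float) -> FrameStack:
    """Load a multi-page TIFF or a directory of same-size grayscale images.

    Intensities are cast to float without rescaling; frames keep acquisition
    (page or numeric-filename) order.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in _IMAGE_EXTS),
            key=_numeric_key,
        )
        if not files:
            raise InputError(f"no image files in {path}")
        frames = []
        for f in files:
            try:
                frames.append(np.asarray(iio.imread(f), dtype=float))
            except Exception as exc:  # noqa: BLE001 - wrap any backend failure
                raise InputError(f"unreadable image {f}: {exc}") from exc
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent frame sizes: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            stack = np.asarray(tifffile.imread(path), dtype=float)
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"unreadable TIFF {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"expected grayscale frames, got array of shape {stack.shape}")
    return FrameStack(frames=stack, dt=dt)


def segment_organism(
    stack: FrameStack,
    smooth_radius: float = 2.0,
    threshold_method: str = "otsu",
    min_hole_area: int = 64,
    bright_foreground: bool | None = None,
) -> OrganismMask:
    """Segment the organism in every frame.

    Each frame is Gaussian-smoothed and thresholded (Otsu by default, which
    is invariant under positive affine intensity rescaling); the largest
    connected component is kept and small holes are filled. ``bright_foreground``
    forces the polarity of the threshold; by default the side with fewer
    pixels is taken as foreground (the organism occupies a minority of the
    field of view).
    """
    if threshold_method != "otsu":
        raise ParameterError(f"unknown threshold method {threshold_method!r}")
    masks = np.empty(stack.frames.shape, dtype=bool)
    for t, frame in enumerate(stack.frames):
        sm = gaussian(frame, sigma=smooth_radius, preserve_range=True)
        if np.ptp(sm) == 0:
            raise SegmentationError(f"frame {t}: empty foreground (flat image)")
        thr = threshold_otsu(sm)
        above = sm > thr
        if bright_foreground is None:
            fg = above if above.sum() <= above.size / 2 else ~above
        elif bright_foreground:
            fg = above
        else:
            fg = ~above
        if not fg.any():
            raise SegmentationError(f"frame {t}: empty foreground")
        lab = label(fg, connectivity=2)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        fg = lab == largest
        fg = remove_small_holes(fg, max_size=min_hole_area)
        masks[t] = fg
    params = {
        "smooth_radius": smooth_radius,
        "threshold_method": threshold_method,
        "min_hole_area": min_hole_area,
        "bright_foreground": bright_foreground,
    }
    return OrganismMask(masks=masks, method_params=params)


def _skeleton_pixels_and_adjacency(skel_img: np.ndarray) -> SkeletonMap:
    coords = np.argwhere(skel_img)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    index = {tuple(c): k for k, c in enumerate(coords)}
    adjacency: list[list[int]] = []
    for r, c in coords:
        nbrs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs.append(j)
        adjacency.append(sorted(nbrs))
    return SkeletonMap(pixels=coords, adjacency=adjacency)


def extract_skeleton(mask_ref: np.ndarray) -> SkeletonMap:
    """One-pixel-wide topological skeleton of a reference mask.

    Adjacency among skeleton pixels is 8-connectivity.
    """
    mask_ref = np.asarray(mask_ref, dtype=bool)
    if not mask_ref.any():
        raise MorphologyError("mask has zero area")
    skel_img = skeletonize(mask_ref)
    if not skel_img.any():
        # a tiny blob can skeletonize to nothing; fall back to its centroid
        r, c = np.argwhere(mask_ref).mean(axis=0).round().astype(int)
        skel_img = np.zeros_like(mask_ref)
        skel_img[r, c] = True
    return _skeleton_pixels_and_adjacency(skel_img)


def sample_intensities(
    stack: FrameStack,
    skel: SkeletonMap,
    radius: float = 2.0,
    mask: OrganismMask | None = None,
    invert_polarity: bool = True,
) -> IntensityMatrix:
    """Sample per-skeleton-pixel intensity time series.

    Entry (p, t) is the mean intensity of frame t over the disk of the given
    radius centered on skeleton pixel p, restricted to the organism mask when
    one is given. Bright-field polarity: thicker tubes transmit less light,
    so by default the stored value is ``max_intensity - recorded`` and larger
    values mean a more dilated tube.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    T = stack.n_frames
    H, W = stack.shape
    P = skel.n_pixels
    if np.any(skel.pixels[:, 0] >= H) or np.any(skel.pixels[:, 1] >= W):
        raise FormatError("skeleton pixels outside image bounds")

    r_int = int(np.floor(radius))
    offs = [
        (dr, dc)
        for dr in range(-r_int, r_int + 1)
        for dc in range(-r_int, r_int + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    values = np.empty((P, T), dtype=float)
    frames = stack.frames
    if invert_polarity:
        frames = frames.max() - frames
    for k, (r, c) in enumerate(skel.pixels):
        pts = [
            (r + dr, c + dc)
            for dr, dc in offs
            if 0 <= r + dr < H and 0 <= c + dc < W
        ]
        rows = np.array([p[0] for p in pts])
        cols = np.array([p[1] for p in pts])
        if mask is not None:
            # per-frame mask restriction; fall back to all disk pixels if the
            # mask excludes the entire disk in some frame
            sel = mask.masks[:, rows, cols]  # (T, n_pts)
            vals = frames[:, rows, cols]
            cnt = sel.sum(axis=1)
            safe = cnt > 0
            out = np.where(
                safe,
                (vals * sel).sum(axis=1) / np.maximum(cnt, 1),
                vals.mean(axis=1),
            )
            values[k] = out
        else:
            values[k] = frames[:, rows, cols].mean(axis=1)
    return IntensityMatrix(values=values, dt=stack.dt, stage="raw")


def detrend_normalize(
    mat: IntensityMatrix,
    trend_window: float,
    normalize_variance: bool = False,
) -> IntensityMatrix:
    """Remove slow per-pixel trends and center each series.

    The trend is the projection of each pixel series onto temporal
    frequencies below ``1/trend_window`` (a DCT low-pass, so boundaries are
    handled by even reflection); subtracting a projection makes the
    operation exactly idempotent, unlike a moving-average detrender. With
    ``normalize_variance`` each series is additionally scaled to unit
    standard deviation.
    """
    from scipy.fft import dct, idct

    win = int(round(trend_window / mat.dt))
    if win < 2:
        raise ParameterError("trend window must span at least 2 frames")
    T = mat.n_frames
    coeffs = dct(mat.values, type=2, axis=1, norm="ortho")
    # DCT bin k oscillates with period 2*T*dt/k; keep k (incl. DC) whose
    # period exceeds the trend window in the trend
    freqs = np.arange(T) / (2 * T * mat.dt)
    keep_low = freqs < 1.0 / trend_window
    trend = idct(np.where(keep_low[None, :], coeffs, 0.0), type=2, axis=1, norm="ortho")
    resid = mat.values - trend
    resid = resid - resid.mean(axis=1, keepdims=True)
    if normalize_variance:
        std = resid.std(axis=1, keepdims=True)
        resid = resid / np.where(std > 0, std, 1.0)
    return IntensityMatrix(values=resid, dt=mat.dt, stage="detrended")


def _endpoints_and_junctions(skel: SkeletonMap) -> tuple[list[int], list[int]]:
    degrees = [len(a) for a in skel.adjacency]
    endpoints = [k for k, d in enumerate(degrees) if d == 1]
    junctions = [k for k, d in enumerate(degrees) if d >= 3]
    return endpoints, junctions


def parameterize_tube(mask_ref: np.ndarray) -> TubeAxis:
    """Order the skeleton of a single tube from one end to the other.

    Arclength accumulates 1 per axis step and sqrt(2) per diagonal step.
    Raises a morphology error when the skeleton branches (a junction or
    more than two endpoints), i.e. the mask is not a single tube.
    """
    skel = extract_skeleton(np.asarray(mask_ref, dtype=bool))
    endpoints, junctions = _endpoints_and_junctions(skel)
    if junctions or len(endpoints) != 2:
        raise MorphologyError(
            f"not a single tube: {len(endpoints)} endpoints, {len(junctions)} junctions"
        )
    # walk from one endpoint to the other
    path = [endpoints[0]]
    prev = -1
    while True:
        nbrs = [j for j in skel.adjacency[path[-1]] if j != prev]
        # prune already-visited (guards against 2x2 squares in the skeleton)
        nbrs = [j for j in nbrs if j not in path[-3:]]
        if not nbrs:
            break
        prev = path[-1]
        path.append(nbrs[0])
        if path[-1] == endpoints[1]:
            break
    coords = skel.pixels[path]
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(steps)])
    return TubeAxis(arclength=arclength, coords=coords)
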