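"""Core data containers for the contraction-mode analysis pipeline.

All image-like arrays use (row, col) pixel coordinates, 0-based frame
indices, and time along the last axis of matrix-valued containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class PipelineError(Exception):
    """Base class for pipeline errors."""


class InputError(PipelineError):
    """Unreadable or malformed input data."""


class FormatError(PipelineError):
    """Inconsistent frame sizes or container layout."""


class SegmentationError(PipelineError):
    """Segmentation produced an empty foreground."""


class MorphologyError(PipelineError):
    """Mask morphology incompatible with the requested operation."""


class ParameterError(PipelineError):
    """Invalid parameter value."""


class DataError(PipelineError):
    """Non-finite or degenerate data."""


class AlignmentError(PipelineError):
    """Time bases or windowings of two inputs do not overlap."""


@dataclass
class FrameStack:
    """A grayscale time-lapse recording.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Scalar intensities in acquisition order.
    dt : float
        Frame interval in seconds.
    pixel_size : float
        Physical length per pixel; 1 (unitless) when uncalibrated.
    """

    frames: np.ndarray
    dt: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(f"expected (T, H, W) frames, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise InputError("a frame stack needs at least 2 frames")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class OrganismMask:
    """Per-frame boolean foreground masks of the organism."""

    masks: np.ndarray
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise FormatError("masks must be (T, H, W)")

    def consensus(self) -> np.ndarray:
        """Pixelwise temporal-median mask (the reference for skeletonization)."""
        return np.median(self.masks.astype(np.uint8), axis=0) >= 0.5


@dataclass
class SkeletonMap:
    """Ordered skeleton pixels with their 8-connectivity adjacency.

    ``pixels[k]`` is the (row, col) of the skeleton pixel mapped to column
    ``k`` of the intensity matrix; ``adjacency`` lists neighbor indices per
    pixel.
    """

    pixels: np.ndarray
    adjacency: list[list[int]]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise FormatError("pixels must be (P, 2)")
        seen = {tuple(p) for p in self.pixels}
        if len(seen) != len(self.pixels):
            raise FormatError("skeleton pixels must be unique")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def index(self, pixel: tuple[int, int]) -> int:
        """Column position of a (row, col) skeleton pixel."""
        if not hasattr(self, "_index"):
            self._index = {tuple(p): k for k, p in enumerate(self.pixels)}
        return self._index[tuple(pixel)]


@dataclass
class TubeAxis:
    """Midline of a single tube, ordered end to end."""

    arclength: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if np.any(np.diff(self.arclength) <= 0):
            raise FormatError("arclength must be strictly increasing")


@dataclass
class IntensityMatrix:
    """Skeleton-pixel x time matrix of contraction-state intensities.

    ``stage`` is ``"raw"`` straight after sampling and ``"detrended"`` once
    slow trends and the temporal mean have been removed.
    """

    values: np.ndarray
    dt: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be (P, T)")
        if not np.all(np.isfinite(self.values)):
            raise DataError("intensity matrix contains non-finite entries")
        if self.stage not in ("raw", "detrended"):
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.stage == "detrended":
            means = self.values.mean(axis=1)
            stds = self.values.std(axis=1)
            if np.any(np.abs(means) > 1e-9 * stds + 1e-12):
                raise DataError("detrended matrix must have near-zero per-pixel mean")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ModeBasis:
    """Orthonormal spatial contraction modes with time coefficients.

    The decomposition writes each centered intensity snapshot as
    ``I(t) - mean = sum_mu a_mu(t) phi_mu`` with ``phi_mu`` the columns of
    ``modes`` and ``a_mu`` the rows of ``coefficients``.
    """

    modes: np.ndarray            # (P, M), orthonormal columns
    eigenvalues: np.ndarray      # (M,), descending
    coefficients: np.ndarray     # (M, T)
    temporal_mean: np.ndarray    # (P,)
    dt: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


@dataclass
class EigenSpectrum:
    """Ranked relative eigenvalue spectrum in percent."""

    relative_eigenvalues: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.relative_eigenvalues = np.asarray(self.relative_eigenvalues, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)


@dataclass
class NullSpectrum:
    """Eigenvalue spectrum of shuffled (temporally randomized) data.

    ``cutoff_eigenvalue`` — the largest null eigenvalue in percent — bounds
    the eigenvalues attributable to noise.
    """

    relative_eigenvalues_null: np.ndarray
    cutoff_eigenvalue: float
    n_shuffles: int
    seed: int
    eigenvalues_null: np.ndarray | None = None  # absolute, averaged over shuffles


@dataclass
class AmplitudeField:
    """Per-mode, per-time squared envelopes and relative amplitudes.

    ``p[mu, t]`` is mode mu's share of the total squared coefficient
    envelope at time t; each column of ``p`` sums to one.
    """

    envelope_sq: np.ndarray
    p: np.ndarray
    smoothing_window: float

    @property
    def n_modes(self) -> int:
        return self.p.shape[0]

    @property
    def n_frames(self) -> int:
        return self.p.shape[1]


@dataclass
class SignificanceSeries:
    """Number of modes needed to reach a cumulative relative-amplitude cutoff."""

    cutoff: float
    n_sig: np.ndarray
    n_modes: int

    @property
    def pct_sig(self) -> np.ndarray:
        return self.n_sig / self.n_modes * 100.0


@dataclass
class DominanceInterval:
    """A maximal run during which one mode stays the most active."""

    mode: int
    t_start: int
    t_end: int            # inclusive
    excess_ratio: float   # mean (p_max - p_runnerup)/p_runnerup over the run
    above_threshold: bool

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start + 1


@dataclass
class CorrelationHistogram:
    """2-D histogram of pairwise coefficient correlations vs n_sig."""

    corr_edges: np.ndarray
    nsig_edges: np.ndarray
    counts: np.ndarray
    window_length: int
    n_skipped: int = 0


@dataclass
class TubeKymograph:
    """Cross-sectional area A(x, t) along a single tube."""

    A: np.ndarray
    x: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.A <= 0):
            raise DataError("cross-sectional area must be positive everywhere")
        dx = np.diff(self.x)
        if len(dx) and not np.allclose(dx, dx[0], rtol=1e-8):
            raise FormatError("x grid must be uniform")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def n_x(self) -> int:
        return self.A.shape[0]

    @property
    def n_frames(self) -> int:
        return self.A.shape[1]


@dataclass
class FlowField:
    """Volume flow rate Q(x, t) and pressure p(x, t) in a contracting tube.

    Positive Q points toward increasing x; pressure is in arbitrary units
    with the viscosity used in the solve recorded alongside.
    """

    Q: np.ndarray
    p_field: np.ndarray
    x: np.ndarray
    dt: float
    viscosity: float = 1.0


@dataclass
class RoiBox:
    """Half-open pixel bounds [row_min, row_max) x [col_min, col_max)."""

    label: str
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ParameterError(f"ROI {self.label!r} is empty")


@dataclass
class GrowthTrack:
    """Percent area change of an ROI relative to a reference frame."""

    label: str
    t0: int
    series: np.ndarray


@dataclass
class WaveSpec:
    """One contraction wave component of a synthetic tube.

    Standing waves are ``eps * sin(k*pi*x/L) * cos(omega*t + phase)``;
    traveling waves are ``eps * sin(2*pi*k*x/L - direction*omega*t + phase)``.
    """

    kind: str                   # "standing" | "traveling"
    k: int = 1
    omega: float = 2 * np.pi / 100.0
    amplitude: float = 0.05
    phase: float = 0.0
    direction: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("standing", "traveling"):
            raise ParameterError(f"unknown wave kind {self.kind!r}")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.omega <= 0:
            raise ParameterError("omega must be > 0")
        if self.direction not in (-1, 1):
            raise ParameterError("direction must be +1 or -1")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic generators."""

    modes: np.ndarray | None = None          # (P, K) orthonormal imposed patterns
    coefficients: np.ndarray | None = None   # (K, T)
    noise_sigma: float = 0.0
    trend: dict | None = None
    seed: int = 0
    epochs: Sequence[dict] = field(default_factory=list)
    waves: Sequence[WaveSpec] = field(default_factory=list)
    extras: dict = field(default_factory=dict)
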