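"""Synthetic ground-truth generators for the contraction-mode pipeline.

The generators emulate the statistical structure the analysis assumes:

* a single tube whose cross-sectional area carries standing and/or
  traveling contraction waves with period ~100 s, sampled every 3 s,
  optionally with slow trends and pixel noise;
* a stable network skeleton whose pixel intensities oscillate as
  superpositions of smooth orthonormal spatial patterns, including a
  "many-timescale" preset whose eigenvalue spectrum is continuous;
* rendered bright-field image stacks (thicker tube = darker pixel) for
  end-to-end tests of the imaging stage.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import tifffile
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.draw import line

from .containers import (
    FrameStack,
    IntensityMatrix,
    ParameterError,
    SkeletonMap,
    SyntheticTruth,
    TubeKymograph,
    WaveSpec,
)

DEFAULT_DT = 3.0        # seconds per frame
DEFAULT_PERIOD = 100.0  # typical contraction period, seconds


def synth_tube_kymograph(
    n_x: int = 64,
    n_frames: int = 400,
    dt: float = DEFAULT_DT,
    L: float | None = None,
    waves: list[WaveSpec] | None = None,
    noise_sigma: float = 0.0,
    trend: dict | None = None,
    seed: int = 0,
) -> tuple[TubeKymograph, SyntheticTruth]:
    """Cross-sectional-area kymograph A(x, t) = 1 + waves + trend + noise.

    Standing waves enter as ``eps sin(k pi x / L) cos(omega t + phase)`` and
    traveling waves as ``eps sin(2 pi k x / L - direction omega t + phase)``.
    The total wave amplitude must leave the area positive.
    """
    if waves is None:
        waves = [WaveSpec(kind="standing")]
    eps_total = sum(w.amplitude for w in waves)
    trend_amp = abs(trend.get("amplitude", 0.0)) if trend else 0.0
    if eps_total + trend_amp + 5 * noise_sigma >= 0.9:
        raise ParameterError("wave + trend + noise amplitudes risk non-positive area")
    if L is None:
        # wavelength scale chosen so a full traveling period tiles the grid
        # exactly (x = 0 .. L*(n-1)/n): the sine/cosine components then have
        # equal discrete norms and a traveling wave decomposes into two
        # exactly equal eigenvalues
        L = float(n_x)
    x = np.arange(n_x) * (L / n_x)
    t = np.arange(n_frames) * dt
    A = np.ones((n_x, n_frames))
    X, Tm = np.meshgrid(x, t, indexing="ij")
    for w in waves:
        if w.kind == "standing":
            A += w.amplitude * np.sin(w.k * np.pi * X / L) * np.cos(w.omega * Tm + w.phase)
        else:
            A += w.amplitude * np.sin(2 * np.pi * w.k * X / L - w.direction * w.omega * Tm + w.phase)
    if trend:
        A += trend.get("amplitude", 0.0) * (Tm / (t[-1] if t[-1] else 1.0) - 0.5)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        A += rng.normal(0, noise_sigma, A.shape)
    truth = SyntheticTruth(noise_sigma=noise_sigma, trend=trend, seed=seed, waves=waves)
    return TubeKymograph(A=A, x=x, dt=dt), truth


def synth_tube_epochs(
    n_x: int = 64,
    dt: float = DEFAULT_DT,
    n_epochs: int = 6,
    epoch_frames: int = 330,
    travel_amplitude: float = 0.12,
    irregular_modes: int = 48,
    irregular_amplitude: float = 0.006,
    period: float = DEFAULT_PERIOD,
    seed: int = 0,
) -> tuple[TubeKymograph, SyntheticTruth]:
    """Tube kymograph alternating coherent and irregular contraction epochs.

    Even epochs carry a single traveling wave (two quadrature modes, strong
    pumping); odd epochs carry ``irregular_modes`` incoherent low-amplitude
    standing waves at random frequencies (a many-mode state with weak
    pumping). Mirrors the regime where high flow rates coincide with few
    significant modes.
    """
    rng = np.random.default_rng(seed)
    T = n_epochs * epoch_frames
    L = float(n_x)
    x = np.arange(n_x, dtype=float)
    t = np.arange(T) * dt
    X, Tm = np.meshgrid(x, t, indexing="ij")
    A = np.ones((n_x, T))
    omega0 = 2 * np.pi / period
    omegas = omega0 * rng.uniform(0.6, 1.6, irregular_modes)
    phases = rng.uniform(0, 2 * np.pi, irregular_modes)
    epochs = []
    for e in range(n_epochs):
        sl = slice(e * epoch_frames, (e + 1) * epoch_frames)
        Xe, Te = X[:, sl], Tm[:, sl]
        # cosine taper over ~2 periods at the epoch edges: activity ramps in
        # and out instead of switching instantaneously, so the abrupt dA/dt
        # of a hard switch does not inject spurious flow at the boundaries
        ramp = min(66, epoch_frames // 4)
        gain = np.ones(epoch_frames)
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        gain[:ramp] = edge
        gain[-ramp:] = edge[::-1]
        if e % 2 == 0:
            A[:, sl] += (
                travel_amplitude * gain[None, :] * np.sin(2 * np.pi * Xe / L - omega0 * Te)
            )
            epochs.append({"start": sl.start, "stop": sl.stop, "kind": "traveling"})
        else:
            for i in range(irregular_modes):
                A[:, sl] += (
                    irregular_amplitude
                    * gain[None, :]
                    * np.sin((i + 1) * np.pi * Xe / L)
                    * np.cos(omegas[i] * Te + phases[i])
                )
            epochs.append({"start": sl.start, "stop": sl.stop, "kind": "irregular"})
    truth = SyntheticTruth(seed=seed, epochs=epochs, extras={"period": period})
    return TubeKymograph(A=A, x=x, dt=dt), truth


def _default_network_graph(spacing: int = 30, n_rows: int = 4, n_cols: int = 4) -> nx.Graph:
    """A jitter-free grid network with a few diagonal shortcuts."""
    g = nx.Graph()
    for r in range(n_rows):
        for c in range(n_cols):
            g.add_node((r, c), pos=(10 + r * spacing, 10 + c * spacing))
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                g.add_edge((r, c), (r, c + 1))
            if r + 1 < n_rows:
                g.add_edge((r, c), (r + 1, c))
    g.add_edge((0, 0), (1, 1))
    g.add_edge((n_rows - 2, n_cols - 2), (n_rows - 1, n_cols - 1))
    return g


def _rasterize_graph(g: nx.Graph) -> np.ndarray:
    """Unique (row, col) pixels along all rasterized edges, lexsorted."""
    if not nx.is_connected(g):
        raise ParameterError("network graph must be connected")
    pts = set()
    pos = nx.get_node_attributes(g, "pos")
    for u, v in g.edges:
        rr, cc = line(*pos[u], *pos[v])
        pts.update(zip(rr.tolist(), cc.tolist()))
    coords = np.array(sorted(pts))
    return coords


def _skeleton_adjacency(coords: np.ndarray) -> list[list[int]]:
    index = {tuple(c): k for k, c in enumerate(coords)}
    adj: list[list[int]] = []
    for r, c in coords:
        nbrs = [
            index[(r + dr, c + dc)]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in index
        ]
        adj.append(sorted(nbrs))
    return adj


def _geodesic_bumps(
    coords: np.ndarray,
    adjacency: list[list[int]],
    n_patterns: int,
    rng: np.random.Generator,
    length_scale: float = 25.0,
) -> np.ndarray:
    """Smooth spatial bumps: Gaussians of the geodesic (along-skeleton)
    distance from random center pixels, progressively finer with rank."""
    P = len(coords)
    rows, cols, w = [], [], []
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            w.append(float(np.linalg.norm(coords[i] - coords[j])))
    graph = csr_matrix((w, (rows, cols)), shape=(P, P))
    centers = rng.choice(P, size=n_patterns, replace=n_patterns > P)
    dists = dijkstra(graph, indices=centers)
    scales = length_scale / (1.0 + 0.05 * np.arange(n_patterns))
    return np.exp(-(dists**2) / (2 * scales[:, None] ** 2)).T  # (P, K)


def _gram_schmidt(raw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sequential orthonormalization in fixed column order."""
    P, K = raw.shape
    Q = np.zeros_like(raw)
    for k in range(K):
        v = raw[:, k].copy()
        v -= Q[:, :k] @ (Q[:, :k].T @ v)
        nrm = np.linalg.norm(v)
        if nrm < 1e-10:  # degenerate bump; replace with seeded random direction
            v = rng.normal(size=P)
            v -= Q[:, :k] @ (Q[:, :k].T @ v)
            nrm = np.linalg.norm(v)
        Q[:, k] = v / nrm
    return Q


def synth_network_dataset(
    graph: nx.Graph | None = None,
    n_patterns: int = 3,
    amplitudes: np.ndarray | None = None,
    periods: np.ndarray | None = None,
    schedule: list[dict] | None = None,
    n_frames: int = 600,
    dt: float = DEFAULT_DT,
    noise_sigma: float | None = None,
    snr: float | None = None,
    amplitude_decay: float = 0.0,
    n_pixels: int | None = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, SkeletonMap, SyntheticTruth]:
    """Skeleton-pixel intensity dynamics from imposed orthonormal patterns.

    Each of ``n_patterns`` smooth patterns oscillates sinusoidally with its
    own period and amplitude; ``schedule`` entries
    ``{"start": f0, "stop": f1, "modes": [...], "gains": [...]}`` modulate
    pattern activity per frame window (default: all active throughout).
    ``amplitude_decay`` > 0 scales amplitudes by rank^(-decay) — with many
    patterns this yields a continuous eigenvalue spectrum. Noise is i.i.d.
    Gaussian per pixel per frame; ``snr`` sets it relative to the signal's
    RMS. The returned matrix is exactly per-pixel centered (detrended stage).
    """
    rng = np.random.default_rng(seed)
    if graph is None:
        graph = _default_network_graph()
    coords = _rasterize_graph(graph)
    adjacency = _skeleton_adjacency(coords)
    bumps = _geodesic_bumps(coords, adjacency, n_patterns, rng)
    if n_pixels is not None and n_pixels < len(coords):
        # deterministic evenly-spaced subsample of the lexsorted raster
        keep = np.linspace(0, len(coords) - 1, n_pixels).round().astype(int)
        coords = coords[keep]
        bumps = bumps[keep]
        adjacency = _skeleton_adjacency(coords)
    P = len(coords)
    if n_patterns > P // 4:
        raise ParameterError(f"too many patterns ({n_patterns}) for {P} pixels")
    patterns = _gram_schmidt(bumps, rng)

    if amplitudes is None:
        amplitudes = np.ones(n_patterns)
        if amplitude_decay > 0:
            amplitudes = (np.arange(1, n_patterns + 1)) ** (-amplitude_decay)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if periods is None:
        if n_patterns <= 10:
            periods = DEFAULT_PERIOD * (1.0 + 0.18 * np.arange(n_patterns))
        else:
            periods = np.exp(rng.uniform(np.log(30.0), np.log(300.0), n_patterns))
    periods = np.asarray(periods, dtype=float)
    phases = rng.uniform(0, 2 * np.pi, n_patterns)

    t = np.arange(n_frames) * dt
    gains = np.ones((n_patterns, n_frames))
    if schedule:
        gains[:] = 0.0
        for entry in schedule:
            sl = slice(int(entry["start"]), int(entry["stop"]))
            g = entry.get("gains", [1.0] * len(entry["modes"]))
            for m, gm in zip(entry["modes"], g):
                gains[m, sl] = gm
    coeffs = (
        gains * amplitudes[:, None] * np.cos(2 * np.pi * t[None, :] / periods[:, None] + phases[:, None])
    )
    signal = patterns @ coeffs
    if snr is not None:
        noise_sigma = float(np.sqrt(np.mean(signal**2)) / snr)
    noise_sigma = noise_sigma or 0.0
    values = signal + rng.normal(0, noise_sigma, signal.shape)
    values = values - values.mean(axis=1, keepdims=True)
    mat = IntensityMatrix(values=values, dt=dt, stage="detrended")
    skel = SkeletonMap(pixels=coords, adjacency=adjacency)
    truth = SyntheticTruth(
        modes=patterns,
        coefficients=coeffs,
        noise_sigma=noise_sigma,
        seed=seed,
        epochs=list(schedule or []),
        extras={"periods": periods, "amplitudes": amplitudes, "phases": phases},
    )
    return mat, skel, truth


def synth_frames(
    thickness: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int],
    dt: float = DEFAULT_DT,
    tube_width: float = 6.0,
    background: float = 40000.0,
    contrast: float = 8000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> FrameStack:
    """Render a bright-field-like image stack from per-pixel thickness series.

    Tubes are drawn as bands of half-width ``tube_width/2`` around the
    skeleton (anti-aliased edge, one-pixel roll-off); pixel darkness under
    the band encodes the local relative thickness, so thicker tubes are
    darker, as in bright field. ``thickness`` is (P, T) with ``coords`` the
    (P, 2) skeleton pixels. Optionally writes a uint16 multi-page TIFF.
    """
    thickness = np.atleast_2d(np.asarray(thickness, dtype=float))
    coords = np.asarray(coords, dtype=int)
    H, W = shape
    if (
        coords[:, 0].min() < tube_width
        or coords[:, 1].min() < tube_width
        or coords[:, 0].max() >= H - tube_width
        or coords[:, 1].max() >= W - tube_width
    ):
        raise ParameterError("tube exits the frame (margin smaller than tube width)")
    skel_img = np.zeros(shape, dtype=bool)
    skel_img[coords[:, 0], coords[:, 1]] = True
    dist, (ir, ic) = ndimage.distance_transform_edt(~skel_img, return_indices=True)
    pix_index = -np.ones(shape, dtype=int)
    pix_index[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    nearest = pix_index[ir, ic]  # (H, W) index of nearest skeleton pixel
    edge = np.clip(tube_width / 2 + 0.5 - dist, 0.0, 1.0)  # anti-aliased band

    rel = thickness / thickness.mean()
    T = thickness.shape[1]
    rng = np.random.default_rng(seed)
    frames = np.empty((T, H, W), dtype=float)
    for t_i in range(T):
        depth = rel[nearest, t_i] * edge
        img = background - contrast * depth
        if noise_sigma > 0:
            img = img + rng.normal(0, noise_sigma, img.shape)
        frames[t_i] = img
    stack_u16 = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    if out_path is not None:
        tifffile.imwrite(Path(out_path), stack_u16, photometric="minisblack")
    return FrameStack(frames=stack_u16.astype(float), dt=dt)


# ---------------------------------------------------------------------------
# Named presets covering the study regimes

def preset(name: str, seed: int = 0):
    """Build a named synthetic dataset.

    Tube presets return ``(TubeKymograph, SyntheticTruth)``; network presets
    return ``(IntensityMatrix, SkeletonMap, SyntheticTruth)``.
    """
    omega = 2 * np.pi / DEFAULT_PERIOD
    if name == "tube-standing":
        return synth_tube_kymograph(
            waves=[WaveSpec(kind="standing", k=1, omega=omega, amplitude=0.05)],
            seed=seed,
        )
    if name == "tube-traveling":
        return synth_tube_kymograph(
            waves=[WaveSpec(kind="traveling", k=1, omega=omega, amplitude=0.05, direction=1)],
            seed=seed,
        )
    if name == "tube-alternating":
        return synth_tube_epochs(seed=seed)
    if name == "network-k3":
        return synth_network_dataset(
            n_patterns=3,
            amplitudes=np.array([1.0, 0.9, 0.8]),
            snr=5.0,
            n_pixels=400,
            seed=seed,
        )
    if name == "network-continuous":
        return synth_network_dataset(
            graph=_default_network_graph(spacing=40, n_rows=5, n_cols=5),
            n_patterns=200,
            amplitude_decay=0.5,
            n_frames=800,
            snr=30.0,
            seed=seed,
        )
    raise ParameterError(f"unknown preset {name!r}")
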