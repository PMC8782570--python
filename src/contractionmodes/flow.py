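"""Peristaltic flow computation in a single contracting tube.

In the lubrication (long-wavelength, low-Reynolds) limit, flow through a
tube of circular cross-section A(x, t) is Poiseuille,

    Q = -(A^2 / (8 pi mu)) dp/dx,

and incompressibility couples it to the contraction kinematics through
mass conservation, dA/dt + dQ/dx = 0. Eliminating Q gives a two-point
boundary-value problem for the pressure at each instant:

    d/dx [ (A^2 / (8 pi mu)) dp/dx ] = dA/dt,   p(0) = p(L) = p0,

with both tube ends open at equal pressure. A traveling contraction wave
pumps net fluid in its propagation direction (at second order in the wave
amplitude), while a standing wave only sloshes fluid back and forth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.signal import hilbert

from .containers import (
    AlignmentError,
    AmplitudeField,
    DataError,
    FlowField,
    ModeBasis,
    ParameterError,
    SignificanceSeries,
    TubeKymograph,
)


def area_from_intensity(
    tube_values: np.ndarray,
    x: np.ndarray | None = None,
    dt: float = 3.0,
    calibration: str = "thickness",
) -> TubeKymograph:
    """Convert an axis-ordered intensity kymograph to cross-sectional area.

    Bright-field intensity (after polarity correction) proxies the local
    tube diameter, so the default "thickness" calibration takes A
    proportional to I^2; "linear" takes A proportional to I. The
    proportionality constant is normalized so the temporal mean of the
    spatial-mean area is 1, making downstream flow rates dimensionless.
    """
    I = np.asarray(tube_values, dtype=float)
    if np.any(I <= 0):
        raise DataError("calibration requires positive intensities")
    if calibration == "thickness":
        A = I**2
    elif calibration == "linear":
        A = I.copy()
    else:
        raise ParameterError(f"unknown calibration {calibration!r}")
    A = A / A.mean(axis=0).mean()
    if x is None:
        x = np.arange(I.shape[0], dtype=float)
    return TubeKymograph(A=A, x=x, dt=dt)


def _binomial_smooth_time(F: np.ndarray) -> np.ndarray:
    """3-point binomial filter [1, 2, 1]/4 along time, ends untouched."""
    out = F.copy()
    out[:, 1:-1] = 0.25 * F[:, :-2] + 0.5 * F[:, 1:-1] + 0.25 * F[:, 2:]
    return out


def _time_derivative(A: np.ndarray, dt: float, smooth: bool = True) -> np.ndarray:
    dAdt = np.gradient(A, dt, axis=1)  # centered; one-sided at ends
    if smooth:
        dAdt = _binomial_smooth_time(dAdt)
    return dAdt


def solve_flow(
    kymo: TubeKymograph,
    mu: float = 1.0,
    p_boundary: float = 0.0,
    smooth_dAdt: bool = False,
) -> FlowField:
    """Solve the pressure BVP frame by frame and return Q and p.

    Centered second-order finite differences on the uniform x grid; the
    conductivity k = A^2/(8 pi mu) is evaluated at cell faces as the mean
    of adjacent nodes and the resulting tridiagonal system is solved
    directly per frame. The temporal derivative of A uses centered
    differences (one-sided at the first/last frame); ``smooth_dAdt``
    optionally applies a 3-frame binomial filter first, useful on noisy
    measured kymographs but off by default to keep the discrete mass
    balance second-order accurate.
    """
    if kymo.n_x < 5:
        raise ParameterError("need at least 5 axial grid points")
    if kymo.n_frames < 3:
        raise ParameterError("need at least 3 frames")
    if mu <= 0:
        raise ParameterError("viscosity must be positive")
    A = kymo.A
    n, T = A.shape
    dx = kymo.dx
    k = A**2 / (8 * np.pi * mu)
    if np.any(k <= 0) or not np.all(np.isfinite(k)):
        t_bad = int(np.argwhere(~((k > 0) & np.isfinite(k)))[0][1])
        raise DataError(f"singular conductivity (A -> 0) at time index {t_bad}")
    source = _time_derivative(A, kymo.dt, smooth=smooth_dAdt)

    p = np.full((n, T), float(p_boundary))
    k_face = 0.5 * (k[:-1] + k[1:])  # (n-1, T) at faces i+1/2
    for t in range(T):
        kf = k_face[:, t]
        # interior unknowns i = 1..n-2
        lower = kf[1:-1]                  # couples p_{i-1}, i = 2..n-2
        diag = -(kf[:-1] + kf[1:])        # i = 1..n-2
        upper = kf[1:-1]                  # couples p_{i+1}, i = 1..n-3
        rhs = source[1:-1, t] * dx**2
        rhs[0] -= kf[0] * p_boundary
        rhs[-1] -= kf[-1] * p_boundary
        ab = np.zeros((3, n - 2))
        ab[0, 1:] = upper
        ab[1] = diag
        ab[2, :-1] = lower
        p[1:-1, t] = solve_banded((1, 1), ab, rhs)

    # flow from the conservative face fluxes: interior nodes average the two
    # adjacent faces; end nodes extrapolate half a cell using dQ/dx = -dA/dt
    Q_face = -k_face * (p[1:] - p[:-1]) / dx  # (n-1, T)
    Q = np.empty_like(p)
    Q[1:-1] = 0.5 * (Q_face[:-1] + Q_face[1:])
    Q[0] = Q_face[0] + 0.5 * dx * source[0]
    Q[-1] = Q_face[-1] - 0.5 * dx * source[-1]
    return FlowField(Q=Q, p_field=p, x=kymo.x, dt=kymo.dt, viscosity=mu)


def mass_conservation_residual(kymo: TubeKymograph, field: FlowField) -> float:
    """Max |dA/dt + dQ/dx| over interior grid points and frames."""
    dAdt = np.gradient(kymo.A, kymo.dt, axis=1)
    dQdx = np.gradient(field.Q, kymo.dx, axis=0)
    resid = dAdt + dQdx
    return float(np.abs(resid[1:-1, 1:-1]).max())


def end_flow_rates(field: FlowField, window: int) -> pd.DataFrame:
    """Per-window maximum |Q| at both tube ends (non-overlapping windows)."""
    if window < 2:
        raise ParameterError("window must be >= 2 frames")
    T = field.Q.shape[1]
    rows = []
    for w, start in enumerate(range(0, T - window + 1, window)):
        seg = field.Q[:, start : start + window]
        rows.append(
            {
                "window": w,
                "t_start": start,
                "t_end": start + window - 1,
                "maxQ_left": float(np.abs(seg[0]).max()),
                "maxQ_right": float(np.abs(seg[-1]).max()),
            }
        )
    return pd.DataFrame(rows)


def _phase_lag_deg(a1: np.ndarray, a2: np.ndarray) -> float:
    """Mean phase of a1 relative to a2 via analytic signals, in degrees."""
    z1 = hilbert(a1 - a1.mean())
    z2 = hilbert(a2 - a2.mean())
    dphi = np.angle(np.sum(z1 * np.conj(z2)))
    return float(np.degrees(dphi))


def _propagation_direction(
    basis: ModeBasis, modes: tuple[int, int], start: int, stop: int
) -> int:
    """Direction of the reconstructed two-mode wave via neighbor cross-correlation.

    Reconstructs I(x, t) from the two modes over the window and finds the
    time lag that maximizes correlation between the series at two interior
    axial positions; a positive lag at larger x means the pattern arrives
    there later, i.e. travels toward increasing x.
    """
    i, j = modes
    seg = (
        basis.modes[:, [i, j]] @ basis.coefficients[[i, j], start:stop]
    )  # (P, W)
    n = seg.shape[0]
    x0, x1 = n // 3, 2 * n // 3
    a = seg[x0] - seg[x0].mean()
    b = seg[x1] - seg[x1].mean()
    corr = np.correlate(b, a, mode="full")
    lag = int(np.argmax(corr)) - (len(a) - 1)
    return 1 if lag > 0 else (-1 if lag < 0 else 0)


def wave_classification(
    basis: ModeBasis,
    field: AmplitudeField,
    window: int,
    standing_ratio: float = 3.0,
) -> pd.DataFrame:
    """Classify each window as standing / traveling(+x|-x) / mixed.

    Uses the two top-ranked modes: a window is *standing* when one mode's
    mean relative amplitude exceeds the other's by ``standing_ratio`` (one
    dominant spatial pattern oscillating in place) or when two comparable
    modes oscillate in phase (their superposition is a phase-shifted
    standing wave); it is *traveling* when the two amplitudes are within a
    factor 2 of each other and the coefficients run in quadrature (phase
    lag within 90 +/- 30 degrees), a sine/cosine pair composing a
    propagating wave whose direction comes from the reconstruction's
    neighbor cross-correlation.
    """
    if basis.n_modes < 2:
        raise ParameterError("need at least 2 modes to classify waves")
    if window < 2:
        raise ParameterError("window must be >= 2 frames")
    T = field.p.shape[1]
    rows = []
    for w, start in enumerate(range(0, T - window + 1, window)):
        stop = start + window
        p1 = float(field.p[0, start:stop].mean())
        p2 = float(field.p[1, start:stop].mean())
        ratio = p1 / max(p2, 1e-300)
        lag = _phase_lag_deg(
            basis.coefficients[0, start:stop], basis.coefficients[1, start:stop]
        )
        if ratio >= standing_ratio or ratio <= 1.0 / standing_ratio:
            label = "standing"
            direction = 0
        elif 0.5 <= ratio <= 2.0 and 60.0 <= abs(lag) <= 120.0:
            direction = _propagation_direction(basis, (0, 1), start, stop)
            label = f"traveling({'+x' if direction > 0 else '-x'})" if direction else "mixed"
        elif 0.5 <= ratio <= 2.0 and abs(lag) <= 30.0:
            label = "standing"  # in-phase superposition is still separable
            direction = 0
        else:
            label = "mixed"
            direction = 0
        rows.append(
            {
                "window": w,
                "t_start": start,
                "t_end": stop - 1,
                "label": label,
                "direction": direction,
                "amplitude_ratio": ratio,
                "phase_lag_deg": lag,
            }
        )
    return pd.DataFrame(rows)


def flow_vs_significance(
    flows: pd.DataFrame,
    series: SignificanceSeries,
    end: str = "left",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair per-window max end flow with the significant-mode count.

    ``n_sig`` is taken at each window's center frame. Returns the paired
    records and the upper envelope (max flow per observed n_sig), which
    expresses the observation that high flow rates only occur when few
    modes are significant as a decreasing-envelope property.
    """
    if end not in ("left", "right"):
        raise ParameterError("end must be 'left' or 'right'")
    if len(flows) == 0:
        raise AlignmentError("no flow windows")
    T = len(series.n_sig)
    col = f"maxQ_{end}"
    records = []
    for _, row in flows.iterrows():
        center = int((row["t_start"] + row["t_end"]) // 2)
        if center >= T:
            raise AlignmentError(
                f"flow window centered at frame {center} outside significance series (T={T})"
            )
        records.append(
            {
                "window": int(row["window"]),
                "max_flow": float(row[col]),
                "n_sig": int(series.n_sig[center]),
            }
        )
    pairs = pd.DataFrame(records)
    envelope = (
        pairs.groupby("n_sig")["max_flow"].max().reset_index().rename(
            columns={"max_flow": "max_flow_envelope"}
        )
    )
    return pairs, envelope
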