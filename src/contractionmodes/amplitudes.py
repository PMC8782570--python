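"""Amplitude statistics over the mode spectrum.

A mode's instantaneous activity is measured by the squared envelope of its
oscillatory coefficient; the relative amplitude

    p_mu(t) = env_sq_mu(t) / sum_nu env_sq_nu(t)

is its share of the total activity and sums to one over modes at every
time. Significant modes at a time point are the smallest set whose relative
amplitudes cumulatively reach a cutoff (70% or 90% in practice); tracking
that count over time distinguishes regular few-mode contraction states from
irregular many-mode states.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert
from scipy.stats import pearsonr

from .containers import (
    AmplitudeField,
    CorrelationHistogram,
    DataError,
    DominanceInterval,
    ParameterError,
    SignificanceSeries,
)


def _moving_average(a: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average along the last axis with reflect padding."""
    if win <= 1:
        return a
    pad = win // 2
    padded = np.pad(a, [(0, 0)] * (a.ndim - 1) + [(pad, pad)], mode="reflect")
    kernel = np.ones(win) / win
    out = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), -1, padded)
    return out[..., pad : pad + a.shape[-1]]


def coefficient_envelope(
    coefficients: np.ndarray,
    dt: float,
    window: float = 100.0,
    method: str = "hilbert",
) -> np.ndarray:
    """Squared amplitude envelope of each mode coefficient.

    ``method="hilbert"`` (default) takes the squared magnitude of the
    analytic signal of the mean-removed coefficient; ``method="rms"`` uses
    twice the windowed mean of the squared coefficient (both coincide for
    narrowband signals). The result is smoothed by a centered moving
    average of length ``window`` seconds.
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    win = int(round(window / dt))
    if win < 2:
        raise ParameterError("envelope window must span at least 2 frames")
    centered = coefficients - coefficients.mean(axis=1, keepdims=True)
    if method == "hilbert":
        env_sq = np.abs(hilbert(centered, axis=1)) ** 2
        env_sq = _moving_average(env_sq, win)
    elif method == "rms":
        env_sq = 2.0 * _moving_average(centered**2, win)
    else:
        raise ParameterError(f"unknown envelope method {method!r}")
    return np.maximum(env_sq, 0.0)


def relative_amplitudes(
    envelope_sq: np.ndarray, smoothing_window: float = 100.0
) -> AmplitudeField:
    """Columnwise-normalized relative amplitudes p_mu(t)."""
    envelope_sq = np.atleast_2d(np.asarray(envelope_sq, dtype=float))
    totals = envelope_sq.sum(axis=0)
    bad = np.nonzero(totals <= 0)[0]
    if len(bad):
        raise DataError(f"all-zero envelope column at t={int(bad[0])}")
    p = envelope_sq / totals
    return AmplitudeField(envelope_sq=envelope_sq, p=p, smoothing_window=smoothing_window)


def significant_mode_count(field: AmplitudeField, cutoff: float) -> SignificanceSeries:
    """Smallest number of modes whose sorted relative amplitudes reach ``cutoff``.

    Modes are ordered by relative amplitude, largest first (ties broken by
    lower mode rank, which is what a stable descending sort gives).
    """
    if not 0 < cutoff < 1:
        raise ParameterError("cutoff must be in (0, 1)")
    # stable sort on -p keeps lower mode index first among ties
    order = np.argsort(-field.p, axis=0, kind="stable")
    sorted_p = np.take_along_axis(field.p, order, axis=0)
    csum = np.cumsum(sorted_p, axis=0)
    # first k (1-based) with cumulative sum >= cutoff; guard roundoff at 1.0
    reached = csum >= min(cutoff, 1.0) - 1e-12
    n_sig = reached.argmax(axis=0) + 1
    return SignificanceSeries(cutoff=cutoff, n_sig=n_sig, n_modes=field.n_modes)


def summarize_significance(series: SignificanceSeries) -> dict:
    """Mean count, mean percent of modes, and relative std (population)."""
    n = np.asarray(series.n_sig, dtype=float)
    if len(n) < 2:
        raise ParameterError("need at least 2 time points")
    mean = float(n.mean())
    return {
        "mean_count": mean,
        "mean_percent": mean / series.n_modes * 100.0,
        "relative_std_percent": float(n.std() / mean * 100.0),
    }


def dominance_intervals(
    field: AmplitudeField,
    min_duration: int = 30,
    excess_threshold: float = 0.2,
) -> list[DominanceInterval]:
    """Maximal runs during which a single mode stays the most active.

    Runs shorter than ``min_duration`` frames are dropped; runs whose mean
    excess of the leading over the runner-up amplitude falls below
    ``excess_threshold`` are kept but flagged.
    """
    if min_duration < 1:
        raise ParameterError("min_duration must be >= 1")
    p = field.p
    if p.shape[0] < 2:
        raise ParameterError("need at least 2 modes")
    argmax = p.argmax(axis=0)
    part = np.partition(p, -2, axis=0)
    pmax, prunner = part[-1], part[-2]
    intervals: list[DominanceInterval] = []
    start = 0
    T = p.shape[1]
    for t in range(1, T + 1):
        if t == T or argmax[t] != argmax[start]:
            if t - start >= min_duration:
                with np.errstate(divide="ignore"):
                    excess = np.mean(
                        (pmax[start:t] - prunner[start:t])
                        / np.maximum(prunner[start:t], 1e-300)
                    )
                intervals.append(
                    DominanceInterval(
                        mode=int(argmax[start]),
                        t_start=start,
                        t_end=t - 1,
                        excess_ratio=float(excess),
                        above_threshold=bool(excess >= excess_threshold),
                    )
                )
            start = t
    return intervals


def dominant_period(coefficient: np.ndarray, dt: float) -> float:
    """Period (seconds) of the dominant spectral peak of a coefficient series.

    The mean-removed series' periodogram peak is refined by quadratic
    interpolation over log-power at the three bins around the maximum.
    """
    a = np.asarray(coefficient, dtype=float)
    a = a - a.mean()
    if np.allclose(a, 0):
        raise DataError("flat series: no oscillation to estimate a period from")
    power = np.abs(np.fft.rfft(a)) ** 2
    freqs = np.fft.rfftfreq(len(a), d=dt)
    k = int(np.argmax(power[1:]) + 1)  # skip DC
    if 1 <= k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        lp = np.log(power[k - 1 : k + 2])
        denom = lp[0] - 2 * lp[1] + lp[2]
        delta = 0.5 * (lp[0] - lp[2]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_peak = (k + delta) * freqs[1]
    return float(1.0 / f_peak)


def correlation_distribution(
    coefficients: np.ndarray,
    series: SignificanceSeries,
    field: AmplitudeField,
    window: int = 66,
    stride: int | None = None,
    n_corr_bins: int = 41,
    nsig_edges: np.ndarray | None = None,
) -> CorrelationHistogram:
    """Distribution of pairwise coefficient correlations vs n_sig.

    Sliding windows (default stride = window/2) contribute, for the set of
    modes significant at the window's center time, the Pearson correlation
    of every unordered pair of their coefficient series within the window.
    Pairs with a zero-variance series in the window are skipped and counted.
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    if window < 8:
        raise ParameterError("window must be >= 8 frames")
    stride = stride or max(window // 2, 1)
    T = coefficients.shape[1]
    if series.n_sig.shape[0] != T:
        raise ParameterError("significance series and coefficients disagree in length")

    corr_vals: list[float] = []
    nsig_vals: list[int] = []
    n_skipped = 0
    for start in range(0, T - window + 1, stride):
        center = start + window // 2
        nsig = int(series.n_sig[center])
        # significant-mode set at the center time: top-nsig by relative amplitude
        order = np.argsort(-field.p[:, center], kind="stable")[:nsig]
        seg = coefficients[:, start : start + window]
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                a, b = seg[order[i]], seg[order[j]]
                if a.std() == 0 or b.std() == 0:
                    n_skipped += 1
                    continue
                r = pearsonr(a, b).statistic
                corr_vals.append(float(r))
                nsig_vals.append(nsig)
    corr_edges = np.linspace(-1, 1, n_corr_bins + 1)
    if nsig_edges is None:
        if nsig_vals:
            lo, hi = min(nsig_vals), max(nsig_vals) + 1
            nsig_edges = np.linspace(lo, hi, min(10, hi - lo) + 1)
        else:
            nsig_edges = np.array([0.0, 1.0])
    counts, _, _ = np.histogram2d(
        corr_vals, nsig_vals, bins=[corr_edges, np.asarray(nsig_edges, dtype=float)]
    )
    return CorrelationHistogram(
        corr_edges=corr_edges,
        nsig_edges=np.asarray(nsig_edges, dtype=float),
        counts=counts,
        window_length=window,
        n_skipped=n_skipped,
    )
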