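# Methods

This note documents the models, numerical choices, and defaults behind
`contractionmodes`, and what the synthetic generators do and do not emulate.

## Data model and ingestion

A recording is a grayscale stack of T frames at fixed interval `dt`
(default 3 s, the sampling of the recordings this analysis targets). The
organism is assumed morphologically stable over an analysis segment, so a
single reference skeleton is computed from the pixelwise temporal-median
mask and reused for every frame; tracking a moving skeleton is out of scope.

Segmentation is Gaussian smoothing (radius 2 px) followed by an Otsu
threshold per frame, keeping the largest connected component and filling
holes below 64 px². Otsu makes the mask invariant under positive affine
intensity rescaling. The foreground polarity defaults to whichever side of
the threshold covers the minority of the frame, since the organism occupies
a minority of the field of view.

Intensity sampling averages each frame over a disk (default radius 2 px,
enough to absorb skeletonization jitter without mixing neighbouring tubes)
centred on each skeleton pixel, restricted to the organism mask. In bright
field, thicker tubes transmit less light; the stored value is
`max_intensity − recorded` so that larger values mean a more dilated tube.
Whether raw transmitted intensity or a calibrated thickness proxy better
represents the contraction state is an open calibration question; intensity
(after polarity flip) is used as the proxy throughout.

Detrending subtracts the projection of each pixel series onto temporal
frequencies below `1/trend_window` (default window 1000 s, about ten
contraction periods), implemented as a DCT low-pass so boundaries are
handled by even reflection. A projection was chosen over the more common
moving-average trend because it is exactly idempotent — applying the
detrender twice changes nothing — which the downstream contracts rely on.
The residual is then exactly mean-centred per pixel. Optional per-pixel
variance normalization exists but is off by default.

## Mode decomposition

The decomposition is PCA of the detrended pixel × time matrix: modes are
eigenvectors of the temporal covariance (divisor T−1), coefficients are
projections of the centred snapshots. When pixels outnumber frames the
eigenproblem is solved through the T × T Gram ("snapshot") matrix, which
shares the nonzero eigenvalues; both routes are implemented and
cross-checked in the tests rather than trusting either alone.

PCA signs are arbitrary, so each mode is flipped to make its
largest-magnitude component positive (ties broken by lowest pixel index),
making repeated runs bit-identical. Among numerically degenerate
eigenvalues the ordering follows the eigensolver's deterministic output;
tests on degenerate pairs assert subspaces, never individual vectors.
Eigenvalues below `1e-12` of the largest are treated as numerical zeros and
dropped from the returned basis.

The ranked spectrum is reported as percentages `λ_μ/Σλ × 100`. The noise
cutoff is estimated from shuffled data: each shuffle independently permutes
every pixel's time series, destroying temporal structure and cross-pixel
alignment while preserving each pixel's marginal distribution (and hence
total variance). Among the randomization schemes compatible with a bare
"randomised data" description (global entry shuffle, phase randomization),
per-pixel permutation is the standard marginal-preserving choice. The
cutoff is the largest null eigenvalue averaged over shuffles (default 10;
smaller counts are used in fast pipelines since the largest null eigenvalue
concentrates tightly).

## Amplitude statistics

A mode's instantaneous activity is the squared envelope of its mean-removed
coefficient, computed from the analytic signal (Hilbert transform) and
smoothed by a centred moving average over one contraction period
(default 100 s). A sliding-RMS estimator (twice the windowed mean of the
squared coefficient) is available behind a flag; the two coincide for
narrowband signals. Relative amplitudes are the columnwise normalization of
these envelopes and sum to one at every time point by construction — this
is asserted on every pipeline run.

The significant-mode count at time t is the smallest k such that the k
largest relative amplitudes sum to at least the cutoff (0.7 and 0.9 by
default); ties resolve toward lower mode rank via a stable sort. The
summary statistic for a count series uses the population standard deviation
(divisor T), as a descriptive statistic of the full series.

Dominance intervals are maximal runs of a constant argmax of p, kept when
at least 30 frames long; the excess ratio is the run-mean of
`(p_max − p_runnerup)/p_runnerup`, and runs below the excess threshold
(default 0.2) are flagged rather than dropped. The dominant period comes
from the periodogram peak of the mean-removed coefficient, refined by
quadratic interpolation of log-power around the maximum.

Correlation distributions use sliding windows of 66 frames (about two
periods at 3 s sampling) with stride 33. For each window, the significant
modes at the window's centre frame (from the 70% cutoff) contribute the
Pearson correlation of every unordered pair of their raw coefficient series
within the window; pairs containing a zero-variance series are skipped and
counted. Correlations bin into 41 uniform bins on [−1, 1]; counts are kept
jointly with the window's significant-mode count.

## Tube flow

For a single tube, cross-sectional area is derived from axis intensity by
`A ∝ I²` by default (intensity proxies diameter, area goes as diameter
squared); a linear calibration is available. Areas are normalized so the
temporal mean of the spatial-mean area is 1, making flow rates
dimensionless — the physical units of the source recordings' flow axis are
not calibrated here.

In the lubrication limit with Poiseuille closure,
`Q = −(πa⁴/8μ)∂x p = −(A²/8πμ)∂x p` for a circular cross-section, and mass
conservation `∂t A + ∂x Q = 0` yields the per-frame two-point boundary
value problem

    ∂x[(A²/8πμ) ∂x p] = ∂t A,   p(0) = p(L) = p₀,

with both ends open at equal pressure, so the net flux feeding the
locomotion fronts emerges from the solve. This boundary condition is the
main modelling commitment; it follows the standard lubrication treatment of
peristaltic tube flow. One consequence worth stating: with equal end
pressures the flow field is exactly independent of the viscosity μ (the
1/μ in the conductivity cancels against the constant fixed by the boundary
condition), while the pressure scales linearly with μ. Tests assert these
exact identities.

Discretization: uniform grid, conductivity evaluated at cell faces as the
mean of adjacent nodes, tridiagonal solve per frame
(`scipy.linalg.solve_banded`). `∂t A` uses centred differences (one-sided
second-order at the first and last frame); an optional 3-frame binomial
pre-smoothing is available for noisy measured kymographs but is off by
default, because the scheme without it keeps the discrete mass balance
`∂t A + ∂x Q` second-order accurate — halving dx and dt shrinks the
residual about fourfold, which the tests verify. Q is reconstructed from
the conservative face fluxes (interior nodes average the two adjacent
faces; end nodes extrapolate half a cell using `∂x Q = −∂t A`), avoiding
the first-order one-sided error a node-centred gradient has at the ends.

Wave classification per window uses the two top-ranked modes: *standing*
when one mode's mean relative amplitude exceeds the other's threefold, or
when two comparable modes oscillate in phase (their superposition is a
phase-shifted standing wave); *traveling* when the amplitudes are within a
factor two and the coefficients' analytic-signal phase lag is within
90° ± 30°, with the propagation direction read off the time lag that
maximizes the cross-correlation of the reconstructed two-mode field at two
interior axial positions; otherwise *mixed*.

End-flow statistics take the maximum |Q| at each end over non-overlapping
windows; pairing with the significant-mode count attributes each window the
count at its centre frame and reports, besides the raw pairs, the upper
envelope of flow per observed count.

## Growth tracking

ROI area is the count of organism-mask pixels inside an axis-aligned box —
the simplest definition consistent with a percentage-area-change readout;
no convex hull or front-specific segmentation. Tracks report
`100·(area(t) − area(t₀))/area(t₀)` and depend only on the mask, never on
raw intensities. Growth slopes within mode-dominance intervals are ordinary
least squares over the full interval.

## Synthetic data

The generators define the conditions under which the chain is verified.

* **Tube kymographs**: `A(x,t) = 1 + Σ waves + trend + noise` on a grid of
  n_x points spanning one wavelength scale L (default L = n_x, so the grid
  tiles a full traveling period exactly and a traveling wave decomposes
  into two modes of exactly equal discrete variance). Standing waves are
  `ε sin(kπx/L)cos(ωt+φ)`, traveling waves `ε sin(2πkx/L − dωt + φ)`;
  defaults ε = 0.05, period 100 s, dt = 3 s. Noise is i.i.d. Gaussian per
  pixel and frame.
* **Alternating-epoch tube**: six 330-frame epochs alternating a single
  traveling wave (ε = 0.12) with 48 incoherent low-amplitude standing
  waves (ε = 0.006 each, random frequencies 0.6–1.6× the base rate).
  Epoch edges carry a two-period cosine taper: a hard switch would inject
  a large spurious ∂t A into the flow solve at the boundary. Epoch length
  is a multiple of the 33-frame analysis window so windows never straddle
  epochs. The irregular-epoch mode count follows from the statistics of
  envelope weights: for K equal incoherent components the decomposition
  mixes the degenerate modes and the instantaneous weights are
  approximately exponential-distributed, so the 90%-cutoff count
  concentrates near 0.55·K — 48 components make counts above 20 a robust
  feature of every run.
* **Networks**: skeleton pixels rasterized along the edges of a planar
  graph; imposed spatial patterns are Gaussians of the geodesic
  (along-skeleton) distance from random centres, progressively finer with
  rank, orthonormalized by sequential Gram–Schmidt in fixed order.
  Coefficients are sinusoids with per-pattern periods and amplitudes,
  optionally gated by an epoch schedule; `amplitude_decay = γ` scales
  amplitudes as rank^(−γ), and with 200 patterns (γ = 0.5) the resulting
  eigenvalue spectrum is continuous, with no dominant gap above the
  shuffled-data cutoff. An `snr` parameter sets the noise level relative
  to the signal RMS.
* **Rendering**: tubes are drawn as fixed-width anti-aliased bands around
  the skeleton with pixel darkness under the band encoding local relative
  thickness (thicker = darker, as in bright field), over a bright
  background, with optional Gaussian noise, quantized to uint16 TIFF.
  Same seed gives byte-identical files.

What the generators do **not** emulate: skeleton motion or growth-induced
morphology change, mechanochemical actomyosin dynamics, uneven
illumination, optical blur beyond the band edge, or depth-dependent
absorption. Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical structure, not robustness to
every artefact of real microscopy.

## Problem sizes

Defaults used by the test suite and the acceptance script: networks of
400–1600 skeleton pixels over 600–800 frames; tubes of 64–128 grid points
over 400–2000 frames; 2–10 shuffles for null spectra. These sizes keep the
full verification chain fast while leaving all qualitative regimes (mode
recovery, degenerate pairs, many-mode states, second-order convergence)
well resolved.

## Known limitations

* The equal-pressure boundary condition is an assumption; a tube feeding
  fronts with differing resistance would need pressure or flux boundary
  data that bright-field recordings do not provide.
* Flow rates are relative (μ = 1, mean area 1); no absolute calibration.
* The envelope estimator assumes coefficients are narrowband on the scale
  of the smoothing window; broadband coefficients bias p toward uniformity.
* Classification uses only the two top-ranked modes; superpositions
  dominated by three or more modes are reported as *mixed*.
* PCA on segments with residual slow trends mixes trend variance into the
  leading modes; the detrend window must stay well above the contraction
  period.
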