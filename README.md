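# contractionmodes

Analysis of rhythmic contraction dynamics in living tubular networks such as
the slime mould *Physarum polycephalum*. The organism's behaviour — cytoplasmic
flow, locomotion, growth — is driven by actomyosin contractions of its tube
walls. This package decomposes time-lapse recordings of those contractions
into spatial modes, quantifies how many modes are active at any moment, and,
for single-tube specimens, computes the peristaltic flow the contractions
pump.

## What it computes

Given a bright-field time-lapse, the organism is segmented, skeletonized, and
each skeleton pixel's intensity (a proxy for local tube dilation) is sampled
over time into a matrix *I(p, t)*. The detrended matrix is decomposed by
principal component analysis:

```
I(t_i) − ⟨I⟩ = Σ_μ a_μ(t_i) φ_μ
```

with orthonormal spatial modes *φ_μ* (eigenvectors of the pixel–pixel
covariance) ranked by eigenvalue *λ_μ*. The package then derives:

* **Relative eigenvalue spectrum** — *λ_μ / Σλ* in percent, with a noise
  cutoff given by the largest eigenvalue of temporally shuffled data.
* **Relative amplitudes** *p_μ(t) = ã²_μ(t) / Σ_ν ã²_ν(t)*, where *ã²_μ* is the
  smoothed squared envelope of the mode coefficient; Σ_μ p_μ(t) = 1.
* **Significant modes** — the smallest set of modes whose relative amplitudes
  cumulatively reach a cutoff (70% or 90%), tracked over time; intervals
  where a single mode dominates; pairwise coefficient correlations versus
  the number of significant modes.
* **Peristaltic flow** — for a single tube with cross-sectional area
  *A(x, t)*, the lubrication-limit pressure problem
  ∂x[(A²/8πμ) ∂x p] = ∂t A with open, equal-pressure ends is solved per frame
  and the volume flow rate *Q = −(A²/8πμ) ∂x p* is returned; windows are
  classified as standing or traveling waves from the top two modes.
* **Growth tracking** — percentage area change of user-defined regions,
  aligned with mode-dominance intervals.

A synthetic-data module generates tube kymographs with standing/traveling
waves, network skeletons with imposed orthonormal modes, and rendered
bright-field TIFF stacks, so the entire chain is verifiable against known
ground truth.

## Worked example

Run the full pipeline on the synthetic traveling-wave tube preset:

```python
from contractionmodes import RunConfig, run_pipeline

report = run_pipeline(RunConfig(preset="tube-traveling", seed=1,
                                n_shuffles=2, flow_window=66))
seg = report["segments"][0]
print(seg["top_relative_eigenvalues_percent"])  # [50.0, 50.0]
print(seg["dominant_period_s"])                 # 99.993
print(seg["flow"]["wave_labels"][:3])           # ['traveling(+x)', 'traveling(+x)', 'traveling(+x)']
print(seg["flow"]["max_abs_Q"])                 # 0.033853
```

A traveling contraction wave decomposes into exactly two modes of equal
variance (a sine/cosine pair, 50% + 50% of the spectrum) whose coefficients
oscillate in quadrature with the imposed ~100 s period; every analysis window
is classified as a wave traveling toward +x, and the solver reports the
(dimensionless) peak flow rate it pumps. The same estimator is available as a
scikit-learn transformer:

```python
from contractionmodes import ContractionModePCA
est = ContractionModePCA().fit(X)        # X: time x pixels
coeffs = est.transform(X)                # a_mu(t)
spectrum = est.explained_variance_ratio_
```

A command-line interface mirrors the stages:
`contractionmodes extract | decompose | stats | simulate | run`.

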