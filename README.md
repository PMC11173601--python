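# gzigpfa

Zero-inflated generalized Poisson factor analysis for high-dimensional
count matrices.

Microbiome OTU tables (and similar sequencing count matrices) are
non-negative integers with three awkward properties at once: many more
taxa than samples, an excess of zeros beyond what any count distribution
explains, and variance far above the mean.  `gzigpfa` reduces such a
matrix to a small number of latent factors while modeling all three
properties explicitly, so that downstream association analysis can work
with a few per-sample scores instead of hundreds of noisy taxon counts.

## Model

For an n × m count matrix Y (samples × taxa) with relative library sizes
T_i (row sum over the median row sum):

```
y_ij ~ phi_ij · δ₀  +  (1 − phi_ij) · GP(T_i λ_ij, α)
log(Λ) = F Lᵀ                 rank K;  F: n×K scores,  L: m×K loadings
logit(phi_ij) = −τ · log(λ_ij)
```

GP(μ, α) is the generalized Poisson distribution with mean μ and variance
μ(1+αμ)² (α = 0 recovers the Poisson), so a single global α captures
over-dispersion.  The structural-zero probability phi is tied to the
latent rate through the shape parameter τ: rare taxa (small λ) are more
likely to drop out, which matches how sequencing zeros arise.

Estimation is alternating maximum likelihood: starting from an SVD of
log((Y+1)/T), the algorithm repeatedly (1) fits the m columns as ZIGP
regressions on the current scores, (2) fits the n rows on the new
loadings — both steps sharing one global (τ, α), fitted by an EM
algorithm over latent structural-zero indicators — and (3) re-identifies
(F, L) by an SVD of F Lᵀ.  The total likelihood is non-decreasing across
steps 1–2 and invariant across step 3.  The rank K is chosen by
entry-wise N-fold cross-validation: individual matrix cells are held
out, the model is fitted on the rest, and the held-out ZIGP likelihood
is summed per candidate rank.

## Worked example

Simulate a rank-3 benchmark dataset at 20% zeros, fit the model, and
compare the recovered log-rate matrix with a log-PCA baseline:

```python
from gzigpfa import ScenarioSpec, generate, GZIGPFA, LogPCA, frobenius_loss

data = generate(ScenarioSpec(scenario=1, zero_target=0.20, seed=7))
print(f"zero fraction: {data.Y.zero_fraction:.3f}, calibrated tau: {data.tau_used:.3f}")

model = GZIGPFA(n_components=3, library_size="ones").fit(data.Y.Y)
print(f"tau_hat={model.tau_:.3f}  alpha_hat={model.alpha_:.3f}  "
      f"iterations={model.n_iter_}  converged={model.converged_}")
print(f"GZIGPFA loss : {frobenius_loss(model.log_rate_, data.logLambda_true):.3f}")

base = LogPCA(n_components=3).fit(data.Y.Y)
print(f"log-PCA loss : {frobenius_loss(base.log_rate_, data.logLambda_true):.3f}")
```

Output:

```
zero fraction: 0.201, calibrated tau: 1.380
tau_hat=1.371  alpha_hat=0.190  iterations=3  converged=True
GZIGPFA loss : 40.818
log-PCA loss : 113.425
```

The generator calibrated the zero-link shape to τ = 1.38 to hit the 20%
zero target, and the fit recovers both global parameters (τ̂ = 1.37,
α̂ = 0.19 against a generating α = 0.2).  The loss is the Frobenius norm
‖log Λ̂ − log Λ‖_F over all 20 000 entries; the ZIGP factor fit recovers
the log-rate matrix with well under half the error of log-PCA (replace
zeros by 0.5, take logs, rank-3 PCA), which has no model for the zeros
it imputes.  `library_size="ones"` tells the fit that the simulated
library sizes are all 1; on real data omit it and the row sums are used.

Estimators follow scikit-learn conventions (`fit`, `transform`,
`fit_transform`, `get_params`); `model.F_` holds the per-sample scores,
`model.components_` the loadings, and `model.predict_zero_proba()` the
entry-wise total zero probability.  Rank selection:

```python
from gzigpfa import cv_select_rank
res = cv_select_rank(data.Y.Y, ranks=range(1, 7), n_folds=10, seed=7,
                     fit_options={"library_size": "ones"})
res.selected_rank   # 3
```

A `gzigpfa` command-line tool wraps the same functionality
(`gzigpfa fit / rank / simulate / bench / zeromap`; see `gzigpfa --help`).

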