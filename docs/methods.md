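# Methods

## Data model and preprocessing

The unit of analysis is one subject's (or one site's) genus × time abundance
table: non-negative read counts aggregated to genus level, one row per
sampled time point. Timestamps may be dates or integer indices; internally
samples are ordered and addressed by step. Irregular spacing is preserved —
a missing sampling day is simply an absent row, and the forecasters treat
the observed points as an ordered sequence. No interpolation, rarefaction or
compositional transform (CLR/ILR) is applied.

Harmonization across subjects re-indexes every table on the union of
observed genera plus optional roster supplements (e.g. baseline gut taxa
lists); a genus absent from one subject is assigned zero abundance
throughout. This zero-fill changes no row sums and keeps the feature axis
identical across tables, which the joint multivariate models require.
Genus matching is exact string match after whitespace trimming; case-variant
collisions are rejected unless lower-case normalization is enabled.
Samples taken on reported-illness days can be excluded before training so
the model learns the healthy baseline.

Abundances are min–max scaled to [0, 1] **per genus**. The scaler is fitted
on the training partition only: fitting on the full series would leak the
test block's range into the detector and silently shrink test-set
excursions. Scaled test values may therefore fall outside [0, 1]; they are
deliberately not clipped. A constant (degenerate) genus — typically one
zero-filled during harmonization — maps to 0.0 and inverts to its constant.
The split is chronological and contiguous: the first 80 % of samples form
the train+validation block (the final 10 % of which is held out for early
stopping, configurable), the last 20 % is the test block. Covariate columns
are min–max scaled with parameters from the same training block.

Supervised framing uses a lag window of 3 (configurable): the input at step
*t* is the 3 preceding rows over all genera plus any covariate columns; the
target is row *t* over all genera. A partition of length *T* yields *T* − 3
windows.

## Forecasters

All backends are **joint multivariate** models — every genus is both input
and output — because cross-genus structure is part of the signal and
feature-importance analysis of genera as inputs requires a joint model.

* **LSTM / GRU** (NumPy implementation): 1–3 recurrent layers, default one
  layer of 2048 cells (tests and the acceptance experiments use 32 cells —
  see *Problem sizes* below), ReLU state activation, inverted dropout 0.2
  on each layer's output (per-sample mask shared across the 3 time steps),
  linear dense head over genus outputs only, Adam (lr 10⁻³) on an MAE loss,
  early stopping with patience 10 on validation MAE with best-weight
  restore, global gradient-norm clipping at 1.0 (ReLU recurrent dynamics
  can otherwise blow up). Backpropagation through time is exact over the
  short lag window; unit tests pin every gate's gradient against central
  finite differences at 10⁻⁴ relative error (10⁻³ for ReLU, whose kinks
  finite differences straddle).
* **Random forest**: the lag window is flattened to a 3 × width feature
  vector; a multi-output `RandomForestRegressor` with 100 trees and the
  absolute-error split criterion (matching the MAE training objective of
  the recurrent nets) is fitted on all genus targets jointly. Seeded, hence
  bit-reproducible.
* **VARMA baseline**: each genus column is screened with the augmented
  Dickey–Fuller test at α = 0.05; if any column is non-stationary the whole
  matrix is differenced once (d = 1) and re-screened. (p, q) is selected
  from a grid (default p, q ∈ 0..3) by AIC, ties broken toward smaller
  p + q; the fit includes a deterministic trend (default constant + linear
  time). Forecasts are integrated back to levels. Near-constant columns are
  excluded by a variance filter and forecast as their mean; a univariate
  matrix degenerates to an ARMA state-space fit. The selection criterion
  (AIC) and the tie rule are package choices — order selection was the one
  genuinely open design point in this pipeline, and AIC is the conventional
  default for state-space grids.

Two prediction modes exist. **Teacher-forced** (default for detection):
every lag window contains observed rows, so the prediction at *t* is
one-step-ahead conditioned on the true recent past — the right conditioning
for asking whether an observation is surprising. **Iterative**: predictions
are fed back into the window, for multi-step trajectory plots; with
covariates configured, future covariate values must be supplied.

## Ensemble interval and outlier rule

*N* = 50 models (10 in the forest experiments) of identical architecture are
trained, differing only in seed (initialization, dropout and shuffling for
the nets; bootstrap draws for the forest). Per genus and time point the
member predictions give a mean and a sample standard deviation (ddof = 1);
the 95 % interval is mean ± z·sd with z the exact normal quantile
(1.959964…; hand-check examples use 1.96). Intervals are computed in scaled
space and back-transformed per genus — the min–max inverse is affine and
monotone, so this equals computing them on the absolute scale (asserted as
a property test). An observation strictly outside its interval is flagged
with direction and exceedance; boundary-equal values are not outliers.
No multiple-testing correction is applied across genus × time cells.

**Coverage caveat.** The interval quantifies *inter-model* spread only; no
observation-noise term is added. For ensembles whose members disagree as
much as the data scatter (independently initialized neural networks), the
flag rate on quiet data approaches the nominal 5 %. For a seed-only forest
ensemble it does not: averaging 100 trees removes most bootstrap
variability, member predictions nearly coincide, and the interval is far
narrower than the one-step innovation noise. Measured on the low-noise
detection scenario, a 10-member forest ensemble flags 46–79 % of quiet
cells (narrowing as noise shrinks) while recovering every 5 σ spike. The
construction is kept as specified and documented rather than patched with a
residual-variance term; users who need calibrated false-flag rates on quiet
data should use the recurrent ensemble or treat forest flags as a ranked
sensitivity signal. Degenerate genera collapse the interval to a point, so
any test-set deviation flags — intentionally sensitive for taxa absent
during training.

## Evaluation

MAE and RMSE are pooled over all (time, genus) cells per split, computed on
the absolute scale after back-transform (a scaled-space mode exists for
debugging). NRMSE divides RMSE by the standard deviation of the *predicted*
values (ddof 1) — an unusual but deliberate convention that makes errors
comparable across genera of very different abundance; constant predictions
yield an explicit not-defined sentinel (NaN), never infinity. The overfit
diagnostic flags a fit when test/train MAE or RMSE exceeds 3.0 (the
threshold is configurable; a stricter 2.0 convention also circulates and
both are representable).

## Correlation networks and importance

All genus pairs are tested with Spearman (default), Pearson or Kendall
correlation; p-values are Benjamini–Hochberg corrected; an edge is retained
iff |ρ| ≥ 0.6 **and** q ≤ 0.05 (the FDR criterion is standard practice on
top of the magnitude convention and can be disabled). Genera with no
retained edge leave the node set; constant genera are excluded from testing.
Hubs are ranked by degree and by summed |ρ| (ties broken by name). Model
feature importance is computed natively by permutation — per genus, jointly
permuting its lag columns across windows and averaging the MAE inflation
over 5 seeded repeats — or supplied externally as a genus → score file
(e.g. Shapley values; their signs are preserved for reporting, ranking uses
magnitude). Top-k hub and importance sets are compared by overlap and
Jaccard index. SparCC and module detection are out of scope.

## Synthetic communities

The generator emulates what the detector assumes about real feature tables.
Per genus, a latent seasonal-AR process

x_t = baseline + amplitude·sin(2π t / period + phase) + d_t,  d_t = φ·d_{t−1} + ε_t

with ε_t ~ N(0, noise_sd²), is rounded to non-negative integer counts
(optional Poisson-like dispersion jitter and zero-inflation masking).
Rounding a Gaussian latent rather than drawing negative-binomial counts
keeps event magnitudes interpretable in σ units. Shift events — transient
spikes, sustained level shifts, dropouts, multiplicative or in σ units —
are applied *after* the noise draw so labels are exact; missingness removes
whole rows (samples), as real gaps do. Covariates are a seasonal temperature
sinusoid and skewed non-negative precipitation draws. Everything regenerates
bit-identically from (specs, events, seed).

Presets: **gut-dense** (T = 396, 20 genera, dense, no covariates) mimics
multi-year daily gut sampling with dominant seasonal structure (relative
amplitude 0.35, φ = 0.35, noise 5 % of baseline — chosen so that learnable
structure, not random drift, dominates: an oracle one-step predictor beats
last-value persistence by ~25 % here, which is the regime the skill tests
probe); **wastewater-monthly-gappy** (T = 72, winter months unsampled,
covariates) and **wastewater-weekly** (T = 104, 5 % random missingness,
covariates) mirror influent-monitoring cadences;
**detection-low-noise** (T = 240, 8 genera, noise 2 % of baseline) is the
spike-recovery scenario.

What passing tests on these data do **not** show: real feature tables have
compositional coupling from sequencing depth, taxa appearing/disappearing
over years, overdispersion far beyond rounding jitter, and covariate
effects that the generator leaves uncoupled from abundances. The synthetic
results demonstrate mechanical correctness and relative model behavior,
not field performance.

## Problem sizes and numerical choices

Experiments and tests run at desk scale on one CPU: 32-cell recurrent nets
instead of 2048, 10-member ensembles in the forest experiments, and
replicate counts of 50–200 for the Monte-Carlo checks — sizes chosen so the
full suite and the reproduction script each finish in minutes while leaving
every algorithmic path identical to a full-size run. Determinism: forest
runs are bit-reproducible given the config seed; recurrent runs are
reproducible under single-threaded BLAS. Sub-seeds derive from
SHA-256(global seed, component, index), so ensembles reproduce without seed
lists in configs. Degenerate inputs are handled explicitly throughout:
constant genera (scaler, correlation, VARMA variance filter), empty
partitions, boundary-equal observations, zero train metrics in the overfit
ratio, constant predictions in NRMSE.

## Known limitations

- Forest-ensemble intervals under-cover on quiet data (see above).
- The VARMA backend fits one joint model; with many genera the parameter
  count grows quadratically and the grid search can be slow or
  ill-conditioned (the variance filter mitigates but does not remove this).
- No conformal or quantile intervals; no multiple-testing control over
  flags; no encoder–decoder or transfer-learning variants.
- Upstream read processing (OTU/ASV calling, taxonomy) is out of scope; the
  package starts from a genus-level feature table.
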