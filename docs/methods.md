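# Methods

`ossdosim` simulates the design of sampling schedules for renal and tumour
dosimetry in ¹⁷⁷Lu-PSMA radioligand therapy. The pipeline has four stages:
a virtual cohort with known ground-truth kinetics, a measurement-noise model,
three estimators of the time-integrated activity coefficient (TIAC), and an
exhaustive Monte-Carlo search ranking candidate schedules by a joint
kidney/tumour root-mean-squared error (RMSE).

## Ground-truth time-activity curves

Each region (one kidney compartment and two tumour lesions per patient) has a
two-exponential uptake/washout curve modulated by physical decay:

    A(t) = C · (e^{−(λ_bio + λ_phys) t} − e^{−(λ_up + λ_phys) t})

with λ_phys = ln 2 / (6.647 · 24) h⁻¹ ≈ 0.0043450 h⁻¹ fixed for ¹⁷⁷Lu. This
is the simplest form with the features that physiologically based
pharmacokinetic (PBPK) outputs of this therapy exhibit: activity starting at
zero, a finite uptake peak within hours of injection, and effectively
mono-exponential washout beyond about a day. The true TIAC is available in
closed form,

    TIAC = (C/A0) · (1/(λ_bio + λ_phys) − 1/(λ_up + λ_phys)),

which the tests verify against adaptive quadrature to 1e−8 relative
tolerance. `λ_up = ∞` degenerates to a pure mono-exponential; several
estimator identities (exactness of the planar fit, systematic-error
cancellation, the single-time-point error ratio) hold exactly in that limit
and are tested there.

## Cohort sampling

Defaults emulate a 13-patient metastasized castration-resistant prostate
cancer cohort treated with ¹⁷⁷Lu-PSMA I&T:

| parameter | default | unit |
|---|---|---|
| patients / lesions per patient | 13 / 2 | — |
| injected activity A0 | Normal(7300, 300) | MBq |
| kidney effective half-life | Triangular(30, 40, 62) | h |
| tumour effective half-life | Triangular(34, 50, 94) | h |
| kidney time of maximum | Uniform(0.6, 3) | h |
| tumour time of maximum | Uniform(0.5, 9) | h |
| kidney peak uptake | Uniform(1, 3) % of A0 | — |
| lesion peak uptake | Uniform(0.05, 2) % of A0 | — |

Only medians and ranges of the half-lives are known for the emulated
population, so a triangular distribution (min, mode, max) is the least
committal choice. The uptake rate λ_up is solved per region (Brent root
finding on ln r = a(r−1), r = λ_up_eff/λ_bio_eff) so that the curve peak
lands at the drawn time of maximum. Kidney draws are additionally
rejection-sampled until at least 96.8 % of the curve maximum is reached by
1 h p.i., reproducing the early renal plateau seen in fitted patient data.

One consequence of the single-uptake-exponential form: the early-plateau
condition and a late peak are incompatible (a Bateman curve peaking at 2–3 h
is still visibly rising at 1 h), so the rejection step concentrates accepted
kidney peaks below roughly 1.6 h. The sampled kidney t_max median therefore
sits below the 2 h reported for PBPK-fitted patients; the plateau condition
was kept because it is what the estimators are sensitive to (all fits start
at ≥ 1 h). Peak-uptake fractions only set the curve scale; all headline
metrics are relative deviations and invariant to them.

## Noise model

Simulated activities are ground truth times median-preserving log-normal
factors (σ_ln = √ln(1+cv²), so the factor's coefficient of variation equals
the nominal cv). Planar noise (total cv 20 %) is split into a systematic
factor drawn once per (patient, region, replicate) and shared by all planar
time points — standing in for region-specific overlap and attenuation errors
of 2-D quantification — and stochastic factors drawn independently per time
point. The systematic share f_syst ∈ {25, 50, 75} % splits the total cv
linearly by default (cv_syst = f_syst·0.20); a variance-proportional split is
available via `NoiseConfig(syst_split="variance")` since the exact partition
used in the original measurement model is not published. SPECT/CT noise is a
single 5 % log-normal factor with no systematic part. Noise levels are
time-independent: a counting-statistics utility
(`planar_poisson_uncertainty`) shows that even a late 3.1 MBq kidney
measurement on a typical camera (9.4 cps/MBq, 38.7 cm field of view,
10 cm/min bed speed) carries only ≈1.2 % Poisson noise, so Poisson growth
over time is negligible for the kidneys.

## TIAC estimators

* **Planar-only.** The planar series is fitted with
  f(t) = A1·e^{−(λ1+λ_phys)t} and integrated analytically:
  TIAC = A1 / (A0(λ1+λ_phys)). Fitting is ordinary least squares on
  ln(activity) versus time — the maximum-likelihood estimate under the
  multiplicative log-normal noise actually simulated; two points give the
  exact interpolant. Nonlinear least squares in linear space is available
  (`fit_monoexp(..., space="linear")`) for sensitivity checks.
* **Hybrid planar/SPECT.** The planar fit supplies the shape, one SPECT/CT
  value rescales it: TIAC_hybrid = A_SPECT/f(t_SPECT) · TIAC_planar. Any
  multiplicative bias common to all planar values scales A1 only and cancels
  exactly in the ratio.
* **Single time point.** TIAC_1TP = (2/ln 2)·A_SPECT(t_ref)·t_ref/A0. On a
  mono-exponential truth the estimate/truth ratio is 2x·2^{−x} with
  x = t_ref/T_eff — exact at x = 1, underestimating for x < 1 or x > 2.

If the fitted slope implies λ1 < 0 (activity not decaying faster than
physical decay — possible under noise for short schedules), λ1 is clamped to
0, the prefactor is refitted with the slope fixed, and the replicate is kept
and flagged. Discarding such replicates would bias the pooled moments;
clamp counts are reported in every metrics table.

## Schedule search

Candidate planar times come from a 24-point grid (1–192 h p.i., working
hours). All 276 / 2024 / 5700 subsets of size 2 / 3 / 4 are enumerated (the
4-point schedules must place one or two points at ≤ 4 h); each planar
schedule expands into one hybrid schedule per possible SPECT anchor
(SPECT/CT fixed 0.5 h after a planar image), and each grid time is a
single-time-point candidate.

Per schedule, relative deviations Δ = 100·(TIAC_sim − TIAC_true)/TIAC_true
are pooled over patients × replicates for kidneys and lesions × patients ×
replicates for tumours (13 000 and 26 000 values at the defaults). Moments
use the population definition (÷N; at N ≥ 13 000 the distinction from ÷(N−1)
is negligible), and

    RMSE = √(σ² + μ²),    RMSE_joint = w_K·RMSE_K + RMSE_T,  w_K = 2.

The schedule minimising RMSE_joint is the optimal sampling schedule (OSS).
Ties (never observed in practice) break deterministically: earlier last
planar time first, then lexicographic schedule order. Constrained searches
re-filter the already-computed metrics by the latest allowed planar time
(the +0.5 h SPECT offset does not count against the limit, mirroring how
shortened protocols are counted clinically), and the last-two-time-point
variation maps RMSE over all admissible (penultimate, last) pairs with the
earlier times and the SPECT anchor rule held fixed.

## Reproducibility and numerics

Every (seed, method, schedule, patient, region) tuple gets its own numpy
`SeedSequence`-derived generator with a fixed draw layout (systematic vector,
stochastic matrix, SPECT vector), so results are independent of evaluation
order and byte-identical across reruns; output CSVs embed the seed and a
configuration hash. All replicates of a region are simulated with vectorised
draws and the closed-form log-space fit, which keeps a full 6072-schedule
search at 200 replicates around half a minute on one core. Schedule times
are exact decimals on the grid and compared exactly.

Default problem sizes: 1000 replicates per schedule and patient for focused
evaluations; the package's own test suite and the bundled acceptance script
run broad searches at 200 replicates, where the Monte-Carlo standard error
of a pooled RMSE (~RMSE/√(2N), N ≥ 5200) is below 0.1 percentage points —
small against the effects of interest (0.5–20 points).

## What the synthetic cohort does and does not show

The generator reproduces the population statistics of the emulated cohort
(half-life ranges, uptake timing, injected activity) but not the individual
PBPK curve shapes, which are not public. Exact published RMSE values are
therefore not reproducible here; what carries over, and what the tests
assert, are structural properties: exactness of the estimators in noiseless
mono-exponential conditions, cancellation of purely systematic planar error
by the hybrid method, RMSE falling as the systematic share rises, the
single-time-point tumour underestimation at 52 h, the OSS retaining a late
(192 h) measurement, and tumour RMSE degrading as protocols shorten. On the
synthetic cohort the absolute RMSE level (kidney ≈ 5–7 %) happens to sit in
the published range, but that agreement is incidental, not asserted.

## Known limitations

* No image-level simulation (projections, scatter, reconstruction) — noise
  enters as multiplicative factors on region activities.
* Tumour noise is size-independent; small lesions would realistically carry
  25–30 % noise at late time points, raising tumour RMSE and possibly
  favouring earlier final time points.
* Only mono-exponential fitting is implemented; model selection over richer
  fit families would change the optimal schedules.
* No absorbed-dose (Gy) conversion: relative TIAC deviations equal relative
  self-dose deviations, which is the quantity optimised.
* Population-level optimisation only; no per-patient schedule adaptation.
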