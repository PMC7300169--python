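# ossdosim

Simulation-based design of sampling schedules for renal and tumour dosimetry
in ¹⁷⁷Lu-PSMA radioligand therapy.

Individualized dosimetry for ¹⁷⁷Lu radioligand therapy requires serial
imaging to estimate each region's **time-integrated activity coefficient**
(TIAC = ∫₀^∞ A(t) dt / A0, in hours — proportional to the self-absorbed
dose). Imaging time is scarce, so the practical question is *when* to image:
which 1–4 measurement times give the most accurate and precise kidney and
tumour TIACs? `ossdosim` answers this by Monte-Carlo simulation: it generates
virtual patients with known ground-truth time-activity curves, perturbs the
"measured" activities with systematic + stochastic log-normal noise, runs
three TIAC estimators, and exhaustively ranks candidate schedules.

The three estimators, for a region with injected activity A0:

* **planar-only** — fit A(tᵢ) with f(t) = A₁·e^{−(λ₁+λ_phys)t} and integrate:
  TIAC = A₁ / (A0(λ₁+λ_phys)), with λ_phys = ln2/(6.647·24 h) for ¹⁷⁷Lu;
* **hybrid planar/SPECT** — the planar fit gives the shape, one quantitative
  SPECT/CT rescales it: TIAC = A_SPECT(t_S)/f(t_S) · TIAC_planar;
* **single time point** — TIAC = (2/ln2)·A_SPECT(t_ref)·t_ref/A0, exact for
  mono-exponential kinetics when t_ref equals the effective half-life.

Schedules are scored by the pooled relative deviations
Δ = 100·(TIAC_sim − TIAC_true)/TIAC_true over patients and replicates:
RMSE = √(σ_Δ² + μ_Δ²) per region class, and ranked by
RMSE_joint = 2·RMSE_kidney + RMSE_tumour. The minimiser is the optimal
sampling schedule (OSS). See `docs/methods.md` for the model details.

## Worked example

```python
import ossdosim as od

cohort = od.sample_cohort(od.CohortConfig(), seed=1)     # 13 virtual patients
grid = od.default_grid()                                  # 24 candidate times
noise = od.NoiseConfig(f_syst=0.5)                        # 20 % planar, 5 % SPECT
cfg = od.SearchConfig(n_reps=200, method="hybrid", seed=1)

metrics = od.evaluate_schedules(
    cohort, od.enumerate_hybrid_schedules(grid, 3), cfg, noise)
best = od.find_oss(metrics)[0]
print("OSS planar times:", best.schedule.planar.times,
      "SPECT at", best.schedule.t_spect, "h")
print(f"RMSE kidney {best.rmse_k:.2f}%  tumour {best.rmse_t:.2f}%  "
      f"joint {best.rmse_joint:.2f}")
```

Output on this cohort (evaluating all 6072 three-point hybrid schedules takes
about half a minute on one core):

```
OSS planar times: (28.0, 68.0, 192.0) SPECT at 68.5 h
RMSE kidney 5.01%  tumour 5.89%  joint 15.90
```

Read: with three planar images at 28, 68 and 192 h p.i. and a SPECT/CT at
68.5 h, kidney TIACs are recovered with a combined accuracy-and-precision
error of ~5 % and tumour TIACs of ~6 %. The late 192 h image is what pins
down the slow tumour washout — every top-ranked schedule keeps it, and
restricting the last measurement to 48 h roughly quintuples the best
achievable tumour RMSE.

The same pipeline is available from the shell:

```
ossdosim generate-cohort --seed 1 --out cohort.json
ossdosim run-search --cohort cohort.json --method hybrid --n-tp 3 \
    --f-syst 0.5 --n-reps 200 --seed 1 --out metrics.csv
ossdosim constrained-search --cohort cohort.json --n-tp 3 \
    --t-last-list 48,72,96,120,144,168,192 --n-reps 200 --seed 1 --out tlast.csv
ossdosim vary-tps --cohort cohort.json --base 3,96,192 --anchor 1 \
    --n-reps 200 --seed 1 --out surface.csv
```

All outputs are CSV with `#` header lines embedding the seed and a config
hash; reruns with identical inputs are byte-identical. A YAML file passed via
`--config` can override the grid (`grid_times`) and the `cohort`, `noise`
and `search` parameter groups.

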