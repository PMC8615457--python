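# wbam

Frontal whole-body angular momentum (WBAM) gait analysis and Bayesian
pre/post rehabilitation-effect modelling.

## The problem

In hemiplegic gait after stroke, the side-to-side (frontal-plane)
rotation of the whole body is poorly regulated, and its excursion over a
gait cycle is a sensitive marker of dynamic walking balance. Gait
rehabilitation studies therefore track the **WBAM range**: compute the
whole body's angular momentum about its own centre of mass,

L(t) = Σᵢ [ (rᵢ − r_com) × mᵢ (vᵢ − v_com) + Iᵢ ωᵢ ],   i = 1…12 segments,

project it on the anterior–posterior axis, normalise by body mass ×
height × walking speed, and take max − min over one gait cycle (paretic
foot contact to paretic foot contact, time-normalised to 0–100%).

To quantify what a two-week intervention did, the package fits Bayesian
models relating each patient's post-rehabilitation range to the pre
value, `post ~ Normal(β·pre, σ)`, where the multiplier decomposes into a
treadmill-training effect β_CT common to both study arms and an extra
auditory-feedback effect β_AF in the treatment arm (β < 1 means the
balance-relevant excursion shrank). Four model variants let either
effect carry patient-level individuality (β_CT,j ~ N(μ_CT, σ_CT), etc.);
the patient-level effects are marginalized in closed form, and models
are compared by WAIC on this new-patient predictive density, so the
ranking answers "which model best predicts the effect for a patient not
in the study?". Posterior summaries include the percent reduction of
the WBAM range attributable to feedback (−100·β_AF), predictive bands
for the pre–post relation, and a drawwise Cohen's d between arms.

The package is for gait-lab and rehabilitation researchers: it consumes
segment-level kinematics (CSV or TRC endpoint markers) plus optional
vertical ground-reaction forces, and trial-level range datasets
(`patient_id, group, phase, trial, range_value`). Seeded synthetic
generators for both levels make every stage testable without clinical
data.

## Worked example

```python
from wbam import (CohortConfig, MCMCConfig, ModelSpec, compute_waic,
                  effect_summary, fit_model, generate_cohort, pair_trials,
                  percent_reduction, rank_models)

dataset, truth = generate_cohort(CohortConfig(seed=1))   # 8 AF + 8 CT patients, 5 paired trials
paired = pair_trials(dataset)

fits, waics = {}, {}
for m in (1, 2, 3, 4):
    fits[m] = fit_model(ModelSpec(m), paired, config=MCMCConfig(seed=m))
    waics[m] = compute_waic(fits[m].pointwise_loglik).waic
print(rank_models(waics))
print(effect_summary(fits[1]))
print(percent_reduction(fits[1].draws("beta_af")))
```

Output (seed 1):

```
 model        individuality  rank        waic   d_waic
     1                   no     1 -621.947706 0.000000
     2            beta_CT,j     2 -620.806332 1.141374
     3            beta_AF,j     3 -620.740166 1.207540
     4 beta_CT,j, beta_AF,j     4 -619.846810 2.100896

 model   effect      mean      lo95      hi95
     1  beta_ct  1.042288  0.995378  1.089093
     1  beta_af -0.216419 -0.281844 -0.149471
     1 combined  0.825869  0.780099  0.871177

{'mean': 21.64190569924289, 'lo95': 14.947060200890766, 'hi95': 28.184366522683227}
```

Reading this: the non-hierarchical model 1 wins the WAIC ranking
(`d_waic` is each model's distance from the best), as it should — the
generating truth had no patient-level effect variation. Its posteriors
recover the generating effects (β_CT = 1.046: treadmill training alone
leaves the WBAM range unchanged; β_AF = −0.209: feedback reduces it),
and the feedback effect reads as a ~22% reduction with a 95% interval
of roughly 15–28%.

The `examples/` directory has one short script per capability
(kinematics → range, model fitting/comparison, predictive bands, CSV
round trips), and the `wbam` command line exposes the same steps
(`wbam compute`, `wbam simulate cohort|gait`, `wbam fit`, `wbam
compare`, `wbam run --config cfg.yaml --out dir`).

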