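# ctfpa — two-scan first-pass CT perfusion with maximum-slope validation

`ctfpa` is a Python library for studying **first-pass analysis (FPA)**, a
low-dose CT perfusion technique that estimates tissue blood flow from only
two volume scans, against the conventional **maximum slope model (MSM)**,
which needs a full dynamic scan train. It targets abdominal (pancreatic)
perfusion, where blood flow separates carcinoma from healthy parenchyma, and
is aimed at researchers prototyping acquisition protocols: because patient
dynamic-CT data are rarely shareable, the package ships a synthetic cohort
generator with known ground-truth blood flow so that every pipeline stage is
verifiable end to end.

## The models

Let AIF(t) be the arterial attenuation (HU) measured in the aorta and TAC(t)
a tissue attenuation curve. With tissue density ρ_t and the factor
6000 converting (HU/s)/HU to ml/100 ml/min:

- **MSM** — BF = 6000 · max(dTAC/dt) / (AIF_max · ρ_t), using all frames;
  the upslope is a sliding-window least-squares fit (default 3 samples).
- **FPA** — two scans only: the first at the bolus-tracking trigger t_base
  (AIF first exceeding 120 HU absolute), the second Δt later. Assuming no
  contrast leaves the tissue between the scans,

      P_avg = 6000 · ΔHU_avg / ∫ AIF_enh dt ,   P_FPA = P_avg · ΔHU / ΔHU_avg ,

  where ΔHU is the per-voxel enhancement change between the two scans, the
  integral runs from t_base to the second scan, and the compartment mean of
  P_FPA equals P_avg by construction.
- **Second-scan timing** — the bolus temporal centre rule
  t_p = t_i/2 + d places the second scan t_p seconds after the trigger,
  where t_i is the injection duration (16 s for 80 ml at 5 ml/s) and d an
  organ-dependent dispersion delay. `run_sweep` evaluates d = 0…13.5 s in
  1.5 s steps against MSM to find the timings where FPA agrees best.

The synthetic generator uses a gamma-variate AIF and a boxcar-residue
indicator-dilution tissue model (see `docs/methods.md`).

## Worked example

```python
from ctfpa import sample_cohort, run_sweep, optimum_delay_window

cohort = sample_cohort(16, seed=0)     # 16 synthetic subjects, known BF
result = run_sweep(cohort)             # FPA1 + ten FPA2 timings vs MSM
print(result.fpa1_record.r_mean_rois)  # 0.956
print(result.optimum_range)            # ['t1', ..., 't10']
print(optimum_delay_window(result))    # (8.0, 21.5)
```

Running `python examples/02_timing_sweep.py` prints (abridged):

```
timing   d (s)   r (ROI means)   r (voxelwise)
peak     -            0.956          0.777
t1       0.0          0.960          0.806
...
t10      13.5         0.957          0.845
optimum timings: ['t1', ..., 't10']
second-scan delay window after the trigger: 8.0-21.5 s
COV across timings (circular ROIs): {'carcinoma': '2.3%', 'parenchyma': '0.9%'}
largest carcinoma-vs-parenchyma p value: 5.77e-06
```

`r (ROI means)` is the Pearson correlation between FPA and MSM blood flow
over subject-level circular-ROI means (both tissues pooled); the COV shows
how little the FPA estimate depends on the exact acquisition time within
the window; the p value is the carcinoma-vs-parenchyma Student's t-test.
`examples/01_simulate_and_map.py` shows single-subject parameter recovery
(noise-free FPA is exact; MSM within ~1.5%), and
`examples/03_dose_accounting.py` the dose arithmetic: two of 34 volumes is
a ~94% effective-dose reduction.

A thin CLI wraps the same stages:

```
ctfpa simulate --out cohort/ -n 16
ctfpa maps --out maps/ cohort/sub-001
ctfpa sweep --out sweep/ cohort/ --figures
ctfpa report --dose
```

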