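# boldcsf

Coupling between the global fMRI BOLD signal and cerebrospinal-fluid (CSF)
inflow, as an imaging marker of glymphatic function in aging and
Alzheimer-disease cohorts.

During drowsiness and light sleep, the brain's global BOLD signal shows
large slow (<0.1 Hz) fluctuations; each one is followed by an inflow of
fresh CSF into the bottom slice of the fMRI acquisition, visible as an
intensity increase. `boldcsf` extracts both series from 4D NIfTI data,
quantifies their coupling as the lagged cross-correlation

    CC(τ) = Pearson( G(t), F(t − τ) ),   τ = k·TR

with the value at τ = +3 s (one TR) as the scalar coupling metric (more
negative = stronger coupling), tests it against a session-shuffling
permutation null, and relates it to cohort covariates — age, gender,
diagnostic group (HC < SMC < MCI < AD), APOE ε4, amyloid-PET SUVR, MMSE and
its 2-year change — using linear mixed models with subject random
intercepts (Spearman ρ reported alongside the mixed-model p).

Because the motivating cohort data are access-restricted, the package
includes a synthetic-cohort generator in which a known gain κ and delay d
link global activity to CSF inflow and covariates are tied to κ with
configurable effect sizes; every pipeline stage is validated by parameter
recovery against that ground truth. See `docs/methods.md` for the model
and all numerical conventions.

Intended users: neuroimaging researchers studying sleep/arousal-coupled
CSF dynamics, and anyone needing a tested reference implementation of the
bottom-slice inflow coupling analysis.

## Worked example

```python
import boldcsf as bc
from boldcsf.pipeline import extract_all, build_cohort_table
from boldcsf.stats import longitudinal_change

cfg = bc.SimulationConfig(n_subjects=40, sessions_per_subject=2, seed=7)
cohort = bc.simulate_cohort(cfg)                    # 80 sessions, known gain/delay
signals = extract_all(cohort.sessions)              # preprocess + extract G and F
table, ccfs = build_cohort_table(cohort, signals)   # per-session coupling metrics

lags, mean_r, sem = bc.session_mean_ccf(ccfs)
print("lag (s):", " ".join(f"{l:+5.0f}" for l in lags[4:11]))
print("mean r :", " ".join(f"{r:+5.2f}" for r in mean_r[4:11]))

null = bc.permutation_null(list(signals.values()), n_permutations=2000,
                           max_lag_seconds=21.0, seed=7)
idx = list(null.lags_seconds).index(3.0)
print(f"coupling at +3 s: mean r = {mean_r[idx]:.3f}, permutation p = {null.p[idx]:.4f}")

table["d_mmse"] = longitudinal_change(table["mmse_base"], table["mmse_fu"])
res = bc.association(table, "coupling", "suvr_base", ("age", "gender"))
print(f"coupling ~ amyloid SUVR: Spearman rho = {res.spearman_rho:.2f}, "
      f"mixed-model p = {res.lmm_p:.2g} (n = {res.n_sessions} sessions)")
```

Output:

```
lag (s):    -9    -6    -3    +0    +3    +6    +9
mean r : +0.34 +0.39 -0.01 -0.41 -0.35 -0.06 +0.04
coupling at +3 s: mean r = -0.347, permutation p = 0.0005
coupling ~ amyloid SUVR: Spearman rho = 0.47, mixed-model p = 3e-05 (n = 80 sessions)
```

Reading it: the session-mean cross-correlation function has the
characteristic shape — a positive peak at a negative lag (CSF changes
preceding the paired BOLD sample) and a negative trough around 0…+3 s.
The +3 s correlation is far outside the shuffled-session null
(p = 1/2001, the resolution floor of 2000 permutations). Across the
synthetic cohort, sessions with higher amyloid burden have *weaker* (less
negative) coupling — a positive Spearman ρ after age/gender adjustment —
which is the direction of association the generator injected.

The same stages are available from the shell:

```bash
boldcsf simulate --out sim/ --seed 7            # NIfTI volumes + masks + tables
boldcsf extract  --volumes sim/sub0000_ses1_bold.nii.gz \
                 --gm-mask sim/sub0000_ses1_gm_mask.nii.gz \
                 --csf-mask sim/sub0000_ses1_csf_mask.nii.gz --out sig/
boldcsf couple   --signals sig/ --n-perm 10000 --seed 7 --out out/
boldcsf run      --out run/ --seed 7            # full synthetic pipeline
```

For real data, point `extract` at preprocessed (motion-corrected,
skull-stripped) volumes with a gray-matter mask and a manually drawn
bottom-slice CSF mask, then `couple`/`metrics`/`associate` on the outputs
together with a session table (`subject_id`, `session_id`, `group`, `age`,
`gender`, `apoe_e4_count`, `suvr_base`, `suvr_fu`, `mmse_base`, `mmse_fu`,
`batch`).

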