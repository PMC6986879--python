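# prpdecode

Analysis of olfactory-bulb LFP during go/no-go odor discrimination:
phase-amplitude coupling (PAC), theta phase-referenced beta/high-gamma
power (PRP), trial-wise decoding of odorant contextual identity,
decision-time estimation, and participation-ratio dimensionality — with
a synthetic-session generator that carries the statistical structure the
analysis assumes, so every estimator can be exercised end-to-end against
known ground truth.

## The problem

A mouse in the go/no-go task smells one of two odorants — rewarded (S+)
or unrewarded (S−) — and licks (or withholds licking) to report its
decision. The olfactory-bulb LFP shows phase-amplitude coupling: bursts
of beta (15–30 Hz) and high-gamma (65–95 Hz) activity ride at a
preferred phase of the theta (6–14 Hz) rhythm. The questions this
package operationalizes:

* how strong is that coupling, and at which theta phase (modulation
  index, peak/trough phase, peak-angle variance)?
* does fast-band power sampled at the learned theta phase (PRP) encode
  whether the odorant is rewarded, and does that code emerge with
  learning (leave-one-out LDA per 0.1 s bin, shuffle control,
  normalized AUC)?
* when does the neural code diverge between odorants relative to the
  behavioral (lick) decision (sustained rank-sum p < 0.05)?
* does the 16-electrode PRP space contract when the odorant arrives
  (participation ratio dim = (Σλ)²/Σλ²)?

Core quantities, in the field's notation:

* **Modulation index.** With p the 51-bin distribution of mean
  fast-band envelope over theta phase,
  `MI = (ln N − H(p)) / ln N`, `H(p) = −Σ p_j ln p_j`; 0 = uniform
  (no coupling), 1 = delta.
* **Normalized decoding AUC.** Mean over the odor window of
  `max(accuracy − 50, 0)/50`; 0 = chance, 1 = perfect.
* **Participation ratio.** `dim = (Σ_i λ_i)² / Σ_i λ_i²` over the
  eigenvalues of the across-trial electrode covariance of PRP.

## Worked example

```python
import numpy as np
from prpdecode import (AnalysisConfig, decode_timecourse, session_pac,
                       session_prp)
from prpdecode.synthetic import proficient_config, simulate_session

config = AnalysisConfig()
session, trials, truth = simulate_session(
    proficient_config(n_trials=40, seed=1, n_electrodes=8, rate=500.0))

pac = session_pac(session, trials, config.bands["theta"],
                  config.bands["high_gamma"], config)
print("S+ mean MI:", pac.table.query("odorant=='S+'").mi.mean().round(4))
print("reference peak phases (deg):", pac.reference_peak_deg[:4])

tensors = session_prp(session, trials, config.bands["high_gamma"],
                      config, pac_series=pac)
tc = decode_timecourse(tensors["peak"], config, seed=3)
odor = (tc.timebins_s >= 0.5) & (tc.timebins_s <= 2.5)
print("odor-window accuracy: %.1f%%" % np.nanmean(tc.accuracy[odor]))
print("normalized AUC: %.2f" % tc.auc)
```

prints

```
S+ mean MI: 0.0313
reference peak phases (deg): [123.52941176 123.52941176 130.58823529 130.58823529]
odor-window accuracy: 95.5%
normalized AUC: 0.91
```

The generator built high-gamma bursts at 120° of theta with an analytic
MI of 0.027, an S+/S− odor gain contrast of 12 dB, and licks diverging
at 0.25 s: the pipeline recovers the burst phase within one phase bin,
the MI within ~15%, and decodes the odorant nearly perfectly during the
odor epoch (chance would give AUC ≈ 0).

## The analysis project

Numbered drivers under `analysis/` run the study end to end, writing
tables under `results/` (simulated raw sessions go to `scratch/`,
which is disposable):

```
python analysis/01_simulate_sessions.py     # proficient / naive / null sessions
python analysis/02_validate_pac_chain.py    # two-oscillation MI validation
python analysis/03_run_pipeline.py          # behavior -> pac -> prp -> decode -> dim
python analysis/04_decoding_over_learning.py
python analysis/05_decision_times.py
python analysis/06_dimensionality_collapse.py
```

The same stages are exposed as a CLI (`prpdecode simulate|pac|prp|
decode|decision-time|dim|run-all|reproduce-sim`) over on-disk session
directories (`metadata.json` + `lfp.f32` + `trials.csv`).

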