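# qmreff

Intrinsic-efficiency analysis of quantitative MRI relaxometry sequences:
which pulse sequence extracts the most information about T1 and T2 per
square root of scan time?

`qmreff` is aimed at MR physicists designing or comparing T1/T2 mapping
protocols.  It provides:

* **Forward signal models** for the common gradient-echo families —
  spoiled (SPGR/Ernst), balanced SSFP with off-resonance banding,
  multi-echo steady state (DESS/TESS via extended phase graphs), and
  transient fingerprinting trains with spoiled (EPG) or balanced (Bloch)
  readouts, including cyclic driven-equilibrium operation.
* **The efficiency metric.**  For an unbiased estimator of θ with standard
  deviation σ_θ,

      η(θ) = (θ/σ_θ) · (σ0/M0) / sqrt(T_acq)   [s^-1/2],

  evaluated at the Cramér–Rao lower bound with all nuisance parameters
  ({T1, T2, M0} for spoiled sets, plus {φ0, ω0} when balanced readouts
  participate) estimated jointly.  η is independent of the noise level and
  of M0 by construction, so it isolates the spin dynamics of the sequence.
* **Sequence optimization** — constrained multi-start minimization of
  Σ_p η(T1)^-2 + η(T2)^-2 over flip-angle trains and repetition times, with
  a catalogue of method-specific design spaces (DESPOT/JSR, PLANET,
  DESS/TESS, spoiled/balanced fingerprinting).
* **Undersampling analysis** — a Monte-Carlo model of the efficiency lost
  when k-space undersampling aliasing is treated as noise by a zero-filled
  reconstruction: the dynamics factor d_R ≈ sqrt(k²(R−1)/R·SNR² + 1) and
  η_R = η/d_R, on a built-in Shepp–Logan phantom with random or
  variable-density spiral sampling.
* **A synthetic validation harness** — repeated noisy DESPOT1 acquisitions
  of a digital phantom, comparing empirical efficiency across flip-angle
  subsets with the theoretical prediction.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

```python
import numpy as np
from qmreff import (TissueParams, SequenceSettings, efficiency,
                    monte_carlo_dr, eta_undersampled, shepp_logan)

wm = TissueParams(t1=781.0, t2=65.0)          # white matter at 3 T

# A DESPOT/JSR-style protocol: 2 SPGR + 6 phase-cycled bSSFP measurements
spgr  = SequenceSettings("SPGR",  [6, 18], 8.0, 2.0)
bssfp = SequenceSettings("bSSFP", [15, 35, 55, 35, 55, 15], 8.0, 2.0,
                         rf_phases=[180, 180, 180, 0, 0, 0])
eff = efficiency(wm.replace(omega0=10.0), [spgr, bssfp])
print(f"eta_T1 = {eff.eta_t1:.3f}  eta_T2 = {eff.eta_t2:.3f}  "
      f"T_acq = {eff.t_acq*1e3:.0f} ms")

# How much of that survives 8-fold undersampling with zero filling?
res = monte_carlo_dr(shepp_logan(128), "random", R=8, snr_image=50.0,
                     n_trials=2000, seed=1)
print(f"d_R = {res.d_r_mean:.1f}  ->  eta_R(T1) = "
      f"{eta_undersampled(eff.eta_t1, res.d_r_mean):.4f}")
```

prints

```
eta_T1 = 0.173  eta_T2 = 0.206  T_acq = 64 ms
d_R = 21.9  ->  eta_R(T1) = 0.0079
```

Read: this 64 ms steady-state protocol encodes T1 at 0.173 s^-1/2 — an
experiment with SNR_max = 200 running for 100 s would reach a
T1-to-noise ratio of 0.173·200·√100 ≈ 346.  At image SNR 50, however,
8-fold-undersampled zero-filled reconstruction amplifies the parameter
error 21.9-fold: aliasing, treated as noise, wipes out almost all of the
efficiency — the case for reconstructions that resolve aliasing instead
of averaging it.

The same functionality is scriptable from the shell:

```bash
qmreff efficiency --sequence seq.yaml --out efficiency.csv
qmreff optimize --method DESPOT_JSR --n 10 --starts 100 --seed 1 --out jsr.json
qmreff undersample --R 2,4,8,16,32 --snr 50 --kind spiral --out dr.csv
qmreff validate --repeats 10 --snr 200 --seed 1 --out validation.csv
```

Every output file embeds its full run configuration; identical options and
seed reproduce byte-identical results.

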