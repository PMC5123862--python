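# tlsquant

Quantitative analysis of polymerase–sliding-clamp–DNA interactions and
translesion DNA synthesis (TLS), for biochemists reducing fluorimeter
titrations and quantified primer-extension gels to binding constants,
inhibition constants and single-nucleotide-resolution processivity
parameters.

During lagging-strand replication the replicative polymerase δ anchors
to the PCNA sliding clamp; at a UV lesion it dissociates and the TLS
polymerase η takes over at the primer/template (P/T) junction. Probing
that hand-off quantitatively requires four recurring analyses, all
implemented here:

1. **Equilibrium binding with ligand depletion.** Raw titration signal
   (FRET ratio I₆₇₀/I₅₇₀, donor-quenching efficiency
   E_dq = 1 − I_DA/I_D, or anisotropy-derived fraction bound) is fit to
   a one-site model, `y = C + R·[L]ₜ/(K_D + [L]ₜ)`, then each point is
   normalized to a fractional saturation F = (y − C)/R, bound ligand
   F·[S]ₜ is subtracted from added ligand, and F vs [L]_free is refit
   with amplitude 1.0. The depletion-corrected K_D is the reported
   constant. The bound complex itself is the physical root of
   C² − (Rₜ + Lₜ + K_D)·C + Rₜ·Lₜ = 0.

2. **Competition titrations and exact IC₅₀ → K_i conversion.**
   Displacement of a pre-assembled labeled complex by an unlabeled
   competitor is fit to a unit-Hill-slope dose-response model in
   log₁₀[competitor]; the inhibition constant follows from the exact
   Munson–Rodbard correction

   K_i = IC₅₀ / [1 + Lₜ(y₀+2)/(2·K_D·(y₀+1)) + y₀] − K_D·y₀/(y₀+2),

   with y₀ the initial bound/free ratio from the depletion quadratic —
   unlike Cheng–Prusoff, valid when the target ligand is substantially
   depleted. A three-species competitive-equilibrium solver provides
   the exact forward model for validation.

3. **Single-turnover processivity ladders.** Gel-quantified product
   concentrations per insertion position give per-step insertion
   probabilities P_i = Σ_{j≥i}B_j / Σ_{j≥i−1}B_j (the probability of
   inserting nucleotide i rather than dissociating), the TLS-complex
   survival curve y(i) = P₃·…·P_i, plateau amplitudes, fold
   stimulation by the clamp, the surviving-holoenzyme fraction, and
   the processivity extrapolation n = ln(threshold)/ln(P) — e.g.
   P = 0.999 gives 0.999⁴⁶⁰⁰ ≈ 0.010, i.e. ~4600 nucleotides per
   binding event. The kinetic partition P = k_pol/(k_pol + k_off)
   links P to rate constants.

4. **Seeded synthetic data** for every input class, drawn from the
   same physical models (depletion quadratic, exact ternary
   equilibrium, Bernoulli insertion chain with multinomial counting
   noise), so the full pipeline is testable without instrument data.

## Worked example

```python
from tlsquant import (SimulationConfig, simulate_equilibrium_titration,
                      OneSiteBindingModel)

curve = simulate_equilibrium_titration(SimulationConfig(seed=7))
res = OneSiteBindingModel(curve).fit()
print(res.summary())
```

```
One-site binding fit (depletion-corrected)
============================================
method:            normalized
points:            12
substrate_total:   20 nM
raw fit:           R = 1.003, C = 0.05292 a.u.
K_D:               130.5 +/- 5.187 nM
passes:            2 (K_D history: 131, 130.5)
flagged points:    0 outside F in [0, 1.05]
```

The generator's true K_D is 120 nM; with 2% signal noise on three
replicates the fit lands at 130.5 ± 5.2 nM (about 2 standard errors,
consistent with the calibration checked in the test suite).

Converting a fitted IC₅₀ to an inhibition constant (here the values
for an unlabeled-clamp competition against a pre-assembled 200 nM
polymerase / 20 nM labeled-clamp complex with K_D = 120 nM):

```bash
$ tlsquant ki --ic50 308 --lt 200 --partner 20 --kd 120 --ic50-se 19.8
Ki = 111.1 +/- 7.39 nM (y0 = 0.06498)
```

And a single-turnover ladder analysis:

```python
from tlsquant import simulate_single_turnover_ladder, ProcessivityModel
res = ProcessivityModel(simulate_single_turnover_ladder(SimulationConfig(seed=7))).fit()
print(res.summary())
```

```
Single-turnover processivity analysis
========================================
time point analyzed:  60 s
clamped bands:        0
TLS-complex abundance P_2 = 0.212
  i    P_i     survival
  2    0.212   1
  3    0.3058  0.3058
  4    0.458   0.1401
  5    0.3124  0.04375
plateau amplitude:    0.4008 +/- 0.001418 (n=3, t > 10 s)
```

P₂ — the fraction of engaged polymerases that replicate both bases of
the di-pyrimidine before dissociating (the "TLS complex") — is
recovered at 0.212 against a generating value of 0.215; the survival
column is the running product of the later P_i.

The same stages are exposed as a CLI: `tlsquant simulate`,
`fit-binding`, `fit-competition`, `ki`, `processivity`, each emitting
a JSON report with parameters, uncertainties and configuration echo.

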