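# flownmr

Compact-NMR process analytics for a continuous lithiation reaction:
quantitative benchtop ¹H NMR by Indirect Hard Modeling (IHM) with
one-point calibration, steady-state-gated calibration transfer to an
NIR spectrometer by PLSR, and economic real-time optimization by
modifier adaptation with quadratic approximation (MAWQA) — exercised
end to end against a simulated pilot plant.

## Who this is for

Process-analytical chemists and control engineers who want a complete,
inspectable reference implementation of the "NMR as online reference
method" workflow: a low-field (43 MHz) NMR sensor quantifies the
reaction mixture with almost no calibration effort, its concentration
readings gate and label NIR spectra to train multivariate calibrations,
and the same readings drive an iterative economic optimizer that
tolerates a deliberately wrong process model.

The chemistry: aniline + 1-fluoro-2-nitrobenzene (o-FNB) + 2 LiHMDS →
lithium 2-nitrodiphenylamine (Li-NDPA) + LiF, in THF, with the
lithiated aniline as an online-observable intermediate.

## The core methods

**IHM quantification.** Each analyte is a frozen sum of pseudo-Voigt
peaks; a mixture spectrum is fitted by a constrained superposition that
may scale, shift, and (jointly per component) widen each model while
holding intra-component area ratios exactly fixed. Concentrations
follow the one-point calibration

    c_i = ξ · A_i / ν_i

where A_i is the fitted absolute integral of component *i*, ν_i its
proton count, and ξ is fixed once from a stream of known concentration
(the pure o-FNB feed at 0.63 mol L⁻¹).

**Steady-state gating.** An 11-point moving linear fit per analyte;
steady iff |slope| < 0.1 mol L⁻¹ h⁻¹ and residual SD < 0.01 mol L⁻¹,
then a trailing 6-point moving average; NMR references pair with NIR
spectra after compensating the 120-s inter-sensor delay.

**PLSR transfer.** SNV over the working window 8957–4611 cm⁻¹ (or
polynomial baselines per analyte), NIPALS PLSR with per-analyte factor
counts (aniline 1, o-FNB 3, Li-NDPA 5, Li-aniline 4), validated by
random 20-segment CV, leave-one-run-out CV, and a held-out run.

**MAWQA.** Profit
`w₄·M·c_LiNDPA/ρ·Σuᵢ − Σwᵢuᵢ` is maximized over the three feed flows by
iteratively correcting the nominal model's optimization problem with a
bias and gradient modifiers, the plant gradient being estimated from a
quadratic surrogate over past operating points (with probing moves when
the geometry degenerates), under the stoichiometric constraint
n_LiHMDS ≥ 2·n_aniline.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import numpy as np
from flownmr import ihm, pipeline, plant_simulator as ps

models = ps.default_model_library()

# start-up: one-point calibration on the pure o-FNB stream
cal_spec = ps.synth_nmr_spectrum({"oFNB": 0.63}, models)
ofnb = next(m for m in models if m.name == "oFNB")
xi = pipeline.calibrate_on_pure_stream(cal_spec, ofnb, known_conc=0.63)

# a noisy production-mixture spectrum
rng = np.random.default_rng(7)
truth = {"aniline": 0.02, "oFNB": 0.12, "LiHMDS": 0.08,
         "Lianiline": 0.01, "LiNDPA": 0.15}
spec = ps.synth_nmr_spectrum(truth, models, noise_sd=0.012, rng=rng)

prepared = pipeline.process_spectrum(spec)
fit = ihm.fit_mixture(prepared, models)
conc = ihm.quantify(fit, xi, {m.name: m.nu for m in models})
for name, c in conc.items():
    print(f"{name:10s} {c*1000:7.1f} mmol/L  (truth {truth[name]*1000:.0f})")
```

prints (values in mmol/L; the few-mmol deviations are the sensor noise
propagated through the fit):

```
aniline       21.0 mmol/L  (truth 20)
oFNB         118.6 mmol/L  (truth 120)
LiHMDS        80.1 mmol/L  (truth 80)
Lianiline     10.1 mmol/L  (truth 10)
LiNDPA       149.7 mmol/L  (truth 150)
```

A command-line interface wraps the same workflows:

```bash
flownmr simulate --seed 42 --out runs/day1/
flownmr rto --u0 3.58,3.58,3.58 --seed 7 --out trajectory.csv
```

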