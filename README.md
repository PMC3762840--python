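# hyperkin

Kinetic analysis of real-time hyperpolarized [1-¹³C]pyruvate magnetic
resonance spectroscopy, built around the **model-free AUC-ratio method**:
the ratio of the total areas under the lactate and pyruvate signal curves
is a direct surrogate for the apparent forward rate constant of the
LDH-catalysed pyruvate→lactate exchange, without fitting a compartmental
model or measuring an arterial input function.

## Who this is for

Dissolution-DNP experiments inject hyperpolarized [1-¹³C]pyruvate into a
cell suspension or an animal and record a train of ¹³C spectra (typically
128 spectra every ~2 s at a 10–20° flip angle) while the label exchanges
into lactate (and, in vivo, alanine). The conventional analysis fits the
modified Bloch (McConnell) equations to the peak-area time courses to
estimate the forward constant k_PL — a procedure that is sensitive to the
assumed input function and reaction network. `hyperkin` implements both
routes: the compartmental models with maximum-likelihood fitting, and the
model-free AUC ratio, together with the synthetic-data machinery needed
to validate one against the other.

## The central identity

For first-order exchange with effective relaxation (T1 plus RF loss,
r = 1/T1 − ln cos θ / TR), the lactate rate equation alone implies

    AUC(L) / AUC(P) = k_PL / (r_L + γ·k_LP),
    γ = (k_EL + r_L) / (k_LE + k_EL + r_L),

where k_LE/k_EL are the MCT-mediated lactate membrane transport rates of
the 3-site model; without transport γ = 1 and the denominator is simply
r_L + k_LP. Because the identity never touches the pyruvate equation, the
ratio is independent of the input function P_in(t), of the pyruvate
relaxation rate, and of any side pathway draining pyruvate (e.g. the
alanine branch). With discrete sampling the AUCs are plain sums of the
per-spectrum peak areas (the spacing cancels in the ratio).

## Worked example

Simulate a noisy in vivo style experiment (20° flip, TR 2 s, 128 spectra,
raised-cosine bolus over 5 s), then compare the model-free ratio with the
closed form and with a full maximum-likelihood fit:

```python
from hyperkin import (KineticParameters, InputFunction, auc_ratio, fit,
                      predicted_ratio_two_site, truncation_corrected_ratio)
from hyperkin.fitting import FitOptions
from hyperkin.synthetic import generate_timeseries, invivo_acquisition

acq = invivo_acquisition()
truth = KineticParameters(k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05)
bolus = InputFunction.raised_cosine(40.0, onset_s=2.0, duration_s=5.0)
data = generate_timeseries(truth, bolus, acq, noise_sigma=0.01, seed=42)

print(f"AUC(L)/AUC(P)       = {auc_ratio(data).ratio:.4f}")
print(f"k_PL/(r_L+k_LP)     = {predicted_ratio_two_site(truth):.4f}")

res = fit(data, "two_site", acq,
          FitOptions(input_mode="raised_cosine", vary_r_P=True, seed=1))
p = res.params_hat
print(f"fitted k_PL         = {p.k_PL:.4f} /s  (SE {res.std_errors['k_PL']:.4f})")
print(f"model-derived ratio = {truncation_corrected_ratio(res):.4f}")
```

Output:

```
AUC(L)/AUC(P)       = 0.3268
k_PL/(r_L+k_LP)     = 0.3333
fitted k_PL         = 0.0204 /s  (SE 0.0008)
model-derived ratio = 0.3301
```

The raw sum-ratio (0.3268) sits within 2% of the closed-form value
0.02/(0.05+0.01) = 0.3333 despite 1% noise, and the fit recovers the
generating k_PL = 0.02 /s with its co-estimated raised-cosine input. For
in vitro records that miss their first samples (injection outside the
magnet), the raw ratio is biased and `truncation_corrected_ratio`
evaluates the closed form at the fitted parameters instead.

## Command line

```bash
hyperkin simulate --preset invitro --seed 1 --noise-sigma 0.01 --out run/
hyperkin aucratio run/timeseries.csv
hyperkin fit run/timeseries.csv --model two_site --cost modified --seed 0 --out run/fit
hyperkin cohort --n 24 --seed 1 --out cohort/
```

Exit codes: 0 success, 2 validation error, 3 convergence failure. All
reports are JSON with stable key order; all curves are CSV
(`time_s` column plus one column per metabolite).

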