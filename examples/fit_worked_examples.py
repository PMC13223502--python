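"""Refit the two published per-patient worked examples from noiseless signals.

Synthesizes the signal decay of each model at the 13 acquisition b-values
from the printed cortical parameter values of the two illustrated patients
(one with reduced eGFR, one with preserved eGFR), then refits each curve.
Printed numbers are recovered-vs-true; agreement to ~12 digits shows the
fitters are exact on clean data.
"""

import numpy as np

from renal_ivim import (
    BiexpParams, BValueScheme, MonoParams, SignalCurve, StretchedParams,
    biexp_signal, fit_all_models, mono_signal, stretched_signal,
)

CASES = {
    "reduced-eGFR patient (66.3 mL/min/1.73 m2)": {
        "mono": MonoParams(adc=2.15e-3),
        "biexp": BiexpParams(d_slow=1.65e-3, d_fast=15.6e-3, f=0.19),
        "stretched": StretchedParams(ddc=2.28e-3, alpha=0.55),
    },
    "preserved-eGFR patient (95 mL/min/1.73 m2)": {
        "mono": MonoParams(adc=2.33e-3),
        "biexp": BiexpParams(d_slow=1.75e-3, d_fast=26.5e-3, f=0.29),
        "stretched": StretchedParams(ddc=3.12e-3, alpha=0.64),
    },
}
FORWARD = {"mono": mono_signal, "biexp": biexp_signal, "stretched": stretched_signal}

scheme = BValueScheme.default()
for label, case in CASES.items():
    print(f"\n== {label}")
    for model, truth in case.items():
        sig = np.asarray(FORWARD[model](truth, scheme.b))
        fit = fit_all_models(SignalCurve(scheme, tuple(sig)))[model].params
        if model == "mono":
            print(f"  ADC      true {truth.adc*1e3:.2f}  fitted {fit.adc*1e3:.4f}  (1e-3 mm2/s)")
        elif model == "biexp":
            print(f"  ADCslow  true {truth.d_slow*1e3:.2f}  fitted {fit.d_slow*1e3:.4f}")
            print(f"  ADCfast  true {truth.d_fast*1e3:.2f}  fitted {fit.d_fast*1e3:.4f}")
            print(f"  f        true {truth.f:.2f}  fitted {fit.f:.4f}")
        else:
            print(f"  DDC      true {truth.ddc*1e3:.2f}  fitted {fit.ddc*1e3:.4f}")
            print(f"  alpha    true {truth.alpha:.2f}  fitted {fit.alpha:.4f}")
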