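import numpy as np
import pytest

from renal_ivim import (
    BiexpParams,
    BValueScheme,
    MonoParams,
    SignalCurve,
    StretchedParams,
    biexp_signal,
    mono_signal,
    stretched_signal,
)

# The two published patient worked examples (display units converted to mm^2/s):
# a reduced-eGFR patient and a preserved-eGFR patient.
CASE_LOW = {
    "mono": MonoParams(adc=2.15e-3),
    "biexp": BiexpParams(d_slow=1.65e-3, d_fast=15.6e-3, f=0.19),
    "stretched": StretchedParams(ddc=2.28e-3, alpha=0.55),
}
CASE_HIGH = {
    "mono": MonoParams(adc=2.33e-3),
    "biexp": BiexpParams(d_slow=1.75e-3, d_fast=26.5e-3, f=0.29),
    "stretched": StretchedParams(ddc=3.12e-3, alpha=0.64),
}

FORWARD = {"mono": mono_signal, "biexp": biexp_signal, "stretched": stretched_signal}


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme.default()


def noiseless_curve(params, scheme) -> SignalCurve:
    model = {MonoParams: mono_signal, BiexpParams: biexp_signal,
             StretchedParams: stretched_signal}[type(params)]
    return SignalCurve(scheme, tuple(np.asarray(model(params, scheme.b))))
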