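"""Short-data Lorenz: the split-SVD fit keeps its structure, HAVOK loses it.

Simulates 3000 samples (three time units) of Lorenz-63 from the standard
chaotic initial condition, fits forced HAVOK and sHAVOK models on a
201-delay centred embedding at rank 4, and prints the structure metrics
and leading eigenvalues.  Lower antisymmetry/tridiagonality indices mean
the fitted dynamics is closer to the antisymmetric tridiagonal form the
Frenet-Serret correspondence predicts; eigenvalues with positive real
part signal an unstable (exponentially growing) model.
"""

import numpy as np

import shavok as sh

spec = sh.SimulatorSpec(
    "lorenz", init=(-8.0, 8.0, 27.0), dt=0.001, steps=3000,
    params=sh.LORENZ_DEFAULTS,
)
ts = sh.simulate_lorenz(spec).observable(0)
print(f"Lorenz x(t): {len(ts)} samples at dt = {ts.dt}")

emb = sh.centre(sh.build_hankel(ts, m=201))
for fit, label in [(sh.fit_havok, "HAVOK "), (sh.fit_shavok, "sHAVOK")]:
    model = fit(emb, r=4, closed=False)
    rep = sh.structure_report(model.A)
    sp = sh.spectrum(model, "discrete_log")
    print(
        f"{label}: antisym={rep.antisym_index:.3f} "
        f"off-band={rep.tridiag_index:.3f} max Re(omega)={sp.max_real:+.3f}"
    )
print("\nsmaller indices = more antisymmetric tridiagonal; the split-SVD fit"
      "\nretains the structure that the plain fit loses on short records")
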