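"""Multifractal analysis of a deterministic cascade, checked against its
closed-form multiscaling exponent.

The three-interval multiplicative cascade with weights (0.2, 0.6, 0.2) has
tau(q) = -log3(2 * 0.2^q + 0.6^q) exactly; MF-DFA should recover it, and
the Legendre transform turns tau(q) into the singularity spectrum D(h).
"""

import numpy as np

from fractkit import (
    CascadeSpec,
    cascade_tau_oracle,
    default_qgrid,
    delta_h,
    generate_cascade,
    generate_fgn,
    legendre_spectrum,
    mf_dfa,
    spectrum_descriptors,
    tau_and_dimensions,
    wide_qgrid,
)

spec = CascadeSpec(base=3, weights=(0.2, 0.6, 0.2), depth=8)
cascade = generate_cascade(spec)
windows = 3 ** np.arange(3, 9)  # align windows with the construction scales

q = default_qgrid()
hq = mf_dfa(cascade, q=q, window_sizes=windows)
tau = tau_and_dimensions(hq)
oracle = cascade_tau_oracle(spec, q)
print("q      tau (MF-DFA)   tau (exact)")
for qi, t_est, t_true in zip(q[::4], tau.tau[::4], oracle[::4]):
    print(f"{qi:5.1f}  {t_est:10.3f}  {t_true:10.3f}")
print(f"max |error| = {np.abs(tau.tau - oracle).max():.3f}")

spectrum = legendre_spectrum(tau)
wide = mf_dfa(cascade, q=wide_qgrid(), window_sizes=windows)
desc = spectrum_descriptors(spectrum, hq_wide=wide)
print(f"\nspectrum peak: D({desc.h_max:.3f}) = {desc.d_max:.3f}")
print(f"spectrum width Delta-h = {desc.delta_h:.3f}")
print("A width near 1 marks a strongly multifractal signal; exact")
print("monofractals of this length show widths well below 0.2.")
noise_width = delta_h(mf_dfa(generate_fgn(2**14, 0.5, seed=0), q=wide_qgrid()))
print(f"compare: Delta-h of white noise = {noise_width:.3f}")
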