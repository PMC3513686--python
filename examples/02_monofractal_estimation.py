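"""Estimate the Hurst exponent of known signals with several monofractal
methods and translate between exponent conventions.

The extended Hurst exponent H' puts both signal classes on one scale:
(0, 1) for stationary fGn, (1, 2) for non-stationary fBm, with the 1/f
boundary at 1.
"""

from fractkit import convert_exponents, dfa, generate_fgn, psd_low, ssc
from fractkit.synthgen import class_convert

noise = generate_fgn(2**13, 0.5, seed=3)        # white noise, H' = 0.5
persistent = generate_fgn(2**13, 0.8, seed=3)   # persistent fGn, H' = 0.8
brownian = class_convert(noise, "sum")          # ordinary Brownian motion, H' = 1.5

for name, ts, truth in [
    ("white noise", noise, 0.5),
    ("fGn H=0.8", persistent, 0.8),
    ("Brownian motion", brownian, 1.5),
]:
    res_ssc = ssc(ts)
    res_dfa = dfa(ts)
    res_psd, _ = psd_low(ts)
    print(
        f"{name:16s} truth H'={truth:4.1f} | "
        f"SSC {res_ssc.hurst_prime:5.2f} ({res_ssc.signal_class}) | "
        f"DFA alpha {res_dfa.exponent:5.2f} | "
        f"PSD beta {res_psd.exponent:5.2f} -> H' {res_psd.hurst_prime:5.2f}"
    )

# All three estimators agree on the H' scale; beta relates to H' as
# beta = 2H' - 1 (0 for white noise, 2 for Brownian motion):
print("\nconversions: H_fGn=0.5 -> beta", convert_exponents(0.5, "H", "beta", "fGn"),
      "| beta_fBm=2 -> H", convert_exponents(2.0, "beta", "H", "fBm"))
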