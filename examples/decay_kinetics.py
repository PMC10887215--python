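"""Fit thermal-inactivation kinetics and discriminate the decay order.

Generates two noiseless inactivation series at the standard sampling times
(0-128 min doubling grid) with the same 9.1-min half-life — one first-order
(dA/dt = -kA), one second-order (dA/dt = -kA^2) — adds 5% multiplicative
noise, and lets AICc model selection recover the generating order.
"""

from protstab import gen_decay, select_decay_model, half_life

for true_order in ("first", "second"):
    data = gen_decay(true_order, t_half=9.1, a0=1.0, sigma=0.05, rng_seed=7)
    fit = select_decay_model(data)
    interp = half_life(data, method="interpolate")
    print(
        f"true order: {true_order:<6}  selected: {fit.model_order:<6} "
        f"(AICc margin {fit.aicc_margin:.1f})  "
        f"t1/2 model {fit.half_life:.2f} min, interpolated {interp:.2f} min"
    )

print(
    "\nBoth curves lose half their activity by ~9 min, but their tails\n"
    "differ: first-order decay vanishes exponentially while second-order\n"
    "decay lingers (1/(1+t/t_half)). The AICc comparison of the two\n"
    "nonlinear fits recovers the generating law despite 5% noise; the\n"
    "interpolated half-life reads the 50% crossing directly off the series."
)
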