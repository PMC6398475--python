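"""The curve-fit models: tip binding, competition decay, FRAP recovery.

Binding of an EB protein to microtubule tips follows a one-site isotherm
I = I_max [EB] / (K_D + [EB]); competition by a second EB empties the tip
following an exponential decay in competitor concentration; and FRAP
recovery 1 - exp(-t/tau) reports the turnover time of tip-bound EB.  Each
fit below runs on synthetic data with 5% noise, so recovered parameters sit
close to, but not exactly at, the generating values.
"""

import numpy as np

from ebtip import fits, simgen

rng = np.random.default_rng(11)

conc = np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
y = 50000.0 * conc / (100.0 + conc) * (1 + rng.normal(0, 0.05, conc.size))
b = fits.fit_binding(conc, y)
print(f"binding:  K_D = {b.kd_nM:5.0f} +/- {b.kd_err_nM:.0f} nM, "
      f"I_max = {b.imax:.0f}   (generated: K_D 100 nM, I_max 50000)")

y = 6000.0 * np.exp(-conc / 1500.0) * (1 + rng.normal(0, 0.05, conc.size))
d = fits.fit_decay(conc, y)
print(f"decay:    K   = {d.K_nM:5.0f} +/- {d.K_err_nM:.0f} nM"
      f"                 (generated: K 1500 nM)")

trace = simgen.simulate_frap_trace(tau_s=2.0, noise_sd=0.05, seed=4)
f = fits.fit_frap(trace)
print(f"FRAP:     tau = {f.tau_s:5.2f} s, half-time {f.half_time_s:.2f} s "
      f"     (generated: tau 2 s)")
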