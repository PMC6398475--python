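"""Peak distance between two EB channels imaged sequentially.

Two-colour experiments acquire the channels 0.5 s apart, so a comet moving
20 nm/s appears ~10 nm displaced between them.  The analysis interpolates
2-fold in time and trims one half-frame from each channel to cancel that
shift, then measures the peak distance of the aligned, averaged profiles.
Positive distances mean the second channel sits deeper in the lattice
(farther behind the tip) -- the simulated ground truth here is 32 nm.
"""

from ebtip import comet, simgen

cfg = simgen.SimKymoConfig(channel_offsets_nm=(0.0, 32.0),
                           channel_delay_s=0.5, noise_sd=0.1,
                           duration_s=40.0, seed=7)
ch_a, ch_b = simgen.simulate_kymograph(cfg)

dist, prof_a, prof_b = comet.dual_colour_peak_distance(ch_a, ch_b)
print(f"growth speed:        {dist.growth_speed_nm_s:.1f} nm/s")
print(f"peak distance:       {dist.distance_nm:+.1f} nm "
      "(simulated +32 nm; resolution one interpolated pixel = 8.1 nm)")

raw, _, _ = comet.dual_colour_peak_distance(ch_a, ch_b, trim=False)
print(f"without correction:  {raw.distance_nm:+.1f} nm "
      "(the half-frame acquisition shift biases the estimate)")
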