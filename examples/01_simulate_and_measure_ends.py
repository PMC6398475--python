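"""Generate a synthetic microtubule movie and localise both ends per frame.

The generator renders a single microtubule growing 2 um -> 4 um -> 2 um at
50 nm per frame with stochastic dye labelling, a 130 nm Gaussian PSF and
background noise at SNR 6; the end-fitting pipeline recovers each end with
a Gauss error function.  The printed statistics compare measured lengths to
the generator's ground truth: the bias tells how accurate the method is on
average, the sd how precise a single frame is.
"""

from ebtip import mtend, simgen

cfg = simgen.SimImageConfig(labeled_fraction=0.18, target_snr=6.0, seed=1)
stack = simgen.simulate_microtubule_stack(cfg)
report = mtend.benchmark_length_accuracy([stack])

print(f"frames analysed:       {report['n_frames']} "
      f"({report['n_excluded']} excluded by the 50-200 nm sigma gate)")
print(f"length bias:           {report['mean_error_nm']:+.1f} nm "
      "(measured - true, averaged)")
print(f"length error sd:       {report['sd_error_nm']:.1f} nm "
      "(single-frame precision)")
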