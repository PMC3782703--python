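"""Clean a BOLD-like series: detrend + bandpass, nuisance regression, scrub.

The 0.001-0.1 Hz passband keeps the slow fluctuations that drive functional
connectivity; nuisance regression removes shared physiological signal; frames
with head motion above 0.2 mm (plus one neighbor each side) are deleted and
the survivors concatenated.
"""

import numpy as np

from fcloo import (
    BandpassParams,
    ScrubParams,
    dvars,
    framewise_displacement,
    nuisance_regression,
    scrub,
    simulate_motion,
    temporal_filter,
)

rng = np.random.default_rng(0)
T, tr = 300, 2.0
t = np.arange(T) * tr

# two channels: slow 0.03 Hz signal + fast 0.2 Hz contamination + drift
slow = np.sin(2 * np.pi * 0.03 * t)
fast = 0.8 * np.sin(2 * np.pi * 0.2 * t)
physio = np.cos(2 * np.pi * 0.09 * t)  # shared "physiological" signal
series = np.vstack(
    [slow + fast + 0.01 * t + 0.5 * physio,
     slow - fast + 0.4 * physio + rng.normal(0, 0.3, T)]
)

filtered = temporal_filter(series, BandpassParams(tr=tr))
gain_slow = np.sqrt((filtered[0] ** 2).mean() / ((slow + fast) ** 2).mean())
print(f"after bandpass, channel 0 keeps {100*gain_slow:.0f}% of its rms "
      "(the 0.2 Hz component and the drift are gone, the 0.03 Hz signal stays)")

resid = nuisance_regression(filtered, physio[None, :])
print(f"nuisance regression: residual variance {resid.var():.3f} "
      f"vs {filtered.var():.3f} before (never increases)")

motion = simulate_motion(T, spike_rate=0.05, seed=1)
fd = framewise_displacement(motion)
dv = dvars(resid)
print(f"sd-scaled DVARS runs {dv[1:].min():.2f}-{dv[1:].max():.2f} here; its scale "
      "is a knob (see docs/methods.md), so this example scrubs on motion alone")
clean, mask = scrub(resid, fd, np.zeros_like(fd), ScrubParams())
print(f"scrubbing: {int((fd > 0.2).sum())} frames exceeded 0.2 mm FD; "
      f"{mask.sum()} of {T} volumes retained after dropping neighbors")
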