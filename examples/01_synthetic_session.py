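"""Generate matched wet/dry synthetic motor-imagery sessions and show the
planted class structure as band power at a signature channel.

The generator emulates a three-class lower-limb imagery recording: 31
channels at 500 Hz, 30 five-second trials per class, narrow-band rhythms
on motor-area channels over 1/f background.  The dry preset only raises
the background RMS (3x), emulating gel-free electrodes.
"""

import numpy as np
from scipy.signal import welch

from mdeeg import SynthConfig, generate_pair

cfg = SynthConfig(seed=7)
wet, dry = generate_pair(cfg)
print(f"wet session: {wet.data.shape} (trials x channels x samples) @ {wet.fs} Hz")
print(f"classes: {wet.class_names}, trials per class: "
      f"{np.bincount(wet.labels).tolist()}")
print(f"background RMS ratio dry/wet: "
      f"{dry.data.std() / wet.data.std():.2f} (configured {cfg.dry_wet_ratio})")

ch, f0, bw, amp = cfg.signatures[0][0]
f, p = welch(wet.data[:, ch], fs=wet.fs, nperseg=512)
band = (f >= f0 - bw) & (f <= f0 + bw)
power = p[:, band].mean(axis=1)
for cls, name in enumerate(wet.class_names):
    print(f"  mean {f0:.0f} Hz band power at {wet.channel_names[ch]} "
          f"for class {name!r}: {power[wet.labels == cls].mean():8.2f} uV^2/Hz")
print("-> the signature class carries visibly higher band power at its "
      "channel; that contrast is what every later stage must pick up.")
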