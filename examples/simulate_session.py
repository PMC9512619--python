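"""Generate one synthetic session and look at what it contains.

The generator produces a 30-Hz behavior video with scheduled fidget
events, a drifting-grating stimulus table, a running-speed trace and
ΔF/F traces built from four response archetypes — plus a ground-truth
record that downstream analyses can be scored against.
"""

import numpy as np

from fidgetlab import synthdata

cfg = synthdata.SynthConfig(session_duration=120.0, n_fidgets=6, n_neurons=100, seed=0)
session = synthdata.generate_session(cfg, with_video=True)

print(f"frames:        {session.frames.shape}  (T, H, W), values in [0, 1]")
print(f"dff:           {session.dff.shape}  (neurons, frames)")
print(f"running speed: {session.running_speed.shape}, "
      f"{np.mean(session.running_speed > 1):.0%} of frames running")
print(f"stimulus rows: {len(session.stim_table)} "
      f"({(session.stim_table.stimulus_type == 'drifting_grating').sum()} gratings)")

events = session.truth["events"]
print(f"\ntrue fidget events ({len(events)}):")
for e in events:
    print(f"  frames {e.onset_frame:5d}-{e.offset_frame:5d}  "
          f"({e.duration_frames / cfg.fps:.2f} s)")

counts = session.truth["neurons"].type_label.value_counts()
print("\nneuron response types (drawn at the configured prevalences):")
print(counts.to_string())
# The fidget-labeled frames exactly cover the true events, so the label
# track doubles as a perfect annotation for detector training.
assert session.labels.n_fidget_frames() == sum(e.duration_frames for e in events)
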