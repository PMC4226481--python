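"""Build a RASP-F flash schedule and inspect its structure.

Each trial spells one letter: a 2 s countdown, then 10 sequences of 12
flashes (135 ms flash + 50 ms gap).  In every sequence each of the 36
symbols appears in exactly two flash sets; virtual rows carry the
user's own face, virtual columns other faces.
"""

import collections

import numpy as np

from erpspell import build_schedule, target_to_target_intervals

schedule = build_schedule("RASP_F", "KOREA", rng=7)
print(f"condition: {schedule.condition}, targets: "
      f"{''.join(schedule.targets)}")
print(f"{len(schedule.events)} flash events "
      f"({schedule.n_trials} trials x 10 sequences x 12 flashes)\n")

print("first sequence of trial 0 (target K):")
for e in schedule.events[:12]:
    mark = "*" if e.is_target else " "
    print(f"  {e.onset:7.3f} s  {''.join(sorted(e.letters))}  "
          f"{e.stimulus_class:>13s} {mark}")

ttis = [t for t in target_to_target_intervals(schedule) if t is not None]
hist = collections.Counter(min(t, 5) for t in ttis)
print("\ntarget-to-target intervals (0 = double flash, 5 = >=5):")
for k in sorted(hist):
    print(f"  TTI {k}: {hist[k]:3d} target flashes")
print("\nA TTI of 0 means the target set flashed twice in a row; the"
      "\nforward model attenuates the P300 for such flashes.")
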