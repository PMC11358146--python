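"""Parse the music-run stimulus schedule and label scanner volumes.

The run is 13 classical pieces (3 happy, 3 sad, 7 neutral) separated by 2 s of
silence.  Each fMRI volume (TR = 2 s) is assigned the condition of the piece
containing its temporal midpoint; neutral pieces that directly follow an
emotional piece also receive a derived carry-over label.
"""

import collections

from musicstates import label_timepoints, table1_schedule

schedule = table1_schedule()
print(f"{len(schedule.events)} pieces, inter-piece silence {schedule.silence_s} s, "
      f"run ends at {schedule.end_s:.0f} s")

labels = label_timepoints(schedule, tr_s=2.0, n_volumes=254)
print("volumes per condition:", dict(collections.Counter(labels.labels)))
print("derived labels:       ", dict(collections.Counter(labels.derived)))
# the counts sum to 254: every volume gets exactly one condition, and the
# derived labels mark the neutral volumes played right after sad/happy music
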