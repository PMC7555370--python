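"""Generate a synthetic neonatal EEG with scheduled amplitude states.

Builds a 5-min, 9-lead recording that walks through the amplitude states of
hypoxic-ischemic encephalopathy — continuous background, an isoelectric
stretch, a 7 Hz spike-and-wave seizure — and prints the epoch amplitude of
each state next to its clinical category boundary.
"""

from neoqeeg.scoring import epoch_amplitude
from neoqeeg.syngen import Segment, StateSchedule, compose_recording

schedule = StateSchedule([
    Segment("continuous", 0, 60),
    Segment("isoelectric", 60, 60),
    Segment("seizure", 120, 60, rhythm_hz=7.0),
    Segment("continuous", 180, 120),
])
recording, truth = compose_recording(schedule, n_leads=9, seed=1)

print(f"{recording.n_leads} leads, {recording.duration_s:.0f} s at "
      f"{recording.fs:.0f} Hz; montage: {', '.join(recording.lead_names)}")
print(f"ground-truth seizure intervals: {truth.seizure_intervals}")
for start, end, label in [(10, 50, "continuous"), (70, 110, "isoelectric")]:
    amp = epoch_amplitude(recording.slice_time(start, end))
    print(f"{label:12s} epoch amplitude {amp:6.1f} uV peak-to-peak "
          f"({'>25 uV: normal background' if amp > 25 else '<10 uV: severe depression'})")

# recording.to_csv("synthetic_eeg.csv")  # plain-matrix export, µV
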