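"""Simulate one subject and write the recording as EDF+ with an events TSV.

Run: python examples/simulate_subject.py
"""

from pathlib import Path

from stereoattn import (GroundTruth, generate_subject,
                        generate_trial_schedule, standard_montage)
from stereoattn.design import schedule_to_events_frame
from stereoattn.io import read_edf, write_edf, write_events_tsv

out = Path("scratch/example_subject")
out.mkdir(parents=True, exist_ok=True)

schedule = generate_trial_schedule(40, (20, 10, 10), seed=1)
rec, artifacts, presses = generate_subject(schedule, GroundTruth(),
                                           standard_montage(), seed=1)
print(f"simulated {rec.n_samples} samples at {rec.rate:.0f} Hz on "
      f"{len(rec.ch_names)} channels")
print(f"{schedule.n_events} coherent-motion events, {len(presses)} button "
      f"presses, {len(artifacts)} ocular artifacts")

edf = write_edf(out / "sub-01_eeg.edf", rec)
write_events_tsv(out / "sub-01_events.tsv", schedule_to_events_frame(schedule))
back = read_edf(edf)
# the writer zero-pads the last record to a full second
err = abs(back.data[:, :rec.n_samples] - rec.data).max()
print(f"EDF+ round trip: max absolute error {err:.4f} uV "
      "(16-bit quantization)")
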