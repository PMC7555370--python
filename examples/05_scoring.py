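"""Ordinal scoring: hourly EEG scores with seizure bonus, neuropathology.

Scores synthetic 10-min epochs of each background state through the default
amplitude table (+2 for a seizure in the hour), then scores two 40-field
cortical injury grids through the 0-9 neuropathology table and computes a
subcortical damaged-neuron percentage.
"""

from neoqeeg.scoring import cortical_score, damaged_percentage, score_eeg_epoch
from neoqeeg.syngen import gen_background_eeg, gen_field_grid

print("EEG epoch scores (0 = continuous high-amplitude ... 3 = isoelectric):")
for state, rms in [("continuous", 10.0), ("discontinuous", 2.5),
                   ("suppressed", 1.0), ("isoelectric", 0.12)]:
    epoch = gen_background_eeg(600, n_leads=2, amplitude_uv_rms=rms, seed=4)
    base = score_eeg_epoch(epoch)
    with_seizure = score_eeg_epoch(epoch, seizure_present=True)
    print(f"  {state:13s} -> {base}   (with a seizure that hour: {with_seizure})")

mild, _ = gen_field_grid(40, {"scattered": 0.10, "none": 0.90}, seed=5)
severe, _ = gen_field_grid(40, {"panlaminar": 0.60, "grouped": 0.40}, seed=5)
print(f"mild grid (4/40 scattered)      -> cortical score {cortical_score(mild)}")
print(f"severe grid (24/40 panlaminar)  -> cortical score {cortical_score(severe)}")
print(f"damaged neurons 250/500         -> {damaged_percentage(250, 500):.0f}%")
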