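"""EEG conditioning and feature extraction for fusion analysis.

Simulates a recording with spike-wave events and a 10 Hz rhythm,
re-references, bandpass filters, and extracts the two fusion features:
event onsets (with bad-block exclusion) and TR-locked alpha-band power.
"""

import numpy as np

import neurofuse as nf
from neurofuse import eeg_features as ef

eeg = nf.simulate_eeg(channels=8, duration_s=120, srate_hz=250,
                      spike_times_s=[20.0, 55.0, 90.0],
                      bands=((10.0, 8.0),), seed=3)
eeg.bad_blocks.append((50.0, 60.0))  # pretend an artifact was marked here

eeg = ef.rereference(eeg, "average")
eeg = ef.filter_eeg(eeg, 1.0, 30.0, method="fir")

onsets = ef.extract_onsets(eeg, ["GSWD"], exclude_bad=True)
print("spike onsets kept:", [float(t) for t in onsets.times_s],
      "(the 55 s event fell in the bad block)")

power = ef.extract_band_power(eeg, (8, 12), window_s=2.0, step_s=2.0)
print(f"TR-locked alpha power: {len(power)} windows, "
      f"median {np.nanmedian(power.values):.0f} uV^2, "
      f"{int(np.isnan(power.values).sum())} flagged missing in bad blocks")

# The onset series drives discharge-related mapping; the per-TR band
# power series (one value per fMRI volume at TR = 2 s) feeds continuous
# EEG-informed regressors.  Missing windows are flagged, never zeroed.
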