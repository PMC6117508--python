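"""Local multimodal serial analysis: CCA fusion with a data-driven HRF.

Couples a 3x3x3 block of voxels to a spike-onset series through a 5 s
hemodynamic response, runs the per-voxel lagged-CCA fusion, and prints
the recovered response latency at the block center.
"""

import numpy as np

import neurofuse as nf
from neurofuse.eeg_features import FeatureSeries

tr, T = 2.0, 150
onsets = np.arange(8.0, T * tr - 30.0, 24.0)
feat = FeatureSeries("onsets", onsets, np.ones(onsets.size))

k = nf.hrf_kernel("single_gamma", dt=tr / 16, peak_s=5.0)
beta = 1.0 / nf.build_regressor(feat, k, tr, T).std()
block = [(x, y, z) for x in (1, 2, 3) for y in (1, 2, 3) for z in (1, 2, 3)]
vol, mask, _ = nf.simulate_bold((5, 5, 5), T=T, tr=tr, seed=20,
                                activation_voxels=block, true_peak_s=5.0,
                                true_beta=beta, event_onsets_s=onsets)

res = nf.lmsa_map(vol, feat, tr=tr, mask=mask, max_lag_trs=6, alpha=0.05)
vr = res.voxel_results[(2, 2, 2)]
print(f"block center: canonical r = {vr.canonical_corr:.3f}, "
      f"CCA p = {vr.p_cca:.2e}, regression T = {vr.t_value:.2f}")
times, weights = nf.estimated_hrf(vr)
print("estimated HRF over lags (s -> weight):",
      {f"{t:g}": round(float(w), 2) for t, w in zip(times, weights)})
print(f"estimated peak latency = {times[np.argmax(weights)]:g} s "
      "(true value 5 s)")
print(f"significant voxels: {int(res.significance.sum())} of {mask.count}")

# The CCA lag weights act as a voxel-specific HRF estimate: no shape is
# assumed, yet the peak lands within one TR of the planted 5 s latency.
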