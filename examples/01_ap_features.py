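"""Extract action-potential morphology from a synthetic pacemaker trace.

Generates a 10 s noiseless spontaneous AP train with known geometry, runs
the segmentation/feature chain, and compares each recovered parameter with
the generator's ground truth.
"""

import sanpace as sp
from sanpace.ap_features import extract_cycles, summarize_window

gt = sp.APGroundTruth(noise_sd_mV=0.0)
trace, truth = sp.generate_ap_train(gt, duration_s=10.0)
summary = summarize_window(extract_cycles(trace), window="baseline")
t0 = truth.iloc[0]

print(f"analyzed {summary.n_cycles} cycles "
      f"({summary.n_invalid} rejected)")
rows = [
    ("firing rate (bpm)", summary.firing_rate_bpm, t0.rate_bpm),
    ("MDP (mV)", summary.mdp_mV, t0.mdp_mV),
    ("TOP (mV)", summary.top_mV, t0.top_op_mV),
    ("amplitude (mV)", summary.amplitude_mV, t0.amplitude_mV),
    ("APD50 (ms)", summary.apd50_ms, t0.apd50_ms),
    ("EDDR (mV/ms)", summary.eddr_mV_per_ms, t0.eddr_mV_per_ms),
    ("max dV/dt (mV/ms)", summary.dvdt_max_mV_per_ms,
     t0.dvdt_max_mV_per_ms),
]
print(f"{'parameter':<20}{'measured':>12}{'truth':>12}")
for name, got, want in rows:
    print(f"{name:<20}{got:>12.4f}{want:>12.4f}")
print("\nEach row should agree to interpolation precision: the extractor "
      "is reading back the waveform the generator constructed.")
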