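"""Simulate a small paired scalp/intracranial cohort and inspect its properties.

Builds three subjects with annotated interictal discharges, then prints the
per-subject event counts and the event-window signal-to-noise ratios of both
modalities.  The intracranial channels should see every event clearly, while
only roughly the configured fraction of events rises above the scalp noise.
"""

import numpy as np

from iedgan import SynthesisConfig, event_window_snr, simulate_subject

cfg = SynthesisConfig(n_subjects=3, duration_s=200.0, n_ieds_per_subject=80,
                      visibility_fraction=0.15, seed=7)

for i in range(cfg.n_subjects):
    rec, gt = simulate_subject(cfg, i, return_clean=True)
    snr_scalp = event_window_snr(gt.seeg_clean, rec.seeg.data - gt.seeg_clean,
                                 rec.ied_peaks)
    snr_ieeg = event_window_snr(gt.ieeg_clean, rec.ieeg.data - gt.ieeg_clean,
                                rec.ied_peaks)
    print(f"{rec.subject_id}: {len(rec.ied_peaks)} IEDs | "
          f"median window SNR  iEEG={np.median(snr_ieeg):.2f}  "
          f"sEEG={np.median(snr_scalp):.2f} | "
          f"scalp-visible fraction={np.mean(snr_scalp > 1):.2f}")

# Typical output: iEEG SNR ~6 (every event visible intracranially), scalp SNR
# well below 1 for most events, with ~15% rising above the scalp noise floor —
# the regime in which scalp-only IED reading misses most discharges.
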