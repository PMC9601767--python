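"""Reproduce the calibration procedure on labelled synthetic RSA profiles.

The decision threshold is the pooled-F1 maximiser; the smoothing window is
grid-searched over odd sizes 1-49, scoring each window by its best
attainable F1 (Fmax).  The block construction creates a plateau of
near-optimal windows around the disorder block length, the analogue of the
20-30 residue plateau reported on real benchmark data.
"""

import warnings

import numpy as np

import afdisorder as afd
from afdisorder.calibration import optimize_threshold, window_grid_search

profiles, labels = afd.noisy_block_profiles(20, seed=1)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")      # even windows are skipped
    search = window_grid_search(profiles, labels, range(1, 51))

print(f"best window: {search.best_window}  (F1 {search.best_metric:.3f})")
best_f1 = search.best_metric
plateau = [w for w, f in search.metric_by_window if f >= best_f1 - 0.005]
print(f"plateau (within 0.005 of the optimum): {plateau}")
print("F1 by window:",
      "  ".join(f"{w}:{f:.3f}" for w, f in search.metric_by_window[:10]), "...")

# threshold calibration at the selected window
smoothed = np.concatenate([afd.windowed_mean(p, search.best_window)
                           for p in profiles])
pooled_labels = np.concatenate(labels)
res = optimize_threshold(smoothed, pooled_labels)
print(f"\nthreshold at window {search.best_window}: "
      f"{res.best_threshold:.3f} (F1 {res.best_metric:.3f})")
print("A small window under-smooths the noisy accessibility signal, a very "
      "large one washes\nout ~20-residue disorder blocks; the F1 curve is "
      "flat in between, so any window in the\nplateau is a reasonable choice.")
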