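"""Cross-subject lagged correlation of band-limited phase trajectories.

Every trial is reduced to the cosine of its electrode-averaged, band-collapsed
phase; Pearson correlations over +-1.5 s lags are averaged over all unordered
within-stimulus trial pairs and compared with a trial/stimulus-shuffled null.
Entrained data peaks at lag zero and beats the null there. Runtime: about a
minute (the 0.05-s lag grid is the expensive part).
"""

import warnings

import numpy as np

from phasedecode import (
    LAG_WINDOW,
    compute_tfr,
    fit_window,
    generate_dataset,
    run_lag_analysis,
    small_config,
)

ds = generate_dataset(small_config(seed=1))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pt = compute_tfr(ds, fit_window(ds, LAG_WINDOW))

res = run_lag_analysis(pt, n_surrogates=100, alpha=0.01, seed=3)
mid = len(res.lags) // 2
for bi, band in enumerate(res.bands):
    obs0 = res.mean_abs_corr[bi, mid]
    null99 = np.quantile(res.surrogate_corr[:, bi, mid], 0.99)
    print(f"band {band[0]:g}-{band[1]:g} Hz ({res.n_pairs} pairs/stimulus): "
          f"lag-0 mean |r| = {obs0:.4f}, null 99th pct = {null99:.4f}, "
          f"significant at lag 0: {bool(res.significant_mask[bi, mid])}")
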