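"""Independent brute-force reference implementations used by the tests."""

import numpy as np


def brute_xcorr(x, y, max_lag, min_overlap=1.0):
    """O(n^2) direct-sum normalized cross-correlation peak.

    Evaluates the zero-mean, unit-energy correlation at every integer lag
    one dot product at a time; returns (r, lag_seconds) of the largest
    magnitude.  Deliberately naive — the oracle for the fast implementation.
    """
    sr = x.sample_rate
    n_min = max(int(round(min_overlap * sr)), 2)
    best = None
    for lag in range(-int(round(max_lag * sr)), int(round(max_lag * sr)) + 1):
        a, b = max(0, lag), min(len(x), len(y) + lag)
        if b - a < n_min:
            continue
        xs = x.samples[a:b] - x.samples[a:b].mean()
        ys = y.samples[a - lag : b - lag] - y.samples[a - lag : b - lag].mean()
        denom = np.sqrt((xs @ xs) * (ys @ ys))
        r = float(xs @ ys / denom) if denom > 0 else 0.0
        if best is None or abs(r) > abs(best[0]):
            best = (r, -lag / sr)  # positive lag: y delayed relative to x
    return best
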