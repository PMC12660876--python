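"""Independent test oracles shared across test modules."""

import numpy as np


def exhaustive_peaks(values, height=0.7, prominence=0.125):
    """Peak counter by exhaustive traversal.

    Scans every interior local maximum of the min-max-normalized curve and
    computes its topographic prominence by walking outward to the nearest
    higher point on each side, tracking the lowest saddle; the prominence is
    the drop to the higher of the two saddles. Independent of
    scipy.signal.find_peaks.
    """
    f = np.asarray(values, float)
    f = (f - f.min()) / (f.max() - f.min())
    n = f.size
    count = 0
    for i in range(1, n - 1):
        left = f[i - 1]
        j = i
        while j + 1 < n and f[j + 1] == f[i]:
            j += 1
        if j == n - 1:
            continue
        if f[i] > left and f[i] > f[j + 1]:
            if f[i] < height:
                continue

            def side_min(indices):
                lo = f[i]
                for k in indices:
                    if f[k] > f[i]:
                        return lo
                    lo = min(lo, f[k])
                return lo

            left_min = side_min(range(i - 1, -1, -1))
            right_min = side_min(range(j + 1, n))
            if f[i] - max(left_min, right_min) >= prominence:
                count += 1
    return count
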