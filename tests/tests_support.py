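"""Independent reference implementations used as test oracles."""

import numpy as np


def naive_median(x, w):
    """Sort-based running median with reflected edges (odd window)."""
    x = np.asarray(x, dtype=float)
    half = w // 2
    padded = np.concatenate([x[1 : half + 1][::-1], x, x[-half - 1 : -1][::-1]])
    return np.array(
        [np.sort(padded[i : i + w])[half] for i in range(x.size)]
    )
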