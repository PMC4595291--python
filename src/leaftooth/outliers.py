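"""3-sigma (PauTa) outlier rejection.

The classical PauTa criterion declares a measurement abnormal when it deviates
from the sample mean by strictly more than three standard deviations.  The
standard deviation is the population one (divide by n), and filtering is a
single pass: mean and sigma are computed once over all values, outliers are
removed, and no re-estimation follows.  A consequence worth knowing: among n
values of which n-1 coincide and one is displaced by any amount d > 0, the
displaced value is rejected iff sqrt(n-1) > 3, i.e. iff n >= 11.
"""

from __future__ import annotations

import numpy as np


def pauta_keep_mask(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Return (keep_mask, mu, sigma) for one-dimensional ``values``.

    A value v is kept iff |v - mu| <= 3*sigma (strict ">" triggers removal,
    so equality with the 3-sigma boundary preserves the value).  With
    sigma == 0 nothing is ever removed.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("pauta_keep_mask expects a 1-D array")
    if v.size == 0:
        return np.zeros(0, dtype=bool), float("nan"), float("nan")
    mu = float(v.mean())
    sigma = float(v.std())  # population (ddof=0)
    keep = np.abs(v - mu) <= 3.0 * sigma
    return keep, mu, sigma
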