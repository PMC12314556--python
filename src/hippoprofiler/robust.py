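"""Robust location/scale helpers shared across the pipeline.

All outlier rules and the modified robust Z' in this package are defined on
the *raw* median absolute deviation — the 1.4826 normal-consistency factor
is never applied, so "2 MADs" means twice the raw MAD.
"""

from __future__ import annotations

import numpy as np

#: Median absolute deviation of a standard normal distribution. Used by the
#: synthetic generator to express planted shifts in control-MAD units.
NORMAL_MAD = 0.6744897501960817


def mad(values, axis=None):
    """Raw median absolute deviation, ``median(|x - median(x)|)``.

    Parameters
    ----------
    values : array-like
    axis : int, optional
        Axis along which to reduce. ``None`` reduces over all elements.
    """
    a = np.asarray(values, dtype=float)
    if axis is None:
        return float(np.median(np.abs(a - np.median(a))))
    med = np.median(a, axis=axis, keepdims=True)
    return np.median(np.abs(a - med), axis=axis)
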