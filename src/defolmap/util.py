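"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round to the nearest integer with ties away from zero.

    Symmetric around zero (unlike banker's rounding), which keeps scaled
    index values and reported thresholds deterministic and sign-symmetric.
    Returns a float array (or scalar) of integral values.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if out.ndim == 0:
        return float(out)
    return out


def round_to_multiple(x, base):
    """Round ``x`` to the nearest multiple of ``base``, ties away from zero."""
    return round_half_away(np.asarray(x, dtype=float) / base) * base
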