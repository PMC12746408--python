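"""Conversions between relaxation times and rates.

Convention used throughout the package: relaxation times are expressed in
milliseconds at the API boundary, relaxation rates in s^-1 internally, and
ADC always in 10^-3 mm^2/s (the conventional display unit).  This module
owns the single factor-of-1000 conversion; nothing else in the package
multiplies or divides by 1000 for time/rate purposes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rate_from_time", "time_from_rate"]


def rate_from_time(t_ms):
    """Relaxation rate in s^-1 from a relaxation time in ms.

    R [s^-1] = 1000 / T [ms].  Involutive with :func:`time_from_rate`.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if np.any(t_ms <= 0):
        raise ValueError("relaxation time must be positive")
    out = 1000.0 / t_ms
    return float(out) if out.ndim == 0 else out


def time_from_rate(r_per_s):
    """Relaxation time in ms from a rate in s^-1 (T = 1000 / R)."""
    r_per_s = np.asarray(r_per_s, dtype=float)
    if np.any(r_per_s <= 0):
        raise ValueError("relaxation rate must be positive")
    out = 1000.0 / r_per_s
    return float(out) if out.ndim == 0 else out
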