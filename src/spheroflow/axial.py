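"""Axial (180-degree-periodic) circular statistics.

Fiber orientations are axial quantities: an angle theta and theta + 180 deg
describe the same fiber. All averaging therefore happens on doubled angles
(the standard trick: map theta -> 2*theta, average on the circle, halve).
Angles are handled in degrees throughout the public API, matching the
convention that 90 deg is the channel flow axis.
"""

from __future__ import annotations

import numpy as np


def wrap_axial(angles_deg):
    """Wrap angles into [0, 180)."""
    return np.mod(angles_deg, 180.0)


def axial_diff(a_deg, b_deg):
    """Smallest absolute axial difference between two orientations, in [0, 90]."""
    d = np.mod(np.asarray(a_deg, dtype=float) - b_deg, 180.0)
    return np.minimum(d, 180.0 - d)


def axial_mean(angles_deg, weights=None):
    """Weighted axial circular mean via angle doubling, in [0, 180).

    The mean of {10, 170} is 0 (the two orientations straddle the seam),
    not the arithmetic 90.
    """
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    if weights is None:
        c, s = np.cos(a).sum(), np.sin(a).sum()
    else:
        w = np.asarray(weights, dtype=float)
        c, s = (w * np.cos(a)).sum(), (w * np.sin(a)).sum()
    return np.degrees(np.arctan2(s, c)) / 2.0 % 180.0


def axial_coherence(angles_deg, weights=None):
    """Resultant length of the doubled-angle vectors, in [0, 1].

    1 means perfectly aligned orientations, 0 an isotropic (or perfectly
    balanced) set.
    """
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    if weights is None:
        n = a.size
        if n == 0:
            return 0.0
        c, s = np.cos(a).sum(), np.sin(a).sum()
        return float(np.hypot(c, s) / n)
    w = np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0:
        return 0.0
    c, s = (w * np.cos(a)).sum(), (w * np.sin(a)).sum()
    return float(np.hypot(c, s) / tot)
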