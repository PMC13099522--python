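"""Angle helpers shared across the package.

All angles are in degrees, measured counterclockwise from the +x axis,
normalized to the half-open interval (-180, +180].
"""

from __future__ import annotations

import numpy as np


def wrap_angle(angle):
    """Wrap an angle (scalar or array) into (-180, +180] degrees."""
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def heading_unit(heading_deg):
    """Unit vector(s) for heading(s) in degrees: returns (ux, uy)."""
    rad = np.deg2rad(heading_deg)
    return np.cos(rad), np.sin(rad)
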