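"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def elbow_index(x: np.ndarray, y: np.ndarray) -> tuple[int, bool]:
    """Elbow of a decreasing curve by maximum perpendicular distance.

    Returns (index, degenerate): the index of the curve point farthest from
    the chord joining the endpoints.  ``degenerate`` is set when the curve
    is (numerically) flat or monotone-increasing so no meaningful elbow
    exists; the first index is returned in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return 0, True
    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y.max()), 1.0):
        return 0, True
    # normalize both axes so the perpendicular distance is scale-free
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y[0]) / span
    chord = np.array([xn[-1] - xn[0], yn[-1] - yn[0]])
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([xn - xn[0], yn - yn[0]])
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(np.argmax(dist)), False
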