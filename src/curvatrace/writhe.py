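"""Writhing number of a polygonal C-alpha trace.

The writhe Wr of a curve is the Gauss double integral of the signed crossing
density over all pairs of curve points; for a polygon it reduces to a double
sum of closed-form solid-angle contributions over segment pairs.  Here it is
evaluated over a five-residue window centred on each residue, giving a
signed, handedness-aware "pseudo-curvature" of the local backbone: unlike the
Frenet curvature (always >= 0) it is positive for right-handed coiling and
negative for left-handed coiling.

The per-pair contribution uses the exact solid-angle formula of Klenin &
Langowski; the sign convention is the standard knot-theory one (right-handed
crossings positive), under which an alpha-helix window has Wr > 0.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateSegmentError, UndefinedWindowError

__all__ = ["WritheWindow", "segment_pair_writhe", "writhe_at"]

WINDOW_HALF = 2  # five-residue window: center +/- 2
_EPS_LEN = 1e-9
_EPS_PLANAR = 1e-12


def segment_pair_writhe(seg_a, seg_b) -> float:
    """Gauss-integral contribution of one ordered pair of directed segments.

    Parameters are segments given as pairs of 3D points ``(start, end)`` in
    angstrom.  Returns the signed solid angle over 4*pi spanned by the pair
    (the exact value of the double Gauss integral over both segments);
    antisymmetric under reversing either segment's direction.

    Coplanar pairs contribute exactly 0.  Segments of (near-)zero length
    raise :class:`DegenerateSegmentError`.
    """
    p1, p2 = (np.asarray(p, dtype=float) for p in seg_a)
    p3, p4 = (np.asarray(p, dtype=float) for p in seg_b)
    r12 = p2 - p1
    r34 = p4 - p3
    if np.linalg.norm(r12) < _EPS_LEN or np.linalg.norm(r34) < _EPS_LEN:
        raise DegenerateSegmentError(
            "degenerate segment: writhe segment shorter than 1e-9 angstrom"
        )
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2

    # coplanarity (includes one segment lying in the plane of the other):
    # zero crossing density, exactly zero contribution
    sign_det = float(np.cross(r34, r12) @ r13)
    if abs(sign_det) < _EPS_PLANAR:
        return 0.0

    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    normals = []
    for n in (n1, n2, n3, n4):
        norm = np.linalg.norm(n)
        if norm < _EPS_PLANAR:
            return 0.0
        normals.append(n / norm)
    n1, n2, n3, n4 = normals
    omega = (
        math.asin(float(np.clip(n1 @ n2, -1.0, 1.0)))
        + math.asin(float(np.clip(n2 @ n3, -1.0, 1.0)))
        + math.asin(float(np.clip(n3 @ n4, -1.0, 1.0)))
        + math.asin(float(np.clip(n4 @ n1, -1.0, 1.0)))
    )
    return omega * math.copysign(1.0, sign_det) / (4.0 * math.pi)


class WritheWindow:
    """Five consecutive C-alpha positions around a central residue."""

    def __init__(self, center_residue: int, vertices) -> None:
        vertices = np.asarray(vertices, dtype=float)
        if vertices.shape != (2 * WINDOW_HALF + 1, 3):
            raise ValueError("a writhe window needs exactly 5 vertices")
        self.center_residue = int(center_residue)
        self.vertices = vertices

    @property
    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Four directed edges joining consecutive vertices."""
        v = self.vertices
        return [(v[k], v[k + 1]) for k in range(len(v) - 1)]

    def writhe(self) -> float:
        """Polygonal writhe: 2 * sum over non-adjacent ordered pairs (i < j).

        Adjacent edge pairs share a vertex and are straight, so their Gauss
        contribution is identically zero; they are excluded from the sum
        (never double counted).
        """
        segs = self.segments
        total = 0.0
        for i in range(len(segs)):
            for j in range(i + 2, len(segs)):
                total += segment_pair_writhe(segs[i], segs[j])
        return 2.0 * total


def writhe_at(trace, center_index: int) -> float:
    """Writhe of the five-residue window centred at ``center_index``.

    ``trace`` is the (n, 3) array of one contiguous segment's C-alpha
    positions.  The window must fit inside the segment (at least two residues
    on each side); otherwise the descriptor is undefined and
    :class:`UndefinedWindowError` is raised.  The value depends only on the
    five positions ``center_index - 2 .. center_index + 2``.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    c = int(center_index)
    if c - WINDOW_HALF < 0 or c + WINDOW_HALF >= n:
        raise UndefinedWindowError(
            f"window undefined: residue index {c} needs {WINDOW_HALF} "
            f"neighbours on each side within the segment (length {n})"
        )
    window = WritheWindow(c, trace[c - WINDOW_HALF : c + WINDOW_HALF + 1])
    return window.writhe()
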