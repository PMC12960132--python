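"""Built-in symmetric landmark template face.

Coordinates are in mm, right-handed: +x toward the subject's anatomical
right, +y superior, +z anterior.  Midline landmarks sit exactly at x=0 and
bilateral landmarks are stored for the right side; the left-side point is
the mirror image across x=0.  The geometry is a schematic adult-scale face
(interlandmark spans in the normal human range), used as the base shape
that the synthetic-cohort generator rescales per subject.
"""

from __future__ import annotations

import numpy as np

# 19 midline landmark codes, top of face to bottom.
MEDIAL_CODES: tuple[str, ...] = (
    "tri", "mf", "g", "n", "se", "mnb", "prn", "c", "sn", "mp",
    "ls", "sto", "li", "sl", "pg", "gn", "me", "mc", "sm",
)

# 25 paired landmark codes (right-side coordinates stored below).
BILATERAL_CODES: tuple[str, ...] = (
    "en", "ex", "ps", "pi", "os", "or", "so", "zy", "ch", "al",
    "ac", "sbal", "cph", "io", "t", "pra", "sa", "sba", "pa",
    "obs", "obi", "go", "ft", "eu", "cdl",
)

MEDIAL_POINTS: dict[str, np.ndarray] = {
    "tri": np.array([0.0, 105.0, 80.0]),
    "mf":  np.array([0.0, 90.0, 88.0]),
    "g":   np.array([0.0, 62.0, 98.0]),
    "n":   np.array([0.0, 55.0, 95.0]),
    "se":  np.array([0.0, 48.0, 94.0]),
    "mnb": np.array([0.0, 35.0, 100.0]),
    "prn": np.array([0.0, 15.0, 118.0]),
    "c":   np.array([0.0, 9.0, 110.0]),
    "sn":  np.array([0.0, 5.0, 103.0]),
    "mp":  np.array([0.0, -1.0, 104.0]),
    "ls":  np.array([0.0, -7.0, 105.0]),
    "sto": np.array([0.0, -13.0, 102.0]),
    "li":  np.array([0.0, -19.0, 103.0]),
    "sl":  np.array([0.0, -26.0, 98.0]),
    "pg":  np.array([0.0, -45.0, 100.0]),
    "gn":  np.array([0.0, -60.0, 92.0]),
    "me":  np.array([0.0, -64.0, 84.0]),
    "mc":  np.array([0.0, -52.0, 97.0]),
    "sm":  np.array([0.0, -63.0, 70.0]),
}

RIGHT_POINTS: dict[str, np.ndarray] = {
    "en":   np.array([17.0, 42.0, 90.0]),
    "ex":   np.array([43.5, 41.0, 82.0]),
    "ps":   np.array([30.0, 46.0, 88.0]),
    "pi":   np.array([30.0, 37.0, 88.0]),
    "os":   np.array([30.0, 52.0, 90.0]),
    "or":   np.array([30.0, 32.0, 87.0]),
    "so":   np.array([28.0, 56.0, 92.0]),
    "zy":   np.array([65.0, 25.0, 45.0]),
    "ch":   np.array([25.0, -13.0, 96.0]),
    "al":   np.array([17.0, 8.0, 100.0]),
    "ac":   np.array([19.0, 10.0, 96.0]),
    "sbal": np.array([12.0, 3.0, 100.0]),
    "cph":  np.array([5.0, -5.0, 105.0]),
    "io":   np.array([30.0, 28.0, 86.0]),
    "t":    np.array([70.0, 30.0, 10.0]),
    "pra":  np.array([72.0, 32.0, 8.0]),
    "sa":   np.array([68.0, 55.0, 5.0]),
    "sba":  np.array([70.0, 8.0, 8.0]),
    "pa":   np.array([75.0, 30.0, -10.0]),
    "obs":  np.array([71.0, 40.0, 2.0]),
    "obi":  np.array([69.0, 5.0, 5.0]),
    "go":   np.array([55.0, -35.0, 30.0]),
    "ft":   np.array([52.0, 60.0, 70.0]),
    "eu":   np.array([72.0, 70.0, 0.0]),
    "cdl":  np.array([60.0, 10.0, 15.0]),
}


def template_points() -> dict[tuple[str, str | None], np.ndarray]:
    """Full symmetric template as a (code, side) -> xyz mapping."""
    pts: dict[tuple[str, str | None], np.ndarray] = {}
    for code, p in MEDIAL_POINTS.items():
        pts[(code, None)] = p.copy()
    mirror = np.array([-1.0, 1.0, 1.0])
    for code, p in RIGHT_POINTS.items():
        pts[(code, "R")] = p.copy()
        pts[(code, "L")] = p * mirror
    return pts
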