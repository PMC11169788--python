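"""AHA 16-segment model maps.

The left ventricle is divided into 16 segments (the 17-segment model
without the apical cap): segments 1-6 basal, 7-12 mid-ventricular, 13-16
apical. Septal segments are those adjacent to the interventricular septum;
the remainder form the free wall. The maps are fixed here in one place and
used for slice-level (base-to-apex) and wall-class groupings.
"""

from __future__ import annotations

SEGMENTS = tuple(range(1, 17))

SLICE_OF_SEGMENT = {
    **{s: "basal" for s in range(1, 7)},
    **{s: "mid" for s in range(7, 13)},
    **{s: "apical" for s in range(13, 17)},
}

# Anteroseptal/inferoseptal segments (2, 3, 8, 9) and the apical septum (14).
SEPTAL_SEGMENTS = frozenset({2, 3, 8, 9, 14})

WALL_CLASS_OF_SEGMENT = {
    s: ("septal" if s in SEPTAL_SEGMENTS else "free_wall") for s in SEGMENTS
}

SLICE_ORDER = ("basal", "mid", "apical")


def segments_of_slice(slice_name: str) -> tuple[int, ...]:
    return tuple(s for s in SEGMENTS if SLICE_OF_SEGMENT[s] == slice_name)
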