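"""Voxel vocabulary for the 16-voxel pontine/cerebellar CSI grid.

The analysis grid comprises six voxels in the right pons (R1-R6), six in the
left pons (L1-L6) and four reference voxels in the cerebellum (C1-C4).  Row
numbering follows the gray-matter gradient of the pons: rows 5/6 are the most
rostral, white-matter-rich rows (~12 %GM), rows 1/2 the most caudal,
gray-matter-rich rows (~63 %GM); the cerebellar voxels are predominantly
gray matter (~90 %GM).
"""

from __future__ import annotations

PONS_RIGHT = ("R1", "R2", "R3", "R4", "R5", "R6")
PONS_LEFT = ("L1", "L2", "L3", "L4", "L5", "L6")
CEREBELLUM = ("C1", "C2", "C3", "C4")

PONS_VOXELS = PONS_RIGHT + PONS_LEFT
ALL_VOXELS = PONS_VOXELS + CEREBELLUM

#: Display bands of the voxel grid, ordered from most WM-rich pons band to the
#: cerebellum.  Mean %GM is expected to increase monotonically along this order.
BANDS = (
    ("R6", "R5", "L5", "L6"),
    ("R4", "R3", "L3", "L4"),
    ("R2", "R1", "L1", "L2"),
    CEREBELLUM,
)

REGIONS = {v: ("cerebellum" if v.startswith("C") else "pons") for v in ALL_VOXELS}

GROUPS = ("control", "low_fatigue", "high_fatigue")


def region_of(voxel: str) -> str:
    """Return ``"pons"`` or ``"cerebellum"`` for a voxel label."""
    try:
        return REGIONS[voxel]
    except KeyError:
        raise ValueError(
            f"unknown voxel label {voxel!r}; expected one of {', '.join(ALL_VOXELS)}"
        ) from None
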