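"""Image-scale constants shared across the pipeline.

The reference trap photographs a 126 x 126 mm sticky card at 1944 x 2592 px,
i.e. ~15.43 px per mm.  The scale is exposed as a module constant rather
than hard-coded in conversions so that data from other optics can override
it consistently everywhere.
"""

#: Pixels per millimetre for the reference camera (1944 px across 126 mm).
PX_PER_MM: float = 1944.0 / 126.0


def mm_to_px(mm: float, px_per_mm: float = PX_PER_MM) -> float:
    """Convert a physical length in mm to image pixels."""
    return mm * px_per_mm


def px_to_mm(px: float, px_per_mm: float = PX_PER_MM) -> float:
    """Convert an image length in px to millimetres."""
    return px / px_per_mm
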