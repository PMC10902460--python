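"""Screen geometry and pixel/visual-angle conversions.

All screen coordinates use the convention: origin at the top-left corner,
x increasing rightward, y increasing downward, units of pixels (continuous,
0-based).  Visual angles are computed for a viewer centred in front of the
screen at ``viewing_distance_mm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScreenGeometry", "pixel_to_degrees", "degrees_to_pixels", "DEFAULT_GEOMETRY"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the recording display.

    Parameters
    ----------
    width_px, height_px : int
        Screen dimensions in pixels.
    px_per_mm : float
        Pixel density.  266 ppi (a Galaxy Tab S7+ class tablet) is
        266 / 25.4 ≈ 10.47 px/mm.
    viewing_distance_mm : float
        Eye-to-screen distance; the experimental setup places the device
        approximately 50 cm from the participant's face.
    """

    width_px: int = 1752
    height_px: int = 2800
    px_per_mm: float = 266.0 / 25.4
    viewing_distance_mm: float = 500.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "px_per_mm", "viewing_distance_mm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)

    @property
    def diagonal_px(self) -> float:
        return math.hypot(self.width_px, self.height_px)

    def max_amplitude_deg(self) -> float:
        """Largest visual angle spanned by two on-screen points (the diagonal)."""
        return pixel_to_degrees((0.0, 0.0), (self.width_px, self.height_px), self)

    def contains(self, x, y) -> bool:
        return (0 <= x < self.width_px) and (0 <= y < self.height_px)


def pixel_to_degrees(p1, p2, geometry: ScreenGeometry) -> float:
    """Visual angle in degrees subtended by two screen points.

    Uses the exact chord formula ``2·atan(d_mm / (2·D))`` where ``d_mm`` is
    the on-screen Euclidean distance and ``D`` the viewing distance.
    """
    d_px = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    d_mm = d_px / geometry.px_per_mm
    return math.degrees(2.0 * math.atan2(d_mm, 2.0 * geometry.viewing_distance_mm))


def degrees_to_pixels(angle_deg: float, geometry: ScreenGeometry) -> float:
    """Inverse of :func:`pixel_to_degrees`: pixel distance subtending ``angle_deg``."""
    if angle_deg < 0:
        raise ValueError("angle must be non-negative")
    d_mm = 2.0 * geometry.viewing_distance_mm * math.tan(math.radians(angle_deg) / 2.0)
    return d_mm * geometry.px_per_mm


DEFAULT_GEOMETRY = ScreenGeometry()
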