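"""Cylindrical vessel geometry and the periodic unrolled chart.

All coordinates are in micrometres.  The vessel axis is ``z``; the lateral
surface is parameterized on the unrolled chart ``(x, z)`` where ``x`` is the
circumferential arc length, periodic with period ``pi * diameter`` (the
circumference of the outer wall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CylinderDomain:
    """A cylindrical vessel wall domain.

    Parameters
    ----------
    diameter:
        Outer vessel diameter in µm.  The default 45 µm is the width of the
        capillary segment the templates emulate.
    axial_length:
        Vessel length in µm along ``z`` (default 200 µm).
    """

    diameter: float = 45.0
    axial_length: float = 200.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if self.axial_length <= 0:
            raise ValueError(
                f"axial_length must be positive, got {self.axial_length}"
            )

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def circumference(self) -> float:
        """Period of the circumferential chart coordinate, ``pi * diameter``."""
        return np.pi * self.diameter

    @property
    def lateral_area(self) -> float:
        return self.circumference * self.axial_length

    def wrap_x(self, x):
        """Wrap circumferential coordinate(s) into the canonical period."""
        return np.mod(x, self.circumference)

    def to_3d(self, x, z, radius: float | None = None) -> np.ndarray:
        """Map unrolled chart points to 3-D points on a cylinder.

        ``radius`` defaults to the outer (abluminal) radius.  The angular
        coordinate is ``theta = 2*pi*x / circumference`` so that arc length on
        the *outer* wall is preserved.
        """
        r = self.radius if radius is None else radius
        theta = 2.0 * np.pi * np.asarray(x, dtype=float) / self.circumference
        z = np.asarray(z, dtype=float)
        return np.stack(
            [r * np.cos(theta), r * np.sin(theta), np.broadcast_to(z, theta.shape)],
            axis=-1,
        )
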