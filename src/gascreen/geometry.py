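"""Physical scan geometry of an OCT volume's en-face grid.

An OCT macular cube is a stack of ``n_bscans`` cross-sectional B-scans, each
composed of ``n_ascans`` depth columns (A-scans).  Collapsing each A-scan to
a per-column property yields an en-face map on an ``n_bscans x n_ascans``
grid covering a physical field of ``height_mm x width_mm``.  Rows index the
slow (B-scan) axis, columns the fast (A-scan) axis, both 0-based.

On typical macular protocols the B-scan spacing greatly exceeds the A-scan
spacing, so all physical distances here respect the anisotropic pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError


@dataclass(frozen=True)
class ScanGeometry:
    """Field-of-view and grid dimensions of an OCT en-face map.

    Defaults correspond to a common Topcon macular cube: 128 B-scans of
    512 A-scans over a 6 x 6 mm field.

    Attributes
    ----------
    n_bscans : int
        Number of B-scans (en-face rows).
    n_ascans : int
        Number of A-scans per B-scan (en-face columns).
    width_mm : float
        Lateral field width spanned by the A-scans, in mm.
    height_mm : float
        Field height spanned across B-scans, in mm.
    """

    n_bscans: int = 128
    n_ascans: int = 512
    width_mm: float = 6.0
    height_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.n_bscans <= 0 or self.n_ascans <= 0:
            raise GeometryError(
                f"grid must be positive, got {self.n_bscans} x {self.n_ascans}"
            )
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise GeometryError(
                f"field of view must be positive, got "
                f"{self.width_mm} x {self.height_mm} mm"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """En-face array shape, (rows, cols) = (n_bscans, n_ascans)."""
        return (self.n_bscans, self.n_ascans)

    @property
    def row_pitch_mm(self) -> float:
        """Physical spacing between adjacent B-scans (mm)."""
        return self.height_mm / self.n_bscans

    @property
    def col_pitch_mm(self) -> float:
        """Physical spacing between adjacent A-scans (mm)."""
        return self.width_mm / self.n_ascans

    @property
    def pixel_area_mm2(self) -> float:
        """Physical area of one en-face pixel (mm^2)."""
        return self.row_pitch_mm * self.col_pitch_mm

    def check_shape(self, array: np.ndarray) -> None:
        """Raise :class:`GeometryError` if ``array`` does not match the grid."""
        if array.shape != self.shape:
            raise GeometryError(
                f"array shape {array.shape} does not match geometry {self.shape}"
            )

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (Y, X) meshgrids of pixel-center coordinates in mm.

        The pixel at (row, col) has its center at
        ``((row + 0.5) * row_pitch, (col + 0.5) * col_pitch)``.
        """
        y = (np.arange(self.n_bscans) + 0.5) * self.row_pitch_mm
        x = (np.arange(self.n_ascans) + 0.5) * self.col_pitch_mm
        return np.meshgrid(y, x, indexing="ij")

    def px_to_mm(self, row: float, col: float) -> tuple[float, float]:
        """Pixel (row, col) -> physical (y, x) center coordinates in mm."""
        return ((row + 0.5) * self.row_pitch_mm, (col + 0.5) * self.col_pitch_mm)

    def mm_to_px(self, y_mm: float, x_mm: float) -> tuple[int, int]:
        """Physical (y, x) in mm -> nearest pixel (row, col), clipped to grid."""
        row = int(round(y_mm / self.row_pitch_mm - 0.5))
        col = int(round(x_mm / self.col_pitch_mm - 0.5))
        return (
            min(max(row, 0), self.n_bscans - 1),
            min(max(col, 0), self.n_ascans - 1),
        )

    def to_dict(self) -> dict:
        return {
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "width_mm": self.width_mm,
            "height_mm": self.height_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            n_bscans=int(d["n_bscans"]),
            n_ascans=int(d["n_ascans"]),
            width_mm=float(d["width_mm"]),
            height_mm=float(d["height_mm"]),
        )
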