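"""GA area, fovea location and fovea-relative lesion classification.

Atrophy is operationalized as absence of the retinal pigment epithelium
(RPE) on the segmentation-derived en-face map: the atrophic region is the
logical complement of the RPE-presence mask, cleaned of sub-threshold
speckle, and its area is the absent-pixel count times the physical pixel
area.  The fovea is located as the minimum of the Gaussian-smoothed
neurosensory-retina thickness within a central search window (scans fixate
on the preferred retinal locus, which in macular disease need not coincide
with the anatomical fovea, so the grid center cannot be trusted).  Two
location criteria common in GA trial protocols are derived from the located
fovea: "central" GA (any atrophy within 1500 um of the foveal center) and
"fovea-involving" GA (atrophy at the center point itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import IncompleteRecordError
from .geometry import ScanGeometry

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import EyeRecord

#: Absent-RPE connected components smaller than this are treated as
#: segmentation speckle and discarded before area summation.
DEFAULT_MIN_COMPONENT_MM2 = 0.05

#: Gaussian smoothing scale for fovea search, in mm.
DEFAULT_FOVEA_SIGMA_MM = 0.25

#: Radius defining "central" GA, in micrometres.
CENTRAL_RADIUS_UM = 1500.0


@dataclass
class ImagingProfile:
    """Per-eye imaging measurements relevant to trial criteria.

    Invariants: ``fovea_involving`` implies ``central_ga``; zero area implies
    both location flags are false.
    """

    area_mm2: float
    central_ga: bool
    fovea_involving: bool
    fovea_px: tuple[int, int]
    atrophy_mask: np.ndarray | None
    is_ga: bool = True

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError("area_mm2 must be non-negative")
        if self.fovea_involving and not self.central_ga:
            raise ValueError("fovea-involving GA is necessarily central")
        if self.area_mm2 == 0 and (self.central_ga or self.fovea_involving):
            raise ValueError("zero area cannot carry location flags")


def compute_ga_area(
    rpe_present: np.ndarray,
    geometry: ScanGeometry,
    ga_flag: bool = True,
    min_component_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
) -> tuple[float, np.ndarray]:
    """Quantify atrophy area from an RPE-presence mask.

    The atrophic region is the complement of ``rpe_present``; connected
    components (8-connectivity) smaller than ``min_component_mm2`` are
    discarded as speckle.  The area is the remaining absent-pixel count
    converted to mm^2 via the pixel pitch.  The area is computed regardless
    of ``ga_flag``; gating on the diagnosis happens downstream (the flag is
    threaded through :func:`profile_eye`).

    Returns
    -------
    (area_mm2, atrophy_mask)
    """
    rpe_present = np.asarray(rpe_present, dtype=bool)
    geometry.check_shape(rpe_present)
    atrophy = ~rpe_present
    if atrophy.any() and min_component_mm2 > 0:
        min_px = int(np.ceil(min_component_mm2 / geometry.pixel_area_mm2))
        if min_px > 1:
            labels = measure.label(atrophy, connectivity=2)
            counts = np.bincount(labels.ravel())
            keep = counts >= min_px
            keep[0] = False
            atrophy = keep[labels]
    area = float(atrophy.sum()) * geometry.pixel_area_mm2
    return area, atrophy


def locate_fovea(
    nsr_thickness: np.ndarray,
    geometry: ScanGeometry,
    sigma_mm: float = DEFAULT_FOVEA_SIGMA_MM,
    window_frac: float = 0.5,
) -> tuple[int, int]:
    """Locate the fovea as the smoothed thickness minimum near the grid center.

    The map is Gaussian-smoothed with scale ``sigma_mm`` (converted to an
    anisotropic pixel sigma) and the argmin is taken over the central
    ``window_frac`` fraction of the grid, which tolerates moderate
    fixation offsets while ignoring peripheral thinning.  Ties break to the
    smallest (row, col) in lexicographic order.  A constant (or otherwise
    degenerate) map yields the window center with a warning.
    """
    t = np.asarray(nsr_thickness, dtype=float)
    geometry.check_shape(t)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("thickness map must be finite and non-negative")

    r0 = int(geometry.n_bscans * (1 - window_frac) / 2)
    c0 = int(geometry.n_ascans * (1 - window_frac) / 2)
    r1 = geometry.n_bscans - r0
    c1 = geometry.n_ascans - c0

    if np.ptp(t) == 0:
        warnings.warn(
            "thickness map is constant; returning search-window center",
            RuntimeWarning,
            stacklevel=2,
        )
        return ((r0 + r1) // 2, (c0 + c1) // 2)

    sigma_px = (sigma_mm / geometry.row_pitch_mm, sigma_mm / geometry.col_pitch_mm)
    smooth = ndimage.gaussian_filter(t, sigma=sigma_px, mode="nearest")
    window = smooth[r0:r1, c0:c1]
    flat = int(np.argmin(window))  # first occurrence = lexicographic tie-break
    dr, dc = np.unravel_index(flat, window.shape)
    return (r0 + int(dr), c0 + int(dc))


def classify_location(
    atrophy_mask: np.ndarray,
    fovea_px: tuple[int, int],
    geometry: ScanGeometry,
    radius_um: float = CENTRAL_RADIUS_UM,
) -> tuple[bool, bool]:
    """Classify atrophy location relative to the fovea.

    Returns ``(central_ga, fovea_involving)``: central iff any atrophic
    pixel's physical center lies within ``radius_um`` (Euclidean, anisotropic
    pitch, inclusive) of the fovea pixel's center; fovea-involving iff the
    fovea pixel itself is atrophic.
    """
    atrophy_mask = np.asarray(atrophy_mask, dtype=bool)
    geometry.check_shape(atrophy_mask)
    fr, fc = fovea_px
    if not (0 <= fr < geometry.n_bscans and 0 <= fc < geometry.n_ascans):
        raise ValueError(f"fovea {fovea_px} outside grid {geometry.shape}")
    if not atrophy_mask.any():
        return (False, False)
    rows, cols = np.nonzero(atrophy_mask)
    dy = (rows - fr) * geometry.row_pitch_mm
    dx = (cols - fc) * geometry.col_pitch_mm
    central = bool(np.min(dy * dy + dx * dx) <= (radius_um / 1000.0) ** 2)
    involving = bool(atrophy_mask[fr, fc])
    return (central, involving)


def profile_eye(
    eye: "EyeRecord",
    geometry: ScanGeometry,
    min_component_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
    fovea_sigma_mm: float = DEFAULT_FOVEA_SIGMA_MM,
    radius_um: float = CENTRAL_RADIUS_UM,
) -> ImagingProfile:
    """Compute the full imaging profile of one eye.

    Composes area quantification, fovea localization and location
    classification.  The classification-network GA flag does not gate the
    area computation — it is recorded on the profile and applied by the
    eligibility rules downstream.
    """
    if eye.rpe_present is None or eye.nsr_thickness is None:
        raise IncompleteRecordError(
            f"eye {eye.laterality} is missing a segmentation map"
        )
    area, atrophy = compute_ga_area(
        eye.rpe_present, geometry, eye.ga_flag, min_component_mm2
    )
    fovea = locate_fovea(eye.nsr_thickness, geometry, fovea_sigma_mm)
    central, involving = classify_location(atrophy, fovea, geometry, radius_um)
    return ImagingProfile(
        area_mm2=area,
        central_ga=central,
        fovea_involving=involving,
        fovea_px=fovea,
        atrophy_mask=atrophy,
        is_ga=bool(eye.ga_flag),
    )
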