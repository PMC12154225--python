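"""Surface areas and membrane contacts from labeled EM volumes.

The estimators follow the slice-wise conventions of serial block-face EM
morphometry with strongly anisotropic voxels (e.g. 7 x 7 x 50 nm):

* the lateral surface area of a segmented object is its total in-plane
  boundary perimeter, summed over slices, multiplied by the z-step
  (``surface area [um^2] = total perimeter [um] x dz [um]``); top and bottom
  z-faces are deliberately not counted,
* two membranes are "in contact" on a slice wherever they approach each
  other to within a gap threshold (30 nm by default), and the contact area
  is half the resulting overlap perimeter times the z-step,
* protrusion contacts, which are too small for the perimeter machinery, are
  scored by their measured contact ranges times a 0.1 um nominal contact
  size.

Perimeters are measured on sub-voxel iso-contours (marching squares at the
0.5 level of a lightly Gaussian-smoothed binary mask) rather than by voxel
edge counting, which would overestimate a disk's perimeter by up to 4/pi.
Contact arcs are measured directly on those contours: a contour segment of
label ``a`` counts as contact wherever its distance to label ``b`` is within
the gap threshold (plus half a pixel to account for the voxel-centre
quantization of the distance field). This is numerically equivalent to the
classical dilate-and-overlap recipe but immune to one-pixel-wide overlap
bands vanishing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr
from skimage.measure import find_contours

from .datatypes import NM_PER_UM, LabeledVolume

#: default membrane apposition threshold (nm)
DEFAULT_GAP_NM = 30.0

#: nominal size of one protrusion contact (um)
PROTRUSION_CONTACT_SIZE_UM = 0.1

#: Gaussian pre-smoothing (pixels) applied before iso-contour extraction
CONTOUR_SMOOTH_SIGMA_PX = 1.0


# ---------------------------------------------------------------------------
# contour helpers
# ---------------------------------------------------------------------------

def _smoothed_contours(mask: np.ndarray, sigma: float = CONTOUR_SMOOTH_SIGMA_PX):
    """Closed sub-voxel iso-0.5 contours of a binary slice, padded coordinates.

    Returns ``(contours, pad)`` where contour coordinates are ``(row, col)``
    in the padded index frame.
    """
    pad = int(np.ceil(3 * sigma)) + 2
    f = np.pad(mask.astype(float), pad)
    if sigma > 0:
        f = ndimage.gaussian_filter(f, sigma)
    return find_contours(f, 0.5), pad


def _contour_length_um(contour: np.ndarray, dx_nm: float, dy_nm: float) -> float:
    d = np.diff(contour, axis=0)
    seg = np.hypot(d[:, 0] * dy_nm, d[:, 1] * dx_nm)  # rows are y, cols are x
    return float(seg.sum()) / NM_PER_UM


def _slice_perimeter_um(mask: np.ndarray, dx_nm: float, dy_nm: float) -> float:
    if not mask.any():
        return 0.0
    contours, _ = _smoothed_contours(mask)
    return sum(_contour_length_um(c, dx_nm, dy_nm) for c in contours)


# ---------------------------------------------------------------------------
# surface areas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceEstimate:
    """Per-slice perimeters and the lateral surface area of one label."""

    label: int
    per_slice_perimeter_um: np.ndarray
    total_perimeter_um: float
    surface_area_um2: float


def surface_area(volume: LabeledVolume, label: int) -> SurfaceEstimate:
    """Lateral surface area of ``label``: total in-plane perimeter x dz.

    A label that is present in the label table but absent from every slice
    has zero area; a label unknown to the table raises ``KeyError``.
    """
    if label not in volume.label_table:
        raise KeyError(f"label {label} not in label table")
    dx, dy = volume.dx_nm, volume.dy_nm
    perims = np.array(
        [_slice_perimeter_um(volume.labels[iz] == label, dx, dy) for iz in range(volume.n_slices)]
    )
    total = float(perims.sum())
    return SurfaceEstimate(label, perims, total, total * volume.dz_um)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceContact:
    """Contact measured on one slice."""

    slice_index: int
    arc_um: float
    overlap_perimeter_um: float
    n_components: int


@dataclass
class ContactSummary:
    """Membrane contact between a label pair, accumulated over slices.

    ``overlap_perimeter_um`` follows the dilate-and-overlap bookkeeping (both
    sides of the contact band, i.e. about twice the apposition arc), so that
    ``contact_area = overlap_perimeter / 2 x dz``.
    """

    pair: tuple[int, int]
    gap_nm: float
    slices: list[SliceContact] = field(default_factory=list)

    @property
    def total_arc_um(self) -> float:
        return sum(s.arc_um for s in self.slices)

    @property
    def overlap_perimeter_um(self) -> float:
        return sum(s.overlap_perimeter_um for s in self.slices)

    @property
    def n_components_total(self) -> int:
        return sum(s.n_components for s in self.slices)

    @property
    def n_slices_with_contact(self) -> int:
        return len(self.slices)

    def first_contact_z_um(self, dz_um: float) -> float | None:
        """z position (slice index x dz) of the most proximal contact."""
        if not self.slices:
            return None
        return min(s.slice_index for s in self.slices) * dz_um


def _contact_arc_one_side(
    mask_a: np.ndarray,
    dist_to_b_nm: np.ndarray,
    pad: int,
    thresh_nm: float,
    dx_nm: float,
    dy_nm: float,
) -> tuple[float, int]:
    """Arc length of ``a``'s contour lying within ``thresh_nm`` of ``b``.

    ``dist_to_b_nm`` is a padded distance field to b's voxel centres.
    Returns (arc um, number of contiguous contact runs).
    """
    contours, cpad = _smoothed_contours(mask_a)
    shift = cpad - pad
    arc = 0.0
    n_runs = 0
    for contour in contours:
        coords = (contour - shift).T  # (2, n) in dist-field frame
        d = ndimage.map_coordinates(dist_to_b_nm, coords, order=1, mode="nearest")
        seg_ok = (d[:-1] <= thresh_nm) & (d[1:] <= thresh_nm)
        if not seg_ok.any():
            continue
        dseg = np.diff(contour, axis=0)
        seg_len = np.hypot(dseg[:, 0] * dy_nm, dseg[:, 1] * dx_nm) / NM_PER_UM
        arc += float(seg_len[seg_ok].sum())
        # contiguous runs, merging across the closed-loop seam
        runs = np.diff(seg_ok.astype(int))
        starts = int((runs == 1).sum()) + int(seg_ok[0])
        closed = np.allclose(contour[0], contour[-1])
        if closed and seg_ok[0] and seg_ok[-1] and not seg_ok.all():
            starts -= 1
        n_runs += max(starts, 1) if seg_ok.any() else 0
    return arc, n_runs


def contact_map(
    volume: LabeledVolume,
    label_a: int,
    label_b: int,
    gap_nm: float = DEFAULT_GAP_NM,
) -> ContactSummary:
    """Slice-wise contact between two labels at a membrane-gap threshold.

    The threshold is inclusive (apposition of exactly ``gap_nm`` counts).
    The measurement is symmetrized — arcs are measured on both labels'
    contours and averaged — so ``contact_map(v, a, b) == contact_map(v, b, a)``
    holds exactly.
    """
    if label_a == label_b:
        raise ValueError("contact requires two distinct labels")
    for lbl in (label_a, label_b):
        if lbl not in volume.label_table:
            raise KeyError(f"label {lbl} not in label table")
    if gap_nm < 0:
        raise ValueError("gap must be non-negative")
    dx, dy = volume.dx_nm, volume.dy_nm
    if gap_nm < min(dx, dy):
        warnings.warn(
            f"gap {gap_nm} nm is below the in-plane pitch ({min(dx, dy)} nm); "
            "contacts resolve at one-voxel granularity",
            stacklevel=2,
        )
    a, b = sorted((label_a, label_b))
    # half-pixel slack: the distance field measures to voxel centres while the
    # membrane (iso-contour) sits ~half a pixel outside the outermost centres
    thresh_nm = gap_nm + 0.5 * max(dx, dy)
    pad = int(np.ceil(3 * CONTOUR_SMOOTH_SIGMA_PX)) + 2
    summary = ContactSummary(pair=(a, b), gap_nm=gap_nm)
    for iz in range(volume.n_slices):
        plane = volume.labels[iz]
        mask_a = plane == a
        mask_b = plane == b
        if not (mask_a.any() and mask_b.any()):
            continue
        dist_a = ndimage.distance_transform_edt(np.pad(~mask_a, pad, constant_values=True), sampling=(dy, dx))
        dist_b = ndimage.distance_transform_edt(np.pad(~mask_b, pad, constant_values=True), sampling=(dy, dx))
        arc_a, runs_a = _contact_arc_one_side(mask_a, dist_b, pad, thresh_nm, dx, dy)
        arc_b, runs_b = _contact_arc_one_side(mask_b, dist_a, pad, thresh_nm, dx, dy)
        arc = 0.5 * (arc_a + arc_b)
        if arc > 0:
            summary.slices.append(
                SliceContact(iz, arc, arc_a + arc_b, max(runs_a, runs_b))
            )
    return summary


def contact_area_from_overlap(summary: ContactSummary, dz_um: float) -> float:
    """Contact area: half the overlap perimeter times the z-step, over slices."""
    if dz_um <= 0:
        raise ValueError("dz must be positive")
    return 0.5 * summary.overlap_perimeter_um * dz_um


def protrusion_contact_area(contact_ranges_um) -> float:
    """Total protrusion contact area: sum of contact ranges x 0.1 um.

    Protrusion contacts are tiny and sparse; each is scored by its measured
    linear extent along the membrane times a nominal 0.1 um contact size.
    """
    ranges = np.asarray(list(contact_ranges_um), dtype=float)
    if ranges.size and ranges.min() < 0:
        raise ValueError("contact ranges must be non-negative")
    return float(ranges.sum()) * PROTRUSION_CONTACT_SIZE_UM


def nucleus_contact_correlation(nucleus_z_um, first_contact_z_um) -> tuple[float, float]:
    """Pearson r (and two-sided p) between nucleus position and first axon contact.

    Used to test the "first-come first-served" ordering of lamellar cells
    along the axon: cells whose nucleus sits more distally first touch the
    axon more distally.
    """
    x = np.asarray(list(nucleus_z_um), dtype=float)
    y = np.asarray(list(first_contact_z_um), dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
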