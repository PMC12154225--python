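"""Voxel phantoms with analytic ground truth for morphometry validation.

The phantoms digitize simple solids of revolution onto an anisotropic voxel
grid: a circular cylinder (the afferent axon), concentric lamellar shells
(lamellar Schwann cells, LSCs) separated by a nanometre-scale membrane gap,
an angular cleft sector in which the shells are interrupted, rod-like axonal
protrusions inside the cleft, and spherical nuclei embedded in the shells.
Because every surface is analytic, lateral surface areas (perimeter x z-step)
and membrane contact arcs are known in closed form and can be used as ground
truth for the voxel-based estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..datatypes import NM_PER_UM, LabeledVolume

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic inner-core phantom.

    Lengths are in micrometres except ``shell_gap`` and ``voxel_size_nm``
    which are in nanometres. The defaults give a small but resolvable
    phantom: a 1.5-um-radius axon wrapped by three 0.4-um lamellae separated
    by 20-nm gaps, with a 60-degree cleft sector. Real inner cores are much
    larger (tens of lamellae over hundreds of micrometres); the defaults are
    chosen so that full construction plus morphometry runs in seconds.
    """

    axon_radius_um: float = 1.5
    axon_length_um: float = 3.0
    n_shells: int = 3
    shell_thickness_um: float = 0.4
    shell_gap_nm: float = 20.0
    cleft_angle_deg: float = 60.0
    protrusion_count: int = 2
    voxel_size_nm: tuple[float, float, float] = (20.0, 20.0, 100.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.axon_radius_um <= 0 or self.axon_length_um <= 0:
            raise ValueError("axon radius and length must be positive")
        if self.n_shells < 0 or self.protrusion_count < 0:
            raise ValueError("counts must be non-negative")
        if self.n_shells and self.shell_thickness_um <= 0:
            raise ValueError("shell thickness must be positive")
        if self.shell_gap_nm < 0:
            raise ValueError("shell gap must be non-negative")
        if not 0 <= self.cleft_angle_deg < 360:
            raise ValueError("cleft angle must be in [0, 360)")
        dx, dy, dz = self.voxel_size_nm
        if dx <= 0 or dy <= 0 or dz <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass(frozen=True)
class ContactTruth:
    """Analytic membrane apposition between two labels."""

    pair: tuple[int, int]
    separation_nm: float
    arc_per_slice_um: float
    area_um2: float


@dataclass
class GroundTruth:
    """Analytic reference values carried alongside a phantom volume."""

    surface_area_um2: dict[int, float] = field(default_factory=dict)
    contacts: dict[tuple[int, int], ContactTruth] = field(default_factory=dict)
    nucleus_centroids_um: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def contact(self, a: int, b: int) -> ContactTruth | None:
        return self.contacts.get((min(a, b), max(a, b)))


class PhantomConstructionError(ValueError):
    """Raised when requested phantom geometry cannot be rasterized."""


def _grid(radius_extent_nm: float, length_um: float, voxel_size_nm) -> tuple:
    """Build voxel-centre coordinate arrays for a centred cylindrical domain."""
    dx, dy, dz = (float(v) for v in voxel_size_nm)
    margin_nm = 4 * max(dx, dy)
    half = radius_extent_nm + margin_nm
    nx = 2 * int(math.ceil(half / dx)) + 1
    ny = 2 * int(math.ceil(half / dy)) + 1
    nz = max(1, int(round(length_um * NM_PER_UM / dz)))
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    X, Y = np.meshgrid(x, y)  # (ny, nx)
    return X, Y, nz, (dx, dy, dz)


def make_cylinder_phantom(
    radius_um: float,
    length_um: float,
    voxel_size_nm: tuple[float, float, float] = (10.0, 10.0, 50.0),
    label: int = 1,
) -> tuple[LabeledVolume, GroundTruth]:
    """Digitize a solid circular cylinder along z.

    The single foreground label has analytic lateral surface area
    ``2 * pi * r * L`` (top and bottom faces are deliberately excluded, to
    match the slice-wise perimeter x dz estimator). The requested length is
    rounded to a whole number of z slices; the ground truth uses the
    effective length ``n_slices * dz``.

    Raises
    ------
    ValueError
        If the radius is non-positive or below 5 in-plane voxel pitches
        (such a cylinder is not resolvable by contour extraction).
    """
    if radius_um <= 0 or length_um <= 0:
        raise ValueError("radius and length must be positive")
    dx = float(voxel_size_nm[0])
    radius_nm = radius_um * NM_PER_UM
    if radius_nm < 5 * dx:
        raise ValueError(
            f"radius {radius_um} um is below 5 in-plane pitches "
            f"({5 * dx / NM_PER_UM} um); not resolvable"
        )
    X, Y, nz, (dx, dy, dz) = _grid(radius_nm, length_um, voxel_size_nm)
    disk = (X * X + Y * Y) <= radius_nm * radius_nm
    labels = np.zeros((nz,) + disk.shape, dtype=np.uint16)
    labels[:, disk] = label
    vol = LabeledVolume(labels, (dx, dy, dz), {label: "axon"})
    eff_length_um = nz * dz / NM_PER_UM
    truth = GroundTruth(surface_area_um2={label: TWO_PI * radius_um * eff_length_um})
    return vol, truth


def _in_cleft(theta_deg: np.ndarray, cleft_angle_deg: float) -> np.ndarray:
    """Angular mask of the cleft sector, centred on 0 degrees."""
    if cleft_angle_deg <= 0:
        return np.zeros_like(theta_deg, dtype=bool)
    half = cleft_angle_deg / 2.0
    d = np.abs((theta_deg + 180.0) % 360.0 - 180.0)  # distance to 0 deg
    return d < half


def make_corpuscle_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, GroundTruth]:
    """Rasterize an inner-core phantom: axon, lamellar shells, cleft, nuclei.

    Label layout: 1 = axon; ``2 .. n_shells+1`` = shells (innermost first);
    then protrusions; then one nucleus per shell. Shells are annuli of the
    configured thickness, separated radially by ``shell_gap_nm`` and
    interrupted over the cleft sector. Protrusions are thin z-aligned rods
    placed inside the cleft, kept >30 nm away from every other label so they
    contribute surface area but no contact. Nuclei are spheres carved out of
    the interior of their shell.

    Ground truth records, per label, the lateral surface area implied by the
    slice-wise perimeter x dz convention, and, per radially adjacent pair,
    the membrane separation and apposition arc
    ``2 * pi * r_boundary * (1 - cleft/360)``.
    """
    gap_um = spec.shell_gap_nm / NM_PER_UM
    r_axon = spec.axon_radius_um
    shell_r = []  # (inner, outer) radii in um
    r = r_axon
    for _ in range(spec.n_shells):
        r_in = r + gap_um
        r_out = r_in + spec.shell_thickness_um
        shell_r.append((r_in, r_out))
        r = r_out
    outer_nm = (shell_r[-1][1] if shell_r else r_axon) * NM_PER_UM

    X, Y, nz, (dx, dy, dz) = _grid(outer_nm, spec.axon_length_um, spec.voxel_size_nm)
    dz_um = dz / NM_PER_UM
    length_um = nz * dz_um
    R_nm = np.hypot(X, Y)
    theta = np.degrees(np.arctan2(Y, X))
    cleft = _in_cleft(theta, spec.cleft_angle_deg)
    sector_frac = 1.0 - spec.cleft_angle_deg / 360.0

    labels = np.zeros((nz,) + R_nm.shape, dtype=np.uint16)
    table: dict[int, str] = {}
    truth = GroundTruth()

    def paint_prism(mask2d: np.ndarray, label: int, role: str) -> None:
        if not mask2d.any():
            raise PhantomConstructionError(f"label {label} ({role}) rasterizes to nothing")
        if labels[0][mask2d].any():
            raise PhantomConstructionError(f"label {label} ({role}) overlaps existing labels")
        labels[:, mask2d] = label
        table[label] = role

    # axon (unaffected by the cleft)
    axon_mask = R_nm <= r_axon * NM_PER_UM
    paint_prism(axon_mask, 1, "axon")
    truth.surface_area_um2[1] = TWO_PI * r_axon * length_um

    # lamellar shells with the cleft sector removed
    for k, (r_in, r_out) in enumerate(shell_r):
        lbl = 2 + k
        ann = (R_nm > r_in * NM_PER_UM) & (R_nm <= r_out * NM_PER_UM) & ~cleft
        paint_prism(ann, lbl, "LSC")
        perim = TWO_PI * (r_in + r_out) * sector_frac
        if sector_frac < 1.0:
            perim += 2.0 * spec.shell_thickness_um  # radial cleft edges
        truth.surface_area_um2[lbl] = perim * length_um

    # apposition ground truth between radially adjacent labels
    def record_contact(a: int, b: int, r_boundary_um: float) -> None:
        arc = TWO_PI * r_boundary_um * sector_frac
        truth.contacts[(a, b)] = ContactTruth(
            pair=(a, b),
            separation_nm=spec.shell_gap_nm,
            arc_per_slice_um=arc,
            area_um2=arc * length_um,
        )

    if spec.n_shells >= 1:
        record_contact(1, 2, r_axon)
    for k in range(spec.n_shells - 1):
        record_contact(2 + k, 3 + k, shell_r[k][1])

    next_label = 2 + spec.n_shells

    # protrusions: z-aligned rods in the cleft, clear of all other labels
    if spec.protrusion_count:
        r_p_nm = max(4 * dx, 60.0)
        clearance_nm = 50.0
        c_nm = r_axon * NM_PER_UM + r_p_nm + clearance_nm
        footprint_deg = math.degrees(math.asin(min(1.0, r_p_nm / c_nm))) + 2.0
        usable = spec.cleft_angle_deg / 2.0 - footprint_deg
        if usable <= 0:
            raise PhantomConstructionError(
                "cleft too narrow to host protrusions; widen cleft_angle or drop them"
            )
        if spec.protrusion_count == 1:
            angles = [0.0]
        else:
            angles = np.linspace(-usable, usable, spec.protrusion_count)
        min_sep_deg = 2 * footprint_deg
        if spec.protrusion_count > 1 and (angles[1] - angles[0]) < min_sep_deg:
            raise PhantomConstructionError("too many protrusions for the cleft sector")
        for ang in angles:
            cx = c_nm * math.cos(math.radians(ang))
            cy = c_nm * math.sin(math.radians(ang))
            rod = (X - cx) ** 2 + (Y - cy) ** 2 <= r_p_nm * r_p_nm
            paint_prism(rod, next_label, "axon_protrusion")
            truth.surface_area_um2[next_label] = TWO_PI * (r_p_nm / NM_PER_UM) * length_um
            next_label += 1

    # nuclei: one sphere per shell, carved out of the shell interior
    z_centers_um = (np.arange(nz) + 0.5) * dz_um
    for k, (r_in, r_out) in enumerate(shell_r):
        t = r_out - r_in
        r_n_um = min(0.4 * t, 0.3, 0.2 * length_um)
        if r_n_um * NM_PER_UM < 3 * dx or 2 * r_n_um < 3 * dz_um:
            continue  # unresolvable at this pitch; skip without error
        r_mid = (r_in + r_out) / 2.0
        ang = 180.0 + (k - (spec.n_shells - 1) / 2.0) * 40.0
        zc = length_um * (k + 1) / (spec.n_shells + 1)
        zc = min(max(zc, r_n_um + dz_um), length_um - r_n_um - dz_um)
        cx = r_mid * math.cos(math.radians(ang)) * NM_PER_UM
        cy = r_mid * math.sin(math.radians(ang)) * NM_PER_UM
        d2_xy = (X - cx) ** 2 + (Y - cy) ** 2  # nm^2
        shell_lbl = 2 + k
        area = 0.0
        painted = False
        for iz, z_um in enumerate(z_centers_um):
            dz_nm2 = ((z_um - zc) * NM_PER_UM) ** 2
            rad2 = (r_n_um * NM_PER_UM) ** 2 - dz_nm2
            if rad2 <= 0:
                continue
            disk = d2_xy <= rad2
            if not disk.any():
                continue
            if not np.all(labels[iz][disk] == shell_lbl):
                raise PhantomConstructionError(
                    f"nucleus of shell {shell_lbl} escapes its shell"
                )
            labels[iz][disk] = next_label
            painted = True
            r_z = math.sqrt(rad2) / NM_PER_UM
            circ = TWO_PI * r_z
            area += circ * dz_um
            # carving a hole adds the same circumference to the shell outline
            truth.surface_area_um2[shell_lbl] += circ * dz_um
        if painted:
            table[next_label] = "nucleus"
            truth.surface_area_um2[next_label] = area
            truth.nucleus_centroids_um[next_label] = (
                cx / NM_PER_UM,
                cy / NM_PER_UM,
                zc,
            )
            next_label += 1

    vol = LabeledVolume(labels, (dx, dy, dz), table)
    return vol, truth
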