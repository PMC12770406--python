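"""Landmark-based cervical biometry from multi-label segmentations.

The measurement protocol mirrors clinical practice for cervical length (CL):
the canal's two open ends (internal os = inlet, external os = outlet) are
found as interfaces between the canal (including cysts) and background; the
inlet/outlet centre-points are the arithmetic means of those interface ROIs;
the canal midpoint is the mean world coordinate of all canal-label voxels;
and CL is the two-line polyline length inlet -> midpoint -> outlet.  The
inlet and outlet diameters are measured by ray-marching from each
centre-point, within the landmark plane and perpendicular to the local canal
axis, until the inner stroma or background is reached.

All computations are in world millimetres (RAS), so results do not depend
on grid orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import LabelVolume

__all__ = [
    "Landmarks",
    "BiometryResult",
    "locate_end_interfaces",
    "compute_centrepoint",
    "compute_midpoint",
    "measure_cervical_length",
    "measure_diameter",
    "run_biometry",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
_FULL_STRUCT = ndimage.generate_binary_structure(3, 3)   # 26-connectivity
_MIN_CANAL_VOXELS = 20


@dataclass
class Landmarks:
    """Inlet/outlet centres and canal midpoint, world mm."""

    inlet_centre: np.ndarray
    outlet_centre: np.ndarray
    midpoint: np.ndarray
    inlet_roi: np.ndarray   # (N,3) voxel indices
    outlet_roi: np.ndarray


@dataclass
class BiometryResult:
    landmarks: Landmarks
    cervical_length_mm: float
    inlet_diameter_mm: float
    outlet_diameter_mm: float
    measurement_plane_point: np.ndarray
    measurement_plane_normal: np.ndarray

    def to_dict(self) -> dict:
        lm = self.landmarks
        return {
            "landmarks_mm": {
                "inlet_centre": lm.inlet_centre.tolist(),
                "outlet_centre": lm.outlet_centre.tolist(),
                "midpoint": lm.midpoint.tolist(),
            },
            "cervical_length_mm": self.cervical_length_mm,
            "inlet_diameter_mm": self.inlet_diameter_mm,
            "outlet_diameter_mm": self.outlet_diameter_mm,
            "measurement_plane": {
                "point": self.measurement_plane_point.tolist(),
                "normal": self.measurement_plane_normal.tolist(),
            },
        }

    def to_json(self, path: str | Path, **provenance) -> None:
        d = self.to_dict()
        if provenance:
            d["provenance"] = provenance
        Path(path).write_text(json.dumps(d, indent=2))


def locate_end_interfaces(vol: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    """Find the two open-end interface ROIs of the canal.

    Interface voxels are canal-or-cyst voxels with at least one face-adjacent
    background voxel (voxels on the grid border count their missing
    neighbours as background).  They are grouped into 26-connected
    components; the two largest are the tube ends.  Returns (inlet, outlet)
    voxel-index arrays using the default superior-end-is-inlet rule; callers
    needing a different rule can reassign.
    """
    canal = np.isin(vol.voxels, (1, 4))
    if int((vol.voxels == 1).sum()) < _MIN_CANAL_VOXELS:
        raise ValueError("no (or too few) canal voxels")
    background = vol.voxels == 0
    bg_padded = np.pad(background, 1, constant_values=True)
    touches_bg = ndimage.binary_dilation(bg_padded, structure=_FACE_STRUCT)[
        1:-1, 1:-1, 1:-1
    ]
    interface = canal & touches_bg
    comp, ncomp = ndimage.label(interface, structure=_FULL_STRUCT)
    if ncomp < 2:
        raise ValueError("no end interfaces: closed or capped canal")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, ncomp + 1))
    order = np.argsort(sizes)[::-1]
    ids = order[:2] + 1
    roi_a = np.argwhere(comp == ids[0])
    roi_b = np.argwhere(comp == ids[1])
    ca, cb = vol.voxel_to_world(roi_a).mean(0), vol.voxel_to_world(roi_b).mean(0)
    if np.linalg.norm(ca - cb) < 5.0 * float(vol.spacing.max()):
        raise ValueError("ambiguous end interfaces: two largest components touch")
    return _assign_inlet_outlet(vol, roi_a, roi_b, rule="superior")


def _assign_inlet_outlet(
    vol: LabelVolume,
    roi_a: np.ndarray,
    roi_b: np.ndarray,
    rule: str = "superior",
    point: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disambiguate which end is the inlet (internal os).

    The protocol itself does not distinguish the ends; by default the more
    superior end (larger S coordinate in RAS, toward the uterine cavity in
    supine imaging) is taken as the inlet.  ``rule`` may be 'superior',
    'inferior' or 'nearest-to' with a world point.
    """
    ca = vol.voxel_to_world(roi_a).mean(0)
    cb = vol.voxel_to_world(roi_b).mean(0)
    if rule == "superior":
        a_is_inlet = ca[2] >= cb[2]
    elif rule == "inferior":
        a_is_inlet = ca[2] < cb[2]
    elif rule == "nearest-to":
        if point is None:
            raise ValueError("rule 'nearest-to' needs a point")
        a_is_inlet = np.linalg.norm(ca - point) <= np.linalg.norm(cb - point)
    else:
        raise ValueError(f"unknown inlet rule: {rule}")
    return (roi_a, roi_b) if a_is_inlet else (roi_b, roi_a)


def compute_centrepoint(roi: np.ndarray, vol: LabelVolume) -> np.ndarray:
    """Arithmetic mean of the world coordinates of the ROI voxel centres."""
    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("empty ROI")
    return vol.voxel_to_world(roi).mean(axis=0)


def compute_midpoint(vol: LabelVolume) -> np.ndarray:
    """Mean world coordinate of the canal label (label 1 only, not cysts)."""
    idx = np.argwhere(vol.voxels == 1)
    if idx.size == 0:
        raise ValueError("no canal voxels")
    return vol.voxel_to_world(idx).mean(axis=0)


def measure_cervical_length(
    inlet: np.ndarray, midpoint: np.ndarray, outlet: np.ndarray
) -> float:
    """Two-line cervical length |inlet-midpoint| + |midpoint-outlet| in mm."""
    pts = np.asarray([inlet, midpoint, outlet], dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite landmark")
    return float(np.linalg.norm(pts[0] - pts[1]) + np.linalg.norm(pts[1] - pts[2]))


def measure_diameter(
    vol: LabelVolume,
    centre: np.ndarray,
    axis_direction: np.ndarray,
    plane_normal: np.ndarray,
    step_mm: float = 0.1,
) -> float:
    """Canal diameter at ``centre`` with boundaries defined by the inner layer.

    Marches from the centre along +/-d, d = normalize(plane_normal x
    axis_direction), sampling labels nearest-neighbour every ``step_mm``.
    Each ray stops at the first *sustained* boundary sample — inner stroma
    or background with no canal/cyst sample within one voxel diagonal
    further along the ray.  The persistence requirement treats isolated
    boundary samples as what they are on a voxel grid: staircase
    rasterisation noise.  The measurement rays run close to the jagged
    canal wall and, at the open inlet/outlet caps, within half a voxel of
    background for their whole length; stopping at the first isolated
    boundary sample would act as a minimum over the staircase and bias the
    diameter low by up to a voxel for oblique grid orientations, breaking
    rotation invariance.  A genuine wall or open-end exit persists (the
    inner stroma is always thicker than one voxel diagonal) and stops the
    ray at the same place either way.
    """
    centre = np.asarray(centre, float)
    if not _near_canal(vol, centre):
        raise ValueError("centre outside canal")
    a = np.asarray(axis_direction, float)
    a = a / np.linalg.norm(a)
    n = np.asarray(plane_normal, float)
    d = np.cross(n, a)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("axis direction and plane normal are parallel")
    d = d / norm
    # The inlet/outlet centre-points lie ON the rasterised open-cap surface,
    # where nearest-neighbour labels alternate between canal and beyond-cap
    # background depending on grid orientation, and the voxelised canal wall
    # deviates from the continuum wall by up to half a voxel diagonal with a
    # staircase phase set by the orientation.  Both effects are averaged out
    # by marching a small bundle of parallel rays insetted along the canal
    # axis over one voxel period (all within ~1 voxel of the centre-point
    # level) and averaging their stop distances per side.
    spacing = float(vol.spacing.max())
    # interior axial sense: the probe must reach past the cap staircase
    # (up to a voxel diagonal), so score each sense over 0.5-1.5 voxels
    def _interior_score(sense: np.ndarray) -> int:
        return sum(
            vol.label_at(centre + f * spacing * sense) in (1, 4)
            for f in (0.5, 1.0, 1.5)
        )
    a_in = a if _interior_score(a) >= _interior_score(-a) else -a
    insets = (0.5 + np.array([0.0, 0.25, 0.5, 0.75, 1.0])) * spacing
    max_steps = int(np.ceil(np.linalg.norm(np.array(vol.shape) * vol.spacing) / step_mm))
    persist = int(np.ceil(np.sqrt(3.0) * spacing / step_mm))
    side_means = []
    for sign in (+1.0, -1.0):
        dists = []
        for inset in insets:
            start = centre + inset * a_in
            if vol.label_at(start) not in (1, 4):
                continue
            labs = _ray_labels(vol, start, sign * d, step_mm, max_steps)
            dist = None
            for k in range(1, len(labs)):
                if labs[k] == 2 or labs[k] == 0:
                    ahead = labs[k + 1 : k + 1 + persist]
                    if not np.any(np.isin(ahead, (1, 4))):
                        dist = k * step_mm
                        break
            if dist is not None:
                dists.append(dist)
        if not dists:
            raise ValueError("ray exited the grid before hitting a boundary")
        side_means.append(float(np.mean(dists)))
    return side_means[0] + side_means[1]


def _near_canal(vol: LabelVolume, point: np.ndarray) -> bool:
    """True if the point's voxel, or a face/edge/corner neighbour, is canal.

    The inlet/outlet centre-points sit on the open cap surface, where
    nearest-voxel rounding may land half a voxel outside the canal; a
    one-voxel tolerance keeps the contract (a centre inside the stroma is
    still rejected, as layer thicknesses exceed one voxel).
    """
    ijk = np.rint(vol.world_to_voxel(point)).astype(int)
    lo = np.maximum(ijk - 1, 0)
    hi = np.minimum(ijk + 2, np.array(vol.shape))
    if np.any(lo >= hi):
        return False
    neigh = vol.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return bool(np.isin(neigh, (1, 4)).any())


def _ray_labels(
    vol: LabelVolume, origin: np.ndarray, direction: np.ndarray,
    step_mm: float, max_steps: int,
) -> np.ndarray:
    """Nearest-neighbour labels along origin + k*step*direction, k=0..; -1 off-grid."""
    ks = np.arange(0, max_steps + 1, dtype=float)[:, None]
    pts = origin[None, :] + ks * step_mm * direction[None, :]
    ijk = np.rint(vol.world_to_voxel(pts)).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(vol.shape)), axis=1)
    # keep samples up to the first off-grid point
    n_ok = int(np.argmin(inside)) if not inside.all() else len(inside)
    ijk = ijk[:n_ok]
    return vol.voxels[ijk[:, 0], ijk[:, 1], ijk[:, 2]]


def _landmark_plane_normal(
    inlet: np.ndarray, midpoint: np.ndarray, outlet: np.ndarray
) -> np.ndarray:
    """Normal of the plane through the three landmarks.

    For (near-)collinear landmarks the plane is undefined; fall back to the
    world left-right axis, matching the clinical mid-sagittal convention.
    """
    v1 = midpoint - inlet
    v2 = outlet - midpoint
    n = np.cross(v1, v2)
    scale = max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12)
    if np.linalg.norm(n) / scale < 1e-3:
        return np.array([1.0, 0.0, 0.0])
    return n / np.linalg.norm(n)


def run_biometry(
    vol: LabelVolume,
    inlet_rule: str = "superior",
    inlet_point: np.ndarray | None = None,
) -> BiometryResult:
    """Full automated biometry: landmarks, length and both diameters."""
    roi_a, roi_b = locate_end_interfaces(vol)
    if inlet_rule != "superior" or inlet_point is not None:
        roi_a, roi_b = _assign_inlet_outlet(
            vol, roi_a, roi_b, rule=inlet_rule, point=inlet_point
        )
    inlet_c = compute_centrepoint(roi_a, vol)
    outlet_c = compute_centrepoint(roi_b, vol)
    mid = compute_midpoint(vol)
    landmarks = Landmarks(
        inlet_centre=inlet_c,
        outlet_centre=outlet_c,
        midpoint=mid,
        inlet_roi=roi_a,
        outlet_roi=roi_b,
    )
    length = measure_cervical_length(inlet_c, mid, outlet_c)
    normal = _landmark_plane_normal(inlet_c, mid, outlet_c)
    inlet_axis = (mid - inlet_c) / np.linalg.norm(mid - inlet_c)
    outlet_axis = (outlet_c - mid) / np.linalg.norm(outlet_c - mid)
    d_in = measure_diameter(vol, inlet_c, inlet_axis, normal)
    d_out = measure_diameter(vol, outlet_c, outlet_axis, normal)
    plane_point = (inlet_c + mid + outlet_c) / 3.0
    return BiometryResult(
        landmarks=landmarks,
        cervical_length_mm=length,
        inlet_diameter_mm=d_in,
        outlet_diameter_mm=d_out,
        measurement_plane_point=plane_point,
        measurement_plane_normal=normal,
    )
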