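"""Parametric digital cervix phantom with analytically known measurements.

The phantom models the pregnant cervix as a two-segment tube: the
endocervical canal is the union of two cylinders of radius ``canal_radius``
mitre-joined at a midpoint hinge, cut flat at the two open ends (internal os / inlet and
external os / outlet).  Concentric open-ended shells around the canal stand
in for the inner stroma (subglandular zone) and outer stroma.  Spherical
cysts may be embedded inside the canal, and an optional bladder sphere sits
in the background.  Because the centreline is exactly two straight segments,
the clinical two-line cervical length (inlet -> canal midpoint -> outlet) is
the true arc length of the canal, and the inlet/outlet diameters are exactly
twice the canal radius.

Rasterisation uses supersampled majority voting so label volumes converge to
the continuum geometry as the grid is refined; ties are broken by priority
cyst > canal > inner > outer > bladder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import ImageVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "IntensityModel",
    "generate_phantom",
    "render_intensity",
    "random_spec",
]

@dataclass
class PhantomSpec:
    """Geometry of a two-segment cervix phantom, in world millimetres."""

    inlet_point: tuple[float, float, float] = (0.0, 0.0, 15.0)
    mid_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    outlet_point: tuple[float, float, float] = (0.0, 0.0, -15.0)
    canal_radius: float = 3.0
    inner_thickness: float = 2.5
    outer_thickness: float = 3.5
    cysts: tuple[tuple[tuple[float, float, float], float], ...] = ()
    include_bladder: bool = False
    grid_size: int = 80
    spacing: float = 0.8
    supersampling: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.canal_radius, self.inner_thickness, self.outer_thickness) <= 0:
            raise ValueError("radius and thicknesses must be positive")
        if self.supersampling < 1 or self.grid_size < 8:
            raise ValueError("supersampling >= 1 and grid_size >= 8 required")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        a, m, b = map(np.asarray, (self.inlet_point, self.mid_point, self.outlet_point))
        if np.linalg.norm(a - m) < 1e-9 or np.linalg.norm(b - m) < 1e-9:
            raise ValueError("degenerate centreline segment")
        half = self.grid_size * self.spacing / 2.0
        r_out = self.canal_radius + self.inner_thickness + self.outer_thickness
        for p in (a, m, b):
            if np.any(np.abs(p) + r_out > half):
                raise ValueError("phantom geometry exceeds the grid extent")
        for centre, r in self.cysts:
            if r <= 0:
                raise ValueError("cyst radius must be positive")
            if not self._inside_canal(np.asarray(centre, float), margin=r):
                raise ValueError("cyst sphere must lie within the canal tube")

    # -- centreline helpers -------------------------------------------------
    @property
    def segments(self) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
        a = np.asarray(self.inlet_point, float)
        m = np.asarray(self.mid_point, float)
        b = np.asarray(self.outlet_point, float)
        return ((m, a), (m, b))

    def _inside_canal(self, p: np.ndarray, margin: float = 0.0) -> bool:
        # radial containment requires the margin; axially a sphere may reach
        # (or poke through) the open end caps, where it is simply truncated
        for start, end in self.segments:
            d = end - start
            L = np.linalg.norm(d)
            u = d / L
            t = float((p - start) @ u)
            radial = np.linalg.norm((p - start) - t * u)
            if 0 <= t <= L and radial <= self.canal_radius - margin:
                return True
        return False

    def affine(self) -> np.ndarray:
        """RAS affine placing the world origin at the grid centre."""
        A = np.eye(4)
        A[:3, :3] *= self.spacing
        A[:3, 3] = -self.spacing * (self.grid_size - 1) / 2.0
        return A

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(json.dumps(d, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for k in ("inlet_point", "mid_point", "outlet_point"):
            d[k] = tuple(d[k])
        d["cysts"] = tuple((tuple(c), r) for c, r in d.get("cysts", []))
        return cls(**d)


@dataclass
class PhantomTruth:
    """Analytic measurements implied by a :class:`PhantomSpec`."""

    length_mm: float
    inlet_diameter_mm: float
    outlet_diameter_mm: float
    volumes_mm3: dict[int, float]

    @property
    def canal_total_mm3(self) -> float:
        return self.volumes_mm3.get(1, 0.0) + self.volumes_mm3.get(4, 0.0)

    def to_json(self, path: str | Path) -> None:
        d = {
            "length_mm": self.length_mm,
            "inlet_diameter_mm": self.inlet_diameter_mm,
            "outlet_diameter_mm": self.outlet_diameter_mm,
            "volumes_mm3": {str(k): v for k, v in self.volumes_mm3.items()},
            "canal_total_mm3": self.canal_total_mm3,
        }
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class IntensityModel:
    """T2w-like per-label appearance model.

    Defaults follow the qualitative contrasts of the cervix on T2w MRI: the
    canal mucosa is a regional mixture of high and low signal (mucus plug),
    the inner stroma is the darkest layer, the outer stroma intermediate,
    and cysts are focal hyperintensities.  A smooth multiplicative bias
    field and i.i.d. Gaussian noise emulate acquisition artefacts.
    """

    means: dict[int, float] = field(
        default_factory=lambda: {0: 0.10, 1: 0.60, 2: 0.20, 3: 0.45, 4: 0.95, 5: 0.90}
    )
    canal_mix_amplitude: float = 0.15  # regional high/low swing inside the canal
    canal_mix_scale_mm: float = 8.0
    noise_sd: float = 0.03
    bias_amplitude: float = 0.2
    bias_scale_mm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not (self.means[2] < self.means[3] < self.means[1] < self.means[4]):
            raise ValueError(
                "per-label means must satisfy inner < outer < canal < cyst"
            )


# ---------------------------------------------------------------------------
# classification of world points against the continuum geometry
# ---------------------------------------------------------------------------

def _classify_points(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Label world points (N,3) by the continuum phantom geometry.

    The two tube segments are mitre-joined at the hinge: each segment is
    clipped by the bisector plane through the mid-point rather than by a
    perpendicular cap, so the joint has no gap on the outer bend and no
    double-covered wedge on the inner bend.  The far ends (inlet and
    outlet) are flat perpendicular caps open to the background.
    """
    r1 = spec.canal_radius
    r2 = r1 + spec.inner_thickness
    r3 = r2 + spec.outer_thickness
    n = points.shape[0]
    m = np.asarray(spec.mid_point, np.float32)
    (_, a), (_, b) = spec.segments
    u1 = (a - m) / np.linalg.norm(a - m)
    u2 = (b - m) / np.linalg.norm(b - m)
    w = (u1 - u2).astype(np.float32)
    w /= np.linalg.norm(w)  # miter-plane normal, points to the inlet side
    oblique = (points - m) @ w
    radial_min = np.full(n, np.inf, dtype=np.float32)
    for (start, end), side in ((spec.segments[0], +1.0), (spec.segments[1], -1.0)):
        d = end - start
        L = float(np.linalg.norm(d))
        u = (d / L).astype(np.float32)
        rel = points - start.astype(np.float32)
        t = rel @ u
        inside_axial = (side * oblique >= 0) & (t <= L)
        radial = np.linalg.norm(rel - np.outer(t, u), axis=1)
        radial = np.where(inside_axial, radial, np.inf).astype(np.float32)
        radial_min = np.minimum(radial_min, radial)
    labels = np.zeros(n, dtype=np.int16)
    labels[radial_min <= r3] = 3
    labels[radial_min <= r2] = 2
    labels[radial_min <= r1] = 1
    for centre, r in spec.cysts:
        d2 = np.einsum(
            "ij,ij->i",
            points - np.asarray(centre, np.float32),
            points - np.asarray(centre, np.float32),
        )
        labels[(d2 <= r * r) & (labels == 1)] = 4
    if spec.include_bladder:
        centre, r = _bladder_geometry(spec)
        d2 = np.einsum("ij,ij->i", points - centre, points - centre)
        labels[(d2 <= r * r) & (labels == 0)] = 5
    return labels


def _bladder_geometry(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """A background sphere anterior to the cervix standing in for the bladder."""
    half = spec.grid_size * spec.spacing / 2.0
    r_out = spec.canal_radius + spec.inner_thickness + spec.outer_thickness
    r = min(8.0, max(2.0, (half - r_out) / 3.0))
    centre = np.array([-(r_out + r + 2.0), 0.0, 0.0], dtype=np.float32)
    return centre, float(r)


# ---------------------------------------------------------------------------
# analytic / high-resolution ground-truth measurements
# ---------------------------------------------------------------------------

def _segment_lengths(spec: PhantomSpec) -> tuple[float, float]:
    a = np.asarray(spec.inlet_point, float)
    m = np.asarray(spec.mid_point, float)
    b = np.asarray(spec.outlet_point, float)
    return float(np.linalg.norm(a - m)), float(np.linalg.norm(b - m))


def _is_collinear(spec: PhantomSpec, tol: float = 1e-9) -> bool:
    a = np.asarray(spec.inlet_point, float)
    m = np.asarray(spec.mid_point, float)
    b = np.asarray(spec.outlet_point, float)
    u = (a - m) / np.linalg.norm(a - m)
    v = (b - m) / np.linalg.norm(b - m)
    return bool(np.linalg.norm(np.cross(u, v)) < tol and u @ v < 0)


def _truth_volumes(spec: PhantomSpec) -> dict[int, float]:
    """Continuum per-label volumes, exact for the mitre-joined geometry.

    Each mitre-clipped segment has the same volume as the corresponding
    perpendicular-capped cylinder slab (the oblique cut through the axis
    point removes and adds point-symmetric wedges), so the union of the two
    segments has volume pi r^2 (L1 + L2) at every bend angle, and each
    stromal shell is the matching annulus.
    """
    L1, L2 = _segment_lengths(spec)
    L = L1 + L2
    r1 = spec.canal_radius
    r2 = r1 + spec.inner_thickness
    r3 = r2 + spec.outer_thickness
    cyst_vol = sum(4.0 / 3.0 * np.pi * r**3 for _, r in spec.cysts)
    vols = {
        0: 0.0,
        1: max(np.pi * r1**2 * L - cyst_vol, 0.0),
        2: np.pi * (r2**2 - r1**2) * L,
        3: np.pi * (r3**2 - r2**2) * L,
        4: cyst_vol,
    }
    if spec.include_bladder:
        vols[5] = 4.0 / 3.0 * np.pi * _bladder_geometry(spec)[1] ** 3
    return vols


def compute_truth(spec: PhantomSpec) -> PhantomTruth:
    L1, L2 = _segment_lengths(spec)
    return PhantomTruth(
        length_mm=L1 + L2,
        inlet_diameter_mm=2.0 * spec.canal_radius,
        outlet_diameter_mm=2.0 * spec.canal_radius,
        volumes_mm3=_truth_volumes(spec),
    )


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterise the phantom by supersampled majority vote.

    Each voxel is subdivided into ``supersampling**3`` sample points that are
    classified against the continuum geometry; the voxel takes the majority
    label, ties broken by priority (cyst > canal > inner > outer > bladder).
    """
    n = spec.grid_size
    s = spec.supersampling
    affine = spec.affine()
    # sub-voxel offsets in voxel units, centred
    off = (np.arange(s) + 0.5) / s - 0.5
    counts = np.zeros((6, n, n, n), dtype=np.uint16)
    idx = np.arange(n, dtype=np.float32)
    for oi in off:
        for oj in off:
            for ok in off:
                # world coords of this sub-lattice, separable per axis
                xs = (idx + oi) * spec.spacing + affine[0, 3]
                ys = (idx + oj) * spec.spacing + affine[1, 3]
                zs = (idx + ok) * spec.spacing + affine[2, 3]
                X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
                pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
                lab = _classify_points(pts, spec).reshape(n, n, n)
                for code in range(6):
                    counts[code] += lab == code
    # majority with priority tie-break
    best = np.zeros((n, n, n), dtype=np.int16)
    best_count = counts[0].astype(np.int32).copy()
    for code in (5, 3, 2, 1, 4):  # ascending priority; later wins ties
        c = counts[code].astype(np.int32)
        take = c >= np.maximum(best_count, 1)
        best = np.where(take, code, best)
        best_count = np.maximum(best_count, c)
    vol = LabelVolume(voxels=best, affine=affine)
    return vol, compute_truth(spec)


# ---------------------------------------------------------------------------
# T2w-like rendering
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, ...], spacing: float, scale_mm: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD smooth Gaussian random field."""
    f = rng.standard_normal(shape).astype(np.float32)
    sigma = max(scale_mm / spacing, 1.0)
    f = ndimage.gaussian_filter(f, sigma=sigma, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def render_intensity(labels: LabelVolume, model: IntensityModel) -> ImageVolume:
    """Render a T2w-like image from a label map; deterministic given seed."""
    rng = np.random.default_rng(model.seed)
    spacing = float(labels.spacing[0])
    img = np.zeros(labels.shape, dtype=np.float32)
    for code, mean in model.means.items():
        img[labels.voxels == code] = mean
    if model.canal_mix_amplitude > 0:
        mix = _smooth_field(labels.shape, spacing, model.canal_mix_scale_mm, rng)
        canal = labels.voxels == 1
        img[canal] += model.canal_mix_amplitude * np.tanh(mix[canal])
    else:
        rng.standard_normal(labels.shape)  # keep the stream aligned across configs
    if model.bias_amplitude > 0:
        bias = _smooth_field(labels.shape, spacing, model.bias_scale_mm, rng)
        img *= 1.0 + model.bias_amplitude * np.tanh(bias)
    else:
        rng.standard_normal(labels.shape)
    if model.noise_sd > 0:
        img += model.noise_sd * rng.standard_normal(labels.shape).astype(np.float32)
    return ImageVolume(voxels=img, affine=labels.affine.copy())


# ---------------------------------------------------------------------------
# randomised phantom suites
# ---------------------------------------------------------------------------

def random_spec(
    rng: np.random.Generator,
    length_range: tuple[float, float] = (20.0, 45.0),
    radius_range: tuple[float, float] = (2.0, 5.0),
    bend_range_deg: tuple[float, float] = (120.0, 180.0),
    spacing: float = 0.8,
    grid_size: int = 96,
    supersampling: int = 3,
    with_cysts: bool = False,
) -> PhantomSpec:
    """Draw a random two-segment phantom with random 3D orientation.

    Total length, canal radius and the inlet-mid-outlet bend angle are
    uniform over the given ranges; the bend plane and overall orientation
    are isotropically random.  Geometry is centred on the grid.
    """
    L = rng.uniform(*length_range)
    r = rng.uniform(*radius_range)
    bend = np.deg2rad(rng.uniform(*bend_range_deg))
    s = L / 2.0
    # canonical frame: hinge at origin, bisector along +z
    half = bend / 2.0
    a = s * np.array([np.sin(half), 0.0, np.cos(half)])
    b = s * np.array([-np.sin(half), 0.0, np.cos(half)])
    Q = _random_rotation(rng)
    # centre the polyline's bounding midpoint at the origin
    pts = np.stack([a, np.zeros(3), b]) @ Q.T
    pts -= pts.mean(axis=0)
    cysts: list[tuple[tuple[float, float, float], float]] = []
    if with_cysts and r > 2.0:
        cr = rng.uniform(0.5, min(1.5, r - 1.0))
        t = rng.uniform(0.25, 0.75)
        centre = pts[1] + t * (pts[0] - pts[1])
        axis = (pts[0] - pts[1]) / np.linalg.norm(pts[0] - pts[1])
        # keep the sphere strictly inside the tube
        if t * s >= cr + 0.2 and (1 - t) * s >= cr + 0.2 and r - cr >= 0.2:
            cysts.append((tuple(centre), float(cr)))
    return PhantomSpec(
        inlet_point=tuple(pts[0]),
        mid_point=tuple(pts[1]),
        outlet_point=tuple(pts[2]),
        canal_radius=float(r),
        cysts=tuple(cysts),
        grid_size=grid_size,
        spacing=spacing,
        supersampling=supersampling,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
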