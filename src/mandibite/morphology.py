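"""Parametric hollow mandible-like shapes with tagged anatomical regions.

The generator emulates what a segmented µCT scan of an ant worker mandible
provides downstream: a watertight, hollow cuticle shell with

* a blade running from the head articulation (base, x = 0) to the tip
  (x = blade_length), curving toward the inner (+y) side,
* a masticatory margin along the inner edge, optionally bearing teeth,
  ending in an apical tooth at the tip,
* two small articulation patches (dorsal / ventral condyles) at the base,
* an apodeme-insertion patch at the inner-posterior base where the closer
  muscle (0md1) pulls.

Shapes are defined as approximate signed-distance functions; the cuticle
shell is the set of points within ``cuticle_thickness`` of the outer
surface (with the local thickness clamped to half the local cross-section
so thin teeth stay solid).  The shell is voxelized and Kuhn-subdivided
into tetrahedra, which guarantees watertightness, positive element
volumes, and bit-identical output for identical parameters.

Morphotypes roughly span the disparity seen across ant workers: the
common shovel shape (narrow base, triangular blade), the falcate (sickle)
blade, the elongate straight blade of trap-jaw ants, and the stout blade
of majors in polymorphic species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import MeshQualityError, ParameterError
from .tetmesh import TaggedTetMesh, boundary_faces, voxels_to_tets

MORPHOTYPES = ("shovel", "falcate", "trapjaw", "robust_major")

#: minimum blade_length / blade_width ratio for a trap-jaw blade
TRAPJAW_ELONGATION = 4.0

# per-morphotype shape coefficients: (width taper slope, minimum width
# fraction, cross-section height/width ratio)
_SHAPE = {
    "shovel": (0.85, 0.14, 0.55),
    "falcate": (0.80, 0.12, 0.60),
    "trapjaw": (0.60, 0.15, 0.80),
    "robust_major": (0.55, 0.30, 0.70),
}


@dataclass(frozen=True)
class MorphotypeParams:
    """Generator parameters for one synthetic mandible.

    Lengths are mm.  ``curvature`` is the dimensionless in-plane bend of the
    blade centerline (tip deflection toward the inner side as a fraction of
    blade length).  ``voxel_size`` controls mesh density (None picks a
    morphotype default yielding a few thousand tetrahedra).
    """

    morphotype: str
    blade_length: float
    blade_width: float
    cuticle_thickness: float
    n_teeth: int = 0
    curvature: float = 0.0
    seed: int = 0
    voxel_size: float | None = None
    patch_radius_frac: float = 0.16
    apical_capable: bool = True

    def __post_init__(self):
        if self.morphotype not in MORPHOTYPES:
            raise ParameterError(
                f"morphotype must be one of {MORPHOTYPES}, got {self.morphotype!r}"
            )
        for name in ("blade_length", "blade_width", "cuticle_thickness"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.cuticle_thickness >= self.blade_width / 2:
            raise ParameterError(
                "cuticle_thickness must be below blade_width/2 "
                f"({self.cuticle_thickness} >= {self.blade_width / 2})"
            )
        if self.n_teeth < 0 or int(self.n_teeth) != self.n_teeth:
            raise ParameterError("n_teeth must be a non-negative integer")
        if self.curvature < 0:
            raise ParameterError("curvature must be >= 0")
        if self.voxel_size is not None and self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")
        if not (0 < self.patch_radius_frac < 1):
            raise ParameterError("patch_radius_frac must be in (0, 1)")
        if (
            self.morphotype == "trapjaw"
            and self.blade_length / self.blade_width < TRAPJAW_ELONGATION
        ):
            raise ParameterError(
                "blade_length/blade_width must be >= "
                f"{TRAPJAW_ELONGATION} for the trapjaw morphotype"
            )

    @classmethod
    def preset(cls, morphotype: str, seed: int = 0, scale: float = 1.0,
               **overrides) -> "MorphotypeParams":
        """Study-condition defaults per morphotype (ant-worker scale, mm)."""
        base = {
            "shovel": dict(blade_length=1.0, blade_width=0.45,
                           cuticle_thickness=0.055, n_teeth=5, curvature=0.25),
            "falcate": dict(blade_length=1.2, blade_width=0.30,
                            cuticle_thickness=0.045, n_teeth=1, curvature=0.50),
            "trapjaw": dict(blade_length=1.6, blade_width=0.28,
                            cuticle_thickness=0.045, n_teeth=2, curvature=0.05,
                            apical_capable=False),
            "robust_major": dict(blade_length=0.9, blade_width=0.55,
                                 cuticle_thickness=0.10, n_teeth=2,
                                 curvature=0.20),
        }
        if morphotype not in base:
            raise ParameterError(
                f"morphotype must be one of {MORPHOTYPES}, got {morphotype!r}"
            )
        kw = dict(base[morphotype])
        for key in ("blade_length", "blade_width", "cuticle_thickness"):
            kw[key] = kw[key] * scale
        kw.update(overrides)
        return cls(morphotype=morphotype, seed=seed, **kw)


class _BladeShape:
    """Evaluates the parametric outer shape and its anatomical frame."""

    def __init__(self, params: MorphotypeParams):
        self.p = params
        slope, wmin, hratio = _SHAPE[params.morphotype]
        self.slope, self.wmin, self.hratio = slope, wmin, hratio
        self.L = params.blade_length
        self.W = params.blade_width
        rng = np.random.default_rng(params.seed)
        # tooth stations along the margin, jittered a little like real
        # dentition; the apical tooth is always present at the tip
        if params.n_teeth > 0:
            s = np.linspace(0.38, 0.88, params.n_teeth)
            s = s + rng.uniform(-0.02, 0.02, size=params.n_teeth)
            self.tooth_s = np.clip(s, 0.35, 0.9)
        else:
            self.tooth_s = np.empty(0)

    # -- cross-section profile -------------------------------------------
    def half_width(self, s):
        return self.W / 2 * np.maximum(1.0 - self.slope * s, self.wmin)

    def half_height(self, s):
        return self.hratio * self.half_width(s)

    def centerline_y(self, s):
        return self.p.curvature * self.L * s**2

    # -- implicit outer surface (approximate signed distance, <0 inside) --
    def outer(self, pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
        s = np.clip(x / self.L, 0.0, 1.0)
        a = self.half_width(s)
        b = self.half_height(s)
        dy = y - self.centerline_y(s)
        r = np.sqrt((dy / a) ** 2 + (z / b) ** 2)
        f = (r - 1.0) * np.minimum(a, b)
        f = np.maximum(f, -x)            # base cap
        f = np.maximum(f, x - self.L)    # tip cap
        for sk in self.tooth_s:
            ak = self.half_width(sk)
            rt = np.clip(0.45 * ak, 0.02 * self.L, 0.12 * self.L)
            cx, cy = sk * self.L, self.centerline_y(sk) + 0.9 * ak
            ax_ = np.array([rt, 1.7 * rt, 0.8 * rt])
            rr = np.sqrt(((x - cx) / ax_[0]) ** 2 + ((y - cy) / ax_[1]) ** 2
                         + (z / ax_[2]) ** 2)
            ft = (rr - 1.0) * ax_.min()
            ft = np.maximum(ft, -x)
            f = np.minimum(f, ft)
        return f

    def local_thickness(self, pts: np.ndarray) -> np.ndarray:
        """Cuticle thickness clamped to half the local cross-section."""
        s = np.clip(pts[..., 0] / self.L, 0.0, 1.0)
        half = np.minimum(self.half_width(s), self.half_height(s))
        return np.minimum(self.p.cuticle_thickness, 0.5 * half)


def _default_voxel_size(params: MorphotypeParams) -> float:
    # aim for a few thousand tets: resolve the cross-section with ~12 voxels
    # but never so coarse that the cuticle shell vanishes
    return min(params.blade_width / 12.0, 0.9 * params.cuticle_thickness)


def generate_mandible(params: MorphotypeParams) -> TaggedTetMesh:
    """Generate a hollow, tagged, watertight mandible mesh.

    Identical parameters (including seed) give bit-identical meshes.
    """
    shape = _BladeShape(params)
    h = params.voxel_size or _default_voxel_size(params)
    L, W = params.blade_length, params.blade_width

    ymax = float(np.max(shape.centerline_y(np.linspace(0, 1, 64))
                        + shape.half_width(np.linspace(0, 1, 64)))) + 0.45 * W
    ymin = -W / 2 - 2 * h
    zmax = shape.half_height(0.0) + 2 * h
    origin = np.array([-h, ymin, -zmax])
    nx = int(np.ceil((L + 2 * h - origin[0]) / h))
    ny = int(np.ceil((ymax - ymin) / h))
    nz = int(np.ceil(2 * zmax / h))

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = origin + (np.stack([ii, jj, kk], axis=-1) + 0.5) * h
    f = shape.outer(centers)
    t_loc = shape.local_thickness(centers)
    inside = f < 0
    shell = inside & (f >= -t_loc)
    if not shell.any():
        raise MeshQualityError(
            "voxelization produced an empty shell; decrease voxel_size"
        )
    # keep the largest face-connected component (drops stray voxels from
    # implicit-surface unions)
    labels, nlab = ndimage.label(shell)
    if nlab > 1:
        sizes = ndimage.sum_labels(shell, labels, index=np.arange(1, nlab + 1))
        shell = labels == (1 + int(np.argmax(sizes)))

    vox = np.argwhere(shell)
    nodes, tets = voxels_to_tets(vox, origin, h)

    hull_volume = float(inside.sum()) * h**3
    shell_volume = float(shell.sum()) * h**3

    mesh = TaggedTetMesh(
        nodes=nodes,
        tets=tets,
        apodeme_direction=_unit(np.array([-0.6, -0.8, 0.0])),
        metadata={
            "morphotype": params.morphotype,
            "seed": params.seed,
            "voxel_size": h,
            "params": asdict(params),
            "apical_capable": params.apical_capable,
            # global bite-contact load direction for strike scenarios:
            # reaction of the bitten object presses the inner margin (-y)
            "strike_direction": [0.0, -1.0, 0.0],
            "outer_hull_volume_mm3": hull_volume,
            "shell_voxel_volume_mm3": shell_volume,
        },
    )
    mesh.region_tags = _tag_regions(mesh, shape, h)
    return mesh


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _patch(points, surf_ids, center, radius, min_count=6):
    d = np.linalg.norm(points - center, axis=1)
    sel = np.flatnonzero(d <= radius)
    if sel.size < min_count:
        sel = np.argsort(d)[:min_count]
    return surf_ids[sel]


def _tag_regions(mesh: TaggedTetMesh, shape: _BladeShape, h: float):
    """Geometric tagging of the five anatomical node sets on the surface."""
    faces, _ = boundary_faces(mesh.tets)
    surf_ids = np.unique(faces)
    pts = mesh.nodes[surf_ids]
    L, W = shape.L, shape.W
    s = np.clip(pts[:, 0] / L, 0.0, 1.0)
    a = shape.half_width(s)
    dy = pts[:, 1] - shape.centerline_y(s)

    # anchor the apical region at the actual distal end of the voxelized
    # surface: strong taper can truncate the shell slightly short of L
    x_tip = pts[:, 0].max()
    apical_len = max(0.08 * L, 2.5 * h)
    apical_mask = pts[:, 0] > x_tip - apical_len
    margin_mask = ((dy > 0.45 * a) & (s > 0.3)) | apical_mask

    b0 = shape.half_height(0.0)
    r_art = max(shape.p.patch_radius_frac * W, 1.8 * h)
    art_d = _patch(pts, surf_ids, np.array([0.06 * L, 0.0, b0]), r_art)
    art_v = _patch(pts, surf_ids, np.array([0.06 * L, 0.0, -b0]), r_art)
    a0 = shape.half_width(0.0)
    apo = _patch(
        pts, surf_ids, np.array([0.06 * L, -0.95 * a0, 0.0]),
        max(0.14 * W, 1.8 * h),
    )

    margin = surf_ids[margin_mask]
    apical = surf_ids[margin_mask & apical_mask]
    art = np.union1d(art_d, art_v)
    # articulations take precedence; keep load/fix sets disjoint
    margin = np.setdiff1d(margin, np.union1d(art, apo))
    apical = np.setdiff1d(apical, np.union1d(art, apo))
    apo = np.setdiff1d(apo, art)
    tags = {
        "articulation_dorsal": art_d,
        "articulation_ventral": np.setdiff1d(art_v, art_d),
        "masticatory_margin": margin,
        "apical_tooth": apical,
        "apodeme_insertion": apo,
    }
    for name, tag in tags.items():
        if tag.size == 0:
            raise MeshQualityError(
                f"region tag '{name}' came out empty; decrease voxel_size"
            )
    return tags
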