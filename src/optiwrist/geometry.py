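"""Tetrahedral wrist geometry: canonical cylinder / truncated-cone meshes and
synthetic labeled digital wrists.

The canonical reconstruction domain is a cylinder (axis along z, z=0 at the
distal face, all lengths in mm).  Meshes are built on a structured
disk-triangulation extruded into triangular prisms, each prism split into
three tetrahedra with the minimum-global-index diagonal rule, which yields a
conforming mesh without any external mesher.  Downstream code relies only on
(nodes, tets, labels), never on how the mesh was produced.

Tissue classes follow the convention 1=muscle, 2=bone, 3=vessel, 4=lipid,
5=skin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: tissue class codes
MUSCLE, BONE, VESSEL, LIPID, SKIN = 1, 2, 3, 4, 5
TISSUE_NAMES = {MUSCLE: "muscle", BONE: "bone", VESSEL: "vessel",
                LIPID: "lipid", SKIN: "skin"}
VALID_LABELS = frozenset(TISSUE_NAMES)


class GeometryError(ValueError):
    """Invalid geometric input (non-positive dimension, overlap, ...)."""


# ---------------------------------------------------------------------------
# mesh containers
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Tetrahedral mesh with cached boundary information.

    Attributes
    ----------
    nodes : (N, 3) float array, coordinates in mm.
    tets : (E, 4) int array of node indices, positively oriented.
    """

    nodes: np.ndarray
    tets: np.ndarray
    _surface_tris: np.ndarray | None = field(default=None, repr=False)
    _surface_normals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise GeometryError("nodes must be an (N, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise GeometryError("tets must be an (E, 4) array")
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= len(self.nodes):
            raise GeometryError("tet node indices out of range")
        self._orient_positive()

    def _orient_positive(self) -> None:
        vols = _signed_volumes(self.nodes, self.tets)
        flip = vols < 0
        if flip.any():
            self.tets[flip, 2], self.tets[flip, 3] = (
                self.tets[flip, 3].copy(), self.tets[flip, 2].copy())
            vols = np.abs(vols)
        if (vols <= 0).any():
            raise GeometryError("degenerate (zero-volume) tetrahedra present")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        cached = getattr(self, "_volumes", None)
        if cached is None:
            cached = np.abs(_signed_volumes(self.nodes, self.tets))
            self._volumes = cached
        return cached

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def surface(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary triangles and their outward unit normals."""
        if self._surface_tris is None:
            self._surface_tris, self._surface_normals = _boundary_faces(
                self.nodes, self.tets)
        return self._surface_tris, self._surface_normals

    def surface_nodes(self) -> np.ndarray:
        tris, _ = self.surface()
        return np.unique(tris)

    def with_nodes(self, nodes: np.ndarray) -> "TetMesh":
        """Same topology on new coordinates (surface cache is recomputed)."""
        return TetMesh(np.asarray(nodes, float), self.tets.copy())


@dataclass
class LabeledTetMesh:
    """A :class:`TetMesh` with a per-node tissue class and size metadata."""

    mesh: TetMesh
    labels: np.ndarray
    radius: float = np.nan     # envelope radius (mean of top/bottom for cones)
    height: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.mesh.n_nodes,):
            raise GeometryError("labels must have one entry per node")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise GeometryError(f"invalid tissue labels {sorted(bad)}; "
                                f"allowed {sorted(VALID_LABELS)}")

    @property
    def nodes(self) -> np.ndarray:
        return self.mesh.nodes

    @property
    def tets(self) -> np.ndarray:
        return self.mesh.tets

    def label_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def relabeled(self, labels: np.ndarray) -> "LabeledTetMesh":
        return replace(self, labels=np.asarray(labels, np.int64))


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _boundary_faces(nodes: np.ndarray, tets: np.ndarray):
    # faces of each tet, oriented so the normal points away from the 4th node
    face_idx = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    faces = tets[:, face_idx].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    key_sorted = key[order]
    dup = np.ones(len(key_sorted), dtype=bool)
    same = (key_sorted[1:] == key_sorted[:-1]).all(axis=1)
    dup[1:] &= ~same
    dup[:-1] &= ~same
    boundary = faces[order][dup]
    p = nodes[boundary]
    normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    # orient outward: away from the owning tet centroid
    owner = order[dup] // 4
    tc = nodes[tets[owner]].mean(axis=1)
    fc = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, fc - tc) < 0
    boundary[flip] = boundary[flip][:, ::-1]
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    return boundary, normals / norms


def _ring_counts(n_rings: int) -> list[int]:
    return [max(6, int(round(2 * np.pi * j))) for j in range(1, n_rings + 1)]


def _disk_points(n_rings: int) -> np.ndarray:
    """Unit-disk layout: centre node plus rings with counts proportional to
    the ring radius (near-isotropic spacing); alternate rings are offset by
    half a step to avoid slivers."""
    pts = [np.zeros((1, 2))]
    for j, n in enumerate(_ring_counts(n_rings), start=1):
        theta = 2 * np.pi * (np.arange(n) + 0.5 * (j % 2)) / n
        pts.append((j / n_rings) * np.column_stack([np.cos(theta),
                                                    np.sin(theta)]))
    return np.vstack(pts)


def _disk_triangulation(n_rings: int):
    """Node layout and 2-D triangulation of the unit disk."""
    from scipy.spatial import Delaunay
    pts = _disk_points(n_rings)
    tris = Delaunay(pts).simplices.astype(np.int64)
    # drop degenerate slivers (cocircular corner cases)
    p = pts[tris]
    u = p[:, 1] - p[:, 0]
    v = p[:, 2] - p[:, 0]
    area2 = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    keep = np.abs(area2) > 1e-12
    tris = tris[keep]
    flip = area2[keep] < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2].copy(), tris[flip, 1].copy()
    return pts, tris


def _prisms_to_tets(tri: np.ndarray, bot: np.ndarray, top: np.ndarray):
    """Split one prism layer into tets with the min-index diagonal rule.

    ``bot``/``top`` map local triangle vertices to global ids; because top ids
    are a constant offset above bottom ids, the prism's smallest global vertex
    is always on the bottom face, so the two quads adjacent to it take their
    diagonal from it and the third quad from its own smallest corner.  Both
    resulting configurations decompose into three conforming tets.
    """
    tets = []
    for t in tri:
        b = bot[list(t)]
        u = top[list(t)]
        # rotate so b[0] is the smallest bottom vertex
        r = int(np.argmin(b))
        b = np.roll(b, -r)
        u = np.roll(u, -r)
        v0, v1, v2 = b
        v3, v4, v5 = u
        if v1 < v2:   # diagonal (v1, v5) on the far quad
            tets.append((v0, v1, v2, v5))
            tets.append((v0, v1, v5, v4))
            tets.append((v0, v4, v5, v3))
        else:         # diagonal (v2, v4)
            tets.append((v0, v1, v2, v4))
            tets.append((v0, v2, v5, v4))
            tets.append((v0, v4, v5, v3))
    return tets


def _lattice_dims(radius: float, height: float, target_nodes: int):
    """Pick (n_rings, n_layers) whose node count is near the target with
    roughly isotropic spacing."""
    best = None
    for nr in range(1, 80):
        npl = 1 + sum(_ring_counts(nr))
        nz0 = max(2, int(round(height / (radius / nr))))
        for nz in {max(2, nz0 + d) for d in (-2, -1, 0, 1, 2)}:
            n = npl * (nz + 1)
            score = abs(n - target_nodes)
            if best is None or score < best[0]:
                best = (score, nr, nz)
    _, nr, nz = best
    return nr, nz


def _extruded_mesh(radius_of_z, height: float, target_nodes: int,
                   ref_radius: float) -> TetMesh:
    n_rings, n_layers = _lattice_dims(ref_radius, height, target_nodes)
    pts2, tris = _disk_triangulation(n_rings)
    npl = len(pts2)
    zs = np.linspace(0.0, height, n_layers + 1)
    nodes = np.empty((npl * (n_layers + 1), 3))
    for l, z in enumerate(zs):
        r = radius_of_z(z)
        nodes[l * npl:(l + 1) * npl, :2] = pts2 * r
        nodes[l * npl:(l + 1) * npl, 2] = z
    all_tets = []
    base = np.arange(npl)
    for l in range(n_layers):
        all_tets.extend(_prisms_to_tets(tris, base + l * npl, base + (l + 1) * npl))
    return TetMesh(nodes, np.asarray(all_tets, dtype=np.int64))


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def build_cylinder_mesh(radius: float, height: float,
                        target_nodes: int) -> TetMesh:
    """Structured cylinder mesh (radius/height in mm).

    The node count lands within +-15% of ``target_nodes``; every node
    satisfies x^2 + y^2 <= R^2 and z in [0, H].
    """
    if radius <= 0 or height <= 0:
        raise GeometryError("cylinder radius and height must be positive")
    if target_nodes < 50:
        raise GeometryError("target_nodes must be at least 50")
    mesh = _extruded_mesh(lambda z: radius, height, target_nodes, radius)
    _check_node_budget(mesh.n_nodes, target_nodes)
    return mesh


def build_truncated_cone_mesh(r_top: float, r_bottom: float, height: float,
                              target_nodes: int) -> TetMesh:
    """Truncated-cone mesh; lateral radius varies linearly from ``r_top`` at
    z=0 (distal face) to ``r_bottom`` at z=H."""
    if r_top <= 0 or r_bottom <= 0 or height <= 0:
        raise GeometryError("cone radii and height must be positive")
    if target_nodes < 50:
        raise GeometryError("target_nodes must be at least 50")
    ref = 0.5 * (r_top + r_bottom)

    def radius_of_z(z):
        return r_top + (r_bottom - r_top) * z / height

    mesh = _extruded_mesh(radius_of_z, height, target_nodes, ref)
    _check_node_budget(mesh.n_nodes, target_nodes)
    return mesh


def _check_node_budget(n: int, target: int) -> None:
    if abs(n - target) > 0.15 * target:
        raise GeometryError(
            f"structured lattice produced {n} nodes, outside +-15% of the "
            f"requested {target}")


# ---------------------------------------------------------------------------
# surface queries
# ---------------------------------------------------------------------------

def _lateral_mask(normals: np.ndarray, z_cos: float = 0.9) -> np.ndarray:
    return np.abs(normals[:, 2]) < z_cos


def surface_radii(mesh: TetMesh, node_indices: np.ndarray | None = None,
                  chunk: int = 256) -> np.ndarray:
    """Distance from the z-axis to the lateral surface along each node's
    radial ray, using the nearest intersected-facet centroid as control point.

    Nodes falling on the axis use the +x direction.  Rays that miss every
    lateral facet (a numerical corner case) fall back to the radius of the
    nearest lateral surface node, with a logged warning.
    """
    tris, normals = mesh.surface()
    lat = tris[_lateral_mask(normals)]
    if len(lat) == 0:
        raise GeometryError("mesh has no lateral surface facets")
    if node_indices is None:
        node_indices = np.arange(mesh.n_nodes)
    node_indices = np.atleast_1d(np.asarray(node_indices, dtype=np.int64))

    v0 = mesh.nodes[lat[:, 0]]
    e1 = mesh.nodes[lat[:, 1]] - v0
    e2 = mesh.nodes[lat[:, 2]] - v0
    centroids = mesh.nodes[lat].mean(axis=1)
    cent_r = np.hypot(centroids[:, 0], centroids[:, 1])

    pts = mesh.nodes[node_indices]
    r_xy = np.hypot(pts[:, 0], pts[:, 1])
    dirs = np.zeros((len(pts), 3))
    on_axis = r_xy < 1e-12
    dirs[~on_axis, 0] = pts[~on_axis, 0] / r_xy[~on_axis]
    dirs[~on_axis, 1] = pts[~on_axis, 1] / r_xy[~on_axis]
    dirs[on_axis, 0] = 1.0
    origins = np.column_stack([np.zeros((len(pts), 2)), pts[:, 2]])

    out = np.empty(len(pts))
    missed = []
    for start in range(0, len(pts), chunk):
        sl = slice(start, min(start + chunk, len(pts)))
        hit, t = _ray_tri_hits(origins[sl], dirs[sl], v0, e1, e2)
        for i in range(hit.shape[0]):
            cand = np.flatnonzero(hit[i])
            if cand.size == 0:
                missed.append(start + i)
                out[start + i] = np.nan
                continue
            # nearest intersected facet centroid to the node
            d = np.linalg.norm(centroids[cand] - pts[sl][i], axis=1)
            out[start + i] = cent_r[cand[np.argmin(d)]]
    if missed:
        logger.warning("surface_radii: %d rays missed all lateral facets; "
                       "falling back to nearest lateral surface node", len(missed))
        lat_nodes = np.unique(lat)
        from scipy.spatial import cKDTree
        tree = cKDTree(mesh.nodes[lat_nodes])
        _, nn = tree.query(mesh.nodes[node_indices[missed]])
        p = mesh.nodes[lat_nodes[nn]]
        out[missed] = np.hypot(p[:, 0], p[:, 1])
    return out


def _ray_tri_hits(origins, dirs, v0, e1, e2, eps=1e-12):
    """Vectorised Moller-Trumbore: (n_rays, n_tris) hit mask and distances."""
    # pvec = dir x e2  -> (R, T, 3)
    pvec = np.cross(dirs[:, None, :], e2[None, :, :])
    det = np.einsum("rtk,tk->rt", pvec, e1)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rtk,rk->rt", qvec, dirs) * inv
    t = np.einsum("rtk,tk->rt", qvec, e2) * inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t > eps)
    return hit, t


def surface_radius_along_ray(mesh: TetMesh, node_index: int) -> float:
    """Radial control-point distance for a single node (see
    :func:`surface_radii`)."""
    return float(surface_radii(mesh, np.array([node_index]))[0])


def surface_distance(mesh: TetMesh, node_indices: np.ndarray | None = None,
                     cache: np.ndarray | None = None) -> np.ndarray:
    """Radial depth of each node below the lateral surface:
    R_surface(ray) - r_node.  A precomputed ``surface_radii`` array may be
    supplied via ``cache``."""
    if node_indices is None:
        node_indices = np.arange(mesh.n_nodes)
    rs = cache[node_indices] if cache is not None else surface_radii(mesh, node_indices)
    pts = mesh.nodes[node_indices]
    return rs - np.hypot(pts[:, 0], pts[:, 1])


# ---------------------------------------------------------------------------
# synthetic wrist anatomy
# ---------------------------------------------------------------------------

@dataclass
class Tube:
    """A z-parallel (optionally gently sinusoidal) circular tube."""
    center: tuple[float, float]
    radius: float
    wobble_amp: float = 0.0
    wobble_phase: float = 0.0

    def axis_at(self, z: np.ndarray, height: float) -> np.ndarray:
        cx, cy = self.center
        if self.wobble_amp == 0.0:
            return np.column_stack([np.full_like(z, cx), np.full_like(z, cy)])
        ph = 2 * np.pi * z / max(height, 1e-9) + self.wobble_phase
        return np.column_stack([cx + self.wobble_amp * np.sin(ph),
                                cy + self.wobble_amp * np.cos(ph)])

    def max_extent(self) -> float:
        cx, cy = self.center
        return float(np.hypot(cx, cy) + self.radius + self.wobble_amp)


@dataclass
class WristAnatomySpec:
    """Synthetic wrist anatomy: two forearm bones, a handful of z-parallel
    vessels, a subcutaneous lipid band and a 1.5 mm skin shell.

    This is a fixture stand-in for MRI-derived anatomy, with enough knobs to
    emulate inter-individual variation (jittered radii/positions/thickness).
    """
    radius: float = 27.0
    height: float = 60.0
    bones: list[Tube] = field(default_factory=list)
    vessels: list[Tube] = field(default_factory=list)
    lipid_thickness: float = 3.0
    skin_thickness: float = 1.5
    seed: int = 0

    @classmethod
    def canonical(cls, radius: float = 27.0, height: float = 60.0,
                  seed: int = 0, jitter: float = 0.0,
                  n_bones: int = 2, n_vessels: int = 4) -> "WristAnatomySpec":
        """Default anatomy scaled to ``radius``; ``jitter`` (fractional, e.g.
        0.1) perturbs radii, positions and the lipid thickness with ``seed``."""
        rng = np.random.default_rng(seed)
        s = radius / 27.0

        def j():
            return 1.0 + jitter * rng.uniform(-1, 1)

        def shift():
            return jitter * radius * 0.3 * rng.uniform(-1, 1)

        bone_layout = [((9.0, -3.0), 6.0), ((-9.5, -4.0), 5.0),
                       ((0.0, 6.0), 3.5), ((0.0, -11.0), 3.0)]
        # arteries (radial/ulnar analogues) run at mid depth; the large
        # cephalic/basilic-like veins are subcutaneous, just under the lipid
        vessel_layout = [((15.5, 9.5), 1.4), ((-15.0, 10.5), 1.3),
                         ((14.5, -15.5), 2.2), ((-13.0, -16.5), 2.0),
                         ((2.0, 17.0), 1.0), ((-3.0, -17.5), 1.0)]
        bones = [Tube((c[0] * s + shift(), c[1] * s + shift()), r * s * j())
                 for c, r in bone_layout[:n_bones]]
        # straight tubes: wrist vessels keep consistent directional
        # orientations across individuals; variation enters through the
        # jittered centres and radii (set wobble on a Tube for curved paths)
        vessels = [Tube((c[0] * s + shift(), c[1] * s + shift()), r * j())
                   for c, r in vessel_layout[:n_vessels]]
        return cls(radius=radius, height=height, bones=bones, vessels=vessels,
                   lipid_thickness=3.0 * s * j(), skin_thickness=1.5,
                   seed=seed)

    def validate(self) -> None:
        inner = self.radius - self.skin_thickness
        tubes = self.bones + self.vessels
        for t in tubes:
            if t.max_extent() > inner + 1e-9:
                raise GeometryError(
                    f"structure at {t.center} (r={t.radius}) does not fit "
                    f"inside the wrist envelope")
        for i in range(len(tubes)):
            for k in range(i + 1, len(tubes)):
                a, b = tubes[i], tubes[k]
                gap = (np.hypot(a.center[0] - b.center[0],
                                a.center[1] - b.center[1])
                       - a.radius - b.radius - a.wobble_amp - b.wobble_amp)
                if gap < 0:
                    raise GeometryError(
                        f"overlapping structures at {a.center} and {b.center}")


def build_synthetic_wrist(spec: WristAnatomySpec,
                          mesh: TetMesh) -> LabeledTetMesh:
    """Label a mesh's nodes according to a :class:`WristAnatomySpec`.

    Priority (deepest wins over background): muscle background, lipid band,
    bone, vessel; the superficial ``skin_thickness`` shell is labeled skin
    last.  Deterministic for a fixed spec.
    """
    spec.validate()
    nodes = mesh.nodes
    rs = surface_radii(mesh)
    depth = rs - np.hypot(nodes[:, 0], nodes[:, 1])

    labels = np.full(mesh.n_nodes, MUSCLE, dtype=np.int64)
    labels[depth < spec.skin_thickness + spec.lipid_thickness] = LIPID
    z = nodes[:, 2]
    for tube in spec.bones:
        ax = tube.axis_at(z, spec.height)
        inside = np.hypot(nodes[:, 0] - ax[:, 0], nodes[:, 1] - ax[:, 1]) <= tube.radius
        labels[inside] = BONE
    # vessels are subgrid structures at typical resolutions: besides the
    # inside-tube rule, label the node nearest each axis sample so every
    # vessel keeps a connected node chain (nearest-node assignment)
    from scipy.spatial import cKDTree
    tree = cKDTree(nodes)
    z_samples = np.linspace(z.min(), z.max(), 4 * max(8, int(spec.height)))
    for tube in spec.vessels:
        ax = tube.axis_at(z, spec.height)
        inside = np.hypot(nodes[:, 0] - ax[:, 0], nodes[:, 1] - ax[:, 1]) <= tube.radius
        labels[inside] = VESSEL
        ax_s = tube.axis_at(z_samples, spec.height)
        pts = np.column_stack([ax_s, z_samples])
        _, nn = tree.query(pts)
        labels[np.unique(nn)] = VESSEL
    labels[depth < spec.skin_thickness] = SKIN
    return LabeledTetMesh(mesh, labels, radius=spec.radius, height=spec.height)
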