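"""Linear tetrahedral FEM for the photon diffusion model.

The Laplace-domain diffusion equation on a labeled mesh,

    -div(kappa grad Phi) + (mu_a + p/c) Phi = q,
    kappa = 1 / [3 (mu_a + mu_s')],

with the Robin (partial-current) boundary condition
``Phi + 2 A kappa dPhi/dn = 0`` discretises to the symmetric positive
definite system ``(K0 + p M) Phi = q`` where ``K0`` collects the stiffness,
absorption-mass and boundary-mass terms and ``M`` is the mass matrix divided
by the in-tissue light speed.  One factorisation per (properties, p) serves
all probe positions.

Sources are isotropic points one transport mean free path below the surface,
injected with barycentric weights onto the enclosing tetrahedron; detector
readings reuse the detector's own injection vector (an adjoint-consistent
sampling that makes source-detector reciprocity exact to solver precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .geometry import LabeledTetMesh, TetMesh

C0_MM_PER_PS = 0.29979          # vacuum light speed


class OpticalModelError(ValueError):
    """Missing or non-physical optical properties."""


@dataclass
class RegionOpticalModel:
    """Per-region absorption / reduced scattering (mm^-1) at one wavelength.

    The in-tissue light speed is always derived as c0/n, never stored.
    """
    mua: dict[int, float]
    musp: dict[int, float]
    n: float = 1.4
    wavelength: float = 830.0

    def __post_init__(self) -> None:
        for c, v in self.mua.items():
            if v <= 0:
                raise OpticalModelError(f"mua must be positive (region {c})")
        for c, v in self.musp.items():
            if v <= 0:
                raise OpticalModelError(f"musp must be positive (region {c})")
        if set(self.mua) != set(self.musp):
            raise OpticalModelError("mua and musp must cover the same regions")

    @property
    def c(self) -> float:
        """In-tissue light speed (mm/ps)."""
        return C0_MM_PER_PS / self.n

    def kappa(self, region: int) -> float:
        return 1.0 / (3.0 * (self.mua[region] + self.musp[region]))

    def regions(self) -> list[int]:
        return sorted(self.mua)

    @classmethod
    def homogeneous(cls, mua: float, musp: float, regions=(1, 2, 3, 4, 5),
                    n: float = 1.4, wavelength: float = 830.0):
        return cls({c: mua for c in regions}, {c: musp for c in regions},
                   n=n, wavelength=wavelength)


def robin_A(n_rel: float) -> float:
    """Internal-reflection parameter from the Groenhuis polynomial fit of the
    effective Fresnel reflection coefficient."""
    r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


def element_labels(labeled: LabeledTetMesh) -> np.ndarray:
    """Majority tissue label per element (ties to the smaller label)."""
    node_labels = labeled.labels[labeled.tets]            # (E, 4)
    classes = np.unique(labeled.labels)
    counts = np.stack([(node_labels == c).sum(axis=1) for c in classes])
    return classes[np.argmax(counts, axis=0)]


@dataclass
class FemSystem:
    """Assembled operators for one labeled mesh + optical model."""
    k0: sp.csr_matrix          # stiffness + absorption mass + boundary mass
    m: sp.csr_matrix           # mass / c   (multiplies the Laplace factor p)
    mass: sp.csr_matrix        # plain mass matrix (volume integration)
    robin_a: float
    model: RegionOpticalModel
    _lu_cache: dict = field(default_factory=dict, repr=False)

    def system(self, p: float) -> sp.csr_matrix:
        if p < 0:
            raise OpticalModelError("Laplace factor p must be >= 0")
        return (self.k0 + p * self.m).tocsc()

    def solve(self, p: float, rhs: np.ndarray) -> np.ndarray:
        if p not in self._lu_cache:
            self._lu_cache[p] = splu(self.system(p))
        return self._lu_cache[p].solve(rhs)


def _element_geometry(nodes: np.ndarray, tets: np.ndarray):
    p = nodes[tets]                                  # (E, 4, 3)
    d = p[:, 1:] - p[:, :1]                          # (E, 3, 3)
    vol = np.abs(np.linalg.det(d)) / 6.0
    inv = np.linalg.inv(d)                           # rows: gradients of 1..3
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:] = np.transpose(inv, (0, 2, 1))
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    return vol, grads


@dataclass
class RegionOperators:
    """Per-tissue unit stiffness/mass blocks, assembled once per labeled
    mesh; a :class:`FemSystem` for any property set is then a cheap weighted
    sum (the reconstruction loop re-solves forward models many times)."""
    stiff: dict[int, sp.csr_matrix]     # unit-kappa stiffness per label
    mass_r: dict[int, sp.csr_matrix]    # mass per label
    mass: sp.csr_matrix                 # total mass matrix
    bmass: sp.csr_matrix                # boundary mass (unit 1/(2A))
    labels_present: frozenset


def region_operators(labeled: LabeledTetMesh) -> RegionOperators:
    cached = getattr(labeled, "_region_ops", None)
    if cached is not None:
        return cached
    mesh = labeled.mesh
    elabels = element_labels(labeled)
    vol, grads = _element_geometry(mesh.nodes, mesh.tets)
    tets = mesh.tets
    n = mesh.n_nodes
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    gg = np.einsum("eik,ejk->eij", grads, grads)
    mloc = (np.ones((4, 4)) + np.eye(4)) / 20.0

    stiff: dict[int, sp.csr_matrix] = {}
    mass_r: dict[int, sp.csr_matrix] = {}
    for c in np.unique(elabels):
        sel = np.repeat(elabels == c, 16)
        sv = (vol[:, None, None] * gg).ravel()
        mv = (vol[:, None, None] * mloc).ravel()
        stiff[int(c)] = sp.coo_matrix(
            (sv[sel], (rows[sel], cols[sel])), shape=(n, n)).tocsr()
        mass_r[int(c)] = sp.coo_matrix(
            (mv[sel], (rows[sel], cols[sel])), shape=(n, n)).tocsr()
    mass = sp.coo_matrix(((vol[:, None, None] * mloc).ravel(), (rows, cols)),
                         shape=(n, n)).tocsr()
    tris, _ = mesh.surface()
    pt = mesh.nodes[tris]
    areas = 0.5 * np.linalg.norm(
        np.cross(pt[:, 1] - pt[:, 0], pt[:, 2] - pt[:, 0]), axis=1)
    bloc = (np.ones((3, 3)) + np.eye(3)) / 12.0
    bvals = (areas[:, None, None] * bloc).ravel()
    brows = np.repeat(tris, 3, axis=1).ravel()
    bcols = np.tile(tris, (1, 3)).ravel()
    bmass = sp.coo_matrix((bvals, (brows, bcols)), shape=(n, n)).tocsr()
    ops = RegionOperators(
        stiff=stiff, mass_r=mass_r, mass=mass, bmass=bmass,
        labels_present=frozenset(int(c)
                                 for c in np.unique(labeled.labels)) |
        frozenset(stiff))
    labeled._region_ops = ops           # cache on the instance
    return ops


def assemble(labeled: LabeledTetMesh, model: RegionOpticalModel,
             robin: bool = True) -> FemSystem:
    """Galerkin assembly on linear tets (weighted sum of the cached
    per-region operators).  ``robin=False`` drops the boundary term (a purely
    reflective boundary, used for conservation checks)."""
    ops = region_operators(labeled)
    missing = ops.labels_present - set(model.mua)
    if missing:
        raise OpticalModelError(f"model lacks properties for regions "
                                f"{sorted(missing)}")
    a = robin_A(model.n)
    k0 = None
    for c, s in ops.stiff.items():
        term = model.kappa(c) * s + model.mua[c] * ops.mass_r[c]
        k0 = term if k0 is None else k0 + term
    if robin:
        k0 = k0 + ops.bmass / (2.0 * a)
    m = (ops.mass / model.c).tocsr()
    return FemSystem(k0=k0.tocsr(), m=m, mass=ops.mass, robin_a=a,
                     model=model)


# ---------------------------------------------------------------------------
# point sources
# ---------------------------------------------------------------------------

def source_vector(mesh: TetMesh, point: np.ndarray,
                  n_candidates: int = 64) -> np.ndarray:
    """Unit isotropic point source injected with barycentric weights onto the
    enclosing tetrahedron (nearest node as a fallback outside the mesh)."""
    point = np.asarray(point, float)
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    tree = getattr(mesh, "_centroid_tree", None)
    if tree is None:
        tree = cKDTree(centroids)
        mesh._centroid_tree = tree            # cached per mesh instance
    _, cand = tree.query(point, k=min(n_candidates, mesh.n_tets))
    cand = np.atleast_1d(cand)
    q = np.zeros(mesh.n_nodes)
    for e in cand:
        tet = mesh.tets[e]
        p = mesh.nodes[tet]
        mat = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
        try:
            lam = np.linalg.solve(mat, point - p[0])
        except np.linalg.LinAlgError:
            continue
        bary = np.array([1 - lam.sum(), *lam])
        if (bary >= -1e-9).all():
            q[tet] = np.clip(bary, 0, None)
            return q
    # fall back to the nearest node
    nn = int(np.argmin(np.linalg.norm(mesh.nodes - point, axis=1)))
    q[nn] = 1.0
    return q
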