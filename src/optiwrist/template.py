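"""Statistical wrist-template construction and personalized scaling.

A cohort of subject wrist meshes is normalised onto one canonical cylinder
(radius ``R_cy``, height ``H_cy``): each node is scaled in-plane by the ratio
of the canonical radius to the subject's lateral-surface radius along that
node's radial ray, and axially by the height ratio, after which labels are
transferred to the fixed canonical node set by minimum-distance registration.
Consensus labels combine a per-node maximum-probability vote for the bulky
tissues (muscle, bone, lipid) with a coordinate-averaging rule for the
vessels, whose small cross-section makes per-node voting unreliable.  The
template is deployed by the inverse map: uniform (cylinder) or linearly
z-interpolated (truncated cone) in-plane factors applied to the canonical
coordinates.

Note on the scaling-factor direction: factors are always
(target dimension) / (source dimension) applied to the source coordinates,
so canonicalisation divides by the subject surface radius and personalized
scaling multiplies by the subject/canonical ratio; the two maps are exact
inverses of each other on the shared node set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (BONE, LIPID, MUSCLE, SKIN, VESSEL, GeometryError,
                       LabeledTetMesh, TetMesh, surface_radii)

logger = logging.getLogger(__name__)

CANONICAL_RADIUS = 27.0   # mm
CANONICAL_HEIGHT = 60.0   # mm


@dataclass
class ScalingFactors:
    """Per-node in-plane factor and the scalar axial factor."""
    m_xoy: np.ndarray
    m_z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.m_xoy)) or np.any(self.m_xoy <= 0):
            raise GeometryError("in-plane scaling factors must be finite and > 0")
        if not np.isfinite(self.m_z) or self.m_z <= 0:
            raise GeometryError("axial scaling factor must be finite and > 0")


@dataclass
class CohortLabels:
    """Per-subject label arrays, all living on one canonical node set."""
    canonical: TetMesh
    subject_labels: list[np.ndarray]

    def __post_init__(self) -> None:
        n = self.canonical.n_nodes
        if not self.subject_labels:
            raise GeometryError("cohort must contain at least one subject")
        for i, lab in enumerate(self.subject_labels):
            lab = np.asarray(lab, np.int64)
            if lab.shape != (n,):
                raise GeometryError(f"subject {i}: label array length mismatch")
            self.subject_labels[i] = lab

    @property
    def n_subjects(self) -> int:
        return len(self.subject_labels)


# ---------------------------------------------------------------------------
# canonicalisation
# ---------------------------------------------------------------------------

def scale_to_canonical(original: LabeledTetMesh,
                       r_cy: float = CANONICAL_RADIUS,
                       h_cy: float = CANONICAL_HEIGHT,
                       ) -> tuple[np.ndarray, ScalingFactors]:
    """Map a subject mesh onto the canonical cylinder envelope.

    Returns the scaled node coordinates and the per-node factors.  Surface
    nodes land on the radius-``r_cy`` circle to within the control-point
    (facet centroid) tolerance; z maps onto [0, h_cy].
    """
    nodes = original.nodes
    z = nodes[:, 2]
    h_src = float(z.max() - z.min())
    if h_src <= 0:
        raise GeometryError("source mesh has no axial extent")
    r_surf = surface_radii(original.mesh)
    if np.any(r_surf <= 1e-9):
        raise GeometryError("zero surface radius along a node ray")
    m_xoy = r_cy / r_surf
    m_z = h_cy / h_src
    scaled = np.column_stack([m_xoy * nodes[:, 0], m_xoy * nodes[:, 1],
                              m_z * (z - z.min())])
    return scaled, ScalingFactors(m_xoy=m_xoy, m_z=m_z)


def register_labels(scaled_nodes: np.ndarray, labels: np.ndarray,
                    canonical: TetMesh, tie_tol: float = 1e-12) -> np.ndarray:
    """Transfer labels onto the canonical node set by nearest-donor lookup.

    Ties (donors equidistant within ``tie_tol``) resolve to the lower donor
    index, which keeps the operation deterministic.
    """
    scaled_nodes = np.asarray(scaled_nodes, float)
    labels = np.asarray(labels, np.int64)
    if len(scaled_nodes) == 0:
        raise GeometryError("no donor nodes to register")
    if len(scaled_nodes) != len(labels):
        raise GeometryError("donor nodes and labels differ in length")
    tree = cKDTree(scaled_nodes)
    k = min(2, len(scaled_nodes))
    dist, idx = tree.query(canonical.nodes, k=k)
    if k == 1:
        return labels[idx]
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    nearest = idx[:, 0].copy()
    tied = dist[:, 1] - dist[:, 0] <= tie_tol
    nearest[tied] = np.minimum(idx[tied, 0], idx[tied, 1])
    return labels[nearest]


def assign_skin(labeled: LabeledTetMesh, depth: float = 1.5) -> LabeledTetMesh:
    """Relabel the superficial ``depth`` mm (radial distance below the
    lateral surface) as skin; deeper labels are untouched."""
    radius = labeled.radius
    if not np.isfinite(radius):
        radius = float(surface_radii(labeled.mesh).max())
    if depth >= radius:
        raise GeometryError("skin depth must be smaller than the wrist radius")
    if depth <= 0:
        return labeled.relabeled(labeled.labels.copy())
    rs = surface_radii(labeled.mesh)
    r_node = np.hypot(labeled.nodes[:, 0], labeled.nodes[:, 1])
    out = labeled.labels.copy()
    out[rs - r_node < depth] = SKIN
    return labeled.relabeled(out)


# ---------------------------------------------------------------------------
# consensus labeling
# ---------------------------------------------------------------------------

def max_probability_labels(cohort: CohortLabels,
                           classes: tuple[int, ...] = (MUSCLE, BONE, LIPID),
                           ) -> np.ndarray:
    """Per-node majority vote over the cohort, restricted to ``classes``.

    Ties go to the class with the larger cohort-wide node count, then to the
    lower class index.  Nodes where no subject carries any of the voted
    classes (e.g. unanimously vessel) fall back to the cohort-wide most
    common voted class so that every node ends up labeled.
    """
    stack = np.stack(cohort.subject_labels)          # (S, N)
    counts = np.stack([(stack == c).sum(axis=0) for c in classes])  # (C, N)
    global_counts = counts.sum(axis=1)               # cohort-wide per class
    n = stack.shape[1]
    best = np.zeros(n, dtype=np.int64)
    best_count = np.full(n, -1, dtype=np.int64)
    # visit classes in ascending tie priority (larger global count, then lower
    # class index, wins); with >=, later classes take tied nodes
    priority = sorted(range(len(classes)),
                      key=lambda i: (global_counts[i], -classes[i]))
    for i in priority:
        take = (counts[i] >= best_count) & (counts[i] > 0)
        best[take] = classes[i]
        best_count[take] = counts[i][take]
    unlabeled = best == 0
    if unlabeled.any():
        best[unlabeled] = classes[int(np.argmax(global_counts))]
    return best


def _nodal_volumes(mesh: TetMesh) -> np.ndarray:
    """Volume share of each node (a quarter of each adjacent element)."""
    vols = mesh.tet_volumes()
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.tets.ravel(), np.repeat(vols / 4.0, 4))
    return out


def _node_adjacency(mesh: TetMesh) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(mesh.n_nodes)]
    for tet in mesh.tets:
        for a in tet:
            adj[a].update(int(b) for b in tet if b != a)
    return adj


def average_vessel(cohort: CohortLabels) -> np.ndarray:
    """Template vessel node set by the coordinate-averaging rule.

    The subject whose vessel centroid lies closest to the cohort-mean vessel
    centroid donates the representative vascular morphology; its support is
    then grown or shrunk from the tube extremities (largest axial offset
    from the vessel midline, growth restricted to mesh neighbours hugging
    the existing tube) until the nodal volume matches the cohort-mean vessel
    volume to within one nodal volume share.
    Returns the canonical node indices of the template vessel.
    """
    mesh = cohort.canonical
    nvol = _nodal_volumes(mesh)
    nodes = mesh.nodes

    subj_sets, subj_vols, subj_cents = [], [], []
    for lab in cohort.subject_labels:
        mask = lab == VESSEL
        if not mask.any():
            raise GeometryError("a subject has no vessel-labeled nodes")
        idx = np.flatnonzero(mask)
        subj_sets.append(idx)
        subj_vols.append(float(nvol[idx].sum()))
        subj_cents.append(nodes[idx].mean(axis=0))
    mean_cent = np.mean(subj_cents, axis=0)
    mean_vol = float(np.mean(subj_vols))
    pick = int(np.argmin([np.linalg.norm(c - mean_cent) for c in subj_cents]))

    current = set(int(i) for i in subj_sets[pick])
    vol = float(nvol[list(current)].sum())
    z_mid = nodes[list(current), 2].mean()
    tol = float(np.median(nvol))          # "one element" worth of volume
    adj = None
    for _ in range(mesh.n_nodes):
        if abs(vol - mean_vol) <= tol:
            break
        if vol > mean_vol:
            n = max(current, key=lambda i: abs(nodes[i, 2] - z_mid))
            if abs(vol - nvol[n] - mean_vol) >= abs(vol - mean_vol):
                break
            current.discard(n)
            vol -= nvol[n]
        else:
            if adj is None:
                adj = _node_adjacency(mesh)
            frontier = set().union(*(adj[i] for i in current)) - current
            if not frontier:
                logger.warning("average_vessel: no growth candidates left")
                break
            cur = np.array(sorted(current))
            # extend the tube: candidates closest (in-plane) to the existing
            # vessel nodes, preferring the axial extremities
            def key(i):
                d_xy = np.min(np.hypot(nodes[cur, 0] - nodes[i, 0],
                                       nodes[cur, 1] - nodes[i, 1]))
                return (d_xy, -abs(nodes[i, 2] - z_mid))
            n = min(frontier, key=key)
            if abs(vol + nvol[n] - mean_vol) >= abs(vol - mean_vol):
                break
            current.add(n)
            vol += nvol[n]
    return np.array(sorted(current), dtype=np.int64)


def build_template(cohort: CohortLabels, skin_depth: float = 1.5,
                   radius: float = CANONICAL_RADIUS,
                   height: float = CANONICAL_HEIGHT) -> LabeledTetMesh:
    """Full consensus pipeline: majority vote for muscle/bone/lipid, vessel
    coordinate averaging, then the fixed superficial skin shell."""
    labels = max_probability_labels(cohort)
    labels[average_vessel(cohort)] = VESSEL
    lm = LabeledTetMesh(cohort.canonical, labels, radius=radius, height=height)
    return assign_skin(lm, skin_depth)


# ---------------------------------------------------------------------------
# error metric
# ---------------------------------------------------------------------------

REPORTED_TISSUES = (MUSCLE, BONE, VESSEL, LIPID)


def label_error(template_labels: np.ndarray, subject_labels: np.ndarray,
                tissues: tuple[int, ...] = REPORTED_TISSUES) -> dict:
    """Per-tissue template error: |N_c(template) - N_c(subject)| / N_total,
    plus the mean over the reported tissues.  Skin is excluded by default
    because its thickness is fixed on both sides by construction."""
    template_labels = np.asarray(template_labels)
    subject_labels = np.asarray(subject_labels)
    if template_labels.shape != subject_labels.shape:
        raise GeometryError("label arrays must share one node set")
    n = len(template_labels)
    per = {c: abs(int((template_labels == c).sum())
                  - int((subject_labels == c).sum())) / n
           for c in tissues}
    per["overall"] = float(np.mean([per[c] for c in tissues]))
    return per


# ---------------------------------------------------------------------------
# personalized scaling
# ---------------------------------------------------------------------------

def personalized_scale(template: LabeledTetMesh, h_t: float,
                       r_t0: float | None = None,
                       r_t1: float | None = None, r_t2: float | None = None,
                       r_cy: float | None = None, h_cy: float | None = None,
                       ) -> LabeledTetMesh:
    """Deploy the canonical template onto an individual's dimensions.

    Cylinder variant (``r_t0``): uniform in-plane factor r_t0 / r_cy.
    Truncated-cone variant (``r_t1``, ``r_t2``): per-node in-plane factor
    interpolating linearly from r_t1 at the distal face (z=0) to r_t2 at the
    proximal face (z=H_cy).  The axial factor is h_t / h_cy in both variants
    and labels are carried unchanged.
    """
    r_cy = template.radius if r_cy is None else r_cy
    h_cy = template.height if h_cy is None else h_cy
    if not (np.isfinite(r_cy) and np.isfinite(h_cy)):
        raise GeometryError("template lacks radius/height metadata")
    if h_t <= 0:
        raise GeometryError("target height must be positive")
    nodes = template.nodes
    m_z = h_t / h_cy
    if r_t0 is not None:
        if r_t0 <= 0:
            raise GeometryError("target radius must be positive")
        m_xoy = np.full(len(nodes), r_t0 / r_cy)
        radius = r_t0
    else:
        if r_t1 is None or r_t2 is None:
            raise GeometryError("provide r_t0 (cylinder) or r_t1 and r_t2 (cone)")
        if r_t1 <= 0 or r_t2 <= 0:
            raise GeometryError("target radii must be positive")
        if r_t1 == r_t2:
            warnings.warn("r_t1 == r_t2: truncated cone degenerates to a "
                          "cylinder", stacklevel=2)
        frac = nodes[:, 2] / h_cy
        m_xoy = (frac * (r_t2 - r_t1) + r_t1) / r_cy
        radius = 0.5 * (r_t1 + r_t2)
    scaled = np.column_stack([m_xoy * nodes[:, 0], m_xoy * nodes[:, 1],
                              m_z * nodes[:, 2]])
    return LabeledTetMesh(template.mesh.with_nodes(scaled),
                          template.labels.copy(), radius=radius, height=h_t)
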