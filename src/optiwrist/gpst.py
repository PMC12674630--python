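"""Region-based GPST inversion for time-domain diffuse optical tomography.

The generalized pulse spectrum technique inverts Laplace-transformed
time-resolved data at two real factors p1 != p2.  The linearised model ties
the data perturbation to an intermediate variable that mixes absorption and
scattering,

    O(r, p) = -dmua(r) - (mua(r) + p/c) dmusp(r) / musp(r),

through the absorption-type adjoint kernel (Jacobian); evaluating O at p1
and p2 then separates dmua and dmusp exactly, because O is linear in p.
With a hard anatomical prior the node Jacobian collapses to one column per
tissue region (muscle, bone, vessel, merged lipid+skin) and the tiny
perturbation system is solved by Kaczmarz row-action sweeps (ART).

Sign convention: with positive Green functions the Jacobian entries are
negative, and the linearisation reads ``J O = Gamma_model - Gamma_measured``
(an absorption increase, O < 0, lowers the boundary flux).  The inner ART
system therefore uses the negated data residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fem import RegionOpticalModel, assemble
from .geometry import BONE, LIPID, MUSCLE, SKIN, VESSEL, LabeledTetMesh
from .tdforward import (DEFAULT_P1, DEFAULT_P2, AttachedProbes,
                        solve_green_functions)

logger = logging.getLogger(__name__)

#: reconstruction regions: lipid and skin merge into one superficial layer
WRIST_REGIONS: tuple[tuple[int, ...], ...] = (
    (MUSCLE,), (BONE,), (VESSEL,), (LIPID, SKIN))
REGION_NAMES = ("muscle", "bone", "vessel", "lipid+skin")


class ReconError(RuntimeError):
    pass


class ReconDivergence(ReconError):
    """Raised when the outer iteration diverges; carries the partial state."""

    def __init__(self, message: str, state: "ReconState"):
        super().__init__(message)
        self.state = state


@dataclass
class RegionMap:
    """Node-to-region assignment (the 0/1 mapping matrix in index form)."""
    region_of_node: np.ndarray       # (N,) values in 0..C-1
    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        counts = np.bincount(self.region_of_node, minlength=len(self.groups))
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            names = [self.groups[i] for i in empty]
            raise ReconError(f"regions with zero nodes: {names}")

    @property
    def n_regions(self) -> int:
        return len(self.groups)

    def g_matrix(self) -> sp.csr_matrix:
        n = len(self.region_of_node)
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.region_of_node)),
            shape=(n, self.n_regions))

    @classmethod
    def from_labels(cls, labels: np.ndarray,
                    groups=WRIST_REGIONS) -> "RegionMap":
        labels = np.asarray(labels)
        region = np.full(len(labels), -1, dtype=np.int64)
        for c, members in enumerate(groups):
            for lab in members:
                region[labels == lab] = c
        if (region < 0).any():
            raise ReconError("labels present that belong to no region group")
        return cls(region_of_node=region, groups=tuple(groups))


def region_model(values_mua: np.ndarray, values_musp: np.ndarray,
                 rmap: RegionMap, n: float = 1.4,
                 wavelength: float = 830.0) -> RegionOpticalModel:
    """Expand per-region values back onto tissue labels."""
    mua, musp = {}, {}
    for c, members in enumerate(rmap.groups):
        for lab in members:
            mua[lab] = float(values_mua[c])
            musp[lab] = float(values_musp[c])
    return RegionOpticalModel(mua, musp, n=n, wavelength=wavelength)


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def _pair_products(phi: np.ndarray, src: np.ndarray, det: np.ndarray,
                   robin_a: float) -> np.ndarray:
    """Adjoint kernel Gamma_d(r) * Phi_s(r) per pair, (n_pairs, N)."""
    return (phi[:, det] * phi[:, src]).T / (2.0 * robin_a)


def _element_means(prod: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Mean of a per-node field over each element's 4 nodes, (n_pairs, E)."""
    return 0.25 * (prod[:, tets[:, 0]] + prod[:, tets[:, 1]]
                   + prod[:, tets[:, 2]] + prod[:, tets[:, 3]])


def jacobian_nodes(mesh: LabeledTetMesh, phi: np.ndarray,
                   probes: AttachedProbes, robin_a: float) -> np.ndarray:
    """Node-basis Jacobian (n_pairs x N): entry n is
    -(1/4) sum over elements containing n of <Gamma Phi>_e V_e."""
    tets = mesh.tets
    vols = mesh.mesh.tet_volumes()
    n = mesh.mesh.n_nodes
    e = len(tets)
    inc = sp.csr_matrix(
        (np.repeat(vols / 4.0, 4), (tets.ravel(), np.repeat(np.arange(e), 4))),
        shape=(n, e))
    prod = _pair_products(phi, probes.layout.src, probes.layout.det, robin_a)
    m = _element_means(prod, tets)
    return -(inc @ m.T).T


def jacobian_regions(mesh: LabeledTetMesh, phi: np.ndarray,
                     probes: AttachedProbes, robin_a: float,
                     rmap: RegionMap) -> np.ndarray:
    """Region-reduced Jacobian (n_pairs x C) computed directly: column c
    accumulates V_e/4 * <Gamma Phi>_e for each element node lying in c."""
    tets = mesh.tets
    vols = mesh.mesh.tet_volumes()
    # W[e, c] = V_e * (#nodes of e in region c) / 4
    reg = rmap.region_of_node[tets]                      # (E, 4)
    w = np.zeros((len(tets), rmap.n_regions))
    for c in range(rmap.n_regions):
        w[:, c] = (reg == c).sum(axis=1) * vols / 4.0
    prod = _pair_products(phi, probes.layout.src, probes.layout.det, robin_a)
    return -(_element_means(prod, tets) @ w)


def region_reduce(j_nodes: np.ndarray, rmap: RegionMap) -> np.ndarray:
    """Collapse a node Jacobian onto regions: J~ = J G."""
    if j_nodes.shape[1] != len(rmap.region_of_node):
        raise ReconError("Jacobian and region map dimensions disagree")
    return j_nodes @ rmap.g_matrix().toarray()


# ---------------------------------------------------------------------------
# ART
# ---------------------------------------------------------------------------

def art_solve(a: np.ndarray, b: np.ndarray, relaxation: float = 0.1,
              sweeps: int = 20, init: np.ndarray | None = None) -> np.ndarray:
    """Kaczmarz row-action solver with fixed relaxation and row order."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    norms = np.einsum("ij,ij->i", a, a)
    if np.all(norms == 0):
        raise ReconError("ART matrix is identically zero")
    x = np.zeros(a.shape[1]) if init is None else np.array(init, float)
    active = np.flatnonzero(norms > 0)
    for _ in range(sweeps):
        for i in active:
            x += relaxation * (b[i] - a[i] @ x) / norms[i] * a[i]
    return x


# ---------------------------------------------------------------------------
# absorption / scattering separation
# ---------------------------------------------------------------------------

def o_form(dmua, dmusp, mua, musp, c: float, p: float):
    """The intermediate variable carried by a property perturbation,

        O(p) = -dmua - (mua + p/c) dmusp / musp,

    i.e. the quantity solving ``J O = Gamma_model - Gamma_measured`` with the
    absorption-type kernel of the Jacobian (derived from the region-wise
    divergence identity; the interface flux term is neglected, which is the
    scheme's standing approximation for scattering)."""
    return -np.asarray(dmua, float) - (np.asarray(mua, float) + p / c) \
        * np.asarray(dmusp, float) / np.asarray(musp, float)


def separate_updates(o_p1: np.ndarray, o_p2: np.ndarray, mua: np.ndarray,
                     musp: np.ndarray, c: float, p1: float, p2: float):
    """Exact inversion of the linear-in-p intermediate variable:

        dmua  = ((mua c + p2) O(p1) - (mua c + p1) O(p2)) / (p1 - p2)
        dmusp = (O(p1) - O(p2)) musp c / (p2 - p1)

    Together with :func:`o_form` this is a linear bijection between
    (O(p1), O(p2)) and (dmua, dmusp) whenever p1 != p2.  Note the absorption
    line is insensitive to the sign convention of the scattering term (the
    cross terms cancel identically)."""
    if p1 == p2:
        raise ReconError("Laplace factors p1 and p2 must differ")
    o_p1 = np.asarray(o_p1, float)
    o_p2 = np.asarray(o_p2, float)
    dmua = ((mua * c + p2) * o_p1 - (mua * c + p1) * o_p2) / (p1 - p2)
    dmusp = (o_p1 - o_p2) * musp * c / (p2 - p1)
    return dmua, dmusp


# ---------------------------------------------------------------------------
# outer iteration
# ---------------------------------------------------------------------------

@dataclass
class ReconConfig:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    relaxation: float = 0.2
    sweeps: int = 40
    max_iter: int = 40
    tol: float = 1e-4              # relative residual change
    abs_tol: float = 1e-6          # residual floor (relative to data norm)
    patience: int = 12             # iterations without a new best residual
    mua_floor: float = 1e-4
    mua_ceil: float = 1.0
    musp_floor: float = 1e-4
    musp_ceil: float = 3.0
    max_step_frac: float = 0.5     # per-iteration trust region (fractional)
    max_step_frac_musp: float = 0.25   # tighter cap for the slow mus' channel
    dynamic_range: float = 0.0
    # pairs whose calibrated amplitude falls below `dynamic_range` times the
    # strongest pair at a given Laplace factor are outside the usable
    # measurement range and are excluded from that factor's ART system


@dataclass
class ReconState:
    mua: np.ndarray                # (C,) current region absorption
    musp: np.ndarray
    residuals: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    def model(self, rmap: RegionMap, n: float = 1.4,
              wavelength: float = 830.0) -> RegionOpticalModel:
        return region_model(self.mua, self.musp, rmap, n=n,
                            wavelength=wavelength)


def reconstruct(gamma_hat: np.ndarray, mesh: LabeledTetMesh, rmap: RegionMap,
                init: RegionOpticalModel, probes: AttachedProbes,
                config: ReconConfig | None = None) -> ReconState:
    """Region-based GPST outer loop.

    ``gamma_hat`` is the calibrated Laplace data table (n_pairs, 2) at
    (p1, p2).  Each iteration re-solves the forward model at the current
    properties, assembles the region Jacobians, runs ART for the
    intermediate variable at both factors, separates the updates and applies
    them per region with positivity floors and a fractional trust region.
    """
    cfg = config or ReconConfig()
    gamma_hat = np.asarray(gamma_hat, float)
    if gamma_hat.shape != (probes.layout.n_pairs, 2):
        raise ReconError("calibrated data must be (n_pairs, 2)")

    first_label = [g[0] for g in rmap.groups]
    state = ReconState(
        mua=np.array([init.mua[lab] for lab in first_label], float),
        musp=np.array([init.musp[lab] for lab in first_label], float))
    amp = np.abs(gamma_hat)
    masks = [amp[:, k] >= cfg.dynamic_range * amp[:, k].max()
             for k in range(2)]
    scale = np.linalg.norm(np.concatenate(
        [gamma_hat[m, k] for k, m in enumerate(masks)]))
    prev_res = None
    best_res = np.inf
    best_it = 0
    best_props = (state.mua.copy(), state.musp.copy())
    n_bad = 0
    for it in range(cfg.max_iter):
        model = region_model(state.mua, state.musp, rmap, n=init.n,
                             wavelength=init.wavelength)
        system = assemble(mesh, model)
        o = np.empty((rmap.n_regions, 2))
        residual_parts = []
        for k, p in enumerate((cfg.p1, cfg.p2)):
            phi, gamma_m = solve_green_functions(system, probes, p)
            delta_k = (gamma_hat[:, k] - gamma_m)[masks[k]]
            jt = jacobian_regions(mesh, phi, probes, system.robin_a,
                                  rmap)[masks[k]]
            o[:, k] = art_solve(jt, -delta_k, cfg.relaxation, cfg.sweeps)
            residual_parts.append(delta_k)
        res = float(np.linalg.norm(np.concatenate(residual_parts)) / scale)
        state.residuals.append(res)
        state.iterations = it + 1
        if res < best_res:
            best_res = res
            best_it = it
            best_props = (state.mua.copy(), state.musp.copy())
        if res < cfg.abs_tol:
            state.converged = True
            break
        if prev_res is not None:
            # genuine blow-up: residual sails past where it started
            n_bad = n_bad + 1 if res > 2.0 * state.residuals[0] else 0
            if n_bad >= 3:
                state.mua, state.musp = best_props
                raise ReconDivergence(
                    f"residual exceeded twice its initial value for "
                    f"{n_bad} iterations ({res:.3e})", state)
            if abs(prev_res - res) / max(prev_res, 1e-300) < cfg.tol:
                state.converged = True
                break
            # noisy plateau: no new best for `patience` iterations
            if it - best_it >= cfg.patience:
                state.converged = True
                break
        prev_res = res

        dmua, dmusp = separate_updates(o[:, 0], o[:, 1], state.mua,
                                       state.musp, init.c, cfg.p1, cfg.p2)
        dmua = np.clip(dmua, -cfg.max_step_frac * state.mua,
                       cfg.max_step_frac * state.mua)
        dmusp = np.clip(dmusp, -cfg.max_step_frac_musp * state.musp,
                        cfg.max_step_frac_musp * state.musp)
        new_mua = state.mua + dmua
        new_musp = state.musp + dmusp
        if (new_mua < cfg.mua_floor).any() or (new_musp < cfg.musp_floor).any():
            logger.warning("reconstruct: property floor engaged")
        state.mua = np.clip(new_mua, cfg.mua_floor, cfg.mua_ceil)
        state.musp = np.clip(new_musp, cfg.musp_floor, cfg.musp_ceil)
    # report the best iterate (robust under noisy plateaus)
    state.mua, state.musp = best_props
    return state


# ---------------------------------------------------------------------------
# error reporting
# ---------------------------------------------------------------------------

@dataclass
class ReconReport:
    """Per-region relative errors in percent and their means."""
    mua_errors: dict[str, float]
    musp_errors: dict[str, float]

    @property
    def mean_mua(self) -> float:
        return float(np.mean(list(self.mua_errors.values())))

    @property
    def mean_musp(self) -> float:
        return float(np.mean(list(self.musp_errors.values())))


def recon_error(truth_mua: np.ndarray, truth_musp: np.ndarray,
                state: ReconState,
                names: tuple[str, ...] = REGION_NAMES) -> ReconReport:
    truth_mua = np.asarray(truth_mua, float)
    truth_musp = np.asarray(truth_musp, float)
    if (truth_mua == 0).any() or (truth_musp == 0).any():
        raise ReconError("ground-truth properties must be nonzero")
    ea = np.abs(state.mua - truth_mua) / truth_mua * 100.0
    es = np.abs(state.musp - truth_musp) / truth_musp * 100.0
    return ReconReport(dict(zip(names, ea.tolist())),
                       dict(zip(names, es.tolist())))
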