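"""Spatial-frequency-domain quantification of superficial tissue.

A white Monte Carlo run (zero absorption, per-photon exit radius and total
pathlength recorded) in a semi-infinite homogeneous medium provides the
radially resolved diffuse reflectance impulse response.  Absorption is
applied afterwards by Beer-Lambert reweighting exp(-mua L), and reduced
scattering by the similarity rescaling (rho mus', L mus' invariant), so a
single photon set serves the whole lookup-table grid.  An order-zero Hankel
transform converts the radial kernel to spatial frequency, giving
Rd(fx; mua, mus') on the published grid (mua 0.001..0.5 step 0.001, mus'
0.5..1.5 step 0.01 mm^-1) at fx = 0 and 0.2 mm^-1.  Inversion restricts the
search to LUT rows bracketing the measured planar reflectance and picks the
two-frequency least-squares minimiser.

Photons launch just below the surface with unit weight (the ~3% normal
specular reflection is excluded from Rd), scatter with Henyey-Greenstein
anisotropy g, undergo Fresnel reflection/transmission at the boundary, and
are terminated by a pathlength cutoff with roulette de-biasing of the long
tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.fft import idctn
from scipy.special import j0

#: published LUT grids (mm^-1)
MUA_GRID = np.round(np.arange(1, 501) * 0.001, 6)          # 0.001..0.5
MUSP_GRID = np.round(0.5 + np.arange(101) * 0.01, 6)       # 0.5..1.5
DEFAULT_FX = (0.0, 0.2)


class SfdiError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Monte Carlo engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fresnel_internal(cos_i, n_rel):
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    # n1 = n_rel (inside), n2 = 1 (outside), up to a common factor
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _mc_kernel(n_photons, mus, g, n_rel, mua, rho_edge_max, n_rho,
               l_min, l_max, n_l, roulette_l, roulette_p, seed):
    """Semi-infinite-medium photon transport; returns the (rho, L) weight
    histogram of transmitted (escaping) photons, the weight lost to the
    pathlength cutoff, and the total launched weight."""
    np.random.seed(seed)
    hist = np.zeros((n_rho, n_l))
    d_rho = rho_edge_max / n_rho
    log_lo = np.log(l_min)
    d_log = (np.log(l_max) - log_lo) / n_l
    mut = mus + mua
    albedo = mus / mut
    truncated = 0.0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        ltot = 0.0
        next_roulette = roulette_l
        alive = True
        while alive:
            s = -np.log(np.random.random()) / mut
            while s > 0.0:
                if uz < 0.0 and z + uz * s < 0.0:
                    sb = -z / uz
                    x += ux * sb
                    y += uy * sb
                    ltot += sb
                    s -= sb
                    z = 0.0
                    if np.random.random() < _fresnel_internal(-uz, n_rel):
                        uz = -uz
                    else:
                        rho = np.sqrt(x * x + y * y)
                        ir = int(rho / d_rho)
                        if ir >= n_rho:
                            ir = n_rho - 1
                        ll = np.log(ltot) if ltot > l_min else log_lo
                        il = int((ll - log_lo) / d_log)
                        if il < 0:
                            il = 0
                        elif il >= n_l:
                            il = n_l - 1
                        hist[ir, il] += w
                        alive = False
                        s = 0.0
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    ltot += s
                    s = 0.0
            if not alive:
                break
            if ltot > l_max:
                truncated += w
                break
            while ltot > next_roulette:
                if np.random.random() < roulette_p:
                    w /= roulette_p
                    next_roulette += roulette_l
                else:
                    alive = False
                    break
            if not alive:
                break
            # Henyey-Greenstein scatter
            if g == 0.0:
                ct = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            psi = 2.0 * np.pi * np.random.random()
            cp = np.cos(psi)
            sp = np.sin(psi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                ux, uy, uz = nux, nuy, nuz
            if mua > 0.0:
                w *= albedo
                if w < 1e-4:
                    if np.random.random() < 0.1:
                        w *= 10.0
                    else:
                        alive = False
    return hist, truncated, float(n_photons)


@dataclass
class WhiteMCResult:
    """Binned (exit radius, total pathlength) weight records of a white MC
    run, plus everything needed for similarity rescaling."""
    hist: np.ndarray               # (n_rho, n_l) escape weights
    rho_edges: np.ndarray
    l_centers: np.ndarray
    n_photons: int
    musp_ref: float
    g: float
    n: float
    seed: int
    truncated_weight: float = 0.0
    baked_mua: float = 0.0

    @property
    def rho_centers(self) -> np.ndarray:
        return 0.5 * (self.rho_edges[1:] + self.rho_edges[:-1])

    def _scale(self, musp: float) -> float:
        return self.musp_ref / musp

    def rd_fx(self, mua, musp: float, fx: float) -> np.ndarray:
        """Spatial-frequency reflectance by Beer-Lambert reweighting and the
        photon-binned Hankel sum; ``mua`` may be an array."""
        mua_arr = np.atleast_1d(np.asarray(mua, float))
        s = self._scale(musp)
        jw = j0(2.0 * np.pi * fx * self.rho_centers * s)    # (n_rho,)
        a = jw @ self.hist                                  # (n_l,)
        e = np.exp(-np.outer(mua_arr, self.l_centers * s))  # (n_mua, n_l)
        out = (e @ a) / self.n_photons
        return float(out[0]) if np.isscalar(mua) else out

    def radial_profile(self, mua: float, musp: float):
        """Per-area reflectance R(rho) on the similarity-scaled radial bins."""
        s = self._scale(musp)
        edges = self.rho_edges * s
        weights = self.hist @ np.exp(-mua * self.l_centers * s)
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        return 0.5 * (edges[1:] + edges[:-1]), weights / (areas * self.n_photons)


def white_mc_reflectance(musp_ref: float = 1.0, g: float = 0.9,
                         n: float = 1.4, photons: int = 400_000,
                         seed: int = 0, mua: float = 0.0,
                         rho_max: float = 250.0, n_rho: int = 500,
                         l_max: float = 2500.0, n_l: int = 600,
                         roulette_l: float = 600.0,
                         roulette_p: float = 0.1) -> WhiteMCResult:
    """Run the Monte Carlo engine.

    With ``mua = 0`` (white mode, the default) absorption is applied later by
    reweighting; a positive ``mua`` bakes absorption into the transport
    (albedo weighting), which provides an independent estimator for
    cross-checking the reweighting.
    """
    if photons < 1e5:
        import warnings
        warnings.warn("fewer than 1e5 photons: radial tail estimates may be "
                      "unstable", stacklevel=2)
    if musp_ref <= 0 or not (0 <= g < 1):
        raise SfdiError("need musp_ref > 0 and 0 <= g < 1")
    mus = musp_ref / (1.0 - g) if g > 0 else musp_ref
    l_min = 0.01
    hist, truncated, _ = _mc_kernel(
        int(photons), mus, g, n, mua, rho_max, n_rho, l_min, l_max, n_l,
        roulette_l, roulette_p, int(seed) % 2**31)
    log_edges = np.linspace(np.log(l_min), np.log(l_max), n_l + 1)
    l_centers = np.exp(0.5 * (log_edges[1:] + log_edges[:-1]))
    return WhiteMCResult(hist=hist, rho_edges=np.linspace(0, rho_max, n_rho + 1),
                         l_centers=l_centers, n_photons=int(photons),
                         musp_ref=musp_ref, g=g, n=n, seed=int(seed),
                         truncated_weight=truncated, baked_mua=mua)


def hankel_to_fx(radial_profile: np.ndarray, rho_centers: np.ndarray,
                 fx: float) -> float:
    """Order-zero Hankel transform of a per-area radial reflectance profile:
    Rd(fx) = 2 pi  int R(rho) J0(2 pi fx rho) rho drho (midpoint quadrature).
    """
    rho_centers = np.asarray(rho_centers, float)
    d_rho = np.diff(rho_centers).mean()
    integrand = radial_profile * j0(2 * np.pi * fx * rho_centers) * rho_centers
    total = 2 * np.pi * np.sum(integrand) * d_rho
    tail = radial_profile[-1] * rho_centers[-1]
    if abs(tail * d_rho * 2 * np.pi) > 0.01 * abs(total):
        import warnings
        warnings.warn("radial bins may truncate the diffuse falloff",
                      stacklevel=2)
    return float(total)


# ---------------------------------------------------------------------------
# lookup table
# ---------------------------------------------------------------------------

@dataclass
class ReflectanceLUT:
    mua_grid: np.ndarray
    musp_grid: np.ndarray
    fx: np.ndarray
    rd: np.ndarray                 # (n_mua, n_musp, n_fx)
    photons: int = 0
    seed: int = 0
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self) -> None:
        expect = (len(self.mua_grid), len(self.musp_grid), len(self.fx))
        if self.rd.shape != expect:
            raise SfdiError(f"LUT table shape {self.rd.shape} != {expect}")

    def entry(self, mua: float, musp: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.mua_grid - mua)))
        k = int(np.argmin(np.abs(self.musp_grid - musp)))
        return self.rd[i, k]

    def monotone_fraction(self) -> float:
        """Fraction of (musp, fx) columns strictly decreasing in mua."""
        dec = np.all(np.diff(self.rd, axis=0) < 0, axis=0)
        return float(dec.mean())

    def save(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("mu_a", data=self.mua_grid)
            f.create_dataset("mu_s_prime", data=self.musp_grid)
            f.create_dataset("fx", data=self.fx)
            f.create_dataset("rd", data=self.rd)
            f.attrs.update({"photons": self.photons, "seed": self.seed,
                            "g": self.g, "n": self.n})

    @classmethod
    def load(cls, path: str) -> "ReflectanceLUT":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(mua_grid=f["mu_a"][:], musp_grid=f["mu_s_prime"][:],
                       fx=f["fx"][:], rd=f["rd"][:],
                       photons=int(f.attrs["photons"]),
                       seed=int(f.attrs["seed"]), g=float(f.attrs["g"]),
                       n=float(f.attrs["n"]))


def build_lut(mc: WhiteMCResult, mua_grid: np.ndarray = MUA_GRID,
              musp_grid: np.ndarray = MUSP_GRID,
              fx: tuple = DEFAULT_FX) -> ReflectanceLUT:
    """Evaluate the reflectance table on the requested grids at each spatial
    frequency (reweighting + similarity scaling of one white-MC photon set)."""
    mua_grid = np.asarray(mua_grid, float)
    musp_grid = np.asarray(musp_grid, float)
    rd = np.empty((len(mua_grid), len(musp_grid), len(fx)))
    for k, f in enumerate(fx):
        for i, musp in enumerate(musp_grid):
            rd[:, i, k] = mc.rd_fx(mua_grid, musp, f)
    lut = ReflectanceLUT(mua_grid=mua_grid, musp_grid=musp_grid,
                         fx=np.asarray(fx, float), rd=rd,
                         photons=mc.n_photons, seed=mc.seed, g=mc.g, n=mc.n)
    frac = lut.monotone_fraction()
    if frac < 0.99:
        import logging
        logging.getLogger(__name__).warning(
            "LUT monotonicity audit: only %.1f%% of columns strictly "
            "decreasing in mua; consider more photons", 100 * frac)
    return lut


# ---------------------------------------------------------------------------
# scenes, patterns, demodulation
# ---------------------------------------------------------------------------

@dataclass
class SfdiScene:
    """Per-pixel top-layer properties on a square pixel grid."""
    mua_map: np.ndarray
    musp_map: np.ndarray
    pitch_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.mua_map.shape != self.musp_map.shape:
            raise SfdiError("property maps must share shape")

    @property
    def shape(self):
        return self.mua_map.shape


def scene_reflectance(scene: SfdiScene, mc: WhiteMCResult,
                      fx: float) -> np.ndarray:
    """Per-pixel diffuse reflectance of a scene at one spatial frequency."""
    out = np.empty(scene.shape)
    flat_mua = scene.mua_map.ravel()
    flat_musp = scene.musp_map.ravel()
    flat = out.ravel()
    for musp in np.unique(flat_musp):
        sel = flat_musp == musp
        flat[sel] = mc.rd_fx(flat_mua[sel], float(musp), fx)
    return flat.reshape(scene.shape)


@dataclass
class PatternMeasurement:
    """Single-pixel measurements under 2-D DCT basis illumination."""
    basis: list[tuple[int, int]]
    values: np.ndarray
    shape: tuple[int, int]
    pitch_mm: float

    def __post_init__(self) -> None:
        if len(self.basis) != len(set(self.basis)):
            raise SfdiError("basis indices must be unique")


def dct_basis_image(shape, kx: int, ky: int) -> np.ndarray:
    """Orthonormal 2-D DCT-II basis pattern."""
    c = np.zeros(shape)
    c[kx, ky] = 1.0
    return idctn(c, norm="ortho")


def pattern_fx(kx: int, n: int, pitch_mm: float) -> float:
    """Physical x-frequency (cycles/mm) of DCT column kx."""
    return kx / (2.0 * n * pitch_mm)


def full_basis(shape) -> list[tuple[int, int]]:
    return [(kx, ky) for kx in range(shape[0]) for ky in range(shape[1])]


def simulate_patterns(scene: SfdiScene, mc: WhiteMCResult,
                      basis: list[tuple[int, int]],
                      available_fx: tuple = DEFAULT_FX,
                      amplitude: float = 1.0, noise_frac: float = 0.0,
                      rng: np.random.Generator | None = None,
                      ) -> PatternMeasurement:
    """Measurement per projected pattern: the per-pixel diffuse response at
    the frequency nearest the pattern's own physical x-frequency, inner-
    producted with the (orthonormal) pattern.  Optional multiplicative
    Gaussian noise."""
    n = scene.shape[0]
    available_fx = np.asarray(available_fx, float)
    maps = {f: scene_reflectance(scene, mc, f) for f in available_fx}
    values = np.empty(len(basis))
    for i, (kx, ky) in enumerate(basis):
        f = pattern_fx(kx, n, scene.pitch_mm)
        fsel = float(available_fx[np.argmin(np.abs(available_fx - f))])
        values[i] = amplitude * np.sum(maps[fsel] * dct_basis_image(scene.shape, kx, ky))
    if noise_frac > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values * (1.0 + noise_frac * rng.standard_normal(len(values)))
    return PatternMeasurement(basis=list(basis), values=values,
                              shape=scene.shape, pitch_mm=scene.pitch_mm)


def dct_demodulate(meas: PatternMeasurement, target_fx: float = 0.2):
    """Planar and AC reflectance maps from pattern measurements.

    The planar (fx = 0) map is the inverse 2-D DCT of the full coefficient
    matrix.  The AC map keeps only the coefficient column whose physical
    frequency is nearest ``target_fx`` (the demodulated component image); for
    a uniform scene it is identically zero because non-DC patterns integrate
    to zero against a flat response.
    """
    n0, n1 = meas.shape
    coeff = np.zeros(meas.shape)
    have = {b: v for b, v in zip(meas.basis, meas.values)}
    if (0, 0) not in have:
        raise SfdiError("basis must include the DC pattern")
    for (kx, ky), v in have.items():
        coeff[kx, ky] = v
    freqs = np.array([pattern_fx(k, n0, meas.pitch_mm) for k in range(n0)])
    kx_star = int(np.argmin(np.abs(freqs - target_fx)))
    if not any(b[0] == kx_star for b in meas.basis):
        raise SfdiError(f"basis lacks the column (kx={kx_star}) nearest "
                        f"fx={target_fx}")
    map_dc = idctn(coeff, norm="ortho")
    col = np.zeros_like(coeff)
    col[kx_star] = coeff[kx_star]
    map_ac = idctn(col, norm="ortho")
    return map_dc, map_ac


def calibrate_sfdi(target, reference, rd_model_ref):
    """Reference calibration per frequency:
    Rd_target = (M_target / M_ref) * Rd_model(reference properties).
    Common multiplicative gains (illumination, detector response) cancel."""
    target = np.asarray(target, float)
    reference = np.asarray(reference, float)
    rd_model_ref = np.asarray(rd_model_ref, float)
    if np.any(reference == 0):
        raise SfdiError("reference measurement contains zeros")
    return target / reference * rd_model_ref


# ---------------------------------------------------------------------------
# LUT inversion
# ---------------------------------------------------------------------------

def lut_invert(rd0, rd_fx, lut: ReflectanceLUT, margin: float = 0.05):
    """Bounded least-squares LUT search.

    Candidates are restricted to entries whose planar reflectance lies within
    the measured min/max (expanded by ``margin``); the two-frequency squared
    distance is minimised over them.  Ties resolve toward smaller mua, then
    smaller mus'.  An empty candidate set falls back to the full grid.
    """
    scalar_in = np.ndim(rd0) == 0
    rd0 = np.atleast_1d(np.asarray(rd0, float))
    rd_fx = np.atleast_1d(np.asarray(rd_fx, float))
    if rd0.shape != rd_fx.shape:
        raise SfdiError("reflectance maps must share shape")
    if not (np.all(np.isfinite(rd0)) and np.all(np.isfinite(rd_fx))):
        raise SfdiError("reflectance values must be finite")
    shape = rd0.shape
    rd0 = rd0.ravel()
    rd_fx = rd_fx.ravel()

    lut0 = lut.rd[:, :, 0].ravel()        # mua-major ordering
    lut1 = lut.rd[:, :, -1].ravel()
    lo = rd0.min() * (1.0 - margin)
    hi = rd0.max() * (1.0 + margin)
    cand = np.flatnonzero((lut0 >= lo) & (lut0 <= hi))
    if cand.size == 0:
        import warnings
        warnings.warn("no LUT entries within measured bounds; searching the "
                      "full grid", stacklevel=2)
        cand = np.arange(lut0.size)
    d = ((lut0[cand][None, :] - rd0[:, None]) ** 2
         + (lut1[cand][None, :] - rd_fx[:, None]) ** 2)
    best = cand[np.argmin(d, axis=1)]     # first minimum: smaller mua, musp
    i_mua, i_musp = np.unravel_index(best, lut.rd.shape[:2])
    mua_out = lut.mua_grid[i_mua].reshape(shape)
    musp_out = lut.musp_grid[i_musp].reshape(shape)
    if scalar_in:
        return float(mua_out[0]), float(musp_out[0])
    return mua_out, musp_out
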