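"""Probabilistic threshold-free cluster enhancement (pTFCE) of z-maps.

Voxelwise z-scores are noisy; true abnormalities tend to be spatially
coherent.  pTFCE re-weights each voxel's evidence by the sizes of the
suprathreshold clusters it belongs to across a ladder of thresholds:

1. For each of ``n_thresholds`` equidistant thresholds h_i on [0, z_max],
   connected suprathreshold components are labelled and each voxel's cluster
   size c_i(v) recorded.
2. Per threshold, an *enhanced exceedance probability* is computed by Bayes'
   rule under Gaussian-random-field (GRF) theory:

       pi_i(c) = f(c | h_i) * Q(h_i) / m(c),     m(c) = Int f(c | h) phi(h) dh

   where Q is the standard-normal survival function (the prior exceedance
   probability), phi the standard-normal density, and f(c | h) the GRF
   cluster-extent density at threshold h (Friston-form, parameterised by the
   field smoothness and search volume).  A cluster much larger than the null
   expectation at h_i makes f(c | h_i) small relative to the marginal, so
   pi_i << Q(h_i): stronger evidence.  An isolated voxel at a high threshold
   is typical of noise, so pi_i > Q(h_i): weaker evidence.
3. The per-threshold -log pi_i are summed over all h_i <= z(v) (with a
   fractional term for the partial last interval).
4. The sum S(v) is mapped back to a z-equivalent scale by inverting the same
   accumulation applied to the uninformative case pi_i = Q(h_i).  When
   cluster size carries no information the map is therefore the identity by
   construction — the calibration invariant that pins the output scale.

The enhancement is deterministic given input and config, and never looks at
voxels outside the analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

from .normative import ZMap
from .volume_io import BinaryMask, VolumeGrid

CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

_LOG_GAMMA_5_2 = float(np.log(gamma_fn(2.5)))  # Gamma(5/2) of the extent density


class PtfceError(Exception):
    """Invalid input to smoothness estimation or enhancement."""


class TooFewVoxelsError(PtfceError):
    """Not enough valid voxels to estimate field smoothness."""


class ConstantFieldError(PtfceError):
    """The field has zero variance; smoothness is undefined."""


@dataclass(frozen=True)
class PtfceConfig:
    """Tuning parameters of the enhancement.

    Attributes
    ----------
    n_thresholds
        Number of equidistant thresholds on [0, z_max_cap]; >= 10.
        The default 400 is dense enough that doubling it changes the
        output by under 1% everywhere (cluster merges make the threshold
        discretization first-order).
    connectivity
        Voxel neighbourhood (6 faces, 18 +edges, 26 +corners) used for
        cluster formation, matching the downstream cluster detection.
    smoothness_fwhm_mm
        Isotropic FWHM of the field in mm, or ``"estimate"`` to derive it
        from the subject's own z-map.
    z_max_cap
        Top of the threshold ladder; defaults to the maximum finite z.
    grf_min_z
        Below this threshold the GRF cluster-extent model is unreliable
        (the Euler-characteristic density changes sign at |z| = 1); the
        likelihood is held flat there, so low thresholds are uninformative.
    """

    n_thresholds: int = 400
    connectivity: int = 26
    smoothness_fwhm_mm: float | str = "estimate"
    z_max_cap: float | None = None
    grf_min_z: float = 1.3

    def __post_init__(self) -> None:
        if self.n_thresholds < 10:
            raise ValueError("n_thresholds must be >= 10")
        if self.connectivity not in CONNECTIVITY_STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.grf_min_z <= 1.0:
            raise ValueError("grf_min_z must exceed 1.0 (EC density validity)")


@dataclass
class EnhancedZMap:
    """pTFCE-enhanced z-scores; NaN exactly where the input z was NaN."""

    grid: VolumeGrid
    z_enh: np.ndarray
    config_used: PtfceConfig
    subject_id: str = ""
    smoothness_fwhm_mm: float = float("nan")

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.z_enh)


def estimate_smoothness(
    zmap: ZMap | np.ndarray,
    mask: BinaryMask,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> float:
    """Estimate the isotropic smoothness (FWHM, mm) of a z field.

    Uses the classic random-field estimator based on the variance of first
    spatial differences of the standardised field: for a Gaussian
    autocorrelation, neighbour correlation R at spacing d implies
    FWHM = d * sqrt(-2 ln 2 / ln R).  Per-axis estimates are combined by
    geometric mean and floored at half the mean voxel size.
    """
    if isinstance(zmap, ZMap):
        data = zmap.z
        voxel_size_mm = zmap.grid.voxel_size_mm
    else:
        data = np.asarray(zmap, dtype=float)
        if voxel_size_mm is None:
            voxel_size_mm = mask.grid.voxel_size_mm
    valid = mask.data & np.isfinite(data)
    n_valid = int(valid.sum())
    if n_valid < 1000:
        raise TooFewVoxelsError(f"{n_valid} valid voxels < 1000")
    x = np.where(valid, data, np.nan)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd <= 0:
        raise ConstantFieldError("field is constant within the mask")
    x = (x - np.nanmean(x)) / sd

    floor = 0.5 * float(np.mean(voxel_size_mm))
    fwhms = []
    for axis, d in enumerate(voxel_size_mm):
        a = np.moveaxis(x, axis, 0)
        diff = a[1:] - a[:-1]
        diff = diff[np.isfinite(diff)]
        if diff.size < 100:
            continue
        r = 1.0 - float(np.mean(diff**2)) / 2.0
        if r <= 0.0:
            fwhms.append(floor)
        elif r >= 1.0:
            fwhms.append(20.0 * d)  # indistinguishable from constant along axis
        else:
            fwhms.append(d * np.sqrt(-2.0 * np.log(2.0) / np.log(r)))
    if not fwhms:
        raise TooFewVoxelsError("no axis had enough neighbour pairs")
    est = float(np.exp(np.mean(np.log(fwhms))))
    return max(est, floor)


def _log_ec3_density(h: np.ndarray) -> np.ndarray:
    """log of the 3D Euler-characteristic density of a unit Gaussian field
    (per resel); only valid for h > 1, where the density is positive."""
    h = np.asarray(h, dtype=float)
    return (
        1.5 * np.log(4 * np.log(2))
        - 2.0 * np.log(2 * np.pi)
        + np.log(h**2 - 1.0)
        - h**2 / 2.0
    )


class _ExtentModel:
    """GRF cluster-extent log-density f(c | h), flat below ``grf_min_z``.

    Friston-form extent distribution: P(C >= c | h) = exp(-beta(h) c^(2/3))
    with beta chosen so the mean extent matches the GRF expectation
    E[N]/E[m] = V Q(h) / (R rho_3(h)) voxels, where V is the search volume in
    voxels and R in resels.
    """

    def __init__(self, n_voxels: int, resels: float, grf_min_z: float):
        self.n_voxels = n_voxels
        self.resels = resels
        self.grf_min_z = grf_min_z

    def log_beta(self, h: np.ndarray) -> np.ndarray:
        h = np.maximum(np.asarray(h, dtype=float), self.grf_min_z)
        log_en = np.log(self.n_voxels) + norm.logsf(h)
        log_em = np.log(self.resels) + _log_ec3_density(h)
        log_nbar = log_en - log_em  # expected cluster extent, voxels
        return (2.0 / 3.0) * (_LOG_GAMMA_5_2 - log_nbar)

    def logpdf(self, c: np.ndarray, h: np.ndarray) -> np.ndarray:
        """log f(c | h); broadcasts c against h."""
        c = np.asarray(c, dtype=float)
        log_beta = self.log_beta(h)
        beta = np.exp(log_beta)
        return np.log(2.0 / 3.0) + log_beta - np.log(c) / 3.0 - beta * c ** (2.0 / 3.0)


def _marginal_log_density(model: _ExtentModel, sizes: np.ndarray, h_top: float) -> np.ndarray:
    """log m(c) = log Int f(c | h) phi(h) dh for each size.

    The integral runs over the whole real line with the likelihood held flat
    below ``grf_min_z`` and above ``h_top`` (where phi mass is negligible), so
    a likelihood that is flat in h integrates exactly to itself — preserving
    the calibration invariant to rounding error.
    """
    gm = model.grf_min_z
    top = max(h_top, gm + 4.0)
    grid = np.linspace(gm, top, 161)
    # log f for every (size, grid) pair
    logf = model.logpdf(sizes[:, None], grid[None, :])
    ref = logf.max(axis=1, keepdims=True)
    f = np.exp(logf - ref)
    cdf = norm.cdf(grid)
    interval_mass = np.diff(cdf)
    mid = 0.5 * (f[:, 1:] + f[:, :-1])
    integral = (mid * interval_mass[None, :]).sum(axis=1)
    integral += f[:, 0] * cdf[0]  # flat extension below grf_min_z
    integral += f[:, -1] * norm.sf(grid[-1])  # flat extension above the top
    return np.log(integral) + ref[:, 0]


def ptfce_enhance(
    zmap: ZMap,
    mask: BinaryMask,
    config: PtfceConfig | None = None,
) -> EnhancedZMap:
    """Enhance a z-map by probabilistic threshold-free cluster enhancement.

    The input is made one-sided non-negative per the z-map's direction
    (abnormality scores), then enhanced as described in the module docstring.
    Output z_enh is NaN exactly where the input z is NaN, non-negative
    elsewhere, and bit-identical across repeated calls.
    """
    config = config or PtfceConfig()
    zs = zmap.one_sided().astype(np.float64)
    valid = mask.data & np.isfinite(zs)
    if np.any(zs[valid] < 0):
        raise PtfceError("one-sided input must be non-negative on valid voxels")

    out = np.full(zmap.grid.shape, np.nan, dtype=np.float32)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return EnhancedZMap(zmap.grid, out, config, zmap.subject_id)

    if config.smoothness_fwhm_mm == "estimate":
        fwhm = estimate_smoothness(zmap, mask)
    else:
        fwhm = float(config.smoothness_fwhm_mm)
        if fwhm <= 0:
            raise PtfceError("smoothness FWHM must be positive")

    z_max = config.z_max_cap
    if z_max is None:
        z_max = float(zs[valid].max())
    if z_max <= 0:  # empty-signal map: nothing to enhance
        out[valid] = 0.0
        return EnhancedZMap(zmap.grid, out, config, zmap.subject_id, fwhm)

    n = config.n_thresholds
    h = np.linspace(0.0, z_max, n)
    dh = h[1] - h[0]
    structure = CONNECTIVITY_STRUCTURES[config.connectivity]

    voxel = zmap.grid.voxel_size_mm
    resels = n_valid * float(np.prod([v / fwhm for v in voxel]))
    model = _ExtentModel(n_voxels=n_valid, resels=resels, grf_min_z=config.grf_min_z)

    zc = np.where(valid, zs, -np.inf)
    S = np.zeros(zmap.grid.shape, dtype=np.float64)
    log_m_cache: dict[int, float] = {}
    logq = norm.logsf(h)

    for i in range(n):
        sup = zc >= h[i]
        if h[i] < config.grf_min_z:
            # outside the GRF extent model's validity the threshold is made
            # exactly uninformative: the contribution is the prior -log Q
            contrib = np.where(sup, -logq[i], 0.0)
            if not sup.any():
                continue
        else:
            labels, n_lab = ndimage.label(sup, structure=structure)
            if n_lab == 0:
                continue
            sizes = np.bincount(labels.ravel())[1:]  # label k -> extent
            uniq = np.unique(sizes)
            missing = [int(c) for c in uniq if int(c) not in log_m_cache]
            if missing:
                log_ms = _marginal_log_density(model, np.asarray(missing, float), z_max)
                log_m_cache.update(zip(missing, log_ms))
            log_f = model.logpdf(uniq.astype(float), np.full(uniq.shape, h[i]))
            log_pi_uniq = log_f + logq[i] - np.array([log_m_cache[int(c)] for c in uniq])
            log_pi_uniq = np.minimum(log_pi_uniq, 0.0)  # pi is a probability
            neglog = -log_pi_uniq
            lut = np.zeros(n_lab + 1)
            size_to_neglog = dict(zip(uniq.tolist(), neglog))
            lut[1:] = [size_to_neglog[int(c)] for c in sizes]
            contrib = lut[labels]
        # trapezoid accumulation over thresholds 0..k(v), plus a fractional
        # term for the partial interval [h_k, z(v)): voxels past this
        # threshold weight it 1 (1/2 at the ends), voxels ending here weight
        # it 1/2 + frac (frac alone when the first interval is also the last)
        band = sup & (zc < h[i] + dh)
        rest = sup & ~band
        w_rest = 0.5 if i == 0 else 1.0
        S[rest] += w_rest * contrib[rest]
        if band.any():
            frac = (zc[band] - h[i]) / dh
            w_band = frac + (0.5 if i > 0 else 0.0)
            S[band] += w_band * contrib[band]

    z_enh = _invert_accumulation(S[valid], h, dh, logq)
    out[valid] = z_enh.astype(np.float32)
    return EnhancedZMap(zmap.grid, out, config, zmap.subject_id, fwhm)


def _invert_accumulation(
    S: np.ndarray, h: np.ndarray, dh: float, logq: np.ndarray
) -> np.ndarray:
    """Map accumulated -log probabilities back to the z scale.

    The reference accumulation applies the same trapezoid-weighted ladder to
    the uninformative terms -log Q(h_i); it is piecewise linear and strictly
    increasing in z, and its inverse is applied to S, so a flat likelihood
    maps back to the identity exactly.  The ladder is extended well beyond
    the data maximum so strongly reinforced voxels still map to finite z.
    """
    n_ext = 2 * len(h)  # extend to 3x z_max for boosted voxels
    h_ext = np.concatenate([h, h[-1] + dh * np.arange(1, n_ext + 1)])
    q = -norm.logsf(h_ext)
    # trapezoid nodes: G_0 = 0, G_k = q_0/2 + q_1 + .. + q_{k-1} + q_k/2
    cums = np.cumsum(q)
    g_nodes = np.empty_like(q)
    g_nodes[0] = 0.0
    g_nodes[1:] = cums[:-1] - 0.5 * q[0] + 0.5 * q[1:]
    # within [h_k, h_{k+1}): G = G_k + frac * q_k
    xs = np.empty(2 * len(h_ext))
    ys = np.empty(2 * len(h_ext))
    xs[0::2] = g_nodes
    xs[1::2] = g_nodes + q
    ys[0::2] = h_ext
    ys[1::2] = h_ext + dh
    z = np.interp(S, xs, ys)
    beyond = S > xs[-1]
    if np.any(beyond):  # linear fallback with the final ladder slope
        slope = dh / q[-1]
        z[beyond] = ys[-1] + (S[beyond] - xs[-1]) * slope
    return z
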