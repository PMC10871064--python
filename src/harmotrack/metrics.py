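"""HMI map assembly, ROI image-quality metrics, and sequence statistics.

Peak-to-peak displacement patches from the raster scan are blended into a
2-D map (distance-weighted overlap blending), normalized axially by a
background displacement curve to compensate radiation-force attenuation
(values become ratios; lower = stiffer), and scored with contrast, CNR and
SNR over matched inclusion/background ROIs.  Sequences are compared with a
Friedman test across speckle realizations followed by post-hoc Dunn tests
against the sequence with the highest median.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mechanics import DisplacementField
from .motion import InterframeDisplacement

__all__ = [
    "P2PPatch",
    "HMIMap",
    "ROISpec",
    "QualityMetrics",
    "FriedmanDunnReport",
    "BiasProfile",
    "stitch_raster",
    "attenuation_correct",
    "quality_metrics",
    "friedman_dunn",
    "lateral_bias_profile",
]


@dataclass
class P2PPatch:
    """One raster point's peak-to-peak displacement patch (um).

    ``values`` is (n_lines, n_depths); ``lines``/``depths`` are absolute
    coordinates in mm; ``origin`` is the raster (FUS focus) position.
    """

    values: np.ndarray
    lines: np.ndarray
    depths: np.ndarray
    origin: tuple[float, float]


@dataclass
class HMIMap:
    """Stitched 2-D HMI displacement map on an (x, z) pixel grid."""

    x: np.ndarray  # lateral pixel centers, mm
    z: np.ndarray  # axial pixel centers, mm
    values: np.ndarray  # (nx, nz); um before normalization, ratio after
    normalized: bool = False
    provenance: dict = field(default_factory=dict)


def stitch_raster(
    patches: list[P2PPatch],
    pixel: tuple[float, float] = (0.1, 0.1),
) -> HMIMap:
    """Blend overlapping raster patches into one map.

    Per pixel, the value is the weighted average over the covering patches
    with weights ``max(0, 1 - d / d_max)`` (renormalized to sum 1), where
    ``d`` is the pixel distance to each patch's raster point and ``d_max``
    the patch half-diagonal, so pixels nearer a raster point trust that
    patch more.  Pixels covered by no patch are NaN.
    """
    if not patches:
        raise ValueError("no patches to stitch")
    x0 = min(p.lines.min() for p in patches)
    x1 = max(p.lines.max() for p in patches)
    z0 = min(p.depths.min() for p in patches)
    z1 = max(p.depths.max() for p in patches)
    gx = np.arange(x0, x1 + pixel[0] / 2, pixel[0])
    gz = np.arange(z0, z1 + pixel[1] / 2, pixel[1])
    acc = np.zeros((len(gx), len(gz)))
    wacc = np.zeros_like(acc)
    for p in patches:
        dmax = 0.5 * np.hypot(p.lines.max() - p.lines.min(),
                              p.depths.max() - p.depths.min())
        ix = np.where((gx >= p.lines.min()) & (gx <= p.lines.max()))[0]
        iz = np.where((gz >= p.depths.min()) & (gz <= p.depths.max()))[0]
        if not len(ix) or not len(iz):
            continue
        vals = _bilinear_grid(p.lines, p.depths, p.values, gx[ix], gz[iz])
        px, pz = p.origin
        d = np.hypot(gx[ix][:, None] - px, gz[iz][None, :] - pz)
        w = np.maximum(0.0, 1.0 - d / dmax)
        ok = np.isfinite(vals)
        w = np.where(ok, w, 0.0)
        acc[np.ix_(ix, iz)] += w * np.where(ok, vals, 0.0)
        wacc[np.ix_(ix, iz)] += w
    n_empty = int(np.sum(wacc == 0))
    if n_empty:
        warnings.warn(f"{n_empty} map pixels not covered by any patch",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        out = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), np.nan)
    return HMIMap(gx, gz, out)


def _bilinear_grid(px, pz, vals, qx, qz):
    """Bilinear sampling of vals[len(px), len(pz)] at the grid qx x qz.

    NaNs propagate: a query cell touching a NaN corner returns NaN.
    """
    xi = np.clip(np.searchsorted(px, qx) - 1, 0, len(px) - 2)
    zi = np.clip(np.searchsorted(pz, qz) - 1, 0, len(pz) - 2)
    fx = np.clip((qx - px[xi]) / (px[xi + 1] - px[xi]), 0, 1)[:, None]
    fz = np.clip((qz - pz[zi]) / (pz[zi + 1] - pz[zi]), 0, 1)[None, :]
    xi = xi[:, None]
    zi = zi[None, :]
    return (vals[xi, zi] * (1 - fx) * (1 - fz)
            + vals[xi + 1, zi] * fx * (1 - fz)
            + vals[xi, zi + 1] * (1 - fx) * fz
            + vals[xi + 1, zi + 1] * fx * fz)


def attenuation_correct(
    hmi_map: HMIMap, background_region: tuple[float, float] | None = None
) -> HMIMap:
    """Normalize the map axially by a background displacement-vs-depth curve.

    The curve is the lateral mean of the map over ``background_region``
    (a lateral interval known to be homogeneous background; the full width
    when None) at each depth.  Depths with no background coverage use a
    Gaussian fit of the available curve, extrapolated.  The result is a
    ratio map whose background median is ~1; lower values mean stiffer.
    """
    vals = hmi_map.values
    if background_region is None:
        sel = np.ones(len(hmi_map.x), dtype=bool)
    else:
        sel = (hmi_map.x >= background_region[0]) & \
              (hmi_map.x <= background_region[1])
    if not np.any(sel):
        raise ValueError("background region selects no map columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(vals[sel, :], axis=0)
    good = np.isfinite(curve) & (curve > 0)
    if not np.any(good):
        raise ValueError("background curve is empty; cannot normalize")
    if not np.all(good):
        curve = _gaussian_extend(hmi_map.z, curve, good)
    out = vals / curve[None, :]
    return HMIMap(hmi_map.x.copy(), hmi_map.z.copy(), out, normalized=True,
                  provenance=dict(hmi_map.provenance))


def _gaussian_extend(z, curve, good):
    """Fill missing depths with a least-squares Gaussian fit of the curve.

    Fit of ``log y = log a - (z - mu)^2 / (2 s^2)`` (quadratic in z),
    initialized implicitly by the closed-form polynomial solution.
    """
    zz = z[good]
    logy = np.log(curve[good])
    c2, c1, c0 = np.polyfit(zz, logy, 2)
    if c2 >= 0:  # degenerate (non-peaked) curve: fall back to edge values
        filled = curve.copy()
        filled[~good] = np.interp(z[~good], zz, curve[good])
        return filled
    fit = np.exp(c2 * z**2 + c1 * z + c0)
    filled = curve.copy()
    filled[~good] = fit[~good]
    return filled


@dataclass(frozen=True)
class ROISpec:
    """Concentric inclusion disc and background ring, matched in area.

    Disc diameter is 80% of the inclusion diameter; the ring starts at 170%
    of it, and its outer diameter is set so ring area equals disc area.
    """

    center: tuple[float, float]  # (x, z) mm
    disc_diameter: float
    ring_inner_diameter: float
    ring_outer_diameter: float

    @classmethod
    def for_inclusion(cls, center: tuple[float, float],
                      inclusion_diameter: float) -> "ROISpec":
        disc = 0.8 * inclusion_diameter
        inner = 1.7 * inclusion_diameter
        outer = float(np.sqrt(inner**2 + disc**2))  # equal-area ring
        return cls(center, disc, inner, outer)

    def masks(self, hmi_map: HMIMap) -> tuple[np.ndarray, np.ndarray]:
        """(inclusion, background) boolean masks over map pixel centers."""
        r2 = (hmi_map.x[:, None] - self.center[0]) ** 2 \
            + (hmi_map.z[None, :] - self.center[1]) ** 2
        disc = r2 <= (self.disc_diameter / 2) ** 2
        ring = (r2 >= (self.ring_inner_diameter / 2) ** 2) \
            & (r2 <= (self.ring_outer_diameter / 2) ** 2)
        return disc, ring


@dataclass
class QualityMetrics:
    """Contrast / CNR / SNR / displacement ratio for one map + ROI pair."""

    contrast: float
    cnr: float
    snr_background: float
    snr_inclusion: float
    dr: float
    mu_b: float
    mu_i: float
    sigma_b: float
    sigma_i: float
    n_b: int
    n_i: int


def quality_metrics(hmi_map: HMIMap, roi: ROISpec,
                    min_pixels: int = 10) -> QualityMetrics:
    """Median-based image-quality metrics over the ROI pair.

    ``contrast = (mu_b - mu_i) / mu_b``, ``CNR = (mu_b - mu_i) /
    sqrt(sigma_b^2 + sigma_i^2)``, ``SNR = mu / sigma`` per region and
    ``DR = mu_i / mu_b = 1 - contrast``, with ``mu`` the median and
    ``sigma`` the standard deviation of the normalized displacements.
    NaN pixels are excluded; fewer than ``min_pixels`` valid pixels in
    either region is an error.
    """
    disc, ring = roi.masks(hmi_map)
    vi = hmi_map.values[disc]
    vb = hmi_map.values[ring]
    vi = vi[np.isfinite(vi)]
    vb = vb[np.isfinite(vb)]
    if len(vi) < min_pixels or len(vb) < min_pixels:
        raise ValueError(
            f"ROIs need >= {min_pixels} valid pixels (got {len(vi)} inclusion,"
            f" {len(vb)} background)"
        )
    mu_i, mu_b = float(np.median(vi)), float(np.median(vb))
    s_i, s_b = float(np.std(vi)), float(np.std(vb))
    denom = np.hypot(s_b, s_i)
    if denom == 0:
        warnings.warn("both ROI standard deviations are zero; CNR undefined",
                      stacklevel=2)
        cnr = np.nan if mu_b != mu_i else 0.0
    else:
        cnr = (mu_b - mu_i) / denom
    return QualityMetrics(
        contrast=(mu_b - mu_i) / mu_b,
        cnr=float(cnr),
        snr_background=mu_b / s_b if s_b > 0 else np.nan,
        snr_inclusion=mu_i / s_i if s_i > 0 else np.nan,
        dr=mu_i / mu_b,
        mu_b=mu_b, mu_i=mu_i, sigma_b=s_b, sigma_i=s_i,
        n_b=len(vb), n_i=len(vi),
    )


# ---------------------------------------------------------------------------
# Friedman / Dunn statistics


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-row ranks (n x k)."""
    n, k = ranks.shape
    col = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col**2) - 3.0 * n * (k + 1)
    # tie correction over rows
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    corr = 1.0 - ties / (n * k * (k**2 - 1))
    if corr <= 0:
        return 0.0
    return float(stat / corr)


@dataclass
class FriedmanDunnReport:
    """Friedman test plus post-hoc Dunn comparisons vs the highest median."""

    statistic: float
    pvalue: float
    df: int
    exact: bool
    best: int  # column with the highest median
    comparisons: list[dict]  # per other column: z, p_adjusted, significant
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def friedman_dunn(
    table: np.ndarray,
    alpha: float = 0.05,
    exact_limit: tuple[int, int] = (6, 3),
) -> FriedmanDunnReport:
    """Friedman test across columns (sequences) over rows (realizations).

    For small tables (rows <= 6 and columns <= 3 by default) the p-value is
    computed exactly by enumerating all within-row rank permutations;
    otherwise the tie-corrected chi-square approximation is used.  If the
    Friedman test is significant at ``alpha``, Dunn's rank-sum tests compare
    the column with the highest median against each other column, two-sided,
    Bonferroni-adjusted over the k - 1 comparisons.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be realizations x sequences")
    n, k = table.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 sequences")
    if n < 5:
        warnings.warn("fewer than 5 realizations; the test has little power",
                      stacklevel=2)
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    stat = _friedman_statistic(ranks)
    exact = n <= exact_limit[0] and k <= exact_limit[1]
    if exact:
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        for assignment in itertools.product(perms, repeat=n):
            permuted = np.vstack([ranks[i, list(p)]
                                  for i, p in enumerate(assignment)])
            total += 1
            if _friedman_statistic(permuted) >= stat - 1e-12:
                count += 1
        pvalue = count / total
    else:
        pvalue = float(stats.chi2.sf(stat, k - 1))
    medians = np.median(table, axis=0)
    best = int(np.argmax(medians))
    comparisons: list[dict] = []
    if pvalue < alpha:
        rbar = ranks.mean(axis=0)
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        for j in range(k):
            if j == best:
                continue
            z = (rbar[best] - rbar[j]) / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * (k - 1))
            comparisons.append(
                {"column": j, "z": float(z), "p_adjusted": float(p),
                 "significant": bool(p < alpha)}
            )
    return FriedmanDunnReport(stat, float(pvalue), k - 1, exact, best,
                              comparisons, alpha)


# ---------------------------------------------------------------------------
# Speckle-biasing lateral profiles


@dataclass
class BiasProfile:
    """Estimated vs true lateral interframe-displacement profiles."""

    est_lines: np.ndarray
    est_profile: np.ndarray  # peak-normalized
    truth_x: np.ndarray
    truth_profile: np.ndarray  # peak-normalized
    width_est: float  # -6 dB (half-max) full width, mm
    width_truth: float
    width_ratio: float  # est / truth
    peak_est_um: float
    peak_truth_um: float
    est_width_truncated: bool = False  # profile stayed above half maximum


def _half_max_width(x: np.ndarray, y: np.ndarray,
                    allow_truncated: bool = False) -> tuple[float, bool]:
    """(-6 dB full width, truncated flag) of a 1-D profile.

    When the profile never falls to half maximum within the measured span
    (strong speckle biasing keeps parallel-tracking profiles on a high
    pedestal), the span edge stands in for the crossing if
    ``allow_truncated`` -- the reported width then bounds the true one from
    below -- otherwise it is an error.
    """
    ipk = int(np.argmax(y))
    target = y[ipk] / 2.0
    if y[ipk] <= 0:
        raise ValueError("flat profile; width undefined")

    def cross(rng, edge):
        prev = ipk
        for i in rng:
            if y[i] <= target:
                f = (y[prev] - target) / (y[prev] - y[i])
                return x[prev] + f * (x[i] - x[prev]), False
            prev = i
        if allow_truncated:
            return edge, True
        raise ValueError("profile does not fall to half maximum within range")

    right, tr = cross(range(ipk + 1, len(y)), x[-1])
    left, tl = cross(range(ipk - 1, -1, -1), x[0])
    return float(right - left), tr or tl


def lateral_bias_profile(
    est: InterframeDisplacement,
    truth: DisplacementField,
    depth: float,
) -> BiasProfile:
    """Compare estimated and true lateral interframe-displacement profiles.

    Both profiles are the mean absolute interframe displacement at the given
    depth, taken over all frame pairs; widths are -6 dB (half-maximum) full
    widths of the peak-normalized profiles.  Parallel tracking with a tight
    transmit focus biases estimates toward the beam center, widening the
    estimated profile relative to the truth.
    """
    wi = int(np.argmin(np.abs(est.depth_centers - depth)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est_prof = np.nanmean(np.abs(est.values[:, :, wi]), axis=0)
    zi = int(np.argmin(np.abs(truth.z - depth)))
    du = np.diff(truth.u[:, zi, :], axis=1)  # (nx, n_pairs)
    n_pairs = min(du.shape[1], est.values.shape[0])
    truth_prof = np.mean(np.abs(du[:, :n_pairs]), axis=1)
    peak_est = float(np.nanmax(est_prof))
    peak_truth = float(truth_prof.max())
    est_n = est_prof / peak_est
    truth_n = truth_prof / peak_truth
    w_est, truncated = _half_max_width(est.lines, est_n, allow_truncated=True)
    if truncated:
        warnings.warn("estimated profile stays above half maximum across the "
                      "measured span; width truncated to the span",
                      stacklevel=2)
    w_truth, _ = _half_max_width(truth.x, truth_n)
    return BiasProfile(est.lines, est_n, truth.x, truth_n,
                       w_est, w_truth, w_est / w_truth, peak_est, peak_truth,
                       truncated)
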