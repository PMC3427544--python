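"""Random-field topological inference over supra-threshold clusters.

Implements the cluster-inference half of the adaptive thresholding
procedure: smoothness (FWHM / resel) estimation from GLM residuals, fixed
cluster-forming thresholds (uncorrected-p and family-wise-error via the
expected Euler characteristic of a t-field), connected-component
extraction, random-field cluster-extent p-values, Benjamini-Hochberg FDR
over clusters, the best-cluster fallback heuristic, and the orchestrating
:func:`threshold_map`.

All random-field formulas assume a stationary Gaussian-related field; the
simulated benchmark fields are stationary by construction.  Connectivity is
maximal-standard: 8 neighbours in 2D, 26 in 3D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import mixture
from .exceptions import InputError, NumericError, ParameterError

__all__ = [
    "SmoothnessEstimate",
    "Cluster",
    "estimate_smoothness",
    "box_smoothness",
    "resel_counts",
    "ec_density",
    "expected_ec",
    "t_threshold_uncorrected",
    "rft_fwe_threshold",
    "label_clusters",
    "cluster_extent_p",
    "fdr_over_clusters",
    "fallback_select",
    "threshold_map",
]

log = logging.getLogger(__name__)

_LN4 = 4.0 * np.log(2.0)


@dataclass
class SmoothnessEstimate:
    """Smoothness of the noise field underlying a statistic map.

    ``fwhm`` is per spatial axis, in voxel units.  ``resels`` is the volume
    of the search region in resolution elements (mask voxels divided by the
    product of the FWHMs).  ``resel_counts`` are the d-dimensional resel
    counts ``R_0 .. R_dim`` of the search region used in the expected-Euler-
    characteristic formula (computed by edge/face/cube counting, so they are
    exact for box-shaped masks).
    """

    fwhm: np.ndarray
    resels: float
    dim: int
    df: int
    resel_counts: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_voxels: int = 0

    def validate(self) -> None:
        if self.dim not in (2, 3):
            raise ParameterError("dim must be 2 or 3")
        if self.df < 1:
            raise ParameterError("df must be >= 1")
        if not (np.all(np.isfinite(self.fwhm)) and np.all(self.fwhm > 0)):
            raise ParameterError("all fwhm must be positive")
        if not self.resels > 0:
            raise ParameterError("resels must be positive")


def resel_counts(mask: np.ndarray, fwhm) -> np.ndarray:
    """Resel counts ``R_0 .. R_dim`` of a binary search region.

    Uses the Euler-characteristic decomposition of the voxel complex:
    voxels, axis-aligned edges, faces and cubes fully inside the mask.  For
    a full 2D a-by-b grid this reduces to ``[1, (a-1)/fx + (b-1)/fy,
    (a-1)(b-1)/(fx fy)]``.
    """
    m = np.asarray(mask, dtype=bool)
    f = np.asarray(fwhm, dtype=float)
    if m.ndim not in (2, 3) or f.shape != (m.ndim,):
        raise InputError("mask must be 2D/3D with one fwhm per axis")

    def pairs(axes):
        out = m
        for ax in axes:
            out = out[tuple(slice(0, -1) if a == ax else slice(None)
                            for a in range(m.ndim))] & \
                  out[tuple(slice(1, None) if a == ax else slice(None)
                            for a in range(m.ndim))]
        return int(out.sum())

    P = int(m.sum())
    if m.ndim == 2:
        ex, ey = pairs([0]), pairs([1])
        fxy = pairs([0, 1])
        r0 = P - ex - ey + fxy
        r1 = (ex - fxy) / f[0] + (ey - fxy) / f[1]
        r2 = fxy / (f[0] * f[1])
        return np.array([r0, r1, r2], dtype=float)
    ex, ey, ez = pairs([0]), pairs([1]), pairs([2])
    fxy, fxz, fyz = pairs([0, 1]), pairs([0, 2]), pairs([1, 2])
    c = pairs([0, 1, 2])
    r0 = P - ex - ey - ez + fxy + fxz + fyz - c
    r1 = ((ex - fxy - fxz + c) / f[0]
          + (ey - fxy - fyz + c) / f[1]
          + (ez - fxz - fyz + c) / f[2])
    r2 = ((fxy - c) / (f[0] * f[1])
          + (fxz - c) / (f[0] * f[2])
          + (fyz - c) / (f[1] * f[2]))
    r3 = c / (f[0] * f[1] * f[2])
    return np.array([r0, r1, r2, r3], dtype=float)


def box_smoothness(shape, fwhm, df: int) -> SmoothnessEstimate:
    """Smoothness descriptor for a full box-shaped search region.

    Convenience constructor for analyses where the FWHM is known a priori
    (e.g. simulated fields) rather than estimated from residuals.
    """
    shape = tuple(int(s) for s in shape)
    f = np.asarray(fwhm, dtype=float)
    if f.size == 1:
        f = np.full(len(shape), float(f))
    mask = np.ones(shape, dtype=bool)
    est = SmoothnessEstimate(
        fwhm=f,
        resels=float(mask.sum() / np.prod(f)),
        dim=len(shape),
        df=int(df),
        resel_counts=resel_counts(mask, f),
        n_voxels=int(mask.sum()),
    )
    est.validate()
    return est


def estimate_smoothness(residuals, df: int, mask=None) -> SmoothnessEstimate:
    """Estimate noise-field FWHM and resel counts from residual frames.

    ``residuals`` is time-by-space (first axis indexes frames, remaining 2
    or 3 axes are spatial).  Each voxel's residual series is normalized to
    unit temporal RMS, the per-axis variances of spatial first differences
    of the normalized frames give the roughness ``lambda``, and
    ``fwhm = sqrt(4 ln 2 / lambda)`` per axis.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim not in (3, 4):
        raise InputError("residuals must be (frames, x, y[, z])")
    n_frames, spatial = r.shape[0], r.shape[1:]
    if n_frames < 3:
        raise InputError(f"need >= 3 residual frames, got {n_frames}")
    dim = len(spatial)
    m = (np.ones(spatial, dtype=bool) if mask is None
         else np.asarray(mask, dtype=bool))
    if m.shape != spatial:
        raise InputError("mask shape does not match residual frames")
    if not m.any():
        raise InputError("mask is empty")

    rms = np.sqrt((r ** 2).mean(axis=0))
    ok = m & (rms > 0)
    if not ok.any():
        raise InputError("all in-mask voxels have zero residual variance")
    u = r / np.where(rms > 0, rms, 1.0)

    lam = np.empty(dim)
    for ax in range(dim):
        d = np.diff(u, axis=ax + 1)
        valid = (ok[tuple(slice(0, -1) if a == ax else slice(None)
                          for a in range(dim))]
                 & ok[tuple(slice(1, None) if a == ax else slice(None)
                            for a in range(dim))])
        if not valid.any():
            raise InputError(f"mask has no adjacent voxel pairs along axis {ax}")
        lam[ax] = float((d[:, valid] ** 2).mean()) if d.ndim == 2 else \
            float((d[(slice(None),) + np.nonzero(valid)] ** 2).mean())
    if np.any(lam <= 0):
        raise NumericError("degenerate roughness estimate")
    fwhm = np.sqrt(_LN4 / lam)
    est = SmoothnessEstimate(
        fwhm=fwhm,
        resels=float(ok.sum() / np.prod(fwhm)),
        dim=dim,
        df=int(df),
        resel_counts=resel_counts(ok, fwhm),
        n_voxels=int(ok.sum()),
    )
    est.validate()
    return est


def ec_density(u, df: int, d: int):
    """Euler-characteristic density of order ``d`` for a t-field."""
    u = np.asarray(u, dtype=float)
    nu = float(df)
    c = (1.0 + u * u / nu) ** (-(nu - 1.0) / 2.0)
    if d == 0:
        return stats.t.sf(u, nu)
    if d == 1:
        return np.sqrt(_LN4) / (2.0 * np.pi) * c
    if d == 2:
        k = (_LN4 / (2.0 * np.pi) ** 1.5
             * np.exp(gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0))
             / np.sqrt(nu / 2.0))
        return k * u * c
    if d == 3:
        return (_LN4 ** 1.5 / (2.0 * np.pi) ** 2
                * c * ((nu - 1.0) / nu * u * u - 1.0))
    raise ParameterError(f"EC density order {d} not supported")


def expected_ec(u, smoothness: SmoothnessEstimate):
    """Expected Euler characteristic of the excursion set above ``u``."""
    smoothness.validate()
    R = smoothness.resel_counts
    return sum(R[d] * ec_density(u, smoothness.df, d) for d in range(len(R)))


def t_threshold_uncorrected(p: float, df: int) -> float:
    """Upper-tail Student-t quantile: the fixed forming threshold at ``p``."""
    if not 0.0 < p < 1.0:
        raise ParameterError(f"p must be in (0, 1), got {p}")
    if df < 1:
        raise ParameterError("df must be >= 1")
    return float(stats.t.isf(p, df))


def rft_fwe_threshold(p_fwe: float, smoothness: SmoothnessEstimate,
                      *, bracket=(1.0, 50.0)) -> float:
    """T-threshold controlling family-wise error over the search region.

    Solves ``E[EC](u) = p_fwe`` by bisection; the expected Euler
    characteristic approximates the probability of any supra-threshold
    excursion for high thresholds.
    """
    if not 0.0 < p_fwe < 1.0:
        raise ParameterError(f"p_fwe must be in (0, 1), got {p_fwe}")
    smoothness.validate()
    lo, hi = bracket
    f_lo = expected_ec(lo, smoothness) - p_fwe
    f_hi = expected_ec(hi, smoothness) - p_fwe
    if f_lo * f_hi > 0:
        raise NumericError(
            f"FWE root not bracketed on [{lo}, {hi}]: "
            f"E[EC]({lo})={f_lo + p_fwe:.3g}, E[EC]({hi})={f_hi + p_fwe:.3g}")
    return float(optimize.brentq(
        lambda u: expected_ec(u, smoothness) - p_fwe, lo, hi, xtol=1e-6))


@dataclass
class Cluster:
    """A supra-threshold connected component of the statistic map."""

    voxel_ids: tuple  # tuple of coordinate arrays, as from np.nonzero
    extent: int
    peak: float
    sum_t: float
    peak_coord: tuple
    p_uncorrected: float | None = None
    q_fdr: float | None = None
    survives: bool = False

    @property
    def min_coord(self) -> tuple:
        coords = np.column_stack(self.voxel_ids)
        order = np.lexsort(coords.T[::-1])
        return tuple(int(v) for v in coords[order[0]])


def label_clusters(tmap, threshold: float, mask=None) -> list[Cluster]:
    """Connected components of ``{T > threshold}`` within the mask.

    8-connectivity in 2D, 26-connectivity in 3D.  Clusters are ordered by
    descending sum of T-values, ties by lexicographically smallest
    coordinate, so the ordering is deterministic.
    """
    t = np.asarray(tmap, dtype=float)
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    if t.ndim not in (2, 3):
        raise InputError("tmap must be 2D or 3D")
    m = np.ones(t.shape, bool) if mask is None else np.asarray(mask, bool)
    supra = (t > threshold) & m
    structure = np.ones((3,) * t.ndim, dtype=int)
    lab, n = ndimage.label(supra, structure=structure)
    clusters = []
    for i in range(1, n + 1):
        ids = np.nonzero(lab == i)
        vals = t[ids]
        j = int(np.argmax(vals))
        clusters.append(Cluster(
            voxel_ids=ids,
            extent=int(vals.size),
            peak=float(vals.max()),
            sum_t=float(vals.sum()),
            peak_coord=tuple(int(a[j]) for a in ids),
        ))
    clusters.sort(key=lambda c: (-c.sum_t, c.min_coord))
    return clusters


def cluster_extent_p(cluster: Cluster, threshold: float,
                     smoothness: SmoothnessEstimate) -> float:
    """Uncorrected random-field p-value for a cluster's spatial extent.

    Under the stationary-field approximation the extent ``k`` (in resels) of
    a cluster formed at threshold ``u`` satisfies
    ``P(K >= k) = exp(-beta k^(2/D))`` with ``beta`` calibrated so that the
    mean matches the expected cluster size: expected supra-threshold resel
    volume over expected cluster count at ``u``.
    """
    smoothness.validate()
    D = smoothness.dim
    u = float(threshold)
    Em = float(expected_ec(u, smoothness))
    EN = float(smoothness.resels * stats.t.sf(u, smoothness.df))
    if not (Em > 0 and EN > 0):
        raise NumericError(
            f"degenerate expected cluster count/volume at u={u:.3g} "
            f"(Em={Em:.3g}, EN={EN:.3g})")
    mean_size = EN / Em  # expected cluster size in resels
    beta = (np.exp(gammaln(D / 2.0 + 1.0)) / mean_size) ** (2.0 / D)
    k_resel = cluster.extent / np.prod(smoothness.fwhm)
    p = float(np.exp(-beta * k_resel ** (2.0 / D)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def fdr_over_clusters(clusters: list[Cluster], q: float = 0.05) -> list[Cluster]:
    """Benjamini-Hochberg step-up over the cluster extent p-values.

    Sets ``q_fdr`` (monotone-adjusted p) and ``survives`` on each cluster,
    in place, and returns the list.
    """
    if not clusters:
        return clusters
    pvals = [c.p_uncorrected for c in clusters]
    if any(p is None for p in pvals):
        raise ParameterError("all clusters need p_uncorrected before FDR")
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    for c, rej, adj in zip(clusters, reject, adjusted):
        c.q_fdr = float(adj)
        c.survives = bool(rej)
    return clusters


def fallback_select(clusters: list[Cluster]) -> list[Cluster]:
    """Heuristic used when a signal model won but no cluster survived FDR.

    Marks exactly one cluster as surviving: the one with the highest sum of
    T-values, ties broken by higher peak, then smallest coordinate.
    """
    if not clusters:
        log.warning("fallback invoked on an empty cluster set")
        return clusters
    best = min(clusters, key=lambda c: (-c.sum_t, -c.peak, c.min_coord))
    for c in clusters:
        c.survives = c is best
    return clusters


def _clusters_to_mask(clusters, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for c in clusters:
        if c.survives:
            out[c.voxel_ids] = True
    return out


def threshold_map(tmap, *, residuals=None, smoothness=None, mask=None,
                  mode: str = "adaptive", q: float = 0.05,
                  fixed_p: float = 0.001, fixed_fwe_p: float = 0.05,
                  df: int | None = None, fallback: bool = True):
    """Threshold a statistic map and perform topological FDR over clusters.

    Modes
    -----
    ``adaptive``
        Fit the three Gamma-Gaussian mixture models to the in-mask T-values,
        select by BIC, form clusters at the highest noise-labeled T-value.
        A model-1 win means "no signal": the returned mask is empty.
    ``fixed-p``
        Form clusters at the uncorrected upper-``fixed_p`` t-quantile.
    ``fixed-fwe``
        Form clusters at the expected-Euler-characteristic FWE threshold.

    In every mode, cluster extents receive random-field p-values which are
    then Benjamini-Hochberg corrected at level ``q``.  In adaptive mode,
    when a signal model was selected but no cluster survives, the
    highest-sum-of-T cluster is reported active (``fallback=True``).

    Returns ``(mask, report)`` where ``mask`` is a boolean activation map
    and ``report`` a dict with the forming threshold, model evidence,
    smoothness, and a per-cluster table.
    """
    t = np.asarray(tmap, dtype=float)
    m = np.ones(t.shape, bool) if mask is None else np.asarray(mask, bool)
    if m.shape != t.shape:
        raise InputError("mask shape does not match tmap")
    if smoothness is None:
        if residuals is None or df is None:
            raise InputError("provide either smoothness or residuals with df")
        smoothness = estimate_smoothness(residuals, df, mask=m)
    smoothness.validate()

    report = {
        "mode": mode,
        "df": smoothness.df,
        "fwhm": [float(f) for f in smoothness.fwhm],
        "resels": smoothness.resels,
        "fdr_q": q,
        "fallback_used": False,
    }

    fit = None
    if mode == "adaptive":
        fit = mixture.select_model(t[m])
        report["model_id"] = fit.params.model_id
        report["bic_scores"] = fit.bic_scores
        report["mu_hat"] = fit.params.mu
        report["sigma_hat"] = fit.params.sigma
        u = mixture.adaptive_threshold(fit)
        if u is None:
            report["forming_threshold"] = None
            report["clusters"] = []
            report["n_surviving"] = 0
            return np.zeros(t.shape, bool), report
    elif mode == "fixed-p":
        u = t_threshold_uncorrected(fixed_p, smoothness.df)
        report["fixed_p"] = fixed_p
    elif mode == "fixed-fwe":
        u = rft_fwe_threshold(fixed_fwe_p, smoothness)
        report["fixed_fwe_p"] = fixed_fwe_p
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    report["forming_threshold"] = float(u)

    # random-field theory describes a zero-mean field; in adaptive mode the
    # fitted noise mean (e.g. a global offset) is subtracted so the extent
    # p-values see the excursion height above the null, not the raw value
    u_field = u - fit.params.mu if mode == "adaptive" else u
    report["rft_height"] = float(u_field)

    clusters = label_clusters(t, u, mask=m)
    for c in clusters:
        c.p_uncorrected = cluster_extent_p(c, u_field, smoothness)
    fdr_over_clusters(clusters, q=q)

    if (mode == "adaptive" and fallback and clusters
            and not any(c.survives for c in clusters)):
        fallback_select(clusters)
        report["fallback_used"] = True

    resel_vol = float(np.prod(smoothness.fwhm))
    report["clusters"] = [
        {
            "cluster_id": i + 1,
            "extent_voxels": c.extent,
            "extent_resels": c.extent / resel_vol,
            "peak_t": c.peak,
            "sum_t": c.sum_t,
            "p_unc": c.p_uncorrected,
            "q_fdr": c.q_fdr,
            "survives": c.survives,
            "peak_coord": c.peak_coord,
        }
        for i, c in enumerate(clusters)
    ]
    report["n_surviving"] = int(sum(c.survives for c in clusters))
    report["_cluster_objects"] = clusters
    return _clusters_to_mask(clusters, t.shape), report
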