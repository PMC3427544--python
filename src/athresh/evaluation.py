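"""Error metrics and comparison statistics for the thresholding benchmark.

Cluster-level false positives are detected clusters overlapping no true
square at all; false negatives are true squares missed by every surviving
cluster.  Their difference (trade-off) and sum (total errors) are the two
headline criteria.  Border accuracy counts, per true square, the surviving
voxels falsely declared active outside it (overestimation) and the true
voxels missed inside it (underestimation).  Method comparisons use paired
per-replicate differences with percentile-bootstrap confidence intervals,
Harrell-Davis medians where a robust location estimate is wanted, and
Benjamini-Hochberg correction across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.mstats import hdquantiles
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, ParameterError

__all__ = [
    "ErrorRecord",
    "BorderAccuracy",
    "cluster_errors",
    "border_accuracy",
    "total_over_under",
    "dice",
    "harrell_davis",
    "percentile_bootstrap_diff",
    "bh_adjust",
    "summarize_benchmark",
    "summarize_global",
]


@dataclass(frozen=True)
class ErrorRecord:
    """Cluster-level error counts for one thresholded map."""

    fp_clusters: int
    fn_clusters: int

    @property
    def trade_off(self) -> int:
        return self.fp_clusters - self.fn_clusters

    @property
    def total(self) -> int:
        return self.fp_clusters + self.fn_clusters


@dataclass(frozen=True)
class BorderAccuracy:
    """Over/under-estimation of one true square's border, in voxels."""

    square_id: int
    over: int
    under: int

    @property
    def trade_off(self) -> int:
        return self.over - self.under


def _cluster_mask(cluster, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[cluster.voxel_ids] = True
    return m


def cluster_errors(surviving_clusters, square_masks) -> ErrorRecord:
    """Count false positive clusters and missed true squares.

    Overlap is "to any extent": a single shared voxel makes a cluster a
    true positive and a square detected.
    """
    if not square_masks:
        raise InputError("need at least one true square mask")
    shape = square_masks[0].shape
    detected = np.zeros(len(square_masks), dtype=bool)
    fp = 0
    for c in surviving_clusters:
        cm = _cluster_mask(c, shape)
        hits = np.array([(cm & sq).any() for sq in square_masks])
        if hits.any():
            detected |= hits
        else:
            fp += 1
    fn = int(len(square_masks) - detected.sum())
    return ErrorRecord(fp_clusters=fp, fn_clusters=fn)


def _nearest_square(coord, overlapped_ids, square_masks):
    """Attribute an outside voxel to the nearest overlapped square.

    Distance is Euclidean to the square's closest voxel; ties go to the
    larger square.
    """
    best = None
    for sid in overlapped_ids:
        pts = np.argwhere(square_masks[sid])
        d = float(np.min(np.linalg.norm(pts - np.asarray(coord), axis=1)))
        area = int(square_masks[sid].sum())
        key = (d, -area)
        if best is None or key < best[0]:
            best = (key, sid)
    return best[1]


def border_accuracy(surviving_clusters, square_masks,
                    comparability=None) -> list[BorderAccuracy]:
    """Per-square border over/under-estimation for one method's clusters.

    ``comparability``, when given, is a collection of surviving-cluster
    lists from the other compared methods: only squares detected (>= 1
    shared voxel) by *every* method enter the analysis, so the counts are
    comparable across methods.  A cluster spanning several squares
    contributes its outside voxels to the nearest overlapped square.
    """
    n_sq = len(square_masks)
    shape = square_masks[0].shape

    def detected_by(clusters):
        det = np.zeros(n_sq, dtype=bool)
        for c in clusters:
            cm = _cluster_mask(c, shape)
            det |= np.array([(cm & sq).any() for sq in square_masks])
        return det

    eligible = detected_by(surviving_clusters)
    for other in comparability or []:
        eligible &= detected_by(other)

    covered = [np.zeros(shape, dtype=bool) for _ in range(n_sq)]
    over = np.zeros(n_sq, dtype=int)
    for c in surviving_clusters:
        cm = _cluster_mask(c, shape)
        hit_ids = [i for i in range(n_sq) if (cm & square_masks[i]).any()]
        if not hit_ids:
            continue
        for i in hit_ids:
            covered[i] |= cm & square_masks[i]
        outside = cm & ~np.any(square_masks, axis=0)
        for coord in np.argwhere(outside):
            over[_nearest_square(coord, hit_ids, square_masks)] += 1

    return [
        BorderAccuracy(
            square_id=i,
            over=int(over[i]),
            under=int(square_masks[i].sum() - covered[i].sum()),
        )
        for i in range(n_sq) if eligible[i]
    ]


def total_over_under(mask, truth_mask) -> tuple[int, int]:
    """Map-wide (overestimated, underestimated) voxel counts."""
    m = np.asarray(mask, bool)
    t = np.asarray(truth_mask, bool)
    return int((m & ~t).sum()), int((t & ~m).sum())


def dice(mask_a, mask_b) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two binary masks.

    Two empty masks agree perfectly (1.0, by convention); exactly one empty
    mask gives 0.0.
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def harrell_davis(sample, quantile: float = 0.5) -> float:
    """Harrell-Davis quantile estimator.

    A smooth, Beta-weighted combination of all order statistics: with
    ``a = (n+1)q`` and ``b = (n+1)(1-q)``, the weight of the i-th order
    statistic is the Beta(a, b) measure of ``((i-1)/n, i/n]``.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 1:
        raise InputError("need at least one value")
    if not 0.0 < quantile < 1.0:
        raise ParameterError("quantile must be in (0, 1)")
    if x.size == 1:
        return float(x[0])
    return float(hdquantiles(x, prob=[quantile])[0])


def percentile_bootstrap_diff(values_a, values_b, *, estimator: str = "mean",
                              n_boot: int = 2000, alpha: float = 0.05,
                              seed: int = 0) -> dict:
    """Percentile bootstrap on paired differences ``a_i - b_i``.

    Resamples the differences with replacement ``n_boot`` times, computes
    the chosen estimator (``"mean"`` or ``"hd-median"``) on each resample,
    and returns the point estimate, the empirical (alpha/2, 1-alpha/2)
    percentile CI, and the two-sided bootstrap p-value
    ``2 min(P*(theta* > 0), P*(theta* < 0))``, clipped below at ``1/n_boot``.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise InputError("need paired samples of equal length >= 2")
    d = a - b
    est_fun = {"mean": np.mean,
               "hd-median": lambda v: harrell_davis(v, 0.5)}[estimator]
    point = float(est_fun(d))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    if estimator == "mean":
        boots = d[idx].mean(axis=1)
    else:
        boots = np.array([est_fun(d[row]) for row in idx])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p_pos = float(np.mean(boots > 0))
    p_neg = float(np.mean(boots < 0))
    p = max(2.0 * min(p_pos, p_neg), 1.0 / n_boot)
    return {"estimate": point, "ci_low": float(lo), "ci_high": float(hi),
            "p_value": min(p, 1.0), "n_boot": n_boot, "estimator": estimator}


def bh_adjust(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


_COMPARISONS = (("AT", "FT-p"), ("AT", "FT-FWE"))


def summarize_benchmark(table: pd.DataFrame, *, n_boot: int = 2000,
                        q: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Paired AT-vs-FT comparisons per signal height.

    For each height and fixed-threshold method, computes the mean paired
    difference of the absolute trade-offs ``|FP - FN|`` and of the total
    errors ``FP + FN``, with percentile-bootstrap CIs and B-H q-values
    corrected across heights within each comparison/metric family.  The
    signed trade-off difference is also reported for transparency.
    """
    required = {"height", "rep", "method", "trade_off", "total"}
    if not required.issubset(table.columns):
        raise InputError(f"benchmark table must have columns {sorted(required)}")
    t = table[~table.get("failed", False).astype(bool)]
    rows = []
    for (meth_a, meth_b) in _COMPARISONS:
        if not {meth_a, meth_b}.issubset(set(t["method"])):
            raise InputError(f"missing method column for {meth_a} vs {meth_b}")
        for metric, col in (("abs_trade_off", "trade_off"),
                            ("total_errors", "total"),
                            ("signed_trade_off", "trade_off")):
            for height in sorted(t["height"].unique()):
                sub = t[t["height"] == height].pivot(
                    index="rep", columns="method", values=col).dropna()
                a, b = sub[meth_a].to_numpy(), sub[meth_b].to_numpy()
                if metric == "abs_trade_off":
                    a, b = np.abs(a), np.abs(b)
                res = percentile_bootstrap_diff(
                    a, b, estimator="mean", n_boot=n_boot, seed=seed)
                rows.append({
                    "comparison": f"{meth_a}-{meth_b}",
                    "metric": metric,
                    "height": height,
                    "n": len(sub),
                    "mean_diff": res["estimate"],
                    "ci_low": res["ci_low"],
                    "ci_high": res["ci_high"],
                    "p_value": res["p_value"],
                })
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for (comp, metric), idx in out.groupby(["comparison", "metric"]).groups.items():
        adj, _ = bh_adjust(out.loc[idx, "p_value"].to_numpy(), q=q)
        out.loc[idx, "q_value"] = adj
    return out


def summarize_global(table: pd.DataFrame, *, n_boot: int = 2000,
                     seed: int = 0) -> dict:
    """Headline statistics of the global-shift experiment.

    Mean paired Dice improvements of AT over each fixed threshold (with
    bootstrap CIs), the Pearson correlation between the applied shift and
    the Gaussian mean fitted on the shifted map, and the correlations of
    each Dice improvement with the absolute shift.
    """
    need = {"shift", "dice_AT", "dice_FT-p", "dice_FT-FWE", "mu_hat_shifted"}
    if not need.issubset(table.columns):
        raise InputError(f"global table must have columns {sorted(need)}")
    out = {}
    shift = table["shift"].to_numpy(dtype=float)
    mu = table["mu_hat_shifted"].to_numpy(dtype=float)
    ok = np.isfinite(mu)
    out["r_shift_mu"] = float(stats.pearsonr(shift[ok], mu[ok])[0])
    for meth, tag in (("FT-p", "ft_p"), ("FT-FWE", "ft_fwe")):
        diff = (table["dice_AT"] - table[f"dice_{meth}"]).to_numpy(dtype=float)
        res = percentile_bootstrap_diff(
            table["dice_AT"], table[f"dice_{meth}"],
            estimator="mean", n_boot=n_boot, seed=seed)
        out[f"dice_improvement_{tag}"] = res["estimate"]
        out[f"dice_improvement_{tag}_ci"] = (res["ci_low"], res["ci_high"])
        out[f"dice_improvement_{tag}_p"] = res["p_value"]
        out[f"r_absshift_dicediff_{tag}"] = float(
            stats.pearsonr(np.abs(shift), diff)[0])
    return out
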