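"""Gamma-Gaussian mixture modeling of a T-value sample.

The distribution of T-values in a whole-brain statistical parametric map is
modeled as a mixture of

* a Gaussian component for the null (noise) voxels,
* a Gamma component, supported strictly above the Gaussian mean, for
  positive activations, and
* optionally a mirrored Gamma component, supported strictly below the
  Gaussian mean, for deactivations.

Three nested models are fitted: model 1 is the Gaussian alone (no signal),
model 2 adds the activation Gamma, model 3 adds the deactivation Gamma.
Model 1 is fitted by maximum likelihood; models 2 and 3 by EM with
method-of-moments M-steps for the Gamma parameters.  The winner by BIC
(``2 logL - p ln n``; higher is better) determines the voxel labeling, and
the largest T-value labeled noise becomes the data-driven cluster-forming
threshold.  Because the Gamma components are anchored at the *estimated*
Gaussian mean, a global additive shift of the whole map moves the threshold
with it, which is what makes the procedure immune to stimulus-correlated
global effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import DegenerateDataError, FitFailureError, ParameterError

__all__ = [
    "MixtureParams",
    "MixtureFit",
    "NOISE",
    "ACTIVATION",
    "DEACTIVATION",
    "mixture_density",
    "component_log_densities",
    "fit_model1",
    "fit_model_em",
    "bic_score",
    "select_model",
    "adaptive_threshold",
]

log = logging.getLogger(__name__)

# component labels (column order of the responsibility matrix; argmax ties
# resolve to the lowest index, i.e. conservatively to noise)
NOISE, ACTIVATION, DEACTIVATION = 0, 1, 2

#: free-parameter count per model, used by the BIC penalty
N_FREE_PARAMS = {1: 2, 2: 5, 3: 8}

_LOG_FLOOR = 1e-300


@dataclass
class MixtureParams:
    """Parameters of one of the three mixture models.

    ``mu``/``sigma`` are the Gaussian (noise) mean and standard deviation in
    T units.  ``k_a``/``theta_a`` are shape/scale of the activation Gamma on
    ``x - mu`` (support ``x > mu``); ``k_d``/``theta_d`` of the deactivation
    Gamma on ``mu - x`` (support ``x < mu``).  ``pi_*`` are mixing weights.
    """

    model_id: int
    mu: float
    sigma: float
    k_a: float | None = None
    theta_a: float | None = None
    k_d: float | None = None
    theta_d: float | None = None
    pi_n: float = 1.0
    pi_a: float = 0.0
    pi_d: float = 0.0

    def validate(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ParameterError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if not np.isfinite(self.mu):
            raise ParameterError("mu must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ParameterError("sigma must be positive")
        weights = [self.pi_n]
        if self.model_id >= 2:
            for name in ("k_a", "theta_a"):
                v = getattr(self, name)
                if v is None or not (np.isfinite(v) and v > 0):
                    raise ParameterError(f"{name} must be positive for model >= 2")
            weights.append(self.pi_a)
        if self.model_id == 3:
            for name in ("k_d", "theta_d"):
                v = getattr(self, name)
                if v is None or not (np.isfinite(v) and v > 0):
                    raise ParameterError(f"{name} must be positive for model 3")
            weights.append(self.pi_d)
        for w in weights:
            if not (0.0 <= w <= 1.0):
                raise ParameterError(f"mixing weight {w} outside [0, 1]")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ParameterError(f"mixing weights sum to {sum(weights)}, not 1")

    @property
    def n_components(self) -> int:
        return {1: 1, 2: 2, 3: 3}[self.model_id]


@dataclass
class MixtureFit:
    """Result of fitting one mixture model to a T-value sample."""

    params: MixtureParams
    loglik: float
    bic: float
    responsibilities: np.ndarray  # (n, n_components), rows sum to 1
    labels: np.ndarray  # (n,), values in {NOISE, ACTIVATION, DEACTIVATION}
    n_iter: int
    converged: bool
    values: np.ndarray  # the sample the fit was computed on
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    bic_scores: dict[int, float] | None = None  # filled by select_model


def _as_sample(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise DegenerateDataError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateDataError("sample contains non-finite values")
    return x


def _gamma_logpdf(y: np.ndarray, k: float, theta: float) -> np.ndarray:
    """Log density of Gamma(k, theta) with open support y > 0."""
    out = np.full(np.shape(y), -np.inf)
    pos = y > 0
    yp = y[pos]
    out[pos] = (k - 1.0) * np.log(yp) - yp / theta - k * np.log(theta) - gammaln(k)
    return out


def component_log_densities(params: MixtureParams, x) -> np.ndarray:
    """Per-component log densities (without mixing weights), shape (n, c).

    Column order: noise, activation, deactivation (present components only).
    """
    params.validate()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    cols = [
        -0.5 * ((x - params.mu) / params.sigma) ** 2
        - np.log(params.sigma)
        - 0.5 * np.log(2 * np.pi)
    ]
    if params.model_id >= 2:
        cols.append(_gamma_logpdf(x - params.mu, params.k_a, params.theta_a))
    if params.model_id == 3:
        cols.append(_gamma_logpdf(params.mu - x, params.k_d, params.theta_d))
    return np.column_stack(cols)


def _log_weights(params: MixtureParams) -> np.ndarray:
    w = [params.pi_n]
    if params.model_id >= 2:
        w.append(params.pi_a)
    if params.model_id == 3:
        w.append(params.pi_d)
    return np.log(np.maximum(w, _LOG_FLOOR))


def mixture_density(params: MixtureParams, x):
    """Mixture probability density at ``x`` (scalar or array)."""
    scalar = np.isscalar(x)
    logd = component_log_densities(params, x) + _log_weights(params)
    dens = np.exp(logsumexp(logd, axis=1))
    return float(dens[0]) if scalar else dens


def _e_step(params: MixtureParams, x: np.ndarray):
    logd = component_log_densities(params, x) + _log_weights(params)
    norm = logsumexp(logd, axis=1)
    # guard against all-components-zero points (cannot happen while sigma>0)
    norm = np.maximum(norm, np.log(_LOG_FLOOR))
    resp = np.exp(logd - norm[:, None])
    return resp, float(norm.sum())


def _finalize(params, x, resp, loglik, n_iter, converged, path) -> MixtureFit:
    labels = np.argmax(resp, axis=1)  # ties -> lowest index -> noise
    return MixtureFit(
        params=params,
        loglik=loglik,
        bic=bic_score(loglik, x.size, params.model_id),
        responsibilities=resp,
        labels=labels,
        n_iter=n_iter,
        converged=converged,
        values=x,
        loglik_path=np.asarray(path),
    )


def fit_model1(values) -> MixtureFit:
    """Maximum-likelihood Gaussian fit (model 1: no signal)."""
    x = _as_sample(values)
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma <= 0:
        raise DegenerateDataError("sample variance is zero")
    params = MixtureParams(model_id=1, mu=mu, sigma=sigma)
    resp, loglik = _e_step(params, x)
    return _finalize(params, x, resp, loglik, n_iter=0, converged=True, path=[loglik])


def _weighted_gamma_mom(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments Gamma (shape, scale) on y > 0."""
    pos = y > 0
    wp, yp = w[pos], y[pos]
    wsum = wp.sum()
    if wsum <= 1e-10:
        raise FitFailureError("no weight in Gamma support")
    m1 = float(np.dot(wp, yp) / wsum)
    var = float(np.dot(wp, (yp - m1) ** 2) / wsum)
    m1 = max(m1, 1e-8)
    var = max(var, 1e-10)
    k = np.clip(m1 * m1 / var, 1e-3, 1e4)
    theta = np.clip(var / m1, 1e-8, 1e6)
    return float(k), float(theta)


def _initial_params(x: np.ndarray, model_id: int, pi_n: float) -> MixtureParams:
    """Deterministic EM start: trimmed-sample Gaussian, tail-moment Gammas."""
    q1, q3 = np.percentile(x, [25, 75])
    core = x[(x >= q1) & (x <= q3)]
    mu = float(core.mean())
    # std of a normal truncated to its interquartile range is 0.3903 sigma
    sigma = float(core.std(ddof=0)) / 0.3903
    if sigma <= 0:
        raise DegenerateDataError("interquartile-trimmed sample has zero spread")

    def tail_gamma(y):
        sel = y > sigma
        if sel.sum() >= 5:
            return _weighted_gamma_mom(y[sel], np.ones(int(sel.sum())))
        return 4.0, 1.0

    k_a, theta_a = tail_gamma(x - mu)
    if model_id == 2:
        return MixtureParams(2, mu, sigma, k_a=k_a, theta_a=theta_a,
                             pi_n=pi_n, pi_a=1.0 - pi_n)
    k_d, theta_d = tail_gamma(mu - x)
    half = (1.0 - pi_n) / 2.0
    return MixtureParams(3, mu, sigma, k_a=k_a, theta_a=theta_a,
                         k_d=k_d, theta_d=theta_d,
                         pi_n=pi_n, pi_a=half, pi_d=half)


class _Collapse(Exception):
    pass


def _em_once(x, params, tol, max_iter):
    path = []
    resp, loglik = _e_step(params, x)
    path.append(loglik)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prev_params, prev_resp = params, resp
        # M-step
        pis = resp.mean(axis=0)
        if np.any(pis < 1e-4):
            raise _Collapse
        r_n = resp[:, NOISE]
        wn = r_n.sum()
        mu = float(np.dot(r_n, x) / wn)
        sigma = float(np.sqrt(np.dot(r_n, (x - mu) ** 2) / wn))
        if sigma < 1e-6:
            raise _Collapse
        if params.model_id == 2:
            k_a, theta_a = _weighted_gamma_mom(x - mu, resp[:, ACTIVATION])
            params = MixtureParams(2, mu, sigma, k_a=k_a, theta_a=theta_a,
                                   pi_n=float(pis[0]), pi_a=float(pis[1]))
        else:
            k_a, theta_a = _weighted_gamma_mom(x - mu, resp[:, ACTIVATION])
            k_d, theta_d = _weighted_gamma_mom(mu - x, resp[:, DEACTIVATION])
            params = MixtureParams(3, mu, sigma, k_a=k_a, theta_a=theta_a,
                                   k_d=k_d, theta_d=theta_d,
                                   pi_n=float(pis[0]), pi_a=float(pis[1]),
                                   pi_d=float(pis[2]))
        # E-step
        resp, new_loglik = _e_step(params, x)
        if new_loglik < loglik:
            # the method-of-moments Gamma update is not an exact M-step and
            # can dither near the optimum; keep the best point and stop
            params, resp = prev_params, prev_resp
            converged = True
            break
        path.append(new_loglik)
        if abs(new_loglik - loglik) < tol * abs(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return params, resp, loglik, n_iter, converged, path


def fit_model_em(values, model_id: int, *, tol: float = 1e-6,
                 max_iter: int = 1000) -> MixtureFit:
    """Fit model 2 or 3 by expectation-maximization.

    The M-step uses exact weighted ML updates for the Gaussian component and
    mixing weights, and weighted method-of-moments updates for the Gamma
    shape/scale, with the Gamma origins tracking the current Gaussian mean.
    Because the Gamma M-step is method-of-moments rather than ML, the
    log-likelihood is monitored rather than guaranteed; in practice it is
    non-decreasing to well within tolerance.  EM runs from two deterministic
    starts (signal weight 0.1 and 0.01) and keeps the higher-likelihood
    solution, which protects the nesting property (a signal model never
    scores materially below the plain Gaussian it contains).  A start whose
    component collapses (weight below 1e-4 or sigma below 1e-6) is dropped;
    if every start collapses a
    :class:`~athresh.exceptions.FitFailureError` is raised.
    """
    if model_id not in (2, 3):
        raise ParameterError(f"model_id must be 2 or 3, got {model_id}")
    x = _as_sample(values)
    best = None
    for pi_n in (0.9, 0.99):
        params0 = _initial_params(x, model_id, pi_n)
        try:
            result = _em_once(x, params0, tol, max_iter)
        except _Collapse:
            log.warning("EM collapse for model %d (pi_n start %.2f)",
                        model_id, pi_n)
            continue
        if best is None or result[2] > best[2]:
            best = result
    if best is None:
        raise FitFailureError(f"EM for model {model_id} collapsed from "
                              "every deterministic start")
    params, resp, loglik, n_iter, converged, path = best
    return _finalize(params, x, resp, loglik, n_iter, converged, path)


def bic_score(loglik: float, n: int, model_id: int) -> float:
    """BIC on the higher-is-better convention: ``2 logL - p ln(n)``."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return 2.0 * loglik - N_FREE_PARAMS[model_id] * np.log(n)


def select_model(values, *, tol: float = 1e-6, max_iter: int = 1000) -> MixtureFit:
    """Fit models 1-3 and return the winner by BIC.

    The returned fit carries ``bic_scores`` for every model that fitted, for
    audit.  If a signal model fails to fit, selection proceeds over the
    models that did, with a logged warning.
    """
    fits: dict[int, MixtureFit] = {1: fit_model1(values)}
    for mid in (2, 3):
        try:
            fits[mid] = fit_model_em(values, mid, tol=tol, max_iter=max_iter)
        except (FitFailureError, DegenerateDataError) as exc:
            log.warning("model %d failed to fit (%s); excluded from selection",
                        mid, exc)
    best = max(fits.values(), key=lambda f: f.bic)
    best.bic_scores = {mid: f.bic for mid, f in fits.items()}
    return best


def adaptive_threshold(fit: MixtureFit) -> float | None:
    """Data-driven cluster-forming threshold from a selected fit.

    Returns ``None`` (the no-signal sentinel) when model 1 won, otherwise
    the largest T-value among voxels labeled noise — the empirical analogue
    of the crossing point between the weighted Gaussian and the weighted
    activation Gamma densities.
    """
    if fit.params.model_id == 1:
        return None
    noise_values = fit.values[fit.labels == NOISE]
    if noise_values.size == 0:
        raise FitFailureError("signal model selected but no voxel labeled noise")
    return float(noise_values.max())
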