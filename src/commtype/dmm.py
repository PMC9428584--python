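"""Dirichlet-multinomial mixture (DMM) model: density, EM fit, Laplace evidence.

The DMM treats each sample's taxon count vector ``x`` as multinomial with
composition drawn from a component-specific Dirichlet.  Integrating the
composition out gives the Dirichlet-multinomial (DM) likelihood

    DM(x | alpha) = n!/prod_j x_j! * Gamma(A)/Gamma(n+A)
                    * prod_j Gamma(x_j + alpha_j)/Gamma(alpha_j),

with ``A = sum_j alpha_j`` and ``n = sum_j x_j``.  A K-component mixture with
weights ``pi`` is fitted by EM; the M-step maximises the responsibility-
weighted DM log-likelihood over ``lambda = log alpha`` by L-BFGS with the
analytic digamma gradient.  Model evidence for choosing K is approximated by
Laplace's method at the posterior mode, with a weak Gamma shrinkage prior on
each ``alpha`` and a block-diagonal (per component) Hessian in log-parameter
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, polygamma, psi
from sklearn.cluster import KMeans

from .tables import TaxaCountTable

__all__ = [
    "DMMFit",
    "ClusterAssignment",
    "dm_log_pmf",
    "fit_dmm",
    "laplace_evidence",
    "assign_clusters",
    "save_fit",
    "load_fit",
]

log = logging.getLogger(__name__)

# Gamma(shape, rate) shrinkage prior on alpha, applied in log-alpha space.
# Weak by design: mode at alpha = shape/rate = 10, matching the scale of
# typical genus-level Dirichlet concentrations.
PRIOR_SHAPE = 1.0
PRIOR_RATE = 0.1

_EIG_FLOOR = 1e-8  # eigenvalue clip for near-singular Hessian blocks


@dataclass
class DMMFit:
    """A fitted K-component Dirichlet-multinomial mixture."""

    K: int
    alpha: np.ndarray  # (K, G) component Dirichlet parameters
    pi: np.ndarray  # (K,) mixing weights
    responsibilities: np.ndarray  # (N, K)
    log_likelihood: float
    genus_ids: list[str]
    laplace_score: Optional[float] = None  # negative log evidence; lower = better
    n_iter: int = 0
    converged: bool = True
    seed: Optional[int] = None
    loglik_trace: list[float] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)  # penalised (MAP) objective
    flags: list[str] = field(default_factory=list)

    def expected_compositions(self) -> np.ndarray:
        """Per-component expected proportions m_kj = alpha_kj / A_k."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)


@dataclass
class ClusterAssignment:
    """Hard cluster labels (1..K) with the winning posterior probability."""

    labels: np.ndarray
    max_posterior: np.ndarray
    sample_ids: list[str]


def _as_matrix(counts) -> np.ndarray:
    if isinstance(counts, TaxaCountTable):
        return counts.counts.to_numpy(dtype=np.float64)
    return np.asarray(counts, dtype=np.float64)


def dm_log_pmf(x, alpha) -> float:
    """Log Dirichlet-multinomial probability of count vector ``x``.

    Computed entirely with log-gamma so large counts never overflow.
    """
    x = np.asarray(x, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if x.shape != alpha.shape:
        raise ValueError(f"length mismatch: x has {x.shape}, alpha has {alpha.shape}")
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("x must be non-negative integers")
    if (alpha <= 0).any():
        raise ValueError("alpha must be strictly positive")
    n = x.sum()
    A = alpha.sum()
    return float(
        gammaln(n + 1)
        - gammaln(x + 1).sum()
        + gammaln(A)
        - gammaln(n + A)
        + (gammaln(x + alpha) - gammaln(alpha)).sum()
    )


def _component_loglik(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """(N, K) matrix of per-sample, per-component DM log-likelihoods."""
    n = X.sum(axis=1)
    const = gammaln(n + 1) - gammaln(X + 1).sum(axis=1)
    A = alpha.sum(axis=1)  # (K,)
    out = np.empty((X.shape[0], alpha.shape[0]))
    for k in range(alpha.shape[0]):
        out[:, k] = (
            const
            + gammaln(A[k])
            - gammaln(n + A[k])
            + gammaln(X + alpha[k]).sum(axis=1)
            - gammaln(alpha[k]).sum()
        )
    return out


def _log_prior(alpha: np.ndarray) -> float:
    """Log density of the Gamma shrinkage prior in log-alpha space.

    p(lambda) = rate^shape / Gamma(shape) * alpha^shape * exp(-rate*alpha),
    i.e. Gamma(shape, rate) on alpha times the Jacobian d(alpha)/d(lambda).
    """
    lam = np.log(alpha)
    per_param = (
        PRIOR_SHAPE * np.log(PRIOR_RATE)
        - gammaln(PRIOR_SHAPE)
        + PRIOR_SHAPE * lam
        - PRIOR_RATE * alpha
    )
    return float(per_param.sum())


def _weighted_neg_objective(lam: np.ndarray, X, n, r_k):
    """Negative (weighted DM log-likelihood + log prior) and its lambda-gradient
    for one component, used by the M-step optimizer."""
    alpha = np.exp(lam)
    A = alpha.sum()
    W = r_k.sum()
    ll = (
        W * (gammaln(A))
        - (r_k * gammaln(n + A)).sum()
        + (r_k[:, None] * (gammaln(X + alpha) - gammaln(alpha))).sum()
    )
    lp = (
        X.shape[1] * (PRIOR_SHAPE * np.log(PRIOR_RATE) - gammaln(PRIOR_SHAPE))
        + PRIOR_SHAPE * lam.sum()
        - PRIOR_RATE * alpha.sum()
    )
    # gradient wrt alpha, then chain rule to lambda
    g_alpha = (
        W * psi(A)
        - (r_k * psi(n + A)).sum()
        + (r_k[:, None] * psi(X + alpha)).sum(axis=0)
        - W * psi(alpha)
    )
    grad = -(alpha * g_alpha + PRIOR_SHAPE - PRIOR_RATE * alpha)
    return -(ll + lp), grad


def _optimize_component(alpha0, X, n, r_k, maxiter=20):
    res = minimize(
        _weighted_neg_objective,
        np.log(np.clip(alpha0, 1e-8, None)),
        args=(X, n, r_k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-30.0, 30.0)] * len(alpha0),
        options={"maxiter": maxiter},
    )
    return np.exp(res.x)


def _init_responsibilities(X, K, rng, start_idx) -> np.ndarray:
    """First start: seeded k-means on proportions; later starts: random."""
    N = X.shape[0]
    if start_idx == 0 and K > 1:
        props = X / X.sum(axis=1, keepdims=True)
        km_seed = int(rng.integers(2**31 - 1))
        labels = KMeans(n_clusters=K, n_init=3, random_state=km_seed).fit_predict(props)
        r = np.full((N, K), 0.05 / max(K - 1, 1))
        r[np.arange(N), labels] = 0.95
    else:
        r = rng.dirichlet(np.ones(K), size=N)
    return r / r.sum(axis=1, keepdims=True)


def _alpha_from_responsibilities(X, r, concentration=20.0) -> np.ndarray:
    """Moment-style initial alpha: weighted mean composition times a fixed
    total concentration."""
    W = r.sum(axis=0)  # (K,)
    props = X / X.sum(axis=1, keepdims=True)
    mean_p = (r.T @ props) / W[:, None]
    return np.clip(concentration * mean_p, 1e-3, None)


def _em_single(X, K, rng, start_idx, tol, max_iter, mstep_iter=15):
    N, G = X.shape
    n = X.sum(axis=1)
    r = _init_responsibilities(X, K, rng, start_idx)
    alpha = _alpha_from_responsibilities(X, r)
    pi = r.mean(axis=0)
    floor = 1.0 / (10.0 * N)

    trace: list[float] = []
    obj_trace: list[float] = []
    prev_obj = -np.inf
    converged = False
    empty = False
    it = 0
    for it in range(1, max_iter + 1):
        L = _component_loglik(X, alpha)  # (N, K)
        logw = L + np.log(pi)[None, :]
        ll = float(logsumexp(logw, axis=1).sum())
        trace.append(ll)
        obj_trace.append(ll + _log_prior(alpha))
        r = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        pi = r.mean(axis=0)
        if (pi < floor).any():
            empty = True
            break
        obj = ll + _log_prior(alpha)
        if it > 1 and abs(obj - prev_obj) <= tol * (abs(prev_obj) + 1.0):
            converged = True
            break
        prev_obj = obj
        for k in range(K):
            alpha[k] = _optimize_component(alpha[k], X, n, r[:, k], maxiter=mstep_iter)
    # polish: full M-steps and E-steps until the penalised objective is tight,
    # so independent starts land on numerically identical optima
    if converged:
        polish_tol = max(0.01 * tol * (abs(prev_obj) + 1.0), 1e-9)
        for _ in range(30):
            for k in range(K):
                alpha[k] = _optimize_component(alpha[k], X, n, r[:, k], maxiter=200)
            L = _component_loglik(X, alpha)
            logw = L + np.log(pi)[None, :]
            ll = float(logsumexp(logw, axis=1).sum())
            r = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
            pi = r.mean(axis=0)
            obj_now = ll + _log_prior(alpha)
            trace.append(ll)
            obj_trace.append(obj_now)
            if abs(obj_now - prev_obj) <= polish_tol:
                break
            prev_obj = obj_now

    obj = trace[-1] + _log_prior(alpha) if trace else -np.inf
    return dict(
        alpha=alpha, pi=pi, r=r, loglik=trace[-1] if trace else -np.inf,
        objective=obj, trace=trace, obj_trace=obj_trace, n_iter=it,
        converged=converged, empty=empty,
    )


def fit_dmm(
    genus_counts,
    K: int,
    seed: int = 0,
    n_starts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    depth_cap: Optional[int] = None,
) -> DMMFit:
    """Fit a K-component Dirichlet-multinomial mixture by multi-start EM.

    The E-step computes responsibilities ``r_ik ∝ pi_k DM(x_i | alpha_k)``;
    the M-step re-estimates ``pi`` in closed form and each ``alpha_k`` by
    L-BFGS over ``log alpha`` (a partial M-step suffices for monotonicity).
    The best of ``n_starts`` runs by final penalised log-likelihood is
    returned.  Runs whose smallest mixing weight falls below ``1/(10N)`` are
    restarted from a fresh random initialisation and flagged if that recurs.

    ``depth_cap`` optionally rescales samples deeper than the cap to that
    total (proportional rounding), damping the weight of ultra-deep
    libraries; raw counts are the default since depth is part of the model.
    """
    X = _as_matrix(genus_counts)
    if depth_cap is not None:
        depths = X.sum(axis=1)
        over = depths > depth_cap
        if over.any():
            X = X.copy()
            X[over] = np.round(X[over] * (depth_cap / depths[over, None]))
    if isinstance(genus_counts, TaxaCountTable):
        genus_ids = genus_counts.taxon_ids
    else:
        genus_ids = [f"g{j}" for j in range(X.shape[1])]
    N = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if N <= K:
        raise ValueError(f"need more samples ({N}) than components ({K})")
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("zero-depth sample; filter before fitting")

    rng = np.random.default_rng(seed)
    best = None
    flags: list[str] = []
    n_attempts = n_starts + 2  # allowance for empty-component restarts
    done = 0
    for start_idx in range(n_attempts):
        if done >= n_starts:
            break
        res = _em_single(X, K, rng, start_idx, tol, max_iter)
        if res["empty"]:
            log.info("start %d: empty component, restarting", start_idx)
            if start_idx == n_attempts - 1:
                flags.append("empty_component")
            continue
        done += 1
        if best is None or res["objective"] > best["objective"]:
            best = res
    if best is None:
        # all starts degenerate; keep the last one and flag it
        best = res
        flags.append("empty_component")
    if not best["converged"]:
        flags.append("not_converged")
        log.warning("EM did not converge in %d iterations", best["n_iter"])
    return DMMFit(
        K=K,
        alpha=best["alpha"],
        pi=best["pi"],
        responsibilities=best["r"],
        log_likelihood=best["loglik"],
        genus_ids=list(genus_ids),
        n_iter=best["n_iter"],
        converged=best["converged"],
        seed=seed,
        loglik_trace=best["trace"],
        objective_trace=best["obj_trace"],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Laplace evidence
# ---------------------------------------------------------------------------

def _component_hessian_lambda(alpha_k, X, n, r_k) -> np.ndarray:
    """Hessian of the component's negative log posterior wrt lambda=log alpha.

    Uses the responsibility-weighted (block-diagonal) approximation: cross-
    component curvature is ignored, matching the standard DMM evidence
    computation.
    """
    A = alpha_k.sum()
    W = r_k.sum()
    # H_alpha of -loglik: rank-one part + diagonal
    c = (r_k * polygamma(1, n + A)).sum() - W * polygamma(1, A)
    diag = W * polygamma(1, alpha_k) - (r_k[:, None] * polygamma(1, X + alpha_k)).sum(axis=0)
    H_alpha = c * np.ones((len(alpha_k), len(alpha_k))) + np.diag(diag)
    # gradient of -loglik wrt alpha (for the chain-rule term)
    g_alpha = -(
        W * psi(A)
        - (r_k * psi(n + A)).sum()
        + (r_k[:, None] * psi(X + alpha_k)).sum(axis=0)
        - W * psi(alpha_k)
    )
    H_lam = (alpha_k[:, None] * alpha_k[None, :]) * H_alpha + np.diag(alpha_k * g_alpha)
    # prior curvature in lambda space: d^2(rate*alpha - shape*lambda)/dlambda^2
    H_lam += np.diag(PRIOR_RATE * alpha_k)
    return H_lam


def laplace_evidence(fit: DMMFit, genus_counts) -> float:
    """Negative log model evidence by Laplace approximation (lower = better).

    score = -[ log p(D|theta) + log prior(theta) + (d/2) log 2pi
               - 1/2 log det H ]

    with ``d = K*G`` free log-alpha parameters and ``H`` the block-diagonal
    Hessian of the negative log posterior at the fitted mode.  Non-positive
    Hessian eigenvalues are clipped at 1e-8 and flagged.
    """
    X = _as_matrix(genus_counts)
    n = X.sum(axis=1)
    r = fit.responsibilities
    d = fit.K * len(fit.genus_ids)
    half_logdet = 0.0
    for k in range(fit.K):
        H = _component_hessian_lambda(fit.alpha[k], X, n, r[:, k])
        eigvals = np.linalg.eigvalsh((H + H.T) / 2.0)
        if (eigvals <= _EIG_FLOOR).any():
            if "hessian_clipped" not in fit.flags:
                fit.flags.append("hessian_clipped")
            eigvals = np.clip(eigvals, _EIG_FLOOR, None)
        half_logdet += 0.5 * float(np.log(eigvals).sum())
    log_evidence = (
        fit.log_likelihood
        + _log_prior(fit.alpha)
        + 0.5 * d * np.log(2.0 * np.pi)
        - half_logdet
    )
    score = -log_evidence
    fit.laplace_score = float(score)
    return float(score)


def assign_clusters(fit: DMMFit, genus_counts) -> ClusterAssignment:
    """Posterior cluster assignment for (possibly new) samples.

    Labels are 1-based argmax responsibilities; ties break to the lowest
    component index.
    """
    if isinstance(genus_counts, TaxaCountTable):
        missing = [g for g in fit.genus_ids if g not in genus_counts.taxon_ids]
        if missing:
            raise ValueError(f"genus set mismatch; missing genera: {missing}")
        X = genus_counts.counts[fit.genus_ids].to_numpy(dtype=np.float64)
        sample_ids = genus_counts.sample_ids
    else:
        X = _as_matrix(genus_counts)
        if X.shape[1] != len(fit.genus_ids):
            raise ValueError(
                f"genus set mismatch: fit has {len(fit.genus_ids)} genera, "
                f"input has {X.shape[1]}"
            )
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    L = _component_loglik(X, fit.alpha)
    logw = L + np.log(fit.pi)[None, :]
    r = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    labels = r.argmax(axis=1) + 1  # argmax takes the lowest index on ties
    return ClusterAssignment(
        labels=labels, max_posterior=r.max(axis=1), sample_ids=list(sample_ids)
    )


# ---------------------------------------------------------------------------
# Serialization (YAML parameters + TSV responsibilities)
# ---------------------------------------------------------------------------

def save_fit(fit: DMMFit, prefix) -> None:
    """Persist a fit as ``<prefix>.yaml`` + ``<prefix>.responsibilities.tsv``."""
    prefix = Path(prefix)
    meta = {
        "K": int(fit.K),
        "genus_ids": list(fit.genus_ids),
        "pi": [float(v) for v in fit.pi],
        "alpha": [[float(v) for v in row] for row in fit.alpha],
        "log_likelihood": float(fit.log_likelihood),
        "laplace_score": None if fit.laplace_score is None else float(fit.laplace_score),
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
        "seed": fit.seed,
        "flags": list(fit.flags),
    }
    with open(prefix.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    pd.DataFrame(
        fit.responsibilities,
        columns=[f"component_{k + 1}" for k in range(fit.K)],
    ).to_csv(str(prefix) + ".responsibilities.tsv", sep="\t", index=False)


def load_fit(prefix) -> DMMFit:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    r = pd.read_csv(str(prefix) + ".responsibilities.tsv", sep="\t").to_numpy()
    return DMMFit(
        K=meta["K"],
        alpha=np.asarray(meta["alpha"], dtype=float),
        pi=np.asarray(meta["pi"], dtype=float),
        responsibilities=r,
        log_likelihood=meta["log_likelihood"],
        genus_ids=meta["genus_ids"],
        laplace_score=meta["laplace_score"],
        n_iter=meta["n_iter"],
        converged=meta["converged"],
        seed=meta["seed"],
        flags=meta.get("flags", []),
    )
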