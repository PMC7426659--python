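"""Dirichlet-multinomial mixture (DMM) enterotyping.

Gut communities cluster into a small number of compositional types
("enterotypes", e.g. *Bacteroides*- vs *Prevotella*-enriched).  This module
fits a finite mixture of Dirichlet-multinomial components to a taxon count
matrix by expectation-maximization, selects the number of components by a
Laplace approximation of the model evidence (BIC optionally, for speed),
assigns hard cluster labels, and compares microbial loads between the two
clusters with a Mann-Whitney U test.

Model: sample ``s`` with counts ``x_s`` (total ``N_s``) under component
``k`` with Dirichlet parameters ``alpha_k`` (``A_k = sum_t alpha_kt``) has

    P(x_s | alpha_k) = C(x_s) * G(A_k)/G(N_s + A_k)
                       * prod_t G(x_st + alpha_kt)/G(alpha_kt)

with ``G`` the gamma function; the multinomial coefficient ``C`` is
constant across components and omitted from the likelihood.  The M-step
uses the standard Polya fixed-point update, which monotonically increases
the weighted component likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-10
#: parameters at/below this are treated as pinned to the boundary and are
#: excluded from the Laplace Hessian and the parameter count
ALPHA_ACTIVE = 1e-8


@dataclass
class DmmModel:
    """A fitted Dirichlet-multinomial mixture."""

    n_components: int
    weights: np.ndarray
    alpha: np.ndarray  # K x T
    responsibilities: np.ndarray  # S x K
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    converged: bool
    taxa: pd.Index
    sample_ids: pd.Index
    #: per-K model-selection table (filled by fit_dmm)
    selection: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if (self.alpha <= 0).any():
            raise ValueError("alpha must be positive")
        if not np.allclose(self.responsibilities.sum(axis=1), 1.0):
            raise ValueError("responsibility rows must sum to 1")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")

    def mean_composition(self) -> pd.DataFrame:
        """Per-component expected proportions ``alpha_k / A_k``."""
        comp = self.alpha / self.alpha.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            comp.T, index=self.taxa,
            columns=[f"component_{k + 1}" for k in range(self.n_components)],
        )


def _as_counts(counts) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if hasattr(counts, "counts"):
        df = counts.counts
    else:
        df = pd.DataFrame(counts)
    X = df.to_numpy().T.astype(np.int64)  # samples x taxa
    return X, df.columns, df.index


def _dm_component_loglik(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """S x K matrix of per-sample per-component DM log-likelihoods."""
    A = alpha.sum(axis=1)  # K
    N = X.sum(axis=1)  # S
    out = gammaln(A)[None, :] - gammaln(N[:, None] + A[None, :])
    out = out + (
        gammaln(X[:, None, :] + alpha[None, :, :]) - gammaln(alpha)[None, :, :]
    ).sum(axis=2)
    return out


def _polya_fixed_point(
    X: np.ndarray, w: np.ndarray, alpha: np.ndarray,
    n_inner: int = 25, tol: float = 1e-9,
) -> np.ndarray:
    """Weighted maximum-likelihood alpha via the Polya fixed-point update."""
    N = X.sum(axis=1)
    for _ in range(n_inner):
        A = alpha.sum()
        num = (w[:, None] * (psi(X + alpha[None, :]) - psi(alpha)[None, :])).sum(axis=0)
        den = float((w * (psi(N + A) - psi(A))).sum())
        if den <= 0:
            break
        new = np.maximum(alpha * num / den, ALPHA_FLOOR)
        if np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-12)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def _initial_responsibilities(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means on proportion rows, softened into responsibilities."""
    s = X.shape[0]
    if k == 1:
        return np.ones((s, 1))
    props = X / np.maximum(X.sum(axis=1, keepdims=True), 1)
    km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(props)
    resp = np.full((s, k), 0.05 / max(k - 1, 1))
    resp[np.arange(s), labels] = 0.95
    return resp / resp.sum(axis=1, keepdims=True)


def _fit_single(
    X: np.ndarray, k: int, resp: np.ndarray,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    s, t = X.shape
    props = X / np.maximum(X.sum(axis=1, keepdims=True), 1)
    alpha = np.empty((k, t))
    for j in range(k):
        w = resp[:, j]
        p_bar = (w[:, None] * props).sum(axis=0) / w.sum()
        alpha[j] = np.maximum(p_bar * 50.0, 1e-6)
    weights = resp.mean(axis=0)

    trace = []
    converged = False
    prev_ll = -np.inf
    for _ in range(max_iter):
        logdm = _dm_component_loglik(X, alpha)
        joint = np.log(np.maximum(weights, 1e-300))[None, :] + logdm
        ll = float(logsumexp(joint, axis=1).sum())
        trace.append(ll)
        resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        weights = resp.mean(axis=0)
        for j in range(k):
            alpha[j] = _polya_fixed_point(X, resp[:, j], alpha[j])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
            converged = True
            break
        prev_ll = ll
    # final E-step consistent with the returned parameters
    logdm = _dm_component_loglik(X, alpha)
    joint = np.log(np.maximum(weights, 1e-300))[None, :] + logdm
    ll = float(logsumexp(joint, axis=1).sum())
    trace.append(ll)
    resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return alpha, weights, resp, np.asarray(trace), converged


# ---------------------------------------------------------------------------
# model evidence


def _pack(alpha: np.ndarray, weights: np.ndarray, active: np.ndarray) -> np.ndarray:
    theta = [np.log(alpha[active])]
    k = weights.size
    if k > 1:
        theta.append(np.log(weights[:-1] / weights[-1]))  # additive log-ratio
    return np.concatenate(theta)


def _unpack(
    theta: np.ndarray, alpha0: np.ndarray, active: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    n_a = int(active.sum())
    alpha = alpha0.copy()
    alpha[active] = np.exp(theta[:n_a])
    if k > 1:
        z = np.concatenate([theta[n_a:], [0.0]])
        z = z - z.max()
        w = np.exp(z)
        weights = w / w.sum()
    else:
        weights = np.ones(1)
    return alpha, weights


def _neg_loglik(theta, X, alpha0, active, k) -> float:
    alpha, weights = _unpack(theta, alpha0, active, k)
    logdm = _dm_component_loglik(X, alpha)
    joint = np.log(np.maximum(weights, 1e-300))[None, :] + logdm
    return -float(logsumexp(joint, axis=1).sum())


#: weak lognormal prior scale on alpha (and on the additive-log-ratio
#: weight coordinates); regularizes directions the data barely constrains
#: so the Laplace integral is well-defined
PRIOR_TAU = 3.0


def _neg_logprior(theta: np.ndarray) -> float:
    return float(
        0.5 * np.sum((theta / PRIOR_TAU) ** 2)
        + theta.size * np.log(PRIOR_TAU * np.sqrt(2.0 * np.pi))
    )


def _laplace_neg_evidence(
    X: np.ndarray, alpha: np.ndarray, weights: np.ndarray
) -> tuple[float, int]:
    """Negative log model evidence via a MAP Laplace approximation.

    Evidence is approximated around the EM optimum in log-alpha /
    additive-log-ratio coordinates under a weak mean-zero normal prior of
    scale ``PRIOR_TAU`` on those coordinates: the prior contributes
    curvature ``1/tau^2`` to otherwise flat directions (parameters the data
    barely constrains), keeping the Gaussian integral finite and neutral
    for unidentified parameters instead of rewarding them.  Parameters
    collapsed to the alpha floor are treated as pinned and excluded.
    Lower is better.
    """
    k = weights.size
    active = alpha > ALPHA_ACTIVE
    theta = _pack(alpha, weights, active)
    p = theta.size
    f0 = _neg_loglik(theta, X, alpha, active, k)
    h = 1e-4 * (1.0 + np.abs(theta))
    # central second differences of the negative log-likelihood
    hess = np.empty((p, p))
    f_plus = np.empty(p)
    f_minus = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        f_plus[i] = _neg_loglik(theta + e, X, alpha, active, k)
        f_minus[i] = _neg_loglik(theta - e, X, alpha, active, k)
        hess[i, i] = (f_plus[i] - 2.0 * f0 + f_minus[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = _neg_loglik(theta + ei + ej, X, alpha, active, k)
            fmm = _neg_loglik(theta - ei - ej, X, alpha, active, k)
            val = (fpp - f_plus[i] - f_plus[j] + 2.0 * f0 - f_minus[i] - f_minus[j] + fmm) / (
                2.0 * h[i] * h[j]
            )
            hess[i, j] = hess[j, i] = val
    hess = (hess + hess.T) / 2.0 + np.eye(p) / PRIOR_TAU**2  # posterior curvature
    eigs = np.linalg.eigvalsh(hess)
    eigs = np.clip(eigs, 1e-8, None)  # numerical safety only
    logdet = float(np.sum(np.log(eigs)))
    neg_evidence = (
        f0 + _neg_logprior(theta) + 0.5 * logdet - 0.5 * p * np.log(2.0 * np.pi)
    )
    return neg_evidence, p


# ---------------------------------------------------------------------------
# public API


def fit_dmm(
    counts,
    k_range=(1, 2, 3),
    n_starts: int = 3,
    seed: int = 0,
    selection: str = "laplace",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DmmModel:
    """Fit DMM models over ``k_range`` and return the best-evidence one.

    For each K, EM is restarted ``n_starts`` times from k-means-based
    responsibilities and the best final log-likelihood kept; K is then
    chosen by minimal Laplace-approximated negative evidence (or BIC with
    ``selection='bic'``).  The per-K selection table is attached to the
    returned model.
    """
    X, sample_ids, taxa = _as_counts(counts)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("empty samples in count matrix")
    nonzero = X.sum(axis=0) > 0
    if not nonzero.all():
        log.info("dropping %d all-zero taxa before DMM fit", int((~nonzero).sum()))
        X = X[:, nonzero]
        taxa = taxa[nonzero]
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 1:
        raise ValueError("K must be >= 1")
    if max(k_range) >= X.shape[0]:
        raise ValueError("K_max must be smaller than the number of samples")
    if selection not in ("laplace", "bic"):
        raise ValueError("selection must be 'laplace' or 'bic'")

    rng = np.random.default_rng(seed)
    fits = {}
    rows = []
    for k in k_range:
        best = None
        for _ in range(max(1 if k == 1 else n_starts, 1)):
            resp0 = _initial_responsibilities(X, k, rng)
            alpha, weights, resp, trace, conv = _fit_single(
                X, k, resp0, max_iter, tol
            )
            ll = trace[-1]
            if best is None or ll > best[4][-1]:
                best = (alpha, weights, resp, conv, trace)
        alpha, weights, resp, conv, trace = best
        n_params = int((alpha > ALPHA_ACTIVE).sum()) + (k - 1)
        bic = -2.0 * trace[-1] + n_params * np.log(X.shape[0])
        if selection == "laplace":
            neg_ev, p_used = _laplace_neg_evidence(X, alpha, weights)
            score = neg_ev
        else:
            score = bic
            p_used = n_params
        fits[k] = (alpha, weights, resp, conv, trace)
        rows.append((k, trace[-1], p_used, bic, score))

    table = pd.DataFrame(
        rows, columns=["K", "log_likelihood", "n_params", "bic", "score"]
    ).set_index("K")
    best_k = int(table["score"].idxmin())
    alpha, weights, resp, conv, trace = fits[best_k]
    model = DmmModel(
        n_components=best_k,
        weights=weights,
        alpha=alpha,
        responsibilities=resp,
        log_likelihood=float(trace[-1]),
        log_likelihood_trace=trace,
        converged=conv,
        taxa=taxa,
        sample_ids=sample_ids,
        selection=table,
    )
    return model


def dmm_assign(model: DmmModel, counts=None) -> pd.Series:
    """Hard cluster labels: argmax responsibility per sample.

    With ``counts`` given, responsibilities are recomputed for that matrix
    (taxa are aligned by name).  Exact ties break to the lowest component
    index, with a logged warning.
    """
    if counts is None:
        resp = model.responsibilities
        ids = model.sample_ids
    else:
        X, ids, taxa = _as_counts(counts)
        if len(taxa) != len(model.taxa) or not list(taxa) == list(model.taxa):
            try:
                df = counts.counts if hasattr(counts, "counts") else pd.DataFrame(counts)
                X = df.loc[model.taxa].to_numpy().T.astype(np.int64)
            except KeyError as exc:
                raise ValueError("count matrix taxa do not match the model") from exc
        logdm = _dm_component_loglik(X, model.alpha)
        joint = np.log(np.maximum(model.weights, 1e-300))[None, :] + logdm
        resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    labels = resp.argmax(axis=1)
    ties = (resp == resp.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.warning(
            "responsibility ties for samples %s; assigned to lowest component",
            list(pd.Index(ids)[ties]),
        )
    return pd.Series(labels + 1, index=ids, name="cluster")


@dataclass
class LoadClusterTest:
    medians: pd.Series
    u_statistic: float
    p_value: float


def loads_by_cluster_test(labels: pd.Series, loads: pd.Series) -> LoadClusterTest:
    """Compare microbial loads between two clusters (Mann-Whitney U).

    ``labels`` and ``loads`` are aligned on their common index; exactly two
    clusters must be represented among the aligned samples.
    """
    from .stats import mann_whitney_u

    labels = pd.Series(labels)
    loads = pd.Series(loads, dtype=float)
    common = labels.index.intersection(loads.index)
    if len(common) == 0:
        raise ValueError("labels and loads share no samples")
    labels = labels.loc[common]
    loads = loads.loc[common]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 clusters required, found {len(groups)}")
    g1 = loads[labels == groups[0]]
    g2 = loads[labels == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("a cluster has no members")
    res = mann_whitney_u(g1.to_numpy(), g2.to_numpy())
    medians = pd.Series(
        {groups[0]: float(g1.median()), groups[1]: float(g2.median())},
        name="median_load",
    )
    return LoadClusterTest(
        medians=medians, u_statistic=float(res.statistic), p_value=float(res.pvalue)
    )
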