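"""Population structure: variance-standardized PCA and admixture inference.

The admixture model is the standard binomial mixture for unlinked genotypes:
P(d_ij) = Binomial(2, sum_k q_ik p_kj), maximized by plain EM over ancestry
fractions Q and population allele frequencies P.  Model choice over K uses
masked-entry cross-validation: a fraction of called genotypes is hidden, the
model is fitted on the rest, and the hidden dosages are predicted as
2 * sum_k q_ik p_kj; the CV error is the RMSE on the hidden entries.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import MISSING, GenotypeDataset
from .qc import allele_freq


@dataclasses.dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending
    eigenvectors: np.ndarray       # samples x components
    pct_variance: np.ndarray       # of all (positive) components
    pct_variance_topk: np.ndarray  # of the computed/kept components only


@dataclasses.dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                  # samples x K
    P: np.ndarray                  # K x SNPs
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    cv_error: float | None = None


def pca(ds: GenotypeDataset, n_components: int | None = None) -> PCAResult:
    """PCA of the variance-standardized genotype matrix.

    Each SNP column is centred at 2p and scaled by 1/sqrt(2p(1-p)); missing
    entries contribute zero.  Eigenvector signs follow the convention that
    the largest-magnitude entry of each component is positive.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    d = ds.dosage_float()
    p = np.nanmean(d, axis=0) / 2.0
    var = 2.0 * p * (1.0 - p)
    keep = var > 0
    if not keep.any():
        raise ValueError("no polymorphic SNPs")
    Z = (d[:, keep] - 2.0 * p[keep]) / np.sqrt(var[keep])
    Z[np.isnan(Z)] = 0.0
    G = (Z @ Z.T) / keep.sum()
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n_components is not None:
        vals, vecs = vals[:n_components], vecs[:, :n_components]
    for k in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] *= -1
    pos = np.clip(vals, 0, None)
    total = pos.sum()
    pct_all = 100.0 * pos / total if total > 0 else pos
    pct_topk = 100.0 * pos / pos.sum() if pos.sum() > 0 else pos
    return PCAResult(eigenvalues=vals, eigenvectors=vecs,
                     pct_variance=pct_all, pct_variance_topk=pct_topk)


def _loglik(d, called, Q, P):
    mu = np.clip(Q @ P, 1e-12, 1 - 1e-12)
    ll = np.where(called, d * np.log(mu) + (2 - d) * np.log1p(-mu), 0.0)
    return float(ll.sum())


def admixture_em(ds: GenotypeDataset, K: int, seed: int | list[int] = 0,
                 max_iter: int = 500, tol: float = 1e-4) -> AdmixtureFit:
    """Fit the K-way admixture model by EM; multi-start keeps the best run.

    The log-likelihood is guaranteed non-decreasing per EM step; convergence
    is declared when the increase drops below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ds.n_samples:
        raise ValueError("K exceeds the number of samples")
    d = ds.dosage.astype(float)
    called = ds.dosage != MISSING
    d[~called] = 0.0
    if K == 1:
        p = allele_freq(ds)[None, :]
        p = np.nan_to_num(p, nan=0.5)
        Q = np.ones((ds.n_samples, 1))
        ll = _loglik(d, called, Q, p)
        return AdmixtureFit(K=1, Q=Q, P=p, loglik=ll,
                            loglik_path=np.array([ll]), n_iter=0, converged=True)
    seeds = [seed] if isinstance(seed, int) else list(seed)
    best: AdmixtureFit | None = None
    for s in seeds:
        fit = _em_single(d, called, K, s, max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em_single(d, called, K, seed, max_iter, tol) -> AdmixtureFit:
    rng = np.random.default_rng(seed)
    n, m = d.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(rng.random((K, m)), 0.05, 0.95)
    w = called.astype(float)
    path = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        mu = np.clip(Q @ P, 1e-12, 1 - 1e-12)      # n x m
        # responsibilities: allele-level expected counts attributed to k
        # A_k = d * (q_ik p_kj / mu), B_k = (2-d) * (q_ik (1-p_kj) / (1-mu))
        ratio_b = w * d / mu                        # n x m
        ratio_a = w * (2.0 - d) / (1.0 - mu)
        # expected b/a-allele counts attributed to k, summed over samples
        num = P * (Q.T @ ratio_b)                   # K x m
        den = num + (1.0 - P) * (Q.T @ ratio_a)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_P = np.where(den > 0, num / den, P)
        # same responsibilities summed over SNPs
        sumA = Q * (ratio_b @ P.T + ratio_a @ (1.0 - P).T)   # n x K
        Q = sumA / np.maximum(sumA.sum(axis=1, keepdims=True), 1e-300)
        P = np.clip(new_P, 1e-9, 1 - 1e-9)
        ll = _loglik(d, called, Q, P)
        path.append(ll)
        if ll - prev < tol and it > 0:
            converged = True
            prev = ll
            break
        prev = ll
    return AdmixtureFit(K=K, Q=Q, P=P, loglik=prev,
                        loglik_path=np.array(path), n_iter=len(path),
                        converged=converged)


def admixture_cv(ds: GenotypeDataset, K: int, folds: int = 3,
                 mask_fraction: float = 0.1, seed: int = 0,
                 max_iter: int = 300, tol: float = 1e-3) -> float:
    """Masked-entry cross-validation error for the K-way admixture model."""
    if mask_fraction <= 0:
        raise ValueError("mask_fraction must be positive")
    rng = np.random.default_rng(seed)
    called = ds.dosage != MISSING
    errors = []
    for _ in range(folds):
        for _attempt in range(20):
            mask = called & (rng.random(ds.dosage.shape) < mask_fraction)
            # every SNP must retain at least one called entry
            if ((called & ~mask).sum(axis=0) > 0).all() and mask.any():
                break
        else:
            raise RuntimeError("could not draw a valid mask")
        masked = ds.dosage.copy()
        masked[mask] = MISSING
        sub = GenotypeDataset(ds.samples, ds.markers, masked)
        fit = admixture_em(sub, K, seed=int(rng.integers(2**31 - 1)),
                           max_iter=max_iter, tol=tol)
        pred = 2.0 * (fit.Q @ fit.P)
        err = ds.dosage[mask].astype(float) - pred[mask]
        errors.append(np.sqrt(np.mean(err**2)))
    return float(np.mean(errors))


def align_q_to_truth(Q: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute the columns of Q to best match Q_true (label switching)."""
    from scipy.optimize import linear_sum_assignment
    K = Q.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(Q[:, i] - Q_true[:, j]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return Q[:, perm]
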