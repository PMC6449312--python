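"""Population structure: PCA, model-based ancestry estimation, CV for K.

PCA uses Patterson normalisation (centre each SNP by its mean dosage,
scale by sqrt(p(1-p)) with a pseudo-count frequency estimate) and an
exact eigendecomposition of the sample covariance, so results are
deterministic.

Ancestry estimation fits the standard admixture model: genotype g_ij is
Binomial(2, sum_k q_ik f_kj) with per-sample ancestry fractions Q and
per-cluster allele frequencies F.  The likelihood is maximised by EM
from seeded random starts; EM guarantees a monotone log-likelihood,
which the tests assert.  The number of clusters K is chosen by v-fold
cross-validation on masked genotype entries (smallest held-out squared
prediction error, ties to the smallest K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix

_F_EPS = 1e-6


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray
    explained_variance_fraction: np.ndarray
    samples: list


@dataclass
class AncestryModel:
    K: int
    Q: np.ndarray  # (n_samples, K), rows sum to 1
    F: np.ndarray  # (K, n_snps) cluster alt-allele frequencies
    loglik: float
    loglik_path: np.ndarray
    cv_error: float | None = None


@dataclass
class CvCurve:
    K_values: list
    cv_error: list

    @property
    def chosen_K(self) -> int:
        errs = np.asarray(self.cv_error)
        return int(self.K_values[int(np.argmin(errs))])  # argmin takes first on ties


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def run_pca(m: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Patterson-normalised PCA of the dosage matrix.

    Missing values are not allowed (impute first); monomorphic columns
    carry no information and are dropped before the decomposition.
    """
    if (m.calls == MISSING).any():
        raise ValueError("PCA requires a fully imputed matrix")
    n, L = m.n_samples, m.n_snps
    if n < 2:
        raise ValueError("need at least 2 samples")
    n_components = min(n_components, n - 1)
    if n_components < 1:
        raise ValueError("fewer samples than requested components")
    G = m.calls.astype(np.float64)
    mean = G.mean(axis=0)
    poly = (G != G[0]).any(axis=0)
    G = G[:, poly]
    mean = mean[poly]
    p_hat = (1.0 + G.sum(axis=0)) / (2.0 + 2.0 * n)
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    X = (G - mean) / scale
    cov = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    k = n_components
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    # deterministic sign: largest-magnitude entry of each component positive
    for c in range(k):
        col = scores[:, c]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            scores[:, c] = -col
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(
        scores=scores,
        eigenvalues=evals[:k],
        explained_variance_fraction=frac,
        samples=list(m.samples),
    )


# ---------------------------------------------------------------------------
# admixture model
# ---------------------------------------------------------------------------

def _admixture_loglik(G, obs, Q, F):
    mu = Q @ F
    mu = np.clip(mu, _F_EPS, 1.0 - _F_EPS)
    ll = G * np.log(mu) + (2.0 - G) * np.log1p(-mu)
    return float(ll[obs].sum())


def _em_fit(G, obs, K, rng, tol, max_iter):
    n, L = G.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), _F_EPS, 1 - _F_EPS)
    A = np.where(obs, G, 0.0)          # alt-allele counts
    B = np.where(obs, 2.0 - G, 0.0)    # ref-allele counts
    denom_q = 2.0 * obs.sum(axis=1, keepdims=True)  # alleles observed per sample
    # pre-allocated buffers keep the hot loop free of large allocations
    n_, L_ = A.shape
    mu = np.empty((n_, L_))
    omm = np.empty_like(mu)
    Ra = np.empty_like(mu)
    Rb = np.empty_like(mu)
    logbuf = np.empty_like(mu)
    path = []
    prev = -np.inf
    for it in range(max_iter):
        np.matmul(Q, F, out=mu)
        np.clip(mu, _F_EPS, 1.0 - _F_EPS, out=mu)
        np.subtract(1.0, mu, out=omm)
        np.divide(A, mu, out=Ra)
        np.divide(B, omm, out=Rb)
        # expected allele-origin counts, accumulated without the (n, K, L) tensor
        alt = Q * (Ra @ F.T)              # (n, K): sum_j (A/mu) q f
        ref = Q * (Rb @ (1.0 - F).T)      # (n, K)
        alt_f = (Q.T @ Ra) * F            # (K, L): f_kj sum_i q_ik A_ij / mu_ij
        ref_f = (Q.T @ Rb) * (1.0 - F)
        Q_new = (alt + ref) / denom_q
        Q_new = np.clip(Q_new, 1e-12, None)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            F_new = alt_f / (alt_f + ref_f)
        F_new = np.where(np.isfinite(F_new), F_new, 0.5)
        F = np.clip(F_new, _F_EPS, 1.0 - _F_EPS)
        Q = Q_new
        np.matmul(Q, F, out=mu)
        np.clip(mu, _F_EPS, 1.0 - _F_EPS, out=mu)
        np.log(mu, out=logbuf)
        ll = float(np.einsum("ij,ij->", A, logbuf))
        np.subtract(1.0, mu, out=omm)
        np.log(omm, out=logbuf)
        ll += float(np.einsum("ij,ij->", B, logbuf))
        path.append(ll)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite admixture log-likelihood")
        if ll - prev < tol and it > 0:
            break
        prev = ll
    return Q, F, np.asarray(path)


def fit_admixture(
    m: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> AncestryModel:
    """Maximum-likelihood admixture fit at a given K (EM, best of restarts).

    K=1 has the closed-form solution Q = 1, F = per-SNP alt frequency.
    Missing entries (from CV masking) are excluded from the likelihood.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = m.calls.astype(np.float64)
    obs = m.calls != MISSING
    if K == 1:
        n_al = 2.0 * obs.sum(axis=0)
        freq = np.where(obs, G, 0.0).sum(axis=0) / np.maximum(n_al, 1.0)
        F = np.clip(freq, _F_EPS, 1 - _F_EPS)[None, :]
        Q = np.ones((m.n_samples, 1))
        ll = _admixture_loglik(G, obs, Q, F)
        return AncestryModel(K=1, Q=Q, F=F, loglik=ll, loglik_path=np.asarray([ll]))
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        Q, F, path = _em_fit(G, obs, K, rng, tol, max_iter)
        if best is None or path[-1] > best[2][-1]:
            best = (Q, F, path)
    Q, F, path = best
    return AncestryModel(K=K, Q=Q, F=F, loglik=float(path[-1]), loglik_path=path)


def dominant_cluster_fractions(model: AncestryModel, is_dom: np.ndarray) -> np.ndarray:
    """Ancestry fraction toward the cluster enriched in known domesticates.

    ``is_dom`` is a boolean vector over samples (e.g. species == 'max');
    the 'domesticated' cluster is the Q column with the largest mean over
    those samples.
    """
    is_dom = np.asarray(is_dom, dtype=bool)
    if not is_dom.any():
        raise ValueError("no reference domesticated samples")
    col = int(np.argmax(model.Q[is_dom].mean(axis=0)))
    return model.Q[:, col]


def cross_validate_K(
    m: GenotypeMatrix,
    K_list,
    v_folds: int = 5,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    n_restarts: int = 2,
) -> CvCurve:
    """Choose K by masked-entry cross-validation.

    Per fold a random ``holdout_fraction`` of observed entries is masked,
    the model refit, and masked dosages predicted as 2 * sum_k q f; the
    CV error for K is the mean squared deviation over folds.  A mask that
    would blank out an entire SNP is redrawn.
    """
    ss = np.random.SeedSequence(seed)
    obs_idx = np.argwhere(m.calls != MISSING)
    errors = []
    fold_seeds = ss.spawn(v_folds)
    for K in K_list:
        fold_err = []
        for fold, fseed in enumerate(fold_seeds):
            rng = np.random.default_rng(fseed)
            for _attempt in range(20):
                take = rng.random(len(obs_idx)) < holdout_fraction
                masked = obs_idx[take]
                calls = m.calls.copy()
                calls[masked[:, 0], masked[:, 1]] = MISSING
                if ((calls != MISSING).sum(axis=0) > 0).all():
                    break
            else:
                raise RuntimeError("could not draw a valid CV mask")
            mm = GenotypeMatrix(list(m.samples), m.snps, calls)
            model = fit_admixture(
                mm, K, seed=int(rng.integers(2**31)), tol=tol,
                max_iter=max_iter, n_restarts=n_restarts,
            )
            pred = 2.0 * (model.Q @ model.F)
            truth = m.calls[masked[:, 0], masked[:, 1]].astype(float)
            fold_err.append(float(np.mean((truth - pred[masked[:, 0], masked[:, 1]]) ** 2)))
        errors.append(float(np.mean(fold_err)))
    return CvCurve(K_values=list(K_list), cv_error=errors)


# ---------------------------------------------------------------------------
# representative-set extraction
# ---------------------------------------------------------------------------

def extract_representative_set(
    pca: PcaResult, labels, n_per_group: int | dict, n_pcs: int = 3
) -> list:
    """Greedy maximin (farthest-point) thinning in PC space, per label.

    Within each label the first pick is the sample nearest the group
    centroid (ties to the smallest id); subsequent picks maximise the
    minimum distance to the already-selected set.  Groups smaller than
    the request are returned whole.
    """
    labels = np.asarray(labels)
    X = pca.scores[:, : min(n_pcs, pca.scores.shape[1])]
    chosen: list = []
    for lab in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lab)
        want = n_per_group[lab] if isinstance(n_per_group, dict) else n_per_group
        if want < 1:
            raise ValueError("n_per_group must be >= 1")
        if want >= len(idx):
            chosen.extend(pca.samples[i] for i in idx)
            continue
        pts = X[idx]
        centroid = pts.mean(axis=0)
        d0 = np.linalg.norm(pts - centroid, axis=1)
        order = np.lexsort(([pca.samples[i] for i in idx], d0))
        picked = [order[0]]
        mind = np.linalg.norm(pts - pts[picked[0]], axis=1)
        while len(picked) < want:
            nxt = int(np.argmax(mind))
            picked.append(nxt)
            mind = np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1))
        chosen.extend(pca.samples[idx[i]] for i in picked)
    return chosen
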