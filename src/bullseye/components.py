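"""Latent structure of the 36 log parcel volumes.

PCA on the correlation matrix, Horn-style parallel analysis for component
retention, and direct oblimin (oblique) rotation via gradient projection.
The rotation is implemented here rather than imported: the gradient-projection
update for oblique rotations (Jennrich 2002; Bernaards & Jennrich 2005) is a
short, well-specified algorithm and keeping it local avoids a dependency that
exists only for this step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParallelAnalysisResult",
    "ComponentModel",
    "RotationError",
    "parallel_analysis",
    "oblimin_rotate",
    "fit_components",
    "interpret_loadings",
]


class RotationError(RuntimeError):
    """Oblique rotation failed to converge."""


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    simulated_quantiles: np.ndarray
    n_retained: int
    n_sim: int
    quantile: float
    seed: int | None


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, float)
    return X, [f"v{j}" for j in range(X.shape[1])]


def _correlation_eigenvalues(X: np.ndarray) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def parallel_analysis(
    X,
    n_sim: int = 500,
    quantile: float = 0.95,
    seed: int | None = None,
) -> ParallelAnalysisResult:
    """Retain components whose observed eigenvalue beats the null quantile.

    Null eigenvalues come from ``n_sim`` iid standard-normal datasets of the
    same shape; retention stops at the first observed eigenvalue that does not
    exceed the per-position quantile.
    """
    X, names = _as_matrix(X)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        raise ValueError(f"constant column(s): {[names[j] for j in const]}")
    if n <= p:
        warnings.warn(
            f"parallel analysis with n={n} <= p={p}: eigenvalue estimates are unstable",
            stacklevel=2,
        )
    observed = _correlation_eigenvalues(X)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, p))
    for s in range(n_sim):
        sims[s] = _correlation_eigenvalues(rng.standard_normal((n, p)))
    thresholds = np.quantile(sims, quantile, axis=0)
    retained = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            retained += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        simulated_quantiles=thresholds,
        n_retained=retained,
        n_sim=n_sim,
        quantile=quantile,
        seed=seed,
    )


# --------------------------------------------------------------------------
# direct oblimin rotation by oblique gradient projection


def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Oblimin criterion value and gradient dQ/dL (gamma=0: quartimin)."""
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    if gamma != 0.0:
        X = X - (gamma / p) * np.ones((p, p)) @ X
    return float(np.sum(L2 * X)) / 4.0, L * X


def oblimin_rotate(
    A: np.ndarray,
    gamma: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rotate loadings ``A`` by direct oblimin (oblique gradient projection).

    Returns ``(pattern, phi, info)`` with the rotated pattern matrix, the
    component correlation matrix, and convergence metadata.
    """
    A = np.asarray(A, float)
    p, k = A.shape
    if k == 1:
        return A.copy(), np.eye(1), {"iterations": 0, "converged": True, "gamma": gamma}
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(50):
            Tt = T - al * Gp
            Tt = Tt / np.sqrt(np.sum(Tt**2, axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _oblimin_criterion(L, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    if not converged:
        raise RotationError(
            f"oblimin rotation did not converge in {max_iter} iterations "
            f"(gradient norm {s:.3e}, tol {tol:g})"
        )
    phi = T.T @ T
    return L, phi, {"iterations": iterations, "converged": True, "gamma": gamma}


@dataclass
class ComponentModel:
    """Rotated principal-component solution on the correlation matrix."""

    k: int
    pattern: pd.DataFrame             # 36 x k pattern loadings
    structure: pd.DataFrame           # 36 x k structure loadings (= pattern @ phi)
    phi: np.ndarray                   # k x k component correlations
    eigenvalues: np.ndarray           # all unrotated eigenvalues (sum = n vars)
    variance_explained: np.ndarray    # unrotated, first k eigenvalues / p
    total_variance_explained: float
    rotated_ssl_proportion: np.ndarray  # sum of squared structure loadings / p
    communalities: pd.Series
    scores: pd.DataFrame              # n x k regression-method scores
    rotation: dict = field(default_factory=dict)

    @property
    def component_names(self) -> list[str]:
        return list(self.pattern.columns)


def fit_components(X, k: int, gamma: float = 0.0) -> ComponentModel:
    """PCA on the correlation matrix with direct oblimin rotation.

    Components are sign-flipped so each one's largest-magnitude loading is
    positive.  Scores are regression (Thurstone) scores of the standardized
    data.  Variance explained is reported from the unrotated eigenvalues;
    per-component contributions after oblique rotation are reported separately
    as sums of squared structure loadings (not additive across components).
    """
    X, names = _as_matrix(X)
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [names[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    A = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0, None))

    pattern, phi, info = oblimin_rotate(A, gamma=gamma)

    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(pattern[np.abs(pattern).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    pattern = pattern * flip
    phi = phi * np.outer(flip, flip)

    structure = pattern @ phi
    communalities = np.sum(pattern * structure, axis=1)

    # regression-method scores: Z R^{-1} S (minimum-norm when R is singular)
    B, *_ = np.linalg.lstsq(R, structure, rcond=None)
    scores = Z @ B

    comp_names = [f"C{i + 1}" for i in range(k)]
    return ComponentModel(
        k=k,
        pattern=pd.DataFrame(pattern, index=names, columns=comp_names),
        structure=pd.DataFrame(structure, index=names, columns=comp_names),
        phi=phi,
        eigenvalues=eigvals,
        variance_explained=eigvals[:k] / p,
        total_variance_explained=float(eigvals[:k].sum() / p),
        rotated_ssl_proportion=np.sum(structure**2, axis=0) / p,
        communalities=pd.Series(communalities, index=names, name="communality"),
        scores=pd.DataFrame(scores, columns=comp_names),
        rotation=info,
    )


def interpret_loadings(model: ComponentModel, threshold: float = 0.4) -> dict[str, list[str]]:
    """Variables whose |structure loading| exceeds the threshold, per component,
    ordered by decreasing magnitude."""
    out: dict[str, list[str]] = {}
    S = model.structure
    for comp in S.columns:
        col = S[comp].abs()
        sel = col[col > threshold].sort_values(ascending=False)
        out[comp] = list(sel.index)
    return out
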