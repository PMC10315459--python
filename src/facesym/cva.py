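"""Canonical variate analysis on asymmetric shape components, with pairwise
Mahalanobis distances between group means and permutation p-values.

Flattened shape components are rank-deficient (166 coordinates for an
83-landmark face, usable rank at most min(n − g, 2p + m − 2)), so all
computations run in the principal subspace of the data, retaining covariance
eigenvalues above ``eig_tol`` times the largest. The pooled within-group
covariance W (divisor n − g) is pseudo-inverted by eigenvalue truncation;
canonical axes solve the generalized eigenproblem B v = λ W v.

The permutation test is pairwise: for each unordered pair of groups only
those two groups' specimens are relabelled, and the pairwise Mahalanobis
distance is recomputed each round. p = (1 + #{D_perm ≥ D_obs}) / (rounds+1),
so p can never be exactly zero and is bounded below by 1/(rounds+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CVAResult:
    """Canonical axes/scores plus, when filled by `analyze_groups`, the
    pairwise Mahalanobis distance matrix and permutation p-values."""

    groups: tuple[str, ...]
    canonical_axes: np.ndarray  # (d, n_axes), columns are axes
    canonical_scores: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray
    mahalanobis: pd.DataFrame | None = None
    p_values: pd.DataFrame | None = None
    permutation_rounds: int = 0
    seed: int | None = None
    retained_rank: int = 0

    @property
    def n_axes(self) -> int:
        return self.canonical_axes.shape[1]


def _as_groups(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    labels = np.asarray([str(x) for x in labels], dtype=object)
    groups = sorted(set(labels))
    codes = np.array([groups.index(x) for x in labels])
    return codes, groups


def _check_groups(codes: np.ndarray, groups: list[str]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    small = [g for g, c in zip(groups, counts) if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")


def _principal_subspace(
    X: np.ndarray, eig_tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center X and project onto the principal directions whose variance
    exceeds ``eig_tol`` times the largest. Returns (mean, basis, reduced)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        raise ValueError("data matrix has no variation")
    keep = (s**2) > eig_tol * (s[0] ** 2)
    V = Vt[keep].T
    return mean, V, Xc @ V


def _pooled_within(
    Z: np.ndarray, codes: np.ndarray, g: int
) -> tuple[np.ndarray, np.ndarray]:
    """Group means and pooled within-group covariance (divisor n − g)."""
    n, d = Z.shape
    means = np.zeros((g, d))
    np.add.at(means, codes, Z)
    counts = np.bincount(codes, minlength=g).astype(float)
    means /= counts[:, None]
    Zc = Z - means[codes]
    W = Zc.T @ Zc / (n - g)
    return means, W


def _truncated_whitener(W: np.ndarray, eig_tol: float) -> np.ndarray:
    """T with TᵀWT = I on the retained eigenspace; W⁺ = TTᵀ."""
    evals, evecs = np.linalg.eigh(W)
    max_ev = evals[-1]
    if max_ev <= 0.0:
        raise ValueError("pooled within-group covariance has no variation")
    keep = evals > eig_tol * max_ev
    return evecs[:, keep] / np.sqrt(evals[keep])


def cva(
    X: np.ndarray,
    labels: Sequence[str],
    eig_tol: float = 1e-10,
) -> CVAResult:
    """Canonical variate analysis: axes maximizing between-group relative to
    pooled within-group variation.

    ``X`` is (n, d) with one flattened component vector per specimen. Axes
    are returned in the original d-dimensional space, ordered by decreasing
    eigenvalue; there are at most min(g − 1, retained rank) of them. Scores
    are the projections of all specimens onto the axes.
    """
    X = np.asarray(X, dtype=float)
    codes, groups = _as_groups(labels)
    _check_groups(codes, groups)
    g = len(groups)

    mean, V, Z = _principal_subspace(X, eig_tol)
    means, W = _pooled_within(Z, codes, g)
    T = _truncated_whitener(W, eig_tol)

    counts = np.bincount(codes).astype(float)
    grand = Z.mean(axis=0)
    Mw = (means - grand) @ T  # whitened group mean offsets
    B = (Mw * counts[:, None]).T @ Mw / (g - 1)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, int(np.sum(evals > max(evals.max(), 0.0) * 1e-12)))
    n_axes = max(n_axes, 1)
    evals = evals[order][:n_axes]
    axes_w = evecs[:, order[:n_axes]]

    axes = V @ T @ axes_w  # back to original coordinate space
    scores = (X - mean) @ axes
    return CVAResult(
        groups=tuple(groups),
        canonical_axes=axes,
        canonical_scores=scores,
        eigenvalues=np.clip(evals, 0.0, None),
        retained_rank=T.shape[1],
    )


def _pair_distance(Z: np.ndarray, codes01: np.ndarray, eig_tol: float) -> float:
    """Mahalanobis distance between two groups given 0/1 codes, with the
    pooled covariance of these specimens only."""
    means, W = _pooled_within(Z, codes01, 2)
    T = _truncated_whitener(W, eig_tol)
    delta = (means[0] - means[1]) @ T
    return float(np.linalg.norm(delta))


def mahalanobis_matrix(
    X: np.ndarray,
    labels: Sequence[str],
    eig_tol: float = 1e-10,
) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between group means,
    D(a,b) = sqrt((μ_a − μ_b)ᵀ W⁺ (μ_a − μ_b)), with W the pooled
    within-group covariance across *all* groups (divisor n − g) and W⁺ its
    eigenvalue-truncated pseudo-inverse."""
    X = np.asarray(X, dtype=float)
    codes, groups = _as_groups(labels)
    _check_groups(codes, groups)
    g = len(groups)
    _, _, Z = _principal_subspace(X, eig_tol)
    means, W = _pooled_within(Z, codes, g)
    T = _truncated_whitener(W, eig_tol)
    Mw = means @ T
    diff = Mw[:, None, :] - Mw[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=groups, columns=groups)


def permutation_test_pairwise(
    X: np.ndarray,
    labels: Sequence[str],
    rounds: int = 10000,
    seed: int | None = None,
    eig_tol: float = 1e-10,
) -> pd.DataFrame:
    """Permutation p-values for every pairwise Mahalanobis distance.

    For each unordered group pair only those specimens are pooled and
    relabelled; the observed distance uses the same two-group pooled
    covariance as the permuted ones. Deterministic given ``seed``.
    """
    if rounds < 100:
        raise ValueError("rounds must be at least 100")
    X = np.asarray(X, dtype=float)
    codes, groups = _as_groups(labels)
    _check_groups(codes, groups)
    g = len(groups)
    rng = np.random.default_rng(seed)

    P = np.ones((g, g))
    for a, b in combinations(range(g), 2):
        sel = (codes == a) | (codes == b)
        Xp = X[sel]
        codes01 = (codes[sel] == b).astype(int)
        n_a = int(np.sum(codes01 == 0))
        # reduce once: the principal span of the pair's data is permutation
        # invariant, so permutations run in at most n_pair−1 dimensions
        _, _, Z = _principal_subspace(Xp, eig_tol)
        d_obs = _pair_distance(Z, codes01, eig_tol)
        perm_codes = np.zeros(Z.shape[0], dtype=int)
        hits = 0
        for _ in range(rounds):
            perm = rng.permutation(Z.shape[0])
            perm_codes[:] = 1
            perm_codes[perm[:n_a]] = 0
            if _pair_distance(Z, perm_codes, eig_tol) >= d_obs:
                hits += 1
        p = (1.0 + hits) / (rounds + 1.0)
        P[a, b] = P[b, a] = p
    return pd.DataFrame(P, index=groups, columns=groups)


def analyze_groups(
    X: np.ndarray,
    labels: Sequence[str],
    rounds: int = 10000,
    seed: int | None = None,
    eig_tol: float = 1e-10,
) -> CVAResult:
    """CVA + distance matrix + pairwise permutation tests in one result."""
    base = cva(X, labels, eig_tol=eig_tol)
    D = mahalanobis_matrix(X, labels, eig_tol=eig_tol)
    P = permutation_test_pairwise(
        X, labels, rounds=rounds, seed=seed, eig_tol=eig_tol
    )
    return CVAResult(
        groups=base.groups,
        canonical_axes=base.canonical_axes,
        canonical_scores=base.canonical_scores,
        eigenvalues=base.eigenvalues,
        mahalanobis=D,
        p_values=P,
        permutation_rounds=rounds,
        seed=seed,
        retained_rank=base.retained_rank,
    )


def plot_cva(
    result: CVAResult,
    labels: Sequence[str],
    path: str | None = None,
    confidence: float = 0.95,
):
    """Scatter of the first two canonical axes with per-group confidence
    ellipses (normal approximation). Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse
    from scipy.stats import chi2

    labels = np.asarray([str(x) for x in labels], dtype=object)
    S = result.canonical_scores
    if S.shape[1] < 2:
        S = np.column_stack([S[:, 0], np.zeros(S.shape[0])])
    fig, ax = plt.subplots(figsize=(6, 5))
    q = chi2.ppf(confidence, df=2)
    for group in result.groups:
        pts = S[labels == group][:, :2]
        (line,) = ax.plot(pts[:, 0], pts[:, 1], "o", ms=4, label=group)
        if len(pts) > 2:
            mu = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False)
            evals, evecs = np.linalg.eigh(cov)
            angle = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1]))
            width, height = 2 * np.sqrt(q * np.clip(evals[::-1], 0, None))
            ax.add_patch(
                Ellipse(
                    mu,
                    width,
                    height,
                    angle=angle,
                    fill=False,
                    color=line.get_color(),
                )
            )
    ax.set_xlabel("CV 1")
    ax.set_ylabel("CV 2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
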