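"""Generalized Procrustes analysis with object symmetry.

A structure with *object symmetry* (a face, a skull) is symmetric about a
midline inside a single landmark configuration. Its asymmetry is isolated by
superimposing each configuration together with its mirrored-and-relabelled
copy: reflect the coordinates about the symmetry axis and swap the members of
every bilateral landmark pair. A joint (doubled) Procrustes superimposition
of the 2n configurations then yields, for each specimen,

    symmetric component   S_i = (aligned original + aligned mirror) / 2
    asymmetric component  A_i = (aligned original - aligned mirror) / 2

so that S_i + A_i reproduces the aligned original exactly. The mean of the
A_i is the directional asymmetry (a side bias shared by the sample);
individual deviations A_i - DA are the fluctuating asymmetry.

Scaling follows the partial-Procrustes convention: every configuration is
fixed at unit centroid size, and only rotations are optimized per iteration
(``full_procrustes=True`` re-scales optimally each round instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LandmarkConfiguration, SymmetryMap


class AlignmentError(RuntimeError):
    """Raised when a configuration cannot be rotationally aligned."""


class ConvergenceWarning(UserWarning):
    pass


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their
    centroid — the scale measure removed by Procrustes superimposition."""
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(coords - coords.mean(axis=0)))


def _swap_permutation(smap: SymmetryMap) -> np.ndarray:
    perm = np.arange(smap.k)
    for l, r in smap.pairs:
        perm[l], perm[r] = r, l
    return perm


def reflect_relabel(coords: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    """Mirror a coordinate matrix about the vertical axis (negate x) and swap
    the rows of each bilateral pair. Involutive: applying it twice returns
    the input exactly."""
    out = np.asarray(coords, dtype=float)[_swap_permutation(smap)].copy()
    out[:, 0] = -out[:, 0]
    return out


def mirror_relabel(
    config: LandmarkConfiguration, smap: SymmetryMap
) -> LandmarkConfiguration:
    """`reflect_relabel` on a configuration, keeping its identifier."""
    smap.validate_for(config.k)
    return LandmarkConfiguration(
        config.specimen_id, reflect_relabel(config.coords, smap)
    )


def align_pair(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Optimal rotation of A onto B: the 2×2 proper orthogonal R minimizing
    ‖A·R − B‖_F for centered A, B (rows are points).

    Closed form from the 2×2 cross-product matrix S = AᵀB:
    with a = tr(S) and b = S01 − S10, R rotates by atan2(b, a).
    Reflections are never introduced here (det R = +1 always); reflection
    enters the analysis only through `reflect_relabel`.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    S = A.T @ B
    a = S[0, 0] + S[1, 1]
    b = S[0, 1] - S[1, 0]
    h = float(np.hypot(a, b))
    scale = np.linalg.norm(A) * np.linalg.norm(B)
    if scale == 0.0 or h < 1e-14 * scale:
        raise AlignmentError(
            "degenerate configuration: rotational alignment undefined "
            "(coincident or vanishing landmarks)"
        )
    c, s = a / h, b / h
    return np.array([[c, s], [-s, c]])


def _rotate_all(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Rotate each configuration in the (N, k, 2) stack X onto C."""
    S = np.einsum("nki,kj->nij", X, C)  # per-config 2×2 cross-products XᵀC
    a = S[:, 0, 0] + S[:, 1, 1]
    b = S[:, 0, 1] - S[:, 1, 0]
    h = np.hypot(a, b)
    if np.any(h < 1e-14):
        raise AlignmentError("degenerate configuration during superimposition")
    c, s = a / h, b / h
    R = np.empty((X.shape[0], 2, 2))
    R[:, 0, 0] = c
    R[:, 0, 1] = s
    R[:, 1, 0] = -s
    R[:, 1, 1] = c
    return np.einsum("nkj,nji->nki", X, R)


@dataclass(frozen=True)
class AlignedShape:
    """One specimen's aligned original and aligned mirror copy, both in the
    consensus frame at unit centroid size."""

    specimen_id: str
    original_aligned: np.ndarray
    mirror_aligned: np.ndarray


@dataclass(frozen=True)
class SymmetryDecomposition:
    """Output of the object-symmetry superimposition.

    Arrays are stacked over specimens in input order: ``original_aligned``,
    ``mirror_aligned``, ``symmetric_components`` and ``asymmetric_components``
    have shape (n, k, 2); ``consensus`` and ``directional_asymmetry`` are
    (k, 2). ``residual_history`` tracks the summed squared residuals around
    the (unscaled) mean shape per iteration, which is non-increasing.
    """

    specimen_ids: tuple[str, ...]
    original_aligned: np.ndarray
    mirror_aligned: np.ndarray
    consensus: np.ndarray
    symmetric_components: np.ndarray
    asymmetric_components: np.ndarray
    directional_asymmetry: np.ndarray
    map: SymmetryMap
    n_iterations: int
    converged: bool
    final_change: float
    residual_history: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def asym_flat(self) -> np.ndarray:
        """Asymmetric components flattened to (n, 2k) row vectors."""
        return self.asymmetric_components.reshape(self.n, -1)

    @property
    def sym_flat(self) -> np.ndarray:
        return self.symmetric_components.reshape(self.n, -1)

    def aligned_shapes(self) -> list[AlignedShape]:
        return [
            AlignedShape(sid, self.original_aligned[i], self.mirror_aligned[i])
            for i, sid in enumerate(self.specimen_ids)
        ]

    def component_configurations(
        self, which: str = "asymmetric"
    ) -> list[LandmarkConfiguration]:
        """Components as LandmarkConfigurations for export via `facesym.io`.

        ``which`` ∈ {"original", "mirror", "symmetric", "asymmetric"}; the
        asymmetric components are exported relative to the consensus
        (consensus + A_i) so they satisfy the k ≥ 3 finite-coordinate type
        invariants while remaining lossless.
        """
        arrays = {
            "original": self.original_aligned,
            "mirror": self.mirror_aligned,
            "symmetric": self.symmetric_components,
            "asymmetric": self.consensus[None] + self.asymmetric_components,
        }[which]
        return [
            LandmarkConfiguration(sid, arrays[i])
            for i, sid in enumerate(self.specimen_ids)
        ]


def _symmetrize(coords: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    return 0.5 * (coords + reflect_relabel(coords, smap))


def _canonical_flip(consensus: np.ndarray) -> bool:
    """Decide whether to rotate the converged frame by 180°.

    The symmetrized consensus is automatically axis-aligned (midline at x=0),
    leaving only a two-fold rotational ambiguity. Resolve it with an
    index-weighted coordinate sum, which flips sign under a 180° rotation and
    is generically nonzero.
    """
    w = np.arange(1, consensus.shape[0] + 1, dtype=float)
    t = float(w @ consensus[:, 1])
    if abs(t) < 1e-9:
        t = float(w @ consensus[:, 0])
    return t < 0.0


def object_symmetry_fit(
    dataset: Sequence[LandmarkConfiguration],
    smap: SymmetryMap,
    tol: float = 1e-10,
    max_iter: int = 100,
    full_procrustes: bool = False,
) -> SymmetryDecomposition:
    """Doubled generalized Procrustes superimposition with object symmetry.

    Each configuration and its mirrored-relabelled copy are centered, scaled
    to unit centroid size, and iteratively rotated to a consensus that is
    re-estimated as the coordinate-wise mean, symmetrized (averaged with its
    own mirror-relabelling) and re-scaled to unit centroid size each round.
    Iteration stops when the consensus moves less than ``tol`` in Frobenius
    norm. The converged frame is canonicalized (symmetry axis vertical, 180°
    ambiguity resolved deterministically) so repeated runs are bit-identical.

    With ``full_procrustes=True`` each configuration is additionally re-scaled
    to its least-squares optimum against the consensus every iteration,
    instead of being pinned at unit centroid size.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("object_symmetry_fit requires at least 2 specimens")
    ks = {c.k for c in dataset}
    if len(ks) != 1:
        raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
    k = ks.pop()
    smap.validate_for(k)

    X = np.stack([c.coords for c in dataset]).astype(float)
    X -= X.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(X, axis=(1, 2), keepdims=True)
    if np.any(sizes == 0):
        raise AlignmentError("configuration with zero centroid size")
    X /= sizes
    M = np.stack([reflect_relabel(x, smap) for x in X])
    Z = np.concatenate([X, M])  # 2n configurations, originals first

    consensus = _symmetrize(Z[0], smap)
    cs = centroid_size(consensus)
    if cs < 1e-12:
        # near-antisymmetric initial shape: fall back to the full mean
        consensus = _symmetrize(Z.mean(axis=0), smap)
        cs = centroid_size(consensus)
    consensus /= cs

    converged = False
    change = np.inf
    history: list[float] = []
    n_done = 0
    for n_done in range(1, max_iter + 1):
        Z = _rotate_all(Z, consensus)
        if full_procrustes:
            betas = np.einsum("nki,ki->n", Z, consensus) / np.einsum(
                "nki,nki->n", Z, Z
            )
            Z *= betas[:, None, None]
        mean = Z.mean(axis=0)
        history.append(float(np.sum((Z - mean) ** 2)))
        new_consensus = _symmetrize(mean, smap)
        new_consensus /= centroid_size(new_consensus)
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"superimposition did not converge in {max_iter} iterations "
            f"(final consensus change {change:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    # final rotation pass against the converged consensus
    Z = _rotate_all(Z, consensus)

    if _canonical_flip(consensus):
        consensus = -consensus
        Z = -Z

    orig, mirr = Z[:n], Z[n:]
    S = 0.5 * (orig + mirr)
    A = 0.5 * (orig - mirr)
    return SymmetryDecomposition(
        specimen_ids=tuple(c.specimen_id for c in dataset),
        original_aligned=orig,
        mirror_aligned=mirr,
        consensus=consensus,
        symmetric_components=S,
        asymmetric_components=A,
        directional_asymmetry=A.mean(axis=0),
        map=smap,
        n_iterations=n_done,
        converged=converged,
        final_change=change,
        residual_history=tuple(history),
    )
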