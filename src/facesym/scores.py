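"""Procrustes ANOVA over the object-symmetry decomposition and per-individual
asymmetry scores.

The two-factor (individual × side) Procrustes ANOVA partitions the total
squared Procrustes variation of the doubled, aligned dataset into

    individual         2 Σ_i ‖S_i − S̄‖²      df (n−1)(2p+m−2)
    side (DA)          2 n ‖DA‖²              df 2p+m−2
    individual × side  2 Σ_i ‖A_i − DA‖²      df (n−1)(2p+m−2)

which sum *exactly* to the total SS of the 2n aligned configurations around
their grand mean (the grand mean of the doubled set equals the mean symmetric
component; the unit-size consensus differs from it by a scale factor of order
the shape variance). With replicate digitizations an error stratum (within-
specimen variation) is appended.

Individual asymmetry scores are Mahalanobis norms of each specimen's
fluctuating-asymmetry deviation against the sample asymmetry covariance —
standardizing by the observed covariance removes anisotropic variation that
would bias plain Procrustes distances. A Procrustes-distance variant is
reported alongside. For sample Mahalanobis distances against the usual n−1
covariance the mean squared score is identically r(n−1)/n, r the retained
subspace rank, so whole-sample means are pinned near √r and group differences
show up as deviations around that level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SymmetryMap
from .symmetry import SymmetryDecomposition


class DegenerateCovarianceWarning(UserWarning):
    pass


def subspace_dims(smap: SymmetryMap) -> tuple[int, int]:
    """Dimensions of the symmetric and asymmetric shape subspaces for 2D
    object symmetry.

    Both equal 2p + m − 2: the symmetric subspace loses translation along the
    axis and scale, the asymmetric subspace loses translation across the axis
    and rotation. Their sum is the full shape-space dimension 2k − 4.
    """
    d = 2 * smap.p + smap.m - 2
    if d < 1:
        raise ValueError(
            f"feature too small for asymmetry analysis: 2p+m-2 = {d} < 1 "
            f"(p={smap.p}, m={smap.m})"
        )
    return d, d


@dataclass(frozen=True)
class ProcrustesAnovaTable:
    """Effect → (SS, df, MS) table from the object-symmetry decomposition."""

    effects: tuple[str, ...]
    ss: Mapping[str, float]
    df: Mapping[str, int]
    total_ss: float

    def ms(self, effect: str) -> float:
        return self.ss[effect] / self.df[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SS": [self.ss[e] for e in self.effects],
                "df": [self.df[e] for e in self.effects],
                "MS": [self.ms(e) for e in self.effects],
            },
            index=pd.Index(self.effects, name="effect"),
        )


def procrustes_anova(
    decomp: SymmetryDecomposition,
    replicates: Sequence[str] | None = None,
) -> ProcrustesAnovaTable:
    """Two-factor Procrustes ANOVA (individual, side, individual×side).

    ``replicates`` optionally maps each configuration (decomposition order)
    to an individual id when the dataset contains repeated digitizations of
    the same specimens; a within-specimen error stratum is then appended and
    the individual/interaction strata use per-individual means. Without
    replicates every configuration is its own individual and no error stratum
    exists.
    """
    dim_sym, dim_asym = subspace_dims(decomp.map)
    S = decomp.sym_flat
    A = decomp.asym_flat
    N = decomp.n

    if replicates is None:
        ind_ids = list(decomp.specimen_ids)
    else:
        ind_ids = [str(r) for r in replicates]
        if len(ind_ids) != N:
            raise ValueError(
                f"replicate grouping has {len(ind_ids)} entries for "
                f"{N} configurations"
            )

    codes, uniques = pd.factorize(np.asarray(ind_ids, dtype=object))
    n_ind = len(uniques)
    counts = np.bincount(codes, minlength=n_ind).astype(float)

    S_bar = S.mean(axis=0)
    DA = A.mean(axis=0)
    S_ind = np.zeros((n_ind, S.shape[1]))
    A_ind = np.zeros((n_ind, A.shape[1]))
    np.add.at(S_ind, codes, S)
    np.add.at(A_ind, codes, A)
    S_ind /= counts[:, None]
    A_ind /= counts[:, None]

    ss = {
        "individual": 2.0 * float(counts @ np.sum((S_ind - S_bar) ** 2, axis=1)),
        "side": 2.0 * N * float(DA @ DA),
        "individual_x_side": 2.0
        * float(counts @ np.sum((A_ind - DA) ** 2, axis=1)),
    }
    df = {
        "individual": (n_ind - 1) * dim_sym,
        "side": dim_asym,
        "individual_x_side": (n_ind - 1) * dim_asym,
    }
    effects = ("individual", "side", "individual_x_side")
    if replicates is not None and n_ind < N:
        ss["error"] = 2.0 * float(
            np.sum((S - S_ind[codes]) ** 2) + np.sum((A - A_ind[codes]) ** 2)
        )
        df["error"] = (N - n_ind) * (dim_sym + dim_asym)
        effects = effects + ("error",)

    # total SS of the doubled aligned dataset around its grand mean;
    # equals 2Σ‖S_i − S̄‖² + 2Σ‖A_i‖² and the strata sum to it exactly
    total = 2.0 * float(np.sum((S - S_bar) ** 2) + np.sum(A**2))
    return ProcrustesAnovaTable(effects=effects, ss=ss, df=df, total_ss=total)


@dataclass(frozen=True)
class FAScoreTable:
    """Per-individual asymmetry scores.

    ``frame`` has columns specimen_id, mahalanobis_score, procrustes_score.
    ``rank`` is the retained asymmetry-subspace rank r (eigenvalues above
    ``eig_tol`` × the largest); ``theoretical_dim`` the 2p+m−2 bookkeeping
    value for comparison. ``da_removed`` records whether directional
    asymmetry was subtracted before scoring.
    """

    frame: pd.DataFrame
    rank: int
    theoretical_dim: int
    da_removed: bool
    eigenvalues: np.ndarray = field(repr=False)

    @property
    def mahalanobis(self) -> np.ndarray:
        return self.frame["mahalanobis_score"].to_numpy()

    @property
    def procrustes(self) -> np.ndarray:
        return self.frame["procrustes_score"].to_numpy()

    def with_metadata(self, metadata: pd.DataFrame) -> pd.DataFrame:
        """Strict join of scores to a metadata frame on specimen_id."""
        from .io import DatasetError

        merged = self.frame.merge(metadata, on="specimen_id", how="left")
        if merged.isna().any(axis=None):
            missing = merged.loc[
                merged.isna().any(axis=1), "specimen_id"
            ].tolist()
            raise DatasetError(f"specimens without metadata: {missing[:5]}")
        return merged


def fa_scores(
    decomp: SymmetryDecomposition,
    remove_da: bool = True,
    eig_tol: float = 1e-10,
) -> FAScoreTable:
    """Individual asymmetry scores from the asymmetric components.

    Each specimen's deviation d_i = A_i − DA (or A_i itself with
    ``remove_da=False``, retaining the directional contribution) is scored as

    * ``mahalanobis_score``: sqrt(Σ_j proj_ij² / λ_j) over the eigenpairs of
      the sample covariance of the d_i (n−1 divisor) whose eigenvalues exceed
      ``eig_tol`` times the largest — a Mahalanobis norm in the retained
      asymmetry subspace, insensitive to anisotropic variation;
    * ``procrustes_score``: the plain Euclidean norm ‖d_i‖.
    """
    if decomp.n < 3:
        raise ValueError("fa_scores requires at least 3 specimens")
    _, dim_asym = subspace_dims(decomp.map)
    D = decomp.asym_flat
    d = D - D.mean(axis=0) if remove_da else D

    cov = np.cov(D, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    max_ev = evals[0] if evals.size else 0.0
    if max_ev <= 0.0:
        warnings.warn(
            "all asymmetric deviations are zero: degenerate covariance, "
            "scores set to 0",
            DegenerateCovarianceWarning,
            stacklevel=2,
        )
        keep = np.zeros(0, dtype=bool)
    else:
        keep = evals > eig_tol * max_ev
    r = int(keep.sum())
    if r == 0:
        maha = np.zeros(decomp.n)
        proc = np.linalg.norm(d, axis=1)
        kept_evals = np.zeros(0)
    else:
        V = evecs[:, keep]
        kept_evals = evals[keep]
        proj = d @ V
        maha = np.sqrt(np.sum(proj**2 / kept_evals, axis=1))
        proc = np.linalg.norm(d, axis=1)

    frame = pd.DataFrame(
        {
            "specimen_id": list(decomp.specimen_ids),
            "mahalanobis_score": maha,
            "procrustes_score": proc,
        }
    )
    return FAScoreTable(
        frame=frame,
        rank=r,
        theoretical_dim=dim_asym,
        da_removed=remove_da,
        eigenvalues=kept_evals,
    )
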