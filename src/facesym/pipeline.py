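"""Config-driven orchestration: whole face plus per-feature reanalysis.

For the whole face and each configured landmark subset (eyes, nose, mouth,
contour by default) the pipeline runs an *independent* object-symmetry
superimposition — features are re-superimposed from the raw coordinates, not
projected out of the whole-face fit — followed by the Procrustes ANOVA,
individual asymmetry scores, CVA with pairwise Mahalanobis distances and
permutation tests per grouping factor, and the group statistics (two-way
sex × ethnicity ANOVA, Tukey HSD on ethnicity, bootstrapped Welch t between
databases). All tables are written as flat CSV under one directory per
feature, reachable from a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cva import CVAResult, analyze_groups, cva, plot_cva
from .io import (
    FeatureDefinition,
    LandmarkConfiguration,
    SymmetryMap,
    join_metadata,
    subset_landmarks,
    write_landmark_csv,
)
from .scores import FAScoreTable, fa_scores, procrustes_anova
from .stats import boot_welch_t, tukey_hsd, two_way_anova
from .symmetry import object_symmetry_fit

logger = logging.getLogger("facesym.pipeline")

_CSV_FMT = "%.17g"


@dataclass(frozen=True)
class PipelineOptions:
    """Analysis options shared by all features.

    ``seed`` drives every stochastic procedure (permutations, bootstrap) and
    is mandatory. ``factors`` are the metadata columns tested by CVA.
    """

    seed: int
    remove_da: bool = True
    permutation_rounds: int = 10000
    n_boot: int = 1000
    eig_tol: float = 1e-10
    full_procrustes: bool = False
    factors: tuple[str, ...] = ("database", "sex", "ethnicity")
    score_kind: str = "mahalanobis"  # column used for group statistics

    def child_seed(self, *tags: str) -> int:
        """A deterministic per-stage seed below 2**31 derived from the run
        seed and a stage tag."""
        h = hashlib.sha256(
            ("/".join([str(self.seed), *tags])).encode()
        ).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class FeatureResult:
    name: str
    decomposition: object
    anova: object
    score_table: FAScoreTable
    scores: pd.DataFrame  # scores joined to metadata
    cva_results: dict[str, CVAResult] = field(default_factory=dict)
    two_way: object | None = None
    tukey: pd.DataFrame | None = None
    welch: object | None = None
    skipped: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    features: dict[str, FeatureResult]
    failures: dict[str, str]
    options: PipelineOptions
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    dataset: Sequence[LandmarkConfiguration],
    smap: SymmetryMap,
    metadata: pd.DataFrame,
    features: Sequence[FeatureDefinition] = (),
    options: PipelineOptions | None = None,
) -> PipelineResult:
    """Run the full analysis on the whole face and each feature subset.

    A stage error aborts that feature (recorded in ``failures``) and the
    remaining features continue.
    """
    if options is None:
        raise ValueError("options (with a seed) are required")
    meta = join_metadata(dataset, metadata)

    jobs: list[tuple[str, FeatureDefinition | None]] = [("face", None)]
    jobs += [(feat.name, feat) for feat in features]

    results: dict[str, FeatureResult] = {}
    failures: dict[str, str] = {}
    for name, feat in jobs:
        try:
            if feat is None:
                subset, sub_map = list(dataset), smap
            else:
                subset, sub_map = subset_landmarks(dataset, smap, feat)
            results[name] = _run_feature(name, subset, sub_map, meta, options)
        except Exception as exc:  # noqa: BLE001 — per-feature isolation
            logger.error("feature %s failed: %s", name, exc)
            failures[name] = f"{type(exc).__name__}: {exc}"
            logger.debug("%s", traceback.format_exc())
    return PipelineResult(features=results, failures=failures, options=options)


def _run_feature(
    name: str,
    subset: Sequence[LandmarkConfiguration],
    sub_map: SymmetryMap,
    meta: pd.DataFrame,
    options: PipelineOptions,
) -> FeatureResult:
    logger.info("feature %s: superimposing %d specimens, k=%d",
                name, len(subset), sub_map.k)
    decomp = object_symmetry_fit(
        subset, sub_map, full_procrustes=options.full_procrustes
    )
    logger.info(
        "feature %s: converged=%s iterations=%d final_change=%.3e",
        name, decomp.converged, decomp.n_iterations, decomp.final_change,
    )
    anova = procrustes_anova(decomp)
    table = fa_scores(decomp, remove_da=options.remove_da,
                      eig_tol=options.eig_tol)
    logger.info("feature %s: retained rank %d (theoretical %d)",
                name, table.rank, table.theoretical_dim)
    scores = table.with_metadata(meta)
    result = FeatureResult(
        name=name, decomposition=decomp, anova=anova,
        score_table=table, scores=scores,
    )

    X = decomp.asym_flat
    for factor in options.factors:
        labels = meta[factor]
        if labels.nunique() < 2:
            result.skipped[f"cva_{factor}"] = "only one level present"
            continue
        result.cva_results[factor] = analyze_groups(
            X,
            labels,
            rounds=options.permutation_rounds,
            seed=options.child_seed(name, "cva", factor),
            eig_tol=options.eig_tol,
        )

    score_col = f"{options.score_kind}_score"
    y = scores[score_col].to_numpy()
    if meta["sex"].nunique() >= 2 and meta["ethnicity"].nunique() >= 2:
        result.two_way = two_way_anova(y, meta["sex"], meta["ethnicity"])
    else:
        result.skipped["two_way_anova"] = "need 2 levels of sex and ethnicity"
    if meta["ethnicity"].nunique() >= 2:
        result.tukey = tukey_hsd(y, meta["ethnicity"])
    else:
        result.skipped["tukey"] = "only one ethnicity"
    dbs = sorted(meta["database"].unique())
    if len(dbs) == 2:
        x0 = y[(meta["database"] == dbs[0]).to_numpy()]
        x1 = y[(meta["database"] == dbs[1]).to_numpy()]
        result.welch = boot_welch_t(
            x0, x1, n_boot=options.n_boot,
            seed=options.child_seed(name, "welch"),
        )
    else:
        result.skipped["welch"] = f"need exactly 2 databases, have {len(dbs)}"
    return result


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_results(
    result: PipelineResult, outdir: str | Path, plots: bool = False
) -> dict:
    """Write every table as CSV under one directory per feature and return
    the manifest (also written as ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "facesym",
        "version": __version__,
        "seed": result.options.seed,
        "options": {
            "remove_da": result.options.remove_da,
            "permutation_rounds": result.options.permutation_rounds,
            "n_boot": result.options.n_boot,
            "eig_tol": result.options.eig_tol,
            "full_procrustes": result.options.full_procrustes,
            "factors": list(result.options.factors),
            "score_kind": result.options.score_kind,
        },
        "features": {},
        "failures": result.failures,
    }

    for name, feat in result.features.items():
        fdir = outdir / name
        fdir.mkdir(exist_ok=True)
        files: dict[str, str] = {}

        feat.anova.to_frame().to_csv(fdir / "anova.csv", float_format=_CSV_FMT)
        files["anova"] = f"{name}/anova.csv"
        feat.scores.to_csv(fdir / "scores.csv", index=False,
                           float_format=_CSV_FMT)
        files["scores"] = f"{name}/scores.csv"
        write_landmark_csv(
            fdir / "consensus.csv",
            [LandmarkConfiguration("consensus", feat.decomposition.consensus)],
        )
        files["consensus"] = f"{name}/consensus.csv"
        write_landmark_csv(
            fdir / "asymmetric_components.csv",
            feat.decomposition.component_configurations("asymmetric"),
        )
        files["asymmetric_components"] = f"{name}/asymmetric_components.csv"

        for factor, cres in feat.cva_results.items():
            cdir = fdir / f"cva_{factor}"
            cdir.mkdir(exist_ok=True)
            cres.mahalanobis.to_csv(cdir / "distances.csv",
                                    float_format=_CSV_FMT)
            cres.p_values.to_csv(cdir / "pvalues.csv", float_format=_CSV_FMT)
            pd.DataFrame(
                cres.canonical_scores,
                columns=[f"CV{i+1}" for i in range(cres.n_axes)],
            ).assign(specimen_id=list(feat.decomposition.specimen_ids)).to_csv(
                cdir / "canonical_scores.csv", index=False,
                float_format=_CSV_FMT,
            )
            files[f"cva_{factor}"] = f"{name}/cva_{factor}"
            if plots:
                plot_cva(
                    cres,
                    feat.scores[factor],
                    path=str(cdir / "cva_scatter.png"),
                )

        if feat.two_way is not None:
            tw = feat.two_way.table.copy()
            tw.loc["shapiro"] = [feat.two_way.shapiro_stat, np.nan, np.nan,
                                 feat.two_way.shapiro_p]
            tw.loc["bartlett"] = [feat.two_way.bartlett_stat, np.nan, np.nan,
                                  feat.two_way.bartlett_p]
            tw.to_csv(fdir / "two_way_anova.csv", float_format=_CSV_FMT)
            files["two_way_anova"] = f"{name}/two_way_anova.csv"
        if feat.tukey is not None:
            feat.tukey.to_csv(fdir / "tukey.csv", index=False,
                              float_format=_CSV_FMT)
            files["tukey"] = f"{name}/tukey.csv"
        if feat.welch is not None:
            feat.welch.to_frame().to_csv(fdir / "welch.csv", index=False,
                                         float_format=_CSV_FMT)
            files["welch"] = f"{name}/welch.csv"
        manifest["features"][name] = {"files": files, "skipped": feat.skipped}

    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    result.manifest = manifest
    return manifest


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def summarize(outdir: str | Path, alpha: float = 0.05) -> str:
    """Human-readable markdown report regenerated from the saved tables.

    Purely a function of the files on disk, so regeneration is idempotent.
    """
    outdir = Path(outdir)
    with (outdir / "manifest.json").open() as fh:
        manifest = json.load(fh)
    lines = [
        "# facesym run report",
        "",
        f"Seed {manifest['seed']}, facesym {manifest['version']}, "
        f"{manifest['options']['permutation_rounds']} permutation rounds, "
        f"{manifest['options']['n_boot']} bootstrap replications.",
        "",
    ]
    for name, entry in manifest["features"].items():
        fdir = outdir / name
        lines.append(f"## {name}")
        scores = pd.read_csv(fdir / "scores.csv")
        by_db = scores.groupby("database")["mahalanobis_score"].mean()
        lines.append(
            "Mean asymmetry score by database: "
            + ", ".join(f"{db} = {v:.2f}" for db, v in by_db.items())
        )
        sep_counts: dict[str, int] = {}
        for factor in ("database", "sex", "ethnicity"):
            key = f"cva_{factor}"
            if key not in entry["files"]:
                if key in entry.get("skipped", {}):
                    lines.append(f"- CVA ({factor}): skipped "
                                 f"({entry['skipped'][key]})")
                continue
            D = pd.read_csv(fdir / key / "distances.csv", index_col=0)
            P = pd.read_csv(fdir / key / "pvalues.csv", index_col=0)
            pairs = [
                (a, b)
                for i, a in enumerate(D.index)
                for b in D.columns[i + 1:]
            ]
            sig = [(a, b) for a, b in pairs if P.loc[a, b] < alpha]
            lines.append(
                f"- CVA ({factor}): "
                + "; ".join(
                    f"{a}–{b} D={D.loc[a, b]:.2f} (p={P.loc[a, b]:.3g})"
                    for a, b in pairs
                )
            )
            lines.append(
                f"  significant at {alpha}: "
                + (", ".join(f"{a}–{b}" for a, b in sig) if sig else "none")
            )
            if factor == "ethnicity":
                for a, b in sig:
                    sep_counts[a] = sep_counts.get(a, 0) + 1
                    sep_counts[b] = sep_counts.get(b, 0) + 1
        if sep_counts:
            driver = max(sorted(sep_counts), key=sep_counts.__getitem__)
            lines.append(
                f"- Group driving pairwise differences: **{driver}** "
                f"({sep_counts[driver]} significant pairs)"
            )
        welch_path = fdir / "welch.csv"
        if welch_path.exists():
            w = pd.read_csv(welch_path).iloc[0]
            lines.append(
                f"- Databases (Welch): t({w['satterthwaite_df']:.1f}) = "
                f"{w['t_obs']:.2f}, p = {w['p_classical']:.3g}, "
                f"bootstrapped p = {w['p_bootstrap']:.3g}, "
                f"95% CI ({w['ci_low']:.2f}, {w['ci_high']:.2f})"
            )
        tw_path = fdir / "two_way_anova.csv"
        if tw_path.exists():
            tw = pd.read_csv(tw_path, index_col=0)
            eth = tw.loc["ethnicity"]
            lines.append(
                f"- Two-way ANOVA ethnicity: F = {eth['F']:.2f}, "
                f"p = {eth['p']:.3g}"
            )
        lines.append("")
    if manifest["failures"]:
        lines.append("## Failures")
        for name, msg in manifest["failures"].items():
            lines.append(f"- {name}: {msg}")
    return "\n".join(lines)
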