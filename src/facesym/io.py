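"""Reading and writing landmark data, symmetry maps, metadata and feature sets.

All landmark indices are **0-based** inside the package. TPS files carry no
indices; JSON symmetry-map and feature files are 0-based by default but may
declare ``"index_base": 1``, in which case indices are converted on read.
Coordinates are plain 2D points in arbitrary length units (pixels are fine):
the downstream Procrustes machinery removes translation, rotation and scale,
so no coordinate convention is imposed on input beyond finiteness.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class LandmarkError(ValueError):
    """Base class for landmark data problems."""


class ParseError(LandmarkError):
    """A file could not be parsed (malformed block, bad header...)."""


class DatasetError(LandmarkError):
    """Configurations are individually fine but inconsistent as a dataset."""


class SymmetryBrokenError(LandmarkError):
    """A landmark subset contains only one member of a bilateral pair."""


METADATA_COLUMNS = ("specimen_id", "database", "sex", "ethnicity")


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's landmark configuration: an identifier plus a k×2 matrix.

    Invariants enforced on construction: coordinates finite, k ≥ 3.
    """

    specimen_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: coords must be k×2, "
                f"got shape {coords.shape}"
            )
        if coords.shape[0] < 3:
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks, "
                f"got {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: non-finite coordinate at "
                f"landmark {bad[0]}"
            )
        coords = coords.copy()
        coords.flags.writeable = False
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "specimen_id", str(self.specimen_id))

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral structure of a landmark set.

    ``pairs`` holds (left_index, right_index) tuples; ``midline`` the indices
    of landmarks lying on the symmetry axis. Reflection negates the ``axis``
    coordinate (only ``"x"`` — the first coordinate — is supported, which is
    the convention used throughout: the symmetry axis is vertical).

    Every index must appear exactly once across pairs ∪ midline, so
    k = 2·|pairs| + |midline|.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    axis: str = "x"

    def __post_init__(self) -> None:
        pairs = tuple((int(l), int(r)) for l, r in self.pairs)
        midline = tuple(int(i) for i in self.midline)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)
        if self.axis != "x":
            raise LandmarkError(
                f"unsupported reflection axis {self.axis!r}; only 'x' "
                "(vertical symmetry axis) is implemented"
            )
        seen: set[int] = set()
        for idx in [i for p in pairs for i in p] + list(midline):
            if idx < 0:
                raise LandmarkError(f"negative landmark index {idx}")
            if idx in seen:
                raise LandmarkError(f"landmark index {idx} used more than once")
            seen.add(idx)
        if seen and seen != set(range(len(seen))):
            raise LandmarkError(
                "pairs and midline must cover indices 0..k-1 without gaps"
            )
        if self.k < 3:
            raise LandmarkError("symmetry map must cover at least 3 landmarks")

    @property
    def p(self) -> int:
        """Number of bilateral pairs."""
        return len(self.pairs)

    @property
    def m(self) -> int:
        """Number of midline landmarks."""
        return len(self.midline)

    @property
    def k(self) -> int:
        return 2 * self.p + self.m

    def validate_for(self, k: int) -> None:
        if self.k != k:
            raise DatasetError(
                f"symmetry map covers {self.k} landmarks but dataset has {k}"
            )

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "midline": list(self.midline),
            "axis": self.axis,
            "index_base": 0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryMap":
        base = int(d.get("index_base", 0))
        if base not in (0, 1):
            raise ParseError(f"index_base must be 0 or 1, got {base}")
        pairs = tuple((int(l) - base, int(r) - base) for l, r in d["pairs"])
        midline = tuple(int(i) - base for i in d.get("midline", ()))
        return cls(pairs=pairs, midline=midline, axis=d.get("axis", "x"))


@dataclass(frozen=True)
class FeatureDefinition:
    """A named subset of landmark indices (eyes, nose, mouth, contour, ...)."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(set(idx)) != len(idx):
            raise LandmarkError(f"feature {self.name!r}: duplicate indices")
        if any(i < 0 for i in idx):
            raise LandmarkError(f"feature {self.name!r}: negative index")


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^\s*(LM|ID|IMAGE|SCALE)\s*=\s*(.*?)\s*$", re.IGNORECASE)


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS file: blocks of ``LM=k`` followed by k coordinate lines,
    with optional ``ID=`` / ``IMAGE=`` lines per block.

    The specimen id is taken from ``ID=``, else ``IMAGE=``, else the 1-based
    block ordinal as text. All blocks must share the same landmark count.
    """
    path = Path(path)
    blocks: list[dict] = []
    current: dict | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            key_match = _TPS_KEY.match(line)
            if key_match:
                key = key_match.group(1).upper()
                value = key_match.group(2)
                if key == "LM":
                    current = {"lm": int(value), "coords": [], "lineno": lineno}
                    blocks.append(current)
                    continue
                if current is None:
                    raise ParseError(f"{path.name}:{lineno}: {key}= before any LM=")
                if key == "ID":
                    current["id"] = value
                elif key == "IMAGE":
                    current["image"] = value
                # SCALE= accepted and ignored: Procrustes removes scale anyway
                continue
            if current is None:
                raise ParseError(
                    f"{path.name}:{lineno}: coordinate line before any LM="
                )
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected two coordinates, got {line!r}"
                )
            try:
                current["coords"].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None

    configs: list[LandmarkConfiguration] = []
    for ordinal, block in enumerate(blocks, start=1):
        if len(block["coords"]) != block["lm"]:
            raise ParseError(
                f"{path.name}: block {ordinal} (line {block['lineno']}) declares "
                f"LM={block['lm']} but has {len(block['coords'])} coordinate lines"
            )
        sid = block.get("id") or block.get("image") or str(ordinal)
        configs.append(LandmarkConfiguration(sid, np.array(block["coords"])))
    _check_shared_k(configs, source=path.name)
    return configs


def write_tps(path: str | Path, configs: Sequence[LandmarkConfiguration]) -> None:
    """Write configurations as a TPS file (LM=, coordinates, ID=)."""
    path = Path(path)
    with path.open("w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


# ---------------------------------------------------------------------------
# Wide CSV
# ---------------------------------------------------------------------------


def read_landmark_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a wide landmark CSV: columns ``id, x1, y1, ..., xk, yk``.

    The landmark count is inferred from the column count; ids come from the
    first column. Rows with non-finite coordinates and duplicate ids are
    rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path.name}: need an id column plus coordinates")
    ncoord = df.shape[1] - 1
    if ncoord % 2 != 0:
        raise ParseError(
            f"{path.name}: odd number of coordinate columns ({ncoord})"
        )
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DatasetError(f"{path.name}: duplicate specimen id {dup!r}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    configs = []
    for row_idx, (sid, row) in enumerate(zip(ids, values)):
        if not np.all(np.isfinite(row)):
            raise LandmarkError(
                f"{path.name}: non-finite coordinate in row {row_idx} "
                f"(specimen {sid!r})"
            )
        configs.append(LandmarkConfiguration(sid, row.reshape(-1, 2)))
    _check_shared_k(configs, source=path.name)
    return configs


def write_landmark_csv(
    path: str | Path, configs: Sequence[LandmarkConfiguration]
) -> None:
    """Write configurations as wide CSV (``id, x1, y1, ..., xk, yk``)."""
    _check_shared_k(configs, source="write_landmark_csv")
    k = configs[0].k
    columns = ["id"] + [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    rows = [[c.specimen_id, *c.coords.reshape(-1)] for c in configs]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, float_format="%.17g"
    )


def _check_shared_k(
    configs: Sequence[LandmarkConfiguration], source: str = "dataset"
) -> None:
    if not configs:
        raise DatasetError(f"{source}: no configurations")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise DatasetError(
            f"{source}: inconsistent landmark counts across specimens: {sorted(ks)}"
        )


# ---------------------------------------------------------------------------
# Symmetry maps, features, metadata
# ---------------------------------------------------------------------------


def read_symmetry_map(path: str | Path) -> SymmetryMap:
    """Read a symmetry map from JSON (``{"pairs": [[l, r], ...], "midline":
    [...], "axis": "x", "index_base": 0}``)."""
    with Path(path).open() as fh:
        return SymmetryMap.from_dict(json.load(fh))


def write_symmetry_map(path: str | Path, smap: SymmetryMap) -> None:
    with Path(path).open("w") as fh:
        json.dump(smap.to_dict(), fh, indent=1)


def read_features(path: str | Path) -> list[FeatureDefinition]:
    """Read feature definitions from JSON: ``{"features": {name: [indices]},
    "index_base": 0}``."""
    with Path(path).open() as fh:
        d = json.load(fh)
    base = int(d.get("index_base", 0))
    return [
        FeatureDefinition(name, tuple(int(i) - base for i in idx))
        for name, idx in d["features"].items()
    ]


def write_features(path: str | Path, features: Sequence[FeatureDefinition]) -> None:
    payload = {
        "features": {f.name: list(f.indices) for f in features},
        "index_base": 0,
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=1)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata CSV (columns id, database, sex, ethnicity).

    Returns a DataFrame with columns ``specimen_id, database, sex, ethnicity``
    and one row per specimen.
    """
    df = pd.read_csv(path, dtype=str)
    rename = {df.columns[0]: "specimen_id"}
    df = df.rename(columns=rename)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata file missing columns: {missing}")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise DatasetError(f"duplicate metadata row for specimen {dup!r}")
    return df[list(METADATA_COLUMNS)]


def join_metadata(
    configs: Sequence[LandmarkConfiguration], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Strictly join configurations to metadata rows.

    Unmatched specimen ids on either side are an error rather than a silent
    drop; the returned frame is in configuration order.
    """
    ids = [c.specimen_id for c in configs]
    meta_ids = set(metadata["specimen_id"])
    missing = [i for i in ids if i not in meta_ids]
    if missing:
        raise DatasetError(f"specimens without metadata: {missing[:5]}...")
    extra = sorted(meta_ids - set(ids))
    if extra:
        raise DatasetError(f"metadata rows without landmark data: {extra[:5]}...")
    return (
        metadata.set_index("specimen_id").loc[ids].reset_index()
    )


# ---------------------------------------------------------------------------
# Landmark subsets
# ---------------------------------------------------------------------------


def subset_landmarks(
    dataset: Sequence[LandmarkConfiguration],
    smap: SymmetryMap,
    feature: FeatureDefinition,
) -> tuple[list[LandmarkConfiguration], SymmetryMap]:
    """Restrict a dataset to a feature's landmarks and re-derive its symmetry
    map.

    Landmarks appear in the order given by the feature definition. A bilateral
    pair is kept only when both members are present; a feature containing
    exactly one member of a pair is rejected (features must be
    symmetry-closed). Midline members are kept individually.
    """
    _check_shared_k(dataset)
    k = dataset[0].k
    idx = feature.indices
    if any(i >= k for i in idx):
        raise LandmarkError(
            f"feature {feature.name!r}: index out of range for k={k}"
        )
    smap.validate_for(k)
    present = set(idx)
    pos = {orig: new for new, orig in enumerate(idx)}
    new_pairs = []
    for l, r in smap.pairs:
        if l in present and r in present:
            new_pairs.append((pos[l], pos[r]))
        elif l in present or r in present:
            raise SymmetryBrokenError(
                f"feature {feature.name!r} is symmetry-broken: contains only "
                f"one member of pair ({l}, {r})"
            )
    new_midline = [pos[i] for i in smap.midline if i in present]
    sub_map = SymmetryMap(pairs=tuple(new_pairs), midline=tuple(new_midline))
    sel = np.array(idx, dtype=int)
    sub = [
        LandmarkConfiguration(c.specimen_id, c.coords[sel]) for c in dataset
    ]
    return sub, sub_map


# ---------------------------------------------------------------------------
# Packaged default layout
# ---------------------------------------------------------------------------


def default_face_layout() -> tuple[SymmetryMap, list[FeatureDefinition]]:
    """Packaged 83-landmark bilateral face layout (39 pairs + 5 midline) with
    eyes/nose/mouth/contour feature blocks.

    This is this package's own synthetic layout for demonstrations and
    simulations — commercial detector layouts differ and any (k, map,
    features) triple supplied by the user is equally accepted.
    """
    data = resources.files("facesym") / "data"
    smap = SymmetryMap.from_dict(
        json.loads((data / "face83_symmetry.json").read_text())
    )
    with (data / "face83_features.json").open() as fh:
        d = json.load(fh)
    feats = [
        FeatureDefinition(name, tuple(idx)) for name, idx in d["features"].items()
    ]
    return smap, feats
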