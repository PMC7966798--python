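"""Landmark and metadata input/output.

Reads and writes TPS landmark files (the community-standard ``LM=`` /
``IMAGE=`` / ``ID=`` / ``SCALE=`` dialect), delimited metadata tables, and
YAML/JSON landmark-template configurations, and assembles them into a
validated joined dataset ready for superimposition.

Coordinate convention is mathematical (x right, y **up**).  TPS files written
by image tools that use a y-down raster convention can be flipped on read
with ``flip_y=True``; silent reflections would otherwise flip the sign of
every sex-difference vector downstream.

Landmark indices are 0-based internally.  Template configuration files use
1-based indices, matching the convention of morphometrics software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LandmarkConfiguration",
    "LandmarkTemplate",
    "IndividualMetadata",
    "TpsParseError",
    "ValidationError",
    "read_tps",
    "write_tps",
    "read_metadata",
    "write_metadata",
    "read_template",
    "write_template",
    "join_report",
    "assemble_dataset",
]

VALID_SEXES = ("female", "male")


class TpsParseError(ValueError):
    """Raised when a TPS file violates the LM= record structure."""


class ValidationError(ValueError):
    """Raised when landmark data and metadata fail joint validation."""


@dataclass
class LandmarkConfiguration:
    """One individual's raw 2D landmark configuration.

    Parameters
    ----------
    id : str
        Individual identifier; must be unique within a dataset.
    points : (k, 2) ndarray
        Ordered landmark coordinates in image units, k >= 3.
    scale : float, optional
        Units-per-pixel factor; when present, coordinates returned by
        :func:`read_tps` have already been multiplied by it.
    image_ref : str, optional
        Name of the source image, if recorded in the file.
    """

    id: str
    points: np.ndarray
    scale: float | None = None
    image_ref: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"configuration {self.id!r}: points must be k x 2, "
                f"got shape {self.points.shape}"
            )
        if self.points.shape[0] < 3:
            raise ValidationError(
                f"configuration {self.id!r}: needs k >= 3 landmarks, "
                f"got {self.points.shape[0]}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(
                f"configuration {self.id!r}: non-finite coordinates"
            )
        if self.scale is not None and self.scale <= 0:
            raise ValidationError(
                f"configuration {self.id!r}: scale must be positive"
            )

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]


@dataclass
class LandmarkTemplate:
    """Structural description of a landmark scheme.

    Fields use 0-based indices.  ``curves`` are ordered index sequences; every
    semilandmark must appear in the interior of some curve so that it has two
    flanking neighbours to define a sliding tangent.  ``bilateral_pairs`` and
    ``midline_indices`` together must partition all landmark indices, with no
    index used twice.
    """

    n_landmarks: int
    semilandmark_indices: tuple[int, ...] = ()
    curves: tuple[tuple[int, ...], ...] = ()
    bilateral_pairs: tuple[tuple[int, int], ...] = ()
    midline_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.semilandmark_indices = tuple(int(i) for i in self.semilandmark_indices)
        self.curves = tuple(tuple(int(i) for i in c) for c in self.curves)
        self.bilateral_pairs = tuple(
            (int(a), int(b)) for a, b in self.bilateral_pairs
        )
        self.midline_indices = tuple(int(i) for i in self.midline_indices)
        self._validate()

    def _validate(self) -> None:
        k = self.n_landmarks
        all_idx = (
            list(self.semilandmark_indices)
            + [i for c in self.curves for i in c]
            + [i for p in self.bilateral_pairs for i in p]
            + list(self.midline_indices)
        )
        if any(i < 0 or i >= k for i in all_idx):
            raise ValidationError("template: landmark index out of range")
        interiors: set[int] = set()
        for curve in self.curves:
            if len(curve) < 3:
                raise ValidationError(
                    "template: curves need >= 3 points (semilandmarks require "
                    "two flanking neighbours)"
                )
            interiors.update(curve[1:-1])
        missing = set(self.semilandmark_indices) - interiors
        if missing:
            raise ValidationError(
                f"template: semilandmarks {sorted(missing)} are not interior "
                "points of any curve"
            )
        if self.bilateral_pairs or self.midline_indices:
            paired = [i for p in self.bilateral_pairs for i in p]
            combined = paired + list(self.midline_indices)
            if len(set(combined)) != len(combined):
                raise ValidationError(
                    "template: an index appears twice in bilateral_pairs/"
                    "midline_indices"
                )
            if set(combined) != set(range(k)):
                raise ValidationError(
                    "template: bilateral_pairs and midline_indices must "
                    "partition all landmark indices"
                )

    def neighbours_of(self, semilandmark: int) -> tuple[int, int]:
        """Return the two flanking curve neighbours of a semilandmark."""
        for curve in self.curves:
            if semilandmark in curve[1:-1]:
                pos = curve.index(semilandmark)
                return curve[pos - 1], curve[pos + 1]
        raise ValidationError(
            f"semilandmark {semilandmark} has no two curve neighbours"
        )


@dataclass
class IndividualMetadata:
    """Per-individual covariates joined to a landmark configuration."""

    id: str
    sex: str
    population: str
    height: float | None = None
    weight: float | None = None
    focal_length: float | None = None
    attractiveness: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValidationError(
                f"id {self.id!r}: unknown sex token {self.sex!r} "
                f"(expected one of {VALID_SEXES})"
            )
        if not self.population:
            raise ValidationError(f"id {self.id!r}: population is required")
        for name in ("height", "weight", "focal_length"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"id {self.id!r}: {name} must be positive")


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------

def read_tps(path: str | Path, flip_y: bool = False) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Each record starts with ``LM=k`` followed by k coordinate lines and
    optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  ``SCALE`` multiplies
    the coordinates.  ``flip_y`` negates y on read for files produced with a
    y-down image convention.

    An empty file yields an empty list.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"{path.name} line {i + 1}: expected 'LM=' record header, "
                f"got {line!r}"
            )
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(
                f"{path.name} line {i + 1}: malformed LM count {line!r}"
            ) from exc
        i += 1
        pts = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise TpsParseError(
                    f"{path.name} record {record_no}: LM={k} but only "
                    f"{j} coordinate lines found"
                )
            tokens = lines[i].split()
            if len(tokens) != 2:
                raise TpsParseError(
                    f"{path.name} line {i + 1}: expected 2 coordinates, "
                    f"got {len(tokens)}"
                )
            try:
                pts[j] = [float(tokens[0]), float(tokens[1])]
            except ValueError as exc:
                raise TpsParseError(
                    f"{path.name} line {i + 1}: non-numeric coordinate"
                ) from exc
            i += 1
        image_ref = None
        rec_id = None
        scale = None
        while i < len(lines) and "=" in lines[i] and not lines[
            i
        ].strip().upper().startswith("LM="):
            key, _, value = lines[i].strip().partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "IMAGE":
                image_ref = value
            elif key == "ID":
                rec_id = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(
                        f"{path.name} line {i + 1}: non-numeric SCALE"
                    ) from exc
            i += 1
        if rec_id is None:
            rec_id = str(record_no - 1)
        if scale is not None:
            pts = pts * scale
        if flip_y:
            pts = pts * np.array([1.0, -1.0])
        configs.append(
            LandmarkConfiguration(id=rec_id, points=pts, scale=scale,
                                  image_ref=image_ref)
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path,
              decimals: int = 6) -> None:
    """Write configurations as a TPS file (round-trips with :func:`read_tps`).

    Coordinates are written post-scale, so SCALE lines are not re-emitted.
    """
    out: list[str] = []
    for cfg in configs:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.points:
            out.append(f"{x:.{decimals}f} {y:.{decimals}f}")
        if cfg.image_ref is not None:
            out.append(f"IMAGE={cfg.image_ref}")
        out.append(f"ID={cfg.id}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

_OPTIONAL_NUMERIC = ("height", "weight", "focal_length", "attractiveness")


def read_metadata(path: str | Path, delimiter: str = ",") -> list[IndividualMetadata]:
    """Read a delimited metadata table into typed records.

    The header must name ``id``, ``sex`` and ``population``; ``height``,
    ``weight``, ``focal_length`` and ``attractiveness`` are optional columns.
    Blank cells become missing values.  Duplicate ids and unknown sex tokens
    raise :class:`ValidationError` listing the offending ids.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"id": str})
    required = {"id", "sex", "population"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"metadata missing columns: {sorted(missing_cols)}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate metadata ids: {sorted(set(dupes))}")
    bad_sex = df.loc[~df["sex"].isin(VALID_SEXES), "id"].tolist()
    if bad_sex:
        raise ValidationError(
            f"unknown sex token for ids: {sorted(bad_sex)} "
            f"(expected one of {VALID_SEXES})"
        )
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for name in _OPTIONAL_NUMERIC:
            if name in df.columns:
                v = getattr(row, name)
                kwargs[name] = None if pd.isna(v) else float(v)
        records.append(
            IndividualMetadata(
                id=str(row.id), sex=str(row.sex),
                population=str(row.population), **kwargs,
            )
        )
    return records


def write_metadata(records: Sequence[IndividualMetadata], path: str | Path,
                   delimiter: str = ",") -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "population": r.population,
                "height": r.height,
                "weight": r.weight,
                "focal_length": r.focal_length,
                "attractiveness": r.attractiveness,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Template configuration files
# ---------------------------------------------------------------------------

def read_template(path: str | Path) -> LandmarkTemplate:
    """Read a YAML or JSON template configuration (1-based indices on disk)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return LandmarkTemplate(
        n_landmarks=int(data["n_landmarks"]),
        semilandmark_indices=tuple(i - 1 for i in data.get("semilandmarks", [])),
        curves=tuple(tuple(i - 1 for i in c) for c in data.get("curves", [])),
        bilateral_pairs=tuple(
            (a - 1, b - 1) for a, b in data.get("bilateral_pairs", [])
        ),
        midline_indices=tuple(i - 1 for i in data.get("midline", [])),
    )


def write_template(template: LandmarkTemplate, path: str | Path) -> None:
    """Write a template as YAML (1-based indices on disk)."""
    data = {
        "n_landmarks": template.n_landmarks,
        "semilandmarks": [i + 1 for i in template.semilandmark_indices],
        "curves": [[i + 1 for i in c] for c in template.curves],
        "bilateral_pairs": [[a + 1, b + 1] for a, b in template.bilateral_pairs],
        "midline": [i + 1 for i in template.midline_indices],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def join_report(config_ids: Sequence[str], metadata_ids: Sequence[str]) -> dict:
    """Set comparison of landmark vs metadata ids."""
    c, m = set(config_ids), set(metadata_ids)
    return {
        "matched": sorted(c & m),
        "configs_without_metadata": sorted(c - m),
        "metadata_without_configs": sorted(m - c),
    }


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration],
    metadata: Sequence[IndividualMetadata],
    template: LandmarkTemplate,
) -> "RawDataset":
    """Join configurations with metadata under a template, sorted by id.

    Every configuration id must have a metadata record and every
    configuration must have ``template.n_landmarks`` points; violations raise
    :class:`ValidationError` naming the offending ids.  Output order is
    deterministic (sorted by id) regardless of input order.
    """
    meta_by_id = {m.id: m for m in metadata}
    missing = sorted(c.id for c in configs if c.id not in meta_by_id)
    if missing:
        raise ValidationError(f"configurations without metadata: {missing}")
    bad_k = sorted(
        c.id for c in configs if c.n_landmarks != template.n_landmarks
    )
    if bad_k:
        raise ValidationError(
            f"landmark count != {template.n_landmarks} for ids: {bad_k}"
        )
    seen: set[str] = set()
    for c in configs:
        if c.id in seen:
            raise ValidationError(f"duplicate configuration id: {c.id!r}")
        seen.add(c.id)
    order = sorted(range(len(configs)), key=lambda i: configs[i].id)
    cfgs = [configs[i] for i in order]
    metas = [meta_by_id[c.id] for c in cfgs]
    return RawDataset(configs=cfgs, metadata=metas, template=template)


@dataclass
class RawDataset:
    """Joined, validated landmark dataset prior to superimposition."""

    configs: list[LandmarkConfiguration]
    metadata: list[IndividualMetadata]
    template: LandmarkTemplate
    counts: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(
            {
                "population": [m.population for m in self.metadata],
                "sex": [m.sex for m in self.metadata],
            }
        )
        self.counts = (
            df.groupby(["population", "sex"]).size().rename("n").reset_index()
        )

    def __len__(self) -> int:
        return len(self.configs)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.configs]

    def points_array(self) -> np.ndarray:
        """Stack configurations as an (n, k, 2) array."""
        return np.stack([c.points for c in self.configs])

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed like the point array rows."""
        return pd.DataFrame(
            {
                "id": [m.id for m in self.metadata],
                "sex": [m.sex for m in self.metadata],
                "population": [m.population for m in self.metadata],
                "height": [m.height for m in self.metadata],
                "weight": [m.weight for m in self.metadata],
                "focal_length": [m.focal_length for m in self.metadata],
                "attractiveness": [m.attractiveness for m in self.metadata],
            }
        )
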