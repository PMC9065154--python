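"""Landmark dataset types and file I/O.

Reads and writes 2-D landmark configurations for ungual outlines in the two
formats morphometric practitioners exchange (TPS records and CSV tables),
plus the semi-landmark slider table and the lever-measurement table that the
biomechanics module consumes.

Conventions
-----------
* Landmark indices are 1-based in every file and error message (community
  convention); internally arrays are 0-based and never exposed as indices.
* Coordinates are lateral view, proximal end left, dorsal up, y increasing
  dorsally.  Readers do not reorient; image-origin data can be flipped with
  ``flip_y=True``.
* Coordinates are arbitrary units unless a TPS ``SCALE=`` line (applied at
  read time) or metadata supplies physical units.  Shape analysis removes
  scale, so mixed units are acceptable there; lever measurements carry their
  own units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Digit",
    "CladeGroup",
    "LandmarkConfiguration",
    "LandmarkDataset",
    "SliderTable",
    "LeverMeasurements",
    "LandmarkParseError",
    "LandmarkValidationError",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_sliders",
    "write_sliders",
    "read_levers",
    "write_levers",
]


class LandmarkParseError(ValueError):
    """A landmark/slider/lever file could not be parsed."""


class LandmarkValidationError(ValueError):
    """Parsed data violates a dataset invariant."""


class Digit(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    unknown = "unknown"


class CladeGroup(str, Enum):
    non_therizinosaurid = "non_therizinosaurid"
    therizinosaurid = "therizinosaurid"
    unknown = "unknown"


def _coerce_enum(value, enum_cls):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return enum_cls.unknown
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value))
    except ValueError:
        return enum_cls.unknown


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark set.

    ``coords`` is a (K, 2) float array; the fixed/sliding split lives in the
    dataset-level :class:`SliderTable`, not per specimen.
    """

    specimen_id: str
    coords: np.ndarray
    taxon: str = ""
    digit: Digit = Digit.unknown
    clade_group: CladeGroup = CladeGroup.unknown
    scale: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: coords must be (K, 2), "
                f"got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "digit", _coerce_enum(self.digit, Digit))
        object.__setattr__(
            self, "clade_group", _coerce_enum(self.clade_group, CladeGroup)
        )
        if self.centroid_size() <= 0:
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: degenerate configuration "
                "(centroid size is zero)"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def centroid_size(self) -> float:
        """Root summed squared distance of landmarks to their centroid."""
        return float(np.linalg.norm(self.coords - self.centroid()))

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


class LandmarkDataset:
    """Ordered collection of configurations with a common landmark count."""

    def __init__(self, configurations: Iterable[LandmarkConfiguration]):
        configs = list(configurations)
        if not configs:
            raise LandmarkValidationError("empty landmark dataset")
        k = configs[0].n_landmarks
        offenders = [c.specimen_id for c in configs if c.n_landmarks != k]
        if offenders:
            raise LandmarkValidationError(
                f"inconsistent landmark counts (expected {k}): "
                + ", ".join(offenders)
            )
        seen: set[str] = set()
        for c in configs:
            if c.specimen_id in seen:
                raise LandmarkValidationError(
                    f"duplicate specimen id {c.specimen_id!r}"
                )
            seen.add(c.specimen_id)
        self._configs = configs

    def __len__(self) -> int:
        return len(self._configs)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self._configs)

    def __getitem__(self, key) -> LandmarkConfiguration:
        if isinstance(key, str):
            for c in self._configs:
                if c.specimen_id == key:
                    return c
            raise KeyError(key)
        return self._configs[key]

    @property
    def n_landmarks(self) -> int:
        return self._configs[0].n_landmarks

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self._configs]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates as an (n, K, 2) array (specimen order preserved)."""
        return np.stack([c.coords for c in self._configs])


@dataclass(frozen=True)
class SliderTable:
    """Semi-landmark sliding definition: (before, slider, after) triples.

    Indices are 0-based internally; use :func:`read_sliders` /
    :func:`write_sliders` for the 1-based file convention.
    """

    rows: tuple[tuple[int, int, int], ...] = ()

    def validate(self, k: int) -> None:
        sliders_seen: set[int] = set()
        for before, slider, after in self.rows:
            for idx in (before, slider, after):
                if not 0 <= idx < k:
                    raise LandmarkValidationError(
                        f"slider row ({before + 1},{slider + 1},{after + 1}): "
                        f"index {idx + 1} outside 1..{k}"
                    )
            if slider in (before, after):
                raise LandmarkValidationError(
                    f"slider {slider + 1} equals its own neighbor"
                )
            if slider in sliders_seen:
                raise LandmarkValidationError(
                    f"repeated slider index {slider + 1}"
                )
            sliders_seen.add(slider)

    @property
    def slider_indices(self) -> np.ndarray:
        return np.array([r[1] for r in self.rows], dtype=int)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class LeverMeasurements:
    """Lever-model inputs for one ungual.

    a
        output lever length, fulcrum to claw tip (length units).
    d
        fulcrum to flexor-tubercle length.
    theta
        angle of the input-force vector to the output lever line, degrees.
    delta
        angle between the fulcrum→tubercle line and the output lever line,
        degrees.
    h, b
        perpendicular tubercle apex height and tubercle base-segment length.
    """

    specimen_id: str
    a: float
    d: float
    theta: float
    delta: float
    h: float
    b: float
    digit: Digit = Digit.unknown
    clade_group: CladeGroup = CladeGroup.unknown

    def __post_init__(self) -> None:
        object.__setattr__(self, "digit", _coerce_enum(self.digit, Digit))
        object.__setattr__(
            self, "clade_group", _coerce_enum(self.clade_group, CladeGroup)
        )
        if self.a <= 0 or self.d <= 0:
            raise LandmarkValidationError(
                f"{self.specimen_id}: lever lengths a and d must be positive"
            )
        if self.b <= 0:
            raise LandmarkValidationError(
                f"{self.specimen_id}: tubercle base length b must be positive"
            )
        if self.h < 0:
            raise LandmarkValidationError(
                f"{self.specimen_id}: tubercle height h must be non-negative"
            )
        if not 0 < self.theta + self.delta < 180:
            raise LandmarkValidationError(
                f"{self.specimen_id}: theta + delta must lie in (0, 180) degrees"
            )


# ---------------------------------------------------------------------------
# TPS format


def read_tps(path: str | Path, flip_y: bool = False) -> LandmarkDataset:
    """Read a TPS landmark file (``LM=``, coordinate lines, ``ID=``, ``SCALE=``).

    ``SCALE=`` values multiply the record's coordinates at read time.
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
            raise LandmarkParseError(
                f"{path}: line {i + 1}: expected 'LM=' record header, got {line!r}"
            )
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise LandmarkParseError(
                f"{path}: record {record_no}: bad LM= value {line!r}"
            ) from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break
            parts = row.split()
            if len(parts) != 2:
                raise LandmarkParseError(
                    f"{path}: line {i + 1}: expected two coordinates, got {row!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise LandmarkParseError(
                    f"{path}: line {i + 1}: non-numeric coordinate {row!r}"
                ) from exc
            i += 1
        if len(coords) != k:
            raise LandmarkParseError(
                f"{path}: record {record_no}: LM={k} but only "
                f"{len(coords)} coordinate lines"
            )
        specimen_id = ""
        scale: float | None = None
        meta: dict[str, str] = {}
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" not in row:
                raise LandmarkParseError(
                    f"{path}: record {record_no}: LM={k} but extra "
                    f"coordinate line {row!r} (line {i + 1})"
                )
            key, value = row.split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise LandmarkParseError(
                        f"{path}: line {i + 1}: bad SCALE= value"
                    ) from exc
            else:
                meta[key] = value.strip()
            i += 1
        if not specimen_id:
            raise LandmarkParseError(
                f"{path}: record {record_no}: missing ID= line"
            )
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        if flip_y:
            arr = arr * np.array([1.0, -1.0])
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                coords=arr,
                taxon=meta.get("TAXON", ""),
                digit=meta.get("DIGIT", Digit.unknown),
                clade_group=meta.get("GROUP", CladeGroup.unknown),
                scale=scale,
            )
        )
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset | Iterable[LandmarkConfiguration],
              path: str | Path) -> None:
    """Write configurations as TPS records (coordinates already scaled)."""
    path = Path(path)
    out: list[str] = []
    for config in dataset:
        out.append(f"LM={config.n_landmarks}")
        for x, y in config.coords:
            out.append(f"{x:.12g} {y:.12g}")
        if config.taxon:
            out.append(f"TAXON={config.taxon}")
        if config.digit is not Digit.unknown:
            out.append(f"DIGIT={config.digit.value}")
        if config.clade_group is not CladeGroup.unknown:
            out.append(f"GROUP={config.clade_group.value}")
        out.append(f"ID={config.specimen_id}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV dialects


def read_landmark_csv(path: str | Path, schema: str = "long",
                      flip_y: bool = False) -> LandmarkDataset:
    """Read landmarks from CSV in the ``long`` or ``wide`` dialect.

    long
        columns ``specimen, landmark, x, y`` (landmark 1-based), one row per
        landmark, plus optional ``taxon``, ``digit``, ``clade_group``.
    wide
        columns ``specimen, x1, y1, x2, y2, ...`` plus the same optional
        metadata columns.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if schema not in ("long", "wide"):
        raise ValueError(f"unknown landmark CSV schema {schema!r}")
    configs: list[LandmarkConfiguration] = []
    if schema == "long":
        required = {"specimen", "landmark", "x", "y"}
        if not required <= set(df.columns):
            raise LandmarkParseError(
                f"{path}: long schema needs columns {sorted(required)}"
            )
        counts = df.groupby("specimen", sort=False).size()
        if counts.nunique() > 1:
            expected = counts.iloc[0]  # first specimen defines K
            offenders = counts[counts != expected].index.tolist()
            raise LandmarkValidationError(
                f"{path}: ragged landmark counts for specimens: "
                + ", ".join(map(str, offenders))
            )
        for spec_id, sub in df.groupby("specimen", sort=False):
            sub = sub.sort_values("landmark")
            coords = sub[["x", "y"]].to_numpy(dtype=float)
            configs.append(_config_from_row(spec_id, coords, sub.iloc[0], flip_y))
    else:
        coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
        k = len(coord_cols) // 2
        expected = [f"{axis}{i}" for i in range(1, k + 1) for axis in ("x", "y")]
        missing = [c for c in expected if c not in df.columns]
        if missing or not coord_cols:
            raise LandmarkParseError(
                f"{path}: wide schema needs x1,y1,...,x{k},y{k}; missing {missing}"
            )
        for _, row in df.iterrows():
            coords = np.array(
                [[row[f"x{i}"], row[f"y{i}"]] for i in range(1, k + 1)],
                dtype=float,
            )
            configs.append(_config_from_row(row["specimen"], coords, row, flip_y))
    return LandmarkDataset(configs)


def _config_from_row(spec_id, coords, row, flip_y) -> LandmarkConfiguration:
    if flip_y:
        coords = coords * np.array([1.0, -1.0])
    get = row.get if hasattr(row, "get") else lambda k, d=None: d
    return LandmarkConfiguration(
        specimen_id=str(spec_id),
        coords=coords,
        taxon=str(get("taxon", "") or ""),
        digit=get("digit", Digit.unknown),
        clade_group=get("clade_group", CladeGroup.unknown),
    )


def write_landmark_csv(dataset: LandmarkDataset, path: str | Path,
                       schema: str = "long") -> None:
    path = Path(path)
    rows = []
    if schema == "long":
        for c in dataset:
            for j, (x, y) in enumerate(c.coords, start=1):
                rows.append(
                    {
                        "specimen": c.specimen_id,
                        "landmark": j,
                        "x": x,
                        "y": y,
                        "taxon": c.taxon,
                        "digit": c.digit.value,
                        "clade_group": c.clade_group.value,
                    }
                )
    elif schema == "wide":
        for c in dataset:
            row: dict = {"specimen": c.specimen_id}
            for j, (x, y) in enumerate(c.coords, start=1):
                row[f"x{j}"] = x
                row[f"y{j}"] = y
            row.update(
                taxon=c.taxon, digit=c.digit.value,
                clade_group=c.clade_group.value,
            )
            rows.append(row)
    else:
        raise ValueError(f"unknown landmark CSV schema {schema!r}")
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Slider and lever tables


def read_sliders(path: str | Path, k: int) -> SliderTable:
    """Read a before/slide/after slider table CSV (1-based indices)."""
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if len(df) == 0:
        return SliderTable(())
    required = {"before", "slide", "after"}
    if not required <= set(df.columns):
        raise LandmarkParseError(
            f"{path}: slider table needs columns {sorted(required)}"
        )
    rows = []
    for _, r in df.iterrows():
        try:
            rows.append((int(r["before"]) - 1, int(r["slide"]) - 1,
                         int(r["after"]) - 1))
        except (TypeError, ValueError) as exc:
            raise LandmarkParseError(
                f"{path}: non-integer slider index in row {r.tolist()}"
            ) from exc
    table = SliderTable(tuple(rows))
    table.validate(k)
    return table


def write_sliders(table: SliderTable, path: str | Path) -> None:
    rows = [
        {"before": b + 1, "slide": s + 1, "after": a + 1}
        for b, s, a in table.rows
    ]
    pd.DataFrame(rows, columns=["before", "slide", "after"]).to_csv(
        path, index=False
    )


_LEVER_COLUMNS = ["specimen_id", "digit", "clade_group",
                  "a", "d", "theta", "delta", "h", "b"]


def read_levers(path: str | Path) -> list[LeverMeasurements]:
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"specimen_id", "a", "d", "theta", "delta", "h", "b"}
    if not required <= set(df.columns):
        raise LandmarkParseError(
            f"{path}: lever table needs columns {sorted(required)}"
        )
    out = []
    for _, r in df.iterrows():
        out.append(
            LeverMeasurements(
                specimen_id=str(r["specimen_id"]),
                a=float(r["a"]), d=float(r["d"]),
                theta=float(r["theta"]), delta=float(r["delta"]),
                h=float(r["h"]), b=float(r["b"]),
                digit=r.get("digit", Digit.unknown),
                clade_group=r.get("clade_group", CladeGroup.unknown),
            )
        )
    return out


def write_levers(levers: Sequence[LeverMeasurements], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": m.specimen_id,
            "digit": m.digit.value,
            "clade_group": m.clade_group.value,
            "a": m.a, "d": m.d, "theta": m.theta, "delta": m.delta,
            "h": m.h, "b": m.b,
        }
        for m in levers
    ]
    pd.DataFrame(rows, columns=_LEVER_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )
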