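"""Reading, writing and validating 2-D landmark datasets.

Landmark configurations travel either in the classic TPS landmark format
(``LM=`` record count, coordinate lines, ``ID=``, optional ``SCALE=``) or as a
flat CSV with one specimen per row (``x1,y1,…,xk,yk,scale`` plus factor
columns).  A dataset couples the configurations with a factor table holding
the categorical design (sex, population, host, rearing condition).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_LEVELS = ("M", "F")
HOST_LEVELS = ("A", "C")
REARING_LEVELS = ("FLD", "LAB-A", "LAB-C")
VIEWS = ("lingual", "occlusial")

FACTOR_COLUMNS = ("sex", "population", "host", "rearing")


class TPSParseError(ValueError):
    """A TPS record could not be parsed."""


class DatasetValidationError(ValueError):
    """A dataset violated a structural invariant."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen: ``k`` landmarks in 2-D plus a scale factor.

    Coordinates are Cartesian with y increasing upward; ``scale`` converts
    image units to physical units (µm) and must be positive.
    """

    specimen_id: str
    coords: np.ndarray  # (k, 2) float
    scale: float = 1.0
    view: str = "lingual"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise DatasetValidationError(
                f"{self.specimen_id}: coords must be (k, 2), got {coords.shape}"
            )
        object.__setattr__(self, "coords", coords)
        if not np.isfinite(coords).all():
            raise DatasetValidationError(f"{self.specimen_id}: non-finite coordinates")
        if not (self.scale > 0):
            raise DatasetValidationError(f"{self.specimen_id}: scale must be > 0")
        if self.view not in VIEWS:
            raise DatasetValidationError(f"{self.specimen_id}: unknown view {self.view!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def scaled_coords(self) -> np.ndarray:
        """Coordinates in physical units (image coords × scale)."""
        return self.coords * self.scale


@dataclass
class LandmarkDataset:
    """Landmark configurations plus the per-specimen factor table."""

    configurations: list[LandmarkConfiguration]
    factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate specimen ids: {dupes}")
        if self.factors is not None:
            self.factors = self.factors.copy()
            if "specimen_id" in self.factors.columns:
                self.factors = self.factors.set_index("specimen_id")
            self.factors.index = self.factors.index.astype(str)

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def k(self) -> int:
        if not self.configurations:
            raise DatasetValidationError("empty dataset has no landmark count")
        return self.configurations[0].k

    def coord_array(self, scaled: bool = True) -> np.ndarray:
        """Stack configurations into an ``(n, k, 2)`` array (physical units)."""
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise DatasetValidationError(f"mixed landmark counts {sorted(ks)}")
        if scaled:
            return np.stack([c.scaled_coords() for c in self.configurations])
        return np.stack([c.coords for c in self.configurations])

    def factor(self, name: str) -> np.ndarray:
        if self.factors is None:
            raise DatasetValidationError("dataset has no factor table")
        return self.factors.loc[self.specimen_ids, name].to_numpy()

    def subset(self, keep: Iterable[str]) -> "LandmarkDataset":
        keep = set(keep)
        configs = [c for c in self.configurations if c.specimen_id in keep]
        factors = None
        if self.factors is not None:
            present = [c.specimen_id for c in configs if c.specimen_id in self.factors.index]
            factors = self.factors.loc[present]
        return LandmarkDataset(configs, factors)


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

def read_tps(path: str | Path, view: str = "lingual", flip_y: bool = False) -> LandmarkDataset:
    """Parse a TPS landmark file into a dataset (no factor table).

    Records must carry ``LM=k`` followed by ``k`` coordinate lines and an
    ``ID=`` line; ``SCALE=`` is optional (defaults to 1.0 with a warning) and
    ``IMAGE=`` lines are ignored.  ``flip_y`` negates y for files digitised
    with an image-style y-down origin.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text().splitlines()
    i, nrec = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path}: expected LM= at line {i + 1}, got {line!r}")
        nrec += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}: bad LM count in record {nrec}") from exc
        i += 1
        pts = []
        while i < len(lines) and len(pts) < k:
            row = lines[i].strip()
            if not row or "=" in row:
                break
            parts = row.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}: record {nrec}: bad coordinate line {row!r}"
                )
            pts.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(pts) != k:
            raise TPSParseError(
                f"{path}: record {nrec} declares LM={k} but has {len(pts)} coordinate lines"
            )
        spec_id, scale = None, None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            key, _, val = row.partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            elif key == "IMAGE":
                logger.warning("%s: record %d: IMAGE= line ignored", path, nrec)
            else:
                raise TPSParseError(f"{path}: record {nrec}: unknown key {row!r}")
            i += 1
        if spec_id is None:
            raise TPSParseError(f"{path}: record {nrec} has no ID= line")
        if scale is None:
            logger.warning("%s: record %d (%s): missing SCALE=, using 1.0", path, nrec, spec_id)
            scale = 1.0
        coords = np.array(pts, dtype=float)
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        configs.append(LandmarkConfiguration(spec_id, coords, scale=scale, view=view))
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset in TPS format, ≥9 significant digits per coordinate."""
    path = Path(path)
    chunks = []
    for c in dataset.configurations:
        rows = [f"LM={c.k}"]
        rows += [f"{x:.10g} {y:.10g}" for x, y in c.coords]
        rows.append(f"ID={c.specimen_id}")
        rows.append(f"SCALE={c.scale:.10g}")
        chunks.append("\n".join(rows))
    path.write_text("\n".join(chunks) + ("\n" if chunks else ""))


# ---------------------------------------------------------------------------
# CSV format
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, view: str = "lingual") -> LandmarkDataset:
    """Read the flat CSV layout: specimen_id, x1,y1,…,xk,yk, scale, factors."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
    k = len(coord_cols) // 2
    configs = []
    for _, row in df.iterrows():
        coords = np.array(
            [[row[f"x{j}"], row[f"y{j}"]] for j in range(1, k + 1)], dtype=float
        )
        scale = float(row["scale"]) if "scale" in df.columns else 1.0
        configs.append(
            LandmarkConfiguration(str(row["specimen_id"]), coords, scale=scale, view=view)
        )
    factor_cols = [c for c in FACTOR_COLUMNS if c in df.columns]
    factors = None
    if factor_cols:
        factors = df[["specimen_id"] + factor_cols].astype(str)
    return LandmarkDataset(configs, factors)


def write_csv(dataset: LandmarkDataset, path: str | Path) -> None:
    rows = []
    for c in dataset.configurations:
        row: dict[str, object] = {"specimen_id": c.specimen_id}
        for j, (x, y) in enumerate(c.coords, start=1):
            row[f"x{j}"] = x
            row[f"y{j}"] = y
        row["scale"] = c.scale
        if dataset.factors is not None and c.specimen_id in dataset.factors.index:
            for col in dataset.factors.columns:
                row[col] = dataset.factors.loc[c.specimen_id, col]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_factors(path: str | Path) -> pd.DataFrame:
    """Read a factor CSV (specimen_id + sex/population/host/rearing)."""
    df = pd.read_csv(path, dtype=str)
    if "specimen_id" not in df.columns:
        raise DatasetValidationError(f"{path}: no specimen_id column")
    return df


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-specimen failure lists; empty everywhere means a clean dataset."""

    k_mismatch: list[str] = field(default_factory=list)
    nonfinite: list[str] = field(default_factory=list)
    missing_factors: list[str] = field(default_factory=list)
    bad_levels: list[str] = field(default_factory=list)
    n_checked: int = 0

    @property
    def failing_ids(self) -> set[str]:
        return set(self.k_mismatch) | set(self.nonfinite) | set(self.missing_factors) | set(self.bad_levels)

    @property
    def clean(self) -> bool:
        return not self.failing_ids

    def to_dict(self) -> dict:
        return {
            "n_checked": self.n_checked,
            "k_mismatch": self.k_mismatch,
            "nonfinite": self.nonfinite,
            "missing_factors": self.missing_factors,
            "bad_levels": self.bad_levels,
            "clean": self.clean,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def validate_dataset(
    dataset: LandmarkDataset, strict: bool = False
) -> tuple[ValidationReport, LandmarkDataset]:
    """Check structural invariants; in strict mode drop failing specimens.

    Never mutates its input; the strict exclusion set is a pure function of
    the dataset.
    """
    report = ValidationReport(n_checked=len(dataset))
    if not dataset.configurations:
        return report, dataset
    from collections import Counter

    kc = Counter(c.k for c in dataset.configurations)
    k_mode = kc.most_common(1)[0][0]
    vocab = {"sex": SEX_LEVELS, "host": HOST_LEVELS, "rearing": REARING_LEVELS}
    for c in dataset.configurations:
        if c.k != k_mode:
            report.k_mismatch.append(c.specimen_id)
        if not np.isfinite(c.coords).all():  # unreachable via constructor, kept for raw arrays
            report.nonfinite.append(c.specimen_id)
        if dataset.factors is not None:
            if c.specimen_id not in dataset.factors.index:
                report.missing_factors.append(c.specimen_id)
            else:
                row = dataset.factors.loc[c.specimen_id]
                for col, levels in vocab.items():
                    if col in row.index and row[col] not in levels:
                        report.bad_levels.append(c.specimen_id)
                        break
    out = dataset
    if strict and not report.clean:
        keep = [i for i in dataset.specimen_ids if i not in report.failing_ids]
        out = dataset.subset(keep)
        logger.info(
            "strict validation dropped %d of %d specimens", len(dataset) - len(out), len(dataset)
        )
    return report, out
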