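"""Shared containers for per-adhesion measurements.

The common currency of the pipeline is the :class:`DensityTable`: one row per
focal adhesion, one column per labeled component (raw densities), plus
geometry / category metadata columns and, after preprocessing, ``z_<name>``
columns holding Box-Cox-transformed z-scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The ten components monitored per adhesion: eight adhesome proteins and two
#: regulatory phosphorylation sites.
DEFAULT_COMPONENTS: tuple[str, ...] = (
    "actin",
    "alpha-actinin",
    "FAK",
    "Hic-5",
    "paxillin",
    "VASP",
    "vinculin",
    "zyxin",
    "FAK-pY397",
    "paxillin-pY118",
)

#: Phosphosite channels are excluded from the mean-normalized internal
#: density score (they report modification state, not protein amount).
PHOSPHO_COMPONENTS: tuple[str, ...] = ("FAK-pY397", "paxillin-pY118")

AGE_CATEGORIES: tuple[str, ...] = (">12'", "12'", "9'", "6'", "3'")
DYNAMICS_CLASSES: tuple[str, ...] = ("AS", "ST", "DS", "NA")
AREA_CATEGORIES: tuple[str, ...] = ("S", "M", "L")
TERNARY_CATEGORIES: tuple[str, ...] = ("low", "mid", "high")

#: Metadata columns a DensityTable may carry besides the component densities.
METADATA_COLUMNS: tuple[str, ...] = (
    "adhesion_id",
    "pixel_count",
    "area",
    "eccentricity",
    "age",
    "dynamics",
    "area_cat",
    "ecc_cat",
    "density_cat",
    "density_score",
)


@dataclass
class AdhesionRecord:
    """A single focal adhesion: identity, geometry, labels and densities."""

    adhesion_id: int
    pixel_count: int
    area: float
    eccentricity: float
    densities: dict[str, float]
    age: str = ">12'"
    dynamics: str = "NA"

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "adhesion_id": self.adhesion_id,
            "pixel_count": self.pixel_count,
            "area": self.area,
            "eccentricity": self.eccentricity,
            "age": self.age,
            "dynamics": self.dynamics,
        }
        row.update(self.densities)
        return row


@dataclass
class DensityTable:
    """Adhesions x components matrix with per-dataset metadata.

    Parameters
    ----------
    data
        One row per adhesion.  Component columns hold raw (nonnegative)
        densities; ``z_<component>`` columns, when present, hold the
        Box-Cox-transformed z-scores produced by :mod:`facomp.preprocess`.
    components
        Names of the component columns, in a fixed order.
    dataset_id
        Label such as ``"R1O1"`` (repeat 1, labeling order 1).
    """

    data: pd.DataFrame
    components: tuple[str, ...] = DEFAULT_COMPONENTS
    dataset_id: str = "R1O1"
    repeat: str = "R1"
    labeling_order: str = "O1"
    transform: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        missing = [c for c in self.components if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing component columns: {missing}")
        if len(set(self.components)) != len(self.components):
            raise ValueError("component names must be unique")

    # -- convenience accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def raw(self) -> pd.DataFrame:
        """Raw densities (adhesions x components)."""
        return self.data[list(self.components)]

    @property
    def zscores(self) -> pd.DataFrame:
        """Transformed z-score matrix; raises if preprocessing has not run."""
        cols = [f"z_{c}" for c in self.components]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"z-score columns absent (run preprocessing first): {missing}")
        out = self.data[cols].copy()
        out.columns = list(self.components)
        return out

    @property
    def has_zscores(self) -> bool:
        return all(f"z_{c}" in self.data.columns for c in self.components)

    def select(self, mask) -> "DensityTable":
        """A new table restricted to the rows where ``mask`` is true."""
        return DensityTable(
            data=self.data.loc[mask].reset_index(drop=True),
            components=self.components,
            dataset_id=self.dataset_id,
            repeat=self.repeat,
            labeling_order=self.labeling_order,
            transform=dict(self.transform),
        )

    def category_slice(self, column: str, value: str) -> "DensityTable":
        return self.select(self.data[column] == value)

    # -- persistence ----------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON sidecar with dataset metadata."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {
            "dataset_id": self.dataset_id,
            "repeat": self.repeat,
            "labeling_order": self.labeling_order,
            "components": list(self.components),
            "transform": self.transform,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityTable":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
        else:  # bare CSV: assume default components
            meta = {"components": [c for c in DEFAULT_COMPONENTS if c in data.columns]}
        return cls(
            data=data,
            components=tuple(meta.get("components", DEFAULT_COMPONENTS)),
            dataset_id=meta.get("dataset_id", "R1O1"),
            repeat=meta.get("repeat", "R1"),
            labeling_order=meta.get("labeling_order", "O1"),
            transform=meta.get("transform", {}),
        )


def from_records(
    records: Iterable[AdhesionRecord],
    components: Sequence[str] = DEFAULT_COMPONENTS,
    **meta,
) -> DensityTable:
    """Assemble a DensityTable from AdhesionRecords."""
    rows = [r.as_row() for r in records]
    columns = ["adhesion_id", "pixel_count", "area", "eccentricity", "age", "dynamics"]
    columns += list(components)
    data = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return DensityTable(data=data, components=tuple(components), **meta)


def group_by_dataset(tables: Sequence[DensityTable]) -> Mapping[str, DensityTable]:
    out: dict[str, DensityTable] = {}
    for t in tables:
        if t.dataset_id in out:
            raise ValueError(f"duplicate dataset id {t.dataset_id!r}")
        out[t.dataset_id] = t
    return out
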