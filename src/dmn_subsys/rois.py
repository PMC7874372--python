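"""Regions of interest for the default mode network and its three subsystems.

The DMN is represented by 11 nodes grouped a priori into three subsystems:
the medial temporal lobe (MTL) subsystem (5 nodes), the dorsal medial
prefrontal cortex (dMPFC) subsystem (4 nodes), and the PCC-aMPFC core
(2 nodes).  Each node is a sphere of fixed radius around an MNI-space
coordinate (mm).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MTL = "MTL"
DMPFC = "dMPFC"
CORE = "Core"

SUBSYSTEMS = (MTL, DMPFC, CORE)

#: label, x, y, z (MNI mm), subsystem
_DEFAULT_ROIS = [
    ("vMPFC", 0, 26, -18, MTL),
    ("pIPL", -44, -74, 32, MTL),
    ("Rsp", -14, -52, 8, MTL),
    ("PHC", -28, -40, -12, MTL),
    ("HF", -22, -20, -26, MTL),
    ("dMPFC", 0, 52, 26, DMPFC),
    ("TPJ", -54, -54, 28, DMPFC),
    ("LTC", -60, -24, -18, DMPFC),
    ("TempP", -50, 14, -40, DMPFC),
    ("aMPFC", -6, 52, -2, CORE),
    ("PCC", -8, -56, 26, CORE),
]

DEFAULT_RADIUS_MM = 8.0


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of spherical ROIs with subsystem membership.

    Parameters
    ----------
    table :
        DataFrame with columns ``label``, ``x``, ``y``, ``z``,
        ``subsystem`` and optionally ``radius`` (mm; default 8).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"label", "x", "y", "z", "subsystem"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        if "radius" not in tab.columns:
            tab["radius"] = DEFAULT_RADIUS_MM
        if tab["label"].duplicated().any():
            dupes = tab.loc[tab["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate ROI labels: {dupes}")
        coords = tab[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite ROI coordinates")
        tab = tab.reset_index(drop=True)
        object.__setattr__(self, "table", tab)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        """ROI centres, shape (n, 3), MNI mm."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def radii(self) -> np.ndarray:
        return self.table["radius"].to_numpy(float)

    @property
    def subsystem(self) -> pd.Series:
        return self.table.set_index("label")["subsystem"]

    def partition(self) -> "ModulePartition":
        """Node → subsystem assignment as a fixed module partition."""
        modules = list(dict.fromkeys(self.table["subsystem"]))
        return ModulePartition(
            assignment=dict(zip(self.table["label"], self.table["subsystem"])),
            modules=modules,
        )

    @classmethod
    def default(cls) -> "RoiSet":
        """The 11-node DMN set: 5 MTL + 4 dMPFC + 2 core nodes."""
        tab = pd.DataFrame(
            _DEFAULT_ROIS, columns=["label", "x", "y", "z", "subsystem"]
        )
        return cls(tab)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiSet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ModulePartition:
    """A fixed assignment of node labels to module labels."""

    assignment: dict[str, str]
    modules: list[str]

    def __post_init__(self) -> None:
        extra = set(self.assignment.values()) - set(self.modules)
        if extra:
            raise ValueError(f"assignment uses unlisted modules: {sorted(extra)}")

    def indices(self, labels: list[str]) -> np.ndarray:
        """Module index per node, in the order of `labels`.

        Raises if any node is missing from the partition.
        """
        missing = [l for l in labels if l not in self.assignment]
        if missing:
            raise ValueError(f"nodes missing from partition: {missing}")
        mod_idx = {m: i for i, m in enumerate(self.modules)}
        return np.array([mod_idx[self.assignment[l]] for l in labels], dtype=int)


def default_partition() -> ModulePartition:
    return RoiSet.default().partition()
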