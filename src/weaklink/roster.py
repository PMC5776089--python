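"""Node roster: motor-network regions of interest in MNI space.

The packaged roster holds the 23 regions that are active in all three
experimental conditions (ankle movement alone, movement plus agonist-muscle
stimulation, movement plus control-area stimulation), with their activation
peak coordinates and a 3 mm sphere radius.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["RoiDefinition", "load_roster", "default_roster", "roster_names"]


@dataclass(frozen=True)
class RoiDefinition:
    """A spherical region of interest: name, MNI center (mm) and radius (mm)."""

    name: str
    x: float
    y: float
    z: float
    radius: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI {self.name!r}: radius must be > 0, got {self.radius}")

    @property
    def center(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def _parse_rows(rows) -> list[RoiDefinition]:
    rois = [
        RoiDefinition(
            name=row["name"],
            x=float(row["x"]),
            y=float(row["y"]),
            z=float(row["z"]),
            radius=float(row.get("radius", 3.0) or 3.0),
        )
        for row in rows
    ]
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate ROI names in roster: {dupes}")
    return rois


def load_roster(path: str | Path) -> list[RoiDefinition]:
    """Read a roster CSV with columns name,x,y,z[,radius]."""
    with open(path, newline="") as fh:
        return _parse_rows(csv.DictReader(fh))


def default_roster() -> list[RoiDefinition]:
    """The packaged 23-region motor-network roster (3 mm spheres)."""
    ref = resources.files("weaklink.data").joinpath("motor_roster.csv")
    with ref.open(newline="") as fh:
        return _parse_rows(csv.DictReader(fh))


def roster_names(rois: list[RoiDefinition]) -> list[str]:
    return [r.name for r in rois]
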