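"""Stereotaxic coordinate utilities.

Talairach<->MNI conversion uses the piecewise (z >= 0 / z < 0) Brett affine;
the forward MNI->Talairach map is applied axis-wise and inverted exactly for
the reverse direction, choosing the branch consistently by the sign of the
superior coordinate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Coordinate",
    "tal_from_mni",
    "mni_from_tal",
    "average_coords",
    "nearest_peak",
    "read_coords_csv",
    "write_coords_csv",
]


@dataclass(frozen=True)
class Coordinate:
    x: float
    y: float
    z: float
    space: str  # "mni" | "tal"

    def __post_init__(self) -> None:
        if self.space not in ("mni", "tal"):
            raise ValueError(f"space must be 'mni' or 'tal', got {self.space!r}")
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (round(self.x, ndigits), round(self.y, ndigits), round(self.z, ndigits))


# Brett MNI->Talairach affines (x row, then y/z block), per z-branch.
_SUP = np.array([
    [0.9900, 0.0000, 0.0000],
    [0.0000, 0.9688, 0.0460],
    [0.0000, -0.0485, 0.9189],
])
_INF = np.array([
    [0.9900, 0.0000, 0.0000],
    [0.0000, 0.9688, 0.0420],
    [0.0000, -0.0485, 0.8390],
])


def tal_from_mni(c: Coordinate) -> Coordinate:
    """Brett MNI->Talairach transform (branch by MNI z sign)."""
    if c.space != "mni":
        raise ValueError("input must be in MNI space")
    m = _SUP if c.z >= 0 else _INF
    out = m @ c.xyz
    return Coordinate(*out, space="tal")


def mni_from_tal(c: Coordinate) -> Coordinate:
    """Inverse Brett transform (branch chosen by the resulting MNI z sign)."""
    if c.space != "tal":
        raise ValueError("input must be in Talairach space")
    sup = np.linalg.solve(_SUP, c.xyz)
    if sup[2] >= 0:
        return Coordinate(*sup, space="mni")
    inf = np.linalg.solve(_INF, c.xyz)
    return Coordinate(*inf, space="mni")


def average_coords(coords, skip_missing: bool = True) -> Coordinate:
    """Arithmetic per-axis mean of same-space coordinates.

    Entries may be ``Coordinate`` or per-axis sequences containing ``None``
    for missing axes; missing axes are skipped axis-wise.
    """
    coords = list(coords)
    if not coords:
        raise ValueError("cannot average an empty list of coordinates")
    spaces = {c.space for c in coords if isinstance(c, Coordinate)}
    if len(spaces) > 1:
        raise ValueError(f"mixed coordinate spaces: {sorted(spaces)}")
    space = spaces.pop() if spaces else "mni"
    sums = np.zeros(3)
    counts = np.zeros(3)
    for c in coords:
        vals = c.xyz if isinstance(c, Coordinate) else np.array(
            [np.nan if v is None else float(v) for v in c]
        )
        ok = np.isfinite(vals)
        if not skip_missing and not ok.all():
            raise ValueError("missing axis value")
        sums[ok] += vals[ok]
        counts[ok] += 1
    if (counts == 0).any():
        raise ValueError("an axis has no observed values")
    return Coordinate(*(sums / counts), space=space)


def nearest_peak(candidates, reference: Coordinate) -> Coordinate:
    """Candidate minimizing Euclidean distance to ``reference`` (ties: first)."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate coordinates")
    for c in candidates:
        if c.space != reference.space:
            raise ValueError("candidates and reference must share a space")
    dists = [float(np.linalg.norm(c.xyz - reference.xyz)) for c in candidates]
    return candidates[int(np.argmin(dists))]


def read_coords_csv(path) -> dict:
    """CSV with columns (label, space, x, y, z) -> {label: Coordinate}."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["label"]] = Coordinate(
                float(row["x"]), float(row["y"]), float(row["z"]), space=row["space"]
            )
    return out


def write_coords_csv(coords: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "space", "x", "y", "z"])
        for label, c in coords.items():
            w.writerow([label, c.space, c.x, c.y, c.z])
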