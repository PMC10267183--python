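"""Named landmark configurations, the packaged roster, and file I/O.

The template roster has 88 anatomical landmarks; the paired Euryon points
are flagged ``gpa_excluded`` because their positions shift with overall
skull shape, so superimposition uses the remaining 86.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "load_roster",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_tps",
    "write_tps",
    "fit_midsagittal_plane",
]


@dataclass
class LandmarkSet:
    """Ordered, named 3D points (mm) for one specimen.

    ``roles`` are "LM" or "SLM"; ``sides`` are "L", "R" or "midline";
    ``gpa_excluded`` marks points left out of superimposition.
    """

    names: list[str]
    coords: np.ndarray
    roles: list[str] = field(default_factory=list)
    sides: list[str] = field(default_factory=list)
    gpa_excluded: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be k x 3, got {self.coords.shape}")
        k = len(self.names)
        if self.coords.shape[0] != k:
            raise ValueError("names and coords length mismatch")
        if len(set(self.names)) != k:
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite landmark coordinates")
        if not self.roles:
            self.roles = ["LM"] * k
        if not self.sides:
            self.sides = ["midline"] * k
        if self.gpa_excluded is None:
            self.gpa_excluded = np.zeros(k, dtype=bool)
        else:
            self.gpa_excluded = np.asarray(self.gpa_excluded, dtype=bool)
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.coords[self._index[name]]
        except KeyError:
            raise KeyError(f"landmark {name!r} not in configuration") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def subset(self, mask: np.ndarray) -> "LandmarkSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LandmarkSet(
            names=[self.names[i] for i in idx],
            coords=self.coords[idx],
            roles=[self.roles[i] for i in idx],
            sides=[self.sides[i] for i in idx],
            gpa_excluded=self.gpa_excluded[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(names=list(self.names), coords=coords,
                           roles=list(self.roles), sides=list(self.sides),
                           gpa_excluded=self.gpa_excluded.copy())

    @property
    def midline_mask(self) -> np.ndarray:
        return np.array([s == "midline" for s in self.sides])


def load_roster() -> pd.DataFrame:
    """The packaged 88-landmark roster table.

    Columns: number, name, side, role, gpa_excluded, and the analytic
    placement direction (ux, uy, uz) used by the synthetic generator.
    """
    with resources.files("craniogrow.data").joinpath(
            "landmark_roster.csv").open() as fh:
        df = pd.read_csv(fh)
    df["gpa_excluded"] = df["gpa_excluded"].astype(bool)
    return df


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    """Read a per-specimen landmark file (columns name,x,y,z[,side,role])."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return LandmarkSet(
        names=df["name"].tolist(),
        coords=df[["x", "y", "z"]].to_numpy(float),
        roles=df["role"].tolist() if "role" in df else [],
        sides=df["side"].tolist() if "side" in df else [],
        gpa_excluded=df["gpa_excluded"].to_numpy(bool)
        if "gpa_excluded" in df else None,
    )


def write_landmarks_csv(lms: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "name": lms.names,
        "x": lms.coords[:, 0],
        "y": lms.coords[:, 1],
        "z": lms.coords[:, 2],
        "side": lms.sides,
        "role": lms.roles,
        "gpa_excluded": lms.gpa_excluded.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_tps(path: str | Path) -> list[np.ndarray]:
    """Read a TPS-format landmark file (LM3=k blocks of x y z rows).

    Returns one (k, 3) array per specimen block; ID/IMAGE/SCALE lines are
    tolerated and ignored.
    """
    configs: list[np.ndarray] = []
    current: list[list[float]] = []
    expected = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith(("LM3=", "LM=")):
                if current:
                    configs.append(np.array(current))
                expected = int(line.split("=", 1)[1])
                current = []
            elif upper.startswith(("ID=", "IMAGE=", "SCALE=")):
                continue
            else:
                current.append([float(v) for v in line.split()])
    if current:
        configs.append(np.array(current))
    for c in configs:
        if c.shape[1] != 3:
            raise ValueError(f"{path}: expected 3D rows, got shape {c.shape}")
    if expected and configs and len(configs[-1]) != expected:
        raise ValueError(f"{path}: last block has {len(configs[-1])} points, "
                         f"header says {expected}")
    return configs


def write_tps(configs: list[np.ndarray], path: str | Path,
              ids: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(configs):
            c = np.asarray(c, dtype=float)
            fh.write(f"LM3={len(c)}\n")
            for row in c:
                fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")
            fh.write(f"ID={ids[i] if ids else i}\n")


def fit_midsagittal_plane(lms: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the midline-tagged landmarks.

    Returns (point_on_plane, unit_normal); the normal is the direction of
    least variance of the midline points.
    """
    pts = lms.coords[lms.midline_mask]
    if len(pts) < 3:
        raise ValueError("need at least 3 midline landmarks to fit a plane")
    centre = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centre)
    if s[1] / max(s[0], 1e-300) < 1e-9:
        raise ValueError("midline landmarks are collinear; plane undefined")
    return centre, vt[2]
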