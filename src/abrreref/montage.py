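"""Electrode montages on the unit sphere.

Coordinate convention (fixed for every file this package reads or writes):
head-centred Cartesian axes with x = right, y = anterior, z = superior, and
electrode positions normalised to the unit sphere.  The vertex electrode Cz
sits exactly at (0, 0, 1).

The default montage reproduces a 32-channel clinical ABR cap: the 30 scalp
electrodes of the extended 10/20 system that such caps expose, the two
mastoid electrodes M1/M2 used for mastoid re-referencing, and the cap's
physical reference electrode (labelled REF) on the midline between Cz and
CPz.  Scalp positions are the idealised spherical 10/20 placements: midline
and circumferential electrodes at their defining angles, intermediate
electrodes at equal fractions along great-circle arcs between them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Electrode",
    "Montage",
    "standard_montage",
    "dense_montage",
    "load_sfp",
    "save_sfp",
    "MIDLINE_CHANNELS",
]

#: The six midline channels compared throughout the analysis.
MIDLINE_CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz", "Oz")

_ROLES = ("scalp", "mastoid_left", "mastoid_right", "physical_reference", "ground")


@dataclass(frozen=True)
class Electrode:
    """A named electrode at a unit-sphere position with an acquisition role."""

    name: str
    position: np.ndarray
    role: str = "scalp"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        r = np.linalg.norm(pos)
        if abs(r - 1.0) > 1e-9:
            raise ValueError(f"|position| must be 1 (got {r:.12f}) for {self.name!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        object.__setattr__(self, "position", pos)

    def __eq__(self, other) -> bool:  # dataclass eq breaks on ndarray fields
        if not isinstance(other, Electrode):
            return NotImplemented
        return (
            self.name == other.name
            and self.role == other.role
            and np.allclose(self.position, other.position, atol=1e-12)
        )

    def __hash__(self) -> int:
        return hash((self.name, self.role, tuple(np.round(self.position, 12))))


@dataclass(frozen=True)
class Montage:
    """An ordered collection of electrodes with unique names."""

    electrodes: tuple[Electrode, ...]
    midline_subset: tuple[str, ...] = MIDLINE_CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        names = [e.name for e in self.electrodes]
        if len(set(names)) != len(names):
            raise ValueError("electrode names must be unique within a montage")
        missing = set(self.midline_subset) - set(names)
        if missing:
            raise ValueError(f"midline subset not in montage: {sorted(missing)}")

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [e.name for e in self.electrodes]

    def __len__(self) -> int:
        return len(self.electrodes)

    def __getitem__(self, name: str) -> Electrode:
        for e in self.electrodes:
            if e.name == name:
                return e
        raise KeyError(f"no electrode named {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.electrodes)

    def with_roles(self, *roles: str) -> "Montage":
        """Sub-montage keeping only electrodes whose role is in ``roles``."""
        kept = tuple(e for e in self.electrodes if e.role in roles)
        midline = tuple(m for m in self.midline_subset if any(e.name == m for e in kept))
        return Montage(kept, midline)

    @property
    def recording_channels(self) -> "Montage":
        """Scalp + mastoid electrodes — the channel set entering re-referencing."""
        return self.with_roles("scalp", "mastoid_left", "mastoid_right")

    def positions(self, names: list[str] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        return np.array([self[n].position for n in names])

    def hash(self) -> str:
        """Stable identity of labels, roles and rounded positions."""
        h = hashlib.sha256()
        for e in self.electrodes:
            h.update(e.name.encode())
            h.update(e.role.encode())
            h.update(np.round(e.position, 12).tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Standard 10/20 construction
# ---------------------------------------------------------------------------

def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from inclination (angle from vertex) and azimuth.

    Azimuth is measured in the horizontal plane from the anterior (+y)
    direction, positive toward the right (+x).
    """
    inc = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(inc) * np.sin(az), np.sin(inc) * np.cos(az), np.cos(inc)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point a fraction ``t`` along the great circle from ``a`` to ``b``."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    p = (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)
    return p / np.linalg.norm(p)


def standard_montage() -> Montage:
    """The default 30-scalp + M1/M2 + REF montage on the unit sphere.

    Circumferential electrodes (FP1/2, F7/8, FT7/8, T7/8, TP7/8, P7/8,
    O1/2) lie on the equator of the spherical model at their standard 10%
    azimuthal spacings; midline electrodes step down the sagittal arc in
    22.5 degree increments; the remaining lateral electrodes (F3, FC3, C3,
    CP3, P3 and right-side mirrors) are midway along the great-circle arc
    from the corresponding circumferential electrode to the midline one.
    M1/M2 sit below the ears at 115 degrees of inclination on the T7/T8
    meridian; REF sits on the midline between Cz and CPz.
    """
    pos: dict[str, np.ndarray] = {}

    # midline, anterior to posterior
    pos["Fz"] = _sph(45, 0)
    pos["FCz"] = _sph(22.5, 0)
    pos["Cz"] = np.array([0.0, 0.0, 1.0])
    pos["CPz"] = _sph(22.5, 180)
    pos["Pz"] = _sph(45, 180)
    pos["Oz"] = _sph(90, 180)

    # circumference (equator of the spherical model); azimuth from anterior
    circ_left = {"FP1": -18, "F7": -54, "FT7": -72, "T7": -90, "TP7": -108, "P7": -126, "O1": -162}
    for name, az in circ_left.items():
        pos[name] = _sph(90, az)
        pos[name.replace("1", "2").replace("7", "8")] = _sph(90, -az)

    # lateral rows: midway along the arc from the outer electrode to the midline
    for outer, mid, inner in [
        ("F7", "Fz", "F3"),
        ("FT7", "FCz", "FC3"),
        ("T7", "Cz", "C3"),
        ("TP7", "CPz", "CP3"),
        ("P7", "Pz", "P3"),
    ]:
        pos[inner] = _slerp(pos[outer], pos[mid], 0.5)
        right_outer = outer.replace("7", "8")
        right_inner = inner.replace("3", "4")
        pos[right_inner] = _slerp(pos[right_outer], pos[mid], 0.5)

    order = [
        "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
        "FT7", "FC3", "FCz", "FC4", "FT8",
        "T7", "C3", "Cz", "C4", "T8",
        "TP7", "CP3", "CPz", "CP4", "TP8",
        "P7", "P3", "Pz", "P4", "P8",
        "O1", "Oz", "O2",
    ]
    electrodes = [Electrode(name, pos[name], "scalp") for name in order]
    electrodes.append(Electrode("M1", _sph(115, -90), "mastoid_left"))
    electrodes.append(Electrode("M2", _sph(115, 90), "mastoid_right"))
    electrodes.append(Electrode("REF", _sph(11.25, 180), "physical_reference"))
    return Montage(tuple(electrodes))


def dense_montage(n: int = 128, min_z: float = -0.45) -> Montage:
    """A synthetic quasi-uniform cap of ``n`` electrodes for density studies.

    Fibonacci-lattice points restricted to z >= ``min_z`` (roughly the
    coverage of a cap that reaches the mastoids).  Labels are E000..E(n-1).
    """
    # oversample the full sphere, keep the upper portion, trim to n
    m = int(np.ceil(n / ((1 - min_z) / 2) * 1.2))
    i = np.arange(m)
    z = 1 - (2 * i + 1) / m
    phi = np.pi * (1 + np.sqrt(5)) * i
    xyz = np.column_stack([np.cos(phi) * np.sqrt(1 - z**2), np.sin(phi) * np.sqrt(1 - z**2), z])
    xyz = xyz[z >= min_z]
    if len(xyz) < n:
        raise ValueError(f"could not place {n} electrodes above z={min_z}")
    xyz = xyz[:n]
    electrodes = tuple(
        Electrode(f"E{k:03d}", p / np.linalg.norm(p), "scalp") for k, p in enumerate(xyz)
    )
    return Montage(electrodes, midline_subset=())


# ---------------------------------------------------------------------------
# BESA .sfp-style text I/O:  "label  x  y  z" per line
# ---------------------------------------------------------------------------

def load_sfp(path: str | Path, roles: dict[str, str] | None = None) -> Montage:
    """Read electrode positions from whitespace-delimited text.

    Each non-empty, non-comment line is ``label x y z``; positions are
    unit-normalised on load.  ``roles`` optionally maps labels to roles
    (default: M1/M2 get their mastoid roles, REF physical_reference,
    GND ground, everything else scalp).
    """
    roles = roles or {}
    default_roles = {"M1": "mastoid_left", "M2": "mastoid_right",
                     "REF": "physical_reference", "GND": "ground"}
    electrodes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {line!r}")
        name = parts[0]
        vec = np.array([float(v) for v in parts[1:]])
        r = np.linalg.norm(vec)
        if r == 0:
            raise ValueError(f"{path}:{lineno}: zero-length position for {name!r}")
        role = roles.get(name, default_roles.get(name, "scalp"))
        electrodes.append(Electrode(name, vec / r, role))
    midline = tuple(m for m in MIDLINE_CHANNELS if any(e.name == m for e in electrodes))
    return Montage(tuple(electrodes), midline)


def save_sfp(montage: Montage, path: str | Path) -> None:
    lines = [
        f"{e.name} {e.position[0]:.9f} {e.position[1]:.9f} {e.position[2]:.9f}"
        for e in montage.electrodes
    ]
    Path(path).write_text("\n".join(lines) + "\n")
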