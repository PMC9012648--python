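"""Dipole forward modelling in a three-shell spherical head.

The scalp potential of a current dipole inside a layered conducting sphere
has a classical solution by separation of variables: expand the dipole's
free-medium potential in solid harmonics about the head centre, propagate
each harmonic degree n through the shell boundary conditions (continuity of
potential and of radial current at each interface, zero radial current at
the outer surface), and sum the series at the electrode positions.  For a
dipole with moment q at position b (radial unit vector b_hat, beta = |b|/R)
and an electrode at unit direction r_hat on the scalp (radius R):

    V = 1/(4 pi sigma_1 R^2) * sum_n tau_n beta^(n-1)
            [ n q_r P_n(x) + (q . r_hat - x q_r) P_n'(x) ]

with x = cos(angle between b and electrode), q_r = q . b_hat, and tau_n the
per-degree radial transfer factor obtained from the boundary conditions
(tau_n = (2n+1)/n for a homogeneous sphere).  The series carries no n = 0
term, so the potential is the physical infinity-referenced one: no
electrode, average or other reference has been subtracted.

A homogeneous-sphere closed form (image-type solution) is provided as an
independent oracle for the series code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import Montage

__all__ = [
    "HeadModel",
    "SourceLayer",
    "LeadField",
    "fibonacci_source_layer",
    "compute_lead_field",
    "dipole_gains",
    "homogeneous_sphere_potential",
    "cached_lead_field",
]


@dataclass(frozen=True)
class HeadModel:
    """Three concentric spherical shells: brain, skull, scalp.

    ``shell_radii`` are the outer radii of the three shells as fractions of
    the scalp radius (strictly increasing, outermost 1.0);
    ``conductivities`` are the corresponding relative conductivities.  The
    defaults are the standard three-shell values (skull 1/80 of brain and
    scalp) with a 9 cm scalp sphere.
    """

    shell_radii: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0)
    scalp_radius_m: float = 0.09

    def __post_init__(self) -> None:
        r = self.shell_radii
        if len(r) != 3 or not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be three strictly increasing positives")
        if abs(r[2] - 1.0) > 1e-12:
            raise ValueError("outermost shell radius must be 1 (fraction of scalp)")
        if len(self.conductivities) != 3 or any(s <= 0 for s in self.conductivities):
            raise ValueError("need three positive conductivities")
        if self.scalp_radius_m <= 0:
            raise ValueError("scalp radius must be positive")

    @property
    def brain_radius_m(self) -> float:
        return self.shell_radii[0] * self.scalp_radius_m

    def key(self) -> str:
        payload = json.dumps(
            [self.shell_radii, self.conductivities, self.scalp_radius_m]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class SourceLayer:
    """Dipole source locations on a sphere inside the brain compartment.

    Each location carries three orthonormal dipole orientations, so the
    layer spans arbitrary moments; a lead field built from it has one
    column per (location, orientation) pair.
    """

    locations: np.ndarray       # (n, 3) metres
    orientations: np.ndarray    # (n, 3, 3) orthonormal rows

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if loc.ndim != 2 or loc.shape[1] != 3:
            raise ValueError("locations must be (n, 3)")
        if ori.shape != (len(loc), 3, 3):
            raise ValueError("orientations must be (n, 3, 3)")
        radii = np.linalg.norm(loc, axis=1)
        if radii.size and np.ptp(radii) > 1e-9 * max(radii.max(), 1e-30):
            raise ValueError("all source locations must lie on one sphere")
        gram = np.einsum("nij,nkj->nik", ori, ori)
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("orientations must be orthonormal per location")
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_sources(self) -> int:
        return len(self.locations)

    @property
    def radius_m(self) -> float:
        return float(np.linalg.norm(self.locations[0])) if self.n_sources else 0.0

    def key(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.locations, 12).tobytes())
        h.update(np.round(self.orientations, 12).tobytes())
        return h.hexdigest()[:16]


def fibonacci_source_layer(n: int = 500, radius_m: float | None = None,
                           head: HeadModel | None = None) -> SourceLayer:
    """Quasi-uniform dipole layer on a sphere at 0.86 x brain radius.

    A Fibonacci lattice gives near-uniform areal coverage; 500 triplet
    sources comfortably over-span a 32-channel montage.
    """
    head = head or HeadModel()
    if radius_m is None:
        radius_m = 0.86 * head.brain_radius_m
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    phi = np.pi * (1 + np.sqrt(5)) * i
    s = np.sqrt(1 - z**2)
    unit = np.column_stack([np.cos(phi) * s, np.sin(phi) * s, z])
    # per-location orthonormal triads: radial + two tangentials
    ori = np.empty((n, 3, 3))
    ori[:, 0] = unit
    helper = np.where(np.abs(unit[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    t1 = np.cross(helper, unit)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    ori[:, 1] = t1
    ori[:, 2] = np.cross(unit, t1)
    return SourceLayer(unit * radius_m, ori)


# ---------------------------------------------------------------------------
# Radial transfer factors
# ---------------------------------------------------------------------------

def _radial_transfer(head: HeadModel, n_terms: int) -> np.ndarray:
    """tau_n for n = 1..n_terms, in scalp-radius units.

    For each degree n the shell coefficients solve a 5x5 linear system:
    unknowns are the regular coefficient in the brain and both coefficients
    in skull and scalp, with a unit irregular (source) coefficient in the
    brain; equations are potential and radial-current continuity at the two
    interfaces plus the insulating outer boundary.
    """
    r1, r2, _ = head.shell_radii
    s1, s2, s3 = head.conductivities
    tau = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        # unknowns: [A1, A2, B2, A3, B3]
        a = np.zeros((5, 5))
        rhs = np.zeros(5)
        # continuity of V at r1:  A1 r1^n - A2 r1^n - B2 r1^-(n+1) = -r1^-(n+1)
        a[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -(r1 ** -(n + 1))
        # continuity of sigma dV/dr at r1
        a[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # continuity of V at r2
        a[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # continuity of sigma dV/dr at r2
        a[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulated outer surface at rho = 1
        a[4] = [0, 0, 0, n, -(n + 1)]
        sol = np.linalg.solve(a, rhs)
        tau[n - 1] = sol[3] + sol[4]  # A3 * 1^n + B3 * 1^-(n+1)
    return tau


# ---------------------------------------------------------------------------
# Lead fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadField:
    """Infinity-referenced gain matrix, channels x (3 x n_sources).

    Columns are grouped per source: the three orientations of source 0,
    then of source 1, and so on.  Entries are potentials per unit dipole
    moment; no reference (electrode, average or otherwise) is subtracted.
    """

    matrix: np.ndarray
    channel_names: tuple[str, ...]
    montage_hash: str
    head_key: str = ""
    layer_key: str = ""
    n_terms: int = 0
    source_locations: np.ndarray | None = None    # (n_sources, 3) metres
    source_orientations: np.ndarray | None = None  # (n_sources, 3, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(self.channel_names):
            raise ValueError("matrix rows must match channel names")
        if m.shape[1] % 3:
            raise ValueError("columns must come in orientation triplets")
        if not np.all(np.isfinite(m)):
            raise ValueError("lead field entries must be finite")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.source_locations is not None:
            loc = np.asarray(self.source_locations, dtype=float)
            ori = np.asarray(self.source_orientations, dtype=float)
            if loc.shape != (self.n_sources, 3) or ori.shape != (self.n_sources, 3, 3):
                raise ValueError("source geometry does not match matrix columns")
            object.__setattr__(self, "source_locations", loc)
            object.__setattr__(self, "source_orientations", ori)

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] // 3

    def gains(self, source_index: int) -> np.ndarray:
        """(channels, 3) gain block of one source location."""
        return self.matrix[:, 3 * source_index : 3 * source_index + 3]

    def nearest_source(self, location: np.ndarray) -> int:
        """Index of the layer source closest to ``location`` (metres)."""
        if self.source_locations is None:
            raise ValueError("lead field carries no source geometry")
        return int(np.argmin(np.linalg.norm(self.source_locations - location, axis=1)))

    def subset(self, channel_names: list[str]) -> "LeadField":
        """Row subset in the given channel order (e.g. drop the REF row)."""
        idx = [self.channel_names.index(c) for c in channel_names]
        return LeadField(self.matrix[idx], tuple(channel_names), self.montage_hash,
                         self.head_key, self.layer_key, self.n_terms,
                         self.source_locations, self.source_orientations)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            matrix=self.matrix,
            channel_names=np.array(self.channel_names),
            meta=np.array(
                [self.montage_hash, self.head_key, self.layer_key, str(self.n_terms)]
            ),
            source_locations=(self.source_locations
                              if self.source_locations is not None else np.empty((0, 3))),
            source_orientations=(self.source_orientations
                                 if self.source_orientations is not None else np.empty((0, 3, 3))),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LeadField":
        with np.load(path) as z:
            meta = [str(v) for v in z["meta"]]
            loc = z["source_locations"] if "source_locations" in z else np.empty((0, 3))
            ori = z["source_orientations"] if "source_orientations" in z else np.empty((0, 3, 3))
            return cls(
                z["matrix"],
                tuple(str(c) for c in z["channel_names"]),
                meta[0],
                meta[1],
                meta[2],
                int(meta[3]),
                loc if len(loc) else None,
                ori if len(ori) else None,
            )


def _series_terms(head: HeadModel, elec_unit: np.ndarray, src_pos: np.ndarray,
                  n_terms: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accumulated Legendre sums for every electrode/source pair.

    Returns (Sa, Sb, x, beta): Sa = sum tau_n beta^(n-1) n P_n(x) and
    Sb = sum tau_n beta^(n-1) P_n'(x), both shaped (n_elec, n_src).
    """
    R = head.scalp_radius_m
    src_r = np.linalg.norm(src_pos, axis=1)
    if np.any(src_r >= head.brain_radius_m - 1e-12):
        raise ValueError("sources must lie strictly inside the brain shell")
    beta = src_r / R
    with np.errstate(invalid="ignore"):
        b_hat = np.where(src_r[:, None] > 0, src_pos / np.where(src_r[:, None] > 0, src_r[:, None], 1.0), [0.0, 0.0, 1.0])
    x = np.clip(elec_unit @ b_hat.T, -1.0, 1.0)  # (n_elec, n_src)

    tau = _radial_transfer(head, n_terms)
    # Legendre recurrences in n, vectorised over pairs
    p_prev = np.ones_like(x)            # P_0
    p_cur = x.copy()                    # P_1
    dp_prev = np.zeros_like(x)          # P_0'
    dp_cur = np.ones_like(x)            # P_1'
    sa = np.zeros_like(x)
    sb = np.zeros_like(x)
    bpow = np.ones_like(beta)           # beta^(n-1)
    for n in range(1, n_terms + 1):
        w = tau[n - 1] * bpow           # (n_src,)
        sa += w * n * p_cur
        sb += w * dp_cur
        # advance to degree n+1
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        bpow = bpow * beta
    return sa, sb, x, beta


def dipole_gains(montage: Montage, head: HeadModel, locations: np.ndarray,
                 moments: np.ndarray, n_terms: int = 60) -> np.ndarray:
    """Scalp gains (channels x n_dipoles) for explicit dipoles.

    ``locations`` (n, 3) in metres, ``moments`` (n, 3) dipole moments.
    Used by the simulator to project a source at its exact position instead
    of snapping to a source-layer grid point.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    moments = np.atleast_2d(np.asarray(moments, dtype=float))
    elec = montage.positions()
    sa, sb, x, _ = _series_terms(head, elec, locations, n_terms)
    src_r = np.linalg.norm(locations, axis=1)
    b_hat = np.where(src_r[:, None] > 0, locations / np.where(src_r[:, None] > 0, src_r[:, None], 1.0), [0.0, 0.0, 1.0])
    q_r = np.einsum("sj,sj->s", moments, b_hat)          # (n_src,)
    q_dot_r = elec @ moments.T                           # (n_elec, n_src)
    k = 1.0 / (4 * np.pi * head.conductivities[0] * head.scalp_radius_m**2)
    return k * (q_r * sa + (q_dot_r - x * q_r) * sb)


def compute_lead_field(montage: Montage, head: HeadModel | None = None,
                       layer: SourceLayer | None = None, n_terms: int = 60) -> LeadField:
    """Infinity-referenced lead field of a source layer at montage electrodes.

    One column per (location, orientation) pair, in layer order.  Raises if
    any source touches or leaves the brain compartment or n_terms < 1.
    """
    head = head or HeadModel()
    layer = layer or fibonacci_source_layer(head=head)
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    elec = montage.positions()
    sa, sb, x, _ = _series_terms(head, elec, layer.locations, n_terms)
    src_r = np.linalg.norm(layer.locations, axis=1)
    b_hat = np.where(src_r[:, None] > 0,
                     layer.locations / np.where(src_r[:, None] > 0, src_r[:, None], 1.0),
                     [0.0, 0.0, 1.0])
    k = 1.0 / (4 * np.pi * head.conductivities[0] * head.scalp_radius_m**2)
    n_elec, n_src = x.shape
    out = np.empty((n_elec, 3 * n_src))
    for o in range(3):
        q = layer.orientations[:, o]                     # (n_src, 3)
        q_r = np.einsum("sj,sj->s", q, b_hat)
        q_dot_r = elec @ q.T
        out[:, o::3] = k * (q_r * sa + (q_dot_r - x * q_r) * sb)
    return LeadField(out, tuple(montage.names), montage.hash(),
                     head.key(), layer.key(), n_terms,
                     layer.locations, layer.orientations)


def cached_lead_field(montage: Montage, head: HeadModel | None = None,
                      layer: SourceLayer | None = None, n_terms: int = 60,
                      cache_dir: str | Path | None = None) -> LeadField:
    """Compute-or-load a lead field, keyed by montage/head/layer identity.

    The cache file name embeds the key, so a change in any ingredient
    regenerates automatically instead of reusing a stale matrix.
    """
    head = head or HeadModel()
    layer = layer or fibonacci_source_layer(head=head)
    if cache_dir is None:
        return compute_lead_field(montage, head, layer, n_terms)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = f"{montage.hash()}-{head.key()}-{layer.key()}-{n_terms}"
    path = cache_dir / f"leadfield-{key}.npz"
    if path.exists():
        try:
            return LeadField.load(path)
        except Exception:
            path.unlink()  # corrupt cache: regenerate
    lf = compute_lead_field(montage, head, layer, n_terms)
    lf.save(path)
    return lf


# ---------------------------------------------------------------------------
# Homogeneous-sphere closed form (testing oracle)
# ---------------------------------------------------------------------------

def homogeneous_sphere_potential(electrode: np.ndarray, dipole_pos: np.ndarray,
                                 dipole_moment: np.ndarray, sigma: float = 1.0,
                                 R: float = 1.0) -> float:
    """Surface potential of a dipole in a homogeneous conducting sphere.

    Closed form (image-type solution for an insulated sphere), with
    d = r - b the vector from dipole b to surface point r (|r| = R):

        V = 1/(4 pi sigma) [ 2 q.d / |d|^3
                             + ( q.r + R q.d / |d| ) / (R F) ],
        F = R^2 - r.b + R |d|.

    Independent of the shell-series machinery; used as its oracle.
    """
    r = np.asarray(electrode, dtype=float)
    b = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_moment, dtype=float)
    if abs(np.linalg.norm(r) - R) > 1e-6 * R:
        raise ValueError("electrode must lie on the sphere surface")
    if np.linalg.norm(b) >= R:
        raise ValueError("dipole must lie strictly inside the sphere")
    d = r - b
    dn = np.linalg.norm(d)
    f = R**2 - r @ b + R * dn
    v = 2 * (q @ d) / dn**3 + ((q @ r) + R * (q @ d) / dn) / (R * f)
    return float(v / (4 * np.pi * sigma))
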