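"""Solvent-accessible surface, buried surface area and cavity volume.

SASA is computed with the Shrake–Rupley method: each atom is dressed with a
sphere of radius ``r_vdw + probe`` carrying a quasi-uniform Fibonacci point
set, and the exposed fraction of points gives the per-atom area.  Buried
surface area of a binary complex is the standard
``SASA(m1) + SASA(m2) − SASA(m1 ∪ m2)``.

The central-cavity estimator rasterizes the structure onto a cubic grid,
marks voxels whose centre lies within ``r_vdw + probe`` of any atom as
occupied (so the free region is the volume accessible to probe *centres*),
flood-fills the exterior from the box boundary, and takes the largest
remaining 6-connected free component as the cavity.  Its voxel count times
the voxel volume is the reported cavity volume; extents are reported both
along the cavity's principal axes and as the axis-aligned bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from oligoface.structure_io import AtomRecord

__all__ = [
    "RadiiTable",
    "SasaResult",
    "CavityReport",
    "fibonacci_sphere",
    "sasa",
    "buried_surface_area",
    "cavity_volume",
    "lipid_capacity",
]


@dataclass
class RadiiTable:
    """Element → van der Waals radius (Å) with a fallback for the rest."""

    radii: dict[str, float]
    fallback: float = 1.70
    probe: float = 1.4

    @classmethod
    def default(cls) -> "RadiiTable":
        with resources.as_file(resources.files("oligoface.data") / "vdw_radii.tsv") as p:
            return cls.from_tsv(p)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RadiiTable":
        radii: dict[str, float] = {}
        fallback = 1.70
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t")
            r = float(val)
            if r <= 0:
                raise ValueError(f"non-positive radius for {key!r}")
            if key.upper() == "DEFAULT":
                fallback = r
            else:
                radii[key.upper()] = r
        return cls(radii=radii, fallback=fallback)

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.fallback)

    def radii_for(self, atoms: Sequence[AtomRecord]) -> np.ndarray:
        return np.array([self.radius(a.element) for a in atoms])


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    per_atom: np.ndarray
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.position for a in atoms], dtype=float)


def sasa(
    atoms: Sequence[AtomRecord],
    radii: RadiiTable | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    ``n_points`` test points are placed on each atom's expanded sphere of
    radius ``r_vdw + probe``; a point is buried when it falls inside any
    neighbour's expanded sphere.  Per-atom area is the exposed point
    fraction times the expanded-sphere area.
    """
    if len(atoms) == 0:
        raise ValueError("sasa requires at least one atom")
    if n_points < 60:
        raise ValueError("n_points must be >= 60")
    radii = radii or RadiiTable.default()
    xyz = _coords(atoms)
    r_ext = radii.radii_for(atoms) + probe
    unit = fibonacci_sphere(n_points)

    max_r = float(r_ext.max())
    tree = cKDTree(xyz)
    per_atom = np.empty(len(atoms))
    # neighbours within r_i + max(r_j) can bury points of atom i
    neighbor_lists = tree.query_ball_point(xyz, r=r_ext + max_r)
    for i in range(len(atoms)):
        pts = xyz[i] + r_ext[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            exposed &= d2 >= r_ext[j] ** 2
            if not exposed.any():
                break
        per_atom[i] = exposed.mean() * 4.0 * np.pi * r_ext[i] ** 2
    return SasaResult(per_atom=per_atom, probe=probe, n_points=n_points)


def buried_surface_area(
    m1: Sequence[AtomRecord],
    m2: Sequence[AtomRecord],
    radii: RadiiTable | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """BSA = SASA(m1) + SASA(m2) − SASA(complex), clamped at 0 (Å²)."""
    if len(m1) == 0 or len(m2) == 0:
        raise ValueError("both atom sets must be non-empty")
    radii = radii or RadiiTable.default()
    a1 = sasa(m1, radii, probe, n_points).total
    a2 = sasa(m2, radii, probe, n_points).total
    a12 = sasa(list(m1) + list(m2), radii, probe, n_points).total
    return max(0.0, a1 + a2 - a12)


@dataclass
class CavityReport:
    """Largest interior probe-accessible void of a structure."""

    volume: float  # Å³
    grid_spacing: float
    voxel_count: int
    principal_extents: tuple[float, float, float]
    bounding_box_extents: tuple[float, float, float]
    included_chains: list[str] = field(default_factory=list)
    diagnostic: str = ""

    @property
    def empty(self) -> bool:
        return self.voxel_count == 0


def _empty_cavity(spacing: float, chains: list[str], why: str) -> CavityReport:
    return CavityReport(
        volume=0.0,
        grid_spacing=spacing,
        voxel_count=0,
        principal_extents=(0.0, 0.0, 0.0),
        bounding_box_extents=(0.0, 0.0, 0.0),
        included_chains=chains,
        diagnostic=why,
    )


def cavity_volume(
    atoms: Sequence[AtomRecord],
    radii: RadiiTable | None = None,
    probe: float = 1.4,
    spacing: float = 1.0,
    included_chains: Sequence[str] | None = None,
) -> CavityReport:
    """Grid flood-fill estimate of the largest enclosed cavity volume.

    Voxels within ``r_vdw + probe`` of any atom centre are occupied; free
    voxels 6-connected to the padded box boundary are exterior solvent; the
    largest remaining free component is the cavity.  A structure whose
    interior is open to the exterior yields an empty report with a
    diagnostic rather than an error.
    """
    if len(atoms) == 0:
        raise ValueError("cavity_volume requires at least one atom")
    if not 0.25 <= spacing <= 2.0:
        raise ValueError("spacing must be within [0.25, 2.0] Å")
    radii = radii or RadiiTable.default()
    chains = sorted({a.chain_id for a in atoms}) if included_chains is None else list(included_chains)

    xyz = _coords(atoms)
    r_eff = radii.radii_for(atoms) + probe
    pad = 2.0 * (float(r_eff.max() - probe) + probe)
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    # occupancy by stamping each atom's sphere onto its local sub-grid
    occupied = np.zeros(shape, dtype=bool)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    for pos, r in zip(xyz, r_eff):
        imin = np.maximum(0, np.floor((pos - r - lo) / spacing).astype(int))
        imax = np.minimum(shape - 1, np.ceil((pos + r - lo) / spacing).astype(int))
        sub = [axes[k][imin[k] : imax[k] + 1] - pos[k] for k in range(3)]
        d2 = (
            sub[0][:, None, None] ** 2
            + sub[1][None, :, None] ** 2
            + sub[2][None, None, :] ** 2
        )
        occupied[imin[0] : imax[0] + 1, imin[1] : imax[1] + 1, imin[2] : imax[2] + 1] |= d2 <= r * r

    free = ~occupied
    labels, n_lab = ndimage.label(free)  # default structure = 6-connectivity
    if n_lab == 0:
        return _empty_cavity(spacing, chains, "no free voxels")
    boundary_labels = set()
    for axis in range(3):
        for idx in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = idx
            boundary_labels.update(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)

    counts = np.bincount(labels.ravel())
    interior = [(counts[lab], lab) for lab in range(1, n_lab + 1) if lab not in boundary_labels]
    if not interior:
        return _empty_cavity(spacing, chains, "cavity open to exterior: all free space connects to the boundary")
    count, lab = max(interior)
    voxels = np.argwhere(labels == lab)
    centers = lo + voxels * spacing

    bbox = centers.max(axis=0) - centers.min(axis=0) + spacing
    centered = centers - centers.mean(axis=0)
    if len(centers) > 1:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt.T
        pext = proj.max(axis=0) - proj.min(axis=0) + spacing
    else:
        pext = np.array([spacing, spacing, spacing])
    pext = np.sort(pext)[::-1]

    return CavityReport(
        volume=float(count) * spacing**3,
        grid_spacing=spacing,
        voxel_count=int(count),
        principal_extents=tuple(float(x) for x in pext),
        bounding_box_extents=tuple(float(x) for x in np.sort(bbox)[::-1]),
        included_chains=chains,
    )


def lipid_capacity(volume: float, v_lipid: float = 1250.0) -> int:
    """Lipids per leaflet a cavity can hold: floor((volume/2) / v_lipid).

    ``v_lipid`` is the volume of one membrane lipid in Å³; the default of
    1250 Å³ corresponds to a typical thylakoid galactolipid.
    """
    if volume < 0:
        raise ValueError("volume must be >= 0")
    if v_lipid <= 0:
        raise ValueError("v_lipid must be positive")
    return int((volume / 2.0) // v_lipid)
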