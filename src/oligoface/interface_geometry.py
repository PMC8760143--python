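"""Interface residues between monomers and chlorophyll Mg–Mg networks.

Two geometric questions about an oligomeric assembly are answered here:

1. Which amino acids form a given monomer–monomer interface?  A residue
   belongs to the interface when its Cα lies within a distance cutoff
   (default 12 Å) of the partner monomer, either of the partner's Cα atoms
   (``ca_to_ca``, the default) or of any partner atom (``ca_to_any``).
2. Which chlorophyll pairs are close enough for fast excitation energy
   transfer?  Pairs are ranked by the distance between their central Mg
   atoms and classified as within-monomer or cross-interface; distance
   comparisons are strict (``<``), so a pair exactly at the threshold is
   excluded.

Neighbour queries go through a k-d tree; an exhaustive all-pairs reference
(`brute force`) is kept alongside for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from oligoface.structure_io import Assembly, Cofactor, MonomerPartition, Residue

__all__ = [
    "InterfaceReport",
    "ChlPair",
    "PlaneAngle",
    "interface_residues",
    "interface_residues_brute_force",
    "chlorophyll_pairs",
    "chlorophyll_pairs_brute_force",
    "parallel_chl_pairs",
    "fit_plane_normal",
    "export_network",
    "interface_class",
]


@dataclass
class InterfaceReport:
    """Residues of a monomer–monomer interface under a distance criterion."""

    pair: tuple[str, str]
    cutoff: float
    criterion: str
    residues_side1: list[Residue]
    residues_side2: list[Residue]
    contact_pairs: list[tuple[Residue, Residue, float]]
    interface_class_tag: str | None = None

    @property
    def n_total(self) -> int:
        return len(self.residues_side1) + len(self.residues_side2)


@dataclass
class ChlPair:
    """A chlorophyll pair ranked by Mg–Mg distance."""

    chl1: Cofactor
    chl2: Cofactor
    mg_distance: float
    relation: str  # 'within_monomer' or 'cross_interface'
    interface_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mg_distance <= 0:
            raise ValueError("Mg-Mg distance must be positive")

    @property
    def threshold_class(self) -> str | None:
        """Smallest of the canonical <10/<15/<20 Å bins containing the pair."""
        if self.mg_distance < 10.0:
            return "lt10"
        if self.mg_distance < 15.0:
            return "lt15"
        if self.mg_distance < 20.0:
            return "lt20"
        return None


@dataclass
class PlaneAngle:
    """Acute angle between the porphyrin planes of a chlorophyll pair."""

    pair: ChlPair
    angle_deg: float
    residual1: float
    residual2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 90.0 + 1e-9:
            raise ValueError(f"plane angle {self.angle_deg} outside [0, 90]")


def interface_class(pair: tuple[str, str], trimer_like: Iterable[tuple[str, str]] = ()) -> str | None:
    """Tag an interface as trimer-like or dimer-dimer from a declared list.

    The tight dimer interfaces (the ones resembling the trimer contact) are
    declared by the caller, typically alongside the chain map; everything
    else between distinct monomers is the dimer-of-dimers class.
    """
    norm = tuple(sorted(pair))
    declared = {tuple(sorted(p)) for p in trimer_like}
    if not declared:
        return None
    return "trimer_like" if norm in declared else "dimer_dimer"


def _monomer_ca(assembly: Assembly, partition: MonomerPartition, label: str) -> tuple[list[Residue], np.ndarray]:
    """Polymer residues of a monomer that have a Cα, plus the Cα coordinates."""
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    for res in assembly.iter_residues(partition.chains_of(label)):
        if not res.is_polymer:
            continue
        ca = res.ca
        if ca is not None:
            residues.append(res)
            coords.append(ca.position)
    if not residues:
        raise ValueError(f"monomer {label!r} has no Cα atoms")
    return residues, np.asarray(coords)


def _monomer_atoms(assembly: Assembly, partition: MonomerPartition, label: str) -> np.ndarray:
    coords = [
        a.position
        for res in assembly.iter_residues(partition.chains_of(label))
        if res.is_polymer
        for a in res.atoms
    ]
    return np.asarray(coords)


def interface_residues(
    assembly: Assembly,
    partition: MonomerPartition,
    pair: tuple[str, str],
    cutoff: float = 12.0,
    criterion: str = "ca_to_ca",
) -> InterfaceReport:
    """Extract the amino acids forming the interface between two monomers.

    A residue of one monomer is part of the interface iff its Cα lies
    strictly within ``cutoff`` Å of the partner monomer — of a partner Cα
    under ``ca_to_ca`` (default), of any partner polymer atom under
    ``ca_to_any``.  Cofactor residues never count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if criterion not in ("ca_to_ca", "ca_to_any"):
        raise ValueError(f"unknown criterion {criterion!r}")
    la, lb = pair
    for label in (la, lb):
        if label not in partition.labels:
            raise ValueError(f"monomer label {label!r} not in partition")

    res1, ca1 = _monomer_ca(assembly, partition, la)
    res2, ca2 = _monomer_ca(assembly, partition, lb)
    if criterion == "ca_to_ca":
        tgt1, tgt2 = ca2, ca1
    else:
        tgt1 = _monomer_atoms(assembly, partition, lb)
        tgt2 = _monomer_atoms(assembly, partition, la)

    tree1 = cKDTree(tgt1)
    tree2 = cKDTree(tgt2)
    d1, _ = tree1.query(ca1)
    d2, _ = tree2.query(ca2)
    side1 = [r for r, d in zip(res1, d1) if d < cutoff]
    side2 = [r for r, d in zip(res2, d2) if d < cutoff]

    # contact pairs on the Cα–Cα metric regardless of criterion
    contacts: list[tuple[Residue, Residue, float]] = []
    tree_ca2 = cKDTree(ca2)
    pairs = cKDTree(ca1).query_ball_tree(tree_ca2, r=cutoff)
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(ca1[i] - ca2[j]))
            if d < cutoff:
                contacts.append((res1[i], res2[j], d))

    return InterfaceReport(
        pair=(la, lb),
        cutoff=cutoff,
        criterion=criterion,
        residues_side1=side1,
        residues_side2=side2,
        contact_pairs=contacts,
    )


def interface_residues_brute_force(
    assembly: Assembly,
    partition: MonomerPartition,
    pair: tuple[str, str],
    cutoff: float = 12.0,
    criterion: str = "ca_to_ca",
) -> InterfaceReport:
    """All-pairs O(n²) reference for :func:`interface_residues` (testing)."""
    la, lb = pair
    res1, ca1 = _monomer_ca(assembly, partition, la)
    res2, ca2 = _monomer_ca(assembly, partition, lb)
    if criterion == "ca_to_ca":
        tgt1, tgt2 = ca2, ca1
    elif criterion == "ca_to_any":
        tgt1 = _monomer_atoms(assembly, partition, lb)
        tgt2 = _monomer_atoms(assembly, partition, la)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    def near(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points[:, None, :] - targets[None, :, :], axis=2)
        return d.min(axis=1) < cutoff

    side1 = [r for r, keep in zip(res1, near(ca1, tgt1)) if keep]
    side2 = [r for r, keep in zip(res2, near(ca2, tgt2)) if keep]
    contacts = []
    for i, r1 in enumerate(res1):
        for j, r2 in enumerate(res2):
            d = float(np.linalg.norm(ca1[i] - ca2[j]))
            if d < cutoff:
                contacts.append((r1, r2, d))
    return InterfaceReport(
        pair=(la, lb),
        cutoff=cutoff,
        criterion=criterion,
        residues_side1=side1,
        residues_side2=side2,
        contact_pairs=contacts,
    )


def _chl_with_anchor(cofactors: Sequence[Cofactor]) -> list[Cofactor]:
    return [c for c in cofactors if c.kind == "chlorophyll_a" and c.anchor_atom is not None]


def _classify(c1: Cofactor, c2: Cofactor) -> tuple[str, tuple[str, str] | None]:
    if c1.monomer_label is not None and c1.monomer_label == c2.monomer_label:
        return "within_monomer", None
    if c1.monomer_label is None or c2.monomer_label is None:
        return "within_monomer", None  # unlabelled pairs default to within
    pair = tuple(sorted((c1.monomer_label, c2.monomer_label)))
    return "cross_interface", pair  # type: ignore[return-value]


def chlorophyll_pairs(
    cofactors: Sequence[Cofactor],
    threshold: float,
) -> list[ChlPair]:
    """All unordered chlorophyll pairs with Mg–Mg distance strictly < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    chls = _chl_with_anchor(cofactors)
    if len(chls) < 2:
        return []
    coords = np.array([c.anchor_atom.position for c in chls])
    tree = cKDTree(coords)
    out: list[ChlPair] = []
    for i, j in sorted(tree.query_pairs(r=threshold)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d >= threshold:  # query_pairs is inclusive at r; enforce strict <
            continue
        relation, pair = _classify(chls[i], chls[j])
        out.append(ChlPair(chl1=chls[i], chl2=chls[j], mg_distance=d, relation=relation, interface_pair=pair))
    return out


def chlorophyll_pairs_brute_force(cofactors: Sequence[Cofactor], threshold: float) -> list[ChlPair]:
    """O(n²) reference for :func:`chlorophyll_pairs` (testing)."""
    chls = _chl_with_anchor(cofactors)
    out: list[ChlPair] = []
    for i in range(len(chls)):
        for j in range(i + 1, len(chls)):
            d = float(np.linalg.norm(chls[i].anchor_atom.position - chls[j].anchor_atom.position))
            if d < threshold:
                relation, pair = _classify(chls[i], chls[j])
                out.append(ChlPair(chl1=chls[i], chl2=chls[j], mg_distance=d, relation=relation, interface_pair=pair))
    return out


PYRROLE_NITROGENS = ("NA", "NB", "NC", "ND")


def fit_plane_normal(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares plane through points; returns (unit normal, RMS residual)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    residual = float(np.sqrt(s[-1] ** 2 / len(pts)))
    return normal / np.linalg.norm(normal), residual


def parallel_chl_pairs(
    cofactors: Sequence[Cofactor],
    max_mg_distance: float = 15.0,
    max_angle_deg: float = 20.0,
) -> list[PlaneAngle]:
    """Chlorophyll pairs whose porphyrin planes are nearly parallel.

    Each plane is fit through the four pyrrole nitrogens (NA, NB, NC, ND);
    the reported angle is the acute angle between plane normals.
    Chlorophylls missing a pyrrole nitrogen are skipped with a warning.
    """
    import warnings as _warnings

    chls = _chl_with_anchor(cofactors)
    normals: dict[int, tuple[np.ndarray, float]] = {}
    usable: list[int] = []
    for idx, chl in enumerate(chls):
        pts = []
        for name in PYRROLE_NITROGENS:
            a = chl.residue.atom(name)
            if a is None:
                break
            pts.append(a.position)
        if len(pts) != 4:
            _warnings.warn(f"chlorophyll {chl.id} lacks pyrrole nitrogens; skipped", stacklevel=2)
            continue
        normals[idx] = fit_plane_normal(np.array(pts))
        usable.append(idx)

    out: list[PlaneAngle] = []
    for ii, i in enumerate(usable):
        for j in usable[ii + 1 :]:
            d = float(np.linalg.norm(chls[i].anchor_atom.position - chls[j].anchor_atom.position))
            if d > max_mg_distance:
                continue
            n1, r1 = normals[i]
            n2, r2 = normals[j]
            cosang = abs(float(np.dot(n1, n2)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= max_angle_deg:
                relation, pair = _classify(chls[i], chls[j])
                cp = ChlPair(chl1=chls[i], chl2=chls[j], mg_distance=d, relation=relation, interface_pair=pair)
                out.append(PlaneAngle(pair=cp, angle_deg=angle, residual1=r1, residual2=r2))
    return out


def export_network(pairs: Sequence[ChlPair], path: str | Path) -> None:
    """Write a TSV edge list: chl1, chl2, Mg–Mg distance, relation, interface."""
    lines = ["chl1\tchl2\tmg_distance\trelation\tinterface"]
    for p in pairs:
        iface = "-".join(p.interface_pair) if p.interface_pair else ""
        lines.append(f"{p.chl1.id}\t{p.chl2.id}\t{p.mg_distance:.4f}\t{p.relation}\t{iface}")
    Path(path).write_text("\n".join(lines) + "\n")
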