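"""Fixture generators with exact, manifest-recorded ground truth.

Every analysis stage of the package has a generator here that writes its
input in the real external format (PDB, aligned FASTA, BLAST outfmt-6 TSV)
together with a :class:`FixtureManifest` stating what the downstream
operation must find: how many residues were planted at which distance
across which interface, the exact Mg–Mg separations and plane angles of
planted chlorophyll pairs, the analytic interior volume of a hollow shell,
which BLAST rows satisfy the ortholog thresholds, and where conserved
blocks sit in an alignment.

Geometry plants use exact placement, never sampling: a residue pair
requested at 8 Å is at 8 Å to machine precision, and decoys are kept
beyond thresholds by construction margins of at least 2 Å, so expected
counts are exact integers rather than statistical statements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from oligoface.structure_io import Assembly, AtomRecord, Residue, write_pdb

__all__ = [
    "FixtureManifest",
    "AssemblySpec",
    "InterfacePlant",
    "ChlPlant",
    "GenerationError",
    "make_assembly",
    "hollow_shell_atoms",
    "make_titratable_system",
    "MsaGroupSpec",
    "make_msa",
    "make_blast_table",
]


class GenerationError(ValueError):
    """A fixture specification cannot be realized."""


@dataclass
class FixtureManifest:
    """Ground truth of a generated fixture; the oracle for downstream tests."""

    seed: int
    kind: str
    paths: dict[str, str] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "kind": self.kind, "paths": self.paths, "expected": self.expected},
            indent=2, sort_keys=True,
        ) + "\n")


# ---------------------------------------------------------------------------
# assemblies

#: Cα radius (Å), rise per residue (Å) and twist (deg) of an ideal α-helix.
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0

#: Mg–N distance in the porphyrin plane of a planted chlorophyll (Å).
_MG_N = 2.05


@dataclass
class InterfacePlant:
    """k residue pairs planted at an exact Cα–Cα distance across an interface."""

    pair: tuple[str, str]
    k: int
    distance: float  # Å

    def __post_init__(self) -> None:
        if self.k < 0 or self.distance <= 0:
            raise GenerationError("interface plant needs k >= 0 and distance > 0")


@dataclass
class ChlPlant:
    """One chlorophyll pair at an exact Mg–Mg distance and plane angle."""

    mg_distance: float  # Å
    plane_angle_deg: float = 0.0
    pair: tuple[str, str] | None = None  # cross-interface when set
    monomer: str | None = None  # within this monomer otherwise

    def __post_init__(self) -> None:
        if self.mg_distance <= 0:
            raise GenerationError("Mg–Mg distance must be positive")
        if not 0.0 <= self.plane_angle_deg <= 90.0:
            raise GenerationError("plane angle must be within [0, 90] degrees")
        if (self.pair is None) == (self.monomer is None):
            raise GenerationError("exactly one of pair/monomer must be set")


@dataclass
class AssemblySpec:
    """Counts and geometry of a synthetic oligomeric assembly."""

    monomer_labels: Sequence[str] = ("A", "B")
    residues_per_monomer: int = 30
    monomer_separation: float = 100.0  # Å between neighbouring monomer centres
    interface_plants: Sequence[InterfacePlant] = ()
    chl_plants: Sequence[ChlPlant] = ()
    cavity_inner_radius: float | None = None  # adds a hollow shell chain
    lane_spacing: float = 16.0  # Å between planted interface residue lanes

    def validate(self, cutoff_hint: float = 12.0) -> None:
        labels = list(self.monomer_labels)
        if len(labels) != len(set(labels)):
            raise GenerationError("monomer labels must be distinct")
        for plant in self.interface_plants:
            for lab in plant.pair:
                if lab not in labels:
                    raise GenerationError(f"interface plant names unknown monomer {lab!r}")
            if plant.distance >= self.monomer_separation / 2:
                raise GenerationError("planted distance too large for the monomer separation")
        for chl in self.chl_plants:
            for lab in (chl.pair or (chl.monomer,)):
                if lab not in labels:
                    raise GenerationError(f"chlorophyll plant names unknown monomer {lab!r}")


def _monomer_centers(labels: Sequence[str], separation: float) -> dict[str, np.ndarray]:
    """Monomer centres: a line for 1–2 monomers, a regular polygon otherwise."""
    n = len(labels)
    if n <= 2:
        return {lab: np.array([i * separation, 0.0, 0.0]) for i, lab in enumerate(labels)}
    circum_r = separation / (2.0 * math.sin(math.pi / n))
    centers = {}
    for i, lab in enumerate(labels):
        ang = 2.0 * math.pi * i / n
        centers[lab] = np.array([circum_r * math.cos(ang), circum_r * math.sin(ang), 0.0])
    return centers


def _helix_ca(center: np.ndarray, n_res: int) -> list[np.ndarray]:
    """Ideal α-helix Cα trace along z, centred at ``center``."""
    out = []
    z0 = -0.5 * (n_res - 1) * _HELIX_RISE
    for i in range(n_res):
        ang = math.radians(_HELIX_TWIST * i)
        out.append(center + np.array([
            _HELIX_RADIUS * math.cos(ang),
            _HELIX_RADIUS * math.sin(ang),
            z0 + i * _HELIX_RISE,
        ]))
    return out


def _ca_residue(chain_id: str, number: int, pos: np.ndarray, name: str = "GLY") -> Residue:
    res = Residue(chain_id=chain_id, residue_name=name, residue_number=number, is_polymer=True)
    res.atoms.append(AtomRecord(
        chain_id=chain_id, residue_name=name, residue_number=number,
        atom_name="CA", element="C", position=pos,
    ))
    return res


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _chl_residue(chain_id: str, number: int, mg: np.ndarray, normal: np.ndarray) -> Residue:
    res = Residue(chain_id=chain_id, residue_name="CLA", residue_number=number, is_cofactor=True)
    res.atoms.append(AtomRecord(
        chain_id=chain_id, residue_name="CLA", residue_number=number,
        atom_name="MG", element="MG", position=mg,
    ))
    e1, e2 = _plane_basis(normal)
    for k, nm in enumerate(("NA", "NB", "NC", "ND")):
        ang = math.radians(90.0 * k)
        pos = mg + _MG_N * (math.cos(ang) * e1 + math.sin(ang) * e2)
        res.atoms.append(AtomRecord(
            chain_id=chain_id, residue_name="CLA", residue_number=number,
            atom_name=nm, element="N", position=pos,
        ))
    return res


def hollow_shell_atoms(
    inner_radius: float,
    center: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    atom_radius: float = 1.52,
    point_spacing: float = 1.0,
    chain_id: str = "S",
    element: str = "O",
) -> tuple[list[Residue], float]:
    """A closed spherical shell of dummy atoms with an analytic interior.

    Atom centres sit on a sphere of radius ``inner_radius + atom_radius``
    so the van der Waals interior surface is at ``inner_radius``; the
    quasi-uniform point density (one atom per ``point_spacing``² of shell
    surface) leaves no gap a 1.4 Å probe could slip through.  Returns the
    residues and the probe-eroded analytic interior volume
    (4/3)·π·(inner_radius − 1.4)³.
    """
    if inner_radius <= 5.0:
        raise GenerationError("inner radius must exceed 5 Å")
    center = np.asarray(center, dtype=float)
    shell_r = inner_radius + atom_radius
    n_atoms = int(math.ceil(4.0 * math.pi * shell_r**2 / point_spacing**2))
    i = np.arange(n_atoms, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_atoms
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = center + shell_r * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    residues = []
    for num, pos in enumerate(pts, start=1):
        res = Residue(chain_id=chain_id, residue_name="SPH", residue_number=num, is_cofactor=True)
        res.atoms.append(AtomRecord(
            chain_id=chain_id, residue_name="SPH", residue_number=num,
            atom_name=element, element=element, position=pos,
        ))
        residues.append(res)
    analytic = 4.0 / 3.0 * math.pi * (inner_radius - 1.4) ** 3
    return residues, analytic


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqr"


def make_assembly(
    spec: AssemblySpec,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[Assembly, dict[str, str], FixtureManifest]:
    """Build a synthetic oligomeric assembly with exactly planted geometry.

    Returns the in-memory assembly, the chain→monomer map, and the
    manifest.  When ``out_dir`` is given, ``assembly.pdb``, ``chains.tsv``
    and ``manifest.json`` are written there and tests exercise the real
    file round trip.
    """
    spec.validate()
    labels = list(spec.monomer_labels)
    if len(labels) + (spec.cavity_inner_radius is not None) > len(_CHAIN_IDS):
        raise GenerationError("too many chains for PDB chain ids")
    centers = _monomer_centers(labels, spec.monomer_separation)
    chain_of = {lab: _CHAIN_IDS[i] for i, lab in enumerate(labels)}
    chains: dict[str, list[Residue]] = {chain_of[lab]: [] for lab in labels}
    next_resnum = {lab: 1 for lab in labels}

    def add_residue(lab: str, res: Residue) -> None:
        chains[chain_of[lab]].append(res)

    def take_resnum(lab: str) -> int:
        n = next_resnum[lab]
        next_resnum[lab] = n + 1
        return n

    # bulk helices
    for lab in labels:
        for pos in _helix_ca(centers[lab], spec.residues_per_monomer):
            add_residue(lab, _ca_residue(chain_of[lab], take_resnum(lab), pos))

    # planted interface residues, one lane per pair along y
    planted_interface: dict[str, dict] = {}
    for plant in spec.interface_plants:
        la, lb = plant.pair
        ca, cb = centers[la], centers[lb]
        u = (cb - ca) / np.linalg.norm(cb - ca)
        lane_dir = np.cross(u, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(lane_dir) < 1e-9:
            lane_dir = np.array([0.0, 1.0, 0.0])
        lane_dir /= np.linalg.norm(lane_dir)
        mid = 0.5 * (ca + cb)
        numbers_a, numbers_b = [], []
        for k in range(plant.k):
            offset = lane_dir * spec.lane_spacing * (k - (plant.k - 1) / 2.0)
            p1 = mid - 0.5 * plant.distance * u + offset
            p2 = mid + 0.5 * plant.distance * u + offset
            na, nb = take_resnum(la), take_resnum(lb)
            add_residue(la, _ca_residue(chain_of[la], na, p1, name="ALA"))
            add_residue(lb, _ca_residue(chain_of[lb], nb, p2, name="ALA"))
            numbers_a.append(na)
            numbers_b.append(nb)
        planted_interface["-".join(plant.pair)] = {
            "k": plant.k,
            "distance": plant.distance,
            "residues_side1": numbers_a,
            "residues_side2": numbers_b,
        }

    # planted chlorophyll pairs, stacked along z with >= 25 Å clearance
    chl_zone = 60.0
    chl_step = 25.0
    planted_chl = []
    for p_idx, chl in enumerate(spec.chl_plants):
        if chl.pair is not None:
            la, lb = chl.pair
            base = 0.5 * (centers[la] + centers[lb])
            u = (centers[lb] - centers[la])
            u = u / np.linalg.norm(u)
        else:
            la = lb = chl.monomer
            base = centers[la].copy()
            u = np.array([0.0, 1.0, 0.0])
        base = base + np.array([0.0, 0.0, chl_zone + chl_step * p_idx])
        mg1 = base - 0.5 * chl.mg_distance * u
        mg2 = base + 0.5 * chl.mg_distance * u
        n1 = np.array([0.0, 0.0, 1.0])
        theta = math.radians(chl.plane_angle_deg)
        axis = np.cross(np.array([0.0, 0.0, 1.0]), u)
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([1.0, 0.0, 0.0])
        axis /= np.linalg.norm(axis)
        # rotate n1 about the in-plane axis by theta (Rodrigues)
        n2 = (
            n1 * math.cos(theta)
            + np.cross(axis, n1) * math.sin(theta)
            + axis * float(np.dot(axis, n1)) * (1.0 - math.cos(theta))
        )
        r1, r2 = take_resnum(la), take_resnum(lb)
        add_residue(la, _chl_residue(chain_of[la], r1, mg1, n1))
        add_residue(lb, _chl_residue(chain_of[lb], r2, mg2, n2))
        planted_chl.append({
            "monomers": [la, lb],
            "mg_distance": chl.mg_distance,
            "plane_angle_deg": chl.plane_angle_deg,
            "residues": [r1, r2],
            "cross_interface": chl.pair is not None,
        })

    cavity_expect = None
    if spec.cavity_inner_radius is not None:
        shell_chain = _CHAIN_IDS[len(labels)]
        shell_center = np.array([0.0, 0.0, -4.0 * spec.cavity_inner_radius - 120.0])
        shell, analytic = hollow_shell_atoms(
            spec.cavity_inner_radius, center=shell_center, chain_id=shell_chain
        )
        chains[shell_chain] = shell
        cavity_expect = {
            "chain": shell_chain,
            "inner_radius": spec.cavity_inner_radius,
            "analytic_volume": analytic,
        }

    assembly = Assembly(chains=chains, metadata={"source": "synthetic", "seed": seed})
    chain_map = {chain_of[lab]: lab for lab in labels}

    manifest = FixtureManifest(
        seed=seed,
        kind="assembly",
        expected={
            "monomer_labels": labels,
            "chain_map": chain_map,
            "n_chains": len(chains),
            "residues_per_chain": {cid: len(res) for cid, res in chains.items()},
            "n_chl": 2 * len(spec.chl_plants),
            "interface_plants": planted_interface,
            "chl_plants": planted_chl,
            "cavity": cavity_expect,
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pdb_path = out / "assembly.pdb"
        write_pdb(assembly, pdb_path)
        map_path = out / "chains.tsv"
        map_path.write_text("".join(f"{cid}\t{lab}\n" for cid, lab in chain_map.items()))
        manifest.paths = {"structure": str(pdb_path), "chain_map": str(map_path)}
        manifest.write(out / "manifest.json")
    return assembly, chain_map, manifest


# ---------------------------------------------------------------------------
# titratable systems


def make_titratable_system(
    kinds_positions: Sequence[tuple[str, Sequence[float]]],
) -> list[Residue]:
    """Residues with ionizable-group atoms at the stated centres.

    Each entry is ``(residue_kind, xyz)``; the ionizable atoms of the kind
    are placed in a tight cluster around the centre (pair atoms 1 Å apart)
    so site–site distances equal the centre separations to good accuracy.
    """
    from oligoface.energetics import IONIZABLE_GROUP_CHARGES

    residues = []
    for num, (kind, xyz) in enumerate(kinds_positions, start=1):
        kind = kind.upper()
        if kind not in IONIZABLE_GROUP_CHARGES:
            raise GenerationError(f"unknown titratable kind {kind!r}")
        center = np.asarray(xyz, dtype=float)
        res = Residue(chain_id="T", residue_name=kind, residue_number=num, is_polymer=True)
        res.atoms.append(AtomRecord(
            chain_id="T", residue_name=kind, residue_number=num,
            atom_name="CA", element="C", position=center + np.array([0.0, 0.0, 3.0]),
        ))
        group = list(IONIZABLE_GROUP_CHARGES[kind])
        for k, atom_name in enumerate(group):
            offset = np.zeros(3)
            if len(group) > 1:
                offset = np.array([(k - 0.5) * 1.0, 0.0, 0.0])
            elem = "N" if atom_name.startswith("N") else ("S" if atom_name.startswith("S") else "O")
            res.atoms.append(AtomRecord(
                chain_id="T", residue_name=kind, residue_number=num,
                atom_name=atom_name, element=elem, position=center + offset,
            ))
        residues.append(res)
    return residues


# ---------------------------------------------------------------------------
# alignments

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MsaGroupSpec:
    """One group alignment: background columns plus near-invariant blocks."""

    n_sequences: int = 24
    n_columns: int = 120
    blocks: Sequence[tuple[int, int]] = ()  # 1-based inclusive column ranges
    block_mutation_rate: float = 0.0
    gap_rate: float = 0.0
    background: Sequence[float] | None = None  # length-20 frequencies

    def validate(self) -> None:
        prev_end = 0
        for start, end in sorted(self.blocks):
            if not 1 <= start <= end <= self.n_columns:
                raise GenerationError(f"block {start}-{end} outside alignment")
            if start <= prev_end:
                raise GenerationError("blocks overlap")
            prev_end = end


def make_msa(
    groups: Mapping[str, MsaGroupSpec],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], FixtureManifest]:
    """Aligned FASTA per group with planted near-invariant blocks.

    Background columns are i.i.d. draws from the stated amino-acid
    frequencies (uniform by default); block columns repeat one consensus
    letter per column, flipped to a random other letter at the block
    mutation rate.  Returns ``{group: [(id, row), ...]}`` and the manifest
    recording block coordinates and consensus letters.
    """
    rng = np.random.default_rng(seed)
    alignments: dict[str, list[tuple[str, str]]] = {}
    expected: dict[str, dict] = {}
    paths: dict[str, str] = {}
    for group, spec in groups.items():
        spec.validate()
        bg = np.asarray(spec.background if spec.background is not None else np.full(20, 0.05))
        bg = bg / bg.sum()
        in_block = np.zeros(spec.n_columns, dtype=bool)
        consensus = {}
        for start, end in spec.blocks:
            in_block[start - 1 : end] = True
            for col in range(start, end + 1):
                consensus[col] = _AA[rng.integers(0, 20)]
        rows = []
        for s in range(spec.n_sequences):
            letters = []
            for col in range(1, spec.n_columns + 1):
                if in_block[col - 1]:
                    letter = consensus[col]
                    if spec.block_mutation_rate > 0 and rng.random() < spec.block_mutation_rate:
                        letter = _AA[rng.integers(0, 20)]
                else:
                    if spec.gap_rate > 0 and rng.random() < spec.gap_rate:
                        letter = "-"
                    else:
                        letter = _AA[rng.choice(20, p=bg)]
                letters.append(letter)
            rows.append((f"{group}_{s:03d}", "".join(letters)))
        alignments[group] = rows
        expected[group] = {
            "n_sequences": spec.n_sequences,
            "n_columns": spec.n_columns,
            "blocks": [list(b) for b in spec.blocks],
            "consensus": {str(c): l for c, l in consensus.items()},
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            fasta = out / f"{group}.afa"
            fasta.write_text("".join(f">{sid}\n{row}\n" for sid, row in rows))
            paths[group] = str(fasta)

    manifest = FixtureManifest(seed=seed, kind="msa", paths=paths, expected=expected)
    if out_dir is not None:
        manifest.write(Path(out_dir) / "msa_manifest.json")
    return alignments, manifest


# ---------------------------------------------------------------------------
# BLAST tables


def make_blast_table(
    n_hits: int,
    n_passing: int,
    min_identity: float = 40.0,
    min_coverage: float = 35.0,
    max_evalue: float = 1e-10,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> tuple[list[str], FixtureManifest]:
    """An outfmt-6 table (with qlen/slen columns) with exactly n_passing rows.

    Passing rows satisfy all three thresholds, one of them exactly at the
    boundary when possible; failing rows miss at least one threshold,
    cycling through boundary-adjacent identity, coverage and e-value
    failures.  Returns the TSV lines and the manifest.
    """
    if n_passing > n_hits:
        raise GenerationError("n_passing cannot exceed n_hits")
    rng = np.random.default_rng(seed)
    qlen = 160
    lines: list[str] = []
    pass_flags: list[bool] = []
    for i in range(n_hits):
        passing = i < n_passing
        if passing:
            ident = min_identity if i == 0 else float(rng.uniform(min_identity + 5, 95))
            cov = min_coverage if i == 1 else float(rng.uniform(min_coverage + 5, 100))
            ev = max_evalue if i == 2 else float(10.0 ** rng.uniform(-40, np.log10(max_evalue) - 1))
            length = int(round(cov * qlen / 100.0))
            while 100.0 * length / qlen < min_coverage:
                length += 1
        else:
            ident = float(rng.uniform(min_identity + 5, 95))
            length = int(math.ceil(min_coverage * qlen / 100.0)) + int(rng.integers(0, 20))
            ev = float(10.0 ** rng.uniform(-40, np.log10(max_evalue) - 1))
            fail_mode = (i - n_passing) % 3
            if fail_mode == 0:
                ident = min_identity - 0.1  # boundary-adjacent identity failure
            elif fail_mode == 1:
                # one aligned column short of the coverage threshold
                length = int(math.ceil(min_coverage * qlen / 100.0)) - 1
            else:
                ev = max_evalue * 2.0
        mism = int(round(length * (1.0 - ident / 100.0)))
        lines.append("\t".join(map(str, [
            "query", f"subj_{i:03d}", f"{ident:.1f}", length, mism, 0,
            1, length, 1, length, f"{ev:.2e}", f"{rng.uniform(50, 300):.1f}",
            qlen, qlen + rng.integers(-10, 10),
        ])))
        pass_flags.append(passing)
    manifest = FixtureManifest(
        seed=seed,
        kind="blast",
        expected={
            "n_hits": n_hits,
            "n_passing": n_passing,
            "pass_flags": pass_flags,
            "thresholds": {
                "min_identity": min_identity,
                "min_coverage": min_coverage,
                "max_evalue": max_evalue,
            },
        },
    )
    if out_path is not None:
        Path(out_path).write_text("\n".join(lines) + "\n")
        manifest.paths = {"table": str(out_path)}
    return lines, manifest
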