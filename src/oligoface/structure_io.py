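"""Reading macromolecular models and partitioning chains into monomers.

Atomic models arrive as mmCIF or PDB files (parsed with :mod:`gemmi`), are
flattened into plain :class:`AtomRecord`/:class:`Residue`/:class:`Assembly`
containers keyed by *author* chain ids, and the chains are grouped into
monomers of the oligomer through a user-supplied two-column chain map.
Cofactors (chlorophyll a, carotenoids, quinones, Fe–S clusters, lipids) are
recognized by residue name through an editable table; chlorophylls carry
their central Mg atom as the positional anchor used by all distance
analyses downstream.

Coordinates are Å throughout; no unit conversion happens anywhere in the
package.  Hydrogens are retained when present but never required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Assembly",
    "MonomerPartition",
    "Cofactor",
    "ParseError",
    "FormatError",
    "ConfigurationError",
    "read_structure",
    "write_pdb",
    "assign_monomers",
    "extract_cofactors",
    "read_chain_map",
    "read_name_table",
    "default_cofactor_names",
    "assembly_summary",
    "STANDARD_AMINO_ACIDS",
]


class ParseError(ValueError):
    """A structure file could not be parsed."""


class FormatError(ValueError):
    """An unknown coordinate format was requested."""


class ConfigurationError(ValueError):
    """An input mapping table is inconsistent."""


#: Three-letter codes treated as polymer (amino acid) residues.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER
    THR TRP TYR VAL MSE SEC PYL""".split()
)

COFACTOR_KINDS = (
    "chlorophyll_a",
    "beta_carotene",
    "phylloquinone",
    "FeS_cluster",
    "lipid",
    "other",
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the model, after altloc resolution."""

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed position for atom {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.atom_name} has empty element")


@dataclass
class Residue:
    """A residue with its atoms; either polymer or cofactor, never both."""

    chain_id: str
    residue_name: str
    residue_number: int
    atoms: list[AtomRecord] = field(default_factory=list)
    is_polymer: bool = False
    is_cofactor: bool = False

    def __post_init__(self) -> None:
        if self.is_polymer and self.is_cofactor:
            raise ValueError(
                f"residue {self.residue_name} {self.residue_number} flagged both polymer and cofactor"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chain_id, self.residue_name, self.residue_number)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Assembly:
    """A parsed model: ordered residues grouped by author chain id."""

    chains: dict[str, list[Residue]]
    metadata: dict = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def polypeptide_chain_ids(self) -> list[str]:
        """Chains containing at least one standard amino-acid residue."""
        return [cid for cid, residues in self.chains.items() if any(r.is_polymer for r in residues)]

    def iter_residues(self, chain_ids: Iterable[str] | None = None) -> Iterator[Residue]:
        ids = self.chain_ids if chain_ids is None else list(chain_ids)
        for cid in ids:
            yield from self.chains.get(cid, [])

    def iter_atoms(self, chain_ids: Iterable[str] | None = None) -> Iterator[AtomRecord]:
        for res in self.iter_residues(chain_ids):
            yield from res.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())


@dataclass
class MonomerPartition:
    """Assignment of chains to monomer labels (e.g. A, B, A', B')."""

    labels: list[str]
    assignment: dict[str, str]
    unassigned: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def chains_of(self, label: str) -> list[str]:
        return [cid for cid, lab in self.assignment.items() if lab == label]

    def label_of(self, chain_id: str) -> str | None:
        return self.assignment.get(chain_id)


@dataclass
class Cofactor:
    """A hetero residue classified by kind, with its positional anchor."""

    kind: str
    residue: Residue
    anchor_atom: AtomRecord | None = None
    monomer_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in COFACTOR_KINDS:
            raise ValueError(f"unknown cofactor kind {self.kind!r}")
        if self.kind == "chlorophyll_a":
            if self.anchor_atom is None or self.anchor_atom.element.upper() != "MG":
                raise ValueError(
                    f"chlorophyll {self.residue.key} lacks an Mg anchor atom"
                )

    @property
    def id(self) -> str:
        c, name, num = self.residue.key
        return f"{c}/{name}{num}"


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(gemmi_res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, first in file on ties."""
    chosen: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in gemmi_res:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:  # strict: ties keep the earlier record
            chosen[atom.name] = atom
    return [chosen[n] for n in order]


def read_structure(path: str | Path, format: str = "auto") -> Assembly:
    """Read an mmCIF or PDB file into an :class:`Assembly`.

    Parameters
    ----------
    path
        Coordinate file.  ``.cif``/``.mmcif`` and ``.pdb``/``.ent`` are
        recognized automatically under ``format='auto'``.
    format
        ``'mmcif'``, ``'pdb'`` or ``'auto'``.

    All ATOM/HETATM records of the first model are represented; alternate
    locations are resolved to the highest-occupancy conformer (ties broken
    by file order); chain ids are the author ids.
    """
    path = Path(path)
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown format {format!r}; expected mmcif, pdb or auto")
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise ParseError(f"{path} contains no atoms")

    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = chains.setdefault(chain.name, [])
        for gres in chain:
            name = gres.name.strip()
            is_poly = name in STANDARD_AMINO_ACIDS
            res = Residue(
                chain_id=chain.name,
                residue_name=name,
                residue_number=gres.seqid.num,
                is_polymer=is_poly,
                is_cofactor=(not is_poly) and name != "HOH",
            )
            for atom in _resolve_altlocs(gres):
                elem = atom.element.name if atom.element else ""
                res.atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_name=name,
                        residue_number=gres.seqid.num,
                        atom_name=atom.name,
                        element=elem or atom.name[:1],
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                    )
                )
            residues.append(res)
    return Assembly(
        chains=chains,
        metadata={"source": str(path), "format": format, "name": st.name},
    )


def _to_gemmi(assembly: Assembly) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(assembly.metadata.get("name", "oligoface"))
    model = gemmi.Model("1")
    for cid, residues in assembly.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.residue_name
            gres.seqid = gemmi.SeqId(res.residue_number, " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for a in res.atoms:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(assembly: Assembly, path: str | Path) -> None:
    """Write an assembly to PDB (one model, author chain ids)."""
    _to_gemmi(assembly).write_pdb(str(path))


def write_mmcif(assembly: Assembly, path: str | Path) -> None:
    """Write an assembly to mmCIF."""
    _to_gemmi(assembly).make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# monomer partition


def read_chain_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``chain_id<TAB>monomer_label`` into a dict."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(f"{path}:{lineno}: expected 2 tab-separated columns")
        cid, label = parts[0].strip(), parts[1].strip()
        if cid in mapping and mapping[cid] != label:
            raise ConfigurationError(
                f"{path}:{lineno}: chain {cid!r} mapped to both {mapping[cid]!r} and {label!r}"
            )
        mapping[cid] = label
    return mapping


def assign_monomers(assembly: Assembly, chain_map: Mapping[str, str]) -> MonomerPartition:
    """Group chains into labelled monomers according to ``chain_map``.

    Chains of the assembly absent from the map are listed in
    ``unassigned``; map entries naming chains absent from the assembly are
    reported as warnings, not errors.
    """
    if hasattr(chain_map, "keys"):
        mapping = dict(chain_map)
    else:
        raise ConfigurationError("chain_map must be a mapping chain_id -> label")

    warns: list[str] = []
    assignment: dict[str, str] = {}
    for cid, label in mapping.items():
        if cid in assembly.chains:
            assignment[cid] = str(label)
        else:
            warns.append(f"chain map names chain {cid!r} absent from the assembly")
    labels = sorted(set(assignment.values()))
    unassigned = [cid for cid in assembly.chain_ids if cid not in assignment]
    part = MonomerPartition(labels=labels, assignment=assignment, unassigned=unassigned, warnings=warns)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return part


def infer_monomers(
    assembly: Assembly,
    n_monomers: int,
    labels: Sequence[str] | None = None,
    seed: int = 0,
) -> MonomerPartition:
    """Partition chains into monomers by clustering chain centroids.

    A fallback for assemblies without a curated chain map: each chain is
    reduced to its centroid and centroids are k-means-clustered into
    ``n_monomers`` spatial groups (monomers of an oligomer are compact and
    well separated, so centroid clustering recovers them).  Labels are
    assigned to clusters in order of chain-id of their first member; use a
    curated map whenever interface identity matters.
    """
    from scipy.cluster.vq import kmeans2

    cids = assembly.chain_ids
    if n_monomers < 1 or n_monomers > len(cids):
        raise ConfigurationError("n_monomers must be within [1, n_chains]")
    centroids = np.array([
        np.mean([a.position for a in assembly.iter_atoms([cid])], axis=0) for cid in cids
    ])
    _, idx = kmeans2(centroids, n_monomers, minit="++", seed=seed)
    label_names = list(labels) if labels is not None else None
    order: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for cid, cluster in zip(cids, idx):
        cluster = int(cluster)
        if cluster not in order:
            name = label_names[len(order)] if label_names else f"M{len(order) + 1}"
            order[cluster] = name
        assignment[cid] = order[cluster]
    return MonomerPartition(labels=sorted(set(assignment.values())), assignment=assignment)


# ---------------------------------------------------------------------------
# cofactors


def read_name_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``residue_name<TAB>kind`` cofactor table."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(f"{path}:{lineno}: expected 2 tab-separated columns")
        name, kind = parts[0].strip().upper(), parts[1].strip()
        if kind not in COFACTOR_KINDS:
            raise ConfigurationError(f"{path}:{lineno}: unknown cofactor kind {kind!r}")
        table[name] = kind
    return table


def default_cofactor_names() -> dict[str, str]:
    """The bundled residue-name → kind table (editable data file)."""
    with resources.as_file(resources.files("oligoface.data") / "cofactor_names.tsv") as p:
        return read_name_table(p)


def extract_cofactors(
    assembly: Assembly,
    name_table: Mapping[str, str] | None = None,
    partition: MonomerPartition | None = None,
) -> list[Cofactor]:
    """Collect cofactor residues by residue name.

    Chlorophyll-a entries must contain a magnesium atom, which becomes the
    anchor of all Mg–Mg distance analyses; a chlorophyll residue lacking Mg
    is excluded with a warning.  When a partition is given each cofactor is
    tagged with the monomer label of its chain.
    """
    table = {k.upper(): v for k, v in (name_table or default_cofactor_names()).items()}
    if not table:
        raise ConfigurationError("cofactor name table is empty")
    out: list[Cofactor] = []
    for res in assembly.iter_residues():
        kind = table.get(res.residue_name.upper())
        if kind is None:
            continue
        label = partition.label_of(res.chain_id) if partition is not None else None
        anchor = None
        if kind == "chlorophyll_a":
            mg = [a for a in res.atoms if a.element.upper() == "MG"]
            if len(mg) != 1:
                warnings.warn(
                    f"chlorophyll residue {res.key} has {len(mg)} Mg atoms; "
                    "excluded from distance analyses",
                    stacklevel=2,
                )
                continue
            anchor = mg[0]
        out.append(Cofactor(kind=kind, residue=res, anchor_atom=anchor, monomer_label=label))
    return out


# ---------------------------------------------------------------------------
# summary


def assembly_summary(
    assembly: Assembly,
    partition: MonomerPartition | None = None,
    cofactors: list[Cofactor] | None = None,
) -> dict:
    """JSON-serializable overview: chains, residues, cofactors by kind/monomer."""
    summary: dict = {
        "n_chains": assembly.n_chains,
        "n_polypeptide_chains": len(assembly.polypeptide_chain_ids()),
        "n_residues": assembly.n_residues,
        "n_atoms": assembly.n_atoms,
        "chains": {cid: len(res) for cid, res in assembly.chains.items()},
    }
    if partition is not None:
        summary["monomers"] = {
            label: sorted(partition.chains_of(label)) for label in partition.labels
        }
        summary["unassigned_chains"] = list(partition.unassigned)
    if cofactors is not None:
        by_kind: dict[str, int] = {}
        by_monomer: dict[str, dict[str, int]] = {}
        for cof in cofactors:
            by_kind[cof.kind] = by_kind.get(cof.kind, 0) + 1
            if cof.monomer_label is not None:
                d = by_monomer.setdefault(cof.monomer_label, {})
                d[cof.kind] = d.get(cof.kind, 0) + 1
        summary["cofactors_by_kind"] = by_kind
        summary["cofactors_by_monomer"] = by_monomer
    return summary


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
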