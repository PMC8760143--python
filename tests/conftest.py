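"""Shared fixtures: synthetic assemblies with manifest-recorded ground truth."""

from __future__ import annotations

import pytest

from oligoface import structure_io as sio
from oligoface import synthetic_data as syn


@pytest.fixture(scope="session")
def dimer_dir(tmp_path_factory):
    """A two-monomer assembly on disk: 5 interface residue pairs at 8 Å,
    chlorophyll pairs at 14/16 Å across the interface and 9 Å within A,
    and a hollow shell of analytic volume."""
    out = tmp_path_factory.mktemp("dimer")
    spec = syn.AssemblySpec(
        monomer_labels=("A", "B"),
        residues_per_monomer=30,
        interface_plants=[syn.InterfacePlant(("A", "B"), k=5, distance=8.0)],
        chl_plants=[
            syn.ChlPlant(mg_distance=14.0, pair=("A", "B")),
            syn.ChlPlant(mg_distance=16.0, pair=("A", "B")),
            syn.ChlPlant(mg_distance=9.0, monomer="A", plane_angle_deg=30.0),
        ],
        cavity_inner_radius=20.0,
    )
    assembly, chain_map, manifest = syn.make_assembly(spec, seed=11, out_dir=out)
    return out, manifest


@pytest.fixture(scope="session")
def dimer(dimer_dir):
    """The dimer fixture re-read from its PDB file (exercises real I/O)."""
    out, manifest = dimer_dir
    assembly = sio.read_structure(out / "assembly.pdb")
    partition = sio.assign_monomers(assembly, sio.read_chain_map(out / "chains.tsv"))
    return assembly, partition, manifest


@pytest.fixture(scope="session")
def tetramer():
    """An in-memory four-monomer assembly with two interface classes."""
    spec = syn.AssemblySpec(
        monomer_labels=("A", "B", "Ap", "Bp"),
        residues_per_monomer=25,
        interface_plants=[
            syn.InterfacePlant(("A", "B"), k=6, distance=8.0),
            syn.InterfacePlant(("Ap", "Bp"), k=6, distance=8.0),
            syn.InterfacePlant(("B", "Ap"), k=3, distance=10.0),
        ],
        chl_plants=[
            syn.ChlPlant(mg_distance=14.0, pair=("A", "B")),
            syn.ChlPlant(mg_distance=14.0, pair=("Ap", "Bp")),
            syn.ChlPlant(mg_distance=18.0, pair=("B", "Ap")),
        ],
    )
    assembly, chain_map, manifest = syn.make_assembly(spec, seed=7)
    partition = sio.assign_monomers(assembly, chain_map)
    return assembly, partition, manifest
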