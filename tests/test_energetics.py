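"""Protonation sampling and screened-Coulomb / Lennard-Jones energetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligoface import energetics as en
from oligoface import interface_geometry as ig
from oligoface import structure_io as sio
from oligoface import synthetic_data as syn


@pytest.fixture()
def model():
    return en.EnergyModel()


def _sites(*kinds_positions):
    return en.identify_sites(syn.make_titratable_system(list(kinds_positions)))


def test_identify_sites_counts_titratable_residues():
    sites = _sites(("ASP", (0, 0, 0)), ("LYS", (20, 0, 0)))
    assert [s.kind for s in sites] == ["ASP", "LYS"]
    assert sites[0].is_acid and not sites[1].is_acid
    assert sites[0].formal_charge == pytest.approx(-1.0)
    assert sites[1].formal_charge == pytest.approx(1.0)


def test_identify_sites_ignores_non_titratable():
    res = sio.Residue(chain_id="A", residue_name="GLY", residue_number=1, is_polymer=True)
    res.atoms.append(sio.AtomRecord("A", "GLY", 1, "CA", "C", np.zeros(3)))
    assert en.identify_sites([res] * 5) == []


def test_identify_sites_warns_when_group_atoms_missing():
    res = sio.Residue(chain_id="A", residue_name="ASP", residue_number=1, is_polymer=True)
    res.atoms.append(sio.AtomRecord("A", "ASP", 1, "CA", "C", np.zeros(3)))
    with pytest.warns(UserWarning, match="ionizable"):
        assert en.identify_sites([res]) == []


def test_screened_coulomb_hand_value(model):
    # two unit charges at 10 Å with eps(r) = 4r: 332.0636 / (4*10*10)
    assert model.coulomb(1.0, 1.0, 10.0) == pytest.approx(0.830159, abs=1e-6)


def test_coulomb_rejects_overlapping_charges(model):
    with pytest.raises(ValueError):
        model.coulomb(1.0, 1.0, 0.3)


@settings(derandomize=True, max_examples=50)
@given(
    q1=st.floats(-2, 2, allow_nan=False).filter(lambda q: abs(q) > 1e-3),
    q2=st.floats(-2, 2, allow_nan=False).filter(lambda q: abs(q) > 1e-3),
    r=st.floats(1.0, 50.0),
)
def test_coulomb_sign_follows_charge_product(q1, q2, r):
    e = en.EnergyModel().coulomb(q1, q2, r)
    assert np.sign(e) == np.sign(q1 * q2)


def test_lj_minimum_at_sigma_two_sixth(model):
    eps, sig = model.lj_class("C")
    r_min = 2 ** (1 / 6) * sig
    assert model.lj("C", "C", r_min) == pytest.approx(-eps, rel=1e-9)


def test_lj_missing_class_falls_back_with_warning(model):
    with pytest.warns(UserWarning, match="fallback"):
        e = model.lj("ZZ", "C", 4.0)
    assert np.isfinite(e)


def test_single_acid_intrinsic_term_zero_at_pka():
    sites = _sites(("ASP", (0, 0, 0)))
    model = en.EnergyModel(ph=3.65)
    assert en.microstate_energy([1], sites, model) == pytest.approx(0.0, abs=1e-12)
    assert en.microstate_energy([0], sites, model) == pytest.approx(0.0, abs=1e-12)


def test_microstate_energy_hand_computed_two_sites():
    # deprotonated ASP (charge -1) and protonated LYS (+1) 10 Å apart
    sites = _sites(("ASP", (0, 0, 0)), ("LYS", (10, 0, 0)))
    model = en.EnergyModel(ph=7.0)
    kt = model.kt
    intrinsic = 2.303 * kt * (7.0 - 10.53)  # only LYS holds a proton
    # atom-pair Coulomb between the split ASP oxygens and NZ
    pairwise = 0.0
    for a, qa in sites[0].charge_atoms:
        for b, qb in sites[1].charge_atoms:
            r = float(np.linalg.norm(a.position - b.position))
            pairwise += 332.0636 * qa * qb / (4.0 * r * r)
    expected = intrinsic + pairwise
    assert en.microstate_energy([0, 1], sites, model) == pytest.approx(expected, rel=1e-9)


def test_all_neutral_microstate_has_no_pairwise_term():
    # protonated acids and deprotonated bases carry no charge
    sites = _sites(("ASP", (0, 0, 0)), ("LYS", (6, 0, 0)))
    model = en.EnergyModel(ph=7.0)
    e = en.microstate_energy([1, 0], sites, model)
    assert e == pytest.approx(2.303 * model.kt * (7.0 - 3.65), rel=1e-9)


def test_isolated_site_at_pka_samples_half_occupancy():
    sites = _sites(("HIS", (0, 0, 0)))
    model = en.EnergyModel(ph=6.5)
    occ = en.sample_protonation(sites, model, n_steps=100_000, burn_in=10_000, seed=4)
    assert occ.p_protonated[0] == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("seed", [0, 1])
def test_sampler_matches_exact_enumeration_coupled_sites(seed):
    rng = np.random.default_rng(seed)
    kinds = ["ASP", "GLU", "LYS", "HIS", "ARG", "TYR", "CYS", "ASP"]
    positions = rng.uniform(0, 14, size=(len(kinds), 3))
    sites = _sites(*zip(kinds, map(tuple, positions)))
    model = en.EnergyModel(ph=7.0)
    exact = en.enumerate_occupancies(sites, model)
    sampled = en.sample_protonation(sites, model, n_steps=200_000, burn_in=20_000, seed=seed)
    assert np.max(np.abs(exact.p_protonated - sampled.p_protonated)) < 0.01


def test_infinite_temperature_limit_randomizes_sites():
    sites = _sites(("ASP", (0, 0, 0)), ("LYS", (5, 0, 0)))
    model = en.EnergyModel(ph=7.0, temperature=1e6)
    occ = en.sample_protonation(sites, model, n_steps=100_000, burn_in=10_000, seed=8)
    assert np.allclose(occ.p_protonated, 0.5, atol=0.02)


def test_detailed_balance_two_sites_across_seeds():
    sites = _sites(("ASP", (0, 0, 0)), ("HIS", (6, 0, 0)))
    model = en.EnergyModel(ph=5.0)  # both sites partially titrated
    exact = en.enumerate_occupancies(sites, model).p_protonated
    estimates = np.array([
        en.sample_protonation(sites, model, n_steps=40_000, burn_in=4_000, seed=s).p_protonated
        for s in range(20)
    ])
    mean = estimates.mean(axis=0)
    sem = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
    assert np.all(np.abs(mean - exact) <= 3 * sem + 1e-3)


def test_energy_extensivity_of_distant_site_pair():
    model = en.EnergyModel(ph=7.0)
    near = _sites(("ASP", (0, 0, 0)), ("LYS", (6, 0, 0)))
    far = _sites(("ASP", (500, 0, 0)), ("LYS", (506, 0, 0)))
    combined = near + far
    e_near = en.microstate_energy([0, 1], near, model)
    e_far = en.microstate_energy([0, 1], far, model)
    e_all = en.microstate_energy([0, 1, 0, 1], combined, model)
    assert e_all == pytest.approx(e_near + e_far, abs=1e-6)


def test_seed_determinism_bit_for_bit():
    sites = _sites(("ASP", (0, 0, 0)), ("LYS", (8, 0, 0)), ("HIS", (4, 4, 0)))
    model = en.EnergyModel()
    a = en.sample_protonation(sites, model, 20_000, 2_000, seed=123)
    b = en.sample_protonation(sites, model, 20_000, 2_000, seed=123)
    assert a.p_protonated.tobytes() == b.p_protonated.tobytes()


def test_zero_sites_yields_empty_table():
    occ = en.sample_protonation([], en.EnergyModel(), 1000, 100, seed=0)
    assert occ.p_protonated.size == 0


def test_state_vector_length_is_checked():
    sites = _sites(("ASP", (0, 0, 0)))
    with pytest.raises(ValueError):
        en.microstate_energy([0, 1], sites, en.EnergyModel())


def _interface_report(dimer):
    assembly, partition, _ = dimer
    return ig.interface_residues(assembly, partition, ("A", "B"), 12.0)


def test_interface_energy_zero_charges_gives_zero_elec(dimer):
    rep = _interface_report(dimer)
    model = en.EnergyModel(fixed_charges={"NONE": 0.0})
    occ = en.OccupancyTable(sites=[], p_protonated=np.array([]), n_samples=0)
    report = en.interface_energy(rep, occ, model)
    assert report.e_elec == 0.0
    assert np.isfinite(report.e_vdw)


def test_interface_energy_matches_brute_force_pair_sum():
    # two planted residues 8 Å apart: single CA-CA pair within cutoff
    spec = syn.AssemblySpec(
        monomer_labels=("A", "B"),
        interface_plants=[syn.InterfacePlant(("A", "B"), k=1, distance=8.0)],
    )
    assembly, chain_map, _ = syn.make_assembly(spec, seed=3)
    partition = sio.assign_monomers(assembly, chain_map)
    rep = ig.interface_residues(assembly, partition, ("A", "B"), 12.0)
    assert rep.n_total == 2
    model = en.EnergyModel()
    occ = en.OccupancyTable(sites=[], p_protonated=np.array([]), n_samples=0)
    report = en.interface_energy(rep, occ, model)
    a1 = rep.residues_side1[0].atoms[0]
    a2 = rep.residues_side2[0].atoms[0]
    r = float(np.linalg.norm(a1.position - a2.position))
    q = model.fixed_charges.get("CA", 0.0)
    assert report.e_elec == pytest.approx(model.coulomb(q, q, r) if q else 0.0, abs=1e-9)
    assert report.e_vdw == pytest.approx(model.lj("C", "C", r), rel=1e-9)


def test_desolvation_energy_weighted_sum():
    params = {"C": 0.012, "N": -0.06}
    assert en.desolvation_energy([10.0], ["C"], params) == pytest.approx(0.12)
    assert en.desolvation_energy([0.0, 0.0], ["C", "N"], params) == 0.0
    rng = np.random.default_rng(5)
    areas = rng.uniform(0, 20, size=10)
    elems = ["C", "N"] * 5
    expected = sum(params[e] * a for e, a in zip(elems, areas))
    assert en.desolvation_energy(areas, elems, params) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        en.desolvation_energy([-1.0], ["C"], params)
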