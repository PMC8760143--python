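"""Simplified interface energetics with Monte Carlo protonation sampling.

Electrostatics use a screened Coulomb potential with a distance-dependent
dielectric ε(r) = k·r (default k = 4), a deliberate closed-form stand-in
for continuum electrostatics: pair energy 332.0636·q_i·q_j/(ε(r)·r)
kcal/mol.  Dispersion/repulsion is a 12-6 Lennard-Jones sum over coarse
united-atom element classes with Lorentz–Berthelot combining.  An optional
empirical desolvation term weights per-atom accessible-surface-area loss
with atomic solvation parameters.

Protonation of titratable residues (Asp, Glu, His, Lys, Arg, Tyr, Cys) is
a two-state variable per site.  The microstate energy couples the
intrinsic cost 2.303·R·T·(pH − pKa) of holding a proton to screened
Coulomb interactions between charged sites; Metropolis single-site flips
sample the Boltzmann distribution and yield per-site protonation
occupancies, which then weight the site charges in the interface
electrostatic sum.

Because the dielectric model is a screening approximation rather than a
Poisson–Boltzmann solution, interface energy components are meaningful in
sign and relative magnitude, not as absolute free energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from oligoface.interface_geometry import InterfaceReport
from oligoface.structure_io import AtomRecord, Residue

__all__ = [
    "TitratableSite",
    "EnergyModel",
    "OccupancyTable",
    "EnergyReport",
    "identify_sites",
    "microstate_energy",
    "enumerate_occupancies",
    "sample_protonation",
    "interface_energy",
    "desolvation_energy",
    "COULOMB_CONSTANT",
    "GAS_CONSTANT",
    "MODEL_PKA",
]

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636
#: Gas constant, kcal/(mol·K).
GAS_CONSTANT = 1.98720425e-3
#: Reference temperature (K) fixing the energy scale of the pH–pKa term.
#: The pKa penalty is parameterized as a standard-condition free energy in
#: kcal/mol; the sampling temperature enters only the Metropolis acceptance,
#: so raising it flattens the distribution as expected.
REFERENCE_TEMPERATURE = 298.15

#: Model pKa values of the titratable side chains.
MODEL_PKA: dict[str, float] = {
    "ASP": 3.65,
    "GLU": 4.25,
    "HIS": 6.5,
    "LYS": 10.53,
    "ARG": 12.5,
    "TYR": 10.07,
    "CYS": 8.3,
}

#: True for residues whose *deprotonated* state is charged (acids);
#: False for bases, charged when protonated.
IS_ACID: dict[str, bool] = {
    "ASP": True,
    "GLU": True,
    "HIS": False,
    "LYS": False,
    "ARG": False,
    "TYR": True,
    "CYS": True,
}

#: Ionizable-group atoms and the partial charges of the *charged* state.
#: The neutral state carries zero on these atoms (no-hydrogen models).
IONIZABLE_GROUP_CHARGES: dict[str, dict[str, float]] = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "HIS": {"ND1": 0.5, "NE2": 0.5},
    "LYS": {"NZ": 1.0},
    "ARG": {"NH1": 0.5, "NH2": 0.5},
    "TYR": {"OH": -1.0},
    "CYS": {"SG": -1.0},
}


@dataclass
class TitratableSite:
    """One two-state ionizable residue."""

    residue: Residue
    kind: str
    model_pka: float
    is_acid: bool
    charge_atoms: list[tuple[AtomRecord, float]]  # (atom, charged-state charge)

    @property
    def formal_charge(self) -> float:
        """Formal charge of the charged state (−1 acids, +1 bases)."""
        return sum(q for _, q in self.charge_atoms)

    @property
    def id(self) -> str:
        r = self.residue
        return f"{r.chain_id}/{r.residue_name}{r.residue_number}"

    def charged_when_protonated(self) -> bool:
        return not self.is_acid


@dataclass
class EnergyModel:
    """Parameters of the screened-Coulomb / Lennard-Jones energy model."""

    dielectric_k: float = 4.0  # ε(r) = k·r
    cutoff: float = 12.0  # Å, pairwise
    ph: float = 7.0
    temperature: float = 298.15  # K
    lj_params: dict[str, tuple[float, float]] = field(default_factory=dict)  # element -> (eps, sigma)
    lj_fallback: tuple[float, float] = (0.105, 3.75)
    fixed_charges: dict[str, float] = field(default_factory=dict)  # atom name -> charge
    min_distance: float = 0.5  # Å, degenerate-geometry guard

    def __post_init__(self) -> None:
        if self.dielectric_k <= 0 or self.cutoff <= 0 or self.temperature <= 0:
            raise ValueError("dielectric_k, cutoff and temperature must be positive")
        if not self.lj_params:
            self.lj_params, self.lj_fallback = _load_lj_table()
        if not self.fixed_charges:
            self.fixed_charges = _load_fixed_charges()

    @property
    def kt(self) -> float:
        return GAS_CONSTANT * self.temperature

    @property
    def kt_ref(self) -> float:
        return GAS_CONSTANT * REFERENCE_TEMPERATURE

    def epsilon(self, r: float | np.ndarray) -> float | np.ndarray:
        return self.dielectric_k * r

    def coulomb(self, q1: float, q2: float, r: float) -> float:
        """Screened Coulomb pair energy, kcal/mol."""
        if r < self.min_distance:
            raise ValueError(f"overlapping charges at r = {r:.3f} Å")
        return COULOMB_CONSTANT * q1 * q2 / (self.epsilon(r) * r)

    def lj_class(self, element: str) -> tuple[float, float]:
        key = element.upper()
        if key in self.lj_params:
            return self.lj_params[key]
        warnings.warn(f"no Lennard-Jones class for element {element!r}; using fallback", stacklevel=2)
        return self.lj_fallback

    def lj(self, elem1: str, elem2: str, r: float) -> float:
        """12-6 Lennard-Jones pair energy with Lorentz–Berthelot combining."""
        e1, s1 = self.lj_class(elem1)
        e2, s2 = self.lj_class(elem2)
        eps = np.sqrt(e1 * e2)
        sig = 0.5 * (s1 + s2)
        x6 = (sig / r) ** 6
        return 4.0 * eps * (x6 * x6 - x6)


def _load_lj_table() -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    table: dict[str, tuple[float, float]] = {}
    fallback = (0.105, 3.75)
    with resources.as_file(resources.files("oligoface.data") / "lj_params.tsv") as p:
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, eps, sig = line.split("\t")
            pair = (float(eps), float(sig))
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError(f"non-positive LJ parameter for {key!r}")
            if key.upper() == "DEFAULT":
                fallback = pair
            else:
                table[key.upper()] = pair
    return table, fallback


def _load_fixed_charges() -> dict[str, float]:
    charges: dict[str, float] = {}
    with resources.as_file(resources.files("oligoface.data") / "fixed_charges.tsv") as p:
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, q = line.split("\t")
            charges[name.strip()] = float(q)
    return charges


def _load_solvation_params() -> tuple[dict[str, float], float]:
    table: dict[str, float] = {}
    fallback = 0.0
    with resources.as_file(resources.files("oligoface.data") / "solvation_params.tsv") as p:
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sig = line.split("\t")
            if key.upper() == "DEFAULT":
                fallback = float(sig)
            else:
                table[key.upper()] = float(sig)
    return table, fallback


@dataclass
class OccupancyTable:
    """Per-site protonation probabilities from Boltzmann sampling."""

    sites: list[TitratableSite]
    p_protonated: np.ndarray
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_protonated, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("occupancies must lie in [0, 1]")
        self.p_protonated = p

    def p_charged(self, i: int) -> float:
        """Probability that site i is in its charged state."""
        p = float(self.p_protonated[i])
        return p if self.sites[i].charged_when_protonated() else 1.0 - p

    def as_dict(self) -> dict[str, float]:
        return {s.id: float(p) for s, p in zip(self.sites, self.p_protonated)}


@dataclass
class EnergyReport:
    """Interface energy decomposition (kcal/mol; BSA in Å²)."""

    pair: tuple[str, str]
    e_elec: float
    e_vdw: float
    e_desolv: float | None = None
    bsa: float | None = None
    n_residues_side1: int = 0
    n_residues_side2: int = 0

    def __post_init__(self) -> None:
        for v in (self.e_elec, self.e_vdw):
            if not np.isfinite(v):
                raise ValueError("energy components must be finite")


# ---------------------------------------------------------------------------
# sites


def identify_sites(residues: Sequence[Residue]) -> list[TitratableSite]:
    """One two-state site per titratable residue among ``residues``.

    The charge of the charged state is distributed over the ionizable-group
    atoms from the bundled table; residues missing all of those atoms are
    skipped with a warning.
    """
    sites: list[TitratableSite] = []
    for res in residues:
        name = res.residue_name.upper()
        if name not in MODEL_PKA:
            continue
        atom_charges = []
        for atom_name, q in IONIZABLE_GROUP_CHARGES[name].items():
            atom = res.atom(atom_name)
            if atom is not None:
                atom_charges.append((atom, q))
        if not atom_charges:
            warnings.warn(
                f"titratable residue {res.key} lacks its ionizable-group atoms; skipped",
                stacklevel=2,
            )
            continue
        # renormalize so the state's charges sum to the formal charge even
        # if some group atoms are missing from the model
        total = sum(q for _, q in atom_charges)
        formal = sum(IONIZABLE_GROUP_CHARGES[name].values())
        scale = formal / total if total != 0 else 1.0
        atom_charges = [(a, q * scale) for a, q in atom_charges]
        sites.append(
            TitratableSite(
                residue=res,
                kind=name,
                model_pka=MODEL_PKA[name],
                is_acid=IS_ACID[name],
                charge_atoms=atom_charges,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# microstate energy and sampling


def _site_coupling_matrix(sites: Sequence[TitratableSite], model: EnergyModel) -> np.ndarray:
    """J[i, j]: Coulomb energy when sites i and j are both charged."""
    k = len(sites)
    J = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            e = 0.0
            for a1, q1 in sites[i].charge_atoms:
                for a2, q2 in sites[j].charge_atoms:
                    r = float(np.linalg.norm(a1.position - a2.position))
                    e += model.coulomb(q1, q2, r)
            J[i, j] = J[j, i] = e
    return J


def _charged_indicator(state: np.ndarray, sites: Sequence[TitratableSite]) -> np.ndarray:
    prot = np.asarray(state, dtype=bool)
    charged = np.empty(len(sites), dtype=float)
    for i, s in enumerate(sites):
        charged[i] = float(prot[i]) if s.charged_when_protonated() else float(not prot[i])
    return charged


def microstate_energy(
    state: Sequence[int] | np.ndarray,
    sites: Sequence[TitratableSite],
    model: EnergyModel,
    coupling: np.ndarray | None = None,
) -> float:
    """Energy (kcal/mol) of one protonation microstate.

    ``state[i] = 1`` means site i protonated.  E = Σ_i x_i·2.303·R·T₀·(pH −
    pKa_i) + Σ_{i<j} screened-Coulomb between charged sites: holding a
    proton is unfavourable above the site's pKa and favourable below it,
    for acids and bases alike.  T₀ is the reference temperature fixing the
    kcal/mol scale of the pKa term; the model temperature only enters the
    Boltzmann weighting.
    """
    state = np.asarray(state)
    if state.shape != (len(sites),):
        raise ValueError("state vector length must equal the number of sites")
    intrinsic = sum(
        2.303 * model.kt_ref * (model.ph - s.model_pka)
        for s, x in zip(sites, state)
        if x
    )
    if coupling is None:
        coupling = _site_coupling_matrix(sites, model)
    c = _charged_indicator(state, sites)
    pairwise = 0.5 * float(c @ coupling @ c)
    return intrinsic + pairwise


def enumerate_occupancies(sites: Sequence[TitratableSite], model: EnergyModel) -> OccupancyTable:
    """Exact Boltzmann occupancies by enumerating all 2^k microstates."""
    k = len(sites)
    if k == 0:
        return OccupancyTable(sites=[], p_protonated=np.array([]), n_samples=0)
    if k > 20:
        raise ValueError("exhaustive enumeration is limited to 20 sites")
    coupling = _site_coupling_matrix(sites, model)
    energies = np.empty(2**k)
    states = np.empty((2**k, k), dtype=int)
    for m in range(2**k):
        s = np.array([(m >> i) & 1 for i in range(k)])
        states[m] = s
        energies[m] = microstate_energy(s, sites, model, coupling)
    w = np.exp(-(energies - energies.min()) / model.kt)
    w /= w.sum()
    p = (w[:, None] * states).sum(axis=0)
    return OccupancyTable(sites=list(sites), p_protonated=p, n_samples=2**k)


def sample_protonation(
    sites: Sequence[TitratableSite],
    model: EnergyModel,
    n_steps: int = 100_000,
    burn_in: int = 10_000,
    seed: int | None = None,
) -> OccupancyTable:
    """Metropolis single-site-flip sampling of protonation microstates.

    Occupancies are post-burn-in state averages; identical seeds give
    identical tables.  Zero sites yields an empty table.
    """
    if not n_steps > burn_in >= 0:
        raise ValueError("need n_steps > burn_in >= 0")
    k = len(sites)
    if k == 0:
        return OccupancyTable(sites=[], p_protonated=np.array([]), n_samples=0, seed=seed)

    rng = np.random.default_rng(seed)
    coupling = _site_coupling_matrix(sites, model)
    intrinsic = np.array([2.303 * model.kt_ref * (model.ph - s.model_pka) for s in sites])
    prot_sign = np.array([1.0 if s.charged_when_protonated() else -1.0 for s in sites])

    state = rng.integers(0, 2, size=k)
    charged = _charged_indicator(state, sites)

    counts = np.zeros(k, dtype=float)
    n_kept = 0
    flips = rng.integers(0, k, size=n_steps)
    unif = rng.random(n_steps)
    kt = model.kt
    for step in range(n_steps):
        i = flips[step]
        new_x = 1 - state[i]
        # charged indicator change for site i when flipping protonation
        new_c = float(new_x) if prot_sign[i] > 0 else float(1 - new_x)
        dc = new_c - charged[i]
        d_e = (new_x - state[i]) * intrinsic[i] + dc * float(coupling[i] @ charged)
        if d_e <= 0 or unif[step] < np.exp(-d_e / kt):
            state[i] = new_x
            charged[i] = new_c
        if step >= burn_in:
            counts += state
            n_kept += 1
    return OccupancyTable(
        sites=list(sites),
        p_protonated=counts / n_kept,
        n_samples=n_kept,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# interface energy


def _atom_charges(
    residues: Sequence[Residue],
    sites: Mapping[tuple[str, str, int], tuple[TitratableSite, float]],
    model: EnergyModel,
) -> tuple[list[AtomRecord], np.ndarray]:
    """Per-atom charges: occupancy-weighted for titratable groups, fixed otherwise."""
    atoms: list[AtomRecord] = []
    charges: list[float] = []
    for res in residues:
        entry = sites.get(res.key)
        group: dict[str, float] = {}
        if entry is not None:
            site, p_charged = entry
            group = {a.atom_name: q * p_charged for a, q in site.charge_atoms}
        for atom in res.atoms:
            q = group.get(atom.atom_name)
            if q is None:
                q = model.fixed_charges.get(atom.atom_name, 0.0)
            atoms.append(atom)
            charges.append(q)
    return atoms, np.asarray(charges)


def interface_energy(
    interface: InterfaceReport,
    occupancies: OccupancyTable,
    model: EnergyModel | None = None,
    bsa: float | None = None,
    e_desolv: float | None = None,
) -> EnergyReport:
    """Occupancy-weighted Coulomb and Lennard-Jones sums across an interface.

    Pairs are cross-interface atom pairs within the model cutoff.  Charges
    of titratable-group atoms are scaled by the Boltzmann probability of
    the charged state; all other atoms use the fixed-charge table.
    """
    model = model or EnergyModel()
    site_map: dict[tuple[str, str, int], tuple[TitratableSite, float]] = {}
    for i, site in enumerate(occupancies.sites):
        site_map[site.residue.key] = (site, occupancies.p_charged(i))

    atoms1, q1 = _atom_charges(interface.residues_side1, site_map, model)
    atoms2, q2 = _atom_charges(interface.residues_side2, site_map, model)
    if not atoms1 or not atoms2:
        return EnergyReport(
            pair=interface.pair, e_elec=0.0, e_vdw=0.0, e_desolv=e_desolv, bsa=bsa,
            n_residues_side1=len(interface.residues_side1),
            n_residues_side2=len(interface.residues_side2),
        )

    xyz1 = np.array([a.position for a in atoms1])
    xyz2 = np.array([a.position for a in atoms2])
    elems1 = [a.element for a in atoms1]
    elems2 = [a.element for a in atoms2]

    tree2 = cKDTree(xyz2)
    neighbor = cKDTree(xyz1).query_ball_tree(tree2, r=model.cutoff)
    e_elec = 0.0
    e_vdw = 0.0
    for i, js in enumerate(neighbor):
        for j in js:
            r = float(np.linalg.norm(xyz1[i] - xyz2[j]))
            if r >= model.cutoff:
                continue
            r = max(r, model.min_distance)
            if q1[i] != 0.0 and q2[j] != 0.0:
                e_elec += model.coulomb(q1[i], q2[j], r)
            e_vdw += model.lj(elems1[i], elems2[j], r)
    return EnergyReport(
        pair=interface.pair,
        e_elec=e_elec,
        e_vdw=e_vdw,
        e_desolv=e_desolv,
        bsa=bsa,
        n_residues_side1=len(interface.residues_side1),
        n_residues_side2=len(interface.residues_side2),
    )


def desolvation_energy(
    delta_asa: Sequence[float],
    elements: Sequence[str],
    params: Mapping[str, float] | None = None,
    fallback: float | None = None,
) -> float:
    """Empirical desolvation: Σ σ(element) · ΔASA_i (kcal/mol).

    ``delta_asa`` is the per-atom accessible-surface-area loss on complex
    formation (Å², all ≥ 0); σ are atomic solvation parameters from the
    bundled table unless overridden.
    """
    d = np.asarray(delta_asa, dtype=float)
    if np.any(d < 0):
        raise ValueError("per-atom ΔASA must be >= 0")
    if len(d) != len(elements):
        raise ValueError("delta_asa and elements must have equal length")
    if params is None:
        params, table_fallback = _load_solvation_params()
        if fallback is None:
            fallback = table_fallback
    fallback = 0.0 if fallback is None else fallback
    return float(sum(params.get(e.upper(), fallback) * a for e, a in zip(elements, d)))
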