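"""Neutral in-memory data model.

The same containers are shared by the AMBER readers, the CHARMM-format
translator and the energy evaluator, so every route through the package
(PRMTOP → energy, templates → PSF → energy) describes systems identically.

Conventions
-----------
* Bond/angle keys are canonicalised under reversal; dihedral keys under
  full reversal of the quadruple.  Improper keys are *ordered* — the
  declaration order defines the out-of-plane angle.
* Dihedral force constants are per-term barrier heights (PK/IDIVF),
  phases in degrees.
* LJ parameters are (ε, Rmin/2) per type; pairwise values combine by
  Lorentz–Berthelot unless a precomputed A/B table or NBFix overrides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

WILDCARD = "X"


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondParam:
    k: float          # kcal/mol/Å²
    b0: float         # Å


@dataclass(frozen=True)
class AngleParam:
    k: float          # kcal/mol/rad²
    theta0: float     # degrees


@dataclass(frozen=True)
class DihedralTerm:
    k: float          # barrier height, kcal/mol (already PK/IDIVF)
    n: int            # periodicity, ≥ 1
    phase: float      # degrees
    scee: float = 1.2
    scnb: float = 2.0


@dataclass(frozen=True)
class LJParam:
    eps: float        # kcal/mol
    rmin_half: float  # Å (Rmin/2)


@dataclass(frozen=True)
class NBFixParam:
    """Pair-specific LJ override; regular and 1-4 columns are independent."""
    eps: float
    rmin: float       # full Rmin_ij, Å
    eps14: float
    rmin14: float


@dataclass
class CmapGrid:
    """Grid-based (φ, ψ) cross-term on a periodic square grid.

    ``residue`` carries the AMBER-style per-residue assignment;
    ``type_key`` the CHARMM-style eight-type dihedral assignment.
    """
    resolution: int
    values: np.ndarray                       # (resolution, resolution)
    residue: Optional[str] = None
    type_key: Optional[tuple] = None         # 8 encoded types

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution < 4:
            raise ValueError("CMAP grid resolution must be ≥ 4")
        if self.values.shape != (self.resolution, self.resolution):
            raise ValueError("CMAP grid shape does not match resolution")


def bond_key(t1: str, t2: str) -> tuple:
    return min((t1, t2), (t2, t1))


def angle_key(t1: str, t2: str, t3: str) -> tuple:
    return min((t1, t2, t3), (t3, t2, t1))


def dihedral_key(t1: str, t2: str, t3: str, t4: str) -> tuple:
    return min((t1, t2, t3, t4), (t4, t3, t2, t1))


@dataclass
class RawParameterSet:
    """AMBER-side parameter collection, keyed by raw atom-type names."""
    atom_types: set = field(default_factory=set)
    masses: dict = field(default_factory=dict)              # type → amu
    bonds: dict = field(default_factory=dict)               # key → BondParam
    angles: dict = field(default_factory=dict)              # key → AngleParam
    dihedrals: dict = field(default_factory=dict)           # key → [DihedralTerm]
    impropers: dict = field(default_factory=dict)           # ordered key → [DihedralTerm]
    lj: dict = field(default_factory=dict)                  # type → LJParam
    cmaps: list = field(default_factory=list)               # [CmapGrid]
    pair_coeffs: Optional[dict] = None                      # (t1,t2) sorted → (A, B)

    def merge(self, delta: "RawParameterSet") -> "RawParameterSet":
        """Overlay ``delta`` on self; later entries win on identical keys."""
        out = RawParameterSet(
            atom_types=set(self.atom_types) | set(delta.atom_types),
            masses={**self.masses, **delta.masses},
            bonds={**self.bonds, **delta.bonds},
            angles={**self.angles, **delta.angles},
            dihedrals={**self.dihedrals, **delta.dihedrals},
            impropers={**self.impropers, **delta.impropers},
            lj={**self.lj, **delta.lj},
            cmaps=list(self.cmaps) + list(delta.cmaps),
            pair_coeffs=self.pair_coeffs,
        )
        return out


@dataclass
class CharmmParameterSet:
    """CHARMM-side parameter collection, keyed by encoded type names.

    AMBER-derived content never carries Urey–Bradley or harmonic-improper
    terms; the channels exist so their absence is checkable.
    """
    atom_types: set = field(default_factory=set)
    masses: dict = field(default_factory=dict)
    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)               # key → (AngleParam, k_ub, s0)
    dihedrals: dict = field(default_factory=dict)            # key (may contain X) → [DihedralTerm]
    impropers: dict = field(default_factory=dict)
    nonbonded: dict = field(default_factory=dict)            # type → (LJParam, LJParam 1-4)
    nbfix: dict = field(default_factory=dict)                # sorted pair → NBFixParam
    cmaps: list = field(default_factory=list)
    # variant → base; variants share every bonded parameter of their base
    type_aliases: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)           # entry key → comment

    def resolve_alias(self, t: str) -> str:
        seen = set()
        while t in self.type_aliases and t not in seen:
            seen.add(t)
            t = self.type_aliases[t]
        return t


# ---------------------------------------------------------------------------
# molecular system
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    segid: str
    resname: str
    resid: int
    name: str
    type: str
    charge: float     # e
    mass: float       # amu


@dataclass
class MolecularSystem:
    atoms: list = field(default_factory=list)                # [Atom]
    bonds: list = field(default_factory=list)                # [(i, j)]
    angles: list = field(default_factory=list)               # [(i, j, k)]
    dihedrals: list = field(default_factory=list)            # [(i, j, k, l)]
    impropers: list = field(default_factory=list)            # ordered (i, j, k, l)
    cmap_terms: list = field(default_factory=list)           # [((i,j,k,l),(j,k,l,m), grid_ref)]
    exclusions: set = field(default_factory=set)             # frozenset pairs (1-2, 1-3)
    scaled14: dict = field(default_factory=dict)             # pair → (scee, scnb)
    coords: Optional[np.ndarray] = None                      # (n, 3) Å

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def copy(self) -> "MolecularSystem":
        out = MolecularSystem(
            atoms=[dataclasses.replace(a) for a in self.atoms],
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            impropers=list(self.impropers),
            cmap_terms=[(tuple(a), tuple(b), g) for a, b, g in self.cmap_terms],
            exclusions=set(self.exclusions),
            scaled14=dict(self.scaled14),
            coords=None if self.coords is None else self.coords.copy(),
        )
        return out


def pair(i: int, j: int) -> frozenset:
    if i == j:
        raise ValueError("self-pair")
    return frozenset((i, j))


@dataclass
class ParametrizedSystem:
    """A MolecularSystem with every bonded term bound to its parameters.

    ``ab_table`` (PRMTOP route) holds precomputed pairwise LJ coefficients
    keyed by sorted raw-type pair; when present the amber-form evaluator
    uses it verbatim, reproducing the limited-precision pathway.
    """
    system: MolecularSystem
    bond_terms: list = field(default_factory=list)       # [(i, j, BondParam)]
    angle_terms: list = field(default_factory=list)      # [(i, j, k, AngleParam)]
    dihedral_terms: list = field(default_factory=list)   # [(i, j, k, l, DihedralTerm)]
    improper_terms: list = field(default_factory=list)   # sinusoidal, same shape
    cmap_assignments: list = field(default_factory=list) # [((i,j,k,l),(j,k,l,m), CmapGrid)]
    lj: dict = field(default_factory=dict)               # type → LJParam
    lj14: dict = field(default_factory=dict)             # type → LJParam (prescaled)
    nbfix: dict = field(default_factory=dict)            # sorted pair → NBFixParam
    ab_table: Optional[dict] = None


# ---------------------------------------------------------------------------
# residue templates and patches
# ---------------------------------------------------------------------------

@dataclass
class TemplateAtom:
    name: str
    type: str
    charge: float


@dataclass
class ResidueTemplate:
    """Residue building block: atoms, intra-residue bonds, connectors and
    the reference geometry used to place atoms when a segment is built."""
    name: str
    atoms: list = field(default_factory=list)          # [TemplateAtom]
    bonds: list = field(default_factory=list)          # [(name, name)]
    head: Optional[str] = None                         # connector atom names
    tail: Optional[str] = None
    impropers: list = field(default_factory=list)      # ordered name quadruples
    coords: dict = field(default_factory=dict)         # name → (x, y, z) Å
    cmap_anchor: Optional[str] = None                  # Cα-analogue atom name

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in residue {self.name}")

    def atom(self, name: str) -> TemplateAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} has no atom {name!r}")


@dataclass
class Patch:
    """Scripted residue modification (psfgen PRES analogue)."""
    name: str
    arity: int = 1
    delete_atoms: list = field(default_factory=list)     # [(target_idx, atom name)]
    add_bonds: list = field(default_factory=list)        # [((ti, name), (tj, name))]
    delete_bonds: list = field(default_factory=list)
    retype: list = field(default_factory=list)           # [(ti, name, new type)]
    recharge: list = field(default_factory=list)         # [(ti, name, new charge)]
    add_impropers: list = field(default_factory=list)    # [[(ti, name) × 4]]
    reorder_impropers: list = field(default_factory=list)  # [(old order, new order)] of (ti, name)


# ---------------------------------------------------------------------------
# energy containers
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    urey_bradley: float = 0.0
    dihedral: float = 0.0
    improper_harmonic: float = 0.0
    cmap: float = 0.0
    vdw: float = 0.0
    vdw14: float = 0.0
    elec: float = 0.0
    elec14: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.urey_bradley + self.dihedral
                + self.improper_harmonic + self.cmap + self.vdw + self.vdw14
                + self.elec + self.elec14)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d["total"] = self.total
        return d


@dataclass
class DeviationReport:
    per_system: list          # |ΔE|/N per system, kcal/mol/atom
    average: float
    maximum: float
    std: float
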