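"""Segment building, patches, term enumeration, exclusions, PSF I/O."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ffport.core import (Atom, BondParam, DihedralTerm, LJParam,
                         MolecularSystem, Patch, RawParameterSet,
                         ResidueTemplate, TemplateAtom, pair)
from ffport.topology_builder import (AssignmentError, BuildError, apply_patch,
                                     assign_parameters, build_exclusions,
                                     build_segment, enumerate_bonded_terms,
                                     read_xplor_psf, write_xplor_psf)


def toy_templates():
    """Three-atom residue with two intra bonds, head/tail connectors."""
    tpl = ResidueTemplate(
        name="RES",
        atoms=[TemplateAtom("A1", "CT", 0.1), TemplateAtom("A2", "OS", -0.2),
               TemplateAtom("A3", "CT", 0.1)],
        bonds=[("A1", "A2"), ("A2", "A3")],
        head="A1", tail="A3",
        coords={"A1": (0.0, 0.0, 0.0), "A2": (1.4, 0.5, 0.0),
                "A3": (2.8, 0.0, 0.0)})
    return {"RES": tpl}


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------

def test_build_segment_counts():
    system = build_segment(toy_templates(), ["RES", "RES", "RES"])
    assert system.n_atoms == 9
    assert len(system.bonds) == 8            # 6 intra + 2 linking
    assert [a.resid for a in system.atoms] == [1, 1, 1, 2, 2, 2, 3, 3, 3]


def test_build_segment_single_residue_verbatim():
    system = build_segment(toy_templates(), ["RES"])
    assert [(a.name, a.type, a.charge) for a in system.atoms] == \
        [("A1", "CT", 0.1), ("A2", "OS", -0.2), ("A3", "CT", 0.1)]
    assert np.allclose(system.coords[1], (1.4, 0.5, 0.0))


def test_build_segment_unknown_residue():
    with pytest.raises(BuildError, match="GHOST"):
        build_segment(toy_templates(), ["RES", "GHOST"])


def test_build_segment_caps():
    system = build_segment(toy_templates(), ["RES"], caps=("RES", "RES"))
    assert system.n_atoms == 9


def test_variant_templates_keep_distinct_charges_and_types():
    """Alternate protonation-style variants resolve to their own template."""
    t = toy_templates()["RES"]
    variants = {}
    for name, q in (("HIE", 0.10), ("HID", -0.05), ("HIP", 0.25)):
        atoms = [TemplateAtom(a.name, a.type, q) for a in t.atoms]
        variants[name] = ResidueTemplate(name=name, atoms=atoms,
                                         bonds=t.bonds, head="A1", tail="A3",
                                         coords=t.coords)
    system = build_segment(variants, ["HIE", "HID", "HIP"])
    assert [a.charge for a in system.atoms[::3]] == [0.10, -0.05, 0.25]


# ---------------------------------------------------------------------------
# bonded-term enumeration
# ---------------------------------------------------------------------------

def brute_paths(n, bonds, length):
    g = nx.Graph(bonds)
    g.add_nodes_from(range(n))
    seen = set()
    for nodes in itertools.permutations(g.nodes, length):
        if all(g.has_edge(a, b) for a, b in zip(nodes, nodes[1:])):
            seen.add(min(nodes, nodes[::-1]))
    return seen


@pytest.mark.parametrize("n", [3, 4, 6])
def test_linear_chain_counts(n):
    bonds = [(i, i + 1) for i in range(n - 1)]
    angles, dihedrals = enumerate_bonded_terms(n, bonds)
    assert len(angles) == n - 2
    assert len(dihedrals) == n - 3


def test_ring_and_star_counts():
    ring = [(i, (i + 1) % 6) for i in range(6)]
    angles, dihedrals = enumerate_bonded_terms(6, ring)
    assert set(angles) == brute_paths(6, ring, 3)
    assert set(dihedrals) == brute_paths(6, ring, 4)
    assert len(angles) == 6 and len(dihedrals) == 6
    star = [(0, 1), (0, 2), (0, 3)]
    angles, dihedrals = enumerate_bonded_terms(4, star)
    assert len(angles) == 3 and len(dihedrals) == 0


# ---------------------------------------------------------------------------
# exclusions / scaled 1-4 partition
# ---------------------------------------------------------------------------

def chain_system(n):
    system = MolecularSystem(
        atoms=[Atom("A", "RES", 1, f"X{i}", "CT", 0.0, 12.0)
               for i in range(n)],
        bonds=[(i, i + 1) for i in range(n - 1)])
    from ffport.topology_builder import autogenerate
    autogenerate(system)
    return system


def test_linear_chain_partition():
    system = chain_system(4)
    build_exclusions(system)
    assert system.exclusions == {pair(0, 1), pair(1, 2), pair(2, 3),
                                 pair(0, 2), pair(1, 3)}
    assert set(system.scaled14) == {pair(0, 3)}
    assert system.scaled14[pair(0, 3)] == (1.2, 2.0)


def test_four_ring_has_no_one_four():
    system = MolecularSystem(
        atoms=[Atom("A", "R", 1, f"X{i}", "CT", 0.0, 12.0)
               for i in range(4)],
        bonds=[(0, 1), (1, 2), (2, 3), (3, 0)])
    from ffport.topology_builder import autogenerate
    autogenerate(system)
    build_exclusions(system)
    # across-ring pairs are 1-3, never 1-4
    assert system.scaled14 == {}
    assert pair(0, 2) in system.exclusions and pair(1, 3) in system.exclusions


def test_double_dihedral_path_pair_counted_once():
    """A bicyclic bridge connects one pair by two distinct dihedral paths."""
    bonds = [(0, 1), (1, 2), (2, 3), (0, 4), (4, 5), (5, 3)]
    system = MolecularSystem(
        atoms=[Atom("A", "R", 1, f"X{i}", "CT", 0.0, 12.0)
               for i in range(6)],
        bonds=bonds)
    from ffport.topology_builder import autogenerate
    autogenerate(system)
    build_exclusions(system)
    n_paths = sum(1 for q in system.dihedrals if {q[0], q[3]} == {0, 3})
    assert n_paths == 2
    assert list(system.scaled14).count(pair(0, 3)) == 1


def test_partition_matches_shortest_path_oracle(sys_full):
    """Exhaustive check against networkx shortest paths on a fixture."""
    system = sys_full.system
    g = nx.Graph(system.bonds)
    g.add_nodes_from(range(system.n_atoms))
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            d = dist.get(i, {}).get(j)
            p = pair(i, j)
            assert (p in system.exclusions) == (d in (1, 2))
            assert (p in system.scaled14) == (d == 3)
    assert not set(system.scaled14) & system.exclusions


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def test_disulfide_analogue_patch():
    system = build_segment(toy_templates(), ["RES", "RES", "RES"])
    disu = Patch(name="DISU", arity=2,
                 add_bonds=[((0, "A2"), (1, "A2"))],
                 delete_atoms=[(0, "A1"), (1, "A1")])
    patched = apply_patch(system, disu, targets=[1, 3])
    assert patched.n_atoms == system.n_atoms - 2
    names = [(a.resid, a.name) for a in patched.atoms]
    assert (1, "A1") not in names and (3, "A1") not in names
    i = names.index((1, "A2"))
    j = names.index((3, "A2"))
    assert tuple(sorted((i, j))) in {tuple(sorted(b)) for b in patched.bonds}


def test_empty_patch_is_identity():
    system = build_segment(toy_templates(), ["RES", "RES"])
    out = apply_patch(system, Patch(name="NOOP", arity=1), targets=[1])
    assert [(a.name, a.type, a.charge) for a in out.atoms] == \
        [(a.name, a.type, a.charge) for a in system.atoms]
    assert out.bonds == system.bonds and out.dihedrals == system.dihedrals


def test_failed_patch_leaves_system_unchanged():
    system = build_segment(toy_templates(), ["RES", "RES"])
    before = ([(a.name, a.type, a.charge) for a in system.atoms],
              list(system.bonds), list(system.impropers))
    bad = Patch(name="BAD", arity=1, retype=[(0, "A2", "XX")],
                delete_atoms=[(0, "NOPE")])
    with pytest.raises(BuildError, match="NOPE"):
        apply_patch(system, bad, targets=[1])
    assert before == ([(a.name, a.type, a.charge) for a in system.atoms],
                      list(system.bonds), list(system.impropers))


def test_patch_arity_mismatch():
    system = build_segment(toy_templates(), ["RES"])
    with pytest.raises(BuildError):
        apply_patch(system, Patch(name="P", arity=2), targets=[1])


def test_reorder_improper_patch_changes_angle_definition():
    """Reordering an improper changes φ and hence its energy; parameters
    are untouched."""
    from ffport.energy import EnergyOptions, compute_potential
    tpl = toy_templates()["RES"]
    coords = {"A1": (0.0, 0.0, 0.2), "A2": (1.4, 0.5, 0.0),
              "A3": (2.6, -0.3, -0.4), "B1": (1.1, -0.8, 0.9)}
    tpl = ResidueTemplate(
        name="RES", atoms=tpl.atoms + [TemplateAtom("B1", "N3", 0.0)],
        bonds=tpl.bonds + [("A2", "B1")], head="A1", tail="A3",
        coords=coords,
        impropers=[("A1", "A3", "A2", "B1")])
    system = build_segment({"RES": tpl}, ["RES"])
    reorder = Patch(name="REO", arity=1, reorder_impropers=[
        (((0, "A1"), (0, "A3"), (0, "A2"), (0, "B1")),
         ((0, "B1"), (0, "A1"), (0, "A2"), (0, "A3")))])
    patched = apply_patch(system, reorder, targets=[1])
    assert patched.impropers != system.impropers
    raw = RawParameterSet(
        atom_types={"CT", "OS", "N3"},
        masses={"CT": 12.0, "OS": 16.0, "N3": 14.0},
        bonds={k: BondParam(300.0, 1.4) for k in
               [("CT", "OS"), ("N3", "OS")]},
        angles={},
        # n=1 so the redefinition of φ is visible (cos 2χ would be
        # invariant under the sign flip this particular permutation causes)
        impropers={q: [DihedralTerm(8.0, 1, 90.0)] for q in
                   [("CT", "CT", "OS", "N3"), ("N3", "CT", "OS", "CT")]},
        lj={t: LJParam(0.1, 1.5) for t in ("CT", "OS", "N3")})
    for s in (system, patched):
        s.angles, s.dihedrals = [], []
        build_exclusions(s)
    e0 = compute_potential(assign_parameters(system, raw), EnergyOptions())
    e1 = compute_potential(assign_parameters(patched, raw), EnergyOptions())
    assert abs(e0.dihedral - e1.dihedral) > 1e-6


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

def assignment_fixture():
    system = chain_system(4)
    build_exclusions(system)
    system.coords = np.array([[0, 0, 0], [1.4, 0.4, 0], [2.8, 0, 0],
                              [4.2, 0.4, 0]], dtype=float)
    from ffport.core import AngleParam
    raw = RawParameterSet(
        atom_types={"CT"}, masses={"CT": 12.0},
        bonds={("CT", "CT"): BondParam(300.0, 1.45)},
        angles={("CT", "CT", "CT"): AngleParam(60.0, 111.0)},
        lj={"CT": LJParam(0.1, 1.7)})
    return system, raw


def test_exact_dihedral_beats_wildcard():
    system, raw = assignment_fixture()
    raw.dihedrals = {
        ("X", "CT", "CT", "X"): [DihedralTerm(9.0, 1, 0.0)],
        ("CT", "CT", "CT", "CT"): [DihedralTerm(1.5, 2, 180.0)],
    }
    ps = assign_parameters(system, raw)
    assert [t.k for *_, t in ps.dihedral_terms] == [1.5]


def test_wildcard_used_when_no_exact_entry():
    system, raw = assignment_fixture()
    raw.dihedrals = {("X", "CT", "CT", "X"): [DihedralTerm(9.0, 1, 0.0)]}
    ps = assign_parameters(system, raw)
    assert [t.k for *_, t in ps.dihedral_terms] == [9.0]


def test_missing_parameter_names_the_types():
    system, raw = assignment_fixture()
    raw.dihedrals = {}
    with pytest.raises(AssignmentError, match="CT"):
        assign_parameters(system, raw)


# ---------------------------------------------------------------------------
# X-PLOR PSF
# ---------------------------------------------------------------------------

def test_psf_counts_and_round_trip(sys_full):
    from ffport.ff_translate import encode_system_types, translate_pipeline
    from ffport.fixtures import gen_forcefield  # noqa: F401  (fixture source)
    system = sys_full.system.copy()
    text = write_xplor_psf(system)
    assert f"{system.n_atoms:10d} !NATOM" in text
    assert f"{len(system.bonds):10d} !NBOND" in text
    assert f"{len(system.cmap_terms):10d} !NCRTERM" in text
    again = read_xplor_psf(text)
    assert [(a.segid, a.resname, a.resid, a.name, a.type, a.charge, a.mass)
            for a in again.atoms] == \
        [(a.segid, a.resname, a.resid, a.name, a.type, a.charge, a.mass)
         for a in system.atoms]
    assert list(map(tuple, again.bonds)) == list(map(tuple, system.bonds))
    assert again.angles == system.angles
    assert again.dihedrals == system.dihedrals
    assert again.impropers == system.impropers
    assert [(a, b) for a, b, _ in again.cmap_terms] == \
        [(tuple(a), tuple(b)) for a, b, _ in system.cmap_terms]


def test_psf_type_width_guard():
    system = chain_system(2)
    system.atoms[0].type = "U" * 11
    with pytest.raises(BuildError, match="column width"):
        write_xplor_psf(system)
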