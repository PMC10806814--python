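"""psfgen-analogue system builder.

Builds a :class:`MolecularSystem` from residue templates and a sequence,
applies patches (disulfide analogues, terminal caps, improper reordering),
autogenerates angles/dihedrals from the bond graph, derives the
exclusion/scaled-1-4 partition, binds parameters by type with wildcard
fallback, and reads/writes X-PLOR-dialect PSF files (wide, EXT-style
columns so postfixed type names never truncate).
"""

from __future__ import annotations

import logging
from collections import deque

import numpy as np

from .core import (Atom, CharmmParameterSet, DihedralTerm, MolecularSystem,
                   ParametrizedSystem, RawParameterSet, WILDCARD,
                   angle_key, bond_key, dihedral_key, pair)

logger = logging.getLogger(__name__)


class BuildError(ValueError):
    pass


class AssignmentError(KeyError):
    """A bonded term has no matching parameter entry (never silent zeros)."""


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------

def build_segment(templates: dict, sequence, caps=None, segid: str = "A",
                  gap: float = 1.5) -> MolecularSystem:
    """Build a linear segment from ``sequence`` of residue names.

    Consecutive residues are linked tail→head.  ``caps`` is an optional
    (first, last) pair of capping residue names prepended/appended to the
    sequence.  Template geometry is used verbatim; each residue is
    translated along x past the previous residue's extent plus ``gap`` Å
    so chains never self-overlap.
    """
    names = list(sequence)
    if caps:
        first, last = caps
        if first:
            names.insert(0, first)
        if last:
            names.append(last)
    unknown = [n for n in names if n not in templates]
    if unknown:
        raise BuildError(f"unknown residue name(s): {', '.join(unknown)}")

    system = MolecularSystem()
    coords = []
    prev_tail = None
    index_of = {}       # (resid, atom name) → global index
    cursor = 0.0
    for resid, rname in enumerate(names, start=1):
        tpl = templates[rname]
        base = len(system.atoms)
        xs = [tpl.coords.get(a.name, (0.0, 0.0, 0.0))[0] for a in tpl.atoms]
        shift = cursor - min(xs)
        cursor = max(xs) + shift + gap
        for a in tpl.atoms:
            index_of[(resid, a.name)] = len(system.atoms)
            system.atoms.append(Atom(segid=segid, resname=rname, resid=resid,
                                     name=a.name, type=a.type,
                                     charge=a.charge, mass=0.0))
            x, y, z = tpl.coords.get(a.name, (0.0, 0.0, 0.0))
            coords.append((x + shift, y, z))
        for n1, n2 in tpl.bonds:
            system.bonds.append((index_of[(resid, n1)],
                                 index_of[(resid, n2)]))
        for quad in tpl.impropers:
            system.impropers.append(tuple(index_of[(resid, n)]
                                          for n in quad))
        if prev_tail is not None:
            if tpl.head is None:
                raise BuildError(f"residue {rname} has no head connector")
            system.bonds.append((prev_tail, index_of[(resid, tpl.head)]))
        prev_tail = (index_of[(resid, tpl.tail)]
                     if tpl.tail is not None else None)
        _ = base
    system.coords = np.array(coords, dtype=float)
    autogenerate(system)
    return system


def autogenerate(system: MolecularSystem) -> None:
    """Derive angles and dihedrals from the bond graph (psfgen behaviour);
    templates never declare extra angles."""
    angles, dihedrals = enumerate_bonded_terms(system.n_atoms, system.bonds)
    system.angles = angles
    system.dihedrals = dihedrals


def enumerate_bonded_terms(n_atoms: int, bonds):
    """All distinct i–j–k and i–j–k–l simple paths of the bond graph,
    each counted once under reversal symmetry."""
    adj = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    angles = []
    for j in range(n_atoms):
        nbrs = sorted(adj[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
    dihedrals = []
    for j, k in sorted(set(tuple(sorted(b)) for b in bonds)):
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                if quad[::-1] < quad:
                    quad = quad[::-1]
                dihedrals.append(quad)
    return sorted(set(angles)), sorted(set(dihedrals))


# ---------------------------------------------------------------------------
# exclusions and 1-4 scaling
# ---------------------------------------------------------------------------

def build_exclusions(system: MolecularSystem, params=None,
                     scee_default: float = 1.2,
                     scnb_default: float = 2.0) -> None:
    """Partition close pairs: 1-2/1-3 are excluded; pairs separated by
    exactly three bonds (and not also 1-2/1-3) are scaled 1-4 pairs.

    Each 1-4 pair is counted once no matter how many dihedral paths or
    multiterm series connect it; its (scee, scnb) comes from the governing
    dihedral term, looked up in ``params`` when given.
    """
    dist = _bond_distances(system, max_depth=3)
    system.exclusions = set()
    system.scaled14 = {}
    for pr, d in dist.items():
        if d in (1, 2):
            system.exclusions.add(pr)
    governing = {}
    for quad in system.dihedrals:
        i, l = quad[0], quad[3]
        pr = pair(i, l)
        if pr not in governing:
            governing[pr] = quad
    for pr, d in dist.items():
        if d == 3:
            scee, scnb = scee_default, scnb_default
            quad = governing.get(pr)
            if quad is not None and params is not None:
                terms = _lookup_dihedral(params, tuple(
                    system.atoms[i].type for i in quad))
                if terms:
                    scee, scnb = terms[0].scee, terms[0].scnb
            system.scaled14[pr] = (scee, scnb)


def _bond_distances(system, max_depth: int = 3) -> dict:
    adj = [[] for _ in range(system.n_atoms)]
    for i, j in system.bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = {}
    for src in range(system.n_atoms):
        seen = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            if seen[u] == max_depth:
                continue
            for v in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    q.append(v)
        for v, d in seen.items():
            if v > src:
                dist[pair(src, v)] = d
    return dist


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def apply_patch(system: MolecularSystem, patch, targets) -> MolecularSystem:
    """Apply a patch to the given target residues (by resid), atomically:
    on any failure the input system is returned unchanged (a modified copy
    is produced on success)."""
    if len(targets) != patch.arity:
        raise BuildError(f"patch {patch.name} expects {patch.arity} "
                         f"target(s), got {len(targets)}")
    work = system.copy()

    def locate(ti, name):
        resid = targets[ti]
        for idx, a in enumerate(work.atoms):
            if a.resid == resid and a.name == name:
                return idx
        raise BuildError(f"patch {patch.name}: residue {resid} has no "
                         f"atom {name!r}")

    for ti, name, new_type in patch.retype:
        work.atoms[locate(ti, name)].type = new_type
    for ti, name, q in patch.recharge:
        work.atoms[locate(ti, name)].charge = q
    for (t1, n1), (t2, n2) in patch.delete_bonds:
        b = tuple(sorted((locate(t1, n1), locate(t2, n2))))
        work.bonds = [bb for bb in work.bonds if tuple(sorted(bb)) != b]
    for (t1, n1), (t2, n2) in patch.add_bonds:
        work.bonds.append((locate(t1, n1), locate(t2, n2)))
    for quad in patch.add_impropers:
        work.impropers.append(tuple(locate(ti, n) for ti, n in quad))
    for old, new in patch.reorder_impropers:
        old_idx = tuple(locate(ti, n) for ti, n in old)
        new_idx = tuple(locate(ti, n) for ti, n in new)
        if sorted(old_idx) != sorted(new_idx):
            raise BuildError(f"patch {patch.name}: improper reorder must "
                             "permute the same four atoms")
        work.impropers = [new_idx if imp == old_idx else imp
                          for imp in work.impropers]
    deletions = sorted((locate(ti, n) for ti, n in patch.delete_atoms),
                       reverse=True)
    for idx in deletions:
        _delete_atom(work, idx)
    autogenerate(work)
    return work


def _delete_atom(system: MolecularSystem, idx: int) -> None:
    def remap(i):
        return i - 1 if i > idx else i

    system.atoms.pop(idx)
    system.bonds = [(remap(i), remap(j)) for i, j in system.bonds
                    if idx not in (i, j)]
    system.impropers = [tuple(remap(i) for i in q) for q in system.impropers
                        if idx not in q]
    if system.coords is not None:
        system.coords = np.delete(system.coords, idx, axis=0)


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

def _alias(params, t: str) -> str:
    if isinstance(params, CharmmParameterSet):
        return params.resolve_alias(t)
    return t


def _lookup_dihedral(params, types) -> list:
    """Exact quadruple first, then wildcard X-t2-t3-X; reversal-symmetric."""
    table = params.dihedrals
    t = tuple(_alias(params, x) for x in types)
    key = dihedral_key(*t)
    if key in table:
        return table[key]
    wkey = dihedral_key(WILDCARD, t[1], t[2], WILDCARD)
    return table.get(wkey)


def _lookup_improper(params, types) -> list:
    table = params.impropers
    t = tuple(_alias(params, x) for x in types)
    if t in table:
        return table[t]
    # wildcard: X-X-c-d and X-b-c-d conventions, centre fixed at slot 3
    for cand in ((WILDCARD, t[1], t[2], t[3]),
                 (WILDCARD, WILDCARD, t[2], t[3])):
        if cand in table:
            return table[cand]
    return None


def assign_parameters(system: MolecularSystem, params) -> ParametrizedSystem:
    """Bind every bonded term to its parameters by atom type.

    Exact dihedral/improper entries win over wildcard entries; a tuple
    with no match raises :class:`AssignmentError` naming the four types.
    ``params`` may be a raw (AMBER-side) or translated (CHARMM-side) set.
    """
    ps = ParametrizedSystem(system=system)
    types = [a.type for a in system.atoms]

    def mass_of(t):
        return params.masses.get(_alias(params, t))

    for a in system.atoms:
        m = mass_of(a.type)
        if m is not None:
            a.mass = m

    for i, j in system.bonds:
        key = bond_key(_alias(params, types[i]), _alias(params, types[j]))
        bp = params.bonds.get(key)
        if bp is None:
            raise AssignmentError(f"no bond parameter for {key}")
        ps.bond_terms.append((i, j, bp))
    for i, j, k in system.angles:
        key = angle_key(*(_alias(params, types[x]) for x in (i, j, k)))
        ap = params.angles.get(key)
        if ap is None:
            raise AssignmentError(f"no angle parameter for {key}")
        if isinstance(params, CharmmParameterSet):
            ap = ap[0]
        ps.angle_terms.append((i, j, k, ap))
    for quad in system.dihedrals:
        terms = _lookup_dihedral(params, tuple(types[x] for x in quad))
        if not terms:
            raise AssignmentError(
                "no dihedral parameter for types "
                f"{tuple(types[x] for x in quad)}")
        for t in terms:
            ps.dihedral_terms.append((*quad, t))
    for quad in system.impropers:
        terms = _lookup_improper(params, tuple(types[x] for x in quad))
        if not terms:
            raise AssignmentError(
                "no improper parameter for types "
                f"{tuple(types[x] for x in quad)}")
        for t in terms:
            ps.improper_terms.append((*quad, t))

    if isinstance(params, CharmmParameterSet):
        for t in set(types):
            base = params.resolve_alias(t)
            if base not in params.nonbonded:
                raise AssignmentError(f"no nonbonded parameters for {t}")
            reg, one4 = params.nonbonded[t if t in params.nonbonded else base]
            ps.lj[t] = reg
            ps.lj14[t] = one4
        ps.nbfix = dict(params.nbfix)
    else:
        for t in set(types):
            if t not in params.lj:
                raise AssignmentError(f"no LJ parameters for {t}")
            ps.lj[t] = params.lj[t]
        ps.ab_table = params.pair_coeffs
    ps.cmap_assignments = list(system.cmap_terms)
    return ps


def enumerate_cmap_sites(system: MolecularSystem, anchors) -> list:
    """Canonical five-atom paths i–j–k–l–m centred on anchor atoms k.

    Both CMAP assignment routes (per-residue, AMBER-style, and
    per-dihedral-type, CHARMM-style) derive their crossterms from this one
    enumeration so they always agree.  Each path and its reverse count
    once; the lexicographically smaller orientation is kept.
    """
    anchors = set(anchors)
    adj = [[] for _ in range(system.n_atoms)]
    for i, j in system.bonds:
        adj[i].append(j)
        adj[j].append(i)
    sites = set()
    for k in sorted(anchors):
        for j in adj[k]:
            for l in adj[k]:
                if j == l:
                    continue
                for i in adj[j]:
                    if i in (k, l):
                        continue
                    for m in adj[l]:
                        if m in (j, k, i):
                            continue
                        path = (i, j, k, l, m)
                        sites.add(min(path, path[::-1]))
    return sorted(sites)


def assign_cmap_crossterms(system: MolecularSystem, params) -> None:
    """Attach CMAP grids to φ/ψ dihedral pairs whose type octuple matches a
    grid's ``type_key`` (CHARMM-style per-dihedral-type assignment);
    wildcard slots in the key match any type."""
    grids = [g for g in getattr(params, "cmaps", [])
             if g.type_key is not None]
    if not grids:
        return
    types = [a.type for a in system.atoms]
    system.cmap_terms = []

    def matches(key, okt):
        return all(k == WILDCARD or k == t for k, t in zip(key, okt))

    for g in grids:
        anchor_type = g.type_key[2]
        anchors = [idx for idx, t in enumerate(types) if t == anchor_type]
        for (i, j, k, l, m) in enumerate_cmap_sites(system, anchors):
            okt = (types[i], types[j], types[k], types[l],
                   types[j], types[k], types[l], types[m])
            if matches(g.type_key, okt):
                system.cmap_terms.append(((i, j, k, l), (j, k, l, m), g))


# ---------------------------------------------------------------------------
# X-PLOR PSF
# ---------------------------------------------------------------------------

_PSF_TYPE_WIDTH = 10


def write_xplor_psf(system: MolecularSystem) -> str:
    """Serialise to X-PLOR-dialect PSF with EXT-style wide columns.

    Atoms are identified by type *name*; an over-wide type name is an
    error rather than a truncation.
    """
    for a in system.atoms:
        if len(a.type) > _PSF_TYPE_WIDTH:
            raise BuildError(f"atom type {a.type!r} exceeds PSF column "
                             f"width {_PSF_TYPE_WIDTH}")
    out = ["PSF EXT CMAP XPLOR", "", f"{1:10d} !NTITLE",
           " REMARKS ffport-generated X-PLOR PSF", ""]
    out.append(f"{system.n_atoms:10d} !NATOM")
    for idx, a in enumerate(system.atoms, start=1):
        out.append(f"{idx:10d} {a.segid:<8.8s} {a.resid:<8d} "
                   f"{a.resname:<8.8s} {a.name:<8.8s} "
                   f"{a.type:<{_PSF_TYPE_WIDTH}s} {a.charge: 24.16E}"
                   f"{a.mass: 24.16E}{0:12d}")
    out.append("")

    def block(label, tuples, per_line):
        out.append(f"{len(tuples):10d} !{label}")
        flat = [i + 1 for tup in tuples for i in tup]
        width = per_line * len(tuples[0]) if tuples else 8
        for off in range(0, len(flat), width):
            out.append("".join(f"{v:10d}" for v in flat[off:off + width]))
        if not flat:
            out.append("")
        out.append("")

    block("NBOND: bonds", [tuple(b) for b in system.bonds], 4)
    block("NTHETA: angles", [tuple(a) for a in system.angles], 3)
    block("NPHI: dihedrals", [tuple(d) for d in system.dihedrals], 2)
    block("NIMPHI: impropers", [tuple(i) for i in system.impropers], 2)
    cross = [tuple(a) + (b[3],) + tuple(b) for a, b, _ in system.cmap_terms]
    # NAMD convention: eight atom indices per crossterm (two dihedrals)
    cross8 = [tuple(a) + tuple(b) for a, b, _ in system.cmap_terms]
    out.append(f"{len(cross8):10d} !NCRTERM: cross-terms")
    for tup in cross8:
        out.append("".join(f"{v + 1:10d}" for v in tup))
    out.append("")
    _ = cross
    return "\n".join(out) + "\n"


def read_xplor_psf(stream) -> MolecularSystem:
    """Read the PSF dialect written by :func:`write_xplor_psf`."""
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").split("\n")
    system = MolecularSystem()
    i = 0
    counts = {}
    while i < len(lines):
        line = lines[i]
        if "!" in line:
            head = line.split("!")[1].split(":")[0].strip()
            n = int(line.split("!")[0])
            counts[head] = n
            if head == "NATOM":
                for k in range(n):
                    f = lines[i + 1 + k].split()
                    system.atoms.append(Atom(
                        segid=f[1], resid=int(f[2]), resname=f[3],
                        name=f[4], type=f[5], charge=float(f[6]),
                        mass=float(f[7])))
                i += n
            elif head in ("NBOND", "NTHETA", "NPHI", "NIMPHI", "NCRTERM"):
                arity = {"NBOND": 2, "NTHETA": 3, "NPHI": 4,
                         "NIMPHI": 4, "NCRTERM": 8}[head]
                vals = []
                j = i + 1
                while j < len(lines) and len(vals) < n * arity:
                    vals.extend(int(v) for v in lines[j].split())
                    j += 1
                tuples = [tuple(v - 1 for v in vals[off:off + arity])
                          for off in range(0, n * arity, arity)]
                if head == "NBOND":
                    system.bonds = tuples
                elif head == "NTHETA":
                    system.angles = tuples
                elif head == "NPHI":
                    system.dihedrals = tuples
                elif head == "NIMPHI":
                    system.impropers = tuples
                else:
                    system.cmap_terms = [(t[:4], t[4:], None) for t in tuples]
                i = j - 1
        i += 1
    return system
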