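"""Synthetic force-field and molecule generator plus independent oracles.

Everything the test suite needs is generated here from a seed: small
AMBER-format file bundles (DAT, FRCMOD, OFF/LIB, PRMTOP, RST7) with
ground truth attached, chemically abstract toy molecules built from
residue templates, and a brute-force energy evaluator that shares no code
with the main evaluator.

The generated conditions mirror the validation protocol this package
supports: exotic atom-type names (lowercase, digits, ``*``, ``+``,
trailing spaces), multiterm dihedrals with PK/IDIVF semantics, wildcard
dihedral entries shadowed by exact ones, optionally a per-residue CMAP
grid and a mixed-SCNB motif in which the same end-type pair experiences
two different 1-4 van-der-Waals scalings on different atom instances.
Identical seeds yield byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEG2RAD, PRMTOP_CHARGE_SCALE
from .core import (AngleParam, BondParam, CmapGrid, DihedralTerm, LJParam,
                   MolecularSystem, ParametrizedSystem, RawParameterSet,
                   ResidueTemplate, TemplateAtom, WILDCARD, angle_key,
                   bond_key, dihedral_key, pair)
from .ff_translate import emulate_tleap_improper_order
from .topology_builder import (assign_parameters, build_exclusions,
                               build_segment, enumerate_cmap_sites)

#: default bondable two-character type palette (uppercase, lowercase,
#: digit, asterisk, trailing space) plus a symbol-bearing ion type
BONDABLE_PALETTE = ("CT", "C ", "cg", "N3", "C*", "OS", "h1", "OH")
ION_TYPE = "Na+"


def _q(v: float) -> float:
    """Quantise to 9 significant digits so every serialiser round-trips."""
    return float(f"{v:.9G}")


def _q_charge(q: float) -> float:
    """Quantise a charge through its PRMTOP representation (q·18.2223 in an
    E16.8 field) so the PRMTOP route recovers the template value exactly."""
    return float(f"{q * PRMTOP_CHARGE_SCALE:.8E}") / PRMTOP_CHARGE_SCALE


def _qa(arr) -> np.ndarray:
    return np.array([_q(v) for v in np.asarray(arr).reshape(-1)],
                    dtype=float).reshape(np.shape(arr))


@dataclass
class FixtureSpec:
    seed: int = 0
    palette: tuple = BONDABLE_PALETTE
    n_residues: int = 3
    atoms_per_residue: int = 4        # backbone atoms; one branch atom added
    include_mixed_scnb: bool = False
    include_cmap: bool = False
    cmap_resolution: int = 8
    jitter: float = 0.1               # Å, conformational noise on templates


@dataclass
class ForcefieldFixture:
    dat: str
    frcmod: str
    lib: str
    raw: RawParameterSet              # ground truth (DAT merged with FRCMOD)
    templates: dict                   # name → ResidueTemplate (ground truth)
    sequence: list                    # residue names of the reference chain


@dataclass
class SystemFixture:
    system: MolecularSystem           # template route, raw types
    prmtop: str
    rst7: str


# ---------------------------------------------------------------------------
# residue templates
# ---------------------------------------------------------------------------

def _make_templates(spec: FixtureSpec, rng) -> tuple:
    if not spec.palette:
        raise ValueError("type palette must not be empty")
    n_tpl = max(1, min(3, spec.n_residues))
    templates = {}
    for t in range(n_tpl):
        name = f"T{t}"
        nb = max(3, spec.atoms_per_residue)
        atoms, bonds, coords = [], [], {}
        for i in range(nb):
            aname = f"A{i + 1}"
            atype = spec.palette[int(rng.integers(len(spec.palette)))]
            atoms.append(TemplateAtom(aname, atype,
                                      _q_charge(rng.uniform(-0.4, 0.4))))
            coords[aname] = tuple(_qa([
                1.35 * i, 0.45 * (i % 2) + 0.05 * rng.standard_normal(),
                0.15 * i + 0.05 * rng.standard_normal()]))
            if i:
                bonds.append((f"A{i}", aname))
        # branch atom on A2 creates an improper centre
        btype = spec.palette[int(rng.integers(len(spec.palette)))]
        atoms.append(TemplateAtom("B1", btype,
                                  _q_charge(rng.uniform(-0.4, 0.4))))
        bonds.append(("A2", "B1"))
        coords["B1"] = tuple(_qa([1.35, -0.9 + 0.05 * rng.standard_normal(),
                                  0.8]))
        tpl = ResidueTemplate(name=name, atoms=atoms, bonds=bonds,
                              head="A1", tail=f"A{nb}", coords=coords)
        type_of = {a.name: a.type for a in atoms}
        quad_names = ("A1", "A3", "A2", "B1")          # centre third
        quad_types = tuple(type_of[n] for n in quad_names)
        _, order = emulate_tleap_improper_order(quad_types,
                                                atom_indices=quad_names)
        tpl.impropers.append(order)
        templates[name] = tpl

    sequence = [f"T{i % n_tpl}" for i in range(spec.n_residues)]

    # the grid's owner must occur at an interior chain position so a
    # five-atom φ/ψ path exists around its anchor
    cmap_residue = sequence[1] if len(sequence) > 1 else sequence[0]
    if spec.include_cmap:
        templates[cmap_residue].cmap_anchor = "A2"

    if spec.include_mixed_scnb:
        # two four-atom paths with identical end types (qa, qd) so the same
        # type pair needs SCNB 2.0 on one atom pair and 1.2 on another
        mixed_types = ["qa", "qb", "qc", "qd", "qa", "qe", "qf", "qd"]
        atoms, bonds, coords = [], [], {}
        for i, ty in enumerate(mixed_types):
            aname = f"P{i + 1}"
            atoms.append(TemplateAtom(aname, ty,
                                      _q_charge(rng.uniform(-0.3, 0.3))))
            coords[aname] = tuple(_qa([
                1.4 * i, 0.5 * (i % 2) + 0.05 * rng.standard_normal(),
                -0.1 * i]))
            if i:
                bonds.append((f"P{i}", aname))
        templates["MIX"] = ResidueTemplate(
            name="MIX", atoms=atoms, bonds=bonds, head="P1", tail="P8",
            coords=coords)
        sequence.append("MIX")

    # single-atom ion residue: exercises symbol-bearing raw types in OFF
    templates["ION"] = ResidueTemplate(
        name="ION", atoms=[TemplateAtom("NA", ION_TYPE, 1.0)],
        coords={"NA": (0.0, 0.0, 0.0)})
    return templates, sequence


# ---------------------------------------------------------------------------
# force-field generation
# ---------------------------------------------------------------------------

def gen_forcefield(spec: FixtureSpec) -> ForcefieldFixture:
    """Generate a synthetic force field whose emitted AMBER-format files
    re-parse to exactly the attached ground truth."""
    rng = np.random.default_rng(spec.seed)
    templates, sequence = _make_templates(spec, rng)
    ref = build_segment(templates, sequence)
    types = [a.type for a in ref.atoms]

    raw = RawParameterSet()
    for t in sorted({a.type for tpl in templates.values()
                     for a in tpl.atoms}):
        raw.atom_types.add(t)
        raw.masses[t] = _q(rng.uniform(10.0, 32.0))
        raw.lj[t] = LJParam(_q(rng.uniform(0.05, 0.3)),
                            _q(rng.uniform(1.0, 1.7)))

    for i, j in ref.bonds:
        key = bond_key(types[i], types[j])
        if key not in raw.bonds:
            raw.bonds[key] = BondParam(_q(rng.uniform(200, 400)),
                                       _q(rng.uniform(1.2, 1.6)))
    for i, j, k in ref.angles:
        key = angle_key(types[i], types[j], types[k])
        if key not in raw.angles:
            raw.angles[key] = AngleParam(_q(rng.uniform(30, 80)),
                                         _q(rng.uniform(100, 120)))

    mixed_quads = {dihedral_key("qa", "qb", "qc", "qd"): 2.0,
                   dihedral_key("qa", "qe", "qf", "qd"): 1.2}
    quad_keys = []
    for quad in ref.dihedrals:
        key = dihedral_key(*(types[x] for x in quad))
        if key not in quad_keys:
            quad_keys.append(key)
    # one non-mixed quadruple is served by a wildcard entry instead of an
    # exact one (exercises wildcard fallback without shadowing ambiguity)
    wildcard_victim = None
    for key in reversed(quad_keys):
        middle = (key[1], key[2])
        if key in mixed_quads:
            continue
        others = [k for k in quad_keys
                  if k != key and (k[1], k[2]) in (middle, middle[::-1])]
        if all(o not in mixed_quads for o in others):
            wildcard_victim = key
            break
    for key in quad_keys:
        scnb = mixed_quads.get(key, 2.0)
        nterms = 2 if (rng.uniform() < 0.4 and key not in mixed_quads) else 1
        terms = [DihedralTerm(_q(rng.uniform(0.2, 2.5)),
                              int(rng.integers(1, 4)),
                              float(rng.choice([0.0, 180.0])),
                              1.2, scnb)
                 for _ in range(nterms)]
        if key == wildcard_victim:
            raw.dihedrals[dihedral_key(WILDCARD, key[1], key[2],
                                       WILDCARD)] = terms
        else:
            raw.dihedrals[key] = terms

    for quad in ref.impropers:
        key = tuple(types[x] for x in quad)
        if key not in raw.impropers:
            raw.impropers[key] = [DihedralTerm(_q(rng.uniform(1, 10)), 2,
                                               180.0)]

    frcmod_delta = RawParameterSet()
    if raw.bonds:
        first = sorted(raw.bonds)[0]
        old = raw.bonds[first]
        frcmod_delta.bonds[first] = BondParam(_q(old.k * 1.1), old.b0)
        frcmod_delta.atom_types.update(t for t in first if t != WILDCARD)
    if spec.include_cmap:
        res = max(4, spec.cmap_resolution)
        owner = next(name for name, tpl in templates.items()
                     if tpl.cmap_anchor is not None)
        grid = CmapGrid(res, _qa(rng.normal(0.0, 1.5, (res, res))),
                        residue=owner)
        frcmod_delta.cmaps.append(grid)

    truth = raw.merge(frcmod_delta)
    dat = serialize_parm_dat(raw, title=f"ffport synthetic parameters "
                                        f"(seed {spec.seed})")
    frcmod = serialize_frcmod(frcmod_delta,
                              title=f"ffport synthetic modifications "
                                    f"(seed {spec.seed})")
    lib = serialize_off_lib(templates)
    return ForcefieldFixture(dat=dat, frcmod=frcmod, lib=lib, raw=truth,
                             templates=templates, sequence=sequence)


# ---------------------------------------------------------------------------
# AMBER-format serialisers (independent of the parsers in amber_io)
# ---------------------------------------------------------------------------

def _t2(t: str) -> str:
    """Two-character bonded type field; the wildcard renders as ``X ``."""
    if t == WILDCARD:
        return "X "
    if len(t) != 2:
        raise ValueError(f"bonded type {t!r} must be two characters")
    return t


def serialize_parm_dat(raw: RawParameterSet, title="synthetic parm") -> str:
    out = [title]
    for t in sorted(raw.masses):
        out.append(f"{t:<4s}{raw.masses[t]:>16.9G}")
    out.append("")
    out.append(" ".join(sorted(t.strip() for t in raw.atom_types)) or "-")
    out.append("")
    for key in sorted(raw.bonds):
        bp = raw.bonds[key]
        out.append(f"{_t2(key[0])}-{_t2(key[1])}{bp.k:>16.9G}{bp.b0:>16.9G}")
    out.append("")
    for key in sorted(raw.angles):
        ap = raw.angles[key]
        out.append(f"{_t2(key[0])}-{_t2(key[1])}-{_t2(key[2])}"
                   f"{ap.k:>16.9G}{ap.theta0:>16.9G}")
    out.append("")
    for key in sorted(raw.dihedrals):
        terms = raw.dihedrals[key]
        for nth, t in enumerate(terms):
            pn = t.n if nth == len(terms) - 1 else -t.n
            idivf = 2 if nth % 2 else 1
            # PK = barrier × IDIVF; ten significant digits so halving on
            # re-parse reproduces the nine-digit barrier exactly
            out.append(
                "-".join(_t2(k) for k in key)
                + f"{idivf:>4d}{t.k * idivf:>17.10G}{t.phase:>10.3f}"
                + f"{pn:>6.1f}    SCEE={t.scee:G} SCNB={t.scnb:G}")
    out.append("")
    for key in sorted(raw.impropers):
        for t in raw.impropers[key]:
            out.append("-".join(_t2(k) for k in key)
                       + f"{t.k:>15.9G}{t.phase:>10.3f}{t.n:>6.1f}")
    out.append("")
    out.append("  HW  OW  0000.  0000.  4.")    # vestigial 10-12 block
    out.append("")
    out.append("")                              # equivalence block (empty)
    out.append("MOD4      RE")
    for t in sorted(raw.lj):
        lj = raw.lj[t]
        out.append(f"  {t:<4s}{lj.rmin_half:>16.9G}{lj.eps:>16.9G}")
    out.append("")
    out.append("END")
    return "\n".join(out) + "\n"


def serialize_frcmod(delta: RawParameterSet,
                     title="synthetic frcmod") -> str:
    out = [title]
    if delta.masses:
        out.append("MASS")
        for t in sorted(delta.masses):
            out.append(f"{t:<4s}{delta.masses[t]:>16.9G}")
        out.append("")
    if delta.bonds:
        out.append("BOND")
        for key in sorted(delta.bonds):
            bp = delta.bonds[key]
            out.append(f"{_t2(key[0])}-{_t2(key[1])}"
                       f"{bp.k:>16.9G}{bp.b0:>16.9G}")
        out.append("")
    if delta.angles:
        out.append("ANGLE")
        for key in sorted(delta.angles):
            ap = delta.angles[key]
            out.append(f"{_t2(key[0])}-{_t2(key[1])}-{_t2(key[2])}"
                       f"{ap.k:>16.9G}{ap.theta0:>16.9G}")
        out.append("")
    if delta.dihedrals:
        out.append("DIHE")
        for key in sorted(delta.dihedrals):
            terms = delta.dihedrals[key]
            for nth, t in enumerate(terms):
                pn = t.n if nth == len(terms) - 1 else -t.n
                out.append("-".join(_t2(k) for k in key)
                           + f"{1:>4d}{t.k:>15.9G}{t.phase:>10.3f}"
                           + f"{pn:>6.1f}    SCEE={t.scee:G} SCNB={t.scnb:G}")
        out.append("")
    if delta.impropers:
        out.append("IMPROPER")
        for key in sorted(delta.impropers):
            for t in delta.impropers[key]:
                out.append("-".join(_t2(k) for k in key)
                           + f"{t.k:>15.9G}{t.phase:>10.3f}{t.n:>6.1f}")
        out.append("")
    if delta.lj:
        out.append("NONBON")
        for t in sorted(delta.lj):
            lj = delta.lj[t]
            out.append(f"  {t:<4s}{lj.rmin_half:>16.9G}{lj.eps:>16.9G}")
        out.append("")
    if delta.cmaps:
        out.append("CMAP")
        out.append(f"%FLAG CMAP_COUNT {len(delta.cmaps)}")
        for g in delta.cmaps:
            out.append("%FLAG CMAP_RESLIST")
            out.append(g.residue)
            out.append(f"%FLAG CMAP_RESOLUTION {g.resolution}")
            out.append("%FLAG CMAP_PARAMETER")
            flat = g.values.reshape(-1)
            for off in range(0, flat.size, 8):
                out.append(" ".join(f"{v:.9G}" for v in flat[off:off + 8]))
        out.append("")
    out.append("END")
    return "\n".join(out) + "\n"


def serialize_off_lib(templates: dict) -> str:
    out = ["!!index array str"]
    for name in templates:
        out.append(f' "{name}"')
    for name, tpl in templates.items():
        out.append(f"!entry.{name}.unit.atoms table  str name  str type  "
                   "int typex  int resx  int flags  int seq  int elmnt  "
                   "dbl chg")
        for i, a in enumerate(tpl.atoms, start=1):
            out.append(f' "{a.name}" "{a.type}" 0 1 131072 {i} 6 '
                       f"{a.charge:.9G}")
        idx = {a.name: i + 1 for i, a in enumerate(tpl.atoms)}
        out.append(f"!entry.{name}.unit.connect array int")
        out.append(f" {idx.get(tpl.head, 0)}")
        out.append(f" {idx.get(tpl.tail, 0)}")
        if len(tpl.atoms) > 1:
            out.append(f"!entry.{name}.unit.connectivity table  int atom1x  "
                       "int atom2x  int flags")
            for n1, n2 in tpl.bonds:
                out.append(f" {idx[n1]} {idx[n2]} 1")
        out.append(f"!entry.{name}.unit.positions table  dbl x  dbl y  "
                   "dbl z")
        for a in tpl.atoms:
            x, y, z = tpl.coords.get(a.name, (0.0, 0.0, 0.0))
            out.append(f" {x:.9G} {y:.9G} {z:.9G}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# system generation and the PRMTOP serialiser
# ---------------------------------------------------------------------------

def gen_system(spec: FixtureSpec, ff: ForcefieldFixture,
               ab_precision: str = "full") -> SystemFixture:
    """Build the reference chain and serialise it as PRMTOP + RST7.

    The PRMTOP route and the template route describe the same physical
    system; with ``ab_precision='prmtop'`` the pair-coefficient table is
    rounded to the eight-decimal exponent fields real files use.
    """
    rng = np.random.default_rng(spec.seed + 1000)
    system = build_segment(ff.templates, ff.sequence)
    for a in system.atoms:
        a.mass = ff.raw.masses[a.type]
    if spec.jitter > 0:
        system.coords = system.coords + rng.normal(
            0.0, spec.jitter, system.coords.shape)
    # quantise to the RST7 field precision so the PRMTOP/RST7 route and the
    # template route evaluate identical coordinates
    system.coords = np.round(system.coords, 7)
    build_exclusions(system, ff.raw)
    for grid in ff.raw.cmaps:
        tpl = ff.templates.get(grid.residue)
        if tpl is None or tpl.cmap_anchor is None:
            raise ValueError(f"CMAP grid residue {grid.residue!r} has no "
                             "anchored template")
        anchors = [i for i, a in enumerate(system.atoms)
                   if a.resname == grid.residue and a.name == tpl.cmap_anchor]
        for site in enumerate_cmap_sites(system, anchors):
            system.cmap_terms.append((site[:4], site[1:], grid))
    prmtop = write_prmtop(system, ff.raw, ab_precision=ab_precision,
                          title=f"ffport synthetic system (seed {spec.seed})")
    rst7 = _write_rst7_local(system.coords)
    return SystemFixture(system=system, prmtop=prmtop, rst7=rst7)


def _write_rst7_local(coords) -> str:
    lines = ["ffport synthetic restart", f"{len(coords):6d}"]
    flat = np.asarray(coords).reshape(-1)
    for off in range(0, len(flat), 6):
        lines.append("".join(f"{v:12.7f}" for v in flat[off:off + 6]))
    return "\n".join(lines) + "\n"


def _fmt_section(flag, fmt, body_lines):
    return [f"%FLAG {flag}", f"%FORMAT({fmt})"] + (body_lines or [""])


def _chunk(values, per_line, fmt):
    lines = []
    for off in range(0, len(values), per_line):
        lines.append("".join(fmt(v) for v in values[off:off + per_line]))
    return lines


def write_prmtop(system: MolecularSystem, raw: RawParameterSet,
                 ab_precision: str = "full",
                 title: str = "ffport synthetic system") -> str:
    """Independent PRMTOP serialiser (fixture side; shares no code with
    the parser).  Charges are stored ×18.2223, angle minima and phases in
    radians, bonded records as 3·index with sign markers: negative third
    index = no 1-4 pair, negative fourth = improper."""
    ps = assign_parameters(system, raw)
    natom = system.n_atoms

    def table(params_list, keyfn):
        uniq, index = [], {}
        for p in params_list:
            k = keyfn(p)
            if k not in index:
                index[k] = len(uniq) + 1
                uniq.append(p)
        return uniq, index

    bond_params, bond_idx = table([bp for _, _, bp in ps.bond_terms],
                                  lambda p: (p.k, p.b0))
    ang_params, ang_idx = table([ap for *_, ap in ps.angle_terms],
                                lambda p: (p.k, p.theta0))
    dih_all = [t for *_, t in ps.dihedral_terms] + \
              [t for *_, t in ps.improper_terms]
    dih_params, dih_idx = table(dih_all,
                                lambda p: (p.k, p.n, p.phase, p.scee, p.scnb))

    bond_rec = []
    for i, j, bp in ps.bond_terms:
        bond_rec += [3 * i, 3 * j, bond_idx[(bp.k, bp.b0)]]
    ang_rec = []
    for i, j, k, ap in ps.angle_terms:
        ang_rec += [3 * i, 3 * j, 3 * k, ang_idx[(ap.k, ap.theta0)]]

    dih_rec = []
    emitted14 = set()
    for i, j, k, l, t in ps.dihedral_terms:
        pidx = dih_idx[(t.k, t.n, t.phase, t.scee, t.scnb)]
        p14 = pair(i, l)
        want14 = (p14 not in system.exclusions and p14 in system.scaled14
                  and p14 not in emitted14)
        if want14:
            emitted14.add(p14)
        if not want14 and k == 0:
            i, j, k, l = l, k, j, i     # negative marker cannot encode atom 0
        k3 = 3 * k if want14 else -3 * k
        dih_rec += [3 * i, 3 * j, k3, 3 * l, pidx]
    for i, j, k, l, t in ps.improper_terms:
        pidx = dih_idx[(t.k, t.n, t.phase, t.scee, t.scnb)]
        if k == 0 or l == 0:
            i, j, k, l = l, k, j, i     # torsion angle is reversal-invariant
        dih_rec += [3 * i, 3 * j, -3 * k, -3 * l, pidx]
    nrec = len(dih_rec) // 5

    # exclusion list (1-2, 1-3 and scaled 1-4 partners, AMBER layout)
    numex, exlist = [], []
    close = set(system.exclusions) | set(system.scaled14)
    for i in range(natom):
        partners = sorted(j for j in range(natom)
                          if j > i and pair(i, j) in close)
        if partners:
            numex.append(len(partners))
            exlist += [j + 1 for j in partners]
        else:
            numex.append(1)
            exlist.append(0)

    type_order = []
    for a in system.atoms:
        if a.type not in type_order:
            type_order.append(a.type)
    ntypes = len(type_order)
    tindex = {t: i + 1 for i, t in enumerate(type_order)}

    def ab_of(t1, t2):
        l1, l2 = raw.lj[t1], raw.lj[t2]
        eps = math.sqrt(l1.eps * l2.eps)
        rmin = l1.rmin_half + l2.rmin_half
        a = eps * rmin ** 12
        b = 2.0 * eps * rmin ** 6
        if ab_precision == "prmtop":
            a, b = float(f"{a:.8E}"), float(f"{b:.8E}")
        return a, b

    nb_index = [0] * (ntypes * ntypes)
    acoef, bcoef = [], []
    slot = 0
    for i in range(ntypes):
        for j in range(i + 1):
            slot += 1
            a, b = ab_of(type_order[j], type_order[i])
            acoef.append(a)
            bcoef.append(b)
            nb_index[ntypes * i + j] = slot
            nb_index[ntypes * j + i] = slot

    res_labels, res_ptr = [], []
    for i, a in enumerate(system.atoms):
        if not res_ptr or a.resid != system.atoms[i - 1].resid:
            res_labels.append(a.resname)
            res_ptr.append(i + 1)

    pointers = [0] * 31
    pointers[0] = natom
    pointers[1] = ntypes
    pointers[3] = len(ps.bond_terms)     # MBONA
    pointers[5] = len(ps.angle_terms)    # MTHETA
    pointers[7] = nrec                   # MPHIA
    pointers[10] = len(exlist)           # NNB
    pointers[11] = len(res_labels)       # NRES
    pointers[12] = len(ps.bond_terms)    # NBONA
    pointers[13] = len(ps.angle_terms)   # NTHETA
    pointers[14] = nrec                  # NPHIA
    pointers[15] = len(bond_params)
    pointers[16] = len(ang_params)
    pointers[17] = len(dih_params)
    pointers[18] = ntypes                # NATYP

    def i10(v):
        return f"{v:8d}"

    def e16(v):
        return f"{v:16.8E}"

    def e24(v):
        return f"{v:24.16E}"

    out = ["%VERSION  VERSION_STAMP = V0001.000  DATE = ffport"]
    out += _fmt_section("TITLE", "20a4", [title[:80]])
    out += _fmt_section("POINTERS", "10I8", _chunk(pointers, 10, i10))
    out += _fmt_section("ATOM_NAME", "20a4", _chunk(
        [f"{a.name:<4.4s}" for a in system.atoms], 20, str))
    out += _fmt_section("CHARGE", "5E16.8", _chunk(
        [a.charge * PRMTOP_CHARGE_SCALE for a in system.atoms], 5, e16))
    out += _fmt_section("MASS", "5E16.8", _chunk(
        [a.mass for a in system.atoms], 5, e16))
    out += _fmt_section("ATOM_TYPE_INDEX", "10I8", _chunk(
        [tindex[a.type] for a in system.atoms], 10, i10))
    out += _fmt_section("NUMBER_EXCLUDED_ATOMS", "10I8",
                        _chunk(numex, 10, i10))
    out += _fmt_section("EXCLUDED_ATOMS_LIST", "10I8",
                        _chunk(exlist, 10, i10))
    out += _fmt_section("NONBONDED_PARM_INDEX", "10I8",
                        _chunk(nb_index, 10, i10))
    out += _fmt_section("RESIDUE_LABEL", "20a4", _chunk(
        [f"{r:<4.4s}" for r in res_labels], 20, str))
    out += _fmt_section("RESIDUE_POINTER", "10I8", _chunk(res_ptr, 10, i10))
    out += _fmt_section("BOND_FORCE_CONSTANT", "3E24.16", _chunk(
        [bp.k for bp in bond_params], 3, e24))
    out += _fmt_section("BOND_EQUIL_VALUE", "3E24.16", _chunk(
        [bp.b0 for bp in bond_params], 3, e24))
    out += _fmt_section("ANGLE_FORCE_CONSTANT", "3E24.16", _chunk(
        [ap.k for ap in ang_params], 3, e24))
    out += _fmt_section("ANGLE_EQUIL_VALUE", "3E24.16", _chunk(
        [ap.theta0 * DEG2RAD for ap in ang_params], 3, e24))
    out += _fmt_section("DIHEDRAL_FORCE_CONSTANT", "3E24.16", _chunk(
        [t.k for t in dih_params], 3, e24))
    out += _fmt_section("DIHEDRAL_PERIODICITY", "3E24.16", _chunk(
        [float(t.n) for t in dih_params], 3, e24))
    out += _fmt_section("DIHEDRAL_PHASE", "3E24.16", _chunk(
        [t.phase * DEG2RAD for t in dih_params], 3, e24))
    out += _fmt_section("SCEE_SCALE_FACTOR", "3E24.16", _chunk(
        [t.scee for t in dih_params], 3, e24))
    out += _fmt_section("SCNB_SCALE_FACTOR", "3E24.16", _chunk(
        [t.scnb for t in dih_params], 3, e24))
    out += _fmt_section("LENNARD_JONES_ACOEF", "3E24.16", _chunk(
        acoef, 3, e24))
    out += _fmt_section("LENNARD_JONES_BCOEF", "3E24.16", _chunk(
        bcoef, 3, e24))
    out += _fmt_section("BONDS_INC_HYDROGEN", "10I8", _chunk([], 10, i10))
    out += _fmt_section("BONDS_WITHOUT_HYDROGEN", "10I8",
                        _chunk(bond_rec, 10, i10))
    out += _fmt_section("ANGLES_INC_HYDROGEN", "10I8", _chunk([], 10, i10))
    out += _fmt_section("ANGLES_WITHOUT_HYDROGEN", "10I8",
                        _chunk(ang_rec, 10, i10))
    out += _fmt_section("DIHEDRALS_INC_HYDROGEN", "10I8", _chunk([], 10, i10))
    out += _fmt_section("DIHEDRALS_WITHOUT_HYDROGEN", "10I8",
                        _chunk(dih_rec, 10, i10))
    out += _fmt_section("AMBER_ATOM_TYPE", "20a4", _chunk(
        [f"{a.type:<4.4s}" for a in system.atoms], 20, str))
    if system.cmap_terms:
        grids = []
        for _, _, g in system.cmap_terms:
            if not any(g is gg for gg in grids):
                grids.append(g)
        out += _fmt_section("CMAP_COUNT", "2I8",
                            [f"{len(system.cmap_terms):8d}"
                             f"{len(grids):8d}"])
        out += _fmt_section("CMAP_RESOLUTION", "20I4", _chunk(
            [g.resolution for g in grids], 20, lambda v: f"{v:4d}"))
        for gi, g in enumerate(grids):
            out += _fmt_section(f"CMAP_PARAMETER_{gi + 1:02d}", "8F16.9",
                                _chunk(list(g.values.reshape(-1)), 8,
                                       lambda v: f" {v:.9G}"))
        cmap_rec = []
        for qa, qb, g in system.cmap_terms:
            gi = next(n for n, gg in enumerate(grids) if gg is g)
            cmap_rec += [qa[0] + 1, qa[1] + 1, qa[2] + 1, qa[3] + 1,
                         qb[3] + 1, gi + 1]
        out += _fmt_section("CMAP_INDEX", "6I8", _chunk(cmap_rec, 6, i10))
    return "\n".join(out) + "\n"


def translated_route(ff: ForcefieldFixture, coords=None):
    """Run the full CHARMM-side pipeline on a fixture force field: encode
    types, translate, resolve mixed SCNB, re-key CMAPs, rebuild the chain,
    retype, derive exclusions/crossterms and bind parameters.

    Returns a :class:`ParametrizedSystem` ready for charmm-form
    evaluation; pass the raw route's coordinates for paired comparisons.
    """
    from .ff_translate import (apply_retyping, encode_system_types,
                               translate_pipeline)
    from .topology_builder import assign_cmap_crossterms
    cps, tpl2, enc, rules = translate_pipeline(ff.raw, ff.templates)
    system = build_segment(tpl2, ff.sequence)
    if coords is not None:
        system.coords = np.asarray(coords, dtype=float).copy()
    encode_system_types(system, enc)
    apply_retyping(system, rules)
    build_exclusions(system, cps)
    assign_cmap_crossterms(system, cps)
    for a in system.atoms:
        a.mass = cps.masses.get(cps.resolve_alias(a.type), a.mass)
    return assign_parameters(system, cps)


# ---------------------------------------------------------------------------
# brute-force energy oracle (no shared code with ffport.energy)
# ---------------------------------------------------------------------------

def _bf_dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle, praxeolitic formulation (independent of the main
    evaluator's lattice-vector formulation)."""
    b0 = [p0[x] - p1[x] for x in range(3)]
    b1 = [p2[x] - p1[x] for x in range(3)]
    b2 = [p3[x] - p2[x] for x in range(3)]
    nb1 = math.sqrt(sum(v * v for v in b1))
    b1 = [v / nb1 for v in b1]
    dot0 = sum(b0[x] * b1[x] for x in range(3))
    dot2 = sum(b2[x] * b1[x] for x in range(3))
    v = [b0[x] - dot0 * b1[x] for x in range(3)]
    w = [b2[x] - dot2 * b1[x] for x in range(3)]
    xx = sum(v[i] * w[i] for i in range(3))
    cross = [b1[1] * v[2] - b1[2] * v[1],
             b1[2] * v[0] - b1[0] * v[2],
             b1[0] * v[1] - b1[1] * v[0]]
    yy = sum(cross[i] * w[i] for i in range(3))
    return -math.atan2(yy, xx)


def bf_cmap(grid: CmapGrid, phi_deg: float, psi_deg: float) -> float:
    """Independent bicubic interpolation: solves the 16 Hermite conditions
    of the query cell as a dense linear system."""
    res = grid.resolution
    h = 360.0 / res
    f = np.asarray(grid.values)

    def wrap(i):
        return i % res

    def deriv(i, j):
        fx = (f[wrap(i + 1), j] - f[wrap(i - 1), j]) / 2.0
        fy = (f[i, wrap(j + 1)] - f[i, wrap(j - 1)]) / 2.0
        fxy = (f[wrap(i + 1), wrap(j + 1)] - f[wrap(i + 1), wrap(j - 1)]
               - f[wrap(i - 1), wrap(j + 1)]
               + f[wrap(i - 1), wrap(j - 1)]) / 4.0
        return fx, fy, fxy

    u = (phi_deg + 180.0) / h
    v = (psi_deg + 180.0) / h
    i0 = int(math.floor(u)) % res
    j0 = int(math.floor(v)) % res
    t = u - math.floor(u)
    s = v - math.floor(v)
    rows, rhs = [], []
    for (ci, cj, tt, ss) in ((i0, j0, 0.0, 1.0), (i0, wrap(j0 + 1), 0.0, 0.0),
                             (wrap(i0 + 1), j0, 1.0, 0.0),
                             (wrap(i0 + 1), wrap(j0 + 1), 1.0, 1.0)):
        tt = 0.0 if ci == i0 else 1.0
        ss = 0.0 if cj == j0 else 1.0
        fx, fy, fxy = deriv(ci, cj)
        val = [tt ** a * ss ** b for a in range(4) for b in range(4)]
        dfdx = [(a * tt ** (a - 1) if a else 0.0) * ss ** b
                for a in range(4) for b in range(4)]
        dfdy = [tt ** a * (b * ss ** (b - 1) if b else 0.0)
                for a in range(4) for b in range(4)]
        dfdxy = [(a * tt ** (a - 1) if a else 0.0)
                 * (b * ss ** (b - 1) if b else 0.0)
                 for a in range(4) for b in range(4)]
        rows += [val, dfdx, dfdy, dfdxy]
        rhs += [f[ci, cj], fx, fy, fxy]
    coeff = np.linalg.solve(np.array(rows), np.array(rhs))
    return float(sum(coeff[4 * a + b] * t ** a * s ** b
                     for a in range(4) for b in range(4)))


def brute_force_energy(ps: ParametrizedSystem, opts):
    """Direct re-evaluation of every term, independently coded.

    Returns an :class:`EnergyBreakdown`-compatible object computed from
    plain-Python loops; used as the oracle the main evaluator must match.
    """
    from .core import EnergyBreakdown
    system = ps.system
    if system.n_atoms > 1000:
        raise ValueError("oracle is for small fixtures (≤ 1000 atoms)")
    x = [tuple(map(float, row)) for row in system.coords]
    e = EnergyBreakdown()

    def dist(i, j):
        return math.sqrt(sum((x[i][d] - x[j][d]) ** 2 for d in range(3)))

    for i, j, bp in ps.bond_terms:
        e.bond += bp.k * (dist(i, j) - bp.b0) ** 2
    for i, j, k, ap in ps.angle_terms:
        v1 = [x[i][d] - x[j][d] for d in range(3)]
        v2 = [x[k][d] - x[j][d] for d in range(3)]
        c = (sum(a * b for a, b in zip(v1, v2))
             / math.sqrt(sum(a * a for a in v1))
             / math.sqrt(sum(b * b for b in v2)))
        th = math.acos(max(-1.0, min(1.0, c)))
        e.angle += ap.k * (th - math.radians(ap.theta0)) ** 2
    for i, j, k, l, t in list(ps.dihedral_terms) + list(ps.improper_terms):
        chi = _bf_dihedral(x[i], x[j], x[k], x[l])
        e.dihedral += t.k * (1.0 + math.cos(t.n * chi
                                            - math.radians(t.phase)))
    for qa, qb, grid in ps.cmap_assignments:
        phi = math.degrees(_bf_dihedral(*(x[i] for i in qa)))
        psi = math.degrees(_bf_dihedral(*(x[i] for i in qb)))
        e.cmap += bf_cmap(grid, phi, psi)

    def lj_ab(t1, t2, one4, scnb):
        if opts.convention == "amber":
            if ps.ab_table is not None:
                a, b = ps.ab_table[tuple(sorted((t1, t2)))]
            else:
                p1, p2 = ps.lj[t1], ps.lj[t2]
                eps = math.sqrt(p1.eps * p2.eps)
                rmin = p1.rmin_half + p2.rmin_half
                a, b = eps * rmin ** 12, 2 * eps * rmin ** 6
            return (a / scnb, b / scnb) if one4 else (a, b)
        key = tuple(sorted((t1, t2)))
        fx = ps.nbfix.get(key)
        if one4:
            if fx is not None:
                eps, rmin = fx.eps14, fx.rmin14
            else:
                p1, p2 = ps.lj14[t1], ps.lj14[t2]
                eps = math.sqrt(p1.eps * p2.eps)
                rmin = p1.rmin_half + p2.rmin_half
        else:
            if fx is not None:
                eps, rmin = fx.eps, fx.rmin
            else:
                p1, p2 = ps.lj[t1], ps.lj[t2]
                eps = math.sqrt(p1.eps * p2.eps)
                rmin = p1.rmin_half + p2.rmin_half
        return eps * rmin ** 12, 2 * eps * rmin ** 6

    kq = opts.coulomb_constant / opts.dielectric
    n = system.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            pr = frozenset((i, j))
            if pr in system.exclusions:
                continue
            r = dist(i, j)
            if opts.cutoff is not None and r > opts.cutoff:
                continue
            if pr in system.scaled14:
                scee, scnb = system.scaled14[pr]
                a, b = lj_ab(system.atoms[i].type, system.atoms[j].type,
                             True, scnb)
                e.vdw14 += a / r ** 12 - b / r ** 6
                if opts.convention == "amber":
                    e.elec14 += (kq * system.atoms[i].charge
                                 * system.atoms[j].charge / (r * scee))
                else:
                    e.elec14 += (kq * system.atoms[i].charge
                                 * system.atoms[j].charge
                                 * opts.scaling14 / r)
            else:
                a, b = lj_ab(system.atoms[i].type, system.atoms[j].type,
                             False, 2.0)
                e.vdw += a / r ** 12 - b / r ** 6
                e.elec += (kq * system.atoms[i].charge
                           * system.atoms[j].charge / r)
    return e
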