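"""Readers for AMBER-format force-field and topology files.

Covers the fixed-column PRMTOP (``%VERSION``/``%FLAG``/``%FORMAT``
records), parm DAT parameter files, FRCMOD modification files (including
CMAP blocks), OFF/LIB residue templates and ASCII RST7 restart
coordinates.  All parsers accept LF and CRLF line endings.

PRMTOP allocates eight digits per integer, so no stored value may reach
100 million; with coordinate array indices N = 3(A−1) the format tops out
near 33 million atoms.  ``validate_prmtop_capacity`` makes that bound
queryable and the section parsers enforce the eight-digit limit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .constants import PRMTOP_CHARGE_SCALE, PRMTOP_MAX_INT
from .core import (Atom, AngleParam, BondParam, CmapGrid, DihedralTerm,
                   LJParam, MolecularSystem, ParametrizedSystem,
                   RawParameterSet, ResidueTemplate, TemplateAtom, WILDCARD,
                   angle_key, bond_key, dihedral_key, pair)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; message names the offending section/line."""


# ---------------------------------------------------------------------------
# capacity check
# ---------------------------------------------------------------------------

def validate_prmtop_capacity(atom_count: int):
    """Whether ``atom_count`` atoms fit in PRMTOP's eight-digit fields.

    The limiting quantity is the largest coordinate-array index
    N = 3(A − 1); returns ``(fits, N)``.
    """
    if atom_count < 1:
        raise ValueError("atom_count must be ≥ 1")
    limiting = 3 * (atom_count - 1)
    return limiting <= PRMTOP_MAX_INT, limiting


def max_prmtop_atoms() -> int:
    """Largest atom count whose coordinate indices stay within 8 digits."""
    return PRMTOP_MAX_INT // 3 + 1


# ---------------------------------------------------------------------------
# PRMTOP
# ---------------------------------------------------------------------------

_FORMAT_RE = re.compile(
    r"%FORMAT\(\s*(\d+)([aIEFG])(\d+)(?:\.(\d+))?\s*\)", re.IGNORECASE)


@dataclass
class PrmtopSection:
    flag: str
    count_per_line: int
    kind: str          # 'a', 'I', 'E', 'F', 'G'
    width: int
    precision: int
    raw_lines: list = field(default_factory=list)

    def strings(self):
        out = []
        for line in self.raw_lines:
            for off in range(0, len(line), self.width):
                out.append(line[off:off + self.width])
        return out

    def integers(self):
        vals = []
        for ln, line in enumerate(self.raw_lines):
            for tok in line.split():
                try:
                    v = int(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"section {self.flag}, line {ln + 1}: "
                        f"bad integer {tok!r}") from exc
                if not -PRMTOP_MAX_INT <= v <= PRMTOP_MAX_INT:
                    raise FormatError(
                        f"section {self.flag}, line {ln + 1}: integer {v} "
                        f"overflows the eight-digit PRMTOP field")
                vals.append(v)
        return vals

    def floats(self):
        vals = []
        for ln, line in enumerate(self.raw_lines):
            for tok in line.split():
                try:
                    vals.append(float(tok))
                except ValueError as exc:
                    raise FormatError(
                        f"section {self.flag}, line {ln + 1}: "
                        f"bad float {tok!r}") from exc
        return vals


@dataclass
class PrmtopDocument:
    version_stamp: str
    sections: dict    # flag → PrmtopSection, insertion-ordered

    def require(self, flag: str) -> PrmtopSection:
        if flag not in self.sections:
            raise FormatError(f"PRMTOP is missing required section {flag}")
        return self.sections[flag]


def read_prmtop_document(stream) -> PrmtopDocument:
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").split("\n")
    version = ""
    sections = {}
    current = None
    pending_flag = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("%VERSION"):
            version = line[8:].strip()
        elif line.startswith("%FLAG"):
            pending_flag = line[5:].strip()
            current = None
        elif line.startswith("%FORMAT"):
            m = _FORMAT_RE.match(line.strip())
            if not m or pending_flag is None:
                raise FormatError(f"line {lineno}: malformed %FORMAT record")
            cnt, kind, width, prec = m.groups()
            current = PrmtopSection(pending_flag, int(cnt), kind,
                                    int(width), int(prec or 0))
            sections[pending_flag] = current
            pending_flag = None
        elif line.startswith("%"):
            continue
        elif current is not None:
            current.raw_lines.append(line)
    if not sections:
        raise FormatError("no %FLAG sections found; not a PRMTOP")
    return PrmtopDocument(version, sections)


# POINTERS offsets (AMBER convention)
_PTR = {"NATOM": 0, "NTYPES": 1, "NBONH": 2, "MBONA": 3, "NTHETH": 4,
        "MTHETA": 5, "NPHIH": 6, "MPHIA": 7, "NNB": 10, "NRES": 11,
        "NUMBND": 15, "NUMANG": 16, "NPTRA": 17}


def parse_prmtop(stream):
    """Parse a PRMTOP into ``(MolecularSystem, RawParameterSet)``.

    Charges are returned in e (the stored values are premultiplied by
    √k_C = 18.2223); dihedral records with a negative third atom index are
    multiterm/ring duplicates carrying no 1-4 pair, and a negative fourth
    index marks a sinusoidal improper.  Precomputed A/B pair coefficients
    are kept verbatim in ``RawParameterSet.pair_coeffs``.
    """
    doc = read_prmtop_document(stream)
    ptrs = doc.require("POINTERS").integers()
    if len(ptrs) < 18:
        raise FormatError("POINTERS section too short")
    p = {k: ptrs[v] for k, v in _PTR.items()}
    natom = p["NATOM"]

    def ints(flag, n):
        vals = doc.require(flag).integers()
        if len(vals) != n:
            raise FormatError(
                f"section {flag}: expected {n} values per POINTERS, "
                f"got {len(vals)}")
        return vals

    def flts(flag, n):
        vals = doc.require(flag).floats()
        if len(vals) != n:
            raise FormatError(
                f"section {flag}: expected {n} values per POINTERS, "
                f"got {len(vals)}")
        return vals

    names = [s.rstrip() for s in doc.require("ATOM_NAME").strings()][:natom]
    charges_raw = flts("CHARGE", natom)
    masses = flts("MASS", natom)
    type_idx = ints("ATOM_TYPE_INDEX", natom)
    type_names = [s.rstrip()
                  for s in doc.require("AMBER_ATOM_TYPE").strings()][:natom]
    res_labels = [s.rstrip()
                  for s in doc.require("RESIDUE_LABEL").strings()][:p["NRES"]]
    res_ptr = ints("RESIDUE_POINTER", p["NRES"])

    system = MolecularSystem()
    res_of = np.zeros(natom, dtype=int)
    for r, start in enumerate(res_ptr):
        end = res_ptr[r + 1] - 1 if r + 1 < len(res_ptr) else natom
        res_of[start - 1:end] = r
    for i in range(natom):
        r = res_of[i]
        system.atoms.append(Atom(
            segid="PRM", resname=res_labels[r], resid=r + 1,
            name=names[i], type=type_names[i],
            charge=charges_raw[i] / PRMTOP_CHARGE_SCALE, mass=masses[i]))

    raw = RawParameterSet()
    raw.atom_types = set(type_names)
    for i, t in enumerate(type_names):
        raw.masses.setdefault(t, masses[i])

    bond_k = flts("BOND_FORCE_CONSTANT", p["NUMBND"])
    bond_b0 = flts("BOND_EQUIL_VALUE", p["NUMBND"])
    ang_k = flts("ANGLE_FORCE_CONSTANT", p["NUMANG"])
    ang_t0 = flts("ANGLE_EQUIL_VALUE", p["NUMANG"])      # radians in PRMTOP
    dih_k = flts("DIHEDRAL_FORCE_CONSTANT", p["NPTRA"])
    dih_n = flts("DIHEDRAL_PERIODICITY", p["NPTRA"])
    dih_ph = flts("DIHEDRAL_PHASE", p["NPTRA"])          # radians in PRMTOP
    scee = flts("SCEE_SCALE_FACTOR", p["NPTRA"]) if \
        "SCEE_SCALE_FACTOR" in doc.sections else [1.2] * p["NPTRA"]
    scnb = flts("SCNB_SCALE_FACTOR", p["NPTRA"]) if \
        "SCNB_SCALE_FACTOR" in doc.sections else [2.0] * p["NPTRA"]
    for s in scee + scnb:
        if s <= 0:
            raise FormatError("non-positive SCEE/SCNB scale factor")

    bond_terms, angle_terms, dihedral_terms, improper_terms = [], [], [], []
    rad2deg = 180.0 / np.pi

    def decode_bonds(flag, n):
        vals = ints(flag, 3 * n)
        for off in range(0, len(vals), 3):
            i, j, pidx = vals[off] // 3, vals[off + 1] // 3, vals[off + 2]
            bp = BondParam(bond_k[pidx - 1], bond_b0[pidx - 1])
            system.bonds.append((i, j))
            bond_terms.append((i, j, bp))
            raw.bonds.setdefault(
                bond_key(type_names[i], type_names[j]), bp)

    def decode_angles(flag, n):
        vals = ints(flag, 4 * n)
        for off in range(0, len(vals), 4):
            i, j, k = (vals[off] // 3, vals[off + 1] // 3, vals[off + 2] // 3)
            pidx = vals[off + 3]
            ap = AngleParam(ang_k[pidx - 1], ang_t0[pidx - 1] * rad2deg)
            system.angles.append((i, j, k))
            angle_terms.append((i, j, k, ap))
            raw.angles.setdefault(
                angle_key(type_names[i], type_names[j], type_names[k]), ap)

    scaled14 = {}

    def decode_dihedrals(flag, n):
        vals = ints(flag, 5 * n)
        for off in range(0, len(vals), 5):
            i3, j3, k3, l3, pidx = vals[off:off + 5]
            i, j = i3 // 3, j3 // 3
            k, l = abs(k3) // 3, abs(l3) // 3
            term = DihedralTerm(dih_k[pidx - 1], int(round(dih_n[pidx - 1])),
                                dih_ph[pidx - 1] * rad2deg,
                                scee[pidx - 1], scnb[pidx - 1])
            if l3 < 0:
                system.impropers.append((i, j, k, l))
                improper_terms.append((i, j, k, l, term))
                okey = (type_names[i], type_names[j],
                        type_names[k], type_names[l])
                raw.impropers.setdefault(okey, []).append(term)
            else:
                if (i, j, k, l) not in _seen_quads:
                    system.dihedrals.append((i, j, k, l))
                    _seen_quads.add((i, j, k, l))
                    _seen_quads.add((l, k, j, i))
                dihedral_terms.append((i, j, k, l, term))
                dkey = dihedral_key(type_names[i], type_names[j],
                                    type_names[k], type_names[l])
                terms = raw.dihedrals.setdefault(dkey, [])
                if term not in terms:
                    terms.append(term)
                if k3 >= 0:
                    scaled14[pair(i, l)] = (scee[pidx - 1], scnb[pidx - 1])

    _seen_quads = set()
    decode_bonds("BONDS_INC_HYDROGEN", p["NBONH"])
    decode_bonds("BONDS_WITHOUT_HYDROGEN", p["NBONA"] if "NBONA" in p
                 else p["MBONA"])
    decode_angles("ANGLES_INC_HYDROGEN", p["NTHETH"])
    decode_angles("ANGLES_WITHOUT_HYDROGEN", p["MTHETA"])
    decode_dihedrals("DIHEDRALS_INC_HYDROGEN", p["NPHIH"])
    decode_dihedrals("DIHEDRALS_WITHOUT_HYDROGEN", p["MPHIA"])

    # exclusions: 1-2 and 1-3 from the bonded lists
    for i, j in system.bonds:
        system.exclusions.add(pair(i, j))
    for i, j, k in system.angles:
        system.exclusions.add(pair(i, k))
    for pr, s in scaled14.items():
        if pr not in system.exclusions:
            system.scaled14[pr] = s

    # LJ: per-type diagonal parameters and the verbatim pair table
    ntypes = p["NTYPES"]
    nb_idx = ints("NONBONDED_PARM_INDEX", ntypes * ntypes)
    acoef = doc.require("LENNARD_JONES_ACOEF").floats()
    bcoef = doc.require("LENNARD_JONES_BCOEF").floats()
    idx_of_type = {}
    for i, t in enumerate(type_names):
        idx_of_type.setdefault(t, type_idx[i] - 1)
    pair_coeffs = {}
    for t1, i1 in idx_of_type.items():
        for t2, i2 in idx_of_type.items():
            if t1 > t2:
                continue
            nb = nb_idx[ntypes * i1 + i2] - 1
            pair_coeffs[(t1, t2)] = (acoef[nb], bcoef[nb])
    raw.pair_coeffs = pair_coeffs
    for t, i1 in idx_of_type.items():
        a, b = pair_coeffs[(t, t)]
        if b > 0 and a > 0:
            rmin = (2.0 * a / b) ** (1.0 / 6.0)
            raw.lj[t] = LJParam(b * b / (4.0 * a), rmin / 2.0)
        else:
            raw.lj[t] = LJParam(0.0, 0.0)

    # optional CMAP sections (CMAP_COUNT / _RESOLUTION / _PARAMETER_nn /
    # _INDEX with five atom indices plus a grid number per term)
    if "CMAP_COUNT" in doc.sections:
        nterm, ngrid = doc.require("CMAP_COUNT").integers()[:2]
        resolutions = ints("CMAP_RESOLUTION", ngrid)
        grids = []
        for g in range(ngrid):
            vals = doc.require(f"CMAP_PARAMETER_{g + 1:02d}").floats()
            res = resolutions[g]
            if len(vals) != res * res:
                raise FormatError(f"CMAP_PARAMETER_{g + 1:02d}: expected "
                                  f"{res * res} values, got {len(vals)}")
            grids.append(CmapGrid(res, np.array(vals).reshape(res, res)))
        raw.cmaps = grids
        idx = ints("CMAP_INDEX", 6 * nterm)
        for off in range(0, len(idx), 6):
            i, j, k, l, m, g = idx[off:off + 6]
            quint = (i - 1, j - 1, k - 1, l - 1, m - 1)
            system.cmap_terms.append(
                (quint[:4], quint[1:], grids[g - 1]))

    system._bond_terms = bond_terms            # carried for the PRMTOP route
    system._angle_terms = angle_terms
    system._dihedral_terms = dihedral_terms
    system._improper_terms = improper_terms
    return system, raw


def prmtop_parametrized(system, raw) -> ParametrizedSystem:
    """Wrap a freshly parsed PRMTOP system with its verbatim parameters."""
    return ParametrizedSystem(
        system=system,
        bond_terms=system._bond_terms,
        angle_terms=system._angle_terms,
        dihedral_terms=system._dihedral_terms,
        improper_terms=system._improper_terms,
        cmap_assignments=list(system.cmap_terms),
        lj=dict(raw.lj),
        ab_table=raw.pair_coeffs,
    )


# ---------------------------------------------------------------------------
# parm DAT / FRCMOD
# ---------------------------------------------------------------------------

def _type_field(line: str, pos: int) -> str:
    """Fixed two-character type field starting at column ``pos``.

    Trailing spaces are significant and preserved; the wildcard field
    ``X `` maps to the internal wildcard sentinel.
    """
    t = line[pos:pos + 2]
    if len(t) < 2:
        t = t + " " * (2 - len(t))
    if t == "X ":
        return WILDCARD
    return t


def _num(tok: str, lineno: int):
    try:
        return float(tok)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable numeric field "
                          f"{tok!r}") from exc


def _scee_scnb(tokens) -> tuple:
    scee, scnb = 1.2, 2.0
    for tok in tokens:
        up = tok.upper().rstrip(",")
        if up.startswith("SCEE="):
            scee = float(up[5:])
        elif up.startswith("SCNB="):
            scnb = float(up[5:])
    return scee, scnb


def _norm_type_token(tok: str) -> str:
    """Whitespace-delimited type token; one-character names are padded to
    the two-character bonded-field spelling so MASS/NONB entries agree with
    the fixed-width bonded sections."""
    return tok + " " if len(tok) == 1 else tok


def _parse_mass_line(line, lineno, out: RawParameterSet):
    toks = line.split()
    t = _norm_type_token(toks[0])
    out.atom_types.add(t)
    out.masses[t] = _num(toks[1], lineno)


def _parse_bond_line(line, lineno, out):
    t1, t2 = _type_field(line, 0), _type_field(line, 3)
    toks = line[5:].split()
    out.atom_types.update((t1, t2))
    out.bonds[bond_key(t1, t2)] = BondParam(_num(toks[0], lineno),
                                            _num(toks[1], lineno))


def _parse_angle_line(line, lineno, out):
    t = (_type_field(line, 0), _type_field(line, 3), _type_field(line, 6))
    toks = line[8:].split()
    out.atom_types.update(t)
    out.angles[angle_key(*t)] = AngleParam(_num(toks[0], lineno),
                                           _num(toks[1], lineno))


def _parse_dihe_line(line, lineno, out, cont: dict):
    t = tuple(_type_field(line, k) for k in (0, 3, 6, 9))
    toks = line[11:].split()
    idivf = _num(toks[0], lineno)
    pk = _num(toks[1], lineno)
    phase = _num(toks[2], lineno)
    pn = _num(toks[3], lineno)
    scee, scnb = _scee_scnb(toks[4:])
    key = dihedral_key(*t)
    out.atom_types.update(x for x in t if x != WILDCARD)
    term = DihedralTerm(pk / idivf, abs(int(round(pn))), phase, scee, scnb)
    if cont.get("key") == key and cont.get("open"):
        out.dihedrals[key].append(term)
    else:
        out.dihedrals[key] = [term]
    cont["key"] = key
    cont["open"] = pn < 0


def _parse_impr_line(line, lineno, out):
    t = tuple(_type_field(line, k) for k in (0, 3, 6, 9))
    toks = line[11:].split()
    pk = _num(toks[0], lineno)
    phase = _num(toks[1], lineno)
    pn = _num(toks[2], lineno)
    out.atom_types.update(x for x in t if x != WILDCARD)
    out.impropers.setdefault(t, []).append(
        DihedralTerm(pk, abs(int(round(pn))), phase))


def _parse_nonb_line(line, lineno, out):
    toks = line.split()
    t = _norm_type_token(toks[0])
    out.atom_types.add(t)
    out.lj[t] = LJParam(eps=_num(toks[2], lineno),
                        rmin_half=_num(toks[1], lineno))


def parse_parm_dat(stream) -> RawParameterSet:
    """Parse an AMBER parm DAT file (MASS, BOND, ANGL, DIHE, IMPR, NONB).

    Dihedral barrier heights are stored as PK/IDIVF per term; a negative
    PN continues a multiterm series on the same type quadruple.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").split("\n")
    out = RawParameterSet()
    # blank-line-delimited blocks in canonical parm order; empty blocks
    # (e.g. a force field without impropers) keep their position
    blocks, cur = [], []
    for line in lines[1:]:               # first line is the title
        if line.strip() == "END":
            break
        if line.strip() == "":
            blocks.append(cur)
            cur = []
        else:
            cur.append(line)
    blocks.append(cur)
    # positions: 0 MASS, 1 hydrophilic types, 2 BOND, 3 ANGLE, 4 DIHE,
    # 5 IMPROPER, 6 10-12 H-bond, 7 equivalences, 8 label+NONB
    def block(i):
        return blocks[i] if i < len(blocks) else []

    cont = {}
    for n, ln in enumerate(block(0), 1):
        _parse_mass_line(ln, n, out)
    for n, ln in enumerate(block(2), 1):
        _parse_bond_line(ln, n, out)
    for n, ln in enumerate(block(3), 1):
        _parse_angle_line(ln, n, out)
    for n, ln in enumerate(block(4), 1):
        _parse_dihe_line(ln, n, out, cont)
    for n, ln in enumerate(block(5), 1):
        _parse_impr_line(ln, n, out)
    nonb = block(8)
    body = nonb[1:] if nonb and nonb[0].split()[-1:] == ["RE"] else nonb
    for n, ln in enumerate(body, 1):
        if ln.split():
            _parse_nonb_line(ln, n, out)
    return out


_FRCMOD_HEADERS = ("MASS", "BOND", "ANGL", "DIHE", "IMPR", "NONB", "CMAP",
                   "HBON")


def parse_frcmod(stream) -> RawParameterSet:
    """Parse a FRCMOD modification file into a delta parameter set.

    Merging is last-wins on identical keys (``RawParameterSet.merge``),
    mirroring LEAPRC load-order semantics.  Unknown section headers are
    skipped with a warning.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").split("\n")
    out = RawParameterSet()
    section = None
    cont = {}
    cmap_lines = []
    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if stripped == "" or stripped == "END":
            if section != "CMAP":
                section = None
            continue
        head = stripped.split()[0].upper()
        if len(stripped.split()) == 1 and any(
                head.startswith(h) for h in _FRCMOD_HEADERS):
            if section == "CMAP" and cmap_lines:
                out.cmaps.extend(_parse_cmap_block(cmap_lines))
                cmap_lines = []
            section = head[:4]
            continue
        if section is None:
            logger.warning("frcmod line %d: unknown section header %r; "
                           "skipping", lineno, stripped)
            continue
        if section == "MASS":
            _parse_mass_line(line, lineno, out)
        elif section == "BOND":
            _parse_bond_line(line, lineno, out)
        elif section == "ANGL":
            _parse_angle_line(line, lineno, out)
        elif section == "DIHE":
            _parse_dihe_line(line, lineno, out, cont)
        elif section == "IMPR":
            _parse_impr_line(line, lineno, out)
        elif section == "NONB":
            _parse_nonb_line(line, lineno, out)
        elif section == "CMAP":
            cmap_lines.append(line)
        elif section == "HBON":
            pass
    if cmap_lines:
        out.cmaps.extend(_parse_cmap_block(cmap_lines))
    return out


def _parse_cmap_block(lines) -> list:
    """CMAP block: %FLAG CMAP_RESLIST / CMAP_RESOLUTION / CMAP_PARAMETER
    records, one grid per residue named in the reslist."""
    grids = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("%FLAG CMAP_RESLIST"):
            residues = lines[i + 1].split()
            i += 2
            resolution, values = None, []
            while i < len(lines):
                ln = lines[i].strip()
                if ln.startswith("%FLAG CMAP_RESOLUTION"):
                    resolution = int(ln.split()[-1])
                elif ln.startswith("%FLAG CMAP_PARAMETER"):
                    i += 1
                    while i < len(lines) and not lines[i].lstrip().startswith("%"):
                        values.extend(float(x) for x in lines[i].split())
                        i += 1
                    break
                elif ln.startswith("%FLAG CMAP_RESLIST"):
                    break
                i += 1
            if resolution is None:
                raise FormatError("CMAP block without CMAP_RESOLUTION")
            arr = np.array(values, dtype=float)
            if arr.size != resolution * resolution:
                raise FormatError(
                    f"CMAP grid has {arr.size} values, expected "
                    f"{resolution * resolution}")
            for res in residues:
                grids.append(CmapGrid(resolution,
                                      arr.reshape(resolution, resolution),
                                      residue=res))
        else:
            i += 1
    return grids


# ---------------------------------------------------------------------------
# OFF / LIB residue templates
# ---------------------------------------------------------------------------

_OFF_ENTRY_RE = re.compile(r"!entry\.([^.]+)\.unit\.(\w+)")


def parse_off_lib(stream) -> list:
    """Parse an OFF/LIB library into residue templates (order preserved).

    Reads the ``atoms``, ``connectivity``, ``connect`` and ``positions``
    tables; raw type names (e.g. ``Na+``) are preserved verbatim.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").split("\n")
    order = []
    tables = {}           # (residue, table) → rows
    current = None
    for line in lines:
        if line.startswith("!!"):
            current = ("__index__", "index")
            tables[current] = []
            continue
        if line.startswith("!"):
            m = _OFF_ENTRY_RE.match(line)
            current = (m.group(1), m.group(2)) if m else None
            if current:
                tables.setdefault(current, [])
            continue
        if current is not None and line.strip():
            tables[current].append(line.strip())
    for row in tables.get(("__index__", "index"), []):
        order.append(row.strip().strip('"'))
    if not order:   # fall back to encounter order of atoms tables
        for (res, tab) in tables:
            if tab == "atoms" and res not in order:
                order.append(res)

    templates = []
    for res in order:
        atom_rows = tables.get((res, "atoms"))
        if atom_rows is None:
            raise FormatError(f"residue {res!r}: missing atoms table")
        atoms = []
        for row in atom_rows:
            fields = _split_off_row(row)
            atoms.append(TemplateAtom(name=fields[0], type=fields[1],
                                      charge=float(fields[-1])))
        bonds = []
        conn = tables.get((res, "connectivity"))
        if conn is None and len(atoms) > 1:
            raise FormatError(
                f"residue {res!r}: missing connectivity table")
        for row in conn or []:
            i, j = int(row.split()[0]), int(row.split()[1])
            bonds.append((atoms[i - 1].name, atoms[j - 1].name))
        head = tail = None
        connect = tables.get((res, "connect"))
        if connect:
            idx = [int(r.split()[0]) for r in connect]
            if len(idx) > 0 and idx[0] > 0:
                head = atoms[idx[0] - 1].name
            if len(idx) > 1 and idx[1] > 0:
                tail = atoms[idx[1] - 1].name
        coords = {}
        for row, a in zip(tables.get((res, "positions"), []), atoms):
            x, y, z = (float(v) for v in row.split()[:3])
            coords[a.name] = (x, y, z)
        templates.append(ResidueTemplate(name=res, atoms=atoms, bonds=bonds,
                                         head=head, tail=tail, coords=coords))
    return templates


def _split_off_row(row: str) -> list:
    """Split an OFF table row honouring double-quoted fields."""
    fields, i, n = [], 0, len(row)
    while i < n:
        if row[i].isspace():
            i += 1
        elif row[i] == '"':
            j = row.index('"', i + 1)
            fields.append(row[i + 1:j])
            i = j + 1
        else:
            j = i
            while j < n and not row[j].isspace():
                j += 1
            fields.append(row[i:j])
            i = j
    return fields


# ---------------------------------------------------------------------------
# coordinates: RST7 (ASCII restart) and PDB
# ---------------------------------------------------------------------------

def read_rst7(stream) -> np.ndarray:
    """Read an ASCII AMBER restart; returns (n, 3) coordinates in Å."""
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").split("\n")
    natom = int(lines[1].split()[0])
    vals = []
    for line in lines[2:]:
        for off in range(0, len(line.rstrip("\n")), 12):
            tok = line[off:off + 12].strip()
            if tok:
                vals.append(float(tok))
        if len(vals) >= 3 * natom:
            break
    if len(vals) < 3 * natom:
        raise FormatError("RST7 truncated: fewer coordinates than atoms")
    return np.array(vals[:3 * natom], dtype=float).reshape(natom, 3)


def write_rst7(coords: np.ndarray, title: str = "ffport restart") -> str:
    coords = np.asarray(coords, dtype=float)
    lines = [title, f"{len(coords):6d}"]
    flat = coords.reshape(-1)
    for off in range(0, len(flat), 6):
        lines.append("".join(f"{v:12.7f}" for v in flat[off:off + 6]))
    return "\n".join(lines) + "\n"


def read_pdb_coords(stream) -> np.ndarray:
    """Coordinates (Å) from ATOM/HETATM records, in file order."""
    text = stream.read() if hasattr(stream, "read") else stream
    rows = []
    for line in text.replace("\r\n", "\n").split("\n"):
        if line.startswith(("ATOM", "HETATM")):
            rows.append((float(line[30:38]), float(line[38:46]),
                         float(line[46:54])))
    if not rows:
        raise FormatError("no ATOM/HETATM records in PDB input")
    return np.array(rows, dtype=float)


def write_pdb(system: MolecularSystem) -> str:
    if system.coords is None:
        raise ValueError("system has no coordinates")
    lines = []
    for i, (a, xyz) in enumerate(zip(system.atoms, system.coords), start=1):
        lines.append(
            f"ATOM  {i:5d} {a.name:<4.4s} {a.resname:<4.4s}{a.resid:5d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00")
    lines.append("END")
    return "\n".join(lines) + "\n"
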