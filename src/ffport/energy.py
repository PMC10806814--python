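"""Dual-convention single-point potential energy evaluator.

Evaluates the classical additive potential

    U = Σ k_b(b−b₀)² + Σ k_θ(θ−θ₀)² + ΣΣ k_χ(1+cos(nχ−δ)) + U_CMAP
        + Σ [A_ij/r¹² − B_ij/r⁶] + Σ k_C q_i q_j /(ε r_ij)

under two conventions that must agree when Urey–Bradley and harmonic
improper channels are empty:

* ``amber``  — sinusoidal impropers through the dihedral term, 1-4 pairs
  divided by per-dihedral SCEE/SCNB, LJ from Lorentz–Berthelot or from a
  verbatim PRMTOP A/B coefficient table.
* ``charmm`` — per-type prescaled 1-4 LJ columns with NBFix pair
  overrides, 1-4 electrostatics multiplied by the engine's 1-4 scaling
  factor.

The validation protocol is direct-space: unbounded cutoff, no switching,
no long-range correction.  The Coulomb constant is selectable because the
reference engines disagree (332.0522173 vs 332.0636 kcal·Å/(mol·e²)) and
that difference dominates inter-engine energy deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import (COULOMB_AMBER, COULOMB_NAMD, DEG2RAD, SCEE_DEFAULT)
from .core import (CmapGrid, DeviationReport, EnergyBreakdown,
                   ParametrizedSystem)


class EvaluationError(ValueError):
    pass


COULOMB_BY_NAME = {"amber": COULOMB_AMBER, "namd": COULOMB_NAMD}


@dataclass
class EnergyOptions:
    convention: str = "amber"                # 'amber' | 'charmm'
    coulomb_constant: float = COULOMB_AMBER  # kcal·Å/(mol·e²)
    dielectric: float = 1.0
    cutoff: Optional[float] = None           # Å; None = unbounded
    scee_default: float = SCEE_DEFAULT
    scaling14: float = 1.0 / 1.2             # charmm-form 1-4 elec factor

    def __post_init__(self):
        if self.convention not in ("amber", "charmm"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.coulomb_constant <= 0:
            raise ValueError("Coulomb constant must be positive")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _angle(x, a, b, c):
    v1 = x[a] - x[b]
    v2 = x[c] - x[b]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(min(1.0, max(-1.0, cosang)))


def dihedral_angle(x, i, j, k, l) -> float:
    """Signed torsion angle in radians (IUPAC sign convention)."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(np.dot(m1, n2), np.dot(n1, n2))


# ---------------------------------------------------------------------------
# CMAP interpolation
# ---------------------------------------------------------------------------

_MINV = np.array([[1.0, 0.0, 0.0, 0.0],
                  [0.0, 0.0, 1.0, 0.0],
                  [-3.0, 3.0, -2.0, -1.0],
                  [2.0, -2.0, 1.0, 1.0]])


def _cmap_derivatives(values: np.ndarray):
    """Centred-difference first and cross derivatives on the periodic grid
    (CHARMM-style), in units of grid spacing."""
    fx = (np.roll(values, -1, axis=0) - np.roll(values, 1, axis=0)) / 2.0
    fy = (np.roll(values, -1, axis=1) - np.roll(values, 1, axis=1)) / 2.0
    fxy = (np.roll(np.roll(values, -1, 0), -1, 1)
           - np.roll(np.roll(values, -1, 0), 1, 1)
           - np.roll(np.roll(values, 1, 0), -1, 1)
           + np.roll(np.roll(values, 1, 0), 1, 1)) / 4.0
    return fx, fy, fxy


def cmap_energy(grid: CmapGrid, phi: float, psi: float) -> float:
    """Bicubic periodic interpolation of the grid at (φ, ψ) in degrees.

    Reproduces stored values exactly at nodes and is C¹-continuous across
    cell boundaries, including the ±180° seam.
    """
    res = grid.resolution
    h = 360.0 / res
    f = grid.values
    fx, fy, fxy = _cmap_derivatives(f)
    u = (phi + 180.0) / h
    v = (psi + 180.0) / h
    i0 = int(math.floor(u)) % res
    j0 = int(math.floor(v)) % res
    t = u - math.floor(u)
    s = v - math.floor(v)
    i1 = (i0 + 1) % res
    j1 = (j0 + 1) % res
    F = np.array([
        [f[i0, j0], f[i0, j1], fy[i0, j0], fy[i0, j1]],
        [f[i1, j0], f[i1, j1], fy[i1, j0], fy[i1, j1]],
        [fx[i0, j0], fx[i0, j1], fxy[i0, j0], fxy[i0, j1]],
        [fx[i1, j0], fx[i1, j1], fxy[i1, j0], fxy[i1, j1]],
    ])
    a = _MINV @ F @ _MINV.T
    tv = np.array([1.0, t, t * t, t * t * t])
    sv = np.array([1.0, s, s * s, s * s * s])
    return float(tv @ a @ sv)


# ---------------------------------------------------------------------------
# pairwise LJ resolution
# ---------------------------------------------------------------------------

def _lb(p1, p2):
    """Lorentz–Berthelot: arithmetic mean of radii, geometric mean of ε."""
    eps = math.sqrt(p1.eps * p2.eps)
    rmin = p1.rmin_half + p2.rmin_half
    return eps, rmin


def _ab_from_eps_rmin(eps, rmin):
    r6 = rmin ** 6
    return eps * r6 * r6, 2.0 * eps * r6


def pair_lj_coefficients(ps: ParametrizedSystem, opts: EnergyOptions,
                         t1: str, t2: str, one_four: bool,
                         scnb: float = 2.0):
    """(A, B) coefficients for one pair under the selected convention."""
    if opts.convention == "amber":
        if ps.ab_table is not None:
            key = tuple(sorted((t1, t2)))
            if key not in ps.ab_table:
                raise EvaluationError(f"no pair coefficients for {key}")
            a, b = ps.ab_table[key]
        else:
            eps, rmin = _lb(ps.lj[t1], ps.lj[t2])
            a, b = _ab_from_eps_rmin(eps, rmin)
        if one_four:
            a, b = a / scnb, b / scnb
        return a, b
    # charmm-form: NBFix overrides, prescaled 1-4 columns
    key = tuple(sorted((t1, t2)))
    fix = ps.nbfix.get(key)
    if one_four:
        if fix is not None:
            return _ab_from_eps_rmin(fix.eps14, fix.rmin14)
        eps, rmin = _lb(ps.lj14[t1], ps.lj14[t2])
        return _ab_from_eps_rmin(eps, rmin)
    if fix is not None:
        return _ab_from_eps_rmin(fix.eps, fix.rmin)
    eps, rmin = _lb(ps.lj[t1], ps.lj[t2])
    return _ab_from_eps_rmin(eps, rmin)


# ---------------------------------------------------------------------------
# evaluator
# ---------------------------------------------------------------------------

def compute_potential(ps: ParametrizedSystem,
                      opts: EnergyOptions) -> EnergyBreakdown:
    """Single-point potential energy with a term-wise breakdown."""
    system = ps.system
    x = system.coords
    if x is None:
        raise EvaluationError("system has no coordinates")
    if not np.all(np.isfinite(x)):
        raise EvaluationError("non-finite coordinate encountered")
    e = EnergyBreakdown()

    for i, j, bp in ps.bond_terms:
        b = float(np.linalg.norm(x[i] - x[j]))
        e.bond += bp.k * (b - bp.b0) ** 2
    for i, j, k, ap in ps.angle_terms:
        th = _angle(x, i, j, k)
        e.angle += ap.k * (th - ap.theta0 * DEG2RAD) ** 2
    for i, j, k, l, t in ps.dihedral_terms:
        chi = dihedral_angle(x, i, j, k, l)
        e.dihedral += t.k * (1.0 + math.cos(t.n * chi - t.phase * DEG2RAD))
    for i, j, k, l, t in ps.improper_terms:
        # sinusoidal impropers go through the standard dihedral term; the
        # angle is defined by the declared atom order
        chi = dihedral_angle(x, i, j, k, l)
        e.dihedral += t.k * (1.0 + math.cos(t.n * chi - t.phase * DEG2RAD))
    for quad_a, quad_b, grid in ps.cmap_assignments:
        if grid is None:
            raise EvaluationError("CMAP crossterm without a grid")
        phi = math.degrees(dihedral_angle(x, *quad_a))
        psi = math.degrees(dihedral_angle(x, *quad_b))
        e.cmap += cmap_energy(grid, phi, psi)

    kq = opts.coulomb_constant / opts.dielectric
    types = [a.type for a in system.atoms]
    q = [a.charge for a in system.atoms]
    n = system.n_atoms
    cutoff2 = None if opts.cutoff is None else opts.cutoff ** 2
    for i in range(n):
        for j in range(i + 1, n):
            pr = frozenset((i, j))
            if pr in system.exclusions:
                continue
            d = x[i] - x[j]
            r2 = float(d @ d)
            if r2 == 0.0:
                raise EvaluationError(f"zero distance between atoms {i},{j}")
            if cutoff2 is not None and r2 > cutoff2:
                continue
            r = math.sqrt(r2)
            one4 = pr in system.scaled14
            if one4:
                scee, scnb = system.scaled14[pr]
                a, b = pair_lj_coefficients(ps, opts, types[i], types[j],
                                            True, scnb)
                e.vdw14 += a / r2 ** 6 - b / r2 ** 3
                if opts.convention == "amber":
                    e.elec14 += kq * q[i] * q[j] / (r * scee)
                else:
                    e.elec14 += kq * q[i] * q[j] * opts.scaling14 / r
            else:
                a, b = pair_lj_coefficients(ps, opts, types[i], types[j],
                                            False)
                e.vdw += a / r2 ** 6 - b / r2 ** 3
                e.elec += kq * q[i] * q[j] / r
    return e


def per_pair_vdw14(ps: ParametrizedSystem, opts: EnergyOptions) -> dict:
    """1-4 LJ energy contribution of each scaled pair (for route checks)."""
    system = ps.system
    x = system.coords
    types = [a.type for a in system.atoms]
    out = {}
    for pr, (scee, scnb) in system.scaled14.items():
        i, j = sorted(pr)
        r2 = float(np.dot(x[i] - x[j], x[i] - x[j]))
        a, b = pair_lj_coefficients(ps, opts, types[i], types[j], True, scnb)
        out[(i, j)] = a / r2 ** 6 - b / r2 ** 3
    return out


def compare_single_points(breakdowns_a, breakdowns_b,
                          atom_counts) -> DeviationReport:
    """Per-system |ΔE|/N with ensemble average, maximum and SD.

    This is the per-atom normalisation used to compare single-point
    energies across engines regardless of molecule size.
    """
    if not (len(breakdowns_a) == len(breakdowns_b) == len(atom_counts)):
        raise ValueError("paired inputs must have equal lengths")
    devs = []
    for ea, eb, na in zip(breakdowns_a, breakdowns_b, atom_counts):
        ta = ea.total if isinstance(ea, EnergyBreakdown) else float(ea)
        tb = eb.total if isinstance(eb, EnergyBreakdown) else float(eb)
        devs.append(abs(ta - tb) / na)
    arr = np.array(devs)
    return DeviationReport(per_system=devs, average=float(arr.mean()),
                           maximum=float(arr.max()), std=float(arr.std()))
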