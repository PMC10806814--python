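# Methods

## Scope and model

`ffport` converts AMBER-family force-field content into CHARMM-format
declarations and verifies, by single-point potential-energy comparison,
that the conversion is exact up to floating-point representation. The
potential is the standard fixed-charge additive model: harmonic bonds
k_b(b−b₀)² and angles k_θ(θ−θ₀)², a cosine series k_χ(1+cos(nχ−δ)) for
proper torsions *and* sinusoidal impropers (AMBER treats impropers as
torsions over the declared atom order), grid-based CMAP cross-terms on
(φ, ψ), 12-6 Lennard-Jones and Coulomb electrostatics. The CHARMM-form
energy additionally has Urey–Bradley and harmonic-improper channels; for
translated AMBER content these are identically zero, which is the
condition under which the two functional forms coincide. The evaluator
implements both conventions so that claim is checked numerically rather
than assumed.

No parameter value is ever re-fit. The translation layer changes only
*declarations*: type names, the keying of 1-4 Lennard-Jones scaling and
CMAP grids, and improper declaration order.

## Conventions and units

Energies kcal/mol, distances Å, charges e, masses amu. Parameter-file
angles are carried in degrees and converted with a single named constant
(π/180 at full native precision); centralising the conversion makes the
harmonic-angle term's sensitivity to that constant auditable, since it is
a known source of small cross-engine discrepancies. Dihedral barrier
heights are stored per term as PK/IDIVF. PRMTOP charges are stored
premultiplied by √k_C = 18.2223 and divided out on parsing. The Coulomb
constant is selectable per evaluation: 332.0522173 (AMBER engines) or
332.0636 (stock NAMD) kcal·Å/(mol·e²); electrostatic terms are exactly
linear in it, so the difference between engine families has a closed
form.

## Validation protocol

Single-point comparisons are direct-space: unbounded cutoff, no switching
function, no long-range Lennard-Jones correction (a finite cutoff exists
as an option but is not the validation path; PME is out of scope).
Deviations are reported per atom, |ΔE|/N, with ensemble average, maximum
and standard deviation, because total energies scale with molecule size
and the test ensembles mix compositions.

Three routes must agree on every fixture:

1. **PRMTOP route** — topology, charges, per-dihedral SCEE/SCNB and the
   precomputed A/B pair coefficients read verbatim from a PRMTOP,
   evaluated in amber-form.
2. **Template route** — the same molecule built from residue templates
   with parameters assigned by type, evaluated in amber-form.
3. **Translated route** — types encoded, parameters translated to
   CHARMM-form (prescaled 1-4 columns, NBFix, per-dihedral-type CMAP),
   evaluated in charmm-form.

An independently coded brute-force evaluator (plain-Python loops, a
different torsion formulation, bicubic coefficients obtained by solving
the 16 Hermite conditions as a dense linear system) serves as the oracle;
it shares no code with the main evaluator.

## Key algorithmic choices

**1-4 pair bookkeeping.** Pairs separated by exactly three bonds (and not
also 1-2/1-3, as in small rings) are scaled, each counted once regardless
of how many dihedral paths connect it; the governing dihedral is the
first enumerated one, matching the PRMTOP writer's convention, so both
routes pick the same SCNB. SCEE is uniform (1.2) across supported
parameter sets; the data model carries it per dihedral so a mixed-SCEE
input fails loudly instead of being silently mis-scaled.

**Mixed SCNB.** The translator collects the SCNB of every dihedral's
end-type pair. A pair key with one non-default value gets an NBFix row
(1-4 columns scaled, regular columns replicating combination-rule values
so only 1-4 behaviour changes — NBFix applies to *all* interactions of
the named pair). A pair key seen under two values means the scaling is
atom-context dependent: the minority quadruple's end type is duplicated
with an `X` postfix, retyping rules map matching dihedral ends to the
variant, and NBFix rows are written against the variant. Three or more
values on one type have no representation in this scheme and raise.
Variants alias their base type for all bonded lookups, which is
equivalent to duplicating every bonded entry but keeps the parameter
files small.

**CMAP.** Interpolation is bicubic Hermite on the periodic grid with
centred-difference first and cross derivatives (the common engine
convention): it reproduces node values exactly and is C¹ across cell
boundaries and the ±180° seam. Per-grid Cα variants are indexed in
first-encounter order. Grid keys store the variant in the two Cα slots of
the eight-type crossterm pattern and wildcards elsewhere; both assignment
routes (per-residue and per-type) enumerate candidate five-atom paths
through one shared function, so they cannot disagree about which
crossterms exist. A path and its reverse denote differently-oriented
(φ, ψ) queries; the lexicographically smaller orientation is kept,
deterministically, on both routes.

**Improper order.** The emulation keeps the centre atom third and sorts
peripherals by encoded type name (wildcards last, ties by atom index);
documented special cases live in an override *table*, not code, because
the set of reorder triggers is force-field-specific data.

**Numeric fields.** CHARMM-dialect writers print 17 significant digits so
a write/read cycle is value-exact; the PSF writer uses wide (EXT-style)
columns so postfixed type names never truncate, and stores charges/masses
in scientific notation for bit-identical round trips. The fixture PRMTOP
serialiser offers two pair-coefficient precisions: full, and the
eight-decimal exponent fields real files use, to exercise the
limited-precision pathway separately.

## Synthetic data

The fixture generator emulates the *structure* of the validation inputs,
not their chemistry: residue templates with head/tail connectors, a
branch atom creating an improper centre, exotic type names (lowercase,
digits, `*`, `+`, trailing space, a symbol-bearing ion), multiterm
dihedrals with PK/IDIVF and negative-periodicity continuation, a wildcard
entry exercised alongside exact ones, an optional per-residue CMAP grid
on an interior residue, and an optional mixed-SCNB motif in which the
same end-type pair needs SCNB 2.0 on one atom pair and 1.2 on another —
the case that forces X-postfix retyping rather than plain NBFix.
Generated values are quantised to 9 significant digits so every emitted
file re-parses to exactly the ground truth; coordinates are quantised to
the RST7 field width so all routes evaluate identical geometry. Default
ensemble conditions: 2–4 residues of 4 backbone atoms plus a branch atom,
0.1 Å coordinate jitter, SCEE 1.2, SCNB 2.0 (1.2 on the mixed path),
charges in ±0.4 e, LJ ε 0.05–0.3 kcal/mol and Rmin/2 1.0–1.7 Å. Identical
seeds give byte-identical files.

What passing these tests shows: parsing, translation and evaluation are
mutually consistent and match an independent oracle on every structural
feature the formats can express. What they do not show: agreement with
external engine binaries on shipped force-field distributions (those
comparisons need the AMBER/NAMD binaries and full parameter sets, which
are not bundled), realistic conformational energetics, or dynamics.

## Problem sizes

The test suite and the acceptance script use ensembles of 200 seeded
systems of roughly 15–30 atoms each — small enough that the O(N²)
direct-space double loop and the brute-force oracle are instantaneous,
large enough to cover every bonded-term category, both 1-4 scaling
factors, wildcard fallback and CMAP crossterms in every run.

## Degenerate inputs and failure modes

Zero interatomic distance, non-finite coordinates, missing parameters
(never silent zeros), unknown residue names, over-wide PSF type names,
PRMTOP integers at or beyond eight digits, KLD with unsupported mass, and
mismatched histogram binning all raise typed errors naming the offending
entity. Patches apply atomically: a failing patch leaves the system
untouched.

## Known limitations

PREP residue input, binary restart files, CHAMBER-extended PRMTOPs, the
memory-optimised binary topology format, solvation/ionisation tooling,
forces/minimisation/dynamics and PME are out of scope. The inverse type
decoding relies on the stored map (the body drops trailing symbols, so
decoding is not reconstructive). Histogram bin choices for property
comparisons are the caller's responsibility — the JSD is bin-sensitive by
design and the package never re-bins silently.
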