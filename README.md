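# ffport

Refactor AMBER-family force fields (AMBERff) into CHARMM-format files so
that NAMD-style engines — which scale to billions of atoms — can run them
without touching a PRMTOP.

## The problem

AMBER encodes molecular topology and parameters in the PRMTOP format,
which allocates **eight digits per integer**. Because coordinate arrays
are indexed as N = 3(A − 1), the format stops working near **33 million
atoms**, and the single-threaded builder that produces PRMTOPs becomes
impractical long before that. CHARMM-format inputs (RTF/TOP residue
topologies, PRM parameter files, STR streams) read by *psfgen* and NAMD
have no such ceiling, but they differ from AMBER conventions in ways that
silently corrupt energies if files are converted naively:

* NAMD capitalises CHARMM-format atom types, drops symbols and spaces,
  and rejects leading digits — yet AMBER type names use all of these
  (`cg`, `C*`, `Na+`, `C` with a trailing space).
* AMBER assigns the 1-4 Lennard-Jones divisor **SCNB per dihedral**;
  CHARMM format prescales per atom type. Modern lipid parameter sets mix
  two SCNB values in one system.
* AMBER assigns CMAP backbone corrections **per residue**; CHARMM format
  assigns them per dihedral type.
* The PRMTOP builder reorders improper-dihedral declarations
  (A–B–C–D → D–A–C–B under certain triggers), which redefines the
  out-of-plane angle; a PSF builder does not.

`ffport` implements a refactoring that changes declarations, never
parameter values:

* **Type encoding** — a prefix with one capital letter per character
  (U/L/S/N/A/P/M for uppercase/lowercase/space/number/asterisk/plus/minus)
  followed by the uppercased alphanumeric body: `CG → UUCG`, `cg → LLCG`,
  `Na+ → ULPNA`. Encoded names are invariant under the engine's
  normalisation, and the scheme is injective on real type sets.
* **Mixed 1-4 scaling** — atoms whose required SCNB depends on the
  partner get an `X`-postfix duplicate type plus NBFix pair rows whose
  1-4 columns carry the alternative scaling while regular columns
  replicate combination-rule values.
* **CMAP re-keying** — each grid gets a numeric-postfix duplicate of the
  owning residues' Cα type (`UUXC` → `UUXC0`, `UUXC1`, …) so grids can be
  declared by dihedral type; the base type stays in use everywhere else.
* **Improper-order emulation** — a configurable canonicalisation (centre
  third; peripherals sorted by type, wildcards last, ties by atom index)
  plus a data-driven override table reproduces the PRMTOP builder's
  declaration order.

The validation methodology ships with the tool: a dual-convention
single-point potential-energy evaluator

    U = Σ k_b(b−b₀)² + Σ k_θ(θ−θ₀)² + ΣΣ k_χ(1+cos(nχ−δ)) + U_CMAP
        + Σ [A_ij/r¹² − B_ij/r⁶] + Σ k_C q_i q_j /(ε r_ij)

with selectable Coulomb constant (332.0522173 AMBER vs 332.0636 NAMD,
kcal·Å/(mol·e²)), per-atom deviation reports |ΔE|/N across system
ensembles, and the Jensen–Shannon divergence (base-2, bounded [0, 1]) for
comparing property distributions.

## Worked example

Everything needed is generated synthetically — no downloads:

```bash
ffport fixtures --seed 11 --out bundle --mixed-scnb --cmap
ffport translate --dat bundle/ff.dat --frcmod bundle/ff.frcmod \
                 --lib bundle/ff.lib --out charmm --cmap-anchor A2
ffport energy --prmtop bundle/system.prmtop --rst7 bundle/system.rst7
```

The last command prints a term-wise breakdown (kcal/mol):

```
bond                448.770246665
angle               469.888323269
urey_bradley        0
dihedral            47.5265765366
improper_harmonic   0
cmap                1.09441731274
vdw                -0.20507044256
vdw14              -0.515537766126
elec                24.254428782
elec14             -20.6123637438
total               970.201020613
```

(The bond/angle terms are large because the synthetic conformers are
jittered away from their reference geometry, not minimised.)

`urey_bradley` and `improper_harmonic` are zero by construction for
AMBERff-derived content — that is exactly the condition under which the
extended CHARMM-form energy reduces to the AMBER form. Evaluating the
same system through the translated parameters in charmm-form reproduces
the total to better than 1e-10 kcal/mol per atom (`scripts/acceptance.py`
measures this over a 200-system ensemble); going through PSF + PRM + PDB
files on disk adds only the 3-decimal PDB coordinate rounding.

A two-point sanity check of the electrostatics: two +1e charges 1 Å
apart evaluate to exactly the selected engine's Coulomb constant,

```bash
ffport energy --prmtop qq.prmtop --rst7 qq.rst7 --coulomb amber  # 332.0522173
ffport energy --prmtop qq.prmtop --rst7 qq.rst7 --coulomb namd   # 332.0636
```

## Layout

| module | role |
|---|---|
| `ffport.amber_io` | PRMTOP / parm DAT / FRCMOD / OFF-LIB / RST7 readers, format-limit validation |
| `ffport.type_encoding` | prefix scheme, CMAP numeric postfixes, SCNB `X` postfixes, injectivity audit |
| `ffport.ff_translate` | parameter translation, mixed-SCNB → NBFix, CMAP re-keying, improper-order emulation, RTF/PRM/STR writers, NAMDRC-style manifest |
| `ffport.topology_builder` | psfgen-analogue segment builder, patches, exclusions/1-4 lists, X-PLOR PSF I/O |
| `ffport.energy` | dual-convention single-point evaluator, periodic bicubic CMAP, deviation reports |
| `ffport.stats` | Jensen–Shannon / Kullback–Leibler divergences, histograms |
| `ffport.fixtures` | seeded synthetic force fields, molecules and independent oracles |
| `ffport.cli` | `ffport` command: fixtures, translate, build, energy, compare, jsd |
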