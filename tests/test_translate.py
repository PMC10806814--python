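"""AMBER→CHARMM refactoring: value preservation, mixed SCNB, CMAP
re-keying, improper-order emulation, manifests and CHARMM-dialect I/O."""

import numpy as np
import pytest

from ffport.core import (CmapGrid, DihedralTerm, LJParam, RawParameterSet,
                         ResidueTemplate, TemplateAtom, WILDCARD)
from ffport.ff_translate import (MixedScalingError, TranslationError,
                                 assign_cmap_types, build_resource_manifest,
                                 emulate_tleap_improper_order, merge_charmm,
                                 read_prm, read_rtf, resolve_mixed_scnb,
                                 translate_parameters, translate_pipeline,
                                 write_prm, write_rtf)
from ffport.type_encoding import audit_injectivity


def small_raw():
    raw = RawParameterSet(
        atom_types={"CT", "OS"},
        masses={"CT": 12.011, "OS": 15.999},
        lj={"CT": LJParam(0.2, 1.7), "OS": LJParam(0.17, 1.5)},
        dihedrals={("CT", "CT", "OS", "CT"):
                   [DihedralTerm(0.383, 3, 0.0, 1.2, 2.0)]})
    return raw


def test_values_preserved_and_lj14_prescaled():
    raw = small_raw()
    enc = audit_injectivity(raw.atom_types)
    cps = translate_parameters(raw, enc)
    reg, one4 = cps.nonbonded["UUCT"]
    assert reg == raw.lj["CT"]                       # untouched
    assert one4.eps == raw.lj["CT"].eps / 2.0        # ε/SCNB, exactly
    assert one4.rmin_half == raw.lj["CT"].rmin_half
    terms = cps.dihedrals[("UUCT", "UUCT", "UUOS", "UUCT")]
    assert terms == raw.dihedrals[("CT", "CT", "OS", "CT")]


def test_uncovered_type_and_mixed_scee_rejected():
    raw = small_raw()
    enc = audit_injectivity({"CT"})                  # OS missing
    with pytest.raises(TranslationError, match="OS"):
        translate_parameters(raw, enc)
    raw2 = small_raw()
    raw2.dihedrals[("CT", "CT", "OS", "CT")].append(
        DihedralTerm(0.1, 1, 0.0, scee=2.0, scnb=2.0))
    with pytest.raises(TranslationError, match="SCEE|electrostatic"):
        translate_parameters(raw2, audit_injectivity(raw2.atom_types))


def test_angles_have_zero_urey_bradley(ff_full):
    cps, *_ = translate_pipeline(ff_full.raw, ff_full.templates)
    assert cps.angles
    for _, kub, s0 in cps.angles.values():
        assert kub == 0.0 and s0 == 0.0


# ---------------------------------------------------------------------------
# mixed SCNB
# ---------------------------------------------------------------------------

def mixed_raw():
    types = {"qa", "qb", "qc", "qd", "qe", "qf"}
    raw = RawParameterSet(
        atom_types=set(types),
        masses={t: 12.0 for t in types},
        lj={t: LJParam(0.1 + 0.01 * i, 1.5 + 0.02 * i)
            for i, t in enumerate(sorted(types))},
        dihedrals={
            ("qa", "qb", "qc", "qd"): [DihedralTerm(1.0, 2, 0.0, 1.2, 2.0)],
            ("qa", "qe", "qf", "qd"): [DihedralTerm(0.8, 3, 0.0, 1.2, 1.2)],
        })
    return raw


def test_mixed_scnb_creates_variant_and_nbfix():
    raw = mixed_raw()
    enc = audit_injectivity(raw.atom_types)
    base = translate_parameters(raw, enc)
    delta, rules = resolve_mixed_scnb(raw, enc, base)
    assert len(rules) == 1
    rule = rules[0]
    assert rule.variant.endswith("X")
    assert rule.variant in delta.type_aliases
    # NBFix rows: regular columns replicate combination values, 1-4 columns
    # carry the alternative scaling
    key = tuple(sorted((enc.encode("qa"), rule.variant)))
    fx = delta.nbfix[key]
    eps = (raw.lj["qa"].eps * raw.lj["qd"].eps) ** 0.5
    rmin = raw.lj["qa"].rmin_half + raw.lj["qd"].rmin_half
    assert fx.eps == pytest.approx(eps, rel=1e-15)
    assert fx.rmin == pytest.approx(rmin, rel=1e-15)
    assert fx.eps14 == pytest.approx(eps / 1.2, rel=1e-15)
    assert fx.rmin14 == fx.rmin
    # other types untouched
    assert not any(t in delta.nonbonded for t in
                   (enc.encode("qb"), enc.encode("qc")))


def test_uniform_scnb_yields_empty_delta():
    raw = mixed_raw()
    raw.dihedrals[("qa", "qe", "qf", "qd")] = \
        [DihedralTerm(0.8, 3, 0.0, 1.2, 2.0)]
    enc = audit_injectivity(raw.atom_types)
    delta, rules = resolve_mixed_scnb(raw, enc,
                                      translate_parameters(raw, enc))
    assert rules == [] and delta.nbfix == {} and delta.type_aliases == {}


def test_three_scnb_values_escalate():
    raw = mixed_raw()
    raw.dihedrals[("qa", "qb", "qf", "qd")] = \
        [DihedralTerm(0.5, 1, 0.0, 1.2, 1.5)]
    enc = audit_injectivity(raw.atom_types)
    with pytest.raises(MixedScalingError):
        resolve_mixed_scnb(raw, enc, translate_parameters(raw, enc))


# ---------------------------------------------------------------------------
# CMAP re-keying
# ---------------------------------------------------------------------------

def two_residue_templates():
    def tpl(name):
        return ResidueTemplate(
            name=name,
            atoms=[TemplateAtom("N", "N3", -0.3),
                   TemplateAtom("CA", "XC", 0.1),
                   TemplateAtom("C", "C ", 0.2)],
            bonds=[("N", "CA"), ("CA", "C")], head="N", tail="C",
            coords={"N": (0, 0, 0), "CA": (1.4, 0.4, 0), "C": (2.8, 0, 0)},
            cmap_anchor="CA")
    return {"ALA": tpl("ALA"), "GLY": tpl("GLY")}


def test_cmap_types_one_variant_per_grid():
    templates = two_residue_templates()
    grids = [CmapGrid(4, np.zeros((4, 4)), residue="ALA"),
             CmapGrid(4, np.ones((4, 4)), residue="GLY")]
    enc = audit_injectivity({"N3", "XC", "C "})
    out, delta = assign_cmap_types(templates, grids, enc)
    assert out["ALA"].atom("CA").type == "UUXC0"
    assert out["GLY"].atom("CA").type == "UUXC1"
    # base type untouched in the originals and for non-anchor uses
    assert templates["ALA"].atom("CA").type == "XC"
    assert delta.type_aliases == {"UUXC0": "UUXC", "UUXC1": "UUXC"}
    assert delta.cmaps[0].type_key[2] == "UUXC0"
    assert delta.cmaps[0].type_key[5] == "UUXC0"


def test_cmap_zero_grids_is_identity():
    templates = two_residue_templates()
    enc = audit_injectivity({"N3", "XC", "C "})
    out, delta = assign_cmap_types(templates, [], enc)
    assert delta.cmaps == [] and delta.type_aliases == {}
    assert out["ALA"].atom("CA").type == "XC"


def test_cmap_grid_for_unknown_residue_raises():
    enc = audit_injectivity({"N3", "XC", "C "})
    with pytest.raises(TranslationError, match="TRP"):
        assign_cmap_types(two_residue_templates(),
                          [CmapGrid(4, np.zeros((4, 4)), residue="TRP")],
                          enc)


def test_sixteen_grids_make_sixteen_variants():
    """A full per-grid Cα split: sixteen grids → sixteen distinct types."""
    templates = {}
    grids = []
    for i in range(16):
        name = f"R{i:02d}"
        t = two_residue_templates()["ALA"]
        templates[name] = ResidueTemplate(
            name=name, atoms=t.atoms, bonds=t.bonds, head="N", tail="C",
            coords=t.coords, cmap_anchor="CA")
        grids.append(CmapGrid(4, np.full((4, 4), float(i)), residue=name))
    enc = audit_injectivity({"N3", "XC", "C "})
    out, delta = assign_cmap_types(templates, grids, enc)
    variants = {out[n].atom("CA").type for n in templates}
    assert variants == {f"UUXC{i}" for i in range(16)}


# ---------------------------------------------------------------------------
# tleap improper-order emulation
# ---------------------------------------------------------------------------

def test_improper_override_table():
    overrides = {("A", "B", "C", "D"): ("D", "A", "C", "B")}
    assert emulate_tleap_improper_order(("A", "B", "C", "D"),
                                        overrides=overrides) == \
        ("D", "A", "C", "B")
    types, idx = emulate_tleap_improper_order(
        ("A", "B", "C", "D"), atom_indices=(10, 11, 12, 13),
        overrides=overrides)
    assert types == ("D", "A", "C", "B") and idx == (13, 10, 12, 11)


def test_improper_canonical_sort_and_idempotence():
    out = emulate_tleap_improper_order(("UC", "UB", "UO", "UA"))
    assert out == ("UA", "UB", "UO", "UC")        # centre fixed third
    assert emulate_tleap_improper_order(out) == out
    # wildcards sort last; ties break by atom index
    types, idx = emulate_tleap_improper_order(
        (WILDCARD, "UB", "UO", WILDCARD), atom_indices=(7, 3, 1, 5))
    assert types == ("UB", WILDCARD, "UO", WILDCARD)
    assert idx == (3, 5, 1, 7)


# ---------------------------------------------------------------------------
# resource manifest
# ---------------------------------------------------------------------------

def test_manifest_order_and_settings():
    man = build_resource_manifest({"base.prm", "delta.prm", "ff.rtf"},
                                  ["ff.rtf", "base.prm", "delta.prm"])
    assert man.parameter_files == ["base.prm", "delta.prm"]
    assert man.topology_files == ["ff.rtf"]
    assert man.settings["1-4scaling"] == 0.833333
    assert man.settings["amber"] == "off"
    assert man.settings["paraTypeCharmm"] == "on"
    text = man.to_text()
    assert "1-4scaling 0.833333" in text


def test_manifest_errors():
    with pytest.raises(TranslationError, match="missing"):
        build_resource_manifest({"a.prm"}, ["a.prm", "gone.prm"])
    with pytest.raises(TranslationError, match="parameter"):
        build_resource_manifest(set(), [])


# ---------------------------------------------------------------------------
# CHARMM-dialect round trips
# ---------------------------------------------------------------------------

def test_prm_round_trip(ff_full):
    cps, *_ = translate_pipeline(ff_full.raw, ff_full.templates)
    again = read_prm(write_prm(cps))
    assert again.bonds == cps.bonds
    assert {k: v[0] for k, v in again.angles.items()} == \
        {k: v[0] for k, v in cps.angles.items()}
    assert again.dihedrals == cps.dihedrals
    assert again.impropers == cps.impropers
    assert again.nonbonded == cps.nonbonded
    assert again.nbfix == cps.nbfix
    assert again.type_aliases == cps.type_aliases
    assert len(again.cmaps) == sum(g.type_key is not None for g in cps.cmaps)
    for g1 in again.cmaps:
        g0 = next(g for g in cps.cmaps if g.type_key == g1.type_key)
        assert np.array_equal(g0.values, g1.values)


def test_rtf_round_trip(ff_full):
    cps, tpl2, enc, _ = translate_pipeline(ff_full.raw, ff_full.templates)
    templates, masses = read_rtf(write_rtf(tpl2, cps, enc))
    assert set(templates) == set(tpl2)
    assert masses == cps.masses
    for name, truth in tpl2.items():
        got = templates[name]
        want_types = [a.type if a.type not in enc.forward
                      else enc.encode(a.type) for a in truth.atoms]
        assert [a.type for a in got.atoms] == want_types
        assert [a.charge for a in got.atoms] == \
            pytest.approx([a.charge for a in truth.atoms], abs=1e-6)
        assert got.bonds == truth.bonds
        assert got.impropers == [tuple(q) for q in truth.impropers]
        assert (got.head, got.tail) == (truth.head, truth.tail)
        assert got.cmap_anchor == truth.cmap_anchor


def test_merge_charmm_prefers_delta():
    raw = small_raw()
    enc = audit_injectivity(raw.atom_types)
    base = translate_parameters(raw, enc)
    delta = translate_parameters(raw, enc)
    delta.nonbonded["UUCT"] = (LJParam(9.0, 9.0), LJParam(9.0, 9.0))
    merged = merge_charmm(base, delta)
    assert merged.nonbonded["UUCT"][0].eps == 9.0
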