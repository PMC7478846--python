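"""Model loading, GPR logic, gene deletions, media and exchange edits."""

import json

import numpy as np
import pytest

from serflux import synth
from serflux.model import (
    GprParseError,
    MediumDefinition,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    apply_gene_deletions,
    apply_medium,
    load_model,
    parse_gpr,
    set_exchange_bound,
    write_model,
    genotype_deletions,
)

# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rule, deleted, expected",
    [
        ("", {"G1", "G2", "G3"}, True),  # empty rule: unconditionally available
        ("G1 or G2", {"G1"}, True),
        ("G1 or G2", {"G1", "G2"}, False),
        ("(G1 and G2) or G3", {"G2"}, True),
        ("(G1 and G2) or G3", {"G2", "G3"}, False),
        ("G1 AND G2", {"G1"}, False),  # case-insensitive keywords
        ("G1 and G2 or G3", {"G1", "G3"}, False),  # and binds tighter than or
        ("G1 and (G2 or G3)", {"G3"}, True),
    ],
)
def test_gpr_evaluation(rule, deleted, expected):
    assert parse_gpr(rule).evaluate(deleted) is expected


@pytest.mark.parametrize("bad", ["(G1 or G2", "G1 or or G2", "G1 G2)", ")G1"])
def test_gpr_parse_errors_carry_position(bad):
    with pytest.raises(GprParseError) as exc:
        parse_gpr(bad)
    assert exc.value.position >= 0


def test_gpr_text_round_trip():
    rule = "(G1 and G2) or G3"
    expr = parse_gpr(rule)
    again = parse_gpr(expr.to_text())
    for deleted in [set(), {"G1"}, {"G1", "G2"}, {"G3"}, {"G1", "G2", "G3"}]:
        assert expr.evaluate(deleted) == again.evaluate(deleted)


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------


def test_load_toy_json_chain(tmp_path, chain_model):
    path = tmp_path / "chain.json"
    write_model(chain_model, path)
    loaded = load_model(path, dialect="toy-json")
    assert len(loaded.reactions) == 3
    assert sum(r.is_exchange for r in loaded.reactions) == 2  # EX_A and BIOMASS drain
    assert loaded.objective_reaction == "BIOMASS"


def test_toy_json_round_trip_identity(tmp_path, serine_model):
    """load_model . write_model is the identity up to reaction ordering."""
    path = tmp_path / "serine.json"
    write_model(serine_model, path)
    loaded = load_model(path)
    assert {m.id for m in loaded.metabolites} == {m.id for m in serine_model.metabolites}
    assert loaded.genes == serine_model.genes
    for r in serine_model.reactions:
        r2 = loaded.reaction(r.id)
        assert r2.stoichiometry == r.stoichiometry
        assert (r2.lower_bound, r2.upper_bound) == (r.lower_bound, r.upper_bound)
        assert r2.gpr.to_text() == r.gpr.to_text()


SBML_CHAIN = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="chain" fbc:strict="true">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_ex" value="-10" constant="true"/>
      <parameter id="zero" value="0" constant="true"/>
      <parameter id="big" value="1000" constant="true"/>
    </listOfParameters>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="G1" fbc:label="G1"/>
      <fbc:geneProduct fbc:id="G2" fbc:label="G2"/>
    </fbc:listOfGeneProducts>
    <listOfReactions>
      <reaction id="EX_A" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_ex" fbc:upperFluxBound="big">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R1" reversible="false" fast="false"
                fbc:lowerFluxBound="zero" fbc:upperFluxBound="big">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:geneProductRef fbc:geneProduct="G1"/>
            <fbc:geneProductRef fbc:geneProduct="G2"/>
          </fbc:or>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="BIOMASS" reversible="false" fast="false"
                fbc:lowerFluxBound="zero" fbc:upperFluxBound="big">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


@pytest.fixture
def sbml_chain_path(tmp_path):
    path = tmp_path / "chain.xml"
    path.write_text(SBML_CHAIN)
    return path


def test_sbml_fbc_loader_matches_toy_json(sbml_chain_path, chain_model):
    """SBML-FBC export of the chain normalizes to the same model."""
    m = load_model(sbml_chain_path, dialect="sbml-fbc")
    assert m.objective_reaction == "BIOMASS"
    assert {r.id for r in m.reactions} == {r.id for r in chain_model.reactions}
    ex = m.reaction("EX_A")
    assert ex.stoichiometry == {"A": -1.0}
    assert (ex.lower_bound, ex.upper_bound) == (-10.0, 1000.0)
    assert m.reaction("R1").gpr.to_text() == "G1 or G2"
    assert m.genes == {"G1", "G2"}


def test_sbml_loader_agrees_with_cobra(sbml_chain_path):
    """Independent cross-check: cobrapy reads the same bounds and GPRs."""
    cobra = pytest.importorskip("cobra")
    ours = load_model(sbml_chain_path, dialect="sbml-fbc")
    theirs = cobra.io.read_sbml_model(str(sbml_chain_path))
    assert len(theirs.reactions) == len(ours.reactions)
    for r in theirs.reactions:
        mine = ours.reaction(r.id)
        assert (mine.lower_bound, mine.upper_bound) == r.bounds
    assert {g.id for g in theirs.genes} == ours.genes


def test_malformed_files_raise_model_error(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ModelError, match="malformed"):
        load_model(bad)
    no_obj = tmp_path / "noobj.json"
    no_obj.write_text(json.dumps({"metabolites": ["A"], "reactions": []}))
    with pytest.raises(ModelError, match="objective"):
        load_model(no_obj)


def test_validation_rejects_inconsistencies():
    mets = [Metabolite("A")]
    with pytest.raises(ModelError, match="unknown metabolite"):
        MetabolicModel(
            mets, [Reaction("R", {"Z": -1.0}, 0, 1)], set(), "R"
        ).validate()
    with pytest.raises(ModelError, match="lower bound"):
        MetabolicModel(
            mets, [Reaction("R", {"A": -1.0}, 5, 1)], set(), "R"
        ).validate()
    with pytest.raises(ModelError, match="objective"):
        MetabolicModel(
            mets, [Reaction("R", {"A": -1.0}, 0, 1)], set(), "MISSING"
        ).validate()


# ---------------------------------------------------------------------------
# gene deletions
# ---------------------------------------------------------------------------


def test_deletion_of_one_isozyme_keeps_reaction(serine_model):
    m = apply_gene_deletions(serine_model, {"GNP1"})
    r = m.reaction("SERt")  # GNP1 or AGP1: the paralog still carries the flux
    assert (r.lower_bound, r.upper_bound) == (0.0, 1000.0)


def test_deletion_of_both_isozymes_blocks_reaction(serine_model):
    m = apply_gene_deletions(serine_model, {"GNP1", "AGP1"})
    r = m.reaction("SERt")
    assert (r.lower_bound, r.upper_bound) == (0.0, 0.0)


def test_deletion_of_complex_subunit_blocks_reaction(serine_model):
    m = apply_gene_deletions(serine_model, {"LCB1"})  # SPT needs LCB1 and LCB2
    assert m.reaction("SPT").upper_bound == 0.0


def test_unknown_gene_warns_and_is_noop(serine_model):
    with pytest.warns(UserWarning, match="not present"):
        m = apply_gene_deletions(serine_model, {"NOPE1"})
    for r in serine_model.reactions:
        r2 = m.reaction(r.id)
        assert (r2.lower_bound, r2.upper_bound) == (r.lower_bound, r.upper_bound)


def test_empty_deletion_is_identity_and_deletions_are_monotone(serine_model):
    base = apply_gene_deletions(serine_model, set())
    for r in serine_model.reactions:
        assert base.reaction(r.id).upper_bound == r.upper_bound
    # supersets of deletions never re-enable a reaction
    small = apply_gene_deletions(serine_model, {"GNP1"})
    big = apply_gene_deletions(serine_model, {"GNP1", "AGP1", "SER2"})
    for r in small.reactions:
        if (r.lower_bound, r.upper_bound) == (0.0, 0.0):
            r2 = big.reaction(r.id)
            assert (r2.lower_bound, r2.upper_bound) == (0.0, 0.0)


def test_sey6210_genotype_preset():
    assert genotype_deletions("sey6210") == {
        "LEU2", "URA3", "HIS3", "TRP1", "LYS2", "SUC2"
    }


# ---------------------------------------------------------------------------
# media and exchange bounds
# ---------------------------------------------------------------------------


def test_apply_medium_sets_uptake_and_closes_rest(serine_model):
    medium = MediumDefinition("glc-only", {"EX_glc": 10.0})
    m = apply_medium(serine_model, medium, closed_default=True)
    assert m.reaction("EX_glc").lower_bound == -10.0
    assert m.reaction("EX_ser").lower_bound == 0.0
    # secretion upper bounds untouched
    assert m.reaction("EX_gly").upper_bound == 1000.0


def test_apply_medium_is_idempotent(serine_model):
    medium = MediumDefinition("glc-only", {"EX_glc": 7.0})
    once = apply_medium(serine_model, medium)
    twice = apply_medium(once, medium)
    for r in once.reactions:
        r2 = twice.reaction(r.id)
        assert (r2.lower_bound, r2.upper_bound) == (r.lower_bound, r.upper_bound)


def test_empty_medium_closes_all_uptake(chain_model):
    from serflux.fva import fba_maximize

    m = apply_medium(chain_model, MediumDefinition("empty", {}), closed_default=True)
    assert fba_maximize(m).objective_value == pytest.approx(0.0, abs=1e-9)


def test_apply_medium_unresolvable_exchange_errors(serine_model):
    with pytest.raises(ModelError, match="EX_missing"):
        apply_medium(serine_model, MediumDefinition("bad", {"EX_missing": 1.0}))
    with pytest.raises(ModelError, match="SHM"):
        apply_medium(serine_model, MediumDefinition("bad", {"SHM": 1.0}))


def test_medium_bounds_must_be_nonnegative():
    with pytest.raises(ModelError):
        MediumDefinition("bad", {"EX_glc": -1.0})


def test_set_exchange_bound_modes(chain_model):
    fixed = set_exchange_bound(chain_model, "EX_A", 0.0, mode="fixed")
    assert (fixed.reaction("EX_A").lower_bound, fixed.reaction("EX_A").upper_bound) == (0.0, 0.0)
    capped = set_exchange_bound(chain_model, "EX_A", 5.0, mode="max")
    assert capped.reaction("EX_A").lower_bound == -5.0
    assert capped.reaction("EX_A").upper_bound == 1000.0
    # re-fixing restores exactly; each call is idempotent in its result
    again = set_exchange_bound(set_exchange_bound(chain_model, "EX_A", 2.5), "EX_A", 0.0)
    assert (again.reaction("EX_A").lower_bound, again.reaction("EX_A").upper_bound) == (0.0, 0.0)


def test_set_exchange_bound_rejects_non_exchange(serine_model):
    with pytest.raises(ModelError, match="not an exchange"):
        set_exchange_bound(serine_model, "SHM", 1.0)
    with pytest.raises(ValueError):
        set_exchange_bound(serine_model, "EX_ser", -1.0)


def test_medium_yaml_presets_load():
    from importlib import resources
    from serflux.model import load_medium

    for name in ("sdc", "ypd"):
        path = resources.files("serflux") / "config" / f"{name}.yaml"
        medium = load_medium(str(path), name=name)
        assert medium.uptake_bounds["EX_glc"] == 10.0
        aa_and_bases = [k for k in medium.uptake_bounds if k != "EX_glc"]
        assert len(aa_and_bases) == 24  # 20 amino acids + 4 nucleobases
        assert all(medium.uptake_bounds[k] == 1.0 for k in aa_and_bases)
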