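"""Gamete rules, cross enumeration, presets and sex-linkage properties."""

import itertools

import pytest

from hybridogen.crosses import (
    AMPHI,
    ELIMINATE_L,
    MENDELIAN,
    FrogGenotype,
    GameteRule,
    GenomeCopy,
    LX,
    LY,
    RX,
    Viability,
    cross,
    cross_from_preset,
    cross_table,
    gamete_distribution,
    generation_step,
    system_preset,
)
from hybridogen.errors import ConfigurationError, ModelError

HYBRID_F = FrogGenotype.parse("LxRx")
HYBRID_M = FrogGenotype.parse("LyRx")
LESSONAE_M = FrogGenotype.parse("LxLy")
LESSONAE_F = FrogGenotype.parse("LxLx")


def test_sex_is_a_pure_function_of_copies():
    assert HYBRID_F.sex == "F"
    assert HYBRID_M.sex == "M"
    assert LESSONAE_M.sex == "M"
    assert FrogGenotype.parse("RxRx").sex == "F"


def test_r_genome_is_strictly_x_linked_by_default():
    with pytest.raises(ModelError, match="X-linked"):
        FrogGenotype.parse("LxRy")
    relaxed = FrogGenotype.parse("LxRy", allow_r_y=True)
    assert relaxed.sex == "M"


def test_hybridogenetic_elimination_transmits_clonal_r():
    dist = gamete_distribution(HYBRID_F, GameteRule(ELIMINATE_L))
    assert dist == {(RX,): 1.0}


def test_amphigamy_splits_by_q():
    dist = gamete_distribution(HYBRID_M, GameteRule(AMPHI, q=0.5))
    assert dist == {(LY,): 0.5, (RX,): 0.5}
    biased = gamete_distribution(HYBRID_M, GameteRule(AMPHI, q=0.9))
    assert biased[(LY,)] == pytest.approx(0.9)


def test_mendelian_segregation_of_lessonae_male():
    dist = gamete_distribution(LESSONAE_M, GameteRule(MENDELIAN))
    assert dist == {(LX,): 0.5, (LY,): 0.5}


def test_inapplicable_rule_raises():
    with pytest.raises(ModelError, match="not applicable"):
        gamete_distribution(LESSONAE_M, GameteRule(ELIMINATE_L))


def test_triploid_rule_recombined_and_unreduced_gametes():
    llr = FrogGenotype.parse("LxLyRx")
    rule = GameteRule(
        "TRIPLOID_RULE", triploid_table={"LLR": (("L", 0.5), ("LL", 0.5))}
    )
    dist = gamete_distribution(llr, rule)
    assert dist[(LX,)] == pytest.approx(0.25)
    assert dist[(LY,)] == pytest.approx(0.25)
    assert dist[tuple(sorted((LX, LY)))] == pytest.approx(0.5)


def test_le_backcross_yields_equal_hybrid_sexes():
    """Hybrid female x lessonae male: clonal R egg meets Mendelian L
    sperm -> half LxRx daughters, half LyRx sons."""
    preset = system_preset("L_E")
    res = cross_from_preset(preset, HYBRID_F, LESSONAE_M)
    assert res.pre == {
        HYBRID_F: pytest.approx(0.5),
        HYBRID_M: pytest.approx(0.5),
    }
    assert res.post == res.pre  # hybrids fully viable


def test_le_interhybrid_cross_is_unviable_rr():
    preset = system_preset("L_E")
    res = cross_from_preset(preset, HYBRID_F, HYBRID_M)
    assert res.pre == {FrogGenotype.parse("RxRx"): pytest.approx(1.0)}
    assert res.post == {}  # w_RR = 0: nothing survives


def test_ee_amphigamy_punnett_square():
    preset = system_preset("E_E_DIPLOID_AMPHIGAMY")
    res = cross_from_preset(preset, HYBRID_F, HYBRID_M)
    expected = {
        FrogGenotype.parse("LxLy"): 0.25,
        FrogGenotype.parse("LxRx"): 0.25,
        FrogGenotype.parse("LyRx"): 0.25,
        FrogGenotype.parse("RxRx"): 0.25,
    }
    assert {g: pytest.approx(p) for g, p in res.pre.items()} == expected
    # homotypic offspring carry the load
    assert set(res.post) == {HYBRID_F, HYBRID_M}


def test_ee_amphigamy_sex_linkage_theorem():
    """Every RR offspring is female and every LL offspring male, each at
    exact pre-viability mass 0.25 — the system's predicted by-products."""
    preset = system_preset("E_E_DIPLOID_AMPHIGAMY")
    res = cross_from_preset(preset, HYBRID_F, HYBRID_M)
    for g, p in res.pre.items():
        if g.composition == "RR":
            assert g.sex == "F" and p == pytest.approx(0.25)
        if g.composition == "LL":
            assert g.sex == "M" and p == pytest.approx(0.25)


def test_cross_equals_gamete_pair_enumeration_for_all_presets():
    """Oracle: for every preset and applicable parent pair, cross() must
    equal the explicit double loop over egg and sperm distributions."""
    parents = {
        "L_E": [(HYBRID_F, LESSONAE_M), (HYBRID_F, HYBRID_M), (LESSONAE_F, LESSONAE_M)],
        "R_E": [
            (FrogGenotype.parse("RxRx"), HYBRID_M),
            (HYBRID_F, HYBRID_M),
        ],
        "E_E_DIPLOID_AMPHIGAMY": [(HYBRID_F, HYBRID_M)],
        "E_E_TRIPLOID": [
            (HYBRID_F, HYBRID_M),  # LR egg + R sperm -> LRR triploid
            (FrogGenotype.parse("LxLxRx"), HYBRID_M),
            (FrogGenotype.parse("LxRxRx"), HYBRID_M),
        ],
    }
    for name, pairs in parents.items():
        preset = system_preset(name)
        for mother, father in pairs:
            res = cross_from_preset(preset, mother, father)
            eggs = gamete_distribution(mother, preset.rule_for(mother))
            sperm = gamete_distribution(father, preset.rule_for(father))
            expected: dict = {}
            for (egg, pe), (sp, ps) in itertools.product(eggs.items(), sperm.items()):
                child = FrogGenotype(egg + sp)
                expected[child] = expected.get(child, 0.0) + pe * ps
            assert set(res.pre) == set(expected)
            for g, p in expected.items():
                assert res.pre[g] == pytest.approx(p)
            assert sum(res.pre.values()) == pytest.approx(1.0)


def test_le_closure_no_homotypic_offspring_over_five_generations():
    """Backcrossing hybrids to lessonae under the L-E preset never
    creates LL or RR frogs from hybrid matings."""
    preset = system_preset("L_E")
    hybrids = {HYBRID_F, HYBRID_M}
    for _ in range(5):
        next_gen = set()
        for mother in [g for g in hybrids if g.sex == "F"]:
            res = cross_from_preset(preset, mother, LESSONAE_M)
            next_gen.update(res.post)
        for father in [g for g in hybrids if g.sex == "M"]:
            res = cross_from_preset(preset, LESSONAE_F, father)
            next_gen.update(res.post)
        assert all(g.is_hybrid for g in next_gen)
        hybrids = next_gen


def test_generation_step_conserves_probability():
    preset = system_preset("E_E_DIPLOID_AMPHIGAMY")
    freqs = {HYBRID_F: 0.5, HYBRID_M: 0.5}
    nxt = generation_step(freqs, preset)
    assert sum(nxt.values()) == pytest.approx(1.0)
    assert set(nxt) == {HYBRID_F, HYBRID_M}  # load removes LL and RR


def test_preset_lookup_and_errors():
    with pytest.raises(ConfigurationError, match="unknown preset"):
        system_preset("X_E")
    with pytest.raises(ModelError, match="not female"):
        cross(HYBRID_M, GameteRule(ELIMINATE_L), HYBRID_M, GameteRule(ELIMINATE_L))


def test_cross_table_layout():
    preset = system_preset("E_E_DIPLOID_AMPHIGAMY")
    df = cross_table(cross_from_preset(preset, HYBRID_F, HYBRID_M))
    assert list(df.columns) == [
        "genotype", "composition", "sex", "pre_viability_p", "post_viability_p"
    ]
    assert df["pre_viability_p"].sum() == pytest.approx(1.0)
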