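"""Free-energy evaluation, reaction algebra, crossovers and windows."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synprop import thermo as th

RT = th.R_KJ * 310.15


def oracle_dg(reaction, conditions):
    """Term-by-term independent evaluation of dG0' + RT * sum(nu_i ln a_i)."""
    total = reaction.dg0_prime
    for sp, coeff in reaction.stoichiometry.items():
        if sp == "H2O":
            a = 1.0
        elif sp == "H+":
            a = 10 ** (-conditions.pH) / 1e-7
        else:
            a = conditions.activities[sp]
        total += float(coeff) * th.R_KJ * conditions.temperature * math.log(a)
    return total


# --------------------------------------------------------------------------
# delta_g_prime


def test_hydrogenotrophic_methanogenesis_at_1e4_atm(registry, digester):
    dg = th.delta_g_prime(
        registry["hydrogenotrophic_methanogenesis"], digester.with_h2(1e-4)
    )
    assert dg == pytest.approx(-32, abs=1)


def test_propionate_oxidation_at_1e1_atm(registry, digester):
    dg = th.delta_g_prime(registry["propionate_oxidation"], digester.with_h2(1e-1))
    assert dg == pytest.approx(48, abs=1)


@pytest.mark.parametrize(
    "name", th.REGISTRY_ORDER
)
def test_unit_activities_recover_dg0(registry, name):
    """With all activities 1 and pH 7 the quotient is 1 and dG' = dG0'."""
    rxn = registry[name]
    species = [s for s in rxn.stoichiometry if s not in ("H2O", "H+")]
    cond = th.Conditions(310.15, {s: 1.0 for s in species}, pH=7.0)
    assert th.delta_g_prime(rxn, cond) == rxn.dg0_prime


@st.composite
def random_reaction_and_conditions(draw):
    n = draw(st.integers(2, 5))
    species = [f"S{i}" for i in range(n)]
    coeffs = [
        Fraction(draw(st.integers(-8, 8)), draw(st.integers(1, 4))) for _ in species
    ]
    if all(c == 0 for c in coeffs):
        coeffs[0] = Fraction(1)
    stoich = dict(zip(species, coeffs))
    stoich["H2O"] = Fraction(draw(st.integers(-3, 3)))
    stoich["H+"] = Fraction(draw(st.integers(-2, 2)))
    rxn = th.Reaction("random", stoich, draw(st.floats(-200, 200)))
    cond = th.Conditions(
        temperature=draw(st.floats(273.0, 373.0)),
        activities={
            s: draw(st.floats(1e-8, 10.0)) for s in species
        },
        pH=draw(st.floats(4.0, 10.0)),
    )
    return rxn, cond


@settings(max_examples=100, deadline=None)
@given(random_reaction_and_conditions())
def test_delta_g_matches_term_by_term_oracle(case):
    rxn, cond = case
    assert th.delta_g_prime(rxn, cond) == pytest.approx(oracle_dg(rxn, cond), rel=1e-12, abs=1e-9)


def test_missing_activity_raises(registry):
    cond = th.Conditions(310.15, {"acetate": 1e-3}, pH=7.0)
    with pytest.raises(th.ThermoError, match="no activity"):
        th.delta_g_prime(registry["propionate_oxidation"], cond)


def test_non_positive_activity_rejected():
    with pytest.raises(th.ThermoError, match="non-positive"):
        th.Conditions(310.15, {"H2": 0.0})


# --------------------------------------------------------------------------
# combine_reactions


def test_syntrophic_coculture_combination(registry):
    """Propionate oxidation + 0.75 x HM gives the net coculture equation."""
    combined = th.combine_reactions(
        [
            (registry["propionate_oxidation"], 1),
            (registry["hydrogenotrophic_methanogenesis"], Fraction(3, 4)),
        ]
    )
    assert combined.stoichiometry == {
        "propionate": Fraction(-1),
        "H2O": Fraction(-3, 4),
        "acetate": Fraction(1),
        "CH4": Fraction(3, 4),
        "HCO3-": Fraction(1, 4),
        "H+": Fraction(1, 4),
    }


def test_self_cancellation_gives_null_reaction(registry):
    rxn = registry["syntrophic_acetate_oxidation"]
    null = th.combine_reactions([(rxn, 1), (rxn, -1)])
    assert null.stoichiometry == {}
    assert null.dg0_prime == 0.0


def test_sao_plus_hm_equals_acetoclastic(registry):
    combined = th.combine_reactions(
        [
            (registry["syntrophic_acetate_oxidation"], 1),
            (registry["hydrogenotrophic_methanogenesis"], 1),
        ]
    )
    am = registry["acetoclastic_methanogenesis"]
    assert combined.stoichiometry == am.stoichiometry
    assert combined.dg0_prime == pytest.approx(-31.0, abs=1e-9)


def test_empty_combination_rejected():
    with pytest.raises(th.ThermoError):
        th.combine_reactions([])


@settings(max_examples=50, deadline=None)
@given(random_reaction_and_conditions(), st.floats(-3, 3))
def test_additivity_of_free_energy(case, mult):
    """dG' of a linear combination is the combination of dG' values."""
    rxn, cond = case
    doubled = th.combine_reactions([(rxn, 1), (rxn, mult)])
    expected = (1 + mult) * th.delta_g_prime(rxn, cond)
    if doubled.stoichiometry:
        assert th.delta_g_prime(doubled, cond) == pytest.approx(expected, abs=1e-6)


# --------------------------------------------------------------------------
# crossovers and windows


def test_sao_crossover_near_5e5_atm(registry, digester):
    p = th.h2_crossover(registry["syntrophic_acetate_oxidation"], digester)
    assert p == pytest.approx(5e-5, rel=0.10)


def test_acetoclastic_has_no_crossover(registry, digester):
    with pytest.raises(th.ThermoError, match="no H2 term"):
        th.h2_crossover(registry["acetoclastic_methanogenesis"], digester)


def test_hm_crossover_matches_bisection_and_sign_change(registry, digester):
    """Analytic crossover agrees with a bracketing root search, and sits in
    the decade where the reference sweep changes sign (+16 at 1e-6, -8 at 1e-5)."""
    hm = registry["hydrogenotrophic_methanogenesis"]
    p = th.h2_crossover(hm, digester)
    assert 1e-6 < p < 1e-5
    assert p == pytest.approx(4.6e-6, rel=0.05)
    lo, hi = 1e-8, 1e-2
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if th.delta_g_prime(hm, digester.with_h2(mid)) > 0:
            lo = mid
        else:
            hi = mid
    assert p == pytest.approx(math.sqrt(lo * hi), rel=1e-6)


def test_syntrophic_window_for_propionate_oxidation(registry, digester):
    lo, hi = th.h2_window(
        registry["propionate_oxidation"],
        registry["hydrogenotrophic_methanogenesis"],
        digester,
    )
    assert lo == pytest.approx(4.6e-6, rel=0.05)
    assert hi == pytest.approx(2.0e-4, rel=0.05)
    assert lo < 1e-5 < 1e-4 < hi  # both sweep points feasible
    assert not (lo < 1e-6 < hi) and not (lo < 1e-3 < hi)


def test_window_rejects_wrong_h2_signs(registry, digester):
    with pytest.raises(th.ThermoError):
        th.h2_window(
            registry["autotrophic_homoacetogenesis"],
            registry["syntrophic_acetate_oxidation"],
            digester,
        )


# --------------------------------------------------------------------------
# sweep table and its invariants


def test_balance_point_row(registry, digester):
    """At 5e-5 atm H2 both methanogenesis routes deliver -25 kJ and the
    acetate/H2 interconversions idle at 0."""
    table = th.free_energy_table(
        [registry[n] for n in th.REGISTRY_ORDER], digester, [5e-5]
    )
    row = table.iloc[0]
    assert row["hydrogenotrophic_methanogenesis"] == pytest.approx(-25, abs=1)
    assert row["acetoclastic_methanogenesis"] == pytest.approx(-25, abs=1)
    assert row["syntrophic_acetate_oxidation"] == pytest.approx(0, abs=1)
    assert row["autotrophic_homoacetogenesis"] == pytest.approx(0, abs=1)


def test_sao_aha_antisymmetry_across_sweep(registry, digester):
    table = th.free_energy_table(
        [registry["syntrophic_acetate_oxidation"], registry["autotrophic_homoacetogenesis"]],
        digester,
        th.REFERENCE_PH2,
    )
    for _, row in table.iterrows():
        assert row["autotrophic_homoacetogenesis"] == pytest.approx(
            -row["syntrophic_acetate_oxidation"], abs=1e-9
        )


def test_acetoclastic_independent_of_ph2(registry, digester):
    table = th.free_energy_table(
        [registry["acetoclastic_methanogenesis"]], digester, th.REFERENCE_PH2
    )
    values = table["acetoclastic_methanogenesis"]
    assert values.max() - values.min() < 1e-12


@pytest.mark.parametrize("name", ["propionate_oxidation", "hydrogenotrophic_methanogenesis"])
def test_per_decade_slope_is_nu_rt_ln10(registry, digester, name):
    """A tenfold pH2 change moves dG' by exactly nu * R * T * ln 10."""
    rxn = registry[name]
    nu = float(rxn.coefficient("H2"))
    for p in (1e-6, 1e-4, 1e-2):
        step = th.delta_g_prime(rxn, digester.with_h2(10 * p)) - th.delta_g_prime(
            rxn, digester.with_h2(p)
        )
        assert step == pytest.approx(nu * RT * math.log(10), abs=1e-9)


def test_monotonicity_in_ph2(registry, digester):
    sweep = [10**e for e in range(-8, 1)]
    for name in th.REGISTRY_ORDER:
        rxn = registry[name]
        nu = float(rxn.coefficient("H2"))
        values = [th.delta_g_prime(rxn, digester.with_h2(p)) for p in sweep]
        diffs = [b - a for a, b in zip(values, values[1:])]
        if nu > 0:
            assert all(d > 0 for d in diffs)
        elif nu < 0:
            assert all(d < 0 for d in diffs)


def test_empty_or_invalid_sweep_rejected(registry, digester):
    with pytest.raises(th.ThermoError):
        th.free_energy_table([registry["propionate_oxidation"]], digester, [])
    with pytest.raises(th.ThermoError):
        th.free_energy_table([registry["propionate_oxidation"]], digester, [-1e-4])


def test_rounding_ties_away_from_zero():
    assert th.round_half_away(0.5) == 1
    assert th.round_half_away(-0.5) == -1
    assert th.round_half_away(-24.5) == -25
    assert th.round_half_away(2.4) == 2
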