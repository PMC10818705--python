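"""Marcus rate law, thermochemistry, and measured-table comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopmap import (
    BOLTZMANN_EV_PER_K,
    ETParameters,
    PotentialTable,
    RateTable,
    RedoxCouple,
    coupling_decay,
    driving_force,
    fold_change_for_potential_shift,
    franck_condon_factor,
    marcus_rate,
    max_potential_spread,
    percent_rate_difference,
    reverse_rate,
    round_to_nearest_ten_percent,
)
from hopmap.errors import ConfigError, DataError

TYR_GROUP = ["Tyr109Met122", "Tyr109Gln122", "Tyr109Arg122"]


def test_thermal_energy_at_298K(params):
    assert params.kbt == pytest.approx(BOLTZMANN_EV_PER_K * 298, rel=1e-12)
    assert params.kbt == pytest.approx(0.02568, abs=5e-6)


@pytest.mark.parametrize(
    "e_donor, e_acceptor, expected",
    [
        (0.975, 1.0, -0.025),  # Tyr109(Met122) at pH 6 -> Ru(III)
        (0.5, 0.5, 0.0),
        (0.288, 1.0, -0.712),  # Cu at pH 9 -> Ru(III)
    ],
)
def test_driving_force_is_minus_potential_difference(e_donor, e_acceptor, expected):
    dg = driving_force(RedoxCouple("d", e_donor), RedoxCouple("a", e_acceptor))
    assert dg == pytest.approx(expected, abs=1e-12)


def test_driving_force_rejects_multielectron_couples():
    with pytest.raises(ConfigError):
        RedoxCouple("two-electron", 0.5, n_electrons=2)


@pytest.mark.parametrize(
    "dg, expected",
    [
        (-0.8, 1.0),  # activationless point dG = -lambda
        (0.0, 4.145705335043189e-4),
        (-1.6, 4.145705335043189e-4),  # symmetric partner of dG = 0
    ],
)
def test_franck_condon_factor_values(params, dg, expected):
    assert franck_condon_factor(dg, params) == pytest.approx(expected, rel=1e-9)


def test_parameter_validation_rejects_nonphysical_values():
    for bad in (
        {"lambda_reorg": -0.1},
        {"lambda_reorg": 0.0},
        {"temperature": 0.0},
        {"beta": -1.0},
        {"k0": 0.0},
        {"r0": -1.0},
    ):
        with pytest.raises(ConfigError):
            ETParameters(**bad)


@pytest.mark.parametrize(
    "r, expected",
    [
        (3.0, 1.0),  # contact
        (16.5, 3.5540779088906284e-7),
        (34.8, 6.432488567727091e-16),
    ],
)
def test_coupling_decay_values(params, r, expected):
    assert coupling_decay(r, params) == pytest.approx(expected, rel=1e-9)


def test_coupling_decay_rejects_distances_inside_contact(params):
    with pytest.raises(ConfigError):
        coupling_decay(2.0, params)


def test_marcus_rate_activationless_contact_equals_k0(params):
    assert marcus_rate(-params.lambda_reorg, params.r0, params) == pytest.approx(
        params.k0, rel=1e-12
    )


def test_marcus_rate_first_hopping_step(params):
    # dG = -0.025 eV over 16.5 A: the Ru(III) <- Tyr109 oxidation step
    assert marcus_rate(-0.025, 16.5, params) == pytest.approx(2379.1528571988, rel=1e-9)


def test_marcus_rate_e_fold_per_inverse_beta(params):
    r = 10.0
    ratio = marcus_rate(-0.3, r + 1 / params.beta, params) / marcus_rate(-0.3, r, params)
    assert ratio == pytest.approx(1 / math.e, rel=1e-12)


@pytest.mark.parametrize(
    "dg, factor",
    [(0.0, 1.0), (-0.025, 0.37774593873897083)],
)
def test_reverse_rate_detailed_balance_factor(params, dg, factor):
    assert reverse_rate(1000.0, dg, params) == pytest.approx(1000.0 * factor, rel=1e-9)


def test_reverse_rate_rejects_nonpositive_forward(params):
    with pytest.raises(ConfigError):
        reverse_rate(0.0, -0.1, params)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    dg=st.floats(-1.5, 1.5),
    r=st.floats(3.0, 40.0),
)
def test_detailed_balance_holds_for_any_driving_force(dg, r):
    """k_f / k_r = exp(-dG/kBT) is intrinsic to the Marcus form."""
    params = ETParameters()
    kf = marcus_rate(dg, r, params)
    kr = marcus_rate(-dg, r, params)
    assert kf / kr == pytest.approx(math.exp(-dg / params.kbt), rel=1e-9)
    # and reverse_rate reproduces the sign-flipped Marcus evaluation
    assert reverse_rate(kf, dg, params) == pytest.approx(kr, rel=1e-9)


def test_franck_condon_symmetric_about_minus_lambda_with_unique_max(params):
    lam = params.lambda_reorg
    offsets = np.linspace(0.0, 1.2, 61)
    left = franck_condon_factor(-lam - offsets, params)
    right = franck_condon_factor(-lam + offsets, params)
    np.testing.assert_allclose(left, right, rtol=1e-12)
    grid = franck_condon_factor(np.linspace(-2.5, 1.5, 401), params)
    assert grid.max() <= 1.0
    assert franck_condon_factor(-lam, params) == 1.0
    assert (grid < 1.0).sum() >= 400  # maximum is unique on the grid


def test_log_rate_is_linear_in_distance_with_slope_minus_beta(params):
    r = np.linspace(5.0, 30.0, 101)
    logk = np.log(marcus_rate(-0.3, r, params))
    slopes = np.diff(logk) / np.diff(r)
    np.testing.assert_allclose(slopes, -params.beta, rtol=1e-9)


# ---------------------------------------------------------------- tables


def test_max_potential_spread_of_tyr_variants_is_0p02(table2):
    assert max_potential_spread(table2, TYR_GROUP) == pytest.approx(0.02)


def test_max_potential_spread_single_species_is_zero(table2):
    assert max_potential_spread(table2, ["Tyr109Met122"]) == 0.0


def test_max_potential_spread_at_single_ph(table2):
    sub = PotentialTable(table2.frame[table2.frame["ph"] == 5])
    assert max_potential_spread(sub, TYR_GROUP) == pytest.approx(0.02)


def test_max_potential_spread_invariant_to_row_order_and_extra_species(table2):
    df = table2.frame
    shuffled = PotentialTable(df.sample(frac=1, random_state=0))
    assert max_potential_spread(shuffled, TYR_GROUP) == max_potential_spread(
        table2, TYR_GROUP
    )
    # Cu rows are outside the group and must not affect the spread
    no_cu = PotentialTable(df[df["species"] != "Cu"])
    assert max_potential_spread(no_cu, TYR_GROUP) == max_potential_spread(
        table2, TYR_GROUP
    )


def test_max_potential_spread_rejects_disjoint_ph_coverage():
    table = PotentialTable([(5.0, "a", 0.5), (7.0, "b", 0.6)])
    with pytest.raises(DataError):
        max_potential_spread(table, ["a", "b"])


@pytest.mark.parametrize(
    "delta_e, baseline, expected",
    [
        (0.0, 0.0, 1.0),
        (0.02, 0.0, 1.4689468338750504),  # rounds to the 1.5-fold change
        (0.02, -0.1, 1.3991557696202563),
    ],
)
def test_fold_change_for_potential_shift(params, delta_e, baseline, expected):
    assert fold_change_for_potential_shift(delta_e, baseline, params) == pytest.approx(
        expected, rel=1e-9
    )


def test_fold_change_0p02V_rounds_to_1p5(params):
    assert round(fold_change_for_potential_shift(0.02, 0.0, params), 1) == 1.5


def test_percent_rate_difference_met_vs_lys(table3):
    ph9 = percent_rate_difference(table3, "Met122", "Lys122", 9)
    assert ph9 == pytest.approx(44.44444444, rel=1e-6)
    assert round_to_nearest_ten_percent(ph9) == 40.0
    assert percent_rate_difference(table3, "Met122", "Lys122", 6) == pytest.approx(
        19.298245614, rel=1e-6
    )
    assert percent_rate_difference(table3, "Met122", "Met122", 7) == 0.0


def test_percent_rate_difference_missing_row_raises(table3):
    with pytest.raises(DataError):
        percent_rate_difference(table3, "Met122", "Lys122", 5)


def test_potential_table_rejects_bad_rows():
    with pytest.raises(DataError):
        PotentialTable([(6.0, "Cu", 0.339), (6.0, "Cu", 0.340)])  # duplicate key
    with pytest.raises(DataError):
        PotentialTable([(6.0, "Cu", 339.0)])  # mV-scale value
    with pytest.raises(DataError):
        PotentialTable([(15.0, "Cu", 0.339)])  # impossible pH


def test_rate_table_rejects_nonpositive_rates():
    with pytest.raises(DataError):
        RateTable([(6.0, "Met122", -1.0, 0.1)])
    with pytest.raises(DataError):
        RateTable([(6.0, "Met122", 1.0, -0.1)])
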