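"""Partition-function model: state enumeration, energies, predictions."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermoprom as tp
from thermoprom.model import _marginals_compressed, _marginals_enumerated
from conftest import oracle_marginals, random_params

GLU, AAS = "glucose", "AAS"


# ---------------------------------------------------------------------------
# state enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sites,competitive,expected", [
    ("", False, 2),
    ("Gcn4", False, 4),
    ("Gcn4", True, 6),
    ("Gcn4;Cbf1;Gcn4", False, 16),
    ("Gcn4;Cbf1;Gcn4", True, 36),
])
def test_state_count(sites, competitive, expected):
    spec = tp.study_spec(competitive=competitive)
    p = tp.Promoter.from_composition("p", sites)
    states = tp.enumerate_states(p, spec)
    assert len(states) == expected
    assert len(set(states)) == expected


def test_enumeration_cap_names_promoter(spec):
    p = tp.Promoter("too_long", tuple(["Cbf1"] * 25))
    with pytest.raises(tp.EnumerationLimitError, match="too_long"):
        tp.enumerate_states(p, spec)


def test_unknown_site_token_rejected(spec):
    p = tp.Promoter("bad", ("Cbf1", "Rap1"))
    with pytest.raises(tp.ConfigurationError, match="Rap1"):
        tp.enumerate_states(p, spec)


# ---------------------------------------------------------------------------
# state energy
# ---------------------------------------------------------------------------

def test_reference_state_energy_zero(spec, params):
    p = tp.Promoter.from_composition("p", "Gcn4;Cbf1")
    state = tp.PromoterState(("empty", "empty"), pol=False)
    assert tp.state_energy(state, p, params, GLU, spec) == 0.0


def test_all_zero_energies_give_zero(spec):
    from thermoprom.inference import default_base_params
    params = default_base_params(spec)
    p = tp.Promoter.from_composition("p", "Cbf1")
    state = tp.PromoterState(("Cbf1",), pol=True)
    assert tp.state_energy(state, p, params, GLU, spec) == 0.0


def test_hand_summed_energy(spec):
    """pol + 2 Gcn4 + 1 Nrg1 bound: pair terms count Gcn4-Gcn4 once, Gcn4-Nrg1 twice.

    By-hand sum: dna 2*(-1) + (-0.5); pol 1 + 2*(-2) + 1; tftf -0.3 + 2*0.2
    = -2.5 - 2.0 + 0.1 = -4.4.
    """
    from thermoprom.inference import default_base_params
    params = default_base_params(spec)
    params.dG_dna[("Gcn4", GLU)] = -1.0
    params.dG_dna[("Nrg1", GLU)] = -0.5
    params.dG_pol_basal[GLU] = 1.0
    params.dG_pol[("Gcn4", GLU)] = -2.0
    params.dG_pol[("Nrg1", GLU)] = 1.0
    params.dG_tftf[("Gcn4", "Gcn4")] = -0.3
    params.dG_tftf[("Gcn4", "Nrg1")] = 0.2
    p = tp.Promoter.from_composition("p", "Gcn4;Gcn4;Nrg1")
    state = tp.PromoterState(("Gcn4", "Gcn4", "Nrg1"), pol=True)
    assert tp.state_energy(state, p, params, GLU, spec) == pytest.approx(-4.4, abs=1e-12)


def test_competitor_has_no_tftf_terms(comp_spec, comp_params):
    """A competitor-bound site contributes DNA/pol energies but no TF pair terms."""
    comp_params.dG_tftf[("Gcn4", "Gcn4")] = -5.0
    p = tp.Promoter.from_composition("p", "Gcn4;Gcn4")
    both_comp = tp.PromoterState(("competitor", "competitor"), pol=False)
    e = tp.state_energy(both_comp, p, comp_params, GLU, comp_spec)
    assert e == pytest.approx(2 * comp_params.dG_comp_dna, abs=1e-12)


# ---------------------------------------------------------------------------
# partition function
# ---------------------------------------------------------------------------

def test_empty_promoter_partition(spec):
    from thermoprom.inference import default_base_params
    params = default_base_params(spec)
    p = tp.Promoter("p", ())
    part = tp.partition(p, params, GLU, spec)
    assert part.Z == pytest.approx(2.0, abs=1e-12)
    pol_prob = sum(pr for pr, s in zip(part.probabilities, part.states) if s.pol)
    assert pol_prob == pytest.approx(0.5, abs=1e-12)


def test_single_site_uniform_partition(spec):
    from thermoprom.inference import default_base_params
    params = default_base_params(spec)
    p = tp.Promoter.from_composition("p", "Nrg1")
    part = tp.partition(p, params, GLU, spec)
    assert part.Z == pytest.approx(4.0, abs=1e-12)
    np.testing.assert_allclose(part.probabilities, 0.25, atol=1e-12)


@pytest.mark.parametrize("competitive", [False, True])
def test_partition_matches_oracle(competitive):
    rng = np.random.default_rng(7)
    spec = tp.study_spec(competitive=competitive)
    p = tp.Promoter.from_composition("p", "Gcn4;Nrg1;Gcn4")
    prms = random_params(rng, spec)
    part = tp.partition(p, prms, AAS, spec)
    pol_prob = sum(pr for pr, s in zip(part.probabilities, part.states) if s.pol)
    o_pol, o_counts = oracle_marginals(p, prms, AAS, spec)
    assert pol_prob == pytest.approx(o_pol, abs=1e-12)
    assert part.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    sites=st.lists(st.sampled_from(tp.DEFAULT_FACTORS), max_size=8),
    competitive=st.booleans(),
    seed=st.integers(0, 10_000),
)
def test_probabilities_normalize(sites, competitive, seed):
    """State probabilities sum to 1 for random promoters and random energies."""
    spec = tp.study_spec(competitive=competitive)
    prms = random_params(np.random.default_rng(seed), spec)
    p = tp.Promoter("p", tuple(sites))
    part = tp.partition(p, prms, GLU, spec)
    assert part.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
    assert ((part.probabilities >= 0) & (part.probabilities <= 1)).all()


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def test_empty_promoter_expression(spec):
    from thermoprom.inference import default_base_params
    params = default_base_params(spec)
    p = tp.Promoter("p", ())
    assert tp.predict_expression(p, params, GLU, spec) == pytest.approx(0.5, abs=1e-12)


def test_saturated_repressor_silences(spec, params):
    """A saturating repressor site (huge favorable DNA, huge unfavorable pol) kills expression."""
    params.dG_dna[("Nrg1", GLU)] = -40.0
    params.dG_pol[("Nrg1", GLU)] = 40.0
    p = tp.Promoter.from_composition("p", "Nrg1")
    assert tp.predict_expression(p, params, GLU, spec) < 1e-12


@pytest.mark.parametrize("competitive", [False, True])
def test_predictions_match_oracle(competitive):
    rng = np.random.default_rng(13)
    spec = tp.study_spec(competitive=competitive)
    for _ in range(10):
        n = rng.integers(0, 6)
        p = tp.Promoter("p", tuple(rng.choice(spec.factors, size=n)))
        prms = random_params(rng, spec)
        cond = str(rng.choice(spec.conditions))
        o_pol, o_counts = oracle_marginals(p, prms, cond, spec)
        assert tp.predict_expression(p, prms, cond, spec) == pytest.approx(
            prms.expr_scale * o_pol, rel=1e-12, abs=1e-12)
        for f in spec.factors:
            assert tp.predict_bound_count(p, f, prms, cond, spec) == pytest.approx(
                o_counts[f], rel=1e-12, abs=1e-12)


def test_bound_count_basics(spec, params):
    p = tp.Promoter.from_composition("p", "Cbf1;Cbf1")
    assert tp.predict_bound_count(p, "Gcn4", params, GLU, spec) == 0.0
    from thermoprom.inference import default_base_params
    zero = default_base_params(spec)
    single = tp.Promoter.from_composition("p", "Met31")
    assert tp.predict_bound_count(single, "Met31", zero, GLU, spec) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(tp.ConfigurationError):
        tp.predict_bound_count(p, "Rap1", params, GLU, spec)


def test_independent_sites_factorize(spec, params):
    """Without TF-TF terms, per-branch site weights factorize: the closed form
    for n identical independent sites matches the joint computation."""
    params.dG_tftf.clear()
    n = 3
    p = tp.Promoter("p", tuple(["Cbf1"] * n))
    q = math.exp(-params.dG_dna[("Cbf1", GLU)])
    w_pol = math.exp(-params.dG_pol_basal[GLU])
    omega = math.exp(-params.dG_pol[("Cbf1", GLU)])
    Z = (1 + q) ** n + w_pol * (1 + q * omega) ** n
    expected_count = n * (q * (1 + q) ** (n - 1) + w_pol * q * omega * (1 + q * omega) ** (n - 1)) / Z
    assert tp.predict_bound_count(p, "Cbf1", params, GLU, spec) == pytest.approx(
        expected_count, rel=1e-12)
    expected_pol = w_pol * (1 + q * omega) ** n / Z
    assert tp.predict_expression(p, params, GLU, spec) == pytest.approx(
        params.expr_scale * expected_pol, rel=1e-12)


def test_relative_occupancy_prediction(spec, params):
    p0 = tp.Promoter.from_composition("p0", "Met31")
    assert tp.predict_relative_occupancy(p0, "Gcn4", params, GLU, spec) == 1.0
    params.occ_scale["Gcn4"] = 0.0
    p2 = tp.Promoter.from_composition("p2", "Gcn4;Gcn4")
    assert tp.predict_relative_occupancy(p2, "Gcn4", params, GLU, spec) == 1.0
    params.occ_scale["Gcn4"] = 3.0
    o_pol, o_counts = oracle_marginals(p2, params, GLU, spec)
    assert tp.predict_relative_occupancy(p2, "Gcn4", params, GLU, spec) == pytest.approx(
        1.0 + 3.0 * o_counts["Gcn4"], rel=1e-12)


def test_tagged_override_changes_pol_not_dna(spec, params):
    """The tagged-library polymerase override shifts expression but shares dG_dna."""
    spec_o = tp.study_spec(pol_overrides=[("Cbf1", "cbf1lib")])
    params.dG_pol_override[("Cbf1", "cbf1lib")] = -3.0
    tagged = tp.Promoter("t", ("Cbf1", "Cbf1"), library_tag="cbf1lib")
    untagged = tp.Promoter("u", ("Cbf1", "Cbf1"), library_tag="other")
    e_t = tp.predict_expression(tagged, params, GLU, spec_o)
    e_u = tp.predict_expression(untagged, params, GLU, spec_o)
    assert e_t > e_u  # more favorable pol contact
    o_pol, o_counts = oracle_marginals(tagged, params, GLU, spec_o)
    assert e_t == pytest.approx(params.expr_scale * o_pol, rel=1e-12)


# ---------------------------------------------------------------------------
# monotonicity and limits
# ---------------------------------------------------------------------------

def test_binding_energy_monotonicity(spec):
    """More favorable dG_dna never decreases bound count; more favorable
    dG_pol never decreases expression when the factor is present."""
    rng = np.random.default_rng(23)
    for _ in range(20):
        prms = random_params(rng, spec)
        n = int(rng.integers(1, 6))
        sites = tuple(rng.choice(spec.factors, size=n))
        p = tp.Promoter("p", sites)
        f = str(rng.choice(list(set(sites))))
        c = str(rng.choice(spec.conditions))
        b0 = tp.predict_bound_count(p, f, prms, c, spec)
        e0 = tp.predict_expression(p, prms, c, spec)
        prms.dG_dna[(f, c)] -= 1.0
        assert tp.predict_bound_count(p, f, prms, c, spec) >= b0 - 1e-12
        prms.dG_dna[(f, c)] += 1.0
        prms.dG_pol[(f, c)] -= 1.0
        assert tp.predict_expression(p, prms, c, spec) >= e0 - 1e-12


def test_competitive_reduces_to_noncompetitive(comp_spec, spec):
    """As the competitor's DNA contact becomes impossible, the competitive
    model converges to the plain two-state model."""
    rng = np.random.default_rng(31)
    prms = random_params(rng, spec, with_tftf=True)
    prms_c = prms.copy()
    prms_c.dG_comp_dna = 50.0
    prms_c.dG_comp_pol = rng.normal()
    p = tp.Promoter("p", ("Gcn4", "Cbf1", "Gcn4", "Nrg1"))
    for c in spec.conditions:
        assert tp.predict_expression(p, prms_c, c, comp_spec) == pytest.approx(
            tp.predict_expression(p, prms, c, spec), abs=1e-9)
        for f in spec.factors:
            assert tp.predict_bound_count(p, f, prms_c, c, comp_spec) == pytest.approx(
                tp.predict_bound_count(p, f, prms, c, spec), abs=1e-9)


def test_adjacent_pair_mode_differs_and_matches_enumeration():
    """Adjacent-only interaction counting gives chain energies; with three
    co-bound TFs it diverges from all-pairs but both marginal paths agree."""
    from dataclasses import replace
    spec_all = tp.study_spec()
    spec_adj = replace(spec_all, pair_mode="adjacent")
    prms = random_params(np.random.default_rng(3), spec_all)
    p = tp.Promoter("p", ("Gcn4", "Cbf1", "Gcn4"))
    e_all = tp.predict_expression(p, prms, GLU, spec_all)
    e_adj = tp.predict_expression(p, prms, GLU, spec_adj)
    assert e_all != pytest.approx(e_adj, rel=1e-6)
    # chain state: Gcn4-Cbf1 and Cbf1-Gcn4 adjacent pairs, no Gcn4-Gcn4 term
    state = tp.PromoterState(("Gcn4", "Cbf1", "Gcn4"), pol=False)
    e = tp.state_energy(state, p, prms, GLU, spec_adj)
    expected = (2 * prms.dG_dna[("Gcn4", GLU)] + prms.dG_dna[("Cbf1", GLU)]
                + 2 * prms.tftf("Gcn4", "Cbf1"))
    assert e == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# parameterization structure
# ---------------------------------------------------------------------------

def test_study_configurations_free_energy_counts():
    """Study-style model structures stay within 6-15 free energies."""
    specs = [
        tp.study_spec(),
        tp.study_spec(switching=True),
        tp.study_spec(competitive=True),
        tp.study_spec(switching=True, pol_overrides=[("Cbf1", "cbf1lib")]),
        tp.study_spec(competitive=True,
                      free_interactions=[("Gcn4", "Gcn4"), ("Gcn4", "Nrg1")]),
    ]
    for s in specs:
        assert 6 <= s.n_free_energies <= 15


def test_free_parameter_map_is_bijective(comp_spec):
    """Every free parameter drives >= 1 slot; no slot is driven twice."""
    from thermoprom.model import free_parameter_map, slot_list
    names, T, free_mask = free_parameter_map(comp_spec)
    assert T.shape == (len(slot_list(comp_spec)), len(names))
    assert (T.sum(axis=1)[free_mask] == 1).all()
    assert (T.sum(axis=1)[~free_mask] == 0).all()
    assert (T.sum(axis=0) >= 1).all()


def test_slot_vector_round_trip(comp_spec, comp_params):
    from thermoprom.model import slot_list
    slots = slot_list(comp_spec)
    v = comp_params.to_slot_vector(slots)
    rebuilt = comp_params.with_slot_vector(slots, v)
    np.testing.assert_allclose(rebuilt.to_slot_vector(slots), v)


def test_parameter_validation(params):
    params.validate()
    params.expr_scale = -1.0
    with pytest.raises(tp.ConfigurationError):
        params.validate()


# ---------------------------------------------------------------------------
# competitive <-> switching degeneracy
# ---------------------------------------------------------------------------

def test_switching_equivalent_reproduces_expression(comp_spec):
    """The collapse map gives identical expression for every promoter/condition."""
    sw_spec = tp.study_spec(switching=True)
    prms = tp.study_truth_params(comp_spec)
    mapped = tp.switching_equivalent(prms, comp_spec)
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(0, 6))
        p = tp.Promoter("p", tuple(rng.choice(comp_spec.factors, size=n)))
        for c in comp_spec.conditions:
            assert tp.predict_expression(p, mapped, c, sw_spec) == pytest.approx(
                tp.predict_expression(p, prms, c, comp_spec), rel=1e-12)


def test_competitive_equivalent_round_trip(comp_spec):
    """collapse -> solve -> collapse is the identity on the effective weights."""
    prms = tp.study_truth_params(comp_spec)
    sw = tp.switching_equivalent(prms, comp_spec)
    back = tp.competitive_equivalent(sw, comp_spec)
    assert back is not None
    sw2 = tp.switching_equivalent(back, comp_spec)
    for c in comp_spec.conditions:
        assert sw2.dG_dna[("Gcn4", c)] == pytest.approx(sw.dG_dna[("Gcn4", c)], abs=1e-9)
        assert sw2.dG_pol[("Gcn4", c)] == pytest.approx(sw.dG_pol[("Gcn4", c)], abs=1e-9)
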