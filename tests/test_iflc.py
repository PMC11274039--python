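"""Controller stages: fuzzification, rule firing, dual-channel COG, output law."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ifpace.ifs_core import IFNumber, TermSet, eval_membership, eval_nonmembership
from ifpace.iflc import (
    ControllerConfig,
    ControllerState,
    RuleBase,
    combine_output,
    controller_step,
    defuzzify_cog,
    fire_rules,
    fuzzify,
)

N, Z, P = "Negative", "Zero", "Positive"


# ---------------------------------------------------------------------------
# Rule base
# ---------------------------------------------------------------------------

def test_default_rule_table_contents(rules):
    expected = {
        (N, N): N, (N, Z): N, (N, P): Z,
        (Z, N): N, (Z, Z): Z, (Z, P): P,
        (P, N): Z, (P, Z): P, (P, P): P,
    }
    assert dict(rules.rules) == expected


def test_rule_base_rejects_incomplete_or_asymmetric_tables():
    with pytest.raises(ValueError):
        RuleBase(rules=(((N, N), N),))
    bad = tuple(
        ((e, c), (P if (e, c) == (N, N) else out))
        for (e, c), out in RuleBase().rules
    )
    with pytest.raises(ValueError):
        RuleBase(rules=bad)


# ---------------------------------------------------------------------------
# Fuzzification
# ---------------------------------------------------------------------------

def test_fuzzify_center_input(terms):
    fz = fuzzify(0.0, 0.75, terms)
    assert fz[Z] == IFNumber(1.0, 0.0)
    assert fz[N].mu == 0.0 and fz[P].mu == 0.0


def test_fuzzify_saturates_at_universe_edge(terms):
    fz = fuzzify(2.0, 0.75, terms)
    assert fz[P] == IFNumber(1.0, 0.0)
    assert fz[N] == IFNumber(0.0, 1.0)


def test_fuzzify_hand_values(terms):
    fz = fuzzify(0.5, 1.0, terms)
    assert fz[N] == IFNumber(0.0, 1.0)
    assert fz[Z].mu == pytest.approx(0.5) and fz[Z].nu == pytest.approx(0.5)
    assert fz[P].mu == pytest.approx(0.5) and fz[P].nu == pytest.approx(0.5)


def test_fuzzify_rejects_non_finite(terms):
    with pytest.raises(ValueError):
        fuzzify(float("nan"), 1.0, terms)


# ---------------------------------------------------------------------------
# Rule firing
# ---------------------------------------------------------------------------

def test_crisp_center_fires_only_zero_rule(terms, rules):
    fz = fuzzify(0.0, 1.0, terms)
    firings = dict_firings(fire_rules(fz, fz, rules))
    assert firings[(Z, Z)][1].mu == 1.0
    for (e, c), (out, f) in firings.items():
        if (e, c) != (Z, Z):
            assert f.mu == 0.0


def test_nothing_fires_on_empty_degrees(terms, rules):
    none = {lab: IFNumber(0.0, 1.0) for lab in terms.labels}
    for _, f in fire_rules(none, none, rules):
        assert f == IFNumber(0.0, 1.0)


def test_firing_strength_is_componentwise_min(terms, rules):
    e_fz = {N: IFNumber(0.0, 1.0), Z: IFNumber(0.5, 0.5), P: IFNumber(0.5, 0.5)}
    ce_fz = {N: IFNumber(0.0, 1.0), Z: IFNumber(1.0, 0.0), P: IFNumber(0.0, 1.0)}
    firings = dict_firings(fire_rules(e_fz, ce_fz, rules))
    out, f = firings[(P, Z)]
    assert out == P and f.mu == 0.5 and f.nu == 0.0


def dict_firings(firings):
    pairs = [p for p, _ in RuleBase().rules]
    return {pair: (out, f) for pair, (out, f) in zip(pairs, firings)}


# ---------------------------------------------------------------------------
# COG defuzzification
# ---------------------------------------------------------------------------

def test_cog_symmetric_cases(terms):
    assert defuzzify_cog([(Z, IFNumber(1.0, 0.0))], terms) == pytest.approx(0.0, abs=1e-12)
    two = [(N, IFNumber(0.5, 0.2)), (P, IFNumber(0.5, 0.2))]
    assert defuzzify_cog(two, terms) == pytest.approx(0.0, abs=1e-12)


def test_cog_positive_shoulder_matches_quadrature_oracle(terms):
    """Full firing of the Positive shoulder: centroid vs brute-force
    quadrature of the same curve at 10^6 points (analytically 2/3)."""
    x = np.linspace(-1.0, 1.0, 1_000_001)
    curve = np.clip(np.where(x > 0, x, 0.0), 0.0, 1.0)  # P: rises 0 -> 1
    oracle = np.trapezoid(x * curve, x) / np.trapezoid(curve, x)
    got = defuzzify_cog([(P, IFNumber(1.0, 0.0))], terms)
    assert oracle == pytest.approx(2.0 / 3.0, abs=1e-9)
    assert got == pytest.approx(oracle, abs=1e-3)


def test_cog_zero_mass_fallback(terms):
    assert defuzzify_cog([(P, IFNumber(0.0, 0.0))], terms) == 0.0


def test_cog_grid_convergence(terms, rng):
    """Centroid at 1001 vs 10001 grid points differs by < 1e-3."""
    for _ in range(20):
        mus = rng.uniform(0.0, 1.0, 3)
        firings = [(lab, IFNumber(m, 0.0)) for lab, m in zip((N, Z, P), mus)]
        coarse = defuzzify_cog(firings, terms, "mu", 1001)
        fine = defuzzify_cog(firings, terms, "mu", 10001)
        assert abs(coarse - fine) < 1e-3


def test_cog_nu_complement_mode(terms):
    """The complement mode defuzzifies 1-nu curves; for a fully fired Zero
    term it equals the mu-channel result by the complement geometry."""
    firings = [(Z, IFNumber(1.0, 0.0))]
    z = defuzzify_cog(firings, terms, "nu", nu_complement=True)
    assert z == pytest.approx(defuzzify_cog(firings, terms, "mu"), abs=1e-12)


# ---------------------------------------------------------------------------
# Output combination
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("z_mu,z_nu,sigma,ku,expected", [
    (0.5, 0.3, 0.0, 100.0, 50.0),
    (0.5, 0.3, 1.0, 100.0, 30.0),
    (0.5, 0.3, 0.0001, 100.0, 49.998),
])
def test_combine_output_law(z_mu, z_nu, sigma, ku, expected):
    cfg = ControllerConfig(sigma_c=sigma, ku=ku)
    assert combine_output(z_mu, z_nu, cfg) == pytest.approx(expected)


def test_config_validation():
    with pytest.raises(ValueError):
        ControllerConfig(sigma_c=1.5)
    with pytest.raises(ValueError):
        ControllerConfig(cog_grid_points=4)
    with pytest.raises(ValueError):
        ControllerConfig(and_mode="sometimes")


# ---------------------------------------------------------------------------
# Full controller step
# ---------------------------------------------------------------------------

def _oracle_step(e, prev_e, cfg=ControllerConfig(), n_grid=1001):
    """Straight-line reimplementation of the whole chain, independent of the
    package's vectorized path: explicit loops over rules and grid points."""
    terms = TermSet.default()
    table = {
        (N, N): N, (N, Z): N, (N, P): Z,
        (Z, N): N, (Z, Z): Z, (Z, P): P,
        (P, N): Z, (P, Z): P, (P, P): P,
    }
    ce = e - prev_e
    se = max(-1.0, min(1.0, e * cfg.ke))
    sce = max(-1.0, min(1.0, ce * cfg.kce))
    grid = [-1.0 + 2.0 * i / (n_grid - 1) for i in range(n_grid)]
    z = {}
    for channel in ("mu", "nu"):
        num = den = 0.0
        for x in grid:
            best = 0.0
            for (el, cl), out in table.items():
                if channel == "mu":
                    fire = min(eval_membership(terms[el], se),
                               eval_membership(terms[cl], sce))
                    h = min(eval_membership(terms[out], x), fire)
                else:
                    fire = min(eval_nonmembership(terms[el], se),
                               eval_nonmembership(terms[cl], sce))
                    h = min(eval_nonmembership(terms[out], x), fire)
                best = max(best, h)
            num += x * best
            den += best
        z[channel] = num / den if den else 0.0
    return cfg.ku * ((1 - cfg.sigma_c) * z["mu"] + cfg.sigma_c * z["nu"])


@pytest.mark.parametrize("e,prev", [(0.5, 0.5), (0.3, 0.1), (-0.7, 0.2)])
def test_controller_step_matches_independent_oracle(e, prev):
    u, _ = controller_step(e, ControllerState(prev_error=prev),
                           ControllerConfig(cog_grid_points=201))
    assert u == pytest.approx(_oracle_step(e, prev, n_grid=201), abs=1e-9)


def test_zero_error_gives_zero_output():
    u, state = controller_step(0.0, ControllerState())
    assert u == pytest.approx(0.0, abs=1e-9)
    assert state.prev_error == 0.0


@given(st.floats(-1.5, 1.5), st.floats(-1.5, 1.5))
def test_odd_symmetry_of_control_surface(e, prev):
    u_pos, _ = controller_step(e, ControllerState(prev_error=prev))
    u_neg, _ = controller_step(-e, ControllerState(prev_error=-prev))
    assert u_neg == pytest.approx(-u_pos, abs=1e-12)


@given(st.floats(-5.0, 5.0), st.floats(-5.0, 5.0))
def test_output_bounded_by_ku(e, prev):
    cfg = ControllerConfig()
    u, _ = controller_step(e, ControllerState(prev_error=prev), cfg)
    assert abs(u) <= cfg.ku + 1e-9


def test_monotone_tendency_in_error(cfg):
    """With ce = 0 the command is non-decreasing in the error."""
    es = np.linspace(-1.0, 1.0, 201)
    us = [controller_step(e, ControllerState(prev_error=e), cfg)[0] for e in es]
    assert np.all(np.diff(us) >= -1e-9)


def test_sigma_zero_equals_classical_mamdani(rng):
    """With sigma_c = 0 the controller is a membership-only Mamdani
    controller; checked against a classical reimplementation."""
    cfg = ControllerConfig(sigma_c=0.0, cog_grid_points=201)
    for _ in range(100):
        e, prev = rng.uniform(-1.3, 1.3, 2)
        u, _ = controller_step(e, ControllerState(prev_error=prev), cfg)
        assert u == pytest.approx(
            _classical_mamdani(e, prev, cfg, 201), abs=1e-9)


def _classical_mamdani(e, prev_e, cfg, n_grid):
    """Membership-only Mamdani controller (no intuitionistic machinery)."""
    terms = TermSet.default()
    table = dict(RuleBase().rules)
    se = max(-1.0, min(1.0, (e) * cfg.ke))
    sce = max(-1.0, min(1.0, (e - prev_e) * cfg.kce))
    x = np.array([-1.0 + 2.0 * i / (n_grid - 1) for i in range(n_grid)])
    agg = np.zeros_like(x)
    for (el, cl), out in table.items():
        fire = min(eval_membership(terms[el], se),
                   eval_membership(terms[cl], sce))
        agg = np.maximum(agg, np.minimum(eval_membership(terms[out], x), fire))
    den = agg.sum()
    return cfg.ku * (float((x * agg).sum() / den) if den else 0.0)


def test_determinism_of_controller_step(cfg):
    a = controller_step(0.37, ControllerState(prev_error=0.11), cfg)
    b = controller_step(0.37, ControllerState(prev_error=0.11), cfg)
    assert a == b
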