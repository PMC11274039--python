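"""Two-input intuitionistic fuzzy logic controller (IFLC).

The controller maps a normalized tracking error ``e`` and its first
difference ``ce`` to a crisp command ``u`` through four stages:

1. **Fuzzification** — each input is scaled by its gain (``Ke``, ``Kce``),
   clipped to the normalized universe ``[-1, 1]`` and evaluated against the
   Negative/Zero/Positive term set, yielding one intuitionistic fuzzy number
   per label per input.
2. **Rule firing** — the 3x3 rule base is evaluated; each rule's firing
   strength is the intuitionistic conjunction of its two antecedent degrees.
3. **Dual-channel defuzzification** — the membership channel clips each fired
   output term's mu-curve at the rule's mu firing degree (Mamdani min
   implication), aggregates pointwise by max, and takes the center of gravity
   ``z_mu``; the non-membership channel does the same with the nu-curves and
   nu firing degrees, yielding ``z_nu``.
4. **Output combination** — ``u = Ku * ((1 - sigma_c) * z_mu + sigma_c * z_nu)``,
   so the hesitancy weight ``sigma_c`` blends the two channels; ``sigma_c = 0``
   is exactly a classical membership-only Mamdani controller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .ifs_core import (
    AS_PRINTED,
    DEFAULT_LABELS,
    NEGATIVE,
    POSITIVE,
    STANDARD,
    ZERO,
    IFNumber,
    TermSet,
    curve_table,
    ifn_and,
)

logger = logging.getLogger("ifpace")

__all__ = [
    "RuleBase",
    "ControllerConfig",
    "ControllerState",
    "fuzzify",
    "fire_rules",
    "defuzzify_cog",
    "combine_output",
    "controller_step",
]

_OPPOSITE = {NEGATIVE: POSITIVE, POSITIVE: NEGATIVE, ZERO: ZERO}

#: rule table: (error term, change-of-error term) -> output term
DEFAULT_RULES: Tuple[Tuple[Tuple[str, str], str], ...] = (
    ((NEGATIVE, NEGATIVE), NEGATIVE),
    ((NEGATIVE, ZERO), NEGATIVE),
    ((NEGATIVE, POSITIVE), ZERO),
    ((ZERO, NEGATIVE), NEGATIVE),
    ((ZERO, ZERO), ZERO),
    ((ZERO, POSITIVE), POSITIVE),
    ((POSITIVE, NEGATIVE), ZERO),
    ((POSITIVE, ZERO), POSITIVE),
    ((POSITIVE, POSITIVE), POSITIVE),
)


@dataclass(frozen=True)
class RuleBase:
    """3x3 Mamdani rule table over the N/Z/P antecedent labels.

    Every (error, change-of-error) label pair must appear exactly once, and
    the table must be antisymmetric under the N<->P swap so the control
    surface is odd.
    """

    rules: Tuple[Tuple[Tuple[str, str], str], ...] = DEFAULT_RULES

    def __post_init__(self) -> None:
        pairs = [p for p, _ in self.rules]
        expected = {(e, c) for e in DEFAULT_LABELS for c in DEFAULT_LABELS}
        if len(pairs) != 9 or set(pairs) != expected:
            raise ValueError(
                "rule base must contain each of the 9 (e, ce) pairs exactly once"
            )
        table = dict(self.rules)
        for (e, c), out in table.items():
            mirrored = table[(_OPPOSITE[e], _OPPOSITE[c])]
            if mirrored != _OPPOSITE[out]:
                raise ValueError(
                    f"rule base is not antisymmetric at ({e}, {c}) -> {out}"
                )
        # canonical row-major order so equal tables compare equal regardless
        # of the order they were supplied in
        order = {lab: i for i, lab in enumerate(DEFAULT_LABELS)}
        canonical = tuple(sorted(
            self.rules, key=lambda r: (order[r[0][0]], order[r[0][1]])
        ))
        object.__setattr__(self, "rules", canonical)

    def __getitem__(self, pair: Tuple[str, str]) -> str:
        return dict(self.rules)[pair]


@dataclass(frozen=True)
class ControllerConfig:
    """Gains and inference options of the controller.

    ``ke``/``kce`` scale the normalized error and change of error before
    fuzzification; ``ku`` scales the defuzzified output; ``sigma_c`` in
    [0, 1] is the hesitancy weight of the non-membership channel (0 recovers
    a classical fuzzy controller).  ``cog_grid_points`` is the odd number of
    samples of the COG grid on [-1, 1]; ``and_mode`` selects the conjunction
    behaviour; ``nu_complement`` makes the nu channel defuzzify the
    complement curves ``1 - nu`` clipped at ``1 - firing_nu`` instead of the
    nu-curves directly.
    """

    ke: float = 0.75
    kce: float = 0.75
    ku: float = 100.0
    sigma_c: float = 0.0001
    cog_grid_points: int = 1001
    and_mode: str = AS_PRINTED
    nu_complement: bool = False

    def __post_init__(self) -> None:
        for name in ("ke", "kce", "ku"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.sigma_c <= 1.0:
            raise ValueError(f"sigma_c must lie in [0, 1], got {self.sigma_c}")
        if self.cog_grid_points < 3 or self.cog_grid_points % 2 == 0:
            raise ValueError(
                f"cog_grid_points must be odd and >= 3, got {self.cog_grid_points}"
            )
        if self.and_mode not in (AS_PRINTED, STANDARD):
            raise ValueError(f"unknown and_mode {self.and_mode!r}")


@dataclass(frozen=True)
class ControllerState:
    """Carry-over between control updates: the previous normalized error,
    from which the change-of-error input is formed as a unit-delay first
    difference."""

    prev_error: float = 0.0


def fuzzify(x: float, gain: float, terms: TermSet) -> Dict[str, IFNumber]:
    """Scale ``x`` by ``gain``, clip to [-1, 1], evaluate every term.

    Saturation at the universe edge is logged (the shoulder terms then fire
    with full membership).
    """
    if not math.isfinite(x):
        raise ValueError(f"input must be finite, got {x}")
    scaled = x * gain
    if abs(scaled) > 1.0:
        logger.debug("fuzzifier input saturated: %.4f clipped to [-1, 1]", scaled)
        scaled = max(-1.0, min(1.0, scaled))
    return terms.evaluate(scaled)


def fire_rules(
    e_fz: Mapping[str, IFNumber],
    ce_fz: Mapping[str, IFNumber],
    rb: RuleBase,
    mode: str = AS_PRINTED,
) -> List[Tuple[str, IFNumber]]:
    """Evaluate every rule; firing strength is the conjunction of the two
    antecedent IFNumbers under the configured mode."""
    return [
        (out, ifn_and(e_fz[e_lab], ce_fz[ce_lab], mode))
        for (e_lab, ce_lab), out in rb.rules
    ]


def defuzzify_cog(
    firings: Sequence[Tuple[str, IFNumber]],
    terms: TermSet,
    channel: str = "mu",
    grid: int = 1001,
    nu_complement: bool = False,
) -> float:
    """Center-of-gravity defuzzification of one channel.

    Each fired rule min-clips its output term's channel curve at the rule's
    firing degree for that channel; the clipped curves are aggregated
    pointwise by max over a uniform symmetric grid on [-1, 1], and the
    centroid ``sum(x * w) / sum(w)`` is returned.  Zero total mass falls back
    to 0 (the universe midpoint).
    """
    if not firings:
        raise ValueError("at least one fired rule is required")
    if channel not in ("mu", "nu"):
        raise ValueError(f"channel must be 'mu' or 'nu', got {channel!r}")
    x, mu_curves, nu_curves = curve_table(terms, grid)
    agg = np.zeros_like(x)
    for label, f in firings:
        if channel == "mu":
            level, curve = f.mu, mu_curves[label]
        elif nu_complement:
            level, curve = 1.0 - f.nu, 1.0 - nu_curves[label]
        else:
            level, curve = f.nu, nu_curves[label]
        np.maximum(agg, np.minimum(curve, level), out=agg)
    mass = float(np.sum(agg))
    if mass == 0.0:
        logger.debug("COG fallback: zero aggregated mass on %s channel", channel)
        return 0.0
    return float(np.dot(x, agg) / mass)


def combine_output(z_mu: float, z_nu: float, cfg: ControllerConfig) -> float:
    """Blend the two channel centroids into the crisp command:
    ``u = Ku * ((1 - sigma_c) * z_mu + sigma_c * z_nu)``."""
    return cfg.ku * ((1.0 - cfg.sigma_c) * z_mu + cfg.sigma_c * z_nu)


def controller_step(
    error_norm: float,
    state: ControllerState,
    cfg: ControllerConfig = ControllerConfig(),
    rb: RuleBase = RuleBase(),
    terms: TermSet = None,
) -> Tuple[float, ControllerState]:
    """One control update: returns ``(u, next_state)``.

    Deterministic — identical inputs and state give identical output.
    """
    if terms is None:
        terms = TermSet.default()
    ce = error_norm - state.prev_error
    e_fz = fuzzify(error_norm, cfg.ke, terms)
    ce_fz = fuzzify(ce, cfg.kce, terms)
    firings = fire_rules(e_fz, ce_fz, rb, cfg.and_mode)
    z_mu = defuzzify_cog(firings, terms, "mu", cfg.cog_grid_points)
    z_nu = defuzzify_cog(
        firings, terms, "nu", cfg.cog_grid_points, cfg.nu_complement
    )
    u = combine_output(z_mu, z_nu, cfg)
    return u, ControllerState(prev_error=error_norm)
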