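"""Intuitionistic fuzzy numbers and triangular intuitionistic fuzzy sets.

An intuitionistic fuzzy set (IFS) extends an ordinary fuzzy set by assigning
each element *x* both a membership degree ``mu(x)`` and an independent
non-membership degree ``nu(x)``, subject to the Atanassov constraint
``mu + nu <= 1``.  The residual ``pi = 1 - mu - nu`` is the hesitancy
(indeterminacy) of the element.  With ``pi = 0`` everywhere the set collapses
to a classical fuzzy set.

This module provides

* :class:`IFNumber` — a single ``(mu, nu)`` pair, the scalar of the algebra,
  with the standard operational rules (sum, product, scalar multiple, scalar
  power) and the logical connectives (conjunction, disjunction, implication,
  negation);
* :class:`TriangularIFS` — the five-breakpoint triangular set whose
  membership triangle ``(a_l, a_m, a_u)`` is nested inside the non-membership
  co-triangle ``(c_l, a_m, c_u)``;
* :class:`TermSet` — an ordered linguistic partition (by default
  Negative / Zero / Positive over the normalized universe ``[-1, 1]``) used by
  the controller for fuzzification and defuzzification.

Two behaviours of the disjunction / implication connectives ship: the
``"as_printed"`` mode applies the component-wise extremum to *both* degrees
(which can break the Atanassov constraint — such results carry a
``flagged=True`` marker and a warning is logged), and the ``"standard"`` mode
uses the classical dual pair (max mu, min nu) / (min mu, max nu) that always
preserves the constraint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Union

import numpy as np

logger = logging.getLogger("ifpace")

#: tolerance used when validating the Atanassov constraint on construction
CONSTRAINT_EPS = 1e-9

AS_PRINTED = "as_printed"
STANDARD = "standard"
_MODES = (AS_PRINTED, STANDARD)

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "IFNumber",
    "TriangularIFS",
    "TermSet",
    "CONSTRAINT_EPS",
    "AS_PRINTED",
    "STANDARD",
    "eval_membership",
    "eval_nonmembership",
    "hesitancy",
    "ifn_sum",
    "ifn_product",
    "ifn_scalar_power",
    "ifn_scalar_mult",
    "ifn_and",
    "ifn_or",
    "ifn_implies",
    "ifn_not",
]


# ---------------------------------------------------------------------------
# IFNumber
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IFNumber:
    """A membership / non-membership degree pair ``(mu, nu)``.

    Both degrees lie in ``[0, 1]``.  In strict mode (the default) construction
    rejects pairs with ``mu + nu > 1 + CONSTRAINT_EPS``; the lenient
    constructor :meth:`clipped` instead clips ``nu`` down to ``1 - mu``.
    ``flagged`` marks results of as-printed connectives that violate the
    constraint; flagged numbers are representable but excluded from strict
    validation so the violation remains observable downstream.
    """

    mu: float
    nu: float
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0) or not (0.0 <= self.nu <= 1.0):
            raise ValueError(
                f"degrees must lie in [0, 1]: mu={self.mu}, nu={self.nu}"
            )
        if not self.flagged and self.mu + self.nu > 1.0 + CONSTRAINT_EPS:
            raise ValueError(
                f"Atanassov constraint violated: mu + nu = {self.mu + self.nu}"
            )

    @classmethod
    def clipped(cls, mu: float, nu: float) -> "IFNumber":
        """Lenient constructor: clip ``nu`` to ``1 - mu`` if the pair
        overshoots the constraint (float round-off in chained operations)."""
        mu = min(max(mu, 0.0), 1.0)
        nu = min(max(nu, 0.0), 1.0)
        if mu + nu > 1.0:
            nu = 1.0 - mu
        return cls(mu, nu)

    @property
    def hesitancy(self) -> float:
        return 1.0 - self.mu - self.nu

    def is_valid(self) -> bool:
        return self.mu + self.nu <= 1.0 + CONSTRAINT_EPS


def hesitancy(n: IFNumber) -> float:
    """Hesitancy (uncertainty) degree ``1 - mu - nu`` of an IFN.

    Zero for classical fuzzy degrees (``mu + nu = 1``); may be negative only
    for flagged constraint-violating pairs.
    """
    return n.hesitancy


def _flag_if_violating(mu: float, nu: float) -> IFNumber:
    if mu + nu > 1.0 + CONSTRAINT_EPS:
        logger.warning(
            "as-printed connective broke the Atanassov constraint: "
            "mu + nu = %.6f > 1", mu + nu,
        )
        return IFNumber(mu, nu, flagged=True)
    return IFNumber(mu, nu)


def ifn_sum(a1: IFNumber, a2: IFNumber) -> IFNumber:
    """Algebraic IFN sum: ``(mu1 + mu2 - mu1*mu2, nu1*nu2)``."""
    return IFNumber(a1.mu + a2.mu - a1.mu * a2.mu, a1.nu * a2.nu)


def ifn_product(a1: IFNumber, a2: IFNumber) -> IFNumber:
    """Algebraic IFN product: ``(mu1*mu2, nu1 + nu2 - nu1*nu2)``."""
    return IFNumber(a1.mu * a2.mu, a1.nu + a2.nu - a1.nu * a2.nu)


def ifn_scalar_power(a: IFNumber, g: float) -> IFNumber:
    """``a ** g = (mu**g, 1 - (1 - nu)**g)`` for ``g >= 0``."""
    if g < 0:
        raise ValueError(f"exponent must be non-negative, got {g}")
    return IFNumber.clipped(a.mu ** g, 1.0 - (1.0 - a.nu) ** g)


def ifn_scalar_mult(a: IFNumber, n: float) -> IFNumber:
    """``n * a = (1 - (1 - mu)**n, nu**n)`` for ``n >= 0``."""
    if n < 0:
        raise ValueError(f"multiplier must be non-negative, got {n}")
    return IFNumber.clipped(1.0 - (1.0 - a.mu) ** n, a.nu ** n)


def ifn_and(a: IFNumber, b: IFNumber, mode: str = AS_PRINTED) -> IFNumber:
    """Conjunction of two IFNs.

    ``as_printed`` mode takes the minimum of both components; ``standard``
    mode is the classical t-norm pair ``(min mu, max nu)``.  Both preserve the
    Atanassov constraint.
    """
    _check_mode(mode)
    if mode == STANDARD:
        return IFNumber(min(a.mu, b.mu), max(a.nu, b.nu))
    return IFNumber(min(a.mu, b.mu), min(a.nu, b.nu))


def ifn_or(a: IFNumber, b: IFNumber, mode: str = AS_PRINTED) -> IFNumber:
    """Disjunction of two IFNs.

    ``as_printed`` mode takes the maximum of both components, which can break
    the constraint (the result is then ``flagged``); ``standard`` mode is the
    dual s-norm pair ``(max mu, min nu)``.
    """
    _check_mode(mode)
    if mode == STANDARD:
        return IFNumber(max(a.mu, b.mu), min(a.nu, b.nu))
    return _flag_if_violating(max(a.mu, b.mu), max(a.nu, b.nu))


def ifn_implies(a: IFNumber, b: IFNumber) -> IFNumber:
    """Implication ``a -> b = (max(nu_a, mu_b), max(mu_a, nu_b))``.

    Can violate the constraint for some arguments; such results are flagged.
    """
    return _flag_if_violating(max(a.nu, b.mu), max(a.mu, b.nu))


def ifn_not(a: IFNumber) -> IFNumber:
    """Standard negation: swap the two degrees."""
    return IFNumber(a.nu, a.mu, flagged=a.flagged)


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


# ---------------------------------------------------------------------------
# Triangular intuitionistic fuzzy sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangularIFS:
    """Five-breakpoint triangular intuitionistic fuzzy set.

    The membership function is the triangle rising from 0 at ``a_l`` to 1 at
    ``a_m`` and falling back to 0 at ``a_u``; the non-membership function is
    the inverted triangle equal to 1 outside ``[c_l, c_u]`` and falling
    linearly to 0 at the peak ``a_m``.  Breakpoints must satisfy
    ``c_l <= a_l <= a_m <= a_u <= c_u`` (the nesting makes
    ``mu + nu <= 1`` hold everywhere, validated on a dense grid).

    Degenerate edges (``a_l == a_m`` or ``a_m == a_u``) are the one-sided
    shoulder shapes: membership is exactly 1 at ``a_m`` and the vertical edge
    acts as a step, which is what the saturated terms at the ends of a
    normalized universe require.
    """

    c_l: float
    a_l: float
    a_m: float
    a_u: float
    c_u: float

    def __post_init__(self) -> None:
        bp = (self.c_l, self.a_l, self.a_m, self.a_u, self.c_u)
        if not all(math.isfinite(v) for v in bp):
            raise ValueError(f"breakpoints must be finite: {bp}")
        if not (self.c_l <= self.a_l <= self.a_m <= self.a_u <= self.c_u):
            raise ValueError(
                f"breakpoints must satisfy c_l <= a_l <= a_m <= a_u <= c_u: {bp}"
            )
        # nesting guarantees pointwise mu + nu <= 1; confirm on a grid
        if self.c_u > self.c_l:
            x = np.linspace(self.c_l, self.c_u, 257)
            excess = np.max(
                eval_membership(self, x) + eval_nonmembership(self, x) - 1.0
            )
            if excess > 1e-9:
                raise ValueError(
                    f"mu + nu exceeds 1 by {excess:.3e} inside [c_l, c_u]: {bp}"
                )

    @property
    def breakpoints(self) -> tuple:
        return (self.c_l, self.a_l, self.a_m, self.a_u, self.c_u)


def eval_membership(s: TriangularIFS, x: ArrayLike) -> ArrayLike:
    """Triangular membership degree of ``x`` in ``s`` (vectorized).

    0 outside ``[a_l, a_u]``, linear up to 1 at ``a_m`` and back down; the
    peak value 1 is taken exactly at ``a_m`` even for degenerate shoulders.
    """
    xv = np.asarray(x, dtype=float)
    out = np.zeros_like(xv)
    if s.a_m > s.a_l:
        m = (xv > s.a_l) & (xv < s.a_m)
        out[m] = (xv[m] - s.a_l) / (s.a_m - s.a_l)
    if s.a_u > s.a_m:
        m = (xv > s.a_m) & (xv < s.a_u)
        out[m] = (s.a_u - xv[m]) / (s.a_u - s.a_m)
    out[xv == s.a_m] = 1.0
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def eval_nonmembership(s: TriangularIFS, x: ArrayLike) -> ArrayLike:
    """Inverted-triangle non-membership degree of ``x`` in ``s`` (vectorized).

    1 outside ``[c_l, c_u]``, linear down to 0 at the peak ``a_m``.
    """
    xv = np.asarray(x, dtype=float)
    out = np.ones_like(xv)
    if s.a_m > s.c_l:
        m = (xv > s.c_l) & (xv < s.a_m)
        out[m] = (xv[m] - s.a_m) / (s.c_l - s.a_m)
    if s.c_u > s.a_m:
        m = (xv > s.a_m) & (xv < s.c_u)
        out[m] = (s.a_m - xv[m]) / (s.a_m - s.c_u)
    out[xv == s.a_m] = 0.0
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


# ---------------------------------------------------------------------------
# Linguistic term sets
# ---------------------------------------------------------------------------

NEGATIVE = "Negative"
ZERO = "Zero"
POSITIVE = "Positive"
DEFAULT_LABELS = (NEGATIVE, ZERO, POSITIVE)


@dataclass(frozen=True)
class TermSet:
    """Ordered linguistic partition of the normalized universe ``[-1, 1]``.

    The controller's default partition has exactly three terms — Negative,
    Zero, Positive — whose membership triangles tile the universe as a
    partition of unity and whose non-membership curves are the complements
    within the same support (zero pointwise hesitancy).  Peaks must be
    strictly increasing in label order.
    """

    terms: tuple  # tuple[(label, TriangularIFS), ...]

    def __post_init__(self) -> None:
        if len(self.terms) < 2:
            raise ValueError("a term set needs at least two terms")
        peaks = [s.a_m for _, s in self.terms]
        if not all(a < b for a, b in zip(peaks, peaks[1:])):
            raise ValueError(f"term peaks must be strictly increasing: {peaks}")

    @classmethod
    def default(cls) -> "TermSet":
        """The symmetric N/Z/P partition on [-1, 1] used by the controller."""
        return cls(terms=(
            (NEGATIVE, TriangularIFS(-1.0, -1.0, -1.0, 0.0, 0.0)),
            (ZERO, TriangularIFS(-1.0, -1.0, 0.0, 1.0, 1.0)),
            (POSITIVE, TriangularIFS(0.0, 0.0, 1.0, 1.0, 1.0)),
        ))

    @property
    def labels(self) -> tuple:
        return tuple(label for label, _ in self.terms)

    def __getitem__(self, label: str) -> TriangularIFS:
        for lab, s in self.terms:
            if lab == label:
                return s
        raise KeyError(label)

    def evaluate(self, x: float) -> dict:
        """Evaluate every term at ``x`` into one :class:`IFNumber` per label."""
        return {
            label: IFNumber.clipped(
                eval_membership(s, x), eval_nonmembership(s, x)
            )
            for label, s in self.terms
        }

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Label -> five breakpoints, round-trippable through YAML/JSON."""
        return {label: list(s.breakpoints) for label, s in self.terms}

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[float]]) -> "TermSet":
        terms = []
        for label, bp in d.items():
            bp = list(bp)
            if len(bp) != 5:
                raise ValueError(
                    f"term {label!r} needs 5 breakpoints, got {len(bp)}"
                )
            terms.append((str(label), TriangularIFS(*map(float, bp))))
        # mapping serializations need not preserve order; recover it from the
        # peak positions, which define the linguistic ordering
        terms.sort(key=lambda item: item[1].a_m)
        return cls(terms=tuple(terms))


@lru_cache(maxsize=16)
def curve_table(terms: TermSet, n: int):
    """Sampled membership / non-membership curves of every term.

    Returns ``(x, mu_curves, nu_curves)`` where ``x`` is an exactly symmetric
    ``n``-point grid on [-1, 1] and the curve dicts map label -> ndarray.
    Cached because the controller re-uses the table every step.
    """
    if n < 3 or n % 2 == 0:
        raise ValueError(f"grid size must be odd and >= 3, got {n}")
    # mirror a half-grid so x[i] == -x[n-1-i] exactly and 0, +-1 are hit exactly
    half = np.linspace(0.0, 1.0, (n + 1) // 2)
    x = np.concatenate([-half[:0:-1], half])
    mu_curves = {lab: eval_membership(s, x) for lab, s in terms.terms}
    nu_curves = {lab: eval_nonmembership(s, x) for lab, s in terms.terms}
    for c in (*mu_curves.values(), *nu_curves.values()):
        c.setflags(write=False)
    x.setflags(write=False)
    return x, mu_curves, nu_curves
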