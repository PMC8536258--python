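"""One-vs-two-lineage mixture deconvolution of clone-category frequencies.

A fraction ``sigma`` of marked ovarioles carries exactly one marked lineage;
the remainder carry exactly two, drawn independently from the single-lineage
type frequencies ``(p_EC, p_ECFSC, p_FSC, p_FC)``. The observable fractions
then satisfy

    f_EC_obs   = sigma*p_EC  + (1-sigma)*(p_EC^2  + 2*p_EC*p_FC)
    f_FC_obs   = sigma*p_FC  + (1-sigma)*(p_FC^2  + 2*p_EC*p_FC)
    f_FSC_obs  = sigma*p_FSC + (1-sigma)*(p_FSC^2 + 2*p_FSC*p_FC)
    f_ECFC_obs = (1-sigma)*2*p_EC*p_FC

Any pairing that involves an EC/FSC lineage, or that mixes an FSC lineage
with an EC lineage, lands in an FSC-containing observable class and so never
contributes to the four fractions above -- the equations deliberately omit
such cross terms. The inverse problem is solved exactly: a damped 2-D Newton
iteration for ``(p_EC, p_FC)`` (with a closed-form 1-D reduction as fallback
for degenerate corners), then a quadratic for ``p_FSC``, then ``p_ECFSC`` by
complement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .errors import EstimationFailureError, InfeasibleFrequenciesError
from .records import AggregatedFrequencies

logger = logging.getLogger(__name__)

_SIMPLEX_TOL = 1e-9


class SigmaMode(str, Enum):
    FIXED = "fixed"
    GRID_ESTIMATED = "grid_estimated"
    ALL_DOUBLE = "all_double"
    ALL_SINGLE = "all_single"


@dataclass(frozen=True)
class MixtureAssumption:
    """Single-lineage fraction ``sigma`` and how it was chosen."""

    sigma: float
    mode: SigmaMode = SigmaMode.FIXED
    residual: float | None = None
    #: (sigma, |predicted - observed f_ECFC| or None if infeasible) per grid point.
    decision_path: tuple[tuple[float, float | None], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma <= 1.0):
            raise InfeasibleFrequenciesError("sigma must lie in [0, 1]")


@dataclass(frozen=True)
class LineageTypeFrequencies:
    """Proportions of the four single-cell lineage types (a simplex point).

    ``p_ec``: lineages producing only ECs; ``p_ecfsc``: ECs and FSCs (with or
    without FCs); ``p_fsc``: FSCs (with or without FCs) but no ECs; ``p_fc``:
    only FCs.
    """

    p_ec: float
    p_ecfsc: float
    p_fsc: float
    p_fc: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(not (-_SIMPLEX_TOL <= v <= 1.0 + _SIMPLEX_TOL) or math.isnan(v) for v in vals):
            raise InfeasibleFrequenciesError(
                f"lineage-type frequencies must lie in [0, 1]: {vals}"
            )
        if abs(sum(vals) - 1.0) > 1e-9:
            raise InfeasibleFrequenciesError(
                f"lineage-type frequencies must sum to 1 (got {sum(vals)!r})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_ec, self.p_ecfsc, self.p_fsc, self.p_fc)


def forward_category_frequencies(
    freqs: LineageTypeFrequencies, sigma: float
) -> AggregatedFrequencies:
    """Expected observable category fractions under the mixture model."""
    _check_sigma(sigma)
    p, q = freqs.p_ec, freqs.p_fc
    r = freqs.p_fsc
    d = 1.0 - sigma
    return AggregatedFrequencies(
        f_ec_obs=sigma * p + d * (p * p + 2.0 * p * q),
        f_fc_obs=sigma * q + d * (q * q + 2.0 * p * q),
        f_fsc_obs=sigma * r + d * (r * r + 2.0 * r * q),
        f_ecfc_obs=d * 2.0 * p * q,
    )


def _check_sigma(sigma: float) -> None:
    if not (0.0 <= sigma <= 1.0):
        raise InfeasibleFrequenciesError("sigma must lie in [0, 1]")


def _positive_quadratic_root(a: float, b: float, c: float) -> float:
    """Root in [0, 1] of ``a*x^2 + b*x + c = 0`` with a >= 0, b >= 0, c <= 0.

    The product of roots is c/a <= 0, so at most one root is positive; when
    both qualify (only the degenerate c = 0, b = 0 corner) the smaller, 0,
    is taken with a logged warning.
    """
    if a == 0.0:
        if b == 0.0:
            if c == 0.0:
                logger.warning("degenerate quadratic 0 = 0; taking root 0")
                return 0.0
            raise InfeasibleFrequenciesError("quadratic has no root", equation="quadratic")
        return -c / b
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        raise InfeasibleFrequenciesError("quadratic discriminant < 0", equation="quadratic")
    return (-b + math.sqrt(disc)) / (2.0 * a)


def _solve_p_given_q(f: float, q: float, sigma: float) -> float:
    """Closed-form p with ``sigma*p + (1-sigma)*(p^2 + 2 p q) = f``."""
    d = 1.0 - sigma
    return _positive_quadratic_root(d, sigma + 2.0 * d * q, -f)


def _solve_pq_newton(
    f_ec: float, f_fc: float, sigma: float, tol: float = 1e-13, max_iter: int = 200
) -> tuple[float, float] | None:
    d = 1.0 - sigma
    p, q = min(f_ec, 1.0), min(f_fc, 1.0)

    def residual(p: float, q: float) -> tuple[float, float]:
        g1 = sigma * p + d * (p * p + 2.0 * p * q) - f_ec
        g2 = sigma * q + d * (q * q + 2.0 * p * q) - f_fc
        return g1, g2

    for _ in range(max_iter):
        g1, g2 = residual(p, q)
        if abs(g1) < tol and abs(g2) < tol:
            return p, q
        j11 = sigma + d * (2.0 * p + 2.0 * q)
        j12 = d * 2.0 * p
        j21 = d * 2.0 * q
        j22 = sigma + d * (2.0 * q + 2.0 * p)
        det = j11 * j22 - j12 * j21
        if abs(det) < 1e-15:
            return None
        dp = (g1 * j22 - g2 * j12) / det
        dq = (g2 * j11 - g1 * j21) / det
        # Damping: halve the step until the residual norm decreases and the
        # iterate stays inside [0, 1]^2.
        norm0 = g1 * g1 + g2 * g2
        step = 1.0
        for _ in range(60):
            pn, qn = p - step * dp, q - step * dq
            if 0.0 <= pn <= 1.0 and 0.0 <= qn <= 1.0:
                h1, h2 = residual(pn, qn)
                if h1 * h1 + h2 * h2 < norm0 or step < 1e-8:
                    p, q = pn, qn
                    break
            step *= 0.5
        else:
            return None
    g1, g2 = residual(p, q)
    return (p, q) if abs(g1) < 1e-9 and abs(g2) < 1e-9 else None


def _polish_pq(f_ec: float, f_fc: float, sigma: float, p: float, q: float) -> tuple[float, float]:
    """Alternating closed-form refinement of a near-solution.

    Each half-step solves its own quadratic exactly, so square-root corners
    (e.g. p_FC ~ sqrt(f_FC_obs) at sigma = 0) are resolved to full parameter
    precision where residual-based iterations stall.
    """
    for _ in range(200):
        p_new = _solve_p_given_q(f_ec, q, sigma)
        q_new = _solve_p_given_q(f_fc, p_new, sigma)
        if abs(p_new - p) < 1e-16 and abs(q_new - q) < 1e-16:
            return p_new, q_new
        p, q = p_new, q_new
    return p, q


def _solve_pq(f_ec: float, f_fc: float, sigma: float) -> tuple[float, float]:
    """Solve the coupled (p_EC, p_FC) pair; exact 1-D reduction as fallback."""
    if sigma == 1.0:
        return f_ec, f_fc
    if f_ec == 0.0 and f_fc == 0.0:
        return 0.0, 0.0
    sol = _solve_pq_newton(f_ec, f_fc, sigma)
    if sol is not None:
        return _polish_pq(f_ec, f_fc, sigma, *sol)
    # Fallback: p has a closed form given q, leaving a bracketed 1-D root.
    d = 1.0 - sigma

    def g2(q: float) -> float:
        p = _solve_p_given_q(f_ec, q, sigma)
        return sigma * q + d * (q * q + 2.0 * p * q) - f_fc

    lo, hi = 0.0, 1.0
    if g2(lo) > 0.0 or g2(hi) < 0.0:
        raise InfeasibleFrequenciesError(
            f"no (p_EC, p_FC) in [0,1] reproduces f_EC_obs={f_ec:.4f}, f_FC_obs={f_fc:.4f} "
            f"at sigma={sigma:.2f}",
            equation="f_FC_obs",
        )
    q = brentq(g2, lo, hi, xtol=1e-14)
    return _polish_pq(f_ec, f_fc, sigma, _solve_p_given_q(f_ec, q, sigma), q)


def solve_lineage_frequencies(
    obs: AggregatedFrequencies, sigma: float
) -> LineageTypeFrequencies:
    """Invert the mixture model for the four lineage-type frequencies.

    Solves the coupled pair for ``(p_EC, p_FC)`` from ``f_EC_obs`` and
    ``f_FC_obs``, then the FSC quadratic

        sigma*p_FSC + (1-sigma)*(p_FSC^2 + 2*p_FSC*p_FC) = f_FSC_obs,

    taking its root in [0, 1], and finally ``p_ECFSC`` by complement. The
    forward model at the solution reproduces the three inputs to 1e-9.
    """
    _check_sigma(sigma)
    p, q = _solve_pq(obs.f_ec_obs, obs.f_fc_obs, sigma)
    d = 1.0 - sigma
    r = _positive_quadratic_root(d, sigma + 2.0 * d * q, -obs.f_fsc_obs)
    for name, v in (("p_EC", p), ("p_FC", q), ("p_FSC", r)):
        if not (-_SIMPLEX_TOL <= v <= 1.0 + _SIMPLEX_TOL):
            raise InfeasibleFrequenciesError(f"{name} = {v:.4f} outside [0, 1]", equation=name)
    pe = 1.0 - p - q - r
    if pe < -_SIMPLEX_TOL:
        raise InfeasibleFrequenciesError(
            f"complement p_ECFSC = {pe:.4f} < 0: observed frequencies exceed the simplex",
            equation="p_ECFSC",
        )
    freqs = LineageTypeFrequencies(
        p_ec=min(max(p, 0.0), 1.0),
        p_ecfsc=min(max(pe, 0.0), 1.0),
        p_fsc=min(max(r, 0.0), 1.0),
        p_fc=min(max(q, 0.0), 1.0),
    )
    check = forward_category_frequencies(freqs, sigma)
    for got, want, name in (
        (check.f_ec_obs, obs.f_ec_obs, "f_EC_obs"),
        (check.f_fc_obs, obs.f_fc_obs, "f_FC_obs"),
        (check.f_fsc_obs, obs.f_fsc_obs, "f_FSC_obs"),
    ):
        if abs(got - want) > 1e-9:
            raise InfeasibleFrequenciesError(
                f"solution fails to reproduce {name}: {got:.6f} vs {want:.6f}", equation=name
            )
    return freqs


def solve_all_double_ecfc_anchored(
    f_ec_only: float, f_ecfc: float, f_fsc_only: float
) -> LineageTypeFrequencies:
    """All-double variant anchored on the EC-only and EC+FC classes.

    Used when an experiment has almost no FC-only ovarioles: assume every
    labeled ovariole carries exactly two lineages, so

        f_EC_only  = p_EC^2,
        f_ECFC     = 2*p_EC*p_FC,
        f_FSC_only = p_FSC^2 + 2*p_FSC*p_FC,

    and ``p_ECFSC`` follows by complement. (The FSC equation is the focal
    form in ``p_FSC``; pairing with an FC-only partner keeps the ovariole in
    the FSC-only observable class.)
    """
    for name, v in (("f_ec_only", f_ec_only), ("f_ecfc", f_ecfc), ("f_fsc_only", f_fsc_only)):
        if not (0.0 <= v <= 1.0):
            raise InfeasibleFrequenciesError(f"{name} must lie in [0, 1]")
    if f_ec_only == 0.0:
        if f_ecfc > 0.0:
            raise InfeasibleFrequenciesError(
                "f_ecfc > 0 requires p_EC > 0, but f_ec_only = 0", equation="f_ECFC"
            )
        p = 0.0
        q = 0.0
    else:
        p = math.sqrt(f_ec_only)
        q = f_ecfc / (2.0 * p)
    r = _positive_quadratic_root(1.0, 2.0 * q, -f_fsc_only)
    pe = 1.0 - p - q - r
    if pe < -_SIMPLEX_TOL:
        raise InfeasibleFrequenciesError(
            f"complement p_ECFSC = {pe:.4f} < 0", equation="p_ECFSC"
        )
    return LineageTypeFrequencies(p_ec=p, p_ecfsc=max(pe, 0.0), p_fsc=r, p_fc=q)


def estimate_single_fraction(
    obs: AggregatedFrequencies, grid_step: float = 0.05
) -> MixtureAssumption:
    """Grid estimate of sigma anchored on the discontinuous EC+FC class.

    For each sigma on the grid, the three-category inversion is attempted
    and the forward-model EC+FC fraction compared with the observed one; the
    grid value minimizing the absolute residual wins, ties breaking toward
    larger sigma (the weaker clustering assumption).
    """
    if obs.f_ecfc_obs is None:
        raise EstimationFailureError("f_ecfc_obs is required to estimate sigma")
    if grid_step <= 0.0 or abs(round(1.0 / grid_step) - 1.0 / grid_step) > 1e-9:
        raise EstimationFailureError("grid_step must divide 1 evenly")
    n_steps = round(1.0 / grid_step)
    best: tuple[float, float] | None = None
    path: list[tuple[float, float | None]] = []
    for i in range(n_steps + 1):
        sigma = i * grid_step
        try:
            freqs = solve_lineage_frequencies(obs, sigma)
        except InfeasibleFrequenciesError:
            path.append((sigma, None))
            continue
        predicted = forward_category_frequencies(freqs, sigma).f_ecfc_obs
        residual = abs(predicted - obs.f_ecfc_obs)  # type: ignore[operator]
        path.append((sigma, residual))
        if best is None or residual <= best[1] + 1e-12:
            best = (sigma, residual)
    if best is None:
        raise EstimationFailureError("no sigma on the grid admits a feasible solution")
    return MixtureAssumption(
        sigma=best[0],
        mode=SigmaMode.GRID_ESTIMATED,
        residual=best[1],
        decision_path=tuple(path),
    )


def enumerate_forward_frequencies(
    freqs: LineageTypeFrequencies, sigma: float
) -> AggregatedFrequencies:
    """Brute-force forward model by enumerating all ordered lineage pairs.

    Independent oracle for :func:`forward_category_frequencies`: marginalizes
    the 4 single lineages and all 16 ordered pairs into observable classes
    by the union of the cell types each lineage type produces.
    """
    _check_sigma(sigma)
    produces = {  # type -> (has_EC, has_FSC, has_FC); FC presence in FSC types
        "EC": (True, False, False),  # does not matter for these four classes
        "ECFSC": (True, True, False),
        "FSC": (False, True, False),
        "FC": (False, False, True),
    }
    probs = dict(zip(produces, freqs.as_tuple(), strict=True))

    def classify(members: list[str]) -> str:
        ec = any(produces[m][0] for m in members)
        fsc = any(produces[m][1] for m in members)
        fc = any(produces[m][2] for m in members)
        if fsc:
            return "EC_FSC" if ec else "FSC_only"
        if ec and fc:
            return "EC_plus_FC"
        return "EC_only" if ec else "FC_only"

    mass: dict[str, float] = {}
    for t, pr in probs.items():
        mass[classify([t])] = mass.get(classify([t]), 0.0) + sigma * pr
    for t1, p1 in probs.items():
        for t2, p2 in probs.items():
            c = classify([t1, t2])
            mass[c] = mass.get(c, 0.0) + (1.0 - sigma) * p1 * p2
    return AggregatedFrequencies(
        f_ec_obs=mass.get("EC_only", 0.0) + mass.get("EC_plus_FC", 0.0),
        f_fc_obs=mass.get("FC_only", 0.0) + mass.get("EC_plus_FC", 0.0),
        f_fsc_obs=mass.get("FSC_only", 0.0),
        f_ecfc_obs=mass.get("EC_plus_FC", 0.0),
    )
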