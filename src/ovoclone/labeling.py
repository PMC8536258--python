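"""Independent-recombination binomial labeling model.

With ``n`` dividing precursor cells per ovariole, each labeled independently
with probability ``p``, the unlabeled-ovariole fraction is ``(1 - p)^n``.
Given an observed labeled fraction ``L``, the expected share of marked
ovarioles whose marks derive from exactly one cell is

    n * p * (1 - p)^(n - 1) / L.

The estimate depends only weakly on the assumed ``n``: it is driven almost
entirely by the unlabeled fraction, which is the model's whole point as a
first-pass single-lineage estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

_CONSISTENCY_TOL = 1e-6


@dataclass(frozen=True)
class LabelingEstimate:
    """A (p, n, L) triple plus the implied single-lineage fraction."""

    n_targets: int
    p_cell: float
    labeled_fraction: float
    single_fraction: float

    @property
    def is_consistent(self) -> bool:
        return abs((1.0 - self.p_cell) ** self.n_targets + self.labeled_fraction - 1.0) < 1e-9


def infer_per_cell_probability(unlabeled_fraction: float, n_targets: int) -> float:
    """Per-cell labeling probability ``p`` with ``(1-p)^n = unlabeled_fraction``."""
    if n_targets < 1:
        raise DegenerateInputError("n_targets must be >= 1")
    if not (0.0 < unlabeled_fraction <= 1.0):
        raise DegenerateInputError(
            "unlabeled_fraction must lie in (0, 1]; p is defined at 0 only in the limit"
        )
    return 1.0 - unlabeled_fraction ** (1.0 / n_targets)


def single_lineage_fraction(
    p_cell: float,
    n_targets: int,
    labeled_fraction: float,
    *,
    strict: bool = False,
) -> float:
    """Expected fraction of marked ovarioles with marks from exactly one cell.

    The divisor is the *given* labeled fraction, mirroring the arithmetic the
    quantity is normally quoted with (the published chains substitute a
    rounded ``p`` but keep the observed ``L``). If the triple is inconsistent
    a warning is logged; ``strict=True`` recomputes ``L`` from ``(p, n)``
    instead. A result > 1 (possible only with inconsistent inputs) is
    returned as-is with a warning, never silently clamped.
    """
    if n_targets < 1:
        raise DegenerateInputError("n_targets must be >= 1")
    if not (0.0 <= p_cell <= 1.0):
        raise DegenerateInputError("p_cell must lie in [0, 1]")
    if labeled_fraction <= 0.0:
        raise DegenerateInputError("labeled_fraction must be > 0 (division undefined at 0)")
    implied_l = 1.0 - (1.0 - p_cell) ** n_targets
    if abs(implied_l - labeled_fraction) > _CONSISTENCY_TOL:
        logger.warning(
            "inconsistent labeling triple: (1-p)^n implies labeled fraction %.4f, given %.4f",
            implied_l, labeled_fraction,
        )
        if strict:
            labeled_fraction = implied_l
    value = n_targets * p_cell * (1.0 - p_cell) ** (n_targets - 1) / labeled_fraction
    if value > 1.0:
        logger.warning(
            "single-lineage fraction %.4f > 1 from inconsistent inputs; reported unclamped",
            value,
        )
    return value


def estimate_from_unlabeled_fraction(
    unlabeled_fraction: float, n_targets: int
) -> LabelingEstimate:
    """Full binomial-model estimate from an observed unlabeled fraction."""
    p = infer_per_cell_probability(unlabeled_fraction, n_targets)
    labeled = 1.0 - unlabeled_fraction
    if labeled == 0.0:
        return LabelingEstimate(n_targets, 0.0, 0.0, 0.0)
    single = single_lineage_fraction(p, n_targets, labeled)
    return LabelingEstimate(n_targets, p, labeled, single)
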