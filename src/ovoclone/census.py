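"""Per-lineage yield disaggregation and the precursor census.

Observed mean marked-cell yields are per *ovariole*; under the mixture model
an ovariole in a focal category may carry one focal lineage, two focal
lineages, or one focal and one FC-only lineage (FC-only partners add no ECs
or FSCs). Dividing the observed mean by the expected number of focal
lineages per ovariole yields the mean output of a single lineage. EC/FSC
lineage yields are then obtained by subtraction from the experiment-wide
marked-cell totals.

The census normalizes so that FSC-producing lineages account for the adult
complement of 16 FSCs per germarium:

    n_total = 16 / (p_ECFSC * x + p_FSC * y)

with ``x`` the FSCs per EC/FSC lineage and ``y`` the FSCs per FSC-only
lineage; per-type precursor counts are the lineage-type frequencies times
``n_total``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .errors import (
    DegenerateInputError,
    InconsistentInputsError,
    NoFSCProductionError,
    UndefinedCompositionError,
)
from .mixture import LineageTypeFrequencies
from .records import CloneCategory, CloneCategoryTable

logger = logging.getLogger(__name__)

#: Adult follicle stem cells per germarium; the census normalization constant.
ADULT_FSC_PER_GERMARIUM = 16.0


@dataclass(frozen=True)
class PerLineageYields:
    """Mean marked-cell output of one lineage, by lineage type.

    ``ec_per_ecfsc_lineage`` and ``fsc_per_ecfsc_lineage`` are ``None`` until
    filled in by :func:`ecfsc_yields_by_subtraction`.
    """

    ec_per_ec_lineage: float
    fsc_per_fsc_lineage: float
    ec_per_ecfsc_lineage: float | None = None
    fsc_per_ecfsc_lineage: float | None = None

    def __post_init__(self) -> None:
        for v in (
            self.ec_per_ec_lineage,
            self.fsc_per_fsc_lineage,
            self.ec_per_ecfsc_lineage,
            self.fsc_per_ecfsc_lineage,
        ):
            if v is not None and v < 0:
                raise InconsistentInputsError("per-lineage yields must be >= 0")


@dataclass(frozen=True)
class PrecursorCensus:
    """Dividing-precursor counts per germarium, normalized to 16 adult FSCs."""

    n_total: float
    n_ec: float
    n_ecfsc: float
    n_fsc: float
    n_fc: float
    total_lineages: float | None = None
    fsc_normalization: float = ADULT_FSC_PER_GERMARIUM

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.n_ec, self.n_ecfsc, self.n_fsc, self.n_fc)


@dataclass(frozen=True)
class GermariumProduction:
    """Adult cells made per germarium from dividing precursors.

    From experiment-wide totals of marked r1 ECs (``x_r1``), r2a ECs
    (``y_r2a``) and FSCs (``z_fsc``), scaled so FSC output equals the adult
    complement of 16: ``r1_made = 16x/z`` etc. Valid whether ovarioles carry
    one or several marked lineages, because only totals enter.
    """

    x_r1: float
    y_r2a: float
    z_fsc: float
    fsc_normalization: float = ADULT_FSC_PER_GERMARIUM

    def __post_init__(self) -> None:
        if self.z_fsc <= 0:
            raise DegenerateInputError("total marked FSCs must be > 0")

    @property
    def r1_made(self) -> float:
        return self.fsc_normalization * self.x_r1 / self.z_fsc

    @property
    def r2a_made(self) -> float:
        return self.fsc_normalization * self.y_r2a / self.z_fsc

    @property
    def ec_made(self) -> float:
        return self.r1_made + self.r2a_made


@dataclass(frozen=True)
class CategoryComposition:
    """Makeup of double-lineage ovarioles observed in a focal category.

    ``w_same``: share that are two focal lineages; ``w_cross``: share that
    are one focal plus one FC-only lineage; ``lineages_per_ovariole``: the
    expected number of focal lineages per ovariole in the category,
    ``sigma + (1 - sigma) * (2*w_same + w_cross)``.
    """

    w_same: float
    w_cross: float
    lineages_per_ovariole: float


def category_pair_composition(
    freqs: LineageTypeFrequencies, sigma: float, category: CloneCategory
) -> CategoryComposition:
    """Double-clone composition of the EC-only or FSC-only observable class.

    For EC-only the same:cross weights are ``p_EC^2 : 2 p_EC p_FC``; for
    FSC-only they are ``p_FSC^2 : 2 p_FSC p_FC`` (an FC-only partner leaves
    the ovariole in the focal class; any other partner moves it elsewhere).
    """
    if category is CloneCategory.EC_ONLY:
        focal = freqs.p_ec
    elif category is CloneCategory.FSC_ONLY:
        focal = freqs.p_fsc
    else:
        raise UndefinedCompositionError(
            f"composition defined only for EC_only/FSC_only, not {category}"
        )
    same = focal * focal
    cross = 2.0 * focal * freqs.p_fc
    tot = same + cross
    if tot == 0.0:
        raise UndefinedCompositionError(
            f"both composition weights are zero for {category.value} "
            f"(focal frequency and p_FC are 0)"
        )
    w_same, w_cross = same / tot, cross / tot
    lineages = sigma + (1.0 - sigma) * (2.0 * w_same + w_cross)
    return CategoryComposition(w_same=w_same, w_cross=w_cross, lineages_per_ovariole=lineages)


def per_lineage_yield(observed_mean_per_ovariole: float, lineages_per_ovariole: float) -> float:
    """Mean cells per single lineage from a per-ovariole mean."""
    if lineages_per_ovariole <= 0:
        raise DegenerateInputError("lineages_per_ovariole must be > 0")
    return observed_mean_per_ovariole / lineages_per_ovariole


def total_lineage_count(n_marked_ovarioles: float, sigma: float) -> float:
    """Expected marked lineages in the experiment: ``N * (2 - sigma)``."""
    return n_marked_ovarioles * (2.0 - sigma)


def ecfsc_yields_by_subtraction(
    table: CloneCategoryTable,
    freqs: LineageTypeFrequencies,
    sigma: float,
    yields_so_far: PerLineageYields,
) -> PerLineageYields:
    """Fill in EC/FSC lineage yields from the experiment-wide totals.

    ECs per EC/FSC lineage = (total marked ECs - EC output of EC-only
    lineages) / (number of EC/FSC lineages), and analogously for FSCs using
    the FSC-only lineages; outputs of EC-only and FSC-only lineages are
    their per-lineage yields times their expected lineage counts.
    """
    if table.total_ec_marked is None or table.total_fsc_marked is None:
        raise InconsistentInputsError("experiment-wide EC and FSC totals are required")
    if freqs.p_ecfsc <= 0:
        raise DegenerateInputError("p_ECFSC must be > 0 for the subtraction step")
    lineages = total_lineage_count(table.marked, sigma)
    n_ecfsc_lineages = lineages * freqs.p_ecfsc
    ec_from_ec_only = lineages * freqs.p_ec * yields_so_far.ec_per_ec_lineage
    fsc_from_fsc_only = lineages * freqs.p_fsc * yields_so_far.fsc_per_fsc_lineage
    ec_residual = table.total_ec_marked - ec_from_ec_only
    fsc_residual = table.total_fsc_marked - fsc_from_fsc_only
    if ec_residual < 0 or fsc_residual < 0:
        raise InconsistentInputsError(
            "subtraction residual negative: "
            f"ECs {table.total_ec_marked:.1f} - {ec_from_ec_only:.1f} = {ec_residual:.2f}, "
            f"FSCs {table.total_fsc_marked:.1f} - {fsc_from_fsc_only:.1f} = {fsc_residual:.2f} "
            f"(lineages={lineages:.1f}, freqs={freqs.as_tuple()})"
        )
    return replace(
        yields_so_far,
        ec_per_ecfsc_lineage=ec_residual / n_ecfsc_lineages,
        fsc_per_ecfsc_lineage=fsc_residual / n_ecfsc_lineages,
    )


def precursor_census(
    freqs: LineageTypeFrequencies,
    yields: PerLineageYields,
    total_lineages: float | None = None,
    n_adult_fsc: float = ADULT_FSC_PER_GERMARIUM,
) -> PrecursorCensus:
    """Precursor counts per germarium normalized to the adult FSC complement."""
    x = yields.fsc_per_ecfsc_lineage
    y = yields.fsc_per_fsc_lineage
    if x is None:
        raise InconsistentInputsError("fsc_per_ecfsc_lineage has not been computed")
    fsc_per_precursor = freqs.p_ecfsc * x + freqs.p_fsc * y
    if fsc_per_precursor <= 0:
        raise NoFSCProductionError(
            "no lineage type produces FSCs; census normalization undefined"
        )
    n_total = n_adult_fsc / fsc_per_precursor
    return PrecursorCensus(
        n_total=n_total,
        n_ec=freqs.p_ec * n_total,
        n_ecfsc=freqs.p_ecfsc * n_total,
        n_fsc=freqs.p_fsc * n_total,
        n_fc=freqs.p_fc * n_total,
        total_lineages=total_lineages,
        fsc_normalization=n_adult_fsc,
    )


def germarium_production(x_r1: float, y_r2a: float, z_fsc: float) -> GermariumProduction:
    """Per-germarium EC production from marked-cell totals (16x/z, 16y/z)."""
    return GermariumProduction(x_r1=x_r1, y_r2a=y_r2a, z_fsc=z_fsc)


def nondividing_ec_estimate(
    production_early: GermariumProduction, production_late: GermariumProduction
) -> float:
    """ECs whose precursors ceased dividing between two labeling times.

    The drop in per-germarium EC production between an early and a late
    clone-induction time; may be negative with noisy inputs, in which case
    it is reported as-is with a warning.
    """
    delta = production_early.ec_made - production_late.ec_made
    if delta < 0:
        logger.warning(
            "non-dividing EC estimate is negative (%.2f): later induction "
            "shows higher EC production", delta,
        )
    return delta
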