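"""Per-ovariole clone records, category tables and observed frequencies.

An ovariole scored after clone induction carries some combination of marked
escort cells (ECs, split into anterior region-1 and posterior region-2a
populations), marked follicle stem cells (FSCs), and marked follicle cells
(FCs, recorded by location code rather than count). Each marked ovariole is
assigned to exactly one observable clone category:

* ``EC_FSC``    -- marked FSCs together with marked ECs (with or without FCs);
* ``FSC_only``  -- marked FSCs, no marked ECs (with or without FCs);
* ``EC_plus_FC``-- marked ECs and FCs but no FSCs: a discontinuous pattern
  taken as the signature of two independent lineages;
* ``EC_only``   -- marked ECs alone;
* ``FC_only``   -- marked FCs alone.

The aggregation convention used throughout the mixture model counts
``EC_plus_FC`` ovarioles inside BOTH the EC-without-FSC and FC-without-FSC
observed fractions. This is deliberate and is the single most error-prone
convention in the pipeline: ``f_EC_obs`` is "ovarioles with marked ECs and no
marked FSCs", not "ovarioles whose only marked cells are ECs".
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd

from .errors import EmptyInputError, MalformedRecordError, UsageError

logger = logging.getLogger(__name__)


class FCLocation(str, Enum):
    """Marked-FC location codes, anterior to posterior.

    ``I`` is immediately posterior to the Fas3 border (germarial region 2b),
    ``G`` the posterior germarium (region 3), ``E1``--``E4`` the budded egg
    chambers numbered anterior to posterior (``E4`` most mature).
    """

    I = "I"  # noqa: E741 - the field's own code
    G = "G"
    E1 = "E1"
    E2 = "E2"
    E3 = "E3"
    E4 = "E4"


#: Locations young enough that a marked FC there implies the ovariole still
#: contained a marked FSC at eclosion (four ~12 hr budding cycles over 2 d).
RECENT_FC_LOCATIONS = frozenset(
    {FCLocation.I, FCLocation.G, FCLocation.E1, FCLocation.E2}
)


class BasalStalk(str, Enum):
    """Trivalent basal-stalk marking flag; never coerced to absent."""

    MARKED = "marked"
    UNMARKED = "unmarked"
    NOT_IMAGED = "not_imaged"


class ScoringAge(str, Enum):
    ECLOSION_DAY0 = "eclosion_day0"
    ADULT_DAY2 = "adult_day2"


class CloneCategory(str, Enum):
    EC_ONLY = "EC_only"
    EC_FSC = "EC_FSC"
    FSC_ONLY = "FSC_only"
    FC_ONLY = "FC_only"
    EC_PLUS_FC = "EC_plus_FC"


CATEGORY_ORDER: tuple[CloneCategory, ...] = (
    CloneCategory.EC_ONLY,
    CloneCategory.EC_FSC,
    CloneCategory.FSC_ONLY,
    CloneCategory.FC_ONLY,
    CloneCategory.EC_PLUS_FC,
)


@dataclass(frozen=True)
class OvarioleRecord:
    """One scored ovariole.

    ``n_r1_ec``/``n_r2a_ec`` carry the optional regional split; ``n_ec`` is
    the total marked-EC count. If only the split is given the total is
    derived; if both are given they must agree. All downstream mixture math
    uses the total.
    """

    ovariole_id: str
    n_fsc: int = 0
    n_ec: int | None = None
    n_r1_ec: int | None = None
    n_r2a_ec: int | None = None
    fc_locations: frozenset[FCLocation] = field(default_factory=frozenset)
    basal_stalk: BasalStalk = BasalStalk.NOT_IMAGED
    scoring_age: ScoringAge = ScoringAge.ECLOSION_DAY0
    fsc_lineage_inferred: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "fc_locations", frozenset(FCLocation(c) for c in self.fc_locations))
        split = [self.n_r1_ec, self.n_r2a_ec]
        if any(s is not None for s in split) and not all(s is not None for s in split):
            raise MalformedRecordError(
                f"{self.ovariole_id}: r1/r2a EC split must be given for both regions or neither"
            )
        if self.n_r1_ec is not None:
            total = self.n_r1_ec + self.n_r2a_ec  # type: ignore[operator]
            if self.n_ec is None:
                object.__setattr__(self, "n_ec", total)
            elif self.n_ec != total:
                raise MalformedRecordError(
                    f"{self.ovariole_id}: n_ec={self.n_ec} != r1+r2a={total}"
                )
        elif self.n_ec is None:
            object.__setattr__(self, "n_ec", 0)
        counts = [self.n_fsc, self.n_ec]
        if self.n_r1_ec is not None:
            counts += [self.n_r1_ec, self.n_r2a_ec]
        if any(c < 0 for c in counts):  # type: ignore[operator]
            raise MalformedRecordError(f"{self.ovariole_id}: negative marked-cell count")

    @property
    def has_marked_fc(self) -> bool:
        return bool(self.fc_locations)

    @property
    def has_fsc_lineage(self) -> bool:
        """FSC-containing by direct count or by day-2 inference."""
        return self.n_fsc > 0 or self.fsc_lineage_inferred

    @property
    def is_marked(self) -> bool:
        return bool(self.n_ec or self.has_fsc_lineage or self.has_marked_fc)

    @property
    def category(self) -> CloneCategory | None:
        """Observable clone category; ``None`` for an unlabeled ovariole.

        Basal-stalk marking is auxiliary and never enters the category.
        """
        if self.has_fsc_lineage:
            return CloneCategory.EC_FSC if self.n_ec else CloneCategory.FSC_ONLY
        if self.n_ec and self.has_marked_fc:
            return CloneCategory.EC_PLUS_FC
        if self.n_ec:
            return CloneCategory.EC_ONLY
        if self.has_marked_fc:
            return CloneCategory.FC_ONLY
        return None


def reclassify_day2_adult(record: OvarioleRecord) -> OvarioleRecord:
    """Apply the day-2 adult rescue rule for FSC lineages lost to FC turnover.

    Marked FSCs present at eclosion may all have become FCs by day 2; those
    FCs can only sit around the two germarial cysts or the two youngest egg
    chambers. An ovariole scored at day 2 with no marked FSC but marked FCs
    at ``I``, ``G``, ``E1`` or ``E2`` is therefore treated as FSC-containing
    with an FSC count of zero. Marked ECs are never reattributed. Idempotent.
    """
    if record.scoring_age is not ScoringAge.ADULT_DAY2:
        raise UsageError(
            f"{record.ovariole_id}: reclassification applies only to day-2 adult records"
        )
    if record.n_fsc == 0 and record.fc_locations & RECENT_FC_LOCATIONS:
        return replace(record, fsc_lineage_inferred=True)
    return record


@dataclass(frozen=True)
class CategoryStats:
    """Ovariole count and mean marked-cell yields for one clone category."""

    n: int = 0
    mean_ec: float | None = None
    mean_fsc: float | None = None
    mean_r1_ec: float | None = None
    mean_r2a_ec: float | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise MalformedRecordError("category ovariole count must be >= 0")
        for v in (self.mean_ec, self.mean_fsc, self.mean_r1_ec, self.mean_r2a_ec):
            if v is not None and v < 0:
                raise MalformedRecordError("mean yields must be >= 0")


@dataclass(frozen=True)
class CloneCategoryTable:
    """Aggregated clone-scoring table for one experiment.

    ``n_scored`` may be ``None`` when the overall labeling fraction was not
    recorded; ``marked`` is then the sum of category counts. ``total_ec_marked``
    and ``total_fsc_marked`` are the experiment-wide marked-cell totals summed
    over all ovarioles (used by the subtraction-based yield disaggregation).
    """

    categories: dict[CloneCategory, CategoryStats]
    n_scored: int | None = None
    n_unlabeled: int | None = None
    total_ec_marked: float | None = None
    total_fsc_marked: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        cats = {CloneCategory(k): v for k, v in self.categories.items()}
        for c in CATEGORY_ORDER:
            cats.setdefault(c, CategoryStats())
        object.__setattr__(self, "categories", cats)
        if self.n_scored is not None and self.n_unlabeled is not None:
            if self.n_scored - self.n_unlabeled != self.marked:
                raise MalformedRecordError(
                    f"category counts sum to {self.marked}, expected "
                    f"{self.n_scored} - {self.n_unlabeled} unlabeled"
                )
        self._check_totals()

    def _check_totals(self) -> None:
        # Printed tables round means to 1-2 digits, and at least one published
        # table is internally inconsistent beyond rounding, so mismatches warn
        # rather than raise; explicit totals always take precedence downstream.
        for total, attr in ((self.total_ec_marked, "mean_ec"), (self.total_fsc_marked, "mean_fsc")):
            if total is None:
                continue
            implied = 0.0
            for stats in self.categories.values():
                m = getattr(stats, attr)
                if m is not None:
                    implied += stats.n * m
            if implied and abs(implied - total) > max(1.0, 0.05 * total):
                logger.warning(
                    "%s: %s total %.1f differs from category-weighted sum %.1f "
                    "(rounded published means?)",
                    self.label or "table", attr, total, implied,
                )

    @property
    def marked(self) -> int:
        return sum(s.n for s in self.categories.values())

    def count(self, category: CloneCategory) -> int:
        return self.categories[category].n

    def stats(self, category: CloneCategory) -> CategoryStats:
        return self.categories[category]

    def observed_ec_mean_ec_category(self) -> float:
        """Mean marked ECs per ovariole across EC_only and EC_plus_FC ovarioles."""
        a, b = self.stats(CloneCategory.EC_ONLY), self.stats(CloneCategory.EC_PLUS_FC)
        n = a.n + b.n
        if n == 0:
            raise EmptyInputError("no EC-category ovarioles")
        total = a.n * (a.mean_ec or 0.0) + b.n * (b.mean_ec or 0.0)
        return total / n

    def observed_fsc_mean_fsc_only(self) -> float:
        s = self.stats(CloneCategory.FSC_ONLY)
        if s.n == 0:
            raise EmptyInputError("no FSC-only ovarioles")
        return s.mean_fsc or 0.0


@dataclass(frozen=True)
class AggregatedFrequencies:
    """Observed clone-category fractions among marked ovarioles.

    ``f_ec_obs``: marked ECs but no FSCs (``EC_only`` + ``EC_plus_FC``);
    ``f_fc_obs``: marked FCs but no FSCs (``FC_only`` + ``EC_plus_FC``);
    ``f_fsc_obs``: marked FSCs but no ECs (``FSC_only``);
    ``f_ecfc_obs``: the discontinuous ``EC_plus_FC`` class alone.
    """

    f_ec_obs: float
    f_fc_obs: float
    f_fsc_obs: float
    f_ecfc_obs: float | None = None

    def __post_init__(self) -> None:
        vals = [self.f_ec_obs, self.f_fc_obs, self.f_fsc_obs]
        if self.f_ecfc_obs is not None:
            vals.append(self.f_ecfc_obs)
        if any(not (0.0 <= v <= 1.0) or math.isnan(v) for v in vals):
            raise MalformedRecordError("observed fractions must lie in [0, 1]")
        if self.f_ecfc_obs is not None and self.f_ecfc_obs > min(
            self.f_ec_obs, self.f_fc_obs
        ) + 1e-9:
            raise MalformedRecordError(
                "f_ecfc_obs cannot exceed min(f_ec_obs, f_fc_obs): "
                "EC_plus_FC ovarioles are counted inside both"
            )


def ingest_records(records: Iterable[OvarioleRecord]) -> CloneCategoryTable:
    """Partition validated records into categories and compute means/totals."""
    records = list(records)
    per_cat: dict[CloneCategory, list[OvarioleRecord]] = {c: [] for c in CATEGORY_ORDER}
    n_unlabeled = 0
    total_ec = 0
    total_fsc = 0
    for rec in records:
        cat = rec.category
        if cat is None:
            n_unlabeled += 1
            continue
        per_cat[cat].append(rec)
        total_ec += rec.n_ec or 0
        total_fsc += rec.n_fsc

    def _mean(vals: Sequence[float | None]) -> float | None:
        clean = [v for v in vals if v is not None]
        if len(clean) != len(vals) or not vals:
            return None
        return float(sum(clean)) / len(clean)

    cats = {}
    for cat, recs in per_cat.items():
        cats[cat] = CategoryStats(
            n=len(recs),
            mean_ec=_mean([r.n_ec for r in recs]),
            mean_fsc=_mean([r.n_fsc for r in recs]),
            mean_r1_ec=_mean([r.n_r1_ec for r in recs]),
            mean_r2a_ec=_mean([r.n_r2a_ec for r in recs]),
        )
    return CloneCategoryTable(
        categories=cats,
        n_scored=len(records),
        n_unlabeled=n_unlabeled,
        total_ec_marked=float(total_ec),
        total_fsc_marked=float(total_fsc),
    )


def aggregate_frequencies(table: CloneCategoryTable) -> AggregatedFrequencies:
    """Observed category fractions among marked ovarioles.

    ``EC_plus_FC`` ovarioles contribute to both ``f_ec_obs`` and ``f_fc_obs``.
    """
    m = table.marked
    if m == 0:
        raise EmptyInputError("table has no marked ovarioles")
    c = table.count
    return AggregatedFrequencies(
        f_ec_obs=(c(CloneCategory.EC_ONLY) + c(CloneCategory.EC_PLUS_FC)) / m,
        f_fc_obs=(c(CloneCategory.FC_ONLY) + c(CloneCategory.EC_PLUS_FC)) / m,
        f_fsc_obs=c(CloneCategory.FSC_ONLY) / m,
        f_ecfc_obs=c(CloneCategory.EC_PLUS_FC) / m,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O (schemas documented in docs/SCHEMAS.md)

_RECORD_COLUMNS = [
    "ovariole_id", "n_r1_ec", "n_r2a_ec", "n_fsc",
    "fc_locations", "basal_stalk", "scoring_age",
]


def records_to_frame(records: Iterable[OvarioleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "ovariole_id": r.ovariole_id,
                "n_r1_ec": r.n_r1_ec if r.n_r1_ec is not None else "",
                "n_r2a_ec": r.n_r2a_ec if r.n_r2a_ec is not None else "",
                "n_ec": r.n_ec,
                "n_fsc": r.n_fsc,
                "fc_locations": ";".join(sorted(c.value for c in r.fc_locations)),
                "basal_stalk": r.basal_stalk.value,
                "scoring_age": r.scoring_age.value,
            }
        )
    return pd.DataFrame(rows)


def write_records_csv(records: Iterable[OvarioleRecord], path, sep: str = ",") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def read_records_csv(path, sep: str = ",") -> list[OvarioleRecord]:
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = {"ovariole_id", "n_fsc"} - set(df.columns)
    if missing:
        raise MalformedRecordError(f"records file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        def _int(col: str) -> int | None:
            v = str(row.get(col, "")).strip()
            return int(float(v)) if v else None

        locs = frozenset(
            FCLocation(tok.strip())
            for tok in str(row.get("fc_locations", "")).split(";")
            if tok.strip()
        )
        out.append(
            OvarioleRecord(
                ovariole_id=str(row["ovariole_id"]),
                n_fsc=_int("n_fsc") or 0,
                n_ec=_int("n_ec"),
                n_r1_ec=_int("n_r1_ec"),
                n_r2a_ec=_int("n_r2a_ec"),
                fc_locations=locs,
                basal_stalk=BasalStalk(str(row.get("basal_stalk", "") or "not_imaged")),
                scoring_age=ScoringAge(str(row.get("scoring_age", "") or "eclosion_day0")),
            )
        )
    return out


def read_aggregated_csv(path, sep: str = ",") -> CloneCategoryTable:
    """Read a category table mirroring the published raw-data rows.

    Expected columns: ``category,n,mean_ec,mean_fsc`` with one row per clone
    category plus optional special rows ``unlabeled``, ``total_EC_marked``
    and ``total_FSC_marked`` (value in the ``n`` column).
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    cats: dict[CloneCategory, CategoryStats] = {}
    unlabeled = None
    total_ec = total_fsc = None
    for _, row in df.iterrows():
        key = str(row["category"]).strip()
        val = str(row["n"]).strip()
        if key == "unlabeled":
            unlabeled = int(float(val))
            continue
        if key == "total_EC_marked":
            total_ec = float(val)
            continue
        if key == "total_FSC_marked":
            total_fsc = float(val)
            continue
        def _flt(col: str) -> float | None:
            v = str(row.get(col, "")).strip()
            return float(v) if v else None

        cats[CloneCategory(key)] = CategoryStats(
            n=int(float(val)), mean_ec=_flt("mean_ec"), mean_fsc=_flt("mean_fsc")
        )
    marked = sum(s.n for s in cats.values())
    n_scored = marked + unlabeled if unlabeled is not None else None
    return CloneCategoryTable(
        categories=cats,
        n_scored=n_scored,
        n_unlabeled=unlabeled,
        total_ec_marked=total_ec,
        total_fsc_marked=total_fsc,
    )
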