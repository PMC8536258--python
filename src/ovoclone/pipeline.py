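"""Full census pipeline: frequencies -> deconvolution -> yields -> census.

`run_full_census` chains the stages on one clone-category table and returns
a report bundle that serializes to JSON (the machine contract) and to a
markdown table shaped like the published summary rows (for humans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

from .census import (
    PerLineageYields,
    PrecursorCensus,
    category_pair_composition,
    ecfsc_yields_by_subtraction,
    per_lineage_yield,
    precursor_census,
    total_lineage_count,
)
from .datasets import CloneDataset, PublishedReference
from .errors import ConfigError, EmptyInputError
from .mixture import (
    LineageTypeFrequencies,
    MixtureAssumption,
    SigmaMode,
    estimate_single_fraction,
    solve_all_double_ecfc_anchored,
    solve_lineage_frequencies,
)
from .records import AggregatedFrequencies, CloneCategory, CloneCategoryTable, aggregate_frequencies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SigmaPolicy:
    """How the single-lineage fraction is fixed or estimated.

    ``mode``: ``fixed`` (use ``value``), ``auto`` (grid estimate anchored on
    the EC+FC class), ``all_double`` (sigma = 0), or
    ``all_double_ecfc_anchored`` (sigma = 0 with the EC-only/EC+FC anchored
    inversion, for experiments with almost no FC-only ovarioles).
    """

    mode: str = "auto"
    value: float | None = None
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in {"fixed", "auto", "all_double", "all_double_ecfc_anchored"}:
            raise ConfigError(f"unknown sigma policy mode: {self.mode!r}")
        if self.mode == "fixed" and self.value is None:
            raise ConfigError("sigma policy 'fixed' requires a value")


@dataclass(frozen=True)
class CensusReport:
    """Everything the pipeline decided and computed for one experiment."""

    label: str
    n_marked: int
    frequencies: AggregatedFrequencies
    mixture: MixtureAssumption
    lineage_freqs: LineageTypeFrequencies
    yields: PerLineageYields
    census: PrecursorCensus
    reference: PublishedReference | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "label": self.label,
            "n_marked_ovarioles": self.n_marked,
            "observed_frequencies": {
                "f_EC_obs": self.frequencies.f_ec_obs,
                "f_FC_obs": self.frequencies.f_fc_obs,
                "f_FSC_obs": self.frequencies.f_fsc_obs,
                "f_ECFC_obs": self.frequencies.f_ecfc_obs,
            },
            "sigma": {
                "value": self.mixture.sigma,
                "mode": self.mixture.mode.value,
                "residual": self.mixture.residual,
                "decision_path": [list(step) for step in self.mixture.decision_path],
            },
            "lineage_frequencies": {
                "p_EC": self.lineage_freqs.p_ec,
                "p_ECFSC": self.lineage_freqs.p_ecfsc,
                "p_FSC": self.lineage_freqs.p_fsc,
                "p_FC": self.lineage_freqs.p_fc,
            },
            "per_lineage_yields": {
                "ec_per_EC_lineage": self.yields.ec_per_ec_lineage,
                "fsc_per_FSC_lineage": self.yields.fsc_per_fsc_lineage,
                "ec_per_ECFSC_lineage": self.yields.ec_per_ecfsc_lineage,
                "fsc_per_ECFSC_lineage": self.yields.fsc_per_ecfsc_lineage,
            },
            "census": {
                "n_total": self.census.n_total,
                "n_EC": self.census.n_ec,
                "n_ECFSC": self.census.n_ecfsc,
                "n_FSC": self.census.n_fsc,
                "n_FC": self.census.n_fc,
                "total_lineages": self.census.total_lineages,
                "fsc_normalization": self.census.fsc_normalization,
            },
            "notes": list(self.notes),
        }
        if self.reference is not None:
            ref = self.reference
            out["published_reference"] = {
                "sigma": ref.sigma,
                "lineage_frequencies": dict(
                    zip(("p_EC", "p_ECFSC", "p_FSC", "p_FC"), ref.lineage_freqs)
                ),
                "n_total": ref.n_total,
                "per_type": list(ref.per_type),
                "notes": list(ref.notes),
            }
            out["deltas_vs_published"] = {
                "n_total": self.census.n_total - ref.n_total,
                "p_EC": self.lineage_freqs.p_ec - ref.lineage_freqs[0],
                "p_ECFSC": self.lineage_freqs.p_ecfsc - ref.lineage_freqs[1],
                "p_FSC": self.lineage_freqs.p_fsc - ref.lineage_freqs[2],
                "p_FC": self.lineage_freqs.p_fc - ref.lineage_freqs[3],
            }
        return out

    def to_markdown(self) -> str:
        f, y, c = self.lineage_freqs, self.yields, self.census
        header = (
            "| dataset | 100·p_EC | 100·p_ECFSC | 100·p_FSC | 100·p_FC | "
            "EC/lin (EC) | FSC/lin (FSC) | EC/lin (ECFSC) | FSC/lin (ECFSC) | "
            "n_total | n_EC | n_ECFSC | n_FSC | n_FC |"
        )
        rule = "|" + "---|" * 14
        def fmt(v: float | None) -> str:
            return "" if v is None else f"{v:.2f}"
        row = (
            f"| {self.label} | {100 * f.p_ec:.1f} | {100 * f.p_ecfsc:.1f} | "
            f"{100 * f.p_fsc:.1f} | {100 * f.p_fc:.1f} | "
            f"{fmt(y.ec_per_ec_lineage)} | {fmt(y.fsc_per_fsc_lineage)} | "
            f"{fmt(y.ec_per_ecfsc_lineage)} | {fmt(y.fsc_per_ecfsc_lineage)} | "
            f"{c.n_total:.1f} | {c.n_ec:.1f} | {c.n_ecfsc:.1f} | {c.n_fsc:.1f} | {c.n_fc:.1f} |"
        )
        lines = [header, rule, row]
        if self.reference is not None:
            ref = self.reference
            rf = ref.lineage_freqs
            ry = ref.yields
            lines.append(
                f"| {self.label} (published) | {100 * rf[0]:.1f} | {100 * rf[1]:.1f} | "
                f"{100 * rf[2]:.1f} | {100 * rf[3]:.1f} | "
                f"{fmt(ry.ec_per_ec_lineage)} | {fmt(ry.fsc_per_fsc_lineage)} | "
                f"{fmt(ry.ec_per_ecfsc_lineage)} | {fmt(ry.fsc_per_ecfsc_lineage)} | "
                f"{ref.n_total:.1f} | " + " | ".join(f"{v:.1f}" for v in ref.per_type) + " |"
            )
        return "\n".join(lines)


def resolve_sigma(
    policy: SigmaPolicy, obs: AggregatedFrequencies
) -> MixtureAssumption:
    if policy.mode == "fixed":
        sigma = float(policy.value)  # type: ignore[arg-type]
        mode = (
            SigmaMode.ALL_DOUBLE if sigma == 0.0
            else SigmaMode.ALL_SINGLE if sigma == 1.0
            else SigmaMode.FIXED
        )
        return MixtureAssumption(sigma=sigma, mode=mode)
    if policy.mode in {"all_double", "all_double_ecfc_anchored"}:
        return MixtureAssumption(sigma=0.0, mode=SigmaMode.ALL_DOUBLE)
    return estimate_single_fraction(obs, grid_step=policy.grid_step)


def run_full_census(
    table: CloneCategoryTable,
    sigma_policy: SigmaPolicy | None = None,
    reference: PublishedReference | None = None,
) -> CensusReport:
    """Run the complete inference chain on one clone-category table."""
    policy = sigma_policy or SigmaPolicy()
    if table.marked == 0:
        raise EmptyInputError("input table has no marked ovarioles")
    obs = aggregate_frequencies(table)
    mixture = resolve_sigma(policy, obs)
    notes: list[str] = []

    if policy.mode == "all_double_ecfc_anchored":
        m = table.marked
        freqs = solve_all_double_ecfc_anchored(
            f_ec_only=table.count(CloneCategory.EC_ONLY) / m,
            f_ecfc=table.count(CloneCategory.EC_PLUS_FC) / m,
            f_fsc_only=table.count(CloneCategory.FSC_ONLY) / m,
        )
        notes.append("EC-only/EC+FC anchored inversion (all ovarioles double)")
    else:
        freqs = solve_lineage_frequencies(obs, mixture.sigma)

    sigma = mixture.sigma
    ec_comp = category_pair_composition(freqs, sigma, CloneCategory.EC_ONLY)
    fsc_comp = category_pair_composition(freqs, sigma, CloneCategory.FSC_ONLY)
    yields = PerLineageYields(
        ec_per_ec_lineage=per_lineage_yield(
            table.observed_ec_mean_ec_category(), ec_comp.lineages_per_ovariole
        ),
        fsc_per_fsc_lineage=per_lineage_yield(
            table.observed_fsc_mean_fsc_only(), fsc_comp.lineages_per_ovariole
        ),
    )
    yields = ecfsc_yields_by_subtraction(table, freqs, sigma, yields)
    census = precursor_census(
        freqs, yields, total_lineages=total_lineage_count(table.marked, sigma)
    )
    if reference is not None and abs(census.n_total - reference.n_total) > 0.5:
        notes.append(
            f"computed n_total {census.n_total:.1f} differs from published "
            f"{reference.n_total:.1f}; see reference notes"
        )
    return CensusReport(
        label=table.label,
        n_marked=table.marked,
        frequencies=obs,
        mixture=mixture,
        lineage_freqs=freqs,
        yields=yields,
        census=census,
        reference=reference,
        notes=tuple(notes) + (reference.notes if reference is not None else ()),
    )


def run_dataset(dataset: CloneDataset, sigma_policy: SigmaPolicy | None = None) -> CensusReport:
    """Run the pipeline on a built-in dataset with its published analysis policy."""
    if sigma_policy is None:
        if dataset.sigma_policy == "fixed":
            sigma_policy = SigmaPolicy(mode="fixed", value=dataset.reference.sigma)
        else:
            sigma_policy = SigmaPolicy(mode=dataset.sigma_policy)
    return run_full_census(dataset.table, sigma_policy, reference=dataset.reference)
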