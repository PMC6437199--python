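"""PE-positive fractions, the antibody index and the seropositivity call.

The antibody index is the proportion of PE-positive cells in the
antigen-transfected population divided by that in the parental population::

    index = pe_pct_transfected / max(pe_pct_parental, floor)

with each percentage measured against its own cell line's calibrated 0.5%
background threshold.  A serum is seropositive when the index is strictly
greater than 1.0: more IgG bound to the antigen-expressing cells than to
the parental cells.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .config import GatingConfig, IndexConfig, PipelineConfig
from .errors import (
    CalibrationPrerequisiteError,
    CytocbaError,
    DomainError,
    InsufficientPopulationError,
)
from .gating import (
    GateMask,
    GatingReport,
    ThresholdSet,
    calibrate_gfp_thresholds,
    calibrate_pe_background,
    gate_live,
    gate_viable,
    select_population,
)
from .io import AssayRun, EventTable


def pe_positive_fraction(table: EventTable, population: GateMask,
                         pe_threshold: float) -> float:
    """Percent of the gated population with PE strictly above the threshold.

    Strict inequality: events tied with the threshold count as negative,
    which is what guarantees the <= 0.5% background contract on the
    calibration control itself.
    """
    n = population.n_retained
    if n == 0:
        raise InsufficientPopulationError(
            f"{table.sample_id}: empty population for PE fraction")
    pe = table.channel("PE")[population.mask]
    return float(100.0 * np.count_nonzero(pe > pe_threshold) / n)


def _round_half_away(x: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def round_index(raw: float) -> float:
    """Report rounding: two decimals below 10, one decimal from 10 up
    (so 0.5652 -> 0.57 and 16.238 -> 16.2)."""
    return _round_half_away(raw, 2 if raw < 10 else 1)


def compute_index(pe_pct_transfected: float, pe_pct_parental: float,
                  floor: float = 0.5, rounded: bool = True) -> float:
    """Antibody index from the two PE-positive percentages.

    The denominator is floored at the background rate (0.5 percent by
    default) so a parental fraction below background cannot produce an
    unbounded index.  Returns the report-rounded value by default; pass
    ``rounded=False`` for the raw ratio.
    """
    for name, value in (("pe_pct_transfected", pe_pct_transfected),
                        ("pe_pct_parental", pe_pct_parental)):
        if not 0.0 <= value <= 100.0:
            raise DomainError(f"{name}={value} outside [0, 100]")
    raw = pe_pct_transfected / max(pe_pct_parental, floor)
    return round_index(raw) if rounded else raw


def call_seropositive(antibody_index: float, cutoff: float = 1.0) -> str:
    """Binary call: ``positive`` iff the index is strictly over the cutoff."""
    if antibody_index < 0:
        raise DomainError(f"antibody index must be >= 0, got {antibody_index}")
    return "positive" if antibody_index > cutoff else "negative"


@dataclass
class IndexResult:
    """Outcome of one serum x antigen assay, with full gating provenance."""

    serum_id: str
    antigen: str
    dilution: int
    pe_pct_parental: float
    pe_pct_transfected: float
    antibody_index: float        # report-rounded
    antibody_index_raw: float
    call: str
    n_population_parental: int
    n_population_transfected: int
    thresholds_used: ThresholdSet
    denominator_floored: bool
    replicate: int = 0
    gating_reports: list[GatingReport] | None = None

    def to_row(self) -> dict:
        row = asdict(self)
        row.pop("gating_reports")
        row.update({f"threshold_{k}": v
                    for k, v in asdict(self.thresholds_used).items()})
        row.pop("thresholds_used")
        return row


def _gate_sample(table: EventTable, config: GatingConfig
                 ) -> tuple[GateMask, GateMask]:
    live = gate_live(table, config)
    viable = gate_viable(table, live, config.aad_threshold)
    return live, viable


def run_assay(run: AssayRun, config: PipelineConfig | None = None) -> IndexResult:
    """Execute the full pipeline on one assay unit.

    Stages: live scatter gate -> 7-AAD viability gate -> GFP cut-off
    calibration from the two secondary-only controls -> population
    selection -> per-cell-line 0.5% PE background calibration -> PE
    fractions on the test pair -> antibody index -> seropositivity call.
    """
    config = config or PipelineConfig.default()
    gcfg, icfg = config.gating, config.index
    for name in ("control_parental", "control_transfected"):
        if getattr(run, name) is None:
            raise CalibrationPrerequisiteError(
                f"serum {run.serum_id!r}: missing {name} background control")

    masks: dict[str, tuple[GateMask, GateMask]] = {}
    for name, table in run.samples.items():
        try:
            masks[name] = _gate_sample(table, gcfg)
        except CytocbaError as exc:
            raise type(exc)(f"[sample {table.sample_id}] {exc}") from exc

    gfp_par, gfp_tr = calibrate_gfp_thresholds(
        run.control_parental, run.control_transfected, mode=gcfg.gfp_mode,
        parental_mask=masks["control_parental"][1],
        transfected_mask=masks["control_transfected"][1],
        tail_rate=gcfg.gfp_tail_rate,
    )

    rate = icfg.background_rate / 100.0
    pe_thresholds: dict[str, float] = {}
    populations: dict[str, GateMask] = {}
    partial = ThresholdSet(gfp_par, gfp_tr, 0.0, 0.0,
                           gcfg.aad_threshold, gcfg.gfp_mode)
    for line, ctl_name in (("parental", "control_parental"),
                           ("transfected", "control_transfected")):
        control = getattr(run, ctl_name)
        try:
            ctl_pop = select_population(control, partial, masks[ctl_name][1],
                                        gcfg.min_population)
            pe_thresholds[line] = calibrate_pe_background(control, ctl_pop, rate)
        except CytocbaError as exc:
            raise type(exc)(f"[sample {control.sample_id}] {exc}") from exc

    thresholds = ThresholdSet(
        gfp_cutoff_parental=gfp_par, gfp_cutoff_transfected=gfp_tr,
        pe_threshold_parental=pe_thresholds["parental"],
        pe_threshold_transfected=pe_thresholds["transfected"],
        aad_threshold=gcfg.aad_threshold, gfp_mode=gcfg.gfp_mode,
    )

    pcts: dict[str, float] = {}
    n_pop: dict[str, int] = {}
    reports: list[GatingReport] = []
    for line, test_name in (("parental", "test_parental"),
                            ("transfected", "test_transfected")):
        table = getattr(run, test_name)
        live, viable = masks[test_name]
        try:
            pop = select_population(table, thresholds, viable, gcfg.min_population)
            populations[test_name] = pop
            pcts[line] = pe_positive_fraction(table, pop, pe_thresholds[line])
        except CytocbaError as exc:
            raise type(exc)(f"[sample {table.sample_id}] {exc}") from exc
        n_pop[line] = populations[test_name].n_retained
        reports.append(GatingReport(
            sample_id=table.sample_id, n_events=table.n_events,
            live_fraction=live.retained_fraction,
            viable_fraction=viable.retained_fraction,
            population_fraction=populations[test_name].retained_fraction,
        ))

    raw = compute_index(pcts["transfected"], pcts["parental"],
                        floor=icfg.denominator_floor, rounded=False)
    return IndexResult(
        serum_id=run.serum_id, antigen=run.antigen, dilution=run.dilution,
        pe_pct_parental=pcts["parental"],
        pe_pct_transfected=pcts["transfected"],
        antibody_index=round_index(raw), antibody_index_raw=raw,
        call=call_seropositive(raw, icfg.cutoff),
        n_population_parental=n_pop["parental"],
        n_population_transfected=n_pop["transfected"],
        thresholds_used=thresholds,
        denominator_floored=pcts["parental"] < icfg.denominator_floor,
        replicate=run.replicate,
        gating_reports=reports,
    )


@dataclass
class SeriesSummary:
    """Stability summary of a series of runs of the same serum x antigen.

    Replicates of one condition (same dilution and nominal cell count) are
    summarised by their mean index, following the triplicate protocol;
    ``max_min_ratio`` is taken over condition means.
    """

    serum_id: str
    antigen: str
    condition_means: dict
    max_min_ratio: float
    mean_index: float
    calls: list
    calls_identical: bool


def run_series(runs: list[AssayRun], config: PipelineConfig | None = None
               ) -> tuple[list[IndexResult], SeriesSummary]:
    """Run every assay of a dilution or cell-number series and summarise
    the stability of the index across conditions."""
    if not runs:
        raise DomainError("run_series requires at least one run")
    serum_ids = {r.serum_id for r in runs}
    antigens = {r.antigen for r in runs}
    if len(serum_ids) > 1 or len(antigens) > 1:
        raise DomainError(
            f"series must share one serum and antigen; got {serum_ids} x {antigens}")

    config = config or PipelineConfig.default()
    results = [run_assay(run, config) for run in runs]

    by_condition: dict[tuple, list[float]] = {}
    for run, res in zip(runs, results):
        key = (run.dilution, run.test_transfected.cell_count_nominal)
        by_condition.setdefault(key, []).append(res.antibody_index_raw)
    condition_means = {key: float(np.mean(vals))
                       for key, vals in by_condition.items()}
    means = list(condition_means.values())
    calls = [r.call for r in results]
    return results, SeriesSummary(
        serum_id=runs[0].serum_id, antigen=runs[0].antigen,
        condition_means=condition_means,
        max_min_ratio=float(max(means) / min(means)) if min(means) > 0 else math.inf,
        mean_index=float(np.mean([r.antibody_index_raw for r in results])),
        calls=calls,
        calls_identical=len(set(calls)) == 1,
    )


def results_table(results: list[IndexResult]) -> pd.DataFrame:
    """One row per (serum, antigen, dilution, replicate) with all result
    fields — the results-TSV payload."""
    return pd.DataFrame([r.to_row() for r in results])
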