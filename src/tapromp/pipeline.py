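"""Full study orchestration: fit every cell, compare phases, exclude outliers.

The analysis follows the study protocol: every (participant, stimulation,
phase, experiment) cell is segmented and fitted with a ProMP per movement
direction; the pre-stimulation baseline (Prae) is compared against each
post-stimulation recording (Post1-3) via the symmetric KL divergence of the
ProMP-reconstructed trajectory distributions; comparisons whose divergence
exceeds mu_D + 3 sigma_D in either direction are excluded as outliers
(one-sided: unusually low divergences are valid); the remainder is
aggregated per stimulation type and comparison, and overall per direction.

The familiarization run (Erst) is fitted for completeness but never enters
the statistics: subjects explore during it, so its divergences do not
measure stimulation effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import PhaseGrid, RawRecording, TrajectoryDistribution
from .divergence import trajectory_kls
from .preprocessing import N_SELECTED_STROKES, preprocess_recording
from .promp import DEFAULT_LAMBDA, DEFAULT_M, ProMPModel, empirical_distribution
from .synthetic import (
    POST_PHASES,
    StudyDesign,
    SyntheticConfig,
    iter_study,
)

__all__ = [
    "ExperimentKey",
    "CellFit",
    "OutlierReport",
    "PipelineConfig",
    "StudyResult",
    "run_experiment_fit",
    "compare_phases",
    "detect_outliers",
    "aggregate_results",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ERST = "Erst"
PRAE = "Prae"

# Columns identifying one exclusion unit: a comparison is kept or dropped as
# a whole across both movement directions.
UNIT_COLUMNS = ["participant", "stimulation", "experiment", "comparison"]


@dataclass(frozen=True)
class ExperimentKey:
    """Index of one fitted cell and movement direction."""

    participant: int
    stimulation: str
    phase: str
    experiment: int
    direction: str


@dataclass(eq=False)
class CellFit:
    """Fit products of one (cell, direction): distributions and optionally the model."""

    key: ExperimentKey
    empirical: TrajectoryDistribution
    reconstructed: TrajectoryDistribution
    n_strokes: int
    model: ProMPModel | None = None


@dataclass(eq=False)
class OutlierReport:
    """Pooled 3-sigma exclusion summary.

    ``mu`` and ``sigma`` pool every Prae-vs-Post divergence (both
    directions); ``flagged`` lists the excluded units with the direction and
    value that exceeded mu + n_sigma * sigma.
    """

    mu: float
    sigma: float
    n_sigma: float
    threshold: float
    flagged: list[dict] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run depends on.

    ``design`` and ``synth`` describe the simulated study (for real data use
    the io module and feed recordings straight to
    :func:`run_experiment_fit`); T, M and lam are the ProMP
    hyper-parameters; ``blacklist`` holds (participant, stimulation,
    experiment) cells excluded by hand, e.g. after video verification of a
    sensor mishap.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    T: int = 100
    M: int = DEFAULT_M
    lam: float = DEFAULT_LAMBDA
    window_fraction: float = 0.1
    tap_threshold: float = 0.5
    refractory: float = 0.1
    n_select: int = N_SELECTED_STROKES
    lowpass_cutoff: float | None = None
    n_sigma: float = 3.0
    include_erst_in_statistics: bool = False
    blacklist: tuple[tuple[int, str, int], ...] = ()
    keep_models: bool = False

    def __post_init__(self) -> None:
        if self.include_erst_in_statistics:
            raise ValueError(
                "the familiarization phase (Erst) cannot enter the statistics: "
                "subjects behave exploratorily during it; it is fitted but "
                "always excluded from divergence comparisons"
            )

    @property
    def grid(self) -> PhaseGrid:
        return PhaseGrid.uniform(self.T)


@dataclass(eq=False)
class StudyResult:
    """Bundle returned by :func:`run_pipeline`."""

    fits: dict[ExperimentKey, CellFit]
    missing: list[dict]
    table: pd.DataFrame
    report: OutlierReport
    filtered: pd.DataFrame
    summary: pd.DataFrame
    overall: pd.DataFrame


def run_experiment_fit(
    recordings: Iterable[tuple[tuple[int, str, str, int], RawRecording]],
    config: PipelineConfig,
) -> tuple[dict[ExperimentKey, CellFit], list[dict]]:
    """Fit one ProMP per (cell, direction) over a stream of recordings.

    Cells whose segmentation yields too few strokes are recorded in the
    ``missing`` list and skipped; the run continues.  Erst cells are fitted
    like any other (they are excluded later, at the comparison stage).
    """
    fits: dict[ExperimentKey, CellFit] = {}
    missing: list[dict] = []
    grid = config.grid
    for (q, s, o, p), rec in recordings:
        try:
            sets = preprocess_recording(
                rec,
                grid,
                threshold=config.tap_threshold,
                refractory=config.refractory,
                n_select=config.n_select,
                lowpass_cutoff=config.lowpass_cutoff,
            )
        except ValueError as exc:
            missing.append(
                {"participant": q, "stimulation": s, "phase": o, "experiment": p,
                 "reason": str(exc)}
            )
            logger.warning("skipping cell (%s, %s, %s, %s): %s", q, s, o, p, exc)
            continue
        for direction, strokes in sets.items():
            key = ExperimentKey(q, s, o, p, direction)
            model = ProMPModel.fit(strokes, M=config.M, lam=config.lam)
            fits[key] = CellFit(
                key,
                empirical_distribution(strokes),
                model.marginal(),
                strokes.n_strokes,
                model if config.keep_models else None,
            )
    return fits, missing


def compare_phases(
    fits: Mapping[ExperimentKey, CellFit], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Prae-vs-Post divergences on the reconstructed distributions.

    One row per (participant, stimulation, experiment, direction,
    comparison); comparisons are computed on the ProMP-reconstructed
    trajectory distributions.  Keys without a Prae fit are skipped with a
    log entry; Erst never enters.
    """
    rows = []
    cells = {
        (k.participant, k.stimulation, k.experiment, k.direction): {}
        for k in fits
    }
    for k, cf in fits.items():
        cells[(k.participant, k.stimulation, k.experiment, k.direction)][k.phase] = cf
    for (q, s, p, direction), by_phase in sorted(
        cells.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
    ):
        if PRAE not in by_phase:
            logger.warning(
                "no Prae fit for participant %s, %s, experiment %s (%s); skipped",
                q, s, p, direction,
            )
            continue
        prae = by_phase[PRAE].reconstructed
        for post in POST_PHASES:
            if post not in by_phase:
                continue
            value = trajectory_kls(prae, by_phase[post].reconstructed).value
            rows.append(
                {
                    "participant": q,
                    "stimulation": s,
                    "experiment": p,
                    "direction": direction,
                    "comparison": f"{PRAE}-{post}",
                    "value": value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant", "stimulation", "experiment", "direction",
                 "comparison", "value"],
    )


def detect_outliers(
    table: pd.DataFrame, n_sigma: float = 3.0
) -> tuple[OutlierReport, pd.DataFrame, pd.DataFrame]:
    """One-sided 3-sigma exclusion of divergence comparisons.

    mu_D and sigma_D pool every row (all comparisons and both directions).
    A unit - one (participant, stimulation, experiment, comparison) - is
    excluded when its inward OR outward value exceeds mu_D + n_sigma *
    sigma_D; unusually low values are valid and never excluded.  Returns the
    report, the filtered table and the flagged rows; filtered + flagged
    always partition the input.
    """
    if len(table) < 2:
        raise ValueError("need at least two divergence rows")
    values = table["value"].to_numpy(dtype=float)
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    threshold = mu + n_sigma * sigma
    exceed = table[table["value"] > threshold]
    flagged_units = set(map(tuple, exceed[UNIT_COLUMNS].itertuples(index=False)))
    unit_tuples = list(map(tuple, table[UNIT_COLUMNS].itertuples(index=False)))
    mask = np.array([u in flagged_units for u in unit_tuples])
    report = OutlierReport(
        mu,
        sigma,
        n_sigma,
        threshold,
        [
            {
                **dict(zip(UNIT_COLUMNS, row[UNIT_COLUMNS])),
                "direction": row["direction"],
                "value": float(row["value"]),
            }
            for _, row in exceed.iterrows()
        ],
    )
    return report, table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)


def aggregate_results(
    filtered: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means/stds of the outlier-filtered divergences.

    Returns ``(summary, overall)``: ``summary`` has mean, std and count per
    (stimulation, comparison, direction) - averaging over participants and
    experiments; ``overall`` collapses everything per movement direction
    (the inward-vs-outward consistency check).  Empty groups are simply
    absent, never reported as zero.
    """
    if filtered.empty:
        raise ValueError("no divergence rows left to aggregate")
    summary = (
        filtered.groupby(["stimulation", "comparison", "direction"])["value"]
        .agg(mean="mean", std="std", count="count")
        .reset_index()
    )
    overall = (
        filtered.groupby("direction")["value"]
        .agg(mean="mean", std="std", count="count")
        .reset_index()
    )
    return summary, overall


def _apply_blacklist(table: pd.DataFrame, blacklist) -> pd.DataFrame:
    if not blacklist:
        return table
    black = {tuple(b) for b in blacklist}
    keep = [
        (row.participant, row.stimulation, row.experiment) not in black
        for row in table.itertuples(index=False)
    ]
    return table[keep].reset_index(drop=True)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> StudyResult:
    """simulate -> preprocess -> fit -> compare -> outliers -> aggregate.

    A pure function of (config, seed): two runs with the same configuration
    produce identical result tables.  If ``outdir`` is given, writes
    ``divergences.csv`` (all rows with an ``outlier`` flag),
    ``outliers.json`` and ``summary.csv``.
    """
    recordings = iter_study(config.design, config.synth, config.seed)
    fits, missing = run_experiment_fit(recordings, config)
    table = compare_phases(fits, config)
    table = _apply_blacklist(table, config.blacklist)
    report, filtered, flagged = detect_outliers(table, config.n_sigma)
    summary, overall = aggregate_results(filtered)
    result = StudyResult(fits, missing, table, report, filtered, summary, overall)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flagged_units = {
            tuple(f[c] for c in UNIT_COLUMNS) for f in report.flagged
        }
        out_table = table.copy()
        out_table["outlier"] = [
            tuple(row[c] for c in UNIT_COLUMNS) in flagged_units
            for _, row in table.iterrows()
        ]
        out_table.to_csv(outdir / "divergences.csv", index=False)
        summary_all = pd.concat(
            [
                summary,
                overall.assign(stimulation="all", comparison="all")[
                    summary.columns
                ],
            ],
            ignore_index=True,
        )
        summary_all.to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "outliers.json", "w") as fh:
            json.dump(
                {
                    "mu": report.mu,
                    "sigma": report.sigma,
                    "n_sigma": report.n_sigma,
                    "threshold": report.threshold,
                    "flagged": report.flagged,
                    "missing_cells": missing,
                },
                fh,
                indent=2,
            )
    return result
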