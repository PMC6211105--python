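"""End-to-end orchestration: simulate -> map -> depth -> CN -> summaries.

Ties the synthetic cohort generator to the depth/CN estimator and the
population summaries so a whole in-silico cohort study runs from a single
:class:`~bchromcnv.simulate.SimConfig`. Individuals are processed one at a
time to keep memory flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import depth as depth_mod
from .depth import Windows, tile_windows
from .mapping import ExactIndex
from .population import CNMatrix, control_report, fragment_cn, summarize_population
from .simulate import (
    CohortTruth,
    Reference,
    SimConfig,
    _insertion_sites,
    build_reference,
    draw_truth,
    individual_genome,
    simulate_reads,
)


@dataclass
class IndividualResult:
    individual: str
    population: str
    windows: Windows | None
    fragment_cn: pd.Series  # fragment_id -> CN (controls included as pseudo-fragments)
    control_window_mean: float  # mean CN over all control-region windows
    n_reads: int
    n_unplaced: int


@dataclass
class CohortResult:
    config: SimConfig
    reference: Reference
    truth: CohortTruth
    matrix: CNMatrix  # columns: B fragments then control ids
    control_ids: list[str]
    control_window_means: pd.Series  # individual -> mean control-window CN
    individuals: list[IndividualResult] = field(default_factory=list)

    @property
    def fragment_matrix(self) -> CNMatrix:
        frag_cols = [c for c in self.matrix.values.columns if c not in self.control_ids]
        return CNMatrix(self.matrix.values[frag_cols], self.matrix.populations)

    def population_summary(self) -> pd.DataFrame:
        return summarize_population(self.fragment_matrix)

    def control_validation(self) -> pd.DataFrame:
        return control_report(self.matrix, self.control_ids)


def process_individual(
    reference: Reference,
    truth: CohortTruth,
    config: SimConfig,
    index: int,
    exact_index: ExactIndex,
    windows_template: Windows,
    keep_windows: bool = False,
    _sites: np.ndarray | None = None,
) -> IndividualResult:
    """Simulate one individual's reads and estimate its copy numbers."""
    ind, pop = truth.individuals[index]
    genome = individual_genome(reference, truth, ind, config, _sites=_sites)
    reads = simulate_reads(genome, config, individual_index=index, individual=ind)
    placements = exact_index.place(reads.codes)
    depth = depth_mod.depth_from_placements(placements, len(reference))

    windows = Windows(
        chrom=windows_template.chrom,
        table=windows_template.table[["chrom", "start", "end", "gc"]].copy(),
        members=windows_template.members,
    )
    windows.add_depth(depth)
    model = depth_mod.fit_gc_model(windows)
    depth_mod.gc_correct(windows, model)
    calibration = depth_mod.calibrate(windows, reference.control_intervals)
    depth_mod.estimate_cn(windows, calibration)

    coords = dict(reference.fragments)
    coords.update({label: (s, e) for label, s, e in reference.controls})
    frag_cn = fragment_cn(windows, coords)

    in_controls = depth_mod.windows_in_intervals(windows, reference.control_intervals)
    control_window_mean = float(windows.table.loc[in_controls, "cn"].mean())

    return IndividualResult(
        individual=ind,
        population=pop,
        windows=windows if keep_windows else None,
        fragment_cn=frag_cn,
        control_window_mean=control_window_mean,
        n_reads=reads.n_reads,
        n_unplaced=placements.n_unplaced,
    )


def run_cohort(config: SimConfig, keep_windows: bool = False) -> CohortResult:
    """Run the full simulated-cohort copy-number study for one config."""
    reference = build_reference(config)
    truth = draw_truth(reference, config)
    exact_index = ExactIndex(reference.chrom, reference.codes, config.read_length)
    windows_template = tile_windows(reference.codes, reference.mask, reference.chrom)
    sites = _insertion_sites(reference)

    results = [
        process_individual(
            reference, truth, config, i, exact_index, windows_template,
            keep_windows=keep_windows, _sites=sites,
        )
        for i in range(len(truth.individuals))
    ]

    values = pd.DataFrame({r.individual: r.fragment_cn for r in results}).T
    values.index.name = "individual"
    pops = pd.Series({r.individual: r.population for r in results}, name="population")
    control_ids = [label for label, _, _ in reference.controls]
    return CohortResult(
        config=config,
        reference=reference,
        truth=truth,
        matrix=CNMatrix(values, pops),
        control_ids=control_ids,
        control_window_means=pd.Series(
            {r.individual: r.control_window_mean for r in results}, name="control_window_mean"
        ),
        individuals=results,
    )


def write_cohort_outputs(result: CohortResult, outdir: str | Path) -> None:
    """Persist the CN matrix, population summary and control validation."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.matrix.write_tsv(out / "cn_matrix.tsv")
    result.population_summary().to_csv(out / "fragment_summary.tsv", sep="\t", index=False)
    result.control_validation().to_csv(out / "control_validation.tsv", sep="\t", index=False)
    result.truth.write_tsv(out / "truth.tsv")
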