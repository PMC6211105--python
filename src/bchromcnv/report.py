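"""Scalar genome-level computations and the consolidated run report.

Covers the flow-cytometry genome-size arithmetic (standard-ratio scaling
and the 1 pg = 0.978e9 bp conversion), SNV and gene densities per kb,
density ratios, the pooled-variance two-sample Student t-test for DNA
content comparisons, and assembly of a single deterministic report from
all upstream outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: bp per pg of DNA
PG_TO_BP = 0.978e9


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """DNA content derived from a fluorescence ratio against a standard.

    All values are 2C (diploid) quantities; ``size_pg = standard_size_pg *
    sample_intensity / standard_intensity`` and ``size_bp = size_pg *
    0.978e9`` rounded to the nearest base pair.
    """

    sample_intensity: float
    standard_intensity: float
    standard_size_pg: float
    size_pg: float
    size_bp: int


def genome_size(
    sample_intensity: float, standard_intensity: float, standard_size_pg: float
) -> GenomeSizeEstimate:
    for name, v in (
        ("sample_intensity", sample_intensity),
        ("standard_intensity", standard_intensity),
        ("standard_size_pg", standard_size_pg),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    size_pg = standard_size_pg * sample_intensity / standard_intensity
    return GenomeSizeEstimate(
        sample_intensity=sample_intensity,
        standard_intensity=standard_intensity,
        standard_size_pg=standard_size_pg,
        size_pg=size_pg,
        size_bp=int(round(size_pg * PG_TO_BP)),
    )


def snv_density(n_snvs: int, length_bp: float) -> float:
    """Variants per kb of sequence."""
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if n_snvs < 0:
        raise ValueError("n_snvs must be >= 0")
    return n_snvs / (length_bp / 1000.0)


class DensityRatio(NamedTuple):
    ratio: float
    nearest_int: int


def density_ratio(density_a: float, density_b: float) -> DensityRatio:
    """Fold difference between two per-kb densities, with its nearest integer."""
    if density_b <= 0:
        raise ValueError("density_b must be > 0")
    r = density_a / density_b
    return DensityRatio(ratio=r, nearest_int=int(round(r)))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided pooled-variance Student t-test on per-individual DNA
    contents (inputs in bp; means/sd reported in Mb)."""

    n_a: int
    n_b: int
    mean_a_mb: float
    sd_a_mb: float
    mean_b_mb: float
    sd_b_mb: float
    t: float
    p: float


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a_mb=float(a.mean() / 1e6),
        sd_a_mb=float(a.std(ddof=1) / 1e6),
        mean_b_mb=float(b.mean() / 1e6),
        sd_b_mb=float(b.std(ddof=1) / 1e6),
        t=float(t),
        p=float(p),
    )


def read_flow_cytometry_csv(path: str | Path) -> pd.DataFrame:
    """Flow-cytometry measurements: sample_id, group, intensity,
    standard_intensity, standard_pg."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "intensity", "standard_intensity", "standard_pg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flow-cytometry CSV missing columns: {sorted(missing)}")
    return df


@dataclass
class DensityReport:
    snv_density_per_kb: float = 0.0
    gene_density_a: float = 0.0
    gene_density_b: float = 0.0
    density_ratio: float = 0.0
    density_ratio_nearest_int: int = 0
    repeat_fraction_b: float = 0.0
    repeat_fraction_genome: float = 0.0
    b_fraction_of_genome: float = 0.0
    notes: list[str] | None = None


def build_report(
    density: DensityReport | None = None,
    genome_sizes: dict[str, GenomeSizeEstimate] | None = None,
    group_comparison: GroupComparison | None = None,
    cn_summary: pd.DataFrame | None = None,
    control_validation: pd.DataFrame | None = None,
    scaffold_stats: pd.DataFrame | None = None,
) -> dict:
    """Assemble all upstream outputs into one JSON-serializable report with
    a deterministic field order."""
    report: dict = {}
    if density is not None:
        report["density"] = asdict(density)
    if genome_sizes:
        report["genome_sizes"] = {k: asdict(v) for k, v in sorted(genome_sizes.items())}
    if group_comparison is not None:
        report["group_comparison"] = asdict(group_comparison)
    if cn_summary is not None:
        report["cn_summary"] = cn_summary.to_dict(orient="records")
    if control_validation is not None:
        report["control_validation"] = {
            "cn_min": control_validation.attrs.get("cn_min"),
            "cn_max": control_validation.attrs.get("cn_max"),
            "all_pass": control_validation.attrs.get("all_pass"),
            "n_checks": int(len(control_validation)),
        }
    if scaffold_stats is not None:
        report["pseudo_scaffolds"] = scaffold_stats.to_dict(orient="records")
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    flat = []
    for section, payload in report.items():
        if isinstance(payload, dict):
            for k, v in payload.items():
                flat.append({"section": section, "key": k, "value": v})
        else:
            flat.append({"section": section, "key": "", "value": payload})
    pd.DataFrame(flat).to_csv(out / "report.tsv", sep="\t", index=False)
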