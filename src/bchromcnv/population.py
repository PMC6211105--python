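"""Population-scale copy-number analysis.

Window copy numbers are classified into the discrete bands used for
genome-wide CN histograms, aggregated into fragment-level copy numbers per
individual (the individuals x fragments CN matrix), and summarized per
population as min/max/range/mean — the representation behind per-fragment
population profiles where diploid controls sit in the 1.5-3 band.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .depth import Windows, windows_in_intervals


class ValidationError(ValueError):
    pass


class CNCategory(str, Enum):
    """Copy-number bands on the continuous diploid-CN axis.

    The printed one-decimal bands (0.1-1.4 / 1.5-2.5 / 2.6-4 / >4) become
    continuous half-open intervals; values below 0.1 are "absent" and more
    than one extra diploid copy beyond the heterozygous-duplication band
    (cn > 6) counts as multiple duplication.
    """

    ABSENT = "absent"  # [0, 0.1)
    HOMOZYGOUS_DELETION = "homozygous_deletion"  # [0.1, 1.5)
    HETEROZYGOUS_DELETION = "heterozygous_deletion"  # [1.5, 2.6)
    NORMAL_DIPLOID = "normal_diploid"  # [2.6, 4.0]
    HETEROZYGOUS_DUPLICATION = "heterozygous_duplication"  # (4.0, 6.0]
    MULTIPLE_DUPLICATION = "multiple_duplication"  # (6.0, inf)


def classify(cn: float) -> CNCategory:
    """Map a non-negative copy number to its unique band."""
    if cn < 0 or not np.isfinite(cn):
        raise ValueError(f"copy number must be a finite non-negative value, got {cn}")
    if cn < 0.1:
        return CNCategory.ABSENT
    if cn < 1.5:
        return CNCategory.HOMOZYGOUS_DELETION
    if cn < 2.6:
        return CNCategory.HETEROZYGOUS_DELETION
    if cn <= 4.0:
        return CNCategory.NORMAL_DIPLOID
    if cn <= 6.0:
        return CNCategory.HETEROZYGOUS_DUPLICATION
    return CNCategory.MULTIPLE_DUPLICATION


# the band in which diploid control regions are expected to fall
NORMAL_CONTROL_BAND = (1.5, 3.0)


@dataclass
class CNMatrix:
    """Individuals x fragments copy-number table with population labels."""

    values: pd.DataFrame  # index: individual, columns: fragment_id
    populations: pd.Series  # individual -> population label

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.populations.index)
        if missing:
            raise ValidationError(f"individuals without population label: {sorted(missing)}")

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "population", self.populations.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="individual", float_format="%.4g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CNMatrix":
        df = pd.read_csv(path, sep="\t", index_col="individual")
        pops = df.pop("population")
        return cls(values=df, populations=pops)


def fragment_cn(
    windows: Windows, fragment_coords: dict[str, tuple[int, int]]
) -> pd.Series:
    """Fragment-level CN: unweighted mean of window cn over windows fully
    inside the fragment; fragments containing no complete window are NaN
    (missing), never zero."""
    cn = windows.table["cn"].to_numpy()
    out = {}
    for frag, (s, e) in sorted(fragment_coords.items()):
        inside = windows_in_intervals(windows, [(s, e)])
        out[frag] = float(cn[inside].mean()) if inside.any() else np.nan
    return pd.Series(out, name="cn")


def fragment_window_counts(
    windows: Windows, fragment_coords: dict[str, tuple[int, int]]
) -> pd.Series:
    """Number of complete windows fully inside each fragment."""
    return pd.Series(
        {
            frag: int(windows_in_intervals(windows, [(s, e)]).sum())
            for frag, (s, e) in sorted(fragment_coords.items())
        }
    )


def summarize_population(matrix: CNMatrix) -> pd.DataFrame:
    """Per fragment per population: min, max, range, mean of fragment CN,
    plus variability flags.

    ``is_variable``: some individual in the population falls outside the
    normal control band [1.5, 3]. ``is_multiplied``: some individual
    exceeds 3 copies.
    """
    lo, hi = NORMAL_CONTROL_BAND
    rows = []
    for pop, group in matrix.values.groupby(matrix.populations):
        for frag in matrix.values.columns:
            vals = group[frag].dropna().to_numpy()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "fragment_id": frag,
                    "population": pop,
                    "n": vals.size,
                    "cn_min": vals.min(),
                    "cn_max": vals.max(),
                    "cn_range": vals.max() - vals.min(),
                    "cn_mean": vals.mean(),
                    "is_variable": bool(((vals < lo) | (vals > hi)).any()),
                    "is_multiplied": bool((vals > hi).any()),
                }
            )
    return pd.DataFrame(rows).sort_values(["fragment_id", "population"]).reset_index(drop=True)


def control_report(matrix: CNMatrix, control_ids: list[str]) -> pd.DataFrame:
    """Per-control, per-individual CN validation table.

    The ``pass`` column flags values inside the normal diploid band
    [1.5, 3]; the table's attrs carry the global min/max and the overall
    pass flag.
    """
    if not control_ids:
        raise ValidationError("no control fragment ids supplied")
    missing = [c for c in control_ids if c not in matrix.values.columns]
    if missing:
        raise ValidationError(f"controls absent from matrix: {missing}")
    lo, hi = NORMAL_CONTROL_BAND
    long = (
        matrix.values[control_ids]
        .reset_index(names="individual")
        .melt(id_vars="individual", var_name="control_id", value_name="cn")
    )
    long["population"] = matrix.populations.reindex(long["individual"]).to_numpy()
    long["pass"] = (long["cn"] >= lo) & (long["cn"] <= hi)
    long = long[["individual", "population", "control_id", "cn", "pass"]]
    long.attrs["cn_min"] = float(long["cn"].min())
    long.attrs["cn_max"] = float(long["cn"].max())
    long.attrs["all_pass"] = bool(long["pass"].all())
    return long
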