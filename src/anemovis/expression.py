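"""Opsin gene expression proportions from per-individual transcript counts.

Expression is reported three ways, matching how retinal transcriptome
studies partition it:

* rod (RH1) vs total cone expression,
* each cone gene as a fraction of total cone expression, and
* single-cone genes (SWS1, SWS2B) and double-cone genes (RH2B, RH2A, LWS)
  normalized separately — the partition established by in-situ labelling,
  which shows SWS opsins confined to single cones and RH2/LWS to doubles.

Counts are assumed already length-normalized per transcript; a helper
divides raw counts by transcript length first when needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROD_GENE = "RH1"
SINGLE_CONE_GENES = ("SWS1", "SWS2B")
DOUBLE_CONE_GENES = ("RH2B", "RH2A", "LWS")
CONE_GENES = SINGLE_CONE_GENES + DOUBLE_CONE_GENES
ALL_GENES = (ROD_GENE,) + CONE_GENES

STAGES = ("female", "male", "immature")


class ExpressionError(ValueError):
    pass


@dataclass
class OpsinCounts:
    """Normalized opsin expression values for one individual."""

    individual: str
    stage: str
    size_cm: float
    counts: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(ALL_GENES)
        if unknown:
            raise ExpressionError(f"unknown opsin genes {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ExpressionError(f"{self.individual}: negative counts")
        if self.cone_total() <= 0:
            raise ExpressionError(f"{self.individual}: no cone opsin expression")

    def get(self, gene: str) -> float:
        return float(self.counts.get(gene, 0.0))

    def cone_total(self) -> float:
        return sum(self.get(g) for g in CONE_GENES)


def normalize_by_length(raw_counts: Mapping[str, float],
                        transcript_lengths: Mapping[str, float]) -> dict[str, float]:
    """Divide raw read counts by transcript length (per-kilobase rate)."""
    out = {}
    for gene, c in raw_counts.items():
        length = transcript_lengths.get(gene)
        if not length or length <= 0:
            raise ExpressionError(f"missing/invalid transcript length for {gene}")
        out[gene] = c / (length / 1000.0)
    return out


def rod_cone_split(c: OpsinCounts) -> tuple[float, float]:
    """(rod, cone) proportions of total opsin expression; sums to 1."""
    rod = c.get(ROD_GENE)
    total = rod + c.cone_total()
    if total <= 0:
        raise ExpressionError(f"{c.individual}: zero total expression")
    return rod / total, (total - rod) / total


def cone_proportions(c: OpsinCounts, mode: str = "all_cones") -> dict[str, float]:
    """Per-gene cone proportions.

    mode 'all_cones': each cone gene over total cone expression.
    mode 'single_double_split': SWS genes normalized within single cones,
    RH2/LWS within double cones (each subset sums to 1).
    """
    if mode == "all_cones":
        total = c.cone_total()
        return {g: c.get(g) / total for g in CONE_GENES}
    if mode == "single_double_split":
        singles = sum(c.get(g) for g in SINGLE_CONE_GENES)
        doubles = sum(c.get(g) for g in DOUBLE_CONE_GENES)
        if singles <= 0 or doubles <= 0:
            raise ExpressionError(
                f"{c.individual}: empty single- or double-cone gene set"
            )
        out = {g: c.get(g) / singles for g in SINGLE_CONE_GENES}
        out.update({g: c.get(g) / doubles for g in DOUBLE_CONE_GENES})
        return out
    raise ExpressionError(f"unknown mode {mode!r}")


def tidy_proportions(cohort: Sequence[OpsinCounts]) -> pd.DataFrame:
    """Long-format per-individual proportion table for all modes."""
    rows = []
    for c in cohort:
        rod, cone = rod_cone_split(c)
        rows.append((c.individual, c.stage, c.size_cm, "rod_cone", ROD_GENE, rod))
        rows.append((c.individual, c.stage, c.size_cm, "rod_cone", "cones", cone))
        for mode in ("all_cones", "single_double_split"):
            for g, p in cone_proportions(c, mode).items():
                rows.append((c.individual, c.stage, c.size_cm, mode, g, p))
    return pd.DataFrame(
        rows, columns=["individual", "stage", "size_cm", "mode", "gene", "proportion"]
    )


def cohort_summary(cohort: Sequence[OpsinCounts]) -> pd.DataFrame:
    """Mean and sample SD of per-individual proportions, per mode and gene."""
    if len(cohort) < 2:
        raise ExpressionError("cohort summary needs at least 2 individuals")
    tidy = tidy_proportions(cohort)
    out = (
        tidy.groupby(["mode", "gene"], sort=False)["proportion"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def read_counts(path: str | Path) -> list[OpsinCounts]:
    """Read a cohort CSV: individual, stage, size_cm, RH1, SWS1, ... columns."""
    df = pd.read_csv(path)
    required = {"individual", "stage", "size_cm"}
    if not required <= set(df.columns):
        raise ExpressionError(f"counts file must have columns {sorted(required)}")
    genes = [g for g in ALL_GENES if g in df.columns]
    return [
        OpsinCounts(
            str(row["individual"]), str(row["stage"]), float(row["size_cm"]),
            {g: float(row[g]) for g in genes},
        )
        for _, row in df.iterrows()
    ]


def write_counts(cohort: Sequence[OpsinCounts], path: str | Path) -> None:
    rows = [
        {"individual": c.individual, "stage": c.stage, "size_cm": c.size_cm,
         **{g: c.get(g) for g in ALL_GENES}}
        for c in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
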