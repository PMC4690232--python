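"""Summary tables (and optional demo plots) over an annotated call set.

Every reported number is a one-pass tabulation over the VCF records:
per-type totals (Number, Length, Min_length, Max_length), the mean
per-individual load with its spread, a log-spaced size-spectrum histogram,
and ancestral-state / mechanism proportions per size bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import VcfRecord

__all__ = ["SummaryTable", "variant_size", "summarize", "SIZE_BINS"]

#: log-spaced size bins echoing the demo-plot axes (1-10, 10-100, ... bp)
SIZE_BINS = [1, 10, 100, 1_000, 10_000, 100_000]


def variant_size(rec: VcfRecord) -> int:
    """Affected length in bp: 1 for SNPs, otherwise the longer allele minus
    the anchor base."""
    if rec.info.get("SVTYPE") == "SNP":
        return 1
    return max(len(rec.ref_allele), len(rec.alt_allele)) - 1


def _carries(fields: dict) -> bool:
    gt = fields.get("GT", "./.")
    return "1" in gt


def _size_bin(size: int) -> str:
    for lo, hi in zip(SIZE_BINS, SIZE_BINS[1:]):
        if lo <= size < hi:
            return f"{lo}-{hi}"
    return f">={SIZE_BINS[-1]}"


@dataclass
class SummaryTable:
    per_type: pd.DataFrame  # Number/Length/Min_length/Max_length/load per type
    size_histogram: pd.DataFrame  # counts per log-spaced size bin per type
    ancestral_proportions: pd.DataFrame  # state proportions per size bin
    mechanism_proportions: pd.DataFrame  # mechanism proportions per size bin


def summarize(records: Sequence[VcfRecord], samples: Sequence[str] | None = None) -> SummaryTable:
    """Tabulate an (annotated) call set; empty input yields empty tables."""
    if samples is None:
        samples = sorted({s for rec in records for s in rec.samples})
    rows = []
    for rec in records:
        rows.append(
            {
                "type": rec.info.get("SVTYPE", "NA"),
                "size": variant_size(rec),
                "bin": _size_bin(variant_size(rec)),
                "ancestral": rec.info.get("AA_STATE", "NA"),
                "mechanism": rec.info.get("MECHANISM", "NA"),
                "carriers": sum(
                    _carries(rec.samples.get(s, {})) for s in samples
                ),
            }
        )
    if not rows:
        empty = pd.DataFrame()
        return SummaryTable(empty, empty, empty, empty)
    table = pd.DataFrame(rows)

    per_sample_number: dict[str, dict[str, int]] = {}
    per_sample_length: dict[str, dict[str, int]] = {}
    for rec in records:
        vtype = rec.info.get("SVTYPE", "NA")
        number = per_sample_number.setdefault(vtype, {s: 0 for s in samples})
        length = per_sample_length.setdefault(vtype, {s: 0 for s in samples})
        size = variant_size(rec)
        for s in samples:
            if _carries(rec.samples.get(s, {})):
                number[s] += 1
                length[s] += size

    def agg(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "Number": len(group),
                "Length": int(group["size"].sum()),
                "Min_length": int(group["size"].min()),
                "Max_length": int(group["size"].max()),
            }
        )

    per_type = table.groupby("type").apply(agg, include_groups=False)
    for column in ("Individual_number_mean", "Individual_number_sd",
                   "Individual_length_mean", "Individual_length_sd"):
        per_type[column] = np.nan
    if samples:
        for vtype in per_type.index:
            numbers = np.array(
                [per_sample_number[vtype][s] for s in samples], dtype=float
            )
            lengths = np.array(
                [per_sample_length[vtype][s] for s in samples], dtype=float
            )
            per_type.loc[vtype, "Individual_number_mean"] = numbers.mean()
            per_type.loc[vtype, "Individual_number_sd"] = numbers.std(ddof=0)
            per_type.loc[vtype, "Individual_length_mean"] = lengths.mean()
            per_type.loc[vtype, "Individual_length_sd"] = lengths.std(ddof=0)

    histogram = (
        table.groupby(["bin", "type"]).size().rename("count").reset_index()
    )

    def proportions(column: str) -> pd.DataFrame:
        counts = table.groupby(["bin", column]).size().rename("count").reset_index()
        totals = counts.groupby("bin")["count"].transform("sum")
        counts["proportion"] = counts["count"] / totals
        return counts

    return SummaryTable(
        per_type=per_type,
        size_histogram=histogram,
        ancestral_proportions=proportions("ancestral"),
        mechanism_proportions=proportions("mechanism"),
    )


def plot_size_spectrum(summary: SummaryTable, path) -> None:
    """Optional demo plot of the size spectrum (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for vtype, group in summary.size_histogram.groupby("type"):
        ax.plot(group["bin"], group["count"], marker="o", label=str(vtype))
    ax.set_yscale("log")
    ax.set_xlabel("size bin (bp)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
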