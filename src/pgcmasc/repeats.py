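"""Repeat-family methylation coverage and rankings from CpG calls.

CpG methylation calls are assigned to RepeatMasker-style repeat intervals
(0-based half-open; a call joins every overlapping annotation, so families
with nested or overlapping copies each count it).  Family-level methylation
is the pooled-read fraction (total methylated reads / total reads), which
weights deeply covered CpGs more; per-locus fractions are available
separately for box/beeswarm-style summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "assign_cpgs",
    "family_stats",
    "coverage_ranking",
    "methylation_ranking",
    "locus_distributions",
    "windowed_methylation",
    "NON_REPEAT",
]

NON_REPEAT = "non-repeat"


def assign_cpgs(calls: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Assign each CpG call to every overlapping repeat annotation.

    Parameters
    ----------
    calls
        DataFrame with columns chrom, pos (0-based), meth, unmeth.
    annotations
        DataFrame with columns chrom, start, end (0-based half-open),
        family, rep_class (strand ignored: calls are destranded).

    Returns
    -------
    DataFrame with one row per (call, overlapping locus) pair — columns
    chrom, pos, meth, unmeth, family, rep_class, locus_id — plus one row
    per unassigned call with family ``"non-repeat"``.  A call at
    ``pos == start`` is inside; at ``pos == end`` it is outside.
    """
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(annotations.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (row.family, row.rep_class, f"{row.family}:{i}")
        )
    rows = []
    for call in calls.itertuples(index=False):
        tree = trees.get(call.chrom)
        hits = tree[call.pos] if tree is not None else set()
        if hits:
            for iv in hits:
                fam, cls, locus = iv.data
                rows.append((call.chrom, call.pos, call.meth, call.unmeth, fam, cls, locus))
        else:
            rows.append((call.chrom, call.pos, call.meth, call.unmeth, NON_REPEAT, NON_REPEAT, NON_REPEAT))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "meth", "unmeth", "family", "rep_class", "locus_id"]
    )


def family_stats(assigned: pd.DataFrame, include_non_repeat: bool = False) -> pd.DataFrame:
    """Per-family CpG coverage and pooled-read methylation.

    Columns: family, rep_class, n_cpg_interrogated, total_meth_reads,
    total_reads, weighted_meth.
    """
    df = assigned if include_non_repeat else assigned[assigned["family"] != NON_REPEAT]
    if df.empty:
        return pd.DataFrame(
            columns=[
                "family",
                "rep_class",
                "n_cpg_interrogated",
                "total_meth_reads",
                "total_reads",
                "weighted_meth",
            ]
        )
    df = df.assign(total=df["meth"] + df["unmeth"])
    out = (
        df.groupby(["family", "rep_class"], sort=True)
        .agg(
            n_cpg_interrogated=("pos", "size"),
            total_meth_reads=("meth", "sum"),
            total_reads=("total", "sum"),
        )
        .reset_index()
    )
    out["weighted_meth"] = out["total_meth_reads"] / out["total_reads"]
    return out


def coverage_ranking(assigned: pd.DataFrame, n: int = 35) -> pd.DataFrame:
    """Top-n families by number of interrogated CpGs (ties by family name)."""
    stats = family_stats(assigned)
    stats = stats.sort_values(
        ["n_cpg_interrogated", "family"], ascending=[False, True], kind="mergesort"
    ).head(n)
    stats = stats.reset_index(drop=True)
    stats.insert(0, "rank", np.arange(1, len(stats) + 1))
    return stats


def methylation_ranking(
    assigned: pd.DataFrame,
    n: int = 35,
    min_cpg: int = 50,
    direction: str = "most",
) -> pd.DataFrame:
    """Top-n most (or least) methylated families among those with at least
    ``min_cpg`` interrogated CpGs; ties by family name.

    The returned table carries the class tag of every family so class
    compositions (how many LINE-1 / IAP / B1-B4 in the top 35) can be read
    off directly.
    """
    if direction not in ("most", "least"):
        raise ValueError("direction must be 'most' or 'least'")
    stats = family_stats(assigned)
    stats = stats[stats["n_cpg_interrogated"] >= min_cpg]
    if stats.empty:
        logger.warning("no family passes min_cpg=%d; empty ranking", min_cpg)
        return stats.assign(rank=pd.Series(dtype=int))
    ascending = direction == "least"
    stats = stats.sort_values(
        ["weighted_meth", "family"], ascending=[ascending, True], kind="mergesort"
    ).head(n)
    stats = stats.reset_index(drop=True)
    stats.insert(0, "rank", np.arange(1, len(stats) + 1))
    return stats


def class_composition(ranking: pd.DataFrame) -> pd.Series:
    """Counts of repeat classes within a ranking table."""
    return ranking["rep_class"].value_counts()


def locus_distributions(assigned: pd.DataFrame, family: str) -> tuple[pd.Series, dict]:
    """Read-weighted methylation fraction per annotated locus of a family.

    Returns the per-locus fractions (indexed by locus id) and a summary
    dict with quartiles and the number of loci excluded for zero coverage
    (loci absent from the assignment, i.e. without any covered CpG, never
    appear in ``assigned`` and are reported only via the caller's
    annotation count when provided).
    """
    sub = assigned[assigned["family"] == family]
    if sub.empty:
        raise KeyError(f"family {family!r} absent from assignment")
    g = sub.groupby("locus_id")
    meth = g["meth"].sum()
    total = meth + g["unmeth"].sum()
    frac = (meth / total).rename("locus_meth")
    q = np.percentile(frac, [25, 50, 75])
    summary = {
        "family": family,
        "n_loci_covered": int(frac.size),
        "q25": float(q[0]),
        "median": float(q[1]),
        "q75": float(q[2]),
    }
    return frac, summary


def windowed_methylation(
    calls: pd.DataFrame, window: int, min_calls: int = 1
) -> pd.DataFrame:
    """Pooled-read methylation in fixed tiling windows per chromosome.

    Windows with fewer than ``min_calls`` covered CpGs get NaN.  Returns a
    DataFrame with chrom, window start/end, n_calls, weighted_meth.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    df = calls.copy()
    df["win"] = (df["pos"] // window).astype(int)
    g = df.groupby(["chrom", "win"])
    out = g.agg(n_calls=("pos", "size"), meth=("meth", "sum"), unmeth=("unmeth", "sum")).reset_index()
    out["start"] = out["win"] * window
    out["end"] = out["start"] + window
    out["weighted_meth"] = out["meth"] / (out["meth"] + out["unmeth"])
    out.loc[out["n_calls"] < min_calls, "weighted_meth"] = np.nan
    return out[["chrom", "start", "end", "n_calls", "weighted_meth"]]
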