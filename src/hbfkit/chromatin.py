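"""Locus-specific chromatin interaction quantification.

Two assays are handled:

* CAPTURE (biotinylated dCas9 affinity purification of a chosen bait
  locus): interaction calls carry a BF significance score; only calls
  with BF >= 20 enter quantitative analysis, and each surviving target's
  read-pair count is normalized to a relative interaction frequency (RIF)
  per kilobase,

      rif_t = count_t * 1e6 / (bait_size_bp * sum of filtered counts)

  which makes the per-bait profile sum to 1e6 / bait_size_bp and
  invariant to sequencing depth.

* 3C qPCR: each ligation product's frequency is normalized to a control
  interaction in the TUBA1A gene within the same replicate
  (efficiency ** (Ct_control - Ct_ligation)), then summarized as
  mean +/- SEM across biological replicates.

Filtering precedes normalization: the filtered total defines "all
interactions from the bait region".
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .globin import DEFAULT_EFFICIENCY, _check_efficiency

__all__ = [
    "MIN_BF_SCORE",
    "filter_significant",
    "bait_size",
    "relative_interaction_frequency",
    "threec_relative",
    "compare_conditions",
]

#: BF-score significance cutoff; records at exactly 20 are kept.
MIN_BF_SCORE = 20.0

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "count", "bf_score",
]


def filter_significant(records: pd.DataFrame, min_bf: float = MIN_BF_SCORE) -> pd.DataFrame:
    """Keep interaction calls with bf_score >= min_bf (inclusive)."""
    if "bf_score" not in records.columns:
        raise KeyError("records lack a bf_score column")
    return records.loc[records["bf_score"] >= min_bf].reset_index(drop=True)


def bait_size(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by the union of bait anchor windows.

    A multiplexed bait (several sgRNA anchors) is measured as the union
    interval of its anchors, so overlapping windows are not double
    counted.
    """
    if not intervals:
        raise ValueError("no bait intervals given")
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if end <= start:
            raise ValueError(f"malformed interval ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return sum(e - s for s, e in merged)


def relative_interaction_frequency(
    records: pd.DataFrame,
    bait_size_bp: int,
    min_bf: float | None = MIN_BF_SCORE,
) -> pd.DataFrame:
    """Per-target RIF for one bait: count * 1e6 / (bait size * total count).

    Records are BF-filtered first (pass ``min_bf=None`` to skip); the
    filtered total is the denominator, so the profile sums to
    1e6 / bait_size_bp regardless of depth.
    """
    if bait_size_bp <= 0:
        raise ValueError("bait_size_bp must be > 0")
    work = records if min_bf is None else filter_significant(records, min_bf)
    if (work["count"] < 0).any():
        raise ValueError("negative interaction counts")
    total = float(work["count"].sum())
    if total == 0:
        raise ValueError("no interactions from the bait after filtering")
    out = work.copy()
    out["rif"] = out["count"].to_numpy(float) * 1e6 / (bait_size_bp * total)
    return out


def threec_relative(
    measurements: pd.DataFrame,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """TUBA1A-normalized 3C interaction per fragment, mean +/- SEM.

    ``measurements`` holds one row per (fragment, replicate) with
    ligation-product and TUBA1A-control Cts; each replicate's relative
    frequency is efficiency**(ct_control - ct_ligation), summarized
    across biological replicates (SEM = sd / sqrt(r); missing for a
    single replicate).
    """
    _check_efficiency(efficiency)
    required = {"fragment", "replicate", "ct_ligation", "ct_control"}
    missing = required - set(measurements.columns)
    if missing:
        raise KeyError(f"3C table is missing columns: {sorted(missing)}")
    if measurements.empty:
        raise ValueError("no 3C measurements supplied")
    if measurements[["ct_ligation", "ct_control"]].isna().any().any():
        raise ValueError("each replicate needs both ligation and control Cts")

    work = measurements.copy()
    work["rel"] = efficiency ** (
        work["ct_control"].to_numpy(float) - work["ct_ligation"].to_numpy(float)
    )
    rows = []
    for fragment, grp in work.groupby("fragment", sort=False):
        vals = grp["rel"].to_numpy(float)
        r = len(vals)
        rows.append(
            {
                "fragment": fragment,
                "n_replicates": r,
                "mean_rel": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / math.sqrt(r)) if r > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def _target_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom2"].astype(str) + ":" +
        df["start2"].astype(int).astype(str) + "-" +
        df["end2"].astype(int).astype(str)
    )


def compare_conditions(
    rif_a: pd.DataFrame,
    rif_b: pd.DataFrame,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Pair two normalized RIF profiles target-by-target.

    Both conditions must cover the same target intervals (exact interval
    match); the output reports each condition's rif, their difference
    (B - A) and ratio (B / A, inf where A is 0 and B is not).
    """
    a = rif_a.copy()
    b = rif_b.copy()
    a["target"] = _target_key(a)
    b["target"] = _target_key(b)
    only_a = sorted(set(a["target"]) - set(b["target"]))
    only_b = sorted(set(b["target"]) - set(a["target"]))
    if only_a or only_b:
        raise ValueError(
            f"target sets differ: only in {labels[0]}: {only_a}; "
            f"only in {labels[1]}: {only_b}"
        )
    la, lb = labels
    merged = a[["target", "rif"]].merge(
        b[["target", "rif"]], on="target", suffixes=(f"_{la}", f"_{lb}")
    )
    ra = merged[f"rif_{la}"].to_numpy(float)
    rb = merged[f"rif_{lb}"].to_numpy(float)
    merged["difference"] = rb - ra
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ra > 0, rb / ra, np.where(rb == 0, np.nan, np.inf))
    merged["ratio"] = ratio
    return merged
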