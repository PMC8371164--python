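"""Per-colony globin mRNA quantification from qPCR and Sanger peak ratios.

HBG1/2 and HBB transcript levels are expressed relative to the HBA1/2
endogenous control by the delta-Ct method, assuming a configurable
amplification efficiency (default 2.0, i.e. perfect doubling per cycle):

    relative expression = efficiency ** (Ct_reference - Ct_target)

The gamma-globin fraction of total beta-like mRNA, 100 * HBG/(HBG+HBB),
is the response modeled downstream; HBG1 vs HBG2 is apportioned from the
G:A nucleotide peak heights at the paralog-discriminating position of the
Sanger chromatogram.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression",
    "beta_like_fraction",
    "split_hbg",
    "quantify_plate",
]

DEFAULT_EFFICIENCY = 2.0


def _check_efficiency(efficiency: float) -> None:
    if not (1.0 < efficiency <= 2.2):
        raise ValueError(f"amplification efficiency {efficiency} outside (1, 2.2]")


def relative_expression(
    ct_target: float, ct_ref: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Delta-Ct relative expression, efficiency**(ct_ref - ct_target).

    Non-finite Cts propagate to NaN (failed wells stay missing instead of
    raising).  The ratio depends only on the Ct difference, so plate-wide
    shifts cancel.
    """
    _check_efficiency(efficiency)
    if ct_target is None or ct_ref is None:
        return math.nan
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        return math.nan
    if ct_target <= 0 or ct_ref <= 0:
        raise ValueError("Ct values must be positive")
    return float(efficiency ** (ct_ref - ct_target))


def beta_like_fraction(hbg_rel: float, hbb_rel: float):
    """(HBG %, HBB %) of total beta-like globin mRNA; the pair sums to 100.

    Undefined (NaN, NaN) when both inputs are zero or missing.
    """
    if hbg_rel is None or hbb_rel is None:
        return math.nan, math.nan
    if not (math.isfinite(hbg_rel) and math.isfinite(hbb_rel)):
        return math.nan, math.nan
    if hbg_rel < 0 or hbb_rel < 0:
        raise ValueError("relative expression must be >= 0")
    total = hbg_rel + hbb_rel
    if total == 0:
        return math.nan, math.nan
    hbg_pct = 100.0 * hbg_rel / total
    return hbg_pct, 100.0 - hbg_pct


def split_hbg(hbg_rel: float, g_peak: float, a_peak: float):
    """Apportion pooled HBG1/2 expression by the G:A chromatogram peaks.

    HBG1 carries the G allele and HBG2 the A allele at the discriminating
    position; the split conserves the pooled total exactly.
    """
    if g_peak < 0 or a_peak < 0:
        raise ValueError("peak heights must be >= 0")
    total = g_peak + a_peak
    if total == 0 or not math.isfinite(total):
        return math.nan, math.nan
    hbg1 = hbg_rel * g_peak / total
    return hbg1, hbg_rel - hbg1


def quantify_plate(
    plate: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    efficiency: float = DEFAULT_EFFICIENCY,
    targets: tuple[str, str, str] = ("HBG1_2", "HBB", "HBA1_2"),
) -> pd.DataFrame:
    """Quantify a whole qPCR plate into per-colony expression measures.

    ``plate`` holds one row per well (sample_id, target, ct); technical
    replicate wells of the same sample/target are averaged before the
    delta-Ct computation, and a sample missing the reference target is
    reported as all-missing.  ``peaks`` optionally supplies per-sample
    g_peak/a_peak columns for the HBG1:HBG2 split.
    """
    _check_efficiency(efficiency)
    required = {"sample_id", "target", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise KeyError(f"plate table is missing columns: {sorted(missing)}")
    hbg_t, hbb_t, ref_t = targets

    mean_ct = (
        plate.dropna(subset=["ct"])
        .groupby(["sample_id", "target"], sort=False)["ct"]
        .mean()
    )
    peak_map = (
        peaks.set_index("sample_id")[["g_peak", "a_peak"]]
        if peaks is not None else None
    )

    rows = []
    for sample in plate["sample_id"].drop_duplicates():
        def ct_of(target):
            try:
                return float(mean_ct.loc[(sample, target)])
            except KeyError:
                return math.nan

        hbg_rel = relative_expression(ct_of(hbg_t), ct_of(ref_t), efficiency)
        hbb_rel = relative_expression(ct_of(hbb_t), ct_of(ref_t), efficiency)
        hbg_pct, hbb_pct = beta_like_fraction(hbg_rel, hbb_rel)
        row = {
            "colony_id": sample,
            "hbg_rel": hbg_rel, "hbb_rel": hbb_rel,
            "hbg_fraction": hbg_pct, "hbb_fraction": hbb_pct,
            "hbg1_rel": math.nan, "hbg2_rel": math.nan,
        }
        if peak_map is not None and sample in peak_map.index:
            g, a = peak_map.loc[sample, "g_peak"], peak_map.loc[sample, "a_peak"]
            if np.isfinite(hbg_rel):
                row["hbg1_rel"], row["hbg2_rel"] = split_hbg(hbg_rel, g, a)
        rows.append(row)
    return pd.DataFrame(rows)
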