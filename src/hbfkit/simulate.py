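"""Synthetic erythroid-colony data with the structure the analysis assumes.

The generator emulates single BFU-E colonies picked after CRISPR editing of
human HSPCs: per-allele editing outcomes at the HBG1/HBG2 proximal-promoter
13 bp element, BCL11A exon 2 / exon 4, ZBTB7A, and paired-guide structural
variants across the adult beta-globin genes (HBB-HBD, HBD-3.5kb and the
combined HBB-3.5kb deletions); globin mRNA fractions generated from dosage
fixed effects, pairwise interactions, donor and gRNA-condition random
intercepts and residual noise; qPCR Ct plates that invert the delta-Ct
formula exactly; and CAPTURE-style interaction-record tables for two
conditions.

Alleles are edited independently (no zygosity coupling), and HBG1/HBG2
promoter edits are phenotypically exchangeable, matching the pooled 0-4
promoter dosage used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import (
    BCL11A_E2_CUT,
    BCL11A_E4_CUT,
    HBG_WINDOW,
    ZBTB7A_CUT,
    PROMOTER_LOCI,
    STRUCTURAL_ELEMENTS,
)

__all__ = [
    "SimConfig",
    "PhenotypeModel",
    "Condition",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_interaction_records",
    "simulate_dataset",
    "DEFAULT_PHENOTYPE",
    "DEFAULT_CONDITIONS",
]

# cut site of the promoter guide, inside the 13 bp element (amplicon coords)
_HBG_CUT = (HBG_WINDOW[0] + HBG_WINDOW[1]) // 2

_CODING_CUTS = {
    "BCL11A_e2": BCL11A_E2_CUT,
    "BCL11A_e4": BCL11A_E4_CUT,
    "ZBTB7A": ZBTB7A_CUT,
}


@dataclass(frozen=True)
class Condition:
    """One nucleofection condition: the gRNA set delivered to a donor pool."""

    guide_set_id: str
    #: loci carrying a single guide ("HBG_prom" targets all four promoter
    #: alleles; "BCL11A_e2", "BCL11A_e4", "ZBTB7A", "AAVS1")
    single_guides: tuple[str, ...] = ()
    #: paired-guide structural elements ("hbb_hbd", "hbd_3p5kb", "hbb_3p5kb")
    paired_guides: tuple[str, ...] = ()


@dataclass
class SimConfig:
    """Ground-truth editing process for the colony simulator.

    Each allele at a targeted locus is edited independently with
    ``per_guide_edit_prob``; edited alleles draw a signed indel length
    from ``indel_spectrum``.  At loci flanked by paired guides an allele
    becomes a deletion with ``paired_deletion_prob``, an inversion with
    ``paired_inversion_prob``, else stays intact.  A small fraction of
    promoter-guide colonies acquires a whole HBG1-to-HBB region deletion
    and is flagged for exclusion.
    """

    donors: int = 3
    colonies_per_condition: int = 40
    conditions: list[Condition] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    per_guide_edit_prob: float = 0.7
    indel_spectrum: dict[int, float] = field(
        default_factory=lambda: {-13: 0.45, -7: 0.1, -2: 0.1, -1: 0.2, 1: 0.15}
    )
    paired_deletion_prob: float = 0.45
    paired_inversion_prob: float = 0.1
    hbg_region_sv_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.per_guide_edit_prob,
            self.paired_deletion_prob,
            self.paired_inversion_prob,
            self.hbg_region_sv_prob,
            *self.indel_spectrum.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        total = sum(self.indel_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel_spectrum probabilities sum to {total}, not 1")
        if self.paired_deletion_prob + self.paired_inversion_prob > 1.0 + 1e-12:
            raise ValueError("paired deletion + inversion probability exceeds 1")
        if self.donors < 1 or self.colonies_per_condition < 1:
            raise ValueError("donors and colonies_per_condition must be >= 1")


#: study-like condition panel: control, promoter series, BCL11A series,
#: ZBTB7A, the three paired deletions and combined perturbations.
DEFAULT_CONDITIONS = (
    Condition("AAVS1", single_guides=("AAVS1",)),
    Condition("HBG_prom", single_guides=("HBG_prom",)),
    Condition("HBG_BCL11A", single_guides=("HBG_prom", "BCL11A_e2", "BCL11A_e4")),
    Condition("ZBTB7A", single_guides=("ZBTB7A",)),
    Condition("BCL11A_ZBTB7A", single_guides=("BCL11A_e2", "ZBTB7A")),
    Condition("HBB35_BCL11A", single_guides=("BCL11A_e2", "BCL11A_e4"),
              paired_guides=("hbb_3p5kb",)),
    Condition("HBB35_ZBTB7A", single_guides=("ZBTB7A",),
              paired_guides=("hbb_3p5kb",)),
    Condition("HBB_HBD", paired_guides=("hbb_hbd",)),
    Condition("HBD_3p5kb", paired_guides=("hbd_3p5kb",)),
    Condition("HBB_HBD__HBD_3p5kb", paired_guides=("hbb_hbd", "hbd_3p5kb")),
    Condition("HBB_3p5kb", paired_guides=("hbb_3p5kb",)),
)

#: dosage columns the genotype table always carries
DOSAGE_COLUMNS = (
    "hbg_dosage", "bcl11a_series", "bcl11a_e2_dosage", "zbtb7a_dosage",
    "hbb_hbd", "hbd_3p5kb", "hbb_3p5kb",
)


@dataclass
class PhenotypeModel:
    """Genotype-to-expression architecture on the beta-like fraction scale.

    The HBG1/2 fraction of beta-like mRNA for colony i in donor d under
    guide condition g is

        f_i = baseline + sum_v beta_v d_iv + sum_(v,w) beta_vw d_iv d_iw
              + u_d + u_g + e_i

    with u_d ~ N(0, donor_sd^2), u_g ~ N(0, guide_sd^2) (control condition
    fixed at zero) and e_i ~ N(0, residual_sd^2); on the identity scale
    fractions are clipped to [0, 1].  ``response_scale="log"`` applies the
    same linear predictor to log(fraction).
    """

    baseline_hbg_fraction: float = 0.20
    main_effects: dict[str, float] = field(
        default_factory=lambda: {
            "hbg_dosage": 0.10,
            "bcl11a_series": 0.12,
            "zbtb7a_dosage": 0.15,
            "hbb_hbd": 0.10,
            "hbd_3p5kb": 0.05,
            "hbb_3p5kb": 0.16,
        }
    )
    interaction_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("hbb_hbd", "hbd_3p5kb"): 0.04,
            ("hbg_dosage", "bcl11a_series"): -0.03,
        }
    )
    donor_sd: float = 0.03
    guide_sd: float = 0.03
    residual_sd: float = 0.08
    response_scale: str = "identity"
    #: total beta-like mRNA relative to the HBA1/2 control, used when
    #: synthesizing qPCR plates
    total_beta_like_rel: float = 1.5

    def validate(self) -> None:
        if not (0.0 < self.baseline_hbg_fraction < 1.0):
            raise ValueError("baseline_hbg_fraction must lie in (0, 1)")
        for name in ("donor_sd", "guide_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.response_scale not in ("identity", "log"):
            raise ValueError(f"unknown response_scale {self.response_scale!r}")


DEFAULT_PHENOTYPE = PhenotypeModel()


def _edit_allele(rng, cfg, locus, cut, records, colony_id, disrupt_window=None):
    """Sample one allele's outcome at a single-guide locus; return truth call."""
    if rng.random() >= cfg.per_guide_edit_prob:
        records.append((colony_id, locus, "WT", cut, cut, 0, 0))
        return False
    lengths = sorted(cfg.indel_spectrum)
    probs = [cfg.indel_spectrum[l] for l in lengths]
    length = int(rng.choice(lengths, p=probs))
    if length < 0:
        start, end = cut, cut - length  # deletion of |length| bases at the cut
        edited = -length
    else:
        start, end = cut, cut  # insertion point, zero-width interval
        edited = length
    records.append((colony_id, locus, "indel", start, end, edited, length))
    if disrupt_window is not None:
        ov = max(0, min(end, disrupt_window[1]) - max(start, disrupt_window[0]))
        if length > 0 and disrupt_window[0] <= start < disrupt_window[1]:
            ov = edited  # insertion inside the window
        return ov > 2
    return length % 3 != 0  # coding locus: frameshift iff net length not 0 mod 3


def simulate_genotypes(config: SimConfig):
    """Draw colony genotypes and per-allele edit records.

    Returns ``(truth, alleles, junctions)``: the ground-truth colony
    dosage table, the allele-level edit records the genotyping module
    re-calls, and the junction-qPCR presence table for paired-guide
    elements.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    truth_rows = []
    allele_rows: list[tuple] = []
    junction_rows = []
    cid = 0
    for cond in config.conditions:
        for _ in range(config.colonies_per_condition):
            cid += 1
            colony_id = f"C{cid:05d}"
            donor_id = f"D{int(rng.integers(config.donors)) + 1}"
            row = {
                "colony_id": colony_id,
                "donor_id": donor_id,
                "guide_set_id": cond.guide_set_id,
                **{c: 0 for c in DOSAGE_COLUMNS},
                "hbb_hbd_inv": False, "hbd_3p5kb_inv": False, "hbb_3p5kb_inv": False,
                "exclude_flag": False, "exclude_reason": "",
            }

            if "HBG_prom" in cond.single_guides:
                if rng.random() < config.hbg_region_sv_prob:
                    allele_rows.append(
                        (colony_id, "HBG_region", "deletion", 0, 0, 0, 0)
                    )
                    row["exclude_flag"] = True
                    row["exclude_reason"] = "hbg_region_sv"
                else:
                    n_disrupted = 0
                    for locus in PROMOTER_LOCI:          # 2x HBG1 + 2x HBG2
                        for _allele in range(2):
                            if _edit_allele(rng, config, locus, _HBG_CUT,
                                            allele_rows, colony_id,
                                            disrupt_window=HBG_WINDOW):
                                n_disrupted += 1
                    row["hbg_dosage"] = n_disrupted

            e2_fs = e4_fs = 0
            for locus in ("BCL11A_e2", "BCL11A_e4", "ZBTB7A", "AAVS1"):
                if locus not in cond.single_guides:
                    continue
                fs = sum(
                    _edit_allele(rng, config, locus, _CODING_CUTS.get(locus, 50),
                                 allele_rows, colony_id)
                    for _allele in range(2)
                )
                if locus == "BCL11A_e2":
                    e2_fs = fs
                elif locus == "BCL11A_e4":
                    e4_fs = fs
                elif locus == "ZBTB7A":
                    row["zbtb7a_dosage"] = fs
            row["bcl11a_e2_dosage"] = e2_fs
            # series: 0 WT, 1 het e2, 2 het e4, 3 biallelic at one exon;
            # het e2 + het e4 cannot be phased by amplicon sequencing
            if e2_fs == 2 or e4_fs == 2:
                row["bcl11a_series"] = 3
            elif e2_fs == 1 and e4_fs == 1:
                row["exclude_flag"] = True
                if not row["exclude_reason"]:
                    row["exclude_reason"] = "bcl11a_e2_e4_ambiguous"
            elif e4_fs == 1:
                row["bcl11a_series"] = 2
            elif e2_fs == 1:
                row["bcl11a_series"] = 1

            for element in STRUCTURAL_ELEMENTS:
                if element not in cond.paired_guides:
                    continue
                states = []
                for _allele in range(2):
                    u = rng.random()
                    if u < config.paired_deletion_prob:
                        states.append("DEL")
                    elif u < config.paired_deletion_prob + config.paired_inversion_prob:
                        states.append("INV")
                    else:
                        states.append("WT")
                n_del = states.count("DEL")
                row[element] = n_del
                row[f"{element}_inv"] = "INV" in states
                junction_rows.append(
                    {
                        "colony_id": colony_id,
                        "element": element,
                        # the inverted segment retains the internal amplicon
                        "internal_amplicon_present": n_del < 2,
                        "deletion_junction_present": n_del > 0,
                        "inversion_junction_present": "INV" in states,
                    }
                )

            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    alleles = pd.DataFrame(
        allele_rows,
        columns=["colony_id", "locus", "edit_type", "start", "end",
                 "edited_bases", "indel_length"],
    )
    junctions = pd.DataFrame(
        junction_rows,
        columns=["colony_id", "element", "internal_amplicon_present",
                 "deletion_junction_present", "inversion_junction_present"],
    )
    return truth, alleles, junctions


def simulate_expression(
    genotypes: pd.DataFrame,
    model: PhenotypeModel = DEFAULT_PHENOTYPE,
    seed: int = 0,
    reference_condition: str = "AAVS1",
    make_ct_plate: bool = False,
    efficiency: float = 2.0,
):
    """Realize globin expression from the genotype table.

    y = X beta + Z mu + eps with donor and guide-condition random
    intercepts; the HBB fraction is 1 minus the HBG fraction.  With
    ``make_ct_plate`` a qPCR Ct table is synthesized by exactly inverting
    the delta-Ct relative-expression formula, so quantification
    round-trips to the generated ratios.
    """
    model.validate()
    needed = set(model.main_effects) | {v for pair in model.interaction_effects for v in pair}
    missing = sorted(needed - set(genotypes.columns))
    if missing:
        raise KeyError(f"genotype table lacks dosage columns: {missing}")

    rng = np.random.default_rng(seed)
    donors = sorted(genotypes["donor_id"].unique())
    guides = sorted(genotypes["guide_set_id"].unique())
    donor_fx = {d: rng.normal(0.0, model.donor_sd) for d in donors}
    guide_fx = {
        g: (0.0 if g == reference_condition else rng.normal(0.0, model.guide_sd))
        for g in guides
    }

    eta = np.full(len(genotypes), model.baseline_hbg_fraction)
    for var, beta in model.main_effects.items():
        eta += beta * genotypes[var].to_numpy(float)
    for (a, b), beta in model.interaction_effects.items():
        eta += beta * genotypes[a].to_numpy(float) * genotypes[b].to_numpy(float)
    eta += genotypes["donor_id"].map(donor_fx).to_numpy(float)
    eta += genotypes["guide_set_id"].map(guide_fx).to_numpy(float)
    eta += rng.normal(0.0, model.residual_sd, size=len(genotypes))

    if model.response_scale == "identity":
        frac = np.clip(eta, 0.0, 1.0)
    else:
        frac = np.clip(np.exp(eta), 0.0, 1.0)

    hbg_rel = model.total_beta_like_rel * frac
    hbb_rel = model.total_beta_like_rel * (1.0 - frac)
    # HBG1:HBG2 split from symmetric G:A chromatogram peaks around 1:1
    g_share = np.clip(rng.beta(50, 50, size=len(genotypes)), 0.0, 1.0)

    expr = pd.DataFrame(
        {
            "colony_id": genotypes["colony_id"].to_numpy(),
            "hbg_fraction": 100.0 * frac,
            "hbb_fraction": 100.0 * (1.0 - frac),
            "hbg_rel": hbg_rel,
            "hbb_rel": hbb_rel,
            "hbg1_rel": hbg_rel * g_share,
            "hbg2_rel": hbg_rel * (1.0 - g_share),
            "g_peak": g_share,
            "a_peak": 1.0 - g_share,
        }
    )
    if not make_ct_plate:
        return expr

    # invert ratio = eff^(ct_ref - ct_target) around a fixed reference Ct
    ct_ref = 20.0
    rows = []
    for _, r in expr.iterrows():
        rows.append({"sample_id": r["colony_id"], "target": "HBA1_2", "ct": ct_ref})
        for target, rel in (("HBG1_2", r["hbg_rel"]), ("HBB", r["hbb_rel"])):
            if rel > 0:
                ct = ct_ref - np.log(rel) / np.log(efficiency)
                rows.append({"sample_id": r["colony_id"], "target": target,
                             "ct": float(ct)})
    plate = pd.DataFrame(rows, columns=["sample_id", "target", "ct"])
    return expr, plate


def simulate_interaction_records(
    profiles: dict[str, dict[tuple[str, int, int], float]],
    total_counts: int = 100_000,
    bait_intervals: dict[str, tuple[str, int, int]] | None = None,
    bf_below_20_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw CAPTURE-style interaction records for each condition.

    ``profiles`` maps condition name -> {target interval: expected count
    proportion}; counts are multinomial around the proportions and BF
    scores are drawn so that ``bf_below_20_fraction`` of records falls
    below the significance cutoff of 20.
    """
    rng = np.random.default_rng(seed)
    if not (0.0 <= bf_below_20_fraction <= 1.0):
        raise ValueError("bf_below_20_fraction must lie in [0, 1]")
    rows = []
    for condition, profile in profiles.items():
        targets = list(profile)
        props = np.array([profile[t] for t in targets], float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"target proportions for {condition!r} sum to {props.sum()}, not 1"
            )
        counts = rng.multinomial(total_counts, props)
        bait = (bait_intervals or {}).get(condition, ("chr11", 5_246_000, 5_248_000))
        for (chrom, start, end), count in zip(targets, counts):
            below = rng.random() < bf_below_20_fraction
            bf = float(rng.uniform(1.0, 19.5)) if below else float(rng.uniform(20.0, 200.0))
            rows.append(
                {
                    "bait_id": condition,
                    "chrom1": bait[0], "start1": bait[1], "end1": bait[2],
                    "chrom2": chrom, "start2": start, "end2": end,
                    "count": int(count), "bf_score": bf,
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimConfig,
    model: PhenotypeModel = DEFAULT_PHENOTYPE,
    make_ct_plate: bool = False,
):
    """Genotypes + expression in one call; seeds derived from config.seed."""
    truth, alleles, junctions = simulate_genotypes(config)
    expr = simulate_expression(
        truth, model, seed=config.seed + 1, make_ct_plate=make_ct_plate
    )
    if make_ct_plate:
        expr, plate = expr
        return truth, alleles, junctions, expr, plate
    return truth, alleles, junctions, expr
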