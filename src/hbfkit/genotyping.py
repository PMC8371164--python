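"""Allele-level edit calling and dosage coding of edited colonies.

Converts per-allele editing outcomes into the ordinal dosage variables
used by the interaction models:

* HBG1/HBG2 proximal promoter: an edit is *disruptive* when more than
  2 bp of it fall inside the 13 bp BCL11A-binding element; the four
  promoter alleles (two per homologous gene) are pooled into a single
  0-4 dosage.
* BCL11A: an allelic series 0-3 (0 wild type, 1 heterozygous exon-2
  frameshift, 2 heterozygous exon-4 frameshift — a dominant-negative,
  stronger-than-haploinsufficient perturbation — 3 biallelic frameshift),
  or a plain exon-2 frameshift count 0-2.
* ZBTB7A: frameshift allele count 0-2.
* Paired-guide structural variants (HBB-HBD, HBD-3.5kb, HBB-3.5kb
  deletions): deletion dosage 0-2 and an inversion flag, inferred from
  junction-qPCR presence/absence of the internal amplicon and of the
  deletion/inversion junctions.

Colonies whose genotype cannot be interpreted (internal amplicon lost
without a junction product, unphaseable heterozygous exon-2 plus exon-4
BCL11A edits, whole HBG1-to-HBB structural variants) are flagged for
exclusion with a reason rather than dropped silently.

All genomic coordinates are 0-based half-open on the unedited amplicon
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AlleleEdit",
    "JunctionQpcrResult",
    "HBG_WINDOW",
    "PROMOTER_LOCI",
    "STRUCTURAL_ELEMENTS",
    "call_promoter_disruption",
    "is_frameshift",
    "count_hbg_dosage",
    "code_bcl11a",
    "code_zbtb7a",
    "call_structural",
    "call_edits_from_amplicons",
    "genotype_colonies",
]

#: 13 bp BCL11A-binding element (-101..-114 of the HBG1/2 promoters) in
#: the local coordinates of the genotyping amplicon, 0-based half-open.
HBG_WINDOW = (100, 113)

PROMOTER_LOCI = ("HBG1_prom", "HBG2_prom")
CODING_LOCI = ("BCL11A_e2", "BCL11A_e4", "ZBTB7A")
STRUCTURAL_ELEMENTS = ("hbb_hbd", "hbd_3p5kb", "hbb_3p5kb")

# guide cut sites within each coding amplicon (amplicon-local)
BCL11A_E2_CUT = 60
BCL11A_E4_CUT = 60
ZBTB7A_CUT = 60

#: threshold on the disruptive-base count inside the 13 bp element;
#: strictly more than this many edited bases calls the allele disrupted
DISRUPTIVE_BP_THRESHOLD = 2


@dataclass(frozen=True)
class AlleleEdit:
    """One allele's editing outcome at one locus.

    ``start``/``end`` delimit the edited reference interval (0-based
    half-open; zero-width at the insertion point for pure insertions);
    ``edited_bases`` counts inserted + deleted + substituted bases and
    ``indel_length`` is the signed net length change (0 for pure
    substitutions).
    """

    colony_id: str
    locus: str
    edit_type: str               # WT | indel | substitution | deletion | inversion
    start: int
    end: int
    edited_bases: int
    indel_length: int = 0

    def __post_init__(self):
        if self.edited_bases < 0:
            raise ValueError("edited_bases must be >= 0")
        if self.end < self.start:
            raise ValueError("malformed interval: end < start")
        if self.edit_type == "WT" and self.edited_bases != 0:
            raise ValueError("WT allele cannot carry edited bases")


@dataclass(frozen=True)
class JunctionQpcrResult:
    """Presence calls from the three junction-qPCR assays of one element."""

    colony_id: str
    element: str
    internal_amplicon_present: bool
    deletion_junction_present: bool
    inversion_junction_present: bool


def call_promoter_disruption(
    edit: AlleleEdit, window: tuple[int, int] = HBG_WINDOW
) -> bool:
    """True iff more than 2 bp of the edit fall inside the 13 bp element.

    Deletions and substitutions contribute the overlap of their edited
    interval with the window; an insertion contributes its full length
    when the insertion point lies inside the window.  The rule is
    monotone in overlap.
    """
    if edit.locus not in PROMOTER_LOCI:
        raise ValueError(f"{edit.locus!r} is not an HBG promoter locus")
    if edit.edit_type == "WT":
        return False
    if edit.indel_length > 0 and edit.start == edit.end:
        # pure insertion: counts iff the breakpoint is inside the window
        inside = window[0] <= edit.start < window[1]
        return inside and edit.edited_bases > DISRUPTIVE_BP_THRESHOLD
    overlap = max(0, min(edit.end, window[1]) - max(edit.start, window[0]))
    return overlap > DISRUPTIVE_BP_THRESHOLD


def is_frameshift(edit: AlleleEdit) -> bool:
    """Frameshift call for a coding-exon allele: net indel not 0 mod 3."""
    return edit.indel_length % 3 != 0


def count_hbg_dosage(calls: list[bool]) -> int:
    """Pooled HBG1/2 promoter dosage 0-4 from the four allele calls."""
    if len(calls) != 4:
        raise ValueError(f"expected 4 promoter allele calls, got {len(calls)}")
    return int(sum(bool(c) for c in calls))


def code_bcl11a(
    e2_frameshifts: list[bool],
    e4_frameshifts: list[bool],
    scheme: str = "allelic_series",
):
    """Code BCL11A edits, returning ``(code, exclude_reason)``.

    ``allelic_series``: 0 wild type; 1 heterozygous exon-2; 2 heterozygous
    exon-4; 3 biallelic frameshift at either exon.  A colony heterozygous
    at both exons cannot be phased from amplicon sequencing and is
    flagged ambiguous (code None).

    ``e2_dosage``: the exon-2 frameshift allele count 0-2.
    """
    e2 = sum(bool(c) for c in e2_frameshifts)
    e4 = sum(bool(c) for c in e4_frameshifts)
    if e2 > 2 or e4 > 2:
        raise ValueError("more than two alleles supplied for one exon")
    if scheme == "e2_dosage":
        return e2, None
    if scheme != "allelic_series":
        raise ValueError(f"unknown BCL11A coding scheme {scheme!r}")
    if e2 == 2 or e4 == 2:
        return 3, None
    if e2 == 1 and e4 == 1:
        return None, "bcl11a_e2_e4_ambiguous"
    if e4 == 1:
        return 2, None
    if e2 == 1:
        return 1, None
    return 0, None


def code_zbtb7a(frameshifts: list[bool]) -> int:
    """ZBTB7A frameshift dosage 0-2 from the two allele calls."""
    if len(frameshifts) != 2:
        raise ValueError(f"expected 2 allele calls, got {len(frameshifts)}")
    return int(sum(bool(c) for c in frameshifts))


def call_structural(result: JunctionQpcrResult):
    """Zygosity of a paired-guide deletion from junction qPCR.

    Returns ``(deletion_dosage, inversion_flag, exclude_reason)``.
    The internal amplicon lies inside the deletable segment and still
    amplifies from an inverted allele, so: internal present without a
    deletion junction means 0 deleted alleles; internal present with a
    deletion junction means 1; internal absent with a deletion junction
    means 2; internal absent without any junction product is
    uninterpretable and excluded.
    """
    internal = result.internal_amplicon_present
    del_j = result.deletion_junction_present
    inv_j = result.inversion_junction_present
    if not internal and not del_j:
        return None, inv_j, f"structural_uninterpretable:{result.element}"
    if internal:
        dosage = 1 if del_j else 0
    else:
        dosage = 2
    return dosage, inv_j, None


def call_edits_from_amplicons(reference: str, allele_seq: str):
    """Derive edited interval and base counts by global alignment.

    Aligns one colony allele's amplicon (Sanger-derived consensus)
    against the unedited reference and reports the edited reference
    interval, the count of inserted + deleted + substituted bases, and
    the signed net indel length.  Intended for small Cas9 indels around a
    single cut site, not read-level variant calling.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-1,
    )
    aln = aligner.align(reference.upper(), allele_seq.upper())[0]
    ref_aln, qry_aln = str(aln[0]), str(aln[1])
    pos = 0  # reference coordinate
    start = end = None
    edited = 0
    for r, q in zip(ref_aln, qry_aln):
        changed = (r != q)
        if changed:
            edited += 1
            at = pos if r != "-" else pos  # insertions anchor at current ref pos
            if start is None:
                start = at
            end = at + (1 if r != "-" else 0)
        if r != "-":
            pos += 1
    net = len(allele_seq) - len(reference)
    if start is None:
        return 0, 0, 0, 0
    return start, max(end, start), edited, net


def _structural_defaults() -> dict:
    out: dict = {}
    for element in STRUCTURAL_ELEMENTS:
        out[element] = 0
        out[f"{element}_inv"] = False
    return out


def genotype_colonies(
    alleles: pd.DataFrame,
    junctions: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    bcl11a_scheme: str = "allelic_series",
) -> pd.DataFrame:
    """Call and dosage-code every colony from allele records + junction qPCR.

    ``alleles`` holds one row per sequenced allele (columns colony_id,
    locus, edit_type, start, end, edited_bases, indel_length);
    ``junctions`` the junction-qPCR presence table for paired-guide
    elements; ``metadata`` optionally supplies donor_id / guide_set_id
    per colony.  Returns one row per colony with all dosage columns and
    exclusion flags.
    """
    colony_ids: list[str] = []
    seen = set()
    for cid in list(alleles["colony_id"]) + (
        list(junctions["colony_id"]) if junctions is not None else []
    ):
        if cid not in seen:
            seen.add(cid)
            colony_ids.append(cid)

    allele_groups = {cid: g for cid, g in alleles.groupby("colony_id", sort=False)}
    junction_groups = (
        {cid: g for cid, g in junctions.groupby("colony_id", sort=False)}
        if junctions is not None else {}
    )

    rows = []
    for cid in colony_ids:
        row = {
            "colony_id": cid, "hbg_dosage": 0, "bcl11a_series": 0,
            "bcl11a_e2_dosage": 0, "zbtb7a_dosage": 0,
            **_structural_defaults(),
            "exclude_flag": False, "exclude_reason": "",
        }

        def exclude(reason: str) -> None:
            row["exclude_flag"] = True
            if not row["exclude_reason"]:
                row["exclude_reason"] = reason

        grp = allele_groups.get(cid)
        if grp is not None:
            edits = [
                AlleleEdit(
                    colony_id=str(r.colony_id), locus=str(r.locus),
                    edit_type=str(r.edit_type), start=int(r.start),
                    end=int(r.end), edited_bases=int(r.edited_bases),
                    indel_length=int(getattr(r, "indel_length", 0)),
                )
                for r in grp.itertuples(index=False)
            ]
            if any(e.locus == "HBG_region" for e in edits):
                exclude("hbg_region_sv")
            promoter = [e for e in edits if e.locus in PROMOTER_LOCI]
            if promoter:
                if len(promoter) != 4:
                    exclude("promoter_allele_count")
                else:
                    calls = [call_promoter_disruption(e) for e in promoter]
                    row["hbg_dosage"] = count_hbg_dosage(calls)
            e2 = [is_frameshift(e) for e in edits if e.locus == "BCL11A_e2"]
            e4 = [is_frameshift(e) for e in edits if e.locus == "BCL11A_e4"]
            if e2 or e4:
                code, reason = code_bcl11a(e2, e4, scheme=bcl11a_scheme)
                if reason is not None:
                    exclude(reason)
                elif bcl11a_scheme == "allelic_series":
                    row["bcl11a_series"] = code
                row["bcl11a_e2_dosage"] = sum(e2)
            zb = [is_frameshift(e) for e in edits if e.locus == "ZBTB7A"]
            if zb:
                row["zbtb7a_dosage"] = code_zbtb7a(zb)

        jgrp = junction_groups.get(cid)
        if jgrp is not None:
            for r in jgrp.itertuples(index=False):
                res = JunctionQpcrResult(
                    colony_id=str(r.colony_id), element=str(r.element),
                    internal_amplicon_present=bool(r.internal_amplicon_present),
                    deletion_junction_present=bool(r.deletion_junction_present),
                    inversion_junction_present=bool(r.inversion_junction_present),
                )
                dosage, inv, reason = call_structural(res)
                if reason is not None:
                    exclude(reason)
                else:
                    row[res.element] = dosage
                row[f"{res.element}_inv"] = inv

        rows.append(row)

    out = pd.DataFrame(rows)
    if metadata is not None:
        keep = [c for c in ("colony_id", "donor_id", "guide_set_id") if c in metadata.columns]
        out = out.merge(metadata[keep], on="colony_id", how="left")
        front = ["colony_id"] + [c for c in ("donor_id", "guide_set_id") if c in out.columns]
        out = out[front + [c for c in out.columns if c not in front]]
    return out
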