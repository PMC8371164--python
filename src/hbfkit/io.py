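"""Readers and writers for the pipeline's tabular and sequence formats.

Conventions: UTF-8 throughout; tab-separated tables for genomic records
(colony genotypes, allele records, BED, BEDPE-like interaction calls),
comma-separated tables for plate data; all genomic coordinates 0-based
half-open (1-based closed inputs must be converted upstream).  Malformed
rows are rejected with the offending line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "read_bed",
    "read_bedpe",
    "write_bedpe",
    "write_fasta",
    "read_fasta",
    "write_json_report",
    "COLONY_SCHEMA",
    "ALLELE_SCHEMA",
    "PLATE_SCHEMA",
    "JUNCTION_SCHEMA",
    "THREEC_SCHEMA",
]


class SchemaError(ValueError):
    """A table failed validation; message names columns/lines at fault."""


COLONY_SCHEMA = {
    "required": ["colony_id", "hbg_dosage", "bcl11a_series", "zbtb7a_dosage",
                 "hbb_hbd", "hbd_3p5kb", "hbb_3p5kb", "exclude_flag"],
    "sep": "\t",
}
ALLELE_SCHEMA = {
    "required": ["colony_id", "locus", "edit_type", "start", "end",
                 "edited_bases", "indel_length"],
    "sep": "\t",
}
PLATE_SCHEMA = {"required": ["sample_id", "target", "ct"], "sep": ","}
JUNCTION_SCHEMA = {
    "required": ["colony_id", "element", "internal_amplicon_present",
                 "deletion_junction_present", "inversion_junction_present"],
    "sep": ",",
}
THREEC_SCHEMA = {
    "required": ["fragment", "replicate", "ct_ligation", "ct_control"],
    "sep": ",",
}


def read_table(path: str | Path, schema: dict) -> pd.DataFrame:
    """Read a delimited table and validate its required columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=schema["sep"])
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ reader (0-based half-open) with per-line validation."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise SchemaError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


_BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "count", "bf_score"]


def read_bedpe(path: str | Path, bait_column: bool = True) -> pd.DataFrame:
    """BEDPE-like interaction records: two intervals + count + BF score.

    An optional leading ``bait_id`` column is accepted; counts must be
    non-negative integers and intervals well formed.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_bait = header[0] == "bait_id"
        expect = (["bait_id"] if has_bait else []) + _BEDPE_COLS
        if header != expect:
            raise SchemaError(f"{path}:1: expected columns {expect}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(expect):
                raise SchemaError(f"{path}:{lineno}: wrong field count")
            rec = dict(zip(expect, parts))
            try:
                for k in ("start1", "end1", "start2", "end2", "count"):
                    rec[k] = int(rec[k])
                rec["bf_score"] = float(rec["bf_score"])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric field") from exc
            if rec["count"] < 0:
                raise SchemaError(f"{path}:{lineno}: negative count")
            for s, e in (("start1", "end1"), ("start2", "end2")):
                if rec[s] < 0 or rec[e] <= rec[s]:
                    raise SchemaError(
                        f"{path}:{lineno}: invalid interval [{rec[s]}, {rec[e]})"
                    )
            rows.append(rec)
    cols = (["bait_id"] if has_bait else []) + _BEDPE_COLS
    return pd.DataFrame(rows, columns=cols)


def write_bedpe(df: pd.DataFrame, path: str | Path) -> Path:
    cols = (["bait_id"] if "bait_id" in df.columns else []) + _BEDPE_COLS
    return write_table(df[cols], path, sep="\t")


def write_fasta(records: dict[str, str], path: str | Path) -> Path:
    """Write amplicon allele sequences (id -> sequence) as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json_report(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
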