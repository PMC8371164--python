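"""End-to-end orchestration: simulate -> genotype -> quantify -> model.

A single YAML config drives the run; each stage writes its outputs and a
log line, colony exclusions are enumerated with reasons, and the whole
run is reproducible from the config plus its seed (the run log records
the config hash and package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotyping import genotype_colonies
from .globin import quantify_plate
from .lmm import GroupSpec, ModelSpec, build_design, fit_reml
from .simulate import (
    DEFAULT_PHENOTYPE,
    PhenotypeModel,
    SimConfig,
    simulate_expression,
    simulate_genotypes,
    simulate_interaction_records,
)
from . import io as hio
from .chromatin import bait_size, compare_conditions, relative_interaction_frequency

logger = logging.getLogger("hbfkit")

__all__ = ["PipelineConfig", "MODEL_PRESETS", "model_spec", "run_pipeline", "demo_config"]

#: the three fitted model variants: (1) the two partial deletions and
#: their interaction; (2) promoter edits, BCL11A series and the combined
#: deletion; (3) ZBTB7A, BCL11A and the combined deletion.
MODEL_PRESETS: dict[str, dict] = {
    "dd_interaction": {
        "fixed_terms": ["hbb_hbd", "hbd_3p5kb"],
        "interaction_pairs": [("hbb_hbd", "hbd_3p5kb")],
    },
    "bcl11a_hbg": {
        "fixed_terms": ["hbg_dosage", "bcl11a_series", "hbb_3p5kb"],
        "interaction_pairs": [
            ("hbg_dosage", "bcl11a_series"),
            ("hbb_3p5kb", "bcl11a_series"),
        ],
    },
    "bcl11a_zbtb7a": {
        "fixed_terms": ["hbb_3p5kb", "zbtb7a_dosage", "bcl11a_series"],
        "interaction_pairs": [
            ("hbb_3p5kb", "zbtb7a_dosage"),
            ("bcl11a_series", "zbtb7a_dosage"),
        ],
    },
}


def model_spec(
    preset: str,
    response: str = "hbg_fraction",
    transform: str = "identity",
    reference_condition: str = "AAVS1",
) -> ModelSpec:
    """Build the ModelSpec for a named preset model."""
    if preset not in MODEL_PRESETS:
        raise KeyError(
            f"unknown model preset {preset!r}; choose from {sorted(MODEL_PRESETS)}"
        )
    cfg = MODEL_PRESETS[preset]
    return ModelSpec(
        response=response,
        fixed_terms=list(cfg["fixed_terms"]),
        interaction_pairs=list(cfg["interaction_pairs"]),
        random_groups=[
            GroupSpec("donor_id"),
            GroupSpec("guide_set_id", reference=reference_condition),
        ],
        transform=transform,
    )


@dataclass
class PipelineConfig:
    outdir: str = "hbfkit_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    phenotype: PhenotypeModel = field(default_factory=lambda: DEFAULT_PHENOTYPE)
    models: list[str] = field(default_factory=lambda: list(MODEL_PRESETS))
    response: str = "hbg_fraction"
    transform: str = "identity"
    reference_condition: str = "AAVS1"
    efficiency: float = 2.0
    min_bf: float = 20.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim_raw = dict(kwargs["sim"])
            if "indel_spectrum" in sim_raw:
                sim_raw["indel_spectrum"] = {
                    int(k): float(v) for k, v in sim_raw["indel_spectrum"].items()
                }
            if "conditions" in sim_raw:
                from .simulate import Condition

                sim_raw["conditions"] = [
                    Condition(
                        c["guide_set_id"],
                        single_guides=tuple(c.get("single_guides", ())),
                        paired_guides=tuple(c.get("paired_guides", ())),
                    )
                    for c in sim_raw["conditions"]
                ]
            kwargs["sim"] = SimConfig(**sim_raw)
        if "phenotype" in kwargs:
            ph = dict(kwargs["phenotype"])
            if "interaction_effects" in ph:
                ph["interaction_effects"] = {
                    tuple(k.split(":")): float(v)
                    for k, v in ph["interaction_effects"].items()
                }
            kwargs["phenotype"] = PhenotypeModel(**ph)
        if not isinstance(kwargs.get("seed", 0), int):
            raise ValueError("seed must be an integer")
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        payload = {
            k: repr(v) for k, v in vars(self).items() if k != "outdir"
        }
        digest = hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()
        return digest[:12]


def demo_config(outdir: str | Path = "hbfkit_demo", seed: int = 0) -> PipelineConfig:
    """Small bundled demonstration configuration (runs in seconds)."""
    return PipelineConfig(outdir=str(outdir), seed=seed,
                          sim=SimConfig(seed=seed, colonies_per_condition=30))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns a manifest of output paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "hbfkit %s | seed=%d | config %s", __version__, config.seed,
        config.config_hash(),
    )
    manifest: dict[str, str] = {}

    # --- stage 1: simulation -------------------------------------------
    try:
        config.sim.seed = config.seed
        truth, alleles, junctions = simulate_genotypes(config.sim)
        expr_truth, plate = simulate_expression(
            truth, config.phenotype, seed=config.seed + 1,
            make_ct_plate=True, efficiency=config.efficiency,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    hio.write_table(truth, out / "truth_genotypes.tsv")
    hio.write_table(alleles, out / "allele_records.tsv")
    hio.write_table(junctions, out / "junction_qpcr.csv", sep=",")
    hio.write_table(plate, out / "qpcr_plate.csv", sep=",")
    manifest["allele_records"] = str(out / "allele_records.tsv")
    logger.info("simulate: %d colonies, %d allele records", len(truth), len(alleles))

    # --- stage 2: genotyping -------------------------------------------
    try:
        genotypes = genotype_colonies(
            alleles, junctions,
            metadata=truth[["colony_id", "donor_id", "guide_set_id"]],
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'genotype' failed: {exc}") from exc
    excluded = genotypes.loc[genotypes["exclude_flag"]]
    for _, row in excluded.iterrows():
        logger.info("exclude %s: %s", row["colony_id"], row["exclude_reason"])
    hio.write_table(genotypes, out / "colony_genotypes.tsv")
    manifest["colony_genotypes"] = str(out / "colony_genotypes.tsv")
    logger.info("genotype: %d colonies, %d excluded", len(genotypes), len(excluded))

    # --- stage 3: quantification ---------------------------------------
    try:
        peaks = expr_truth[["colony_id", "g_peak", "a_peak"]].rename(
            columns={"colony_id": "sample_id"}
        )
        expression = quantify_plate(plate, peaks=peaks, efficiency=config.efficiency)
    except Exception as exc:
        raise RuntimeError(f"stage 'quantify' failed: {exc}") from exc
    hio.write_table(expression, out / "globin_expression.csv", sep=",")
    manifest["globin_expression"] = str(out / "globin_expression.csv")

    merged = genotypes.merge(expression, on="colony_id", how="inner")
    hio.write_table(merged, out / "colony_table.csv", sep=",")
    manifest["colony_table"] = str(out / "colony_table.csv")

    # --- stage 4: mixed models -----------------------------------------
    fit_reports = {}
    for preset in config.models:
        spec = model_spec(
            preset, response=config.response, transform=config.transform,
            reference_condition=config.reference_condition,
        )
        try:
            dm = build_design(merged, spec)
            fit = fit_reml(dm)
        except Exception as exc:
            raise RuntimeError(f"stage 'fit:{preset}' failed: {exc}") from exc
        fit_reports[preset] = fit.to_dict()
        logger.info(
            "fit %s: n=%d, reml_loglik=%.3f", preset, fit.n, fit.reml_loglik
        )
    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_colonies": int(len(merged)),
        "n_excluded": int(len(excluded)),
        "exclusions": excluded[["colony_id", "exclude_reason"]]
        .to_dict(orient="records"),
        "models": fit_reports,
    }
    hio.write_json_report(report, out / "fit_report.json")
    manifest["fit_report"] = str(out / "fit_report.json")

    # --- stage 5: chromatin demonstration ------------------------------
    try:
        targets = {
            ("chr11", 5_269_000, 5_271_000): 0.35,   # HBG1/2 promoters
            ("chr11", 5_290_000, 5_292_000): 0.40,   # LCR HS region
            ("chr11", 5_255_000, 5_257_000): 0.25,   # HBD upstream
        }
        shifted = {
            ("chr11", 5_269_000, 5_271_000): 0.50,
            ("chr11", 5_290_000, 5_292_000): 0.30,
            ("chr11", 5_255_000, 5_257_000): 0.20,
        }
        records = simulate_interaction_records(
            {"WT": targets, "KO": shifted}, seed=config.seed + 2,
            bf_below_20_fraction=0.0,
        )
        bait_bp = bait_size([(5_246_000, 5_248_000)])
        rif = {
            cond: relative_interaction_frequency(
                records[records["bait_id"] == cond], bait_bp, min_bf=config.min_bf
            )
            for cond in ("WT", "KO")
        }
        comparison = compare_conditions(rif["WT"], rif["KO"], labels=("WT", "KO"))
    except Exception as exc:
        raise RuntimeError(f"stage 'chromatin' failed: {exc}") from exc
    hio.write_bedpe(records, out / "interaction_records.tsv")
    hio.write_table(comparison, out / "rif_comparison.csv", sep=",")
    manifest["rif_comparison"] = str(out / "rif_comparison.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
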