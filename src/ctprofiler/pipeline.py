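"""End-to-end pipeline: QC -> detection -> imputation -> quantile
normalization -> PCA / overlap / bootstrap -> differential expression,
driven by one config, with a JSON run manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import bootstrap_overlap, overlap_regions, pca, profile_similarity
from .containers import CtMatrix, GroupDesign
from .diffexp import anova_dunnett, fit_moderated_t
from .io import (
    read_count_matrix,
    read_well_records,
    records_to_matrix,
    write_bootstrap,
    write_ct_matrix,
    write_de_table,
    write_overlap,
    write_well_records,
)
from .normalize import quantile_normalize, relative_expression
from .qc import QcThresholds, call_detection, filter_wells, impute_missing
from .rnaseq import filter_counts, log_cpm, merge_platforms, to_ct_scale
from .simulate import SimConfig, design_from_config, generate_plate

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``wells`` (path to a long-format well CSV) or
    ``simulate`` (a :class:`SimConfig` parameter dict) must be given.
    ``seed`` drives every stochastic stage.
    """

    outdir: str = "ctprofiler_run"
    wells: str | None = None
    simulate: dict | None = None
    groups: dict | None = None  # group -> [sample ids]; inferred for simulations
    control_group: str | None = None
    qc: dict = field(default_factory=dict)  # QcThresholds kwargs
    min_fraction: float = 2.0 / 3.0
    normalization: str = "quantile"
    contrasts: list = field(default_factory=list)  # [[group_a, group_b], ...]
    alpha: float = 0.05
    bootstrap_n_iter: int = 1000
    run_anova: bool = False
    harmonize: dict | None = None  # {"counts": path, "min_count": 10, ...}
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.wells is None) == (self.simulate is None):
            raise ValueError("exactly one of 'wells' or 'simulate' must be set")
        if self.normalization not in ("quantile", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full stage sequence and return the run manifest.

    Writes every intermediate artifact under ``config.outdir`` and a
    ``manifest.json`` recording parameters, per-stage record counts and
    artifact checksums. Reruns with an identical config and inputs
    produce identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "qc": dict(config.qc),
            "min_fraction": config.min_fraction,
            "normalization": config.normalization,
            "contrasts": [list(c) for c in config.contrasts],
            "alpha": config.alpha,
            "bootstrap_n_iter": config.bootstrap_n_iter,
            "seed": config.seed,
        },
        "stages": {},
        "artifacts": {},
        "inputs": {},
    }

    def _record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def _stage(name: str, **info) -> None:
        manifest["stages"][name] = {"status": "complete", **info}

    try:
        # ---- ingest -------------------------------------------------
        if config.simulate is not None:
            sim = SimConfig.from_dict({"seed": config.seed, **config.simulate})
            records, _truth = generate_plate(sim)
            design = design_from_config(sim, control_group=config.control_group)
            wells_path = outdir / "wells.csv"
            write_well_records(records, wells_path)
            manifest["inputs"]["simulate"] = sim.to_dict()
        else:
            wells_path = Path(config.wells)
            manifest["inputs"]["wells"] = {
                "path": str(wells_path),
                "sha256": _sha256(wells_path),
            }
            records = read_well_records(wells_path)
            if config.groups:
                design = GroupDesign(config.groups, control_group=config.control_group)
            else:
                members: dict[str, list[str]] = {}
                for r in records:
                    if r.sample_id not in members.setdefault(r.group, []):
                        members[r.group].append(r.sample_id)
                design = GroupDesign(members, control_group=config.control_group)
        _stage("ingest", n_records=len(records), n_groups=len(design.groups))

        # ---- qc filter ----------------------------------------------
        thresholds = QcThresholds(**config.qc)
        passing, drops = filter_wells(records, thresholds)
        filtered_path = outdir / "wells_filtered.csv"
        write_well_records(passing, filtered_path)
        _record("wells_filtered", filtered_path)
        _stage("qc_filter", n_pass=len(passing), n_drop=sum(drops.values()),
               drops=drops)

        # ---- detection + imputation ---------------------------------
        matrix = records_to_matrix(passing, design)
        detection = call_detection(matrix, design, min_fraction=config.min_fraction)
        det_path = outdir / "detection.csv"
        det_df = detection.detected.copy()
        det_df.index.name = "mirna_id"
        det_df.to_csv(det_path)
        _record("detection", det_path)
        imputed = impute_missing(matrix, detection, design)
        imputed_path = outdir / "ct_imputed.csv"
        write_ct_matrix(imputed, imputed_path)
        _record("ct_imputed", imputed_path)
        n_imputed = int(imputed.values.notna().sum().sum()
                        - matrix.values.notna().sum().sum())
        _stage("detect_impute",
               detected_per_group={g: detection.n_detected(g)
                                   for g in detection.groups},
               union=detection.union_size(), n_imputed=n_imputed)

        # ---- normalization ------------------------------------------
        if config.normalization == "quantile":
            normalized = quantile_normalize(imputed)
            prov = normalized.provenance
        else:
            normalized = imputed
            prov = {"method": "none"}
        norm_path = outdir / "ct_normalized.csv"
        write_ct_matrix(normalized, norm_path)
        _record("ct_normalized", norm_path)
        _stage("normalize", **{k: v for k, v in prov.items() if k != "raw_rows"})

        # ---- PCA + overlap + bootstrap ------------------------------
        scores, var_ratio = pca(normalized)
        pca_path = outdir / "pca_scores.csv"
        out_scores = scores.copy()
        out_scores.index.name = "sample_id"
        out_scores.to_csv(pca_path)
        _record("pca_scores", pca_path)
        overlap = overlap_regions(detection)
        overlap_path = outdir / "overlap.json"
        write_overlap(overlap, overlap_path)
        _record("overlap", overlap_path)
        boot = bootstrap_overlap(
            detection, n_iter=config.bootstrap_n_iter, seed=config.seed
        )
        boot_path = outdir / "bootstrap.json"
        write_bootstrap(boot, boot_path)
        _record("bootstrap", boot_path)
        relexpr = relative_expression(normalized, design, detection)
        relexpr_path = outdir / "relative_expression.csv"
        out_rel = relexpr.copy()
        out_rel.index.name = "mirna_id"
        out_rel.to_csv(relexpr_path)
        _record("relative_expression", relexpr_path)
        similarities = {}
        ref = design.control_group or design.groups[0]
        for g in design.groups:
            if g == ref:
                continue
            try:
                score = profile_similarity(relexpr[ref], relexpr[g])
                similarities[g] = {
                    "pearson_r": score.pearson_r,
                    "mse": score.mse,
                    "n_common": score.n_common,
                }
            except ValueError:
                similarities[g] = None
        _stage("compare",
               pca_variance_ratio=[float(v) for v in var_ratio],
               universe_size=overlap.universe_size,
               similarity_vs=ref,
               similarity=similarities)

        # ---- differential expression --------------------------------
        de_summaries = {}
        for a, b in config.contrasts:
            res = fit_moderated_t(normalized, design, (a, b))
            de_path = outdir / f"de_{a}_vs_{b}.csv"
            write_de_table(res, de_path)
            _record(f"de_{a}_vs_{b}", de_path)
            de_summaries[f"{a}_vs_{b}"] = {
                "n_tested": len(res.mirna_ids),
                "n_de": int((res.p_adjusted < config.alpha).sum()),
                "similarity_fraction": res.similarity_fraction(config.alpha),
                "prior_d0": float(res.prior.d0),
            }
        _stage("diffexp", contrasts=de_summaries)

        if config.run_anova and design.control_group:
            anova = anova_dunnett(normalized, design, design.control_group,
                                  seed=config.seed)
            anova_path = outdir / "anova_dunnett.csv"
            anova.to_frame().to_csv(anova_path)
            _record("anova_dunnett", anova_path)
            _stage("anova_dunnett", n_tested=len(anova.model.mirna_ids))

        # ---- cross-platform harmonization (optional) ----------------
        if config.harmonize:
            h = dict(config.harmonize)
            counts = read_count_matrix(h["counts"])
            kept = filter_counts(counts, min_count=h.get("min_count", 10))
            lcpm = log_cpm(kept, prior=h.get("prior", 2.0))
            seq_ct = to_ct_scale(
                lcpm,
                ct_low=h.get("ct_low", 10.0),
                ct_high=h.get("ct_high", 35.0),
                invert=h.get("invert", True),
            )
            merged = merge_platforms(normalized, seq_ct)
            merged_path = outdir / "harmonized.csv"
            hm = CtMatrix(merged.values, merged.sample_groups)
            write_ct_matrix(hm, merged_path)
            _record("harmonized", merged_path)
            log_path = outdir / "mapping_log.json"
            log_path.write_text(json.dumps(merged.mapping_log, indent=2) + "\n")
            _record("mapping_log", log_path)
            _stage("harmonize",
                   n_counts_in=len(counts.mirna_ids),
                   n_counts_kept=len(kept.mirna_ids),
                   n_common=merged.mapping_log["n_common"])
    except Exception as exc:
        failed = "unknown"
        order = ["ingest", "qc_filter", "detect_impute", "normalize",
                 "compare", "diffexp", "anova_dunnett", "harmonize"]
        for name in order:
            if name not in manifest["stages"]:
                failed = name
                break
        manifest["failed_stage"] = failed
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
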