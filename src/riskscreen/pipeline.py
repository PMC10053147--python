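"""End-to-end pipeline: simulate -> screen stats -> classification ->
enrichment -> enhancer mapping -> single-cell pair testing -> summary.

A run is driven by one nested config (YAML/JSON-serializable dict) with named
per-stage seeds; all artifacts are plain text under the output directory, and
``manifest.json`` records the tool version, a config hash and the sha256 of
every artifact, so a re-run with identical config is byte-identical.
Timestamps and narrative record counts go to ``run.log``, keeping the
manifest deterministic.

Externally computed gene-result or pair-result tables in the documented
schema can be supplied through the ``inputs`` block and flow through
classification / pair calling unchanged.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as rio
from .classify import (
    HitThresholds, assay_family_totals, call_screen_hits, classify_hits,
    flag_bidirectional_confounds, summarize_hits,
)
from .effects import EffectSpec, effects_for_class
from .enhancers import define_candidate_enhancers, intersect_peaks, tile_sgrnas
from .enrichment import driver_downgrade, enrichment_panel
from .library import LibraryConfig, SgRNALibrary, make_library, promoter_pairs
from .qtl import CellQCThresholds, CisWindow, call_pairs, pair_summary, qc_cells, test_all_pairs, tss_positive_control_check
from .screen_stats import qc_screen, score_all_screens
from .screens import ScreenDesign, simulate_screen_counts
from .singlecell import SingleCellSimConfig, simulate_single_cells
from .tracks import GenomeTrackConfig, simulate_genome_tracks


def default_run_config() -> dict:
    """Desk-scale default configuration for a fully simulated run.

    The library and screen layout are scaled down from the emulated study so
    a complete run finishes in about a minute; composition ratios, planted
    effect sizes, thresholds and QC rules keep their defaults.
    """
    return {
        "out_dir": "riskscreen_run",
        "seeds": {
            "library": 11, "screens": 12, "tracks": 13,
            "gene_score": 14, "single_cell": 15, "qtl": 16,
        },
        "simulation": {
            "library": {
                "n_genes_per_category": {"INQ_1": 30, "INQ_2": 60, "TWAS": 40, "background": 60},
                "sgrnas_per_gene": 5,
                "n_negative_controls": 300,
                "n_essential_genes": 20,
                "n_essential_sgrnas": 96,
                "n_known_driver_genes": 6,
                "tss_spacing": 20_000,
            },
            "planted": {
                "magnitude": 2.0,
                "per_category": {
                    "INQ_1": {"tumor_suppressor": 4, "oncogene": 3, "ddr": 2, "context_dependent": 1},
                    "INQ_2": {"tumor_suppressor": 2, "oncogene": 1, "ddr": 1},
                    "TWAS": {"tumor_suppressor": 1, "oncogene": 1},
                    "background": {"tumor_suppressor": 1},
                },
            },
            "design": {
                "cell_lines": ["B80-T5", "K5K19pos"],
                "modalities": ["ko", "i", "a"],
                "assays": ["2D", "3D", "in_vivo", "olaparib"],
            },
            "tracks": {"length": 5_000_000, "n_atac_peaks": 120, "n_h3k27ac_peaks": 120,
                       "n_ccvs": 60, "fraction_planted": 0.3},
            "single_cell": {
                "n_cells": 1500, "moi": 5.0, "mean_umis_per_cell": 4000.0,
                "n_nt_controls": 30, "n_tss_control_genes": 10,
                "n_planted_pairs": 3, "planted_change": -0.5,
            },
        },
        # the resampled-p floor is 2/(n_resample+1); 2500 keeps the BH-adjusted
        # floor below the -log10(FDR) > 1 threshold even when only a few
        # genes in a screen are truly significant
        "screen_stats": {"n_resample": 2500, "pseudocount": 0.5, "method": "negctrl_median"},
        "thresholds": {"lfc_magnitude_min": 1.0, "neg_log10_fdr_min": 1.0, "min_cell_lines": 1},
        "cell_qc": {"min_sgrna_umis_per_cell": 2, "min_reads_per_sgrna_umi": 3,
                    "max_mito_fraction": 0.2, "min_genes_detected": 100},
        "enrichment": {"comparison": "all_others", "downgrade_drivers": []},
        "qtl": {"n_perm": 500, "p_max": 0.1, "cis_halfwidth": 2_000_000, "min_perturbed": 10},
        "inputs": {},
    }


#: dict-valued fields that are compositions, not option groups: an override
#: replaces them wholesale instead of being merged key-by-key
_REPLACE_KEYS = {"per_category", "n_genes_per_category", "planted_effects", "inputs"}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if k not in _REPLACE_KEYS and isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_run_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Default config merged with a YAML file and/or an override dict."""
    config = default_run_config()
    if path is not None:
        import yaml

        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    return config


def plant_effects(library: SgRNALibrary, planted: dict, seed: int) -> list[EffectSpec]:
    """Choose planted genes per category and build their effect specs.

    Essential genes always carry the essential signature and driver positive
    controls alternate oncogene / tumor-suppressor signatures; candidate-
    category genes are drawn without replacement at the configured counts.
    """
    rng = np.random.default_rng(seed)
    magnitude = float(planted.get("magnitude", 2.0))
    specs: list[EffectSpec] = []
    for gene in library.genes_in_category("essential"):
        specs.append(effects_for_class(gene, "essential", magnitude))
    for i, gene in enumerate(library.genes_in_category("driver_control")):
        specs.append(effects_for_class(gene, "oncogene" if i % 2 == 0 else "tumor_suppressor", magnitude))
    for category, classes in planted.get("per_category", {}).items():
        pool = library.genes_in_category(category)
        need = sum(classes.values())
        chosen = list(rng.choice(pool, size=min(need, len(pool)), replace=False))
        it = iter(chosen)
        for cls, n in classes.items():
            for _ in range(n):
                gene = next(it, None)
                if gene is None:
                    break
                specs.append(effects_for_class(gene, cls, magnitude))
    return specs


def effects_table(specs: list[EffectSpec]) -> pd.DataFrame:
    rows = []
    for s in specs:
        for (modality, assay), lfc in sorted(s.effects.items()):
            rows.append({"gene_id": s.gene_id, "true_class": s.true_class,
                         "modality": modality, "assay": assay, "effect_lfc": lfc,
                         "context": s.context or ""})
        if not s.effects:
            rows.append({"gene_id": s.gene_id, "true_class": s.true_class,
                         "modality": "", "assay": "", "effect_lfc": 0.0, "context": ""})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    """Hash of the analysis-relevant config (output location excluded, so
    identical analyses in different directories share a hash)."""
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _require_input(inputs: dict, key: str, stage: str) -> Path | None:
    if key not in inputs:
        return None
    path = Path(inputs[key])
    if not path.exists():
        raise FileNotFoundError(f"stage {stage}: configured input {key!r} not found: {path}")
    return path


class StageError(RuntimeError):
    """Failure inside one named pipeline stage."""


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the run summary dict.

    Stages run in dependency order; an exception in any stage aborts the run
    with an error naming the stage. All artifacts land under
    ``config['out_dir']`` (overridable by the ``out_dir`` argument).
    """
    config = _merge(default_run_config(), config or {})
    if out_dir is not None:
        config["out_dir"] = str(out_dir)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = config["seeds"]
    inputs = config.get("inputs") or {}
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED ({exc})")
                    (out / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                log(f"stage {name}: done")

        return _Ctx()

    summary: dict = {}

    # ------------------------------------------------------------ simulate
    with stage("simulate"):
        sim = config["simulation"]
        lib_cfg = LibraryConfig(**{**sim["library"], "seed": seeds["library"]})
        library = make_library(lib_cfg)
        specs = plant_effects(library, sim.get("planted", {}), seeds["library"] + 1)
        design = ScreenDesign(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in sim["design"].items()}
        )
        counts = simulate_screen_counts(library, specs, design, seed=seeds["screens"])
        tracks = simulate_genome_tracks(
            GenomeTrackConfig(**{**sim["tracks"], "seed": seeds["tracks"]})
        )
        sim_dir = out / "simulate"
        rio.write_library(library, sim_dir)
        rio.write_counts(counts, sim_dir)
        rio.write_bed(tracks.atac, sim_dir / "atac.bed", extra_cols=["peak_id"])
        rio.write_bed(tracks.h3k27ac, sim_dir / "h3k27ac.bed", extra_cols=["peak_id"])
        rio.write_bed(tracks.ccvs, sim_dir / "ccvs.bed", extra_cols=["ccv_id"])
        effects_table(specs).to_csv(sim_dir / "effects_truth.tsv", sep="\t", index=False)
        log(f"simulated {library.n_sgrnas} sgRNAs x {len(counts.samples)} samples; "
            f"{len(tracks.atac)} ATAC peaks, {len(tracks.ccvs)} CCVs")

    # -------------------------------------------------------------- screen
    with stage("screen"):
        screen_dir = out / "screen"
        screen_dir.mkdir(exist_ok=True)
        gene_results_path = _require_input(inputs, "gene_results", "screen")
        if gene_results_path is not None:
            results = pd.read_csv(gene_results_path, sep="\t", keep_default_na=False)
            results = results.replace("", np.nan)
            for col in ("gene_lfc", "fdr"):
                results[col] = pd.to_numeric(results[col], errors="coerce")
            lfcs = {}
            log(f"loaded external gene results: {len(results)} rows")
        else:
            ss = config["screen_stats"]
            results, lfcs = score_all_screens(
                counts, library, n_resample=ss["n_resample"], seed=seeds["gene_score"],
                pseudocount=ss["pseudocount"], method=ss["method"],
            )
            log(f"scored {results['screen_id'].nunique()} screens, {len(results)} gene results")
        results.to_csv(screen_dir / "gene_results.tsv", sep="\t", index=False)
        qc_rows = []
        for screen_id, lfc in lfcs.items():
            sub = results[results["screen_id"] == screen_id]
            modality = sub["modality"].iloc[0] if len(sub) else ""
            rep = qc_screen(sub, library, modality, control_lfc=lfc)
            qc_rows.append({"screen_id": screen_id, "passed": rep.passed,
                            "essential_median_lfc": rep.essential_median_lfc,
                            "negctrl_median_lfc": rep.negctrl_median_lfc,
                            "messages": "; ".join(rep.messages)})
        pd.DataFrame(qc_rows).to_csv(screen_dir / "screen_qc.tsv", sep="\t", index=False)

    # ------------------------------------------------------------ classify
    with stage("classify"):
        thresholds = HitThresholds(**config["thresholds"])
        directions = call_screen_hits(results, thresholds)
        calls = classify_hits(directions, thresholds)
        calls = flag_bidirectional_confounds(calls, directions, promoter_pairs(library.genes))
        cls_dir = out / "classify"
        cls_dir.mkdir(exist_ok=True)
        directions.to_csv(cls_dir / "directions.tsv", sep="\t", index=False)
        call_rows = [
            {"gene_id": g, "calls": ",".join(sorted(c.calls)),
             "n_evidence": len(c.evidence), "n_supporting_only": len(c.supporting_only),
             "confound_flags": ",".join(c.confound_flags)}
            for g, c in sorted(calls.items()) if c.calls or c.supporting_only or c.confound_flags
        ]
        pd.DataFrame(call_rows, columns=["gene_id", "calls", "n_evidence",
                                         "n_supporting_only", "confound_flags"]).to_csv(
            cls_dir / "hit_calls.tsv", sep="\t", index=False)
        hit_table = summarize_hits(calls, library.genes)
        hit_table.to_csv(cls_dir / "hit_summary.tsv", sep="\t")
        family = assay_family_totals(calls)
        family.to_csv(cls_dir / "assay_family_totals.tsv", sep="\t")
        n_hits = int(sum(1 for c in calls.values() if c.calls))
        log(f"{n_hits} genes with >= 1 call")
        summary["hit_table"] = {str(k): {kk: int(vv) for kk, vv in v.items()}
                                for k, v in hit_table.to_dict(orient="index").items()}
        summary["assay_family_totals"] = {k: int(v) for k, v in family.items()}

    # -------------------------------------------------------------- enrich
    with stage("enrich"):
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        enr_cfg = config["enrichment"]
        annotation = library.genes
        panel = enrichment_panel(
            calls, annotation, cell_lines=tuple(design.cell_lines), comparison=enr_cfg["comparison"]
        )
        panel.to_csv(enr_dir / "enrichment.tsv", sep="\t", index=False)
        if enr_cfg.get("downgrade_drivers"):
            downgraded = driver_downgrade(annotation, enr_cfg["downgrade_drivers"])
            enrichment_panel(calls, downgraded, comparison=enr_cfg["comparison"]).to_csv(
                enr_dir / "enrichment_driver_downgraded.tsv", sep="\t", index=False)
        combined = panel[(panel["scope"] == "combined") & (panel["category"] == "INQ_1")]
        if len(combined):
            summary["inq1_fold_enrichment"] = (
                None if combined["fold_enrichment"].isna().all()
                else float(combined["fold_enrichment"].iloc[0])
            )
            summary["inq1_enrichment_p"] = (
                None if combined["p_value"].isna().all() else float(combined["p_value"].iloc[0])
            )

    # ----------------------------------------------------------- enhancers
    with stage("enhancers"):
        if inputs:
            atac_p = _require_input(inputs, "atac", "enhancers")
            k27_p = _require_input(inputs, "h3k27ac", "enhancers")
            if atac_p is not None and "ccv" not in inputs:
                raise FileNotFoundError("stage enhancers: 'ccv' input missing while 'atac' given")
            ccv_p = _require_input(inputs, "ccv", "enhancers")
        else:
            atac_p = k27_p = ccv_p = None
        atac = rio.read_bed(atac_p, ["peak_id"]) if atac_p else tracks.atac
        h3k27ac = rio.read_bed(k27_p, ["peak_id"]) if k27_p else tracks.h3k27ac
        ccvs = rio.read_bed(ccv_p, ["ccv_id"]) if ccv_p else tracks.ccvs
        marked = intersect_peaks(atac, h3k27ac)
        enhancers = define_candidate_enhancers(marked, ccvs)
        tiling = tile_sgrnas(enhancers)
        enh_dir = out / "enhancers"
        enh_dir.mkdir(exist_ok=True)
        rio.write_enhancers_bed(enhancers, enh_dir / "enhancers.bed")
        tiling.to_csv(enh_dir / "tiling.tsv", sep="\t", index=False)
        log(f"{len(marked)} marked peaks -> {len(enhancers)} candidate enhancers, "
            f"{len(tiling)} tiled positions")
        summary["n_candidate_enhancers"] = int(len(enhancers))
        summary["n_tiled_positions"] = int(len(tiling))

    # ------------------------------------------------------------------ qtl
    with stage("qtl"):
        qtl_dir = out / "qtl"
        qtl_dir.mkdir(exist_ok=True)
        sc_cfg = dict(config["simulation"]["single_cell"])
        n_pairs = int(sc_cfg.pop("n_planted_pairs", 0))
        change = float(sc_cfg.pop("planted_change", -0.5))

        # gene panel: library genes inside the simulated genomic region, so
        # screen hits and single-cell targets share a namespace
        track_len = int(config["simulation"]["tracks"]["length"])
        panel = library.genes.loc[library.genes["tss"] < track_len,
                                  ["gene_id", "contig", "tss"]].reset_index(drop=True)
        hit_genes = sorted(g for g, c in calls.items() if c.calls)
        planted_pairs: dict[str, tuple[str, float]] = {}
        window = CisWindow(halfwidth=int(config["qtl"]["cis_halfwidth"]))
        panel_tss = panel.set_index("gene_id")["tss"]
        used: set[str] = set()
        for _, enh in enhancers.iterrows():
            if len(planted_pairs) >= n_pairs:
                break
            mid = (int(enh["start"]) + int(enh["end"])) // 2
            near = [g for g in hit_genes
                    if g in panel_tss.index and g not in used
                    and abs(int(panel_tss[g]) - mid) <= window.halfwidth]
            if near:
                gene = min(near, key=lambda g: abs(int(panel_tss[g]) - mid))
                planted_pairs[enh["enhancer_id"]] = (gene, change)
                used.add(gene)
        sc_config = SingleCellSimConfig(
            **sc_cfg, planted_effects=planted_pairs, seed=seeds["single_cell"],
        )
        dataset = simulate_single_cells(enhancers, sc_config, tiling=tiling, genes=panel)
        rio.write_single_cell(dataset, qtl_dir / "single_cell")

        qc_thr = CellQCThresholds(**config["cell_qc"])
        filtered, qc_log = qc_cells(dataset, qc_thr)
        (qtl_dir / "cell_qc_log.json").write_text(json.dumps(qc_log, indent=2, sort_keys=True))
        log(f"cell QC: {qc_log['input_cells']} -> {qc_log['output_cells']} cells")

        pair_results_path = _require_input(inputs, "pair_results", "qtl")
        if pair_results_path is not None:
            pairs = pd.read_csv(pair_results_path, sep="\t", keep_default_na=False)
            pairs["evaluable"] = pairs.get("evaluable", True)
            for col in ("z", "p"):
                pairs[col] = pd.to_numeric(pairs[col], errors="coerce")
        else:
            q = config["qtl"]
            pairs = test_all_pairs(
                filtered, enhancers, window=window, n_perm=q["n_perm"],
                seed=seeds["qtl"], min_perturbed=q["min_perturbed"],
            )
        pairs.to_csv(qtl_dir / "pair_results.tsv", sep="\t", index=False)
        called = call_pairs(pairs, p_max=config["qtl"]["p_max"])
        called.to_csv(qtl_dir / "called_pairs.tsv", sep="\t", index=False)
        pair_summary(called).to_csv(qtl_dir / "pairs_per_enhancer.tsv", sep="\t", index=False)
        tss_rep = tss_positive_control_check(
            filtered, n_perm=config["qtl"]["n_perm"], seed=seeds["qtl"] + 1,
            min_perturbed=config["qtl"]["min_perturbed"],
        )
        (qtl_dir / "tss_control_report.json").write_text(
            json.dumps(asdict(tss_rep), indent=2, sort_keys=True))
        n_called = int(called["called"].sum())
        log(f"{n_called} called enhancer-gene pairs; "
            f"TSS controls passing: {tss_rep.n_passing}/{tss_rep.n_controls}")
        summary["n_called_pairs"] = n_called
        summary["planted_sc_pairs"] = {e: list(v) for e, v in planted_pairs.items()}

    # -------------------------------------------------------------- summary
    with stage("summary"):
        # cross-view overlap: screen hits x loop-anchored genes x qtl targets
        loops_path = _require_input(inputs, "loops", "summary")
        if loops_path is not None:
            loops = pd.read_csv(loops_path, sep="\t", keep_default_na=False)
            loop_genes = set(loops["gene_id"])
        else:
            # simulated ground-truth loops: each planted enhancer-gene pair
            # is anchored by a chromatin interaction
            loop_rows = [
                {"enhancer_id": e, "gene_id": g}
                for e, (g, _) in sorted(planted_pairs.items())
            ]
            loops = pd.DataFrame(loop_rows, columns=["enhancer_id", "gene_id"])
            loops.to_csv(out / "qtl" / "loops.tsv", sep="\t", index=False)
            loop_genes = set(loops["gene_id"])
        qtl_genes = set(called.loc[called["called"], "gene_id"])
        hit_set = set(hit_genes)
        overlap = sorted(hit_set & loop_genes & qtl_genes)
        summary["overlap"] = {
            "screen_hits": len(hit_set),
            "loop_anchored_hits": len(hit_set & loop_genes),
            "qtl_regulated_hits": len(hit_set & qtl_genes),
            "all_three": overlap,
        }
        summary["config_hash"] = _config_hash(config)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # manifest: deterministic — no timestamps
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name not in ("manifest.json", "run.log"))
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log("run complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
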