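"""Directional oncogene / tumor-suppressor / DDR classification of screen hits.

The rules mirror the screen design's directionality logic:

* hit threshold — |log2 fold change| > 1 and -log10(FDR) > 1 in at least one
  cell line (both configurable);
* oncogene — activation (CRISPRa) increases proliferation in 2D, 3D or
  in-vivo screens;
* tumor suppressor — suppression (CRISPRko/CRISPRi) increases proliferation
  in 2D, 3D or in-vivo screens; activation-induced *depletion* in 2D is
  recorded as supporting evidence only, never a stand-alone criterion
  (immortalized lines cannot grow in 3D without an oncogenic insult, so 3D
  depletion is excluded from evidence entirely);
* DDR — depletion in the olaparib-vs-DMSO contrast under any modality
  (suppression or overexpression sensitizing cells to PARP inhibition);
  olaparib *enrichment* (resistance) is recorded but establishes nothing.

A gene can carry several calls (context-dependent behavior is real). Genes
whose CRISPRi and CRISPRko directions disagree and whose
bidirectional-promoter partner is essential get a confound flag, since
promoter-targeted CRISPRi silences both genes of a shared promoter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CANDIDATE_CATEGORIES, CONTROL_CATEGORIES

PROLIFERATION_ASSAYS = ("2D", "3D", "in_vivo")
CALL_TYPES = ("oncogene", "tumor_suppressor", "ddr")


@dataclass(frozen=True)
class HitThresholds:
    lfc_magnitude_min: float = 1.0
    neg_log10_fdr_min: float = 1.0
    min_cell_lines: int = 1

    def __post_init__(self) -> None:
        if min(self.lfc_magnitude_min, self.neg_log10_fdr_min, self.min_cell_lines) <= 0:
            raise ValueError("all hit thresholds must be strictly positive")


@dataclass
class Evidence:
    screen_id: str
    modality: str
    assay: str
    cell_line: str
    direction: str
    gene_lfc: float
    fdr: float
    rule: str


@dataclass
class HitCall:
    gene_id: str
    calls: set[str] = field(default_factory=set)
    evidence: list[Evidence] = field(default_factory=list)
    supporting_only: list[Evidence] = field(default_factory=list)
    confound_flags: list[str] = field(default_factory=list)


def call_screen_hits(results: pd.DataFrame, thresholds: HitThresholds) -> pd.DataFrame:
    """Per (gene, screen) direction: enriched / depleted / none.

    ``results`` rows need gene_id, screen_id, gene_lfc, fdr (plus modality /
    assay / cell_line metadata, carried through). Rows with missing FDR are
    dropped with a warning.
    """
    out = results.copy()
    missing = out["fdr"].isna() | out["gene_lfc"].isna()
    if missing.any():
        warnings.warn(
            f"skipping {int(missing.sum())} gene-screen results with missing FDR or LFC",
            stacklevel=2,
        )
        out = out[~missing].copy()
    sig = -np.log10(np.maximum(out["fdr"].to_numpy(dtype=float), 1e-300)) > thresholds.neg_log10_fdr_min
    lfc = out["gene_lfc"].to_numpy(dtype=float)
    direction = np.where(
        sig & (lfc > thresholds.lfc_magnitude_min), "enriched",
        np.where(sig & (lfc < -thresholds.lfc_magnitude_min), "depleted", "none"),
    )
    out["direction"] = direction
    return out


def _count_lines(records: list[Evidence]) -> int:
    return len({r.cell_line for r in records})


def classify_gene(
    gene_id: str,
    directions: pd.DataFrame,
    thresholds: HitThresholds,
    crispra_depletion_establishes: bool = False,
) -> HitCall:
    """Aggregate one gene's per-screen directions into calls with evidence.

    ``directions`` holds this gene's rows from :func:`call_screen_hits`.
    ``crispra_depletion_establishes`` restores the literal definition in
    which CRISPRa-induced 2D depletion alone can establish a tumor-suppressor
    call; by default it only supports.
    """
    call = HitCall(gene_id=gene_id)
    onc: list[Evidence] = []
    tsg: list[Evidence] = []
    ddr: list[Evidence] = []

    for _, row in directions.iterrows():
        modality, assay = row["modality"], row["assay"]
        if modality not in ("ko", "i", "a"):
            raise ValueError(f"unknown modality tag {modality!r}")
        if assay not in PROLIFERATION_ASSAYS + ("olaparib",):
            raise ValueError(f"unknown assay tag {assay!r}")
        if row["direction"] == "none":
            continue
        ev = Evidence(
            screen_id=row["screen_id"], modality=modality, assay=assay,
            cell_line=row["cell_line"], direction=row["direction"],
            gene_lfc=float(row["gene_lfc"]), fdr=float(row["fdr"]), rule="",
        )
        if assay == "olaparib":
            if ev.direction == "depleted":
                ev.rule = "olaparib_sensitization"
                ddr.append(ev)
            else:
                ev.rule = "olaparib_resistance"
                call.supporting_only.append(ev)
        elif ev.direction == "enriched":
            if modality == "a":
                ev.rule = "activation_proliferation"
                onc.append(ev)
            else:
                ev.rule = "suppression_proliferation"
                tsg.append(ev)
        else:  # depleted in a proliferation assay
            if assay == "3D":
                continue  # 3D depletion never contributes evidence
            if modality == "a" and assay == "2D":
                ev.rule = "activation_2d_depletion"
                if crispra_depletion_establishes:
                    tsg.append(ev)
                else:
                    call.supporting_only.append(ev)
            # ko/i 2D or in-vivo depletion: not evidence under any rule

    if _count_lines(onc) >= thresholds.min_cell_lines and onc:
        call.calls.add("oncogene")
        call.evidence.extend(onc)
    if _count_lines(tsg) >= thresholds.min_cell_lines and tsg:
        call.calls.add("tumor_suppressor")
        call.evidence.extend(tsg)
    elif tsg:
        call.supporting_only.extend(tsg)
    if _count_lines(ddr) >= thresholds.min_cell_lines and ddr:
        call.calls.add("ddr")
        call.evidence.extend(ddr)
    elif ddr:
        call.supporting_only.extend(ddr)
    if onc and "oncogene" not in call.calls:
        call.supporting_only.extend(onc)
    return call


def classify_hits(
    directions: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    crispra_depletion_establishes: bool = False,
) -> dict[str, HitCall]:
    """Classify every gene in a direction table. Pure: input order is irrelevant."""
    thresholds = thresholds or HitThresholds()
    calls = {}
    for gene_id in sorted(directions["gene_id"].unique()):
        sub = directions[directions["gene_id"] == gene_id]
        calls[gene_id] = classify_gene(
            gene_id, sub, thresholds, crispra_depletion_establishes=crispra_depletion_establishes
        )
    return calls


BIDIR_FLAG = "bidirectional_promoter_partner_essential"


def flag_bidirectional_confounds(
    calls: dict[str, HitCall],
    directions: pd.DataFrame,
    promoter_pairs: pd.DataFrame,
) -> dict[str, HitCall]:
    """Flag genes whose ko and i directions disagree with an essential partner.

    A gene enriched under CRISPRko but depleted under CRISPRi (or vice versa)
    whose shared-promoter partner is essential is flagged — the CRISPRi signal
    plausibly reflects silencing of the essential partner, not the gene
    itself. Calls are never removed, only flagged.
    """
    flagged = set()
    essential_partner = set(
        promoter_pairs.loc[promoter_pairs["partner_essential"], "gene_id"]
    )
    for gene_id in essential_partner:
        sub = directions[directions["gene_id"] == gene_id]
        ko_dirs = set(sub.loc[sub["modality"] == "ko", "direction"]) - {"none"}
        i_dirs = set(sub.loc[sub["modality"] == "i", "direction"]) - {"none"}
        if ("enriched" in ko_dirs and "depleted" in i_dirs) or (
            "depleted" in ko_dirs and "enriched" in i_dirs
        ):
            flagged.add(gene_id)
    for gene_id, call in calls.items():
        if gene_id in flagged and BIDIR_FLAG not in call.confound_flags:
            call.confound_flags.append(BIDIR_FLAG)
    return calls


def summarize_hits(calls: dict[str, HitCall], genes: pd.DataFrame) -> pd.DataFrame:
    """Distinct-gene counts per annotation category x call type.

    Candidate categories come first; control classes (essential genes,
    known-driver positive controls) are reported separately, and called genes
    without an annotation land in an ``unannotated`` row rather than being
    dropped.
    """
    category_of = dict(zip(genes["gene_id"], genes["category"]))
    rows = list(CANDIDATE_CATEGORIES) + list(CONTROL_CATEGORIES) + ["unannotated"]
    table = pd.DataFrame(0, index=pd.Index(rows, name="category"), columns=list(CALL_TYPES))
    for gene_id, call in calls.items():
        cat = category_of.get(gene_id, "unannotated")
        if cat not in table.index:
            cat = "unannotated"
        for c in call.calls:
            table.loc[cat, c] += 1
    table["any_call"] = 0
    for gene_id, call in calls.items():
        if call.calls:
            cat = category_of.get(gene_id, "unannotated")
            if cat not in table.index:
                cat = "unannotated"
            table.loc[cat, "any_call"] += 1
    return table


def assay_family_totals(calls: dict[str, HitCall]) -> pd.Series:
    """Distinct called genes with establishing evidence per assay family."""
    prolif = {
        g for g, c in calls.items()
        if any(e.assay in PROLIFERATION_ASSAYS for e in c.evidence) and c.calls & {"oncogene", "tumor_suppressor"}
    }
    ddr = {g for g, c in calls.items() if "ddr" in c.calls}
    return pd.Series(
        {"proliferation": len(prolif), "ddr": len(ddr), "either": len(prolif | ddr)},
        name="n_genes",
    )
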