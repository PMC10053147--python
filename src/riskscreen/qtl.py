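"""Single-cell enhancer-perturbation analysis (CRISPRqtl).

Cell QC follows the emulated experiment: guide UMIs with fewer than three
supporting reads are discarded as ambient noise, then cells need at least two
surviving sgRNA UMIs, bounded mitochondrial content and a minimum number of
detected genes. Cells are "perturbed" for an enhancer if they carry any
surviving guide against it (cells carry several perturbations at MOI ~ 5).

The enhancer-gene pair test is a covariate-stratified permutation test: the
observed statistic is the difference in library-size-normalized log1p mean
expression between perturbed and unperturbed cells, and its null is built by
permuting the perturbation label within strata defined by sequencing-depth,
mitochondrial-content and guide-count bins, which preserves the confounding
structure by construction. z is the standardized observed statistic; p uses
the add-one rule on |null| >= |observed|. Pairs are called regulated when
p <= 0.1 with a negative z (reduced expression under CRISPRi). TSS-targeting
positive-control guides are expected to knock down their own gene; a QC
report tracks the fraction that do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .singlecell import SingleCellDataset


@dataclass(frozen=True)
class CellQCThresholds:
    min_sgrna_umis_per_cell: int = 2
    min_reads_per_sgrna_umi: int = 3
    max_mito_fraction: float = 0.2
    min_genes_detected: int = 200

    def __post_init__(self) -> None:
        if min(
            self.min_sgrna_umis_per_cell,
            self.min_reads_per_sgrna_umi,
            self.max_mito_fraction,
            self.min_genes_detected,
        ) < 0:
            raise ValueError("all QC thresholds must be >= 0")


@dataclass(frozen=True)
class CisWindow:
    """Genomic band around the enhancer midpoint within which genes are tested."""

    halfwidth: int = 2_000_000

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be > 0")


@dataclass
class PairTestResult:
    enhancer_id: str
    gene_id: str
    z: float
    p: float
    n_perturbed: int
    n_control: int
    evaluable: bool = True


def qc_cells(
    dataset: SingleCellDataset, thresholds: CellQCThresholds | None = None
) -> tuple[SingleCellDataset, dict[str, int]]:
    """Filter cells by guide support, mitochondrial content and gene detection.

    Guide UMIs below the read floor are discarded before the per-cell UMI
    count is taken. The QC log reports cells removed per criterion, assessed
    in order (sgRNA support, mito, genes detected). Idempotent.
    """
    thresholds = thresholds or CellQCThresholds()
    log = {"input_cells": dataset.n_cells}

    assigns = dataset.assignments
    good_assigns = assigns[assigns["reads_per_umi"] >= thresholds.min_reads_per_sgrna_umi]
    log["assignments_dropped_low_reads"] = len(assigns) - len(good_assigns)

    umis_per_cell = good_assigns.groupby("cell_id")["umi_count"].sum()
    qc = dataset.cell_qc.set_index("cell_id")
    cells = pd.Index(dataset.cell_ids)

    ok_sgrna = umis_per_cell.reindex(cells, fill_value=0) >= thresholds.min_sgrna_umis_per_cell
    log["cells_removed_sgrna_support"] = int((~ok_sgrna).sum())

    if "mito_fraction" in qc.columns and qc["mito_fraction"].notna().all():
        ok_mito = qc["mito_fraction"].reindex(cells) <= thresholds.max_mito_fraction
    else:
        warnings.warn("mitochondrial annotation missing; mito filter skipped", stacklevel=2)
        ok_mito = pd.Series(True, index=cells)
    log["cells_removed_mito"] = int((ok_sgrna & ~ok_mito).sum())

    genes_detected = pd.Series(
        np.asarray((dataset.matrix > 0).sum(axis=1)).ravel(), index=cells
    )
    ok_genes = genes_detected >= thresholds.min_genes_detected
    log["cells_removed_genes_detected"] = int((ok_sgrna & ok_mito & ~ok_genes).sum())

    keep = (ok_sgrna & ok_mito & ok_genes).to_numpy()
    kept_cells = cells[keep]
    log["output_cells"] = int(keep.sum())

    filtered = SingleCellDataset(
        matrix=dataset.matrix[keep],
        cell_ids=list(kept_cells),
        genes=dataset.genes,
        cell_qc=dataset.cell_qc[dataset.cell_qc["cell_id"].isin(set(kept_cells))].reset_index(drop=True),
        assignments=good_assigns[good_assigns["cell_id"].isin(set(kept_cells))].reset_index(drop=True),
        guides=dataset.guides,
        truth=dataset.truth,
    )
    return filtered, log


def assign_perturbations(dataset: SingleCellDataset) -> pd.DataFrame:
    """Boolean cell x target indicator from surviving guide assignments.

    Columns are enhancer ids plus TSS-control target ids (prefixed ``tss:``)
    and the implicit non-targeting class is simply absence of any column.
    Raises if an assigned sgRNA has no mapping in the guide table.
    """
    guide_map = dataset.guides.set_index("sgrna_id")
    unknown = set(dataset.assignments["sgrna_id"]) - set(guide_map.index)
    if unknown:
        raise ValueError(f"assignments reference unmapped sgRNAs: {sorted(unknown)[:5]}")

    targets = sorted(set(guide_map.loc[guide_map["target_type"] == "enhancer", "target_id"])) + [
        f"tss:{g}" for g in sorted(set(guide_map.loc[guide_map["target_type"] == "tss_control", "target_id"]))
    ]
    ind = pd.DataFrame(False, index=pd.Index(dataset.cell_ids, name="cell_id"), columns=targets)
    for row in dataset.assignments.itertuples(index=False):
        ttype = guide_map.at[row.sgrna_id, "target_type"]
        if ttype == "enhancer":
            ind.at[row.cell_id, guide_map.at[row.sgrna_id, "target_id"]] = True
        elif ttype == "tss_control":
            ind.at[row.cell_id, f"tss:{guide_map.at[row.sgrna_id, 'target_id']}"] = True
    return ind


def _normalized_log_expression(dataset: SingleCellDataset, gene_ids: list[str]) -> np.ndarray:
    """Cells x genes matrix of log1p(1e4 * count / cell total)."""
    index = {g: i for i, g in enumerate(dataset.genes["gene_id"])}
    cols = [index[g] for g in gene_ids]
    counts = np.asarray(dataset.matrix[:, cols].todense()).astype(float)
    totals = np.asarray(dataset.matrix.sum(axis=1)).ravel().astype(float)
    totals = np.maximum(totals, 1.0)
    return np.log1p(1e4 * counts / totals[:, None])


def covariate_strata(
    dataset: SingleCellDataset, n_depth_bins: int = 4, n_mito_bins: int = 2, n_guide_bins: int = 2
) -> np.ndarray:
    """Integer stratum label per cell from depth x mito x guide-count bins."""
    qc = dataset.cell_qc.set_index("cell_id").reindex(dataset.cell_ids)
    totals = np.asarray(dataset.matrix.sum(axis=1)).ravel().astype(float)
    guide_counts = (
        dataset.assignments.groupby("cell_id")["umi_count"].sum().reindex(dataset.cell_ids).fillna(0)
    )

    def bins(values: np.ndarray, k: int) -> np.ndarray:
        if k <= 1 or len(np.unique(values)) <= 1:
            return np.zeros(len(values), dtype=int)
        qs = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
        return np.searchsorted(qs, values, side="right")

    depth_b = bins(totals, n_depth_bins)
    mito = qc["mito_fraction"].to_numpy(dtype=float) if "mito_fraction" in qc else np.zeros(len(totals))
    mito_b = bins(mito, n_mito_bins)
    guide_b = bins(guide_counts.to_numpy(dtype=float), n_guide_bins)
    return depth_b * (n_mito_bins * n_guide_bins) + mito_b * n_guide_bins + guide_b


def permutation_label_matrix(
    perturbed: np.ndarray, strata: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_cells) boolean labels permuted within each stratum.

    Every row carries exactly the observed number of perturbed cells in each
    stratum, so stratum margins are preserved by construction.
    """
    perturbed = perturbed.astype(bool)
    n = len(perturbed)
    labels = np.zeros((n_perm, n), dtype=bool)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        k = int(perturbed[idx].sum())
        if k == 0:
            continue
        if k == len(idx):
            labels[:, idx] = True
            continue
        order = np.argsort(rng.random((n_perm, len(idx))), axis=1)[:, :k]
        sub = np.zeros((n_perm, len(idx)), dtype=bool)
        np.put_along_axis(sub, order, True, axis=1)
        labels[:, idx] = sub
    return labels


def _null_mean_differences(labels: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Mean-difference statistic for each permuted labeling (vectorized).

    ``expr`` may be a vector (one gene) or a cells x genes matrix.
    """
    n_p = int(labels[0].sum())
    n_c = labels.shape[1] - n_p
    s_p = labels.astype(float) @ expr
    total = expr.sum(axis=0)
    return s_p / n_p - (total - s_p) / n_c


def stratified_permutation_pvalue(
    expr: np.ndarray,
    perturbed: np.ndarray,
    strata: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """(z, p) for the mean-difference statistic under within-stratum label permutation."""
    rng = np.random.default_rng(seed)
    perturbed = perturbed.astype(bool)
    obs = float(expr[perturbed].mean() - expr[~perturbed].mean())
    labels = permutation_label_matrix(perturbed, strata, n_perm, rng)
    null = _null_mean_differences(labels, expr.astype(float))
    sd = float(null.std())
    z = (obs - float(null.mean())) / sd if sd > 0 else 0.0
    p = (1 + int(np.sum(np.abs(null) >= abs(obs)))) / (1 + n_perm)
    return z, p


def test_pair(
    dataset: SingleCellDataset,
    perturbation: pd.DataFrame | pd.Series,
    enhancer_id: str,
    gene_id: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_perturbed: int = 10,
    strata: np.ndarray | None = None,
) -> PairTestResult:
    """Stratified permutation test of one enhancer-gene pair.

    ``perturbation`` is the indicator table from :func:`assign_perturbations`
    (or one of its columns). Controls are all QC-passing cells not perturbed
    for this enhancer. Flagged not-evaluable below ``min_perturbed`` cells.
    """
    ind = perturbation[enhancer_id] if isinstance(perturbation, pd.DataFrame) else perturbation
    perturbed = ind.reindex(dataset.cell_ids).fillna(False).to_numpy(dtype=bool)
    n_p, n_c = int(perturbed.sum()), int((~perturbed).sum())
    if n_p < min_perturbed or n_c < min_perturbed:
        return PairTestResult(enhancer_id, gene_id, np.nan, np.nan, n_p, n_c, evaluable=False)

    expr = _normalized_log_expression(dataset, [gene_id])[:, 0]
    if strata is None:
        strata = covariate_strata(dataset)
    z, p = stratified_permutation_pvalue(expr, perturbed, strata, n_perm=n_perm, seed=seed)
    return PairTestResult(enhancer_id, gene_id, z, p, n_p, n_c)


def cis_genes(
    genes: pd.DataFrame, enhancer: pd.Series | dict, window: CisWindow | None = None
) -> list[str]:
    """Genes whose TSS lies within the cis window of an enhancer midpoint."""
    window = window or CisWindow()
    mid = (int(enhancer["start"]) + int(enhancer["end"])) // 2
    same = genes["contig"] == enhancer["contig"]
    near = (genes["tss"] - mid).abs() <= window.halfwidth
    return list(genes.loc[same & near, "gene_id"])


def test_all_pairs(
    dataset: SingleCellDataset,
    enhancers: pd.DataFrame,
    window: CisWindow | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    min_perturbed: int = 10,
) -> pd.DataFrame:
    """Test every (enhancer, cis gene) pair; returns a tidy result table."""
    perturbation = assign_perturbations(dataset)
    strata = covariate_strata(dataset)
    rows = []
    for i, (_, enh) in enumerate(enhancers.iterrows()):
        eid = enh["enhancer_id"]
        if eid not in perturbation.columns:
            continue
        genes = cis_genes(dataset.genes, enh, window)
        if not genes:
            continue
        perturbed = perturbation[eid].reindex(dataset.cell_ids).fillna(False).to_numpy(dtype=bool)
        n_p, n_c = int(perturbed.sum()), int((~perturbed).sum())
        if n_p < min_perturbed or n_c < min_perturbed:
            rows.extend(
                {"enhancer_id": eid, "gene_id": g, "z": np.nan, "p": np.nan,
                 "n_perturbed": n_p, "n_control": n_c, "evaluable": False}
                for g in genes
            )
            continue
        # one permutation label matrix per enhancer serves all its cis genes
        rng = np.random.default_rng(seed + 1009 * i)
        labels = permutation_label_matrix(perturbed, strata, n_perm, rng)
        expr = _normalized_log_expression(dataset, genes)
        obs = expr[perturbed].mean(axis=0) - expr[~perturbed].mean(axis=0)
        null = _null_mean_differences(labels, expr)  # n_perm x n_genes
        sd = null.std(axis=0)
        z = np.where(sd > 0, (obs - null.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        p = (1 + np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)) / (1 + n_perm)
        rows.extend(
            {"enhancer_id": eid, "gene_id": g, "z": float(z[j]), "p": float(p[j]),
             "n_perturbed": n_p, "n_control": n_c, "evaluable": True}
            for j, g in enumerate(genes)
        )
    return pd.DataFrame(
        rows, columns=["enhancer_id", "gene_id", "z", "p", "n_perturbed", "n_control", "evaluable"]
    )


def call_pairs(results: pd.DataFrame, p_max: float = 0.1) -> pd.DataFrame:
    """Regulated pairs: p <= p_max (inclusive) and z < 0."""
    out = results.copy()
    out["called"] = out["evaluable"] & (out["p"] <= p_max) & (out["z"] < 0)
    return out


def pair_summary(called: pd.DataFrame) -> pd.DataFrame:
    """Distinct called genes per enhancer."""
    sub = called[called["called"]]
    return (
        sub.groupby("enhancer_id")["gene_id"].nunique().rename("n_regulated_genes").reset_index()
    )


@dataclass
class TSSControlReport:
    evaluable: bool
    n_controls: int
    n_passing: int
    pass_fraction: float | None
    p_bound: float
    warn: bool
    messages: list[str] = field(default_factory=list)


def tss_positive_control_check(
    dataset: SingleCellDataset,
    n_perm: int = 1000,
    seed: int = 0,
    p_bound: float = 0.05,
    warn_fraction: float = 0.8,
    min_perturbed: int = 10,
) -> TSSControlReport:
    """Fraction of TSS-targeting controls that knock down their own gene.

    A control passes if its self-gene test gives z < 0 and p below
    ``p_bound``; the pipeline warns when fewer than ``warn_fraction`` pass.
    """
    perturbation = assign_perturbations(dataset)
    strata = covariate_strata(dataset)
    tss_targets = sorted(
        set(dataset.guides.loc[dataset.guides["target_type"] == "tss_control", "target_id"])
    )
    gene_panel = set(dataset.genes["gene_id"])
    n_pass = 0
    n_eval = 0
    for k, gene in enumerate(tss_targets):
        col = f"tss:{gene}"
        if gene not in gene_panel or col not in perturbation.columns:
            continue
        r = test_pair(
            dataset, perturbation[col], col, gene,
            n_perm=n_perm, seed=seed + k, min_perturbed=min_perturbed, strata=strata,
        )
        if not r.evaluable:
            continue
        n_eval += 1
        if r.z < 0 and r.p < p_bound:
            n_pass += 1
    if n_eval == 0:
        return TSSControlReport(False, 0, 0, None, p_bound, False,
                                ["no evaluable TSS controls"])
    frac = n_pass / n_eval
    warn = frac < warn_fraction
    messages = []
    if warn:
        messages.append(
            f"only {frac:.0%} of TSS controls knocked down their target (bound p<{p_bound})"
        )
    return TSSControlReport(True, n_eval, n_pass, frac, p_bound, warn, messages)
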