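"""Simulation of single-cell CRISPRi enhancer-perturbation (CRISPRqtl) data.

Cells are infected at high multiplicity (default MOI 5) with a guide library
made of enhancer-tiling sgRNAs, non-targeting negative controls and
TSS-targeting positive controls. Each cell's transcriptome is a Poisson draw
around gene baselines scaled by the cell's library size; carrying a guide
against enhancer E multiplies the expected expression of E's target gene by
(1 + planted fractional change), and TSS guides knock their target down by a
fixed fraction. Ambient (spurious) guide assignments with low read support are
planted so the UMI/read QC filters have something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class SingleCellSimConfig:
    n_cells: int = 2000
    moi: float = 5.0
    mean_umis_per_cell: float = 5000.0
    n_genes: int = 300
    gene_mean_sigma: float = 0.8
    cell_size_sigma: float = 0.3
    mito_beta: tuple[float, float] = (2.0, 38.0)  # mean 0.05
    high_mito_fraction: float = 0.05
    high_mito_beta: tuple[float, float] = (8.0, 12.0)  # mean 0.4
    low_quality_fraction: float = 0.05  # cells with ~10x fewer UMIs
    #: enhancer_id -> (gene_id, fractional expression change); -0.5 halves it
    planted_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_nt_controls: int = 50
    n_tss_control_genes: int = 50
    sgrnas_per_tss_control: int = 2
    tss_knockdown: float = 0.9
    ambient_rate: float = 0.15
    tiling_spacing: int = 100
    contig: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.moi <= 0:
            raise ValueError("moi must be > 0")
        if self.n_cells < 0 or self.n_genes <= 0:
            raise ValueError("n_cells must be >= 0 and n_genes > 0")
        for _, (gene, change) in self.planted_effects.items():
            if change <= -1:
                raise ValueError(f"fractional change for {gene} must be > -1")


@dataclass
class SingleCellDataset:
    """Cell x gene UMI counts plus guide assignments and QC covariates.

    ``matrix`` is CSR, cells x genes; ``genes`` carries gene_id/contig/tss;
    ``cell_qc`` carries mito_fraction, total_umis, genes_detected;
    ``assignments`` is the cell x sgRNA table (umi_count, reads_per_umi);
    ``guides`` maps each sgRNA to an enhancer, a TSS control gene, or a
    non-targeting class. ``truth`` records the planted effects.
    """

    matrix: sparse.csr_matrix
    cell_ids: list[str]
    genes: pd.DataFrame
    cell_qc: pd.DataFrame
    assignments: pd.DataFrame
    guides: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def to_anndata(self):
        """View the expression matrix as an AnnData (guides stay in .uns)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.matrix.copy(),
            obs=self.cell_qc.set_index("cell_id"),
            var=self.genes.set_index("gene_id"),
        )
        adata.uns["guide_assignments"] = self.assignments.copy()
        adata.uns["guides"] = self.guides.copy()
        return adata


def _empty_dataset(genes: pd.DataFrame, guides: pd.DataFrame, truth: dict) -> SingleCellDataset:
    return SingleCellDataset(
        matrix=sparse.csr_matrix((0, len(genes))),
        cell_ids=[],
        genes=genes,
        cell_qc=pd.DataFrame(columns=["cell_id", "mito_fraction", "total_umis", "genes_detected"]),
        assignments=pd.DataFrame(columns=["cell_id", "sgrna_id", "umi_count", "reads_per_umi"]),
        guides=guides,
        truth=truth,
    )


def _gene_panel(config: SingleCellSimConfig, enhancers: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Gene panel spanning the enhancer region so cis windows are populated."""
    if len(enhancers):
        lo = int(enhancers["start"].min())
        hi = int(enhancers["end"].max())
        span_lo, span_hi = max(0, lo - 500_000), hi + 500_000
    else:
        span_lo, span_hi = 0, 10_000_000
    tss = np.sort(rng.integers(span_lo, span_hi, size=config.n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:04d}" for i in range(config.n_genes)],
            "contig": config.contig,
            "tss": tss.astype(np.int64),
        }
    )


def build_guide_table(config: SingleCellSimConfig, tiling: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Guide library: tiling sgRNAs + non-targeting + TSS positive controls."""
    rows = [
        {"sgrna_id": f"{e}_pos{p}", "target_type": "enhancer", "target_id": e, "position": int(p)}
        for e, p in zip(tiling["enhancer_id"], tiling["position"])
    ]
    n_tss = min(config.n_tss_control_genes, len(genes))
    tss_genes = genes["gene_id"].iloc[:n_tss]
    for g in tss_genes:
        for i in range(config.sgrnas_per_tss_control):
            rows.append({"sgrna_id": f"TSS_{g}_sg{i + 1}", "target_type": "tss_control",
                         "target_id": g, "position": -1})
    for i in range(config.n_nt_controls):
        rows.append({"sgrna_id": f"NT_{i + 1:03d}", "target_type": "non_targeting",
                     "target_id": "", "position": -1})
    return pd.DataFrame(rows, columns=["sgrna_id", "target_type", "target_id", "position"])


def simulate_single_cells(
    enhancers: pd.DataFrame,
    config: SingleCellSimConfig,
    tiling: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
) -> SingleCellDataset:
    """Simulate a CRISPRqtl experiment over the given candidate enhancers.

    ``enhancers`` needs contig/start/end/enhancer_id columns (the candidate
    enhancer table). A tiling design and gene panel may be supplied; otherwise
    the enhancers are tiled at ``config.tiling_spacing`` and a panel is drawn
    around them. Planted effects must reference simulated enhancers and genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if genes is None:
        genes = _gene_panel(config, enhancers, rng)
    gene_ids = list(genes["gene_id"])
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    enh_ids = set(enhancers["enhancer_id"]) if len(enhancers) else set()
    for enh, (gene, _) in config.planted_effects.items():
        if enh not in enh_ids:
            raise ValueError(f"planted effect references unknown enhancer {enh!r}")
        if gene not in gene_index:
            raise ValueError(f"planted effect references gene {gene!r} absent from gene panel")

    if tiling is None:
        from .enhancers import tile_sgrnas

        tiling = tile_sgrnas(enhancers, spacing=config.tiling_spacing)
    guides = build_guide_table(config, tiling, genes)
    truth = {
        "planted_effects": dict(config.planted_effects),
        "tss_knockdown": config.tss_knockdown,
    }
    if config.n_cells == 0:
        return _empty_dataset(genes, guides, truth)

    n_guides = len(guides)
    guide_type = guides["target_type"].to_numpy()
    guide_target = guides["target_id"].to_numpy()

    # baseline expression program, scaled to the target library size
    base = rng.lognormal(0.0, config.gene_mean_sigma, size=len(gene_ids))
    base = base / base.sum() * config.mean_umis_per_cell
    size_factor = rng.lognormal(0.0, config.cell_size_sigma, size=config.n_cells)
    low_q = rng.random(config.n_cells) < config.low_quality_fraction
    size_factor[low_q] /= 10.0

    cell_ids = [f"CELL_{i + 1:05d}" for i in range(config.n_cells)]
    n_sgrnas_per_cell = rng.poisson(config.moi, size=config.n_cells)

    assign_rows: list[tuple[str, str, int, int]] = []
    mult = np.ones((config.n_cells, len(gene_ids)))
    for c in range(config.n_cells):
        k = n_sgrnas_per_cell[c]
        pert_enh: set[str] = set()
        tss_hit: set[str] = set()
        if k > 0:
            chosen = rng.choice(n_guides, size=k, replace=False) if k <= n_guides else np.arange(n_guides)
            for gi in chosen:
                umis = 1 + rng.poisson(2)
                reads = 3 + rng.poisson(10)
                assign_rows.append((cell_ids[c], guides["sgrna_id"].iat[gi], int(umis), int(reads)))
                if guide_type[gi] == "enhancer":
                    pert_enh.add(guide_target[gi])
                elif guide_type[gi] == "tss_control":
                    tss_hit.add(guide_target[gi])
        # real integrations act on expression once per perturbed element,
        # regardless of how many guides against it the cell carries
        for enh in pert_enh:
            eff = config.planted_effects.get(enh)
            if eff is not None:
                mult[c, gene_index[eff[0]]] *= 1.0 + eff[1]
        for g in tss_hit:
            mult[c, gene_index[g]] *= 1.0 - config.tss_knockdown
        # ambient guide detections: present in the assignment table at low
        # read support, but with no biological effect
        n_ambient = rng.poisson(config.ambient_rate * config.moi)
        if n_ambient:
            for gi in rng.choice(n_guides, size=min(n_ambient, n_guides), replace=False):
                assign_rows.append((cell_ids[c], guides["sgrna_id"].iat[gi], 1, int(1 + rng.integers(0, 2))))

    mean = base[None, :] * size_factor[:, None] * mult
    counts = rng.poisson(mean)
    matrix = sparse.csr_matrix(counts)

    mito = rng.beta(*config.mito_beta, size=config.n_cells)
    hi = rng.random(config.n_cells) < config.high_mito_fraction
    mito[hi] = rng.beta(*config.high_mito_beta, size=int(hi.sum()))

    cell_qc = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "mito_fraction": mito,
            "total_umis": counts.sum(axis=1),
            "genes_detected": (counts > 0).sum(axis=1),
        }
    )
    assignments = pd.DataFrame(
        assign_rows, columns=["cell_id", "sgrna_id", "umi_count", "reads_per_umi"]
    )
    return SingleCellDataset(
        matrix=matrix,
        cell_ids=cell_ids,
        genes=genes,
        cell_qc=cell_qc,
        assignments=assignments,
        guides=guides,
        truth=truth,
    )
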