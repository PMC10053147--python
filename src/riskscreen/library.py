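"""Synthetic pooled sgRNA library construction.

The perturbation library mirrors the composition of a GWAS-candidate CRISPR
screen: candidate genes drawn from four prediction categories (high- and
moderate-confidence in-silico predictions, TWAS/eQTL genes, and background
genes with no supporting functional evidence), each targeted by a fixed number
of sgRNAs; non-targeting negative controls; core-essential genes as depletion
controls; and a small panel of known driver genes as positive controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANDIDATE_CATEGORIES = ("INQ_1", "INQ_2", "TWAS", "background")
CONTROL_CATEGORIES = ("essential", "driver_control")

#: driver genes that are high-confidence predictions solely through their
#: known-driver status; used by the enrichment sensitivity analysis
DEFAULT_DOWNGRADE_DRIVERS = ("CASZ1", "CCNE1", "CREBBP", "NF1")


@dataclass(frozen=True)
class LibraryConfig:
    """Composition of the synthetic sgRNA library.

    Defaults mirror the screen this package emulates: 5 sgRNAs per gene,
    1000 negative controls, 960 sgRNAs spread over 193 core-essential genes
    and 16 known-driver positive controls.
    """

    n_genes_per_category: dict[str, int] = field(
        default_factory=lambda: {"INQ_1": 184, "INQ_2": 678, "TWAS": 371, "background": 605}
    )
    sgrnas_per_gene: int = 5
    n_negative_controls: int = 1000
    n_essential_genes: int = 193
    n_essential_sgrnas: int = 960
    n_known_driver_genes: int = 16
    n_bidirectional_pairs: int = 1
    contig: str = "chr1"
    tss_spacing: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.sgrnas_per_gene < 1:
            raise ValueError("sgrnas_per_gene must be >= 1")
        counts = list(self.n_genes_per_category.values()) + [
            self.n_negative_controls,
            self.n_essential_genes,
            self.n_essential_sgrnas,
            self.n_known_driver_genes,
            self.n_bidirectional_pairs,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all library counts must be >= 0")
        unknown = set(self.n_genes_per_category) - set(CANDIDATE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if self.n_essential_genes == 0 and self.n_essential_sgrnas > 0:
            raise ValueError("essential sgRNAs requested but no essential genes")


@dataclass
class SgRNALibrary:
    """A pooled sgRNA library plus its gene annotation.

    ``sgrnas``: one row per sgRNA — ``sgrna_id``, ``target_id`` (empty for
    controls), ``target_type`` (``gene`` or ``negative_control``).

    ``genes``: one row per gene — ``gene_id``, ``category`` (candidate
    categories plus the control classes ``essential``/``driver_control``),
    ``known_driver`` flag, ``contig``, ``tss`` and ``partner_id`` (the other
    member of a shared bidirectional promoter, empty if none).
    """

    sgrnas: pd.DataFrame
    genes: pd.DataFrame

    @property
    def n_sgrnas(self) -> int:
        return len(self.sgrnas)

    @property
    def negative_control_ids(self) -> pd.Index:
        mask = self.sgrnas["target_type"] == "negative_control"
        return pd.Index(self.sgrnas.loc[mask, "sgrna_id"])

    def sgrnas_for_gene(self, gene_id: str) -> pd.Index:
        mask = self.sgrnas["target_id"] == gene_id
        return pd.Index(self.sgrnas.loc[mask, "sgrna_id"])

    def genes_in_category(self, category: str) -> list[str]:
        return list(self.genes.loc[self.genes["category"] == category, "gene_id"])


def _essential_sgrna_split(n_sgrnas: int, n_genes: int) -> list[int]:
    """Distribute a total sgRNA budget as evenly as possible over genes.

    floor(n/g) per gene with the remainder handed out one-by-one, so e.g.
    960 sgRNAs over 193 genes gives 188 genes with 5 and 5 genes with 4.
    """
    base, extra = divmod(n_sgrnas, n_genes)
    return [base + 1] * extra + [base] * (n_genes - extra)


def make_library(config: LibraryConfig) -> SgRNALibrary:
    """Build a deterministic synthetic sgRNA library from ``config``.

    Every non-control gene receives exactly ``config.sgrnas_per_gene`` sgRNAs;
    essential genes share ``n_essential_sgrnas`` as evenly as the total allows;
    negative controls target nothing. At least one bidirectional-promoter pair
    in which one partner is essential is planted (when both an essential gene
    and a candidate gene exist), so the promoter-confound logic downstream has
    something to exercise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_rows: list[dict] = []
    sgrna_rows: list[dict] = []

    def add_gene(gene_id: str, category: str, known_driver: bool, n_sgrnas: int) -> None:
        gene_rows.append(
            {
                "gene_id": gene_id,
                "category": category,
                "known_driver": known_driver,
                "contig": config.contig,
                "tss": 0,  # assigned after all genes exist
                "partner_id": "",
                "n_sgrnas": n_sgrnas,
            }
        )
        for i in range(n_sgrnas):
            sgrna_rows.append(
                {"sgrna_id": f"{gene_id}_sg{i + 1}", "target_id": gene_id, "target_type": "gene"}
            )

    for category in CANDIDATE_CATEGORIES:
        n = config.n_genes_per_category.get(category, 0)
        for g in range(n):
            add_gene(f"{category}_{g + 1:04d}", category, False, config.sgrnas_per_gene)

    if config.n_essential_genes:
        split = _essential_sgrna_split(config.n_essential_sgrnas, config.n_essential_genes)
        for g, k in enumerate(split):
            add_gene(f"ESS_{g + 1:03d}", "essential", False, k)

    for g in range(config.n_known_driver_genes):
        add_gene(f"DRIVER_{g + 1:02d}", "driver_control", True, config.sgrnas_per_gene)

    for i in range(config.n_negative_controls):
        sgrna_rows.append(
            {"sgrna_id": f"NC_{i + 1:04d}", "target_id": "", "target_type": "negative_control"}
        )

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "category", "known_driver", "contig", "tss", "partner_id", "n_sgrnas"],
    )
    sgrnas = pd.DataFrame(sgrna_rows, columns=["sgrna_id", "target_id", "target_type"])

    if len(genes):
        # TSSs on a regular grid with seeded jitter; order shuffled so that
        # category blocks are not collinear with genomic position.
        order = rng.permutation(len(genes))
        jitter = rng.integers(0, config.tss_spacing // 2, size=len(genes))
        tss = np.empty(len(genes), dtype=np.int64)
        tss[order] = config.tss_spacing * (1 + np.arange(len(genes))) + jitter
        genes["tss"] = tss

    # Plant bidirectional-promoter pairs: a candidate gene sharing a promoter
    # with an essential partner (divergent TSSs a few hundred bp apart).
    candidate_idx = genes.index[genes["category"].isin(CANDIDATE_CATEGORIES)].to_numpy()
    essential_idx = genes.index[genes["category"] == "essential"].to_numpy()
    n_pairs = min(config.n_bidirectional_pairs, len(candidate_idx), len(essential_idx))
    if n_pairs:
        cand = rng.choice(candidate_idx, size=n_pairs, replace=False)
        ess = rng.choice(essential_idx, size=n_pairs, replace=False)
        for ci, ei in zip(cand, ess):
            genes.loc[ci, "partner_id"] = genes.loc[ei, "gene_id"]
            genes.loc[ei, "partner_id"] = genes.loc[ci, "gene_id"]
            genes.loc[ei, "tss"] = genes.loc[ci, "tss"] + 300

    return SgRNALibrary(sgrnas=sgrnas, genes=genes)


def promoter_pairs(genes: pd.DataFrame) -> pd.DataFrame:
    """Symmetric table of shared bidirectional-promoter pairs.

    Columns: ``gene_id``, ``partner_id``, ``partner_essential``. One row per
    directed pair (so each shared promoter yields two rows).
    """
    paired = genes[genes["partner_id"] != ""]
    essential = set(genes.loc[genes["category"] == "essential", "gene_id"])
    return pd.DataFrame(
        {
            "gene_id": paired["gene_id"].to_numpy(),
            "partner_id": paired["partner_id"].to_numpy(),
            "partner_essential": [p in essential for p in paired["partner_id"]],
        }
    )
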