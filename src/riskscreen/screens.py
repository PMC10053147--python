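"""Negative-binomial simulation of pooled CRISPR screen count data.

Each screen is a (cell line, modality, assay) combination read out as sgRNA
counts at an endpoint sample, contrasted against a reference: the plasmid DNA
pool for proliferation and xenograft screens, or the paired vehicle (DMSO) arm
for PARP-inhibitor synthetic-lethality screens. The expected endpoint
abundance of an sgRNA is its pool abundance scaled by 2**lfc, where lfc is the
planted fitness effect applicable to that sample; counts are Gamma–Poisson
(negative binomial) around the expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import ASSAYS, MODALITIES, EffectSpec
from .library import SgRNALibrary

DEFAULT_CELL_LINES = ("B80-T5", "B80-T17", "HMLE", "mesHMLE", "K5K19pos", "K5K19neg")


@dataclass(frozen=True)
class ScreenDesign:
    """Layout and noise model of a simulated screen campaign.

    ``coverage_cells_per_sgrna`` mirrors the 1000 cells/sgRNA infection
    coverage of the emulated screens; ``depth`` is the mean sequenced reads
    per sgRNA per sample and ``dispersion`` the Gamma–Poisson overdispersion
    (variance = m + dispersion * m**2; 0 gives Poisson counts).
    """

    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    modalities: tuple[str, ...] = ("ko", "i", "a")
    assays: tuple[str, ...] = ("2D", "3D", "in_vivo", "olaparib")
    in_vivo_modalities: tuple[str, ...] = ("ko", "a")
    coverage_cells_per_sgrna: int = 1000
    dispersion: float = 0.05
    depth: float = 500.0
    pool_lognormal_sigma: float = 0.25
    founder_fraction: float = 0.1

    def validate(self) -> None:
        if self.coverage_cells_per_sgrna <= 0 or self.depth <= 0:
            raise ValueError("coverage and depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.founder_fraction <= 1:
            raise ValueError("founder_fraction must be in (0, 1]")
        bad = set(self.modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        bad = set(self.assays) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assays: {sorted(bad)}")


@dataclass(frozen=True)
class ScreenContrast:
    """One statistical comparison: endpoint sample vs its reference."""

    screen_id: str
    reference_id: str
    endpoint_id: str
    modality: str
    assay: str
    cell_line: str


@dataclass
class ScreenCountMatrix:
    """sgRNA x sample integer counts plus the sample design sheet.

    ``counts`` is indexed by sgrna_id with one column per sample; ``samples``
    has one row per sample with cell_line/modality/assay/arm/role and, for
    endpoint samples, the id of their contrast reference.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def contrasts(self) -> list[ScreenContrast]:
        out = []
        for _, row in self.samples.iterrows():
            if row["role"] != "endpoint":
                continue
            out.append(
                ScreenContrast(
                    screen_id=f"{row['cell_line']}_{row['modality']}_{row['assay']}",
                    reference_id=row["reference_id"],
                    endpoint_id=row["sample_id"],
                    modality=row["modality"],
                    assay=row["assay"],
                    cell_line=row["cell_line"],
                )
            )
        return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw with the given mean vector; Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = np.where(mean > 0, rng.gamma(1.0 / dispersion, np.maximum(mean, 1e-300) * dispersion), 0.0)
    return rng.poisson(lam)


def _partner_map(library: SgRNALibrary) -> dict[str, str]:
    paired = library.genes[library.genes["partner_id"] != ""]
    return dict(zip(paired["gene_id"], paired["partner_id"]))


def simulate_screen_counts(
    library: SgRNALibrary,
    effects: list[EffectSpec] | dict[str, EffectSpec],
    design: ScreenDesign,
    seed: int = 0,
) -> ScreenCountMatrix:
    """Simulate a full screen campaign from planted effects.

    Samples produced: one shared DNA-pool reference, one endpoint per
    (cell line, modality, assay) for 2D/3D, a founder-bottlenecked endpoint
    for the in-vivo arm (MEK-activated context, restricted to
    ``design.in_vivo_modalities``), and paired DMSO + olaparib arms for the
    synthetic-lethality assay. Under modality ``i``, sgRNAs targeting a gene
    that shares a bidirectional promoter also silence the partner gene, so
    they additionally carry the partner's fitness effect — the promoter
    confound the classifier must flag.
    """
    design.validate()
    if isinstance(effects, dict):
        effect_map = dict(effects)
    else:
        effect_map = {e.gene_id: e for e in effects}
    known_genes = set(library.genes["gene_id"])
    unknown = set(effect_map) - known_genes
    if unknown:
        raise ValueError(f"effects reference unknown genes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sgrna_ids = library.sgrnas["sgrna_id"].to_numpy()
    targets = library.sgrnas["target_id"].to_numpy()
    n = len(sgrna_ids)
    partner_of = _partner_map(library)

    # Plasmid pool composition: lognormal representation spread, sequenced at
    # the design depth.
    rel = rng.lognormal(0.0, design.pool_lognormal_sigma, size=n)
    pool_mean = design.depth * rel / rel.mean()
    pool_counts = _nb_counts(rng, pool_mean, design.dispersion)

    def sgrna_lfcs(modality: str, assay_keys: list[str], arm: str) -> np.ndarray:
        lfc = np.zeros(n)
        cache: dict[str, float] = {}
        for i, gene in enumerate(targets):
            if not gene:
                continue
            if gene not in cache:
                total = 0.0
                spec = effect_map.get(gene)
                if spec is not None:
                    total += sum(spec.lfc(modality, a, arm) for a in assay_keys)
                if modality == "i" and gene in partner_of:
                    pspec = effect_map.get(partner_of[gene])
                    if pspec is not None:
                        total += sum(pspec.lfc(modality, a, arm) for a in assay_keys)
                cache[gene] = total
            lfc[i] = cache[gene]
        return lfc

    columns: dict[str, np.ndarray] = {"pool": pool_counts}
    sample_rows = [
        {"sample_id": "pool", "cell_line": "", "modality": "", "assay": "", "arm": "",
         "role": "reference", "reference_id": ""}
    ]

    def add_sample(sample_id: str, mean_rel: np.ndarray, lfc: np.ndarray, meta: dict) -> None:
        # expected abundance = pool abundance x 2**lfc; neutral guides keep
        # the design depth, so planted fold changes survive on the raw scale
        denom = mean_rel.mean() if mean_rel.mean() > 0 else 1.0
        mean = design.depth * mean_rel * np.exp2(lfc) / denom
        columns[sample_id] = _nb_counts(rng, mean, design.dispersion)
        sample_rows.append({"sample_id": sample_id, **meta})

    for cell_line in design.cell_lines:
        for modality in design.modalities:
            for assay in design.assays:
                base = f"{cell_line}_{modality}_{assay}"
                if assay in ("2D", "3D"):
                    lfc = sgrna_lfcs(modality, [assay], arm="")
                    add_sample(
                        base, rel, lfc,
                        {"cell_line": cell_line, "modality": modality, "assay": assay,
                         "arm": "", "role": "endpoint", "reference_id": "pool"},
                    )
                elif assay == "in_vivo":
                    if modality not in design.in_vivo_modalities:
                        continue
                    # engraftment bottleneck: only a fraction of infected cells
                    # found the tumor, resampling the pool composition
                    n_founders = max(1, int(design.founder_fraction * design.coverage_cells_per_sgrna * n))
                    founders = rng.multinomial(n_founders, rel / rel.sum()).astype(float)
                    lfc = sgrna_lfcs(modality, ["in_vivo"], arm="mekdd")
                    add_sample(
                        base, founders, lfc,
                        {"cell_line": cell_line, "modality": modality, "assay": assay,
                         "arm": "mekdd", "role": "endpoint", "reference_id": "pool"},
                    )
                elif assay == "olaparib":
                    # both arms grow in 2D; the drug arm additionally applies
                    # the synthetic-lethality effect
                    dmso_id = f"{base}_dmso"
                    lfc_growth = sgrna_lfcs(modality, ["2D"], arm="")
                    add_sample(
                        dmso_id, rel, lfc_growth,
                        {"cell_line": cell_line, "modality": modality, "assay": assay,
                         "arm": "dmso", "role": "arm_reference", "reference_id": "pool"},
                    )
                    lfc_drug = lfc_growth + sgrna_lfcs(modality, ["olaparib"], arm="olaparib")
                    add_sample(
                        f"{base}_olaparib", rel, lfc_drug,
                        {"cell_line": cell_line, "modality": modality, "assay": assay,
                         "arm": "olaparib", "role": "endpoint", "reference_id": dmso_id},
                    )

    counts = pd.DataFrame(columns, index=pd.Index(sgrna_ids, name="sgrna_id"), dtype=np.int64)
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "cell_line", "modality", "assay", "arm", "role", "reference_id"],
    )
    return ScreenCountMatrix(counts=counts, samples=samples)
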