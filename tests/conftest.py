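import numpy as np
import pandas as pd
import pytest

from riskscreen import (
    CellQCThresholds,
    EffectSpec,
    LibraryConfig,
    ScreenDesign,
    SingleCellSimConfig,
    make_library,
    qc_cells,
    simulate_screen_counts,
    simulate_single_cells,
)


@pytest.fixture(scope="session")
def small_library():
    """Compact library: 40 candidate genes, controls, essentials, drivers."""
    return make_library(
        LibraryConfig(
            n_genes_per_category={"INQ_1": 10, "INQ_2": 10, "TWAS": 10, "background": 10},
            sgrnas_per_gene=5,
            n_negative_controls=150,
            n_essential_genes=5,
            n_essential_sgrnas=24,
            n_known_driver_genes=2,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def planted_effects(small_library):
    """One planted gene per class, on fixed genes for reproducibility."""
    from riskscreen import effects_for_class

    specs = [
        effects_for_class("INQ_1_0001", "tumor_suppressor", 2.0),
        effects_for_class("INQ_1_0002", "oncogene", 2.0),
        effects_for_class("INQ_2_0001", "ddr", 2.0),
        effects_for_class("TWAS_0001", "context_dependent", 2.0),
    ]
    specs += [effects_for_class(g, "essential", 2.0) for g in small_library.genes_in_category("essential")]
    return specs


@pytest.fixture(scope="session")
def screen_counts(small_library, planted_effects):
    design = ScreenDesign(
        cell_lines=("B80-T5",),
        modalities=("ko", "i", "a"),
        assays=("2D", "3D", "in_vivo", "olaparib"),
    )
    return simulate_screen_counts(small_library, planted_effects, design, seed=11)


@pytest.fixture(scope="session")
def enhancer_frame():
    n = 10
    return pd.DataFrame(
        {
            "contig": "chr1",
            "start": [1_000_000 + 100_000 * i for i in range(n)],
            "end": [1_001_000 + 100_000 * i for i in range(n)],
            "enhancer_id": [f"ENH_{i + 1:04d}" for i in range(n)],
        }
    )


@pytest.fixture(scope="session")
def sc_dataset(enhancer_frame):
    """Single-cell simulation with one planted 50% knockdown pair."""
    cfg = SingleCellSimConfig(
        n_cells=1500,
        n_genes=250,
        mean_umis_per_cell=4000,
        planted_effects={"ENH_0001": ("G0050", -0.5)},
        n_tss_control_genes=5,
        n_nt_controls=20,
        seed=42,
    )
    return simulate_single_cells(enhancer_frame, cfg)


@pytest.fixture(scope="session")
def sc_filtered(sc_dataset):
    filtered, _ = qc_cells(sc_dataset, CellQCThresholds(min_genes_detected=100))
    return filtered
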