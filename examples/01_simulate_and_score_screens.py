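"""Simulate a pooled CRISPR screen with planted effects and score it.

Builds a small sgRNA library (four candidate-gene categories, negative
controls, core-essential depletion controls), plants one tumor suppressor
and one oncogene at |log2FC| = 2, simulates negative-binomial counts for a
knockout and an activation screen, and runs the gene-level test.
"""

from riskscreen import (
    HitThresholds, LibraryConfig, ScreenDesign, call_screen_hits,
    effects_for_class, make_library, score_all_screens, simulate_screen_counts,
)

library = make_library(
    LibraryConfig(
        n_genes_per_category={"INQ_1": 20, "INQ_2": 20, "TWAS": 20, "background": 20},
        n_negative_controls=300,
        n_essential_genes=5,
        n_essential_sgrnas=24,
        n_known_driver_genes=2,
        seed=1,
    )
)
print(f"library: {library.n_sgrnas} sgRNAs, {len(library.genes)} genes")

effects = [
    effects_for_class("INQ_1_0001", "tumor_suppressor", 2.0),
    effects_for_class("INQ_1_0002", "oncogene", 2.0),
] + [effects_for_class(g, "essential", 2.0) for g in library.genes_in_category("essential")]

design = ScreenDesign(cell_lines=("B80-T5",), modalities=("ko", "a"), assays=("2D",))
counts = simulate_screen_counts(library, effects, design, seed=2)
print(f"simulated {len(counts.samples)} samples (pool + one endpoint per screen)")

results, _ = score_all_screens(counts, library, n_resample=1000, seed=3)
directions = call_screen_hits(results, HitThresholds())
hits = directions[directions["direction"] != "none"]
print("\ngenes passing |log2FC| > 1 and -log10(FDR) > 1:")
print(hits[["gene_id", "screen_id", "gene_lfc", "fdr", "direction"]].to_string(index=False))
print(
    "\nThe planted tumor suppressor is enriched under knockout, the planted"
    "\noncogene under activation, and the essential controls deplete only in"
    "\nthe knockout screen — negative controls stay at log2FC ~ 0."
)
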