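"""Synthetic genome tracks: ATAC peaks, H3K27ac peaks and credible causal variants.

Coordinates are 0-based half-open throughout; BED is the interchange format.
A configurable fraction of ATAC peaks are planted positives: they overlap an
H3K27ac peak and carry at least one CCV within 500 bp of their center, so the
candidate-enhancer construction downstream has known loci to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeTrackConfig:
    contig: str = "chr1"
    length: int = 10_000_000
    n_atac_peaks: int = 200
    n_h3k27ac_peaks: int = 200
    n_ccvs: int = 80
    peak_width_mean: float = 400.0
    peak_width_sd: float = 100.0
    min_peak_width: int = 100
    fraction_planted: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("contig length must be > 0")
        if min(self.n_atac_peaks, self.n_h3k27ac_peaks, self.n_ccvs) < 0:
            raise ValueError("track counts must be >= 0")
        if not 0 <= self.fraction_planted <= 1:
            raise ValueError("fraction_planted must be in [0, 1]")
        if self.min_peak_width <= 0 or self.peak_width_mean <= 0:
            raise ValueError("peak widths must be positive")


@dataclass
class GenomeTracks:
    """Simulated peak/variant sets plus the planted ground truth.

    ``atac``/``h3k27ac``: contig, start, end, peak_id. ``ccvs``: contig,
    start, end (end = start + 1), ccv_id. ``planted``: the ATAC peaks that
    were constructed to survive candidate-enhancer construction.
    """

    atac: pd.DataFrame
    h3k27ac: pd.DataFrame
    ccvs: pd.DataFrame
    planted: pd.DataFrame


def _widths(rng: np.random.Generator, cfg: GenomeTrackConfig, n: int) -> np.ndarray:
    w = rng.normal(cfg.peak_width_mean, cfg.peak_width_sd, size=n)
    return np.maximum(np.round(w), cfg.min_peak_width).astype(np.int64)


def simulate_genome_tracks(config: GenomeTrackConfig) -> GenomeTracks:
    """Generate ATAC/H3K27ac/CCV tracks with planted positive loci."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pad = int(config.peak_width_mean + 4 * config.peak_width_sd) + 600

    def bed(starts: np.ndarray, widths: np.ndarray, prefix: str) -> pd.DataFrame:
        starts = np.clip(starts, 0, np.maximum(config.length - widths, 0))
        df = pd.DataFrame(
            {
                "contig": config.contig,
                "start": starts.astype(np.int64),
                "end": (starts + widths).astype(np.int64),
            }
        )
        df = df.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
        df["peak_id"] = [f"{prefix}_{i + 1:04d}" for i in range(len(df))]
        return df

    n_planted = int(round(config.fraction_planted * config.n_atac_peaks))
    n_planted = min(n_planted, config.n_ccvs, config.n_h3k27ac_peaks)

    atac_starts = rng.integers(pad, max(config.length - pad, pad + 1), size=config.n_atac_peaks)
    atac_w = _widths(rng, config, config.n_atac_peaks)
    atac = bed(atac_starts, atac_w, "ATAC")

    planted_rows = rng.choice(len(atac), size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    planted = atac.iloc[np.sort(planted_rows)].reset_index(drop=True)

    # H3K27ac: one overlapping peak per planted ATAC peak, remainder random.
    k_starts, k_widths = [], []
    k_w_planted = _widths(rng, config, n_planted)
    for (_, row), w in zip(planted.iterrows(), k_w_planted):
        center = (row["start"] + row["end"]) // 2
        k_starts.append(max(center - int(w) // 2, 0))
        k_widths.append(w)
    n_rest = config.n_h3k27ac_peaks - n_planted
    if n_rest > 0:
        k_starts.extend(rng.integers(0, config.length, size=n_rest).tolist())
        k_widths.extend(_widths(rng, config, n_rest).tolist())
    h3k27ac = bed(np.asarray(k_starts, dtype=np.int64), np.asarray(k_widths, dtype=np.int64), "K27")

    # CCVs: one inside each planted peak's 1-kb window, remainder random points.
    ccv_pos = []
    for _, row in planted.iterrows():
        center = (row["start"] + row["end"]) // 2
        ccv_pos.append(int(rng.integers(center - 450, center + 450)))
    n_rest = config.n_ccvs - n_planted
    if n_rest > 0:
        ccv_pos.extend(rng.integers(0, config.length, size=n_rest).tolist())
    ccv_pos_arr = np.sort(np.clip(np.asarray(ccv_pos, dtype=np.int64), 0, config.length - 1))
    ccvs = pd.DataFrame(
        {
            "contig": config.contig,
            "start": ccv_pos_arr,
            "end": ccv_pos_arr + 1,
            "ccv_id": [f"rs{i + 1:05d}" for i in range(len(ccv_pos_arr))],
        }
    )
    return GenomeTracks(atac=atac, h3k27ac=h3k27ac, ccvs=ccvs, planted=planted)
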