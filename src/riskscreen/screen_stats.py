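"""Per-screen statistics: normalization, sgRNA log2 fold changes, and a
negative-control-based gene-level test with Benjamini–Hochberg FDR.

The gene statistic is the median of its sgRNAs' log2 fold changes; its
empirical null is built by resampling same-size sgRNA sets from the
negative-control guides, with the add-one rule so p-values are never zero.
Two-sided p = 2 * min(p_enriched, p_depleted), capped at 1, then BH-adjusted
per screen across genes — the scale the downstream hit thresholds
(-log10[FDR] > 1) consume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .library import SgRNALibrary
from .screens import ScreenContrast, ScreenCountMatrix

MIN_NEGCTRL_FOR_NORM = 10
DEFAULT_MIN_CONTROLS = 100
EXACT_ENUMERATION_CAP = 500_000
#: scaled abundance of the median negative control after normalization; a
#: data-independent anchor makes gene results exactly invariant to
#: rescaling any single sample's counts
NOMINAL_CONTROL_ABUNDANCE = 100.0


def normalize_counts(
    counts: ScreenCountMatrix | pd.DataFrame,
    method: str = "negctrl_median",
    negative_controls: pd.Index | list[str] | None = None,
    min_controls: int = MIN_NEGCTRL_FOR_NORM,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale counts by per-sample size factors.

    ``negctrl_median`` derives each sample's size factor from the median
    count of its negative-control sgRNAs, anchored so the median scaled
    control abundance equals ``NOMINAL_CONTROL_ABUNDANCE`` in every sample —
    depth shifts cancel exactly and a small pseudocount stays small relative
    to typical abundances. ``total`` uses the sample sum scaled to the mean
    total. Returns (scaled abundance, size factors).
    """
    mat = counts.counts if isinstance(counts, ScreenCountMatrix) else counts
    zero = mat.columns[(mat.sum(axis=0) == 0)]
    if len(zero):
        raise ValueError(f"samples with all-zero counts: {list(zero)}")
    if method == "negctrl_median":
        if negative_controls is None:
            raise ValueError("negctrl_median normalization requires negative-control ids")
        ctrl = pd.Index(negative_controls).intersection(mat.index)
        if len(ctrl) < min_controls:
            raise ValueError(
                f"need >= {min_controls} negative-control sgRNAs, got {len(ctrl)}"
            )
        medians = mat.loc[ctrl].median(axis=0)
        bad = medians.index[medians <= 0]
        if len(bad):
            raise ValueError(f"non-positive control-median size factor in samples: {list(bad)}")
        factors = medians / NOMINAL_CONTROL_ABUNDANCE
    elif method == "total":
        totals = mat.sum(axis=0).astype(float)
        factors = totals / totals.mean()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return mat / factors, factors.astype(float)


def sgrna_lfc(
    scaled: pd.DataFrame,
    contrast: ScreenContrast,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-sgRNA log2 fold change of the contrast's endpoint vs reference."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ref = scaled[contrast.reference_id].to_numpy(dtype=float)
    end = scaled[contrast.endpoint_id].to_numpy(dtype=float)
    if pseudocount == 0 and (np.any(ref == 0) or np.any(end == 0)):
        raise ValueError("zero scaled counts require a positive pseudocount")
    lfc = np.log2(end + pseudocount) - np.log2(ref + pseudocount)
    return pd.Series(lfc, index=scaled.index, name=contrast.screen_id)


@dataclass
class ScreenQCReport:
    """Outcome of screen-level QC against control expectations."""

    passed: bool | None  # None = not evaluable
    essential_median_lfc: float | None
    negctrl_median_lfc: float | None
    messages: list[str]


def _null_medians_resampled(
    rng: np.random.Generator, ctrl: np.ndarray, k: int, n_resample: int
) -> np.ndarray:
    draws = rng.choice(ctrl, size=(n_resample, k), replace=True)
    return np.median(draws, axis=1)


def _null_medians_exact(ctrl: np.ndarray, k: int) -> np.ndarray:
    if len(ctrl) ** k > EXACT_ENUMERATION_CAP:
        raise ValueError("null pool too large for exact enumeration")
    return np.array([np.median(t) for t in itertools.product(ctrl, repeat=k)])


def gene_score(
    lfc: pd.Series,
    library: SgRNALibrary,
    n_resample: int = 1000,
    seed: int = 0,
    min_controls: int = DEFAULT_MIN_CONTROLS,
    exact: bool = False,
    screen_id: str | None = None,
) -> pd.DataFrame:
    """Gene-level log2 fold change, empirical p-values and BH FDR.

    For each gene, the observed statistic is the median LFC of its usable
    sgRNAs; the null is the distribution of medians of same-size draws (with
    replacement) from the negative-control sgRNA LFCs — exhaustively
    enumerated when ``exact`` is set, resampled ``n_resample`` times
    otherwise. Ties with the observed value count as extreme (>= / <=), the
    conservative convention. Genes without any usable sgRNA are flagged
    missing (NaN p, excluded from the BH adjustment).
    """
    rng = np.random.default_rng(seed)
    ctrl_ids = library.negative_control_ids.intersection(lfc.index)
    ctrl = lfc.loc[ctrl_ids].dropna().to_numpy(dtype=float)
    if not exact and len(ctrl) < min_controls:
        raise ValueError(f"need >= {min_controls} negative-control sgRNAs, got {len(ctrl)}")
    if exact and len(ctrl) == 0:
        raise ValueError("no negative-control sgRNAs for the empirical null")

    targeting = library.sgrnas[library.sgrnas["target_type"] == "gene"]
    groups = targeting.groupby("target_id")["sgrna_id"]

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for gene_id, ids in groups:
        vals = lfc.reindex(ids).dropna().to_numpy(dtype=float)
        k = len(vals)
        if k == 0:
            rows.append((gene_id, np.nan, np.nan, np.nan, np.nan, 0, True))
            continue
        if exact:
            # the exhaustive null depends only on the draw size, so cache it
            if k not in null_cache:
                null_cache[k] = _null_medians_exact(ctrl, k)
            null = null_cache[k]
        else:
            # an independent null per gene keeps p-values independent across
            # genes (a shared realized null would correlate them)
            null = _null_medians_resampled(rng, ctrl, k, n_resample)
        obs = float(np.median(vals))
        n_null = len(null)
        p_enr = (1 + int(np.sum(null >= obs))) / (1 + n_null)
        p_dep = (1 + int(np.sum(null <= obs))) / (1 + n_null)
        p_two = min(1.0, 2.0 * min(p_enr, p_dep))
        rows.append((gene_id, obs, p_enr, p_dep, p_two, k, False))

    out = pd.DataFrame(
        rows,
        columns=["gene_id", "gene_lfc", "p_enriched", "p_depleted", "p_two_sided", "n_sgrnas", "missing"],
    )
    out["fdr"] = np.nan
    usable = ~out["missing"]
    if usable.any():
        out.loc[usable, "fdr"] = multipletests(out.loc[usable, "p_two_sided"], method="fdr_bh")[1]
    out.insert(1, "screen_id", screen_id or getattr(lfc, "name", None) or "")
    return out


def score_all_screens(
    counts: ScreenCountMatrix,
    library: SgRNALibrary,
    n_resample: int = 1000,
    seed: int = 0,
    pseudocount: float = 0.5,
    method: str = "negctrl_median",
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Run normalization -> LFC -> gene test over every contrast in a screen set.

    Returns the concatenated gene-result table and the per-screen sgRNA LFC
    vectors (used by QC and the confound flagging).
    """
    scaled, _ = normalize_counts(counts, method=method, negative_controls=library.negative_control_ids)
    results, lfcs = [], {}
    for j, contrast in enumerate(counts.contrasts()):
        lfc = sgrna_lfc(scaled, contrast, pseudocount=pseudocount)
        lfcs[contrast.screen_id] = lfc
        res = gene_score(
            lfc, library, n_resample=n_resample, seed=seed + j, screen_id=contrast.screen_id
        )
        res["modality"] = contrast.modality
        res["assay"] = contrast.assay
        res["cell_line"] = contrast.cell_line
        results.append(res)
    table = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    return table, lfcs


def qc_screen(
    results: pd.DataFrame,
    library: SgRNALibrary,
    modality: str,
    control_lfc: pd.Series | None = None,
    negctrl_tolerance: float = 0.2,
) -> ScreenQCReport:
    """Check a screen against its control expectations.

    Suppression screens (ko/i) must deplete core-essential genes (median
    essential gene LFC < 0); activation screens carry no such requirement.
    Negative controls must sit near zero (|median| <= tolerance), evaluated
    from the sgRNA-level LFCs of the control guides when provided.
    """
    messages: list[str] = []
    essential = library.genes.loc[library.genes["category"] == "essential", "gene_id"]
    ess_res = results[results["gene_id"].isin(set(essential))]
    if len(essential) == 0 or ess_res.empty:
        return ScreenQCReport(None, None, None, ["no essential-gene annotations; not evaluable"])
    ess_median = float(ess_res["gene_lfc"].median())

    nc_median = None
    if control_lfc is not None:
        ctrl_ids = library.negative_control_ids.intersection(control_lfc.index)
        if len(ctrl_ids):
            # pseudo-genes: consecutive control guides grouped in fives
            vals = control_lfc.loc[ctrl_ids].dropna().to_numpy(dtype=float)
            n_groups = max(1, len(vals) // 5)
            pseudo = [np.median(g) for g in np.array_split(vals[: n_groups * 5], n_groups)]
            nc_median = float(np.median(pseudo))

    passed = True
    if modality in ("ko", "i") and ess_median >= 0:
        passed = False
        messages.append(
            f"essential genes not depleted under {modality} (median LFC {ess_median:.3f} >= 0)"
        )
    if nc_median is not None and abs(nc_median) > negctrl_tolerance:
        passed = False
        messages.append(
            f"negative-control pseudo-gene median LFC {nc_median:.3f} exceeds tolerance {negctrl_tolerance}"
        )
    return ScreenQCReport(passed, ess_median, nc_median, messages)
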