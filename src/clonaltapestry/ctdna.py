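"""Detection of tumour mutations in plasma cell-free DNA counts.

Each assayed site is tested with a one-sided exact binomial test of the
variant-read count against the sequencing-error background; p-values are
adjusted per patient panel with Benjamini–Hochberg and sites with q below
the FDR threshold are called detected.  The module also computes the
minimum allelic ratio detectable at a given depth and a one-sided Fisher
test for enrichment of ancestral-clone mutations among the detected sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DetectionSummary",
    "binomial_detection_test",
    "fdr_adjust",
    "min_detectable_ratio",
    "ancestral_enrichment",
    "detect_ctdna",
]


@dataclass
class DetectionSummary:
    n_assayed: int
    n_covered: int
    n_detected: int
    min_detectable_ratio: float
    enrichment_p: float


def binomial_detection_test(var_count, depth, error_rate: float):
    """One-sided upper-tail exact binomial p, P(X >= var | depth, error).

    Vectorized; sites with depth 0 get NaN (no coverage, excluded from
    testing).
    """
    if not (0 < error_rate < 1):
        raise ValueError("error_rate must be in (0, 1)")
    var = np.asarray(var_count)
    n = np.asarray(depth)
    if np.any(var < 0) or np.any(n < 0):
        raise ValueError("negative counts")
    p = stats.binom.sf(var - 1, np.maximum(n, 1), error_rate)
    p = np.where(n >= 1, p, np.nan)
    if p.ndim == 0:
        return float(p)
    return p


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def min_detectable_ratio(depth: int, error_rate: float, alpha: float = 0.05) -> float:
    """Smallest k/depth whose exact tail P(X >= k) falls below alpha.

    k is at least 1 (a site with zero variant reads is never detected).
    If no k <= depth is significant the ratio saturates at 1.0.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    k0 = int(stats.binom.isf(min(alpha, 1 - 1e-12), depth, error_rate))
    for k in range(max(1, k0 - 2), depth + 1):
        if stats.binom.sf(k - 1, depth, error_rate) < alpha:
            return k / depth
    warnings.warn("no variant count is significant at this depth; ratio = 1.0")
    return 1.0


def ancestral_enrichment(detected, ancestral) -> float:
    """One-sided Fisher exact test: are detected mutations enriched for the
    ancestral clone?

    The 2x2 table is {detected, not} x {ancestral, not} over covered
    mutations; the p-value is the upper hypergeometric tail.  A zero margin
    makes the test degenerate and returns p = 1.
    """
    det = np.asarray(detected, dtype=bool)
    anc = np.asarray(ancestral, dtype=bool)
    if det.shape != anc.shape:
        raise ValueError("detected and ancestral flags differ in length")
    a = int(np.sum(det & anc))
    b = int(np.sum(det & ~anc))
    c = int(np.sum(~det & anc))
    d = int(np.sum(~det & ~anc))
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def detect_ctdna(
    plasma_counts: pd.DataFrame,
    ancestral_mutations: set[str] | None = None,
    error_rate: float = 0.001,
    fdr: float = 0.05,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, DetectionSummary]:
    """Run the full plasma detection analysis for one patient panel.

    plasma_counts: count table (mutation_id, ref_count, var_count, ...) for
    the plasma pseudo-sample.  Returns the per-mutation result table and a
    summary with the minimum detectable allelic ratio (at the panel's median
    covered depth, unadjusted alpha) and the ancestral-enrichment p-value.
    """
    tbl = plasma_counts.copy()
    tbl["depth"] = tbl["ref_count"] + tbl["var_count"]
    tbl["covered"] = tbl["depth"] >= 1
    tbl["allelic_ratio"] = np.where(
        tbl["covered"], tbl["var_count"] / tbl["depth"].replace(0, np.nan), np.nan
    )
    tbl["p_value"] = binomial_detection_test(tbl["var_count"], tbl["depth"], error_rate)
    covered = tbl["covered"].to_numpy()
    q = np.full(len(tbl), np.nan)
    if covered.any():
        q[covered] = fdr_adjust(tbl.loc[covered, "p_value"])
    tbl["q_value"] = q
    tbl["detected"] = tbl["covered"] & (tbl["q_value"] < fdr)
    if ancestral_mutations is not None:
        tbl["ancestral"] = tbl["mutation_id"].isin(ancestral_mutations)

    if covered.any():
        median_depth = int(tbl.loc[tbl["covered"], "depth"].median())
        mdr = min_detectable_ratio(median_depth, error_rate, alpha)
    else:
        mdr = 1.0
    if ancestral_mutations is not None and covered.any():
        enr = ancestral_enrichment(
            tbl.loc[tbl["covered"], "detected"], tbl.loc[tbl["covered"], "ancestral"]
        )
    else:
        enr = np.nan
    summary = DetectionSummary(
        n_assayed=len(tbl),
        n_covered=int(covered.sum()),
        n_detected=int(tbl["detected"].sum()),
        min_detectable_ratio=mdr,
        enrichment_p=enr,
    )
    return tbl, summary
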