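"""Cellular-frequency estimation and intra-sample clonal-diversity scoring.

The estimator converts an observed allelic ratio into the fraction of cells
carrying the mutation, correcting for tumour content and local copy number:

    phi = vaf * (c_n * (1 - t) + c_t * t) / (t * m)

with t the tumour content, c_t / c_n the tumour / normal total copy numbers
at the locus and m the mutation multiplicity.  It is a deterministic
single-site stand-in for full Dirichlet-process clustering of mutations.
Diversity within a sample is scored as the interquartile range of its
cellular frequencies (linear-interpolation, "type-7", quantiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityScore",
    "cellular_frequency",
    "diversity_iqr",
    "estimate_frequencies",
    "diversity_by_sample",
]


@dataclass
class DiversityScore:
    sample_id: str
    iqr: float
    n_mutations: int
    low_confidence: bool  # fewer than 4 frequencies


def cellular_frequency(vaf, t, c_t=2, c_n=2, m=1):
    """Copy-number- and purity-adjusted cellular frequency, clamped to [0, 1].

    Vectorized over vaf / c_t / m.  Raises for t <= 0 (undefined purity).
    """
    t = float(t)
    if t <= 0 or t > 1:
        raise ValueError("tumour content t must lie in (0, 1]")
    vaf = np.asarray(vaf, dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("vaf must lie in [0, 1]")
    c_t = np.asarray(c_t, dtype=float)
    m_arr = np.asarray(m, dtype=float)
    if np.any(c_t < 1):
        raise ValueError("tumour copy number must be >= 1")
    if np.any((m_arr < 1) | (m_arr > c_t)):
        raise ValueError("multiplicity must satisfy 1 <= m <= c_t")
    phi = vaf * (c_n * (1.0 - t) + c_t * t) / (t * m_arr)
    phi = np.clip(phi, 0.0, 1.0)
    if phi.ndim == 0:
        return float(phi)
    return phi


def diversity_iqr(frequencies, sample_id: str = "") -> DiversityScore:
    """Interquartile range of cellular frequencies (type-7 quantiles)."""
    arr = np.asarray(list(frequencies), dtype=float)
    if arr.size == 0:
        raise ValueError("no frequencies supplied")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation = type 7
    return DiversityScore(
        sample_id=sample_id,
        iqr=float(q3 - q1),
        n_mutations=int(arr.size),
        low_confidence=arr.size < 4,
    )


def _site_copy_number(segments: pd.DataFrame | None, chrom, pos) -> int:
    if segments is None:
        return 2
    hit = segments[
        (segments["chrom"] == chrom) & (segments["start"] <= pos) & (pos < segments["end"])
    ]
    if len(hit) == 0:
        return -1  # gap sentinel
    return int(hit.iloc[0]["major_cn"] + hit.iloc[0]["minor_cn"])


def estimate_frequencies(
    matrix,
    tumour_content: dict[str, float],
    segments: dict[str, pd.DataFrame] | None = None,
    c_n: int = 2,
    m: int = 1,
    present_only: bool = True,
) -> pd.DataFrame:
    """Per-(mutation, sample) cellular frequencies from a presence matrix.

    tumour_content maps sample -> t.  segments optionally maps sample -> an
    allele-specific segment profile used to look up the local tumour copy
    number; sites falling in coverage gaps (or with no profile) default to
    c_t = 2 with a warning.  With present_only, only PRESENT calls are
    estimated (absent sites carry no mutation to place in a clone).
    """
    rows = []
    gap_sites = 0
    for sample in matrix.samples:
        if sample not in tumour_content:
            raise ValueError(f"no tumour content for sample {sample!r}")
        t = tumour_content[sample]
        seg = segments.get(sample) if segments else None
        for mut in matrix.mutations:
            call = matrix.calls.loc[mut, sample]
            if present_only and call != "P":
                continue
            vaf = matrix.vaf.loc[mut, sample]
            if np.isnan(vaf):
                continue
            chrom, pos = matrix.loci.loc[mut, "chrom"], matrix.loci.loc[mut, "pos"]
            c_t = _site_copy_number(seg, chrom, pos)
            if c_t < 1:
                gap_sites += 1
                c_t = 2
            mult = min(m, c_t)
            rows.append(
                {
                    "mutation_id": mut,
                    "sample_id": sample,
                    "vaf": float(vaf),
                    "tumour_content": t,
                    "c_t": c_t,
                    "multiplicity": mult,
                    "phi": cellular_frequency(vaf, t, c_t, c_n, mult),
                }
            )
    if gap_sites:
        warnings.warn(f"{gap_sites} sites outside segment coverage; assumed diploid")
    return pd.DataFrame(rows)


def diversity_by_sample(frequencies: pd.DataFrame) -> pd.DataFrame:
    """Per-sample IQR diversity from an estimate_frequencies table."""
    rows = []
    for sample, sub in frequencies.groupby("sample_id"):
        score = diversity_iqr(sub["phi"], sample_id=str(sample))
        rows.append(
            {
                "sample_id": score.sample_id,
                "iqr": score.iqr,
                "n_mutations": score.n_mutations,
                "low_confidence": score.low_confidence,
            }
        )
    return pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
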