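"""Allele-specific copy-number zygosity states and compound-event analysis.

Segments carry integer allele-specific copies (major >= minor >= 0).  States
that require at least two sequential events (copy-neutral LOH, amplified LOH)
are the "compound" classes; integer weights over genes feed a
Euclidean-distance neighbour-joining tree of genome architectures, and an
allele-wise comparison of two samples detects the whole-genome-doubling
signature (hemizygous deletion -> NLOH, diploid heterozygous -> 2+2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .phylo import CONTROL_LABEL, DistanceMatrix, PhyloTree, neighbour_joining

SEGMENT_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn"]

__all__ = [
    "ZygosityState",
    "COMPOUND_WEIGHTS",
    "DoublingEvidence",
    "classify_zygosity",
    "classify_segments",
    "compound_weight",
    "compound_fraction",
    "project_to_genes",
    "gene_weight_matrix",
    "cna_distance_tree",
    "pairwise_state_concordance",
    "intersect_segmentations",
    "detect_doubling",
]


class ZygosityState(str, Enum):
    HOMD = "HOMD"    # (0,0) homozygous deletion
    HEMD = "HEMD"    # (1,0) hemizygous deletion
    HET = "HET"      # (1,1) diploid heterozygous
    NLOH = "NLOH"    # (2,0) copy-neutral LOH
    ALOH = "ALOH"    # (>=3,0) amplified LOH
    ASCNA = "ASCNA"  # allele-specific amplification, minor >= 1
    BCNA = "BCNA"    # balanced amplification (m,m), m >= 2


#: Integer weights over genes for the architecture tree: the compound
#: classes (two sequential events) and homozygous deletion score 2,
#: a single deletion scores 1, everything without LOH scores 0.
COMPOUND_WEIGHTS: dict[ZygosityState, int] = {
    ZygosityState.ALOH: 2,
    ZygosityState.NLOH: 2,
    ZygosityState.HOMD: 2,
    ZygosityState.HEMD: 1,
    ZygosityState.HET: 0,
    ZygosityState.ASCNA: 0,
    ZygosityState.BCNA: 0,
}


def classify_zygosity(major: int, minor: int) -> ZygosityState:
    """Total classification of an (major, minor) allele-specific state."""
    major, minor = int(major), int(minor)
    if minor > major:
        raise ValueError(f"minor copy number {minor} exceeds major {major}")
    if minor < 0:
        raise ValueError("copy numbers must be non-negative")
    if minor == 0:
        if major == 0:
            return ZygosityState.HOMD
        if major == 1:
            return ZygosityState.HEMD
        if major == 2:
            return ZygosityState.NLOH
        return ZygosityState.ALOH
    if major == 1:  # minor == 1
        return ZygosityState.HET
    if major == minor:
        return ZygosityState.BCNA
    return ZygosityState.ASCNA


def classify_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a segment table with 'state' and 'weight' columns."""
    segments = validate_segments(segments)
    states = [
        classify_zygosity(ma, mi)
        for ma, mi in zip(segments["major_cn"], segments["minor_cn"])
    ]
    out = segments.copy()
    out["state"] = [s.value for s in states]
    out["weight"] = [COMPOUND_WEIGHTS[s] for s in states]
    return out


def compound_weight(state: ZygosityState | str) -> int:
    return COMPOUND_WEIGHTS[ZygosityState(state)]


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    if (segments["end"] <= segments["start"]).any():
        raise ValueError("segments must satisfy end > start (0-based half-open)")
    if (segments["minor_cn"] > segments["major_cn"]).any():
        raise ValueError("minor_cn exceeds major_cn")
    if (segments["minor_cn"] < 0).any():
        raise ValueError("negative copy numbers")
    seg = segments.sort_values(["chrom", "start"]).reset_index(drop=True)
    prev_end = seg.groupby("chrom")["end"].shift()
    if (seg["start"] < prev_end.fillna(-1)).any():
        raise ValueError("overlapping segments within a chromosome")
    return seg


def compound_fraction(segments: pd.DataFrame) -> float:
    """Fraction of the assessable genome in a compound state (NLOH or ALOH).

    The assessable genome is the total length covered by the profile's
    segments.  Homozygous deletions contribute to gene weights but not to
    this statistic.
    """
    if len(segments) == 0:
        warnings.warn("empty segment profile; compound fraction is 0")
        return 0.0
    seg = classify_segments(segments)
    lengths = seg["end"] - seg["start"]
    total = lengths.sum()
    compound = lengths[seg["state"].isin([ZygosityState.NLOH.value, ZygosityState.ALOH.value])].sum()
    return float(compound / total)


def project_to_genes(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene the state of the segment containing its midpoint.

    genes: DataFrame with gene_id, chrom, start, end (0-based half-open).
    Genes whose midpoint falls in a coverage gap are returned with NaN
    copy numbers and state "unassessed".
    """
    seg = classify_segments(segments)
    rows = []
    for chrom, gsub in genes.groupby("chrom"):
        ssub = seg[seg["chrom"] == chrom]
        starts = ssub["start"].to_numpy()
        ends = ssub["end"].to_numpy()
        for _, g in gsub.iterrows():
            mid = (g["start"] + g["end"]) // 2
            hit = np.flatnonzero((starts <= mid) & (mid < ends))
            if hit.size == 0:
                rows.append(
                    {"gene_id": g["gene_id"], "major_cn": np.nan, "minor_cn": np.nan,
                     "state": "unassessed", "weight": np.nan}
                )
            else:
                s = ssub.iloc[hit[0]]
                rows.append(
                    {"gene_id": g["gene_id"], "major_cn": s["major_cn"],
                     "minor_cn": s["minor_cn"], "state": s["state"], "weight": s["weight"]}
                )
    return pd.DataFrame(rows).set_index("gene_id").loc[genes["gene_id"]]


def gene_weight_matrix(profiles: dict[str, pd.DataFrame], genes: pd.DataFrame) -> pd.DataFrame:
    """Samples x genes matrix of compound-event weights.

    Genes unassessed in any sample are dropped so all samples share a gene
    universe.
    """
    per_sample = {s: project_to_genes(seg, genes)["weight"] for s, seg in profiles.items()}
    mat = pd.DataFrame(per_sample).T  # samples x genes
    mat = mat.dropna(axis=1)
    return mat


def cna_distance_tree(weights: pd.DataFrame) -> tuple[DistanceMatrix, PhyloTree]:
    """Euclidean-distance neighbour-joining tree over gene weight vectors.

    A control sample of all-zero weights (an unaberrated genome) is appended
    before computing distances; it acts as the root on serialization.
    """
    if weights.shape[1] == 0:
        raise ValueError("empty gene universe")
    if weights.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if CONTROL_LABEL in weights.index:
        raise ValueError(f"a sample is already named {CONTROL_LABEL!r}")
    full = pd.concat(
        [weights, pd.DataFrame([np.zeros(weights.shape[1])], index=[CONTROL_LABEL],
                               columns=weights.columns)]
    )
    d = squareform(pdist(full.to_numpy(dtype=float), metric="euclidean"))
    dm = DistanceMatrix(d, [str(i) for i in full.index])
    return dm, neighbour_joining(dm)


def pairwise_state_concordance(
    profile_a: pd.DataFrame, profile_b: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Gene counts by (total CN in A, total CN in B, same zygosity status).

    Zygosity is collapsed to LOH (minor = 0) versus heterozygous (minor >= 1);
    the counts back the dot-plot comparison of two genome architectures.
    Genes unassessed in either profile are excluded.
    """
    a = project_to_genes(profile_a, genes)
    b = project_to_genes(profile_b, genes)
    ok = (a["state"] != "unassessed") & (b["state"] != "unassessed")
    a, b = a[ok], b[ok]
    tbl = pd.DataFrame(
        {
            "cn_a": (a["major_cn"] + a["minor_cn"]).astype(int),
            "cn_b": (b["major_cn"] + b["minor_cn"]).astype(int),
            "same_zygosity": (a["minor_cn"] == 0) == (b["minor_cn"] == 0),
        }
    )
    out = (
        tbl.groupby(["cn_a", "cn_b", "same_zygosity"]).size().rename("n_genes").reset_index()
    )
    return out


def intersect_segmentations(ref: pd.DataFrame, test: pd.DataFrame) -> pd.DataFrame:
    """Intersect two segmentations on their common breakpoint grid.

    Returns chrom, start, end, ref_major, ref_minor, test_major, test_minor
    over the regions assessable in both profiles.
    """
    ref = validate_segments(ref)
    test = validate_segments(test)
    chroms = sorted(set(ref["chrom"]) & set(test["chrom"]))
    if not chroms:
        raise ValueError("profiles share no chromosomes")
    rows = []
    for chrom in chroms:
        r = ref[ref["chrom"] == chrom]
        t = test[test["chrom"] == chrom]
        cuts = np.unique(
            np.concatenate([r["start"], r["end"], t["start"], t["end"]])
        )
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mid = (lo + hi) // 2
            rhit = r[(r["start"] <= mid) & (mid < r["end"])]
            thit = t[(t["start"] <= mid) & (mid < t["end"])]
            if len(rhit) == 0 or len(thit) == 0:
                continue
            rows.append(
                {
                    "chrom": chrom, "start": int(lo), "end": int(hi),
                    "ref_major": int(rhit.iloc[0]["major_cn"]),
                    "ref_minor": int(rhit.iloc[0]["minor_cn"]),
                    "test_major": int(thit.iloc[0]["major_cn"]),
                    "test_minor": int(thit.iloc[0]["minor_cn"]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DoublingEvidence:
    """Per-chromosome whole-genome-doubling signal of test relative to ref."""

    per_chromosome: pd.DataFrame  # chrom, assessable, consistent, fraction, doubled
    threshold: float

    @property
    def n_doubled(self) -> int:
        return int(self.per_chromosome["doubled"].sum())


def detect_doubling(
    ref: pd.DataFrame, test: pd.DataFrame, threshold: float = 0.5
) -> DoublingEvidence:
    """Flag chromosomes whose test profile looks like a doubled ref profile.

    A region is doubling-consistent when the test state is the exact
    allele-wise doubling of the reference state, (m, n) -> (2m, 2n) with
    (m, n) != (0, 0); this covers the two diagnostic signatures, hemizygous
    deletion -> copy-neutral LOH and diploid heterozygous -> balanced 2+2.
    A chromosome is flagged doubled when the consistent fraction of its
    assessable length reaches `threshold`.
    """
    inter = intersect_segmentations(ref, test)
    if len(inter) == 0:
        raise ValueError("profiles share no assessable regions")
    length = inter["end"] - inter["start"]
    consistent = (
        (inter["test_major"] == 2 * inter["ref_major"])
        & (inter["test_minor"] == 2 * inter["ref_minor"])
        & ~((inter["ref_major"] == 0) & (inter["ref_minor"] == 0))
    )
    df = inter.assign(length=length, consistent_len=length.where(consistent, 0))
    per = (
        df.groupby("chrom")
        .agg(assessable=("length", "sum"), consistent=("consistent_len", "sum"))
        .reset_index()
    )
    per["fraction"] = per["consistent"] / per["assessable"]
    per["doubled"] = per["fraction"] >= threshold
    return DoublingEvidence(per_chromosome=per, threshold=threshold)
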