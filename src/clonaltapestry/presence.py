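"""Presence/absence calling from deep-amplicon read counts.

A mutation is called PRESENT in a sample when its variant-read count is
incompatible with the sequencing-error background (one-sided exact binomial
test), ABSENT when coverage is adequate but the test is not significant, and
INCONCLUSIVE when coverage is below the depth floor.  On top of the resulting
three-state matrix the module computes mutation-conservation statistics
(fraction of a case's mutations present in every sample) and the
ancestral / shared / private partition of mutations within a case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PRESENT = "P"
ABSENT = "A"
INCONCLUSIVE = "I"

COUNT_COLUMNS = ["mutation_id", "chrom", "pos", "sample_id", "ref_count", "var_count"]

__all__ = [
    "PRESENT",
    "ABSENT",
    "INCONCLUSIVE",
    "PresenceMatrix",
    "ConservationReport",
    "call_presence",
    "conservation_stats",
    "classify_mutations",
    "summarise_fractions",
]


@dataclass
class PresenceMatrix:
    """Three-state calls and allelic ratios, mutations x samples.

    calls : DataFrame of {"P", "A", "I"}
    vaf   : DataFrame of var/(ref+var); NaN where depth is 0
    depth : DataFrame of total read depth
    loci  : per-mutation (chrom, pos) metadata, indexed by mutation_id
    """

    calls: pd.DataFrame
    vaf: pd.DataFrame
    depth: pd.DataFrame
    loci: pd.DataFrame

    @property
    def mutations(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def to_frame(self) -> pd.DataFrame:
        """Compact text form: cells 'P:0.1234' / 'A:0.0002' / 'I'."""
        out = self.calls.copy()
        for s in out.columns:
            vafs = self.vaf[s]
            out[s] = [
                c if c == INCONCLUSIVE else f"{c}:{0.0 if np.isnan(v) else v:.6g}"
                for c, v in zip(self.calls[s], vafs)
            ]
        return out


@dataclass
class ConservationReport:
    """Per-group conservation fractions plus the cross-group summary."""

    per_group: pd.DataFrame  # group, n_mutations, n_ancestral, fraction_conserved
    mean: float
    sd: float
    categories: pd.DataFrame  # mutation_id, group, category


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts["ref_count"] < 0).any() or (counts["var_count"] < 0).any():
        raise ValueError("negative read counts")
    dup = counts.duplicated(subset=["mutation_id", "sample_id"])
    if dup.any():
        raise ValueError("duplicate (mutation, sample) pairs in count table")
    return counts


def call_presence(
    counts: pd.DataFrame,
    error_rate: float = 0.001,
    alpha: float = 0.01,
    min_depth: int = 50,
    min_var_reads: int = 5,
) -> PresenceMatrix:
    """Call presence/absence/inconclusive for every (mutation, sample) pair.

    PRESENT iff depth >= min_depth, var_count >= min_var_reads and the
    one-sided binomial tail P(X >= var_count | depth, error_rate) < alpha.
    ABSENT iff depth >= min_depth and the evidence falls short.
    INCONCLUSIVE iff depth < min_depth (including pairs missing from the
    table, which are treated as depth 0).
    """
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    counts = _validate_counts(counts)

    depth = counts["ref_count"] + counts["var_count"]
    var = counts["var_count"]
    # one-sided upper tail, exact
    pvals = stats.binom.sf(var - 1, depth.clip(lower=1), error_rate)
    significant = (pvals < alpha) & (var >= min_var_reads)
    call = np.where(
        depth < min_depth, INCONCLUSIVE, np.where(significant, PRESENT, ABSENT)
    )
    tbl = counts.assign(
        depth=depth,
        vaf=np.where(depth > 0, var / depth.replace(0, np.nan), np.nan),
        call=call,
    )
    calls = tbl.pivot(index="mutation_id", columns="sample_id", values="call").fillna(
        INCONCLUSIVE
    )
    vaf = tbl.pivot(index="mutation_id", columns="sample_id", values="vaf")
    dep = (
        tbl.pivot(index="mutation_id", columns="sample_id", values="depth")
        .fillna(0)
        .astype(int)
    )
    loci = (
        counts[["mutation_id", "chrom", "pos"]]
        .drop_duplicates("mutation_id")
        .set_index("mutation_id")
        .loc[calls.index]
    )
    return PresenceMatrix(calls=calls, vaf=vaf, depth=dep, loci=loci)


def _groups(matrix: PresenceMatrix, grouping: dict[str, str]) -> dict[str, list[str]]:
    unmapped = [s for s in matrix.samples if s not in grouping]
    if unmapped:
        raise ValueError(f"samples not mapped to a group: {unmapped}")
    groups: dict[str, list[str]] = {}
    for s in matrix.samples:
        groups.setdefault(grouping[s], []).append(s)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"empty group {g!r}")
    return groups


def classify_mutations(matrix: PresenceMatrix, grouping: dict[str, str]) -> pd.DataFrame:
    """Partition each group's mutations into ancestral / shared / private.

    Within a group (typically a case): ancestral = PRESENT in every evaluable
    sample (INCONCLUSIVE cells are not held against the mutation); private =
    PRESENT in exactly one sample; shared = PRESENT in >= 2 samples but not
    all evaluable.  Mutations never PRESENT in the group are reported as
    "undetected".
    """
    groups = _groups(matrix, grouping)
    rows = []
    for g, samples in sorted(groups.items()):
        sub = matrix.calls[samples]
        n_present = (sub == PRESENT).sum(axis=1)
        n_evaluable = (sub != INCONCLUSIVE).sum(axis=1)
        for mut in matrix.mutations:
            p, e = int(n_present[mut]), int(n_evaluable[mut])
            if p == 0:
                cat = "undetected"
            elif e > 0 and p == e:
                cat = "ancestral"
            elif p == 1:
                cat = "private"
            else:
                cat = "shared"
            rows.append({"mutation_id": mut, "group": g, "category": cat})
    return pd.DataFrame(rows)


def conservation_stats(matrix: PresenceMatrix, grouping: dict[str, str]) -> ConservationReport:
    """Fraction of each group's mutations conserved across all its samples.

    For each group the mutation universe is the set of mutations PRESENT in
    at least one sample of the group; the conserved (ancestral) subset is
    PRESENT in every evaluable sample.  Fractions are percentages; the
    summary is the mean and sample SD (n-1) over groups.
    """
    cats = classify_mutations(matrix, grouping)
    rows = []
    for g, sub in cats.groupby("group"):
        detected = sub[sub["category"] != "undetected"]
        n_univ = len(detected)
        n_anc = int((detected["category"] == "ancestral").sum())
        if n_univ == 0:
            warnings.warn(f"group {g!r} has no detected mutations")
            frac = np.nan
        else:
            frac = 100.0 * n_anc / n_univ
        rows.append(
            {"group": g, "n_mutations": n_univ, "n_ancestral": n_anc, "fraction_conserved": frac}
        )
    per_group = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    mean, sd = summarise_fractions(per_group["fraction_conserved"].dropna().to_numpy())
    return ConservationReport(per_group=per_group, mean=mean, sd=sd, categories=cats)


def summarise_fractions(fractions) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of a set of fractions."""
    arr = np.asarray(list(fractions), dtype=float)
    if arr.size == 0:
        return (np.nan, np.nan)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return (float(np.mean(arr)), sd)
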