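"""Readers/writers for the pipeline's plain-text formats.

Counts are TSV (mutation_id, chrom, pos, sample_id, ref_count, var_count);
segment profiles are BED-like TSV (chrom, start, end, major_cn, minor_cn;
0-based half-open); sample metadata is TSV (sample_id, group,
tumour_content); ground truth is JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .presence import COUNT_COLUMNS
from .cna import SEGMENT_COLUMNS
from .simulate import CloneTree, CNAEvent, SampleComposition

__all__ = [
    "read_counts",
    "write_counts",
    "read_segments",
    "write_segments",
    "read_metadata",
    "write_truth",
    "read_truth",
    "validate_inputs",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "chrom": str, "sample_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_segments(df: pd.DataFrame, path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df


def write_truth(tree: CloneTree, compositions: list[SampleComposition], path) -> None:
    payload = {
        "clones": tree.clones,
        "parent": tree.parent,
        "branch_mutations": tree.branch_mutations,
        "branch_cna_events": {
            c: [dataclasses.asdict(ev) for ev in evs]
            for c, evs in tree.branch_cna_events.items()
        },
        "wgd_clone": tree.wgd_clone,
        "mutation_loci": {m: list(l) for m, l in tree.mutation_loci.items()},
        "carriers": {m: sorted(tree.carriers(m)) for m in tree.mutations()},
        "compositions": [dataclasses.asdict(c) for c in compositions],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> tuple[CloneTree, list[SampleComposition]]:
    with open(path) as fh:
        payload = json.load(fh)
    tree = CloneTree(
        clones=payload["clones"],
        parent=payload["parent"],
        branch_mutations=payload["branch_mutations"],
        branch_cna_events={
            c: [CNAEvent(**ev) for ev in evs]
            for c, evs in payload["branch_cna_events"].items()
        },
        wgd_clone=payload["wgd_clone"],
        mutation_loci={m: tuple(l) for m, l in payload["mutation_loci"].items()},
    )
    comps = [SampleComposition(**c) for c in payload["compositions"]]
    return tree, comps


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Schema checks on input files; returns a machine-readable issue list.

    paths maps kind in {"counts", "segments", "metadata"} to a file path.
    Each issue is {"file", "severity" ("fatal"|"warning"), "message"}.
    """
    issues: list[dict] = []

    def fatal(path, msg):
        issues.append({"file": str(path), "severity": "fatal", "message": msg})

    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            fatal(p, "file does not exist")
            continue
        try:
            if kind == "counts":
                df = read_counts(p)
                if (df["ref_count"] < 0).any() or (df["var_count"] < 0).any():
                    fatal(p, "negative read counts")
                if df.duplicated(subset=["mutation_id", "sample_id"]).any():
                    fatal(p, "duplicate (mutation, sample) pairs")
                if (df["pos"] < 1).any():
                    fatal(p, "positions must be 1-based (>= 1)")
            elif kind == "segments":
                df = read_segments(p)
                if (df["end"] <= df["start"]).any():
                    fatal(p, "segment with end <= start")
                if (df["minor_cn"] > df["major_cn"]).any():
                    fatal(p, "minor_cn exceeds major_cn")
                if (df[["major_cn", "minor_cn"]] < 0).any().any():
                    fatal(p, "negative copy numbers")
            elif kind == "metadata":
                df = read_metadata(p)
                if "tumour_content" in df.columns and (
                    (df["tumour_content"] < 0) | (df["tumour_content"] > 1)
                ).any():
                    fatal(p, "tumour_content outside [0, 1]")
            else:
                fatal(p, f"unknown input kind {kind!r}")
        except Exception as exc:  # noqa: BLE001 - surfaced as an issue
            fatal(p, str(exc))
    return issues
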