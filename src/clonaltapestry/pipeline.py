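"""End-to-end orchestration: simulate -> presence -> phylo -> cna -> ctdna -> diversity.

Each stage is also callable on its own (see :mod:`clonaltapestry.cli`); the
orchestrator wires their file inputs/outputs together under one output
directory and records a manifest of parameters and output hashes so a run is
reproducible bit-for-bit from its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ctio
from .cna import (
    classify_segments,
    cna_distance_tree,
    compound_fraction,
    detect_doubling,
    gene_weight_matrix,
)
from .ctdna import detect_ctdna
from .phylo import neighbour_joining, profile_distance_matrix, write_newick
from .presence import PresenceMatrix, call_presence, conservation_stats
from .prevalence import diversity_by_sample, estimate_frequencies
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger("clonaltapestry")

ALL_STAGES = ["simulate", "presence", "phylo", "cna", "ctdna", "diversity"]

DEPENDENCIES = {
    "presence": ["counts", "metadata"],
    "phylo": ["presence_matrix"],
    "cna": ["segments"],
    "ctdna": ["plasma_counts", "presence_matrix"],
    "diversity": ["presence_matrix", "metadata"],
}


@dataclass
class PipelineConfig:
    outdir: str
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    presence: dict = field(default_factory=dict)
    phylo: dict = field(default_factory=dict)
    cna: dict = field(default_factory=dict)
    ctdna: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # pre-existing files for non-simulated runs

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(matrix: PresenceMatrix, path: Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="mutation_id")


def parse_matrix(path) -> PresenceMatrix:
    """Read the compact presence-matrix TSV (cells 'P:vaf'/'A:vaf'/'I')."""
    raw = pd.read_csv(path, sep="\t", index_col="mutation_id", dtype=str)
    calls = raw.map(lambda c: c.split(":")[0])
    vaf = raw.map(lambda c: float(c.split(":")[1]) if ":" in c else np.nan)
    loci = pd.DataFrame(index=calls.index, columns=["chrom", "pos"])
    depth = pd.DataFrame(0, index=calls.index, columns=calls.columns)
    return PresenceMatrix(calls=calls, vaf=vaf, depth=depth, loci=loci)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in ALL_STAGES if s in config.stages]

    artefacts: dict[str, object] = {}
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    # seed in-memory artefacts from pre-existing files
    if "counts" in config.inputs:
        artefacts["counts"] = ctio.read_counts(config.inputs["counts"])
    if "plasma_counts" in config.inputs:
        artefacts["plasma_counts"] = ctio.read_counts(config.inputs["plasma_counts"])
    if "metadata" in config.inputs:
        artefacts["metadata"] = ctio.read_metadata(config.inputs["metadata"])
    if "segments" in config.inputs:
        artefacts["segments"] = {
            sample: ctio.read_segments(path)
            for sample, path in config.inputs["segments"].items()
        }

    def require(stage: str) -> None:
        missing = [d for d in DEPENDENCIES.get(stage, []) if d not in artefacts]
        if missing:
            raise RuntimeError(
                f"stage {stage!r} is missing upstream artefacts: {missing} "
                f"(enable the producing stage or provide them under inputs)"
            )

    for stage in stages:
        t0 = time.monotonic()
        logger.info("stage %s: start", stage)

        if stage == "simulate":
            sim_cfg = SimulationConfig(**{"random_seed": config.seed, **config.simulate})
            result = simulate_all(sim_cfg)
            artefacts["counts"] = result["counts"]
            artefacts["plasma_counts"] = result["plasma_counts"]
            artefacts["segments"] = result["cna_profiles"]
            artefacts["truth"] = result
            meta = pd.DataFrame(
                {
                    "sample_id": [c.sample_id for c in result["compositions"]],
                    "group": "case",
                    "tumour_content": [c.tumour_content for c in result["compositions"]],
                }
            )
            artefacts["metadata"] = meta
            ctio.write_counts(result["counts"], outdir / "counts.tsv")
            ctio.write_counts(result["plasma_counts"], outdir / "plasma_counts.tsv")
            for sample, seg in result["cna_profiles"].items():
                ctio.write_segments(seg, outdir / f"segments_{sample}.tsv")
                outputs[f"segments_{sample}.tsv"] = outdir / f"segments_{sample}.tsv"
            meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
            ctio.write_truth(result["tree"], result["compositions"], outdir / "truth.json")
            outputs["counts.tsv"] = outdir / "counts.tsv"
            outputs["plasma_counts.tsv"] = outdir / "plasma_counts.tsv"
            outputs["metadata.tsv"] = outdir / "metadata.tsv"
            outputs["truth.json"] = outdir / "truth.json"

        elif stage == "presence":
            require(stage)
            matrix = call_presence(artefacts["counts"], **config.presence)
            artefacts["presence_matrix"] = matrix
            grouping = dict(
                zip(artefacts["metadata"]["sample_id"], artefacts["metadata"]["group"])
            )
            report = conservation_stats(matrix, grouping)
            _write_matrix(matrix, outdir / "presence_matrix.tsv")
            report.per_group.to_csv(outdir / "conservation.csv", index=False)
            with open(outdir / "conservation_summary.json", "w") as fh:
                json.dump({"mean": report.mean, "sd": report.sd}, fh, indent=1)
            report.categories.to_csv(outdir / "mutation_categories.csv", index=False)
            for name in (
                "presence_matrix.tsv",
                "conservation.csv",
                "conservation_summary.json",
                "mutation_categories.csv",
            ):
                outputs[name] = outdir / name

        elif stage == "phylo":
            require(stage)
            dm = profile_distance_matrix(
                artefacts["presence_matrix"], mode=config.phylo.get("mode", "vaf")
            )
            tree = neighbour_joining(dm)
            dm.to_frame().to_csv(outdir / "snv_distance.tsv", sep="\t")
            write_newick(tree, outdir / "snv_tree.nwk")
            outputs["snv_distance.tsv"] = outdir / "snv_distance.tsv"
            outputs["snv_tree.nwk"] = outdir / "snv_tree.nwk"

        elif stage == "cna":
            require(stage)
            segments: dict[str, pd.DataFrame] = artefacts["segments"]
            states = pd.concat(
                [classify_segments(seg).assign(sample_id=s) for s, seg in segments.items()],
                ignore_index=True,
            )
            states.to_csv(outdir / "cna_states.csv", index=False)
            fracs = pd.DataFrame(
                {
                    "sample_id": list(segments),
                    "compound_fraction": [compound_fraction(seg) for seg in segments.values()],
                }
            )
            fracs.to_csv(outdir / "compound_fractions.csv", index=False)
            genes = config.cna.get("genes")
            if genes is not None:
                genes = pd.read_csv(genes, sep="\t")
            else:
                genes = _grid_genes(segments)
            weights = gene_weight_matrix(segments, genes)
            dm, tree = cna_distance_tree(weights)
            dm.to_frame().to_csv(outdir / "cna_distance.tsv", sep="\t")
            write_newick(tree, outdir / "cna_tree.nwk")
            reference = config.cna.get("reference_sample")
            doubling_rows = []
            if reference is not None:
                for sample, seg in segments.items():
                    if sample == reference:
                        continue
                    ev = detect_doubling(
                        segments[reference], seg,
                        threshold=config.cna.get("doubling_threshold", 0.5),
                    )
                    doubling_rows.append(
                        {"sample_id": sample, "n_chromosomes_doubled": ev.n_doubled}
                    )
                pd.DataFrame(doubling_rows).to_csv(outdir / "doubling.csv", index=False)
                outputs["doubling.csv"] = outdir / "doubling.csv"
            for name in ("cna_states.csv", "compound_fractions.csv",
                         "cna_distance.tsv", "cna_tree.nwk"):
                outputs[name] = outdir / name

        elif stage == "ctdna":
            require(stage)
            matrix: PresenceMatrix = artefacts["presence_matrix"]
            grouping = dict(
                zip(artefacts["metadata"]["sample_id"], artefacts["metadata"]["group"])
            )
            report = conservation_stats(matrix, grouping)
            ancestral = set(
                report.categories.loc[
                    report.categories["category"] == "ancestral", "mutation_id"
                ]
            )
            results, summary = detect_ctdna(
                artefacts["plasma_counts"], ancestral_mutations=ancestral, **config.ctdna
            )
            results.to_csv(outdir / "ctdna_results.csv", index=False)
            with open(outdir / "ctdna_summary.json", "w") as fh:
                json.dump(
                    {
                        "n_assayed": summary.n_assayed,
                        "n_covered": summary.n_covered,
                        "n_detected": summary.n_detected,
                        "min_detectable_ratio": summary.min_detectable_ratio,
                        "enrichment_p": summary.enrichment_p,
                    },
                    fh,
                    indent=1,
                )
            outputs["ctdna_results.csv"] = outdir / "ctdna_results.csv"
            outputs["ctdna_summary.json"] = outdir / "ctdna_summary.json"

        elif stage == "diversity":
            require(stage)
            meta = artefacts["metadata"]
            tc = dict(zip(meta["sample_id"], meta.get("tumour_content", 1.0)))
            phi = estimate_frequencies(
                artefacts["presence_matrix"], tc,
                segments=artefacts.get("segments"), **config.diversity,
            )
            phi.to_csv(outdir / "cellular_frequencies.csv", index=False)
            diversity_by_sample(phi).to_csv(outdir / "diversity.csv", index=False)
            outputs["cellular_frequencies.csv"] = outdir / "cellular_frequencies.csv"
            outputs["diversity.csv"] = outdir / "diversity.csv"

        timings[stage] = time.monotonic() - t0
        logger.info("stage %s: done in %.2fs", stage, timings[stage])

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "parameters": {
            s: getattr(config, s) for s in ("simulate", "presence", "phylo", "cna", "ctdna", "diversity")
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _grid_genes(segments: dict[str, pd.DataFrame], spacing: int = 10_000_000) -> pd.DataFrame:
    """Default gene universe: fixed-width loci tiled over the covered genome.

    Used when no gene BED is supplied, so the architecture tree and the
    concordance table have a deterministic locus grid to project onto.
    """
    spans: dict[str, int] = {}
    for seg in segments.values():
        for chrom, sub in seg.groupby("chrom"):
            spans[chrom] = max(spans.get(chrom, 0), int(sub["end"].max()))
    rows = []
    for chrom in sorted(spans):
        for i, start in enumerate(range(0, spans[chrom], spacing)):
            end = min(start + spacing, spans[chrom])
            rows.append(
                {"gene_id": f"{chrom}_g{i}", "chrom": chrom, "start": start, "end": end}
            )
    return pd.DataFrame(rows)
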