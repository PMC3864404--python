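"""Clonal-evolution simulator.

Generates the ground truth and observable data every downstream stage
consumes: a clone phylogeny carrying a founder (TP53-like) mutation on the
root branch and branch-private mutations under infinite sites, regional
tumour samples drawn as sparse clone mixtures, deep-amplicon read counts
(negative-binomial depths around ~5000x with a sequencing-error floor),
per-clone allele-specific copy-number profiles with optional whole-genome
doubling, and a low-tumour-fraction plasma pseudo-sample.

All randomness derives from ``SimulationConfig.random_seed``; every operation
is a pure function of the configuration and its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLASMA_SAMPLE = "plasma"

#: 22 autosomes with round 1e8-scale lengths (Mb-rounded human-like genome).
DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i + 1}", mb * 1_000_000)
    for i, mb in enumerate(
        [248, 242, 198, 190, 182, 171, 159, 145, 138, 134,
         135, 133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51]
    )
)

__all__ = [
    "PLASMA_SAMPLE",
    "DEFAULT_GENOME",
    "CNAEvent",
    "CloneTree",
    "SampleComposition",
    "SimulationConfig",
    "simulate_clone_tree",
    "simulate_regions",
    "simulate_amplicon_counts",
    "simulate_cna_profiles",
    "simulate_ctdna",
    "simulate_all",
]


@dataclass(frozen=True)
class CNAEvent:
    """A segmental copy-number change on one parental allele.

    ``allele`` names the affected parental haplotype ("major" = haplotype A,
    "minor" = haplotype B, fixed labels independent of the current state);
    ``delta`` is the signed integer copy change.  ``is_wgd`` marks the
    genome-wide doubling pseudo-event.
    """

    chrom: str
    start: int
    end: int
    allele: str
    delta: int
    is_wgd: bool = False

    def __post_init__(self):
        if not self.is_wgd:
            if self.end <= self.start:
                raise ValueError("CNA event must satisfy end > start")
            if self.allele not in ("major", "minor"):
                raise ValueError("allele must be 'major' or 'minor'")


@dataclass
class CloneTree:
    """Ground-truth clone phylogeny.

    ``parent`` maps each clone to its parent (root maps to None).  Mutations
    and CNA events are attached to the branch leading into a clone; a
    mutation acquired on a branch is carried by that clone and all of its
    descendants (infinite sites, no back-mutation).
    """

    clones: list[str]
    parent: dict[str, str | None]
    branch_mutations: dict[str, list[str]]
    branch_cna_events: dict[str, list[CNAEvent]]
    wgd_clone: str | None = None
    mutation_loci: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        roots = [c for c in self.clones if self.parent.get(c) is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        # acyclicity: every clone must reach the root
        for c in self.clones:
            seen = set()
            while c is not None:
                if c in seen:
                    raise ValueError("cycle in parent relation")
                seen.add(c)
                c = self.parent[c]
        all_muts = [m for muts in self.branch_mutations.values() for m in muts]
        if len(all_muts) != len(set(all_muts)):
            raise ValueError("mutation ids must be unique across branches (infinite sites)")

    @property
    def root(self) -> str:
        return next(c for c in self.clones if self.parent[c] is None)

    def children(self, clone: str) -> list[str]:
        return [c for c in self.clones if self.parent[c] == clone]

    def descendants(self, clone: str) -> set[str]:
        """Clone plus all clones below it."""
        out = {clone}
        stack = [clone]
        while stack:
            for ch in self.children(stack.pop()):
                out.add(ch)
                stack.append(ch)
        return out

    def lineage(self, clone: str) -> list[str]:
        """Path root -> clone, inclusive."""
        path = []
        c: str | None = clone
        while c is not None:
            path.append(c)
            c = self.parent[c]
        return path[::-1]

    def mutations(self) -> list[str]:
        return [m for c in self.clones for m in self.branch_mutations.get(c, [])]

    def carriers(self, mutation: str) -> set[str]:
        for clone, muts in self.branch_mutations.items():
            if mutation in muts:
                return self.descendants(clone)
        raise KeyError(f"mutation {mutation!r} is on no branch")

    def ancestral_mutations(self) -> set[str]:
        """Mutations on the root branch, carried by every clone."""
        return set(self.branch_mutations.get(self.root, []))


@dataclass
class SampleComposition:
    sample_id: str
    clone_fractions: dict[str, float]
    tumour_content: float

    def __post_init__(self):
        total = sum(self.clone_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total}, not 1")
        if not (0 <= self.tumour_content <= 1):
            raise ValueError("tumour content must lie in [0, 1]")

    def dominant_clone(self) -> str:
        # ties broken by clone id for determinism
        return max(sorted(self.clone_fractions), key=lambda c: self.clone_fractions[c])


@dataclass(frozen=True)
class SimulationConfig:
    n_clones: int = 6
    n_samples: int = 6
    mutations_per_branch_mean: float = 10.0
    cna_events_per_branch_mean: float = 1.5
    wgd_clone: int | None = None  # clone index acquiring a whole-genome doubling
    depth_mean: float = 5000.0
    depth_dispersion: float = 10.0  # NB shape k: var = mu + mu^2 / k
    sequencing_error_rate: float = 0.001
    tumour_content: float = 0.7
    plasma_tumour_fraction: float = 0.1
    region_min_clones: int = 1
    region_max_clones: int = 3
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    random_seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mutations_per_branch_mean < 0 or self.cna_events_per_branch_mean < 0:
            raise ValueError("event means must be non-negative")
        for rate in (self.sequencing_error_rate, self.tumour_content, self.plasma_tumour_fraction):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not (1 <= self.region_min_clones <= self.region_max_clones):
            raise ValueError("invalid region sparsity range")
        if self.wgd_clone is not None and not (0 <= self.wgd_clone < self.n_clones):
            raise ValueError("wgd_clone out of range")
        if not self.genome:
            raise ValueError("genome must be non-empty")
        return self

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.random_seed), stage])


def _clone_id(i: int) -> str:
    return f"c{i}"


def _draw_locus(rng: np.random.Generator, genome) -> tuple[str, int]:
    chroms = [c for c, _ in genome]
    lengths = np.array([l for _, l in genome], dtype=float)
    ci = rng.choice(len(chroms), p=lengths / lengths.sum())
    pos = int(rng.integers(1, genome[ci][1] + 1))  # 1-based position
    return chroms[ci], pos


def _draw_cna_event(rng: np.random.Generator, genome) -> CNAEvent:
    # Mixture of focal events (exponential, ~10 Mb scale) and occasional
    # arm-to-chromosome-scale events, mirroring real segmental CNA spectra.
    chroms = [c for c, _ in genome]
    lengths = np.array([l for _, l in genome], dtype=float)
    ci = rng.choice(len(chroms), p=lengths / lengths.sum())
    chrom, clen = genome[ci]
    if rng.random() < 0.15:
        seg_len = int(rng.uniform(0.4, 1.0) * clen)  # arm / whole-chromosome
    else:
        seg_len = int(min(clen, 1_000_000 + rng.exponential(10_000_000)))  # focal
    seg_len = max(1, seg_len)
    start = int(rng.integers(0, clen - seg_len + 1))
    allele = "major" if rng.random() < 0.5 else "minor"
    delta = 1 if rng.random() < 0.5 else -1
    return CNAEvent(chrom=chrom, start=start, end=start + seg_len, allele=allele, delta=delta)


def simulate_clone_tree(config: SimulationConfig) -> CloneTree:
    """Random clone phylogeny with branch mutations and CNA events.

    Topology is a random recursive tree (each new clone attaches to a
    uniformly chosen existing clone).  Mutation counts per branch are
    Poisson(mutations_per_branch_mean); the root branch always carries at
    least one mutation, the founder (TP53-like) event.  CNA events per
    branch are Poisson(cna_events_per_branch_mean); ``config.wgd_clone``
    marks one clone as acquiring a whole-genome doubling on its branch.
    """
    config.validate()
    rng = config.rng(0)
    n = config.n_clones
    clones = [_clone_id(i) for i in range(n)]
    parent: dict[str, str | None] = {clones[0]: None}
    for i in range(1, n):
        parent[clones[i]] = clones[int(rng.integers(0, i))]

    branch_mutations: dict[str, list[str]] = {}
    loci: dict[str, tuple[str, int]] = {}
    counter = 0
    for i, clone in enumerate(clones):
        k = int(rng.poisson(config.mutations_per_branch_mean))
        if i == 0:
            k = max(1, k)  # founder mutation always present
        ids = [f"m{counter + j:04d}" for j in range(k)]
        counter += k
        branch_mutations[clone] = ids
        for mid in ids:
            loci[mid] = _draw_locus(rng, config.genome)

    branch_cna: dict[str, list[CNAEvent]] = {}
    wgd_clone = _clone_id(config.wgd_clone) if config.wgd_clone is not None else None
    for clone in clones:
        k = int(rng.poisson(config.cna_events_per_branch_mean))
        events = [_draw_cna_event(rng, config.genome) for _ in range(k)]
        if clone == wgd_clone:
            events.append(
                CNAEvent(chrom="*", start=0, end=0, allele="major", delta=0, is_wgd=True)
            )
        branch_cna[clone] = events

    return CloneTree(
        clones=clones,
        parent=parent,
        branch_mutations=branch_mutations,
        branch_cna_events=branch_cna,
        wgd_clone=wgd_clone,
        mutation_loci=loci,
    )


def simulate_regions(tree: CloneTree, config: SimulationConfig) -> list[SampleComposition]:
    """Regional samples as sparse Dirichlet clone mixtures.

    Each sample supports 1-3 clones (uniform support size within the
    configured range, clones chosen uniformly) with fractions drawn from a
    symmetric Dirichlet(1, ..., 1), so regional clone dominance varies.
    """
    config.validate()
    rng = config.rng(1)
    n_clones = len(tree.clones)
    out = []
    for s in range(config.n_samples):
        k_max = min(config.region_max_clones, n_clones)
        k_min = min(config.region_min_clones, k_max)
        k = int(rng.integers(k_min, k_max + 1))
        support = sorted(rng.choice(n_clones, size=k, replace=False).tolist())
        fracs = np.array([1.0]) if k == 1 else rng.dirichlet(np.ones(k))
        out.append(
            SampleComposition(
                sample_id=f"s{s}",
                clone_fractions={tree.clones[i]: float(f) for i, f in zip(support, fracs)},
                tumour_content=config.tumour_content,
            )
        )
    return out


def _expected_vaf(carrier_fraction: float, tumour_content: float,
                  multiplicity: int = 1, c_t: int = 2, c_n: int = 2) -> float:
    """E[VAF] = t * f * m / ((1 - t) * c_n + t * c_t); diploid default t*f/2."""
    denom = (1.0 - tumour_content) * c_n + tumour_content * c_t
    return tumour_content * carrier_fraction * multiplicity / denom


def _draw_counts(
    rng: np.random.Generator,
    tree: CloneTree,
    composition: SampleComposition,
    config: SimulationConfig,
) -> pd.DataFrame:
    muts = tree.mutations()
    if not muts:
        raise ValueError("clone tree carries no mutations")
    carrier_sets = {m: tree.carriers(m) for m in muts}
    err = config.sequencing_error_rate
    k = config.depth_dispersion
    p_nb = k / (k + config.depth_mean)
    rows = []
    for m in muts:
        f = sum(
            composition.clone_fractions.get(c, 0.0) for c in carrier_sets[m]
        )
        vaf = _expected_vaf(f, composition.tumour_content)
        p_eff = vaf + err * (1.0 - vaf)
        depth = int(rng.negative_binomial(k, p_nb))
        var = int(rng.binomial(depth, p_eff)) if depth > 0 else 0
        chrom, pos = tree.mutation_loci[m]
        rows.append(
            {
                "mutation_id": m,
                "chrom": chrom,
                "pos": pos,
                "sample_id": composition.sample_id,
                "ref_count": depth - var,
                "var_count": var,
            }
        )
    return pd.DataFrame(rows)


def simulate_amplicon_counts(
    tree: CloneTree, compositions: list[SampleComposition], config: SimulationConfig
) -> pd.DataFrame:
    """Deep-amplicon read counts for every (mutation, sample) pair.

    Depth ~ NegBin(mean=depth_mean, shape=depth_dispersion); variant reads ~
    Binomial(depth, vaf + error * (1 - vaf)) with vaf = t * f / 2 for carrier
    fraction f (diploid loci, multiplicity 1); non-carried sites draw at the
    error rate alone.
    """
    config.validate()
    rng = config.rng(2)
    return pd.concat(
        [_draw_counts(rng, tree, comp, config) for comp in compositions],
        ignore_index=True,
    )


def _apply_event(segments: list[tuple[int, int, int, int]], ev: CNAEvent
                 ) -> list[tuple[int, int, int, int]]:
    """Apply one event to a chromosome's (start, end, a, b) segment list."""
    out = []
    ai = 2 if ev.allele == "major" else 3  # haplotype A / B slot
    for (s, e, a, b) in segments:
        pieces = []
        lo, hi = max(s, ev.start), min(e, ev.end)
        if lo >= hi:
            out.append((s, e, a, b))
            continue
        if s < lo:
            pieces.append((s, lo, a, b))
        mid = [lo, hi, a, b]
        mid[ai] = max(0, mid[ai] + ev.delta)  # copies never go negative
        pieces.append(tuple(mid))
        if hi < e:
            pieces.append((hi, e, a, b))
        out.extend(pieces)
    return out


def _merge_segments(segments: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    merged = []
    for seg in segments:
        if merged and merged[-1][1] == seg[0] and merged[-1][2:] == seg[2:]:
            merged[-1] = (merged[-1][0], seg[1], seg[2], seg[3])
        else:
            merged.append(list(seg))
            merged[-1] = tuple(merged[-1])
    return [tuple(s) for s in merged]


def clone_cna_profile(tree: CloneTree, clone: str, config: SimulationConfig) -> pd.DataFrame:
    """Integer allele-specific profile of one clone.

    Events are applied in ancestral order along the lineage from the root;
    the whole-genome doubling (if on the lineage) doubles both haplotypes
    genome-wide after its branch's segmental events.
    """
    genome = dict(config.genome)
    state: dict[str, list[tuple[int, int, int, int]]] = {
        chrom: [(0, length, 1, 1)] for chrom, length in config.genome
    }
    for anc in tree.lineage(clone):
        for ev in tree.branch_cna_events.get(anc, []):
            if ev.is_wgd:
                continue
            if ev.chrom not in genome:
                raise ValueError(f"event chromosome {ev.chrom!r} not in genome")
            if ev.end > genome[ev.chrom]:
                raise ValueError("CNA event outside chromosome bounds")
            state[ev.chrom] = _apply_event(state[ev.chrom], ev)
        if any(ev.is_wgd for ev in tree.branch_cna_events.get(anc, [])):
            for chrom in state:
                state[chrom] = [(s, e, 2 * a, 2 * b) for (s, e, a, b) in state[chrom]]
    rows = []
    for chrom, _ in config.genome:
        for (s, e, a, b) in _merge_segments(state[chrom]):
            rows.append(
                {"chrom": chrom, "start": s, "end": e,
                 "major_cn": max(a, b), "minor_cn": min(a, b)}
            )
    return pd.DataFrame(rows)


def simulate_cna_profiles(
    tree: CloneTree, compositions: list[SampleComposition], config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Per-sample allele-specific segment profiles.

    A bulk sample's profile is its dominant clone's integer profile (arrays
    on bulk DNA report the major cell population); clone-mixture fractional
    copy numbers are deliberately out of scope.
    """
    config.validate()
    return {
        comp.sample_id: clone_cna_profile(tree, comp.dominant_clone(), config)
        for comp in compositions
    }


def simulate_ctdna(tree: CloneTree, config: SimulationConfig) -> pd.DataFrame:
    """Plasma pseudo-sample counts at low tumour fraction.

    Clone fractions in plasma are a shedding-weighted average over all clones
    (shedding weights ~ Dirichlet(1, ..., 1)); the effective tumour content
    is ``plasma_tumour_fraction``.
    """
    config.validate()
    rng = config.rng(3)
    weights = rng.dirichlet(np.ones(len(tree.clones)))
    comp = SampleComposition(
        sample_id=PLASMA_SAMPLE,
        clone_fractions={c: float(w) for c, w in zip(tree.clones, weights)},
        tumour_content=config.plasma_tumour_fraction,
    )
    return _draw_counts(rng, tree, comp, config)


def simulate_all(config: SimulationConfig) -> dict:
    """Run the whole simulator; returns a dict of ground truth and observables."""
    tree = simulate_clone_tree(config)
    compositions = simulate_regions(tree, config)
    counts = simulate_amplicon_counts(tree, compositions, config)
    profiles = simulate_cna_profiles(tree, compositions, config)
    plasma = simulate_ctdna(tree, config)
    return {
        "tree": tree,
        "compositions": compositions,
        "counts": counts,
        "cna_profiles": profiles,
        "plasma_counts": plasma,
    }
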