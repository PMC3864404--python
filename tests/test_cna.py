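"""Zygosity states, compound-event statistics and doubling detection."""

import numpy as np
import pandas as pd
import pytest

from clonaltapestry.cna import (
    COMPOUND_WEIGHTS,
    ZygosityState,
    classify_zygosity,
    cna_distance_tree,
    compound_fraction,
    compound_weight,
    detect_doubling,
    gene_weight_matrix,
    intersect_segmentations,
    pairwise_state_concordance,
    project_to_genes,
)


def seg(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "major_cn", "minor_cn"])


@pytest.mark.parametrize(
    "major,minor,state",
    [
        (0, 0, ZygosityState.HOMD),
        (1, 0, ZygosityState.HEMD),
        (1, 1, ZygosityState.HET),
        (2, 0, ZygosityState.NLOH),
        (3, 0, ZygosityState.ALOH),
        (5, 0, ZygosityState.ALOH),
        (2, 1, ZygosityState.ASCNA),
        (3, 2, ZygosityState.ASCNA),
        (2, 2, ZygosityState.BCNA),
        (4, 4, ZygosityState.BCNA),
    ],
)
def test_zygosity_classification_total(major, minor, state):
    assert classify_zygosity(major, minor) is state


def test_invalid_zygosity_rejected():
    with pytest.raises(ValueError):
        classify_zygosity(1, 2)
    with pytest.raises(ValueError):
        classify_zygosity(1, -1)


def test_compound_weight_table():
    expected = {"ALOH": 2, "NLOH": 2, "HOMD": 2, "HEMD": 1, "HET": 0,
                "ASCNA": 0, "BCNA": 0}
    assert {s.value: w for s, w in COMPOUND_WEIGHTS.items()} == expected
    assert compound_weight("NLOH") == 2


def test_compound_fraction_examples():
    all_het = seg([("chr1", 0, 100, 1, 1)])
    assert compound_fraction(all_het) == 0.0

    half = seg([("chr1", 0, 50, 2, 0), ("chr1", 50, 100, 1, 1)])
    assert compound_fraction(half) == pytest.approx(0.5)

    # chr lengths 100/200/300: NLOH on chr1, ALOH on half of chr3 -> 250/600
    prof = seg(
        [("chr1", 0, 100, 2, 0), ("chr2", 0, 200, 1, 1),
         ("chr3", 0, 150, 3, 0), ("chr3", 150, 300, 1, 1)]
    )
    assert compound_fraction(prof) == pytest.approx(250 / 600)


def test_compound_fraction_split_invariant():
    base = seg([("chr1", 0, 100, 2, 0), ("chr1", 100, 300, 1, 1)])
    split = seg([("chr1", 0, 40, 2, 0), ("chr1", 40, 100, 2, 0),
                 ("chr1", 100, 180, 1, 1), ("chr1", 180, 300, 1, 1)])
    assert compound_fraction(base) == pytest.approx(compound_fraction(split))


def test_gene_projection_midpoint_rule():
    prof = seg([("chr1", 0, 100, 2, 0), ("chr1", 100, 200, 1, 1)])
    genes = pd.DataFrame(
        [
            {"gene_id": "inside", "chrom": "chr1", "start": 10, "end": 50},
            {"gene_id": "spanning", "chrom": "chr1", "start": 80, "end": 130},  # mid 105
            {"gene_id": "gap", "chrom": "chr1", "start": 250, "end": 260},
            {"gene_id": "other", "chrom": "chr2", "start": 0, "end": 10},
        ]
    )
    got = project_to_genes(prof, genes)
    assert got.loc["inside", "state"] == "NLOH"
    assert got.loc["spanning", "state"] == "HET"  # midpoint decides
    assert got.loc["gap", "state"] == "unassessed"
    assert got.loc["other", "state"] == "unassessed"


def test_distance_tree_arithmetic_and_control():
    genes = pd.DataFrame(
        [{"gene_id": f"g{i}", "chrom": "chr1", "start": i * 10, "end": i * 10 + 10}
         for i in range(3)]
    )
    # A weights (2,2,0), B weights (2,0,0)
    prof_a = seg([("chr1", 0, 20, 2, 0), ("chr1", 20, 30, 1, 1)])
    prof_b = seg([("chr1", 0, 10, 2, 0), ("chr1", 10, 30, 1, 1)])
    weights = gene_weight_matrix({"A": prof_a, "B": prof_b}, genes)
    dm, tree = cna_distance_tree(weights)
    d = dm.to_frame()
    assert d.loc["A", "B"] == pytest.approx(2.0)
    assert d.loc["A", "control"] == pytest.approx(np.sqrt(8), abs=1e-6)
    assert d.loc["B", "control"] == pytest.approx(2.0)
    assert tree.control == "control"


def test_all_het_sample_coincides_with_control():
    genes = pd.DataFrame([{"gene_id": "g0", "chrom": "chr1", "start": 0, "end": 10},
                          {"gene_id": "g1", "chrom": "chr1", "start": 10, "end": 20}])
    het = seg([("chr1", 0, 20, 1, 1)])
    other = seg([("chr1", 0, 20, 2, 0)])
    weights = gene_weight_matrix({"A": het, "B": other}, genes)
    dm, _ = cna_distance_tree(weights)
    assert dm.to_frame().loc["A", "control"] == 0.0


def test_concordance_counts():
    genes = pd.DataFrame(
        [{"gene_id": f"g{i}", "chrom": "chr1", "start": i * 10, "end": i * 10 + 10}
         for i in range(4)]
    )
    a = seg([("chr1", 0, 40, 1, 0)])
    b = seg([("chr1", 0, 40, 2, 0)])
    got = pairwise_state_concordance(a, b, genes)
    assert len(got) == 1
    row = got.iloc[0]
    assert (row["cn_a"], row["cn_b"], row["same_zygosity"], row["n_genes"]) == (1, 2, True, 4)

    # equal total CN but different zygosity: (1,1) vs (2,0)
    a2 = seg([("chr1", 0, 40, 1, 1)])
    got2 = pairwise_state_concordance(a2, b, genes)
    row2 = got2.iloc[0]
    assert (row2["cn_a"], row2["cn_b"], bool(row2["same_zygosity"])) == (2, 2, False)


def test_identical_profiles_concordance_diagonal():
    genes = pd.DataFrame(
        [{"gene_id": f"g{i}", "chrom": "chr1", "start": i * 10, "end": i * 10 + 10}
         for i in range(5)]
    )
    prof = seg([("chr1", 0, 20, 2, 0), ("chr1", 20, 50, 2, 1)])
    got = pairwise_state_concordance(prof, prof, genes)
    assert (got["cn_a"] == got["cn_b"]).all()
    assert got["same_zygosity"].all()


def test_doubling_exact_signature():
    ref = seg([("chr1", 0, 50, 1, 0), ("chr1", 50, 100, 1, 1),
               ("chr2", 0, 100, 2, 1)])
    test = seg([("chr1", 0, 50, 2, 0), ("chr1", 50, 100, 2, 2),
                ("chr2", 0, 100, 4, 2)])
    ev = detect_doubling(ref, test)
    assert ev.n_doubled == 2
    assert ev.per_chromosome["fraction"].tolist() == [1.0, 1.0]


def test_doubling_self_comparison_not_flagged():
    ref = seg([("chr1", 0, 50, 1, 0), ("chr1", 50, 100, 1, 1), ("chr2", 0, 100, 0, 0)])
    ev = detect_doubling(ref, ref)
    # (m,n)->(m,n) is never (2m,2n) except (0,0), which is excluded
    assert ev.n_doubled == 0
    assert (ev.per_chromosome["fraction"] == 0.0).all()


def test_doubling_half_chromosome_at_threshold():
    ref = seg([("chr1", 0, 50, 1, 0), ("chr1", 50, 100, 1, 1)])
    test = seg([("chr1", 0, 50, 2, 0), ("chr1", 50, 100, 1, 1)])
    ev = detect_doubling(ref, test, threshold=0.5)
    assert ev.per_chromosome.loc[0, "fraction"] == pytest.approx(0.5)
    assert ev.n_doubled == 1
    assert detect_doubling(ref, test, threshold=0.51).n_doubled == 0


def test_intersection_respects_breakpoints():
    ref = seg([("chr1", 0, 100, 1, 1)])
    test = seg([("chr1", 0, 60, 2, 2), ("chr1", 60, 100, 1, 1)])
    inter = intersect_segmentations(ref, test)
    assert inter["end"].tolist() == [60, 100]


def test_disjoint_genomes_rejected():
    with pytest.raises(ValueError):
        intersect_segmentations(seg([("chr1", 0, 10, 1, 1)]),
                                seg([("chr2", 0, 10, 1, 1)]))


def test_wgd_recovery_on_simulated_profiles():
    """Samples dominated by WGD-descendant clones show >= 20/22 doubled
    autosomes against a non-WGD reference; non-WGD pairs show <= 2/22."""
    from clonaltapestry.simulate import (
        SampleComposition, SimulationConfig, simulate_clone_tree, simulate_cna_profiles,
    )

    for seed in range(5):
        cfg = SimulationConfig(n_clones=4, wgd_clone=1, random_seed=seed)
        tree = simulate_clone_tree(cfg)
        comps = [SampleComposition(f"s_{c}", {c: 1.0}, 0.7) for c in tree.clones]
        profiles = simulate_cna_profiles(tree, comps, cfg)
        wgd_set = tree.descendants("c1")
        ref = profiles["s_c0"]
        for clone in tree.clones[1:]:
            n = detect_doubling(ref, profiles[f"s_{clone}"]).n_doubled
            if clone in wgd_set:
                assert n >= 20
            else:
                assert n <= 2
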