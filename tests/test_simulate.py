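"""Clonal-evolution simulator: determinism, moments and ground-truth logic."""

import numpy as np
import pandas as pd
import pytest

from clonaltapestry.simulate import (
    CNAEvent,
    CloneTree,
    SampleComposition,
    SimulationConfig,
    clone_cna_profile,
    simulate_all,
    simulate_amplicon_counts,
    simulate_clone_tree,
    simulate_cna_profiles,
    simulate_ctdna,
    simulate_regions,
)


def test_single_clone_tree_all_mutations_ancestral():
    tree = simulate_clone_tree(SimulationConfig(n_clones=1, random_seed=3))
    assert tree.clones == ["c0"]
    assert set(tree.mutations()) == tree.ancestral_mutations()
    assert len(tree.mutations()) >= 1  # founder mutation guaranteed


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_clones=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(mutations_per_branch_mean=-1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(wgd_clone=9, n_clones=4).validate()


def test_same_seed_identical_output():
    cfg = SimulationConfig(random_seed=7)
    a, b = simulate_all(cfg), simulate_all(cfg)
    assert a["tree"] == b["tree"]
    pd.testing.assert_frame_equal(a["counts"], b["counts"])
    pd.testing.assert_frame_equal(a["plasma_counts"], b["plasma_counts"])
    for s in a["cna_profiles"]:
        pd.testing.assert_frame_equal(a["cna_profiles"][s], b["cna_profiles"][s])


def test_total_mutation_count_matches_poisson_mean():
    # 5 branches x Poisson(20) => mean total 100; 1000 replicates within 3 SE
    totals = [
        len(
            simulate_clone_tree(
                SimulationConfig(n_clones=5, mutations_per_branch_mean=20, random_seed=s)
            ).mutations()
        )
        for s in range(1000)
    ]
    se = np.sqrt(100 / 1000)
    assert abs(np.mean(totals) - 100) < 3 * se


def test_regions_single_clone_and_pure_sparsity():
    tree1 = simulate_clone_tree(SimulationConfig(n_clones=1, random_seed=5))
    comps = simulate_regions(tree1, SimulationConfig(n_clones=1, n_samples=4, random_seed=5))
    assert all(c.clone_fractions == {"c0": 1.0} for c in comps)

    cfg = SimulationConfig(n_clones=5, n_samples=8, region_min_clones=1,
                           region_max_clones=1, random_seed=5)
    tree = simulate_clone_tree(cfg)
    for comp in simulate_regions(tree, cfg):
        assert len(comp.clone_fractions) == 1
        assert list(comp.clone_fractions.values()) == [1.0]


def test_dirichlet_mixture_moments():
    # support fixed at all 3 clones, alpha=(1,1,1): mean fraction 1/3 within 3 SE
    cfg = SimulationConfig(n_clones=3, n_samples=10_000, region_min_clones=3,
                           region_max_clones=3, random_seed=2)
    tree = simulate_clone_tree(cfg)
    comps = simulate_regions(tree, cfg)
    fracs = np.array([[c.clone_fractions.get(cl, 0.0) for cl in tree.clones] for c in comps])
    se = np.sqrt((1 / 3) * (2 / 3) / 4 / len(fracs))
    assert np.all(np.abs(fracs.mean(axis=0) - 1 / 3) < 3 * se)


def test_expected_vaf_rule_and_error_floor():
    # pure sample, t=1, diploid: E[VAF]=0.5; mean over ~1000 loci at depth 5000
    cfg = SimulationConfig(
        n_clones=1, n_samples=1, mutations_per_branch_mean=1000,
        sequencing_error_rate=0.0, tumour_content=1.0, random_seed=9,
    )
    tree = simulate_clone_tree(cfg)
    comp = SampleComposition("s0", {"c0": 1.0}, 1.0)
    counts = simulate_amplicon_counts(tree, [comp], cfg)
    vaf = counts["var_count"] / (counts["ref_count"] + counts["var_count"])
    assert abs(vaf.mean() - 0.5) < 0.01

    # absent mutation at error 0.001, depth 5000: ~5 variant reads on average
    cfg2 = SimulationConfig(
        n_clones=1, n_samples=1, mutations_per_branch_mean=1000,
        sequencing_error_rate=0.001, random_seed=9,
    )
    tree2 = simulate_clone_tree(cfg2)
    null_comp = SampleComposition("s0", {"c0": 1.0}, 0.0)  # no tumour content
    counts2 = simulate_amplicon_counts(tree2, [null_comp], cfg2)
    assert abs(counts2["var_count"].mean() - 5.0) < 1.0


def test_zero_carrier_zero_error_gives_zero_variant_reads():
    cfg = SimulationConfig(n_clones=2, sequencing_error_rate=0.0, random_seed=4)
    tree = simulate_clone_tree(cfg)
    # sample composed purely of c0: c1-private mutations have carrier fraction 0
    comp = SampleComposition("s0", {"c0": 1.0}, 0.8)
    counts = simulate_amplicon_counts(tree, [comp], cfg).set_index("mutation_id")
    for m in tree.branch_mutations["c1"]:
        assert counts.loc[m, "var_count"] == 0


def test_ancestral_mutations_nonzero_vaf_everywhere(default_sim):
    tree = default_sim["tree"]
    counts = default_sim["counts"]
    anc = tree.ancestral_mutations()
    sub = counts[counts["mutation_id"].isin(anc)]
    vaf = sub["var_count"] / (sub["ref_count"] + sub["var_count"])
    # every tumour sample carries every ancestral mutation well above error
    assert (vaf > 0.01).all()


def test_cna_profiles_no_events_diploid():
    cfg = SimulationConfig(n_clones=1, cna_events_per_branch_mean=0.0, random_seed=6)
    tree = simulate_clone_tree(cfg)
    prof = clone_cna_profile(tree, "c0", cfg)
    assert (prof["major_cn"] == 1).all() and (prof["minor_cn"] == 1).all()
    assert len(prof) == len(cfg.genome)


def test_deletion_then_wgd_gives_nloh():
    # minor-allele deletion followed by a genome doubling on the same lineage
    genome = (("chr1", 1000),)
    tree = CloneTree(
        clones=["c0", "c1"],
        parent={"c0": None, "c1": "c0"},
        branch_mutations={"c0": ["m0"], "c1": []},
        branch_cna_events={
            "c0": [CNAEvent("chr1", 0, 500, "minor", -1)],
            "c1": [CNAEvent("*", 0, 0, "major", 0, is_wgd=True)],
        },
        wgd_clone="c1",
        mutation_loci={"m0": ("chr1", 1)},
    )
    cfg = SimulationConfig(n_clones=2, genome=genome, random_seed=0)
    prof = clone_cna_profile(tree, "c1", cfg).set_index("start")
    assert (prof.loc[0, ["major_cn", "minor_cn"]] == [2, 0]).all()  # NLOH
    assert (prof.loc[500, ["major_cn", "minor_cn"]] == [2, 2]).all()  # balanced 2+2


def test_deletion_then_gain_gives_nloh():
    genome = (("chr1", 1000),)
    tree = CloneTree(
        clones=["c0"],
        parent={"c0": None},
        branch_mutations={"c0": ["m0"]},
        branch_cna_events={
            "c0": [
                CNAEvent("chr1", 0, 1000, "minor", -1),
                CNAEvent("chr1", 0, 1000, "major", +1),
            ]
        },
        mutation_loci={"m0": ("chr1", 1)},
    )
    cfg = SimulationConfig(n_clones=1, genome=genome, random_seed=0)
    prof = clone_cna_profile(tree, "c0", cfg)
    assert (prof[["major_cn", "minor_cn"]].to_numpy() == [[2, 0]]).all()


def test_event_outside_genome_bounds_raises():
    genome = (("chr1", 100),)
    tree = CloneTree(
        clones=["c0"], parent={"c0": None}, branch_mutations={"c0": ["m0"]},
        branch_cna_events={"c0": [CNAEvent("chr1", 0, 200, "major", 1)]},
        mutation_loci={"m0": ("chr1", 1)},
    )
    with pytest.raises(ValueError, match="bounds"):
        clone_cna_profile(tree, "c0", SimulationConfig(n_clones=1, genome=genome))


def test_ctdna_zero_fraction_is_pure_noise_and_deterministic():
    cfg = SimulationConfig(plasma_tumour_fraction=0.0, random_seed=12)
    tree = simulate_clone_tree(cfg)
    plasma = simulate_ctdna(tree, cfg)
    vaf = plasma["var_count"] / (plasma["ref_count"] + plasma["var_count"])
    assert vaf.mean() < 0.005  # error floor only
    pd.testing.assert_frame_equal(plasma, simulate_ctdna(tree, cfg))


def test_ctdna_ancestral_vaf_scales_with_plasma_fraction():
    cfg = SimulationConfig(
        n_clones=1, mutations_per_branch_mean=500, plasma_tumour_fraction=0.1,
        sequencing_error_rate=0.0, random_seed=13,
    )
    tree = simulate_clone_tree(cfg)
    plasma = simulate_ctdna(tree, cfg)
    vaf = plasma["var_count"] / (plasma["ref_count"] + plasma["var_count"])
    assert abs(vaf.mean() - 0.05) < 0.005  # E[VAF] = 0.1 / 2


def test_composition_invariants():
    with pytest.raises(ValueError):
        SampleComposition("s0", {"c0": 0.6, "c1": 0.3}, 0.7)  # fractions don't sum to 1
    with pytest.raises(ValueError):
        SampleComposition("s0", {"c0": 1.0}, 1.5)
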