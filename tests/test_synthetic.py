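"""Generator contracts: planted copy numbers, rates, determinism."""

import numpy as np
import pandas as pd
import pytest

import karyoshift as ks
from karyoshift.synthetic import ELEMENTS


@pytest.mark.parametrize(
    "kwargs",
    [
        {"element_proportions": {"A": 0.5, "B": 0.6}},  # sums to 1.1
        {"depth_mean": 0.0},
        {"depth_mean": -3.0},
        {"heterogamety": "XX"},
        {"hit_noise_rate": 1.5},
        {"compensation_mode": "both"},
        {"sexbias_fractions": (0.7, 0.7)},
        # diff_Z under male heterogamety is contradictory
        {"per_element_scenario": {"B": ks.ElementScenario("diff_Z")}, "heterogamety": "XY"},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ks.ConfigError):
        ks.ScenarioConfig(**kwargs)


def test_scenario_parameter_bounds():
    with pytest.raises(ks.ConfigError):
        ks.ElementScenario("neo_X", d=1.2)
    with pytest.raises(ks.ConfigError):
        ks.ElementScenario("partial_sexlinked", q=-0.1)
    assert ks.ElementScenario.parse("neo_X:0.3").d == 0.3
    assert ks.ElementScenario.parse("partial_sexlinked:0.5").q == 0.5


def test_genome_counts_lengths_and_proportions():
    cfg = ks.ScenarioConfig(n_scaffolds=1000, seed=7)
    scaffolds, truth = ks.simulate_genome(cfg)
    assert len(scaffolds) == 1000
    assert (scaffolds["length_bp"] >= cfg.scaffold_length_law[2]).all()
    # F at 5%: binomial mean 50, sd ~6.9 -> 5 sd band
    n_f = (scaffolds["true_element"] == "F").sum()
    assert abs(n_f - 50) < 5 * 6.9
    # every element frequency within 5 binomial sd of its proportion
    for e, p in cfg.element_proportions.items():
        n_e = (scaffolds["true_element"] == e).sum()
        sd = np.sqrt(1000 * p * (1 - p))
        assert abs(n_e - 1000 * p) < 5 * sd


def test_empty_genome_is_not_an_error():
    cfg = ks.ScenarioConfig(n_scaffolds=0, seed=1)
    study = ks.simulate_study(cfg)
    assert len(study.scaffolds) == 0
    assert len(study.depth) == 0
    assert all(len(df) == 0 for df in study.pileups.values())
    assert len(study.gene_hits) == 0


def test_same_seed_reproduces_all_tables_exactly():
    cfg = dict(
        per_element_scenario={"D": ks.ElementScenario("neo_X", d=0.4)},
        xy_divergence_rate=2e-3, hit_noise_rate=0.05, seed=11, n_scaffolds=300,
    )
    a = ks.simulate_study(ks.ScenarioConfig(**cfg))
    b = ks.simulate_study(ks.ScenarioConfig(**cfg))
    pd.testing.assert_frame_equal(a.scaffolds, b.scaffolds)
    pd.testing.assert_frame_equal(a.depth, b.depth)
    for sex in ("male", "female"):
        pd.testing.assert_frame_equal(a.pileups[sex], b.pileups[sex])
    pd.testing.assert_frame_equal(a.gene_hits, b.gene_hits)
    pd.testing.assert_frame_equal(a.expression, b.expression)
    pd.testing.assert_frame_equal(a.ancestral_expression, b.ancestral_expression)


def test_planted_copy_numbers():
    cfg = ks.ScenarioConfig(
        n_scaffolds=500,
        per_element_scenario={
            "F": ks.ElementScenario("diff_X"),
            "D": ks.ElementScenario("neo_X", d=0.6),
            "B": ks.ElementScenario("partial_sexlinked", q=0.5),
        },
        seed=3,
    )
    _, truth = ks.simulate_genome(cfg)
    t = truth.scaffolds
    # homogametic sex always diploid
    assert (t["female_cn"] == 2.0).all()
    assert (t.loc[t["element"] == "F", "male_cn"] == 1.0).all()
    # neo-X multiplier 2(1 - d/2) = 2 - d
    assert np.allclose(t.loc[t["element"] == "D", "male_cn"], 2.0 - 0.6)
    b = t.loc[t["element"] == "B", "male_cn"]
    assert set(b.unique()) == {1.0, 2.0}
    assert abs((b == 1.0).mean() - 0.5) < 0.1


def test_depth_means_follow_copy_number():
    cfg = ks.ScenarioConfig(
        n_scaffolds=3000, per_element_scenario={"F": ks.ElementScenario("diff_X")},
        seed=5,
    )
    scaffolds, truth = ks.simulate_genome(cfg)
    depth = ks.simulate_depth(scaffolds, truth, cfg).merge(
        truth.scaffolds[["scaffold_id", "element"]], on="scaffold_id"
    )
    f = depth[depth["element"] == "F"]
    a = depth[depth["element"] != "F"]
    assert abs(f["male_depth"].mean() - 10.0) < 0.5
    assert abs(f["female_depth"].mean() - 20.0) < 0.5
    # 10,000+ autosomal draws: empirical mean within 1% of depth_mean
    draws = np.concatenate([a["male_depth"], a["female_depth"]])
    assert draws.size >= 5000
    assert abs(draws.mean() - 20.0) / 20.0 < 0.01


def test_neo_x_depth_limits_and_monotonicity():
    means = []
    for d in (0.0, 0.3, 0.7, 1.0):
        cfg = ks.ScenarioConfig(
            n_scaffolds=800, per_element_scenario={"E": ks.ElementScenario("neo_X", d=d)},
            seed=9,
        )
        scaffolds, truth = ks.simulate_genome(cfg)
        depth = ks.simulate_depth(scaffolds, truth, cfg).merge(
            truth.scaffolds[["scaffold_id", "element"]], on="scaffold_id"
        )
        e = depth[depth["element"] == "E"]
        means.append(e["male_depth"].mean())
        if d == 0.0:  # undifferentiated limit: sexes equal
            assert abs(e["male_depth"].mean() - e["female_depth"].mean()) < 0.5
        if d == 1.0:  # fully differentiated limit: half depth
            assert abs(e["male_depth"].mean() - 10.0) < 0.5
    assert all(m1 >= m2 - 0.3 for m1, m2 in zip(means, means[1:]))


def test_pileup_site_rates():
    # ~1 Mb of autosome at 1e-3/bp: ~1000 sites per sex, Poisson sd ~32
    cfg = ks.ScenarioConfig(
        n_scaffolds=300, scaffold_length_law=(8.1, 0.1, 500), seed=13
    )
    scaffolds, truth = ks.simulate_genome(cfg)
    total_bp = scaffolds["length_bp"].sum()
    pileups = ks.simulate_pileups(scaffolds, truth, cfg)
    for sex in ("male", "female"):
        expected = cfg.base_het_rate * total_bp
        assert abs(len(pileups[sex]) - expected) < 5 * np.sqrt(expected)
    # null contract: without divergence the two sexes' densities agree
    ratio = len(pileups["male"]) / len(pileups["female"])
    assert 0.85 < ratio < 1.15


def test_neo_x_male_snp_rate_addition():
    cfg = ks.ScenarioConfig(
        n_scaffolds=400,
        per_element_scenario={"E": ks.ElementScenario("neo_X", d=0.1)},
        xy_divergence_rate=5e-3, seed=17,
    )
    scaffolds, truth = ks.simulate_genome(cfg)
    pileups = ks.simulate_pileups(scaffolds, truth, cfg)
    t = truth.scaffolds.set_index("scaffold_id")
    neo_bp = t.loc[t["neo"], "length_bp"].sum()
    male_neo = pileups["male"]["scaffold_id"].isin(t.index[t["neo"]]).sum()
    female_neo = pileups["female"]["scaffold_id"].isin(t.index[t["neo"]]).sum()
    # male density base + divergence = 6e-3/bp, female 1e-3/bp
    assert abs(male_neo / neo_bp - 6e-3) < 5 * np.sqrt(6e-3 * neo_bp) / neo_bp
    assert abs(female_neo / neo_bp - 1e-3) < 5 * np.sqrt(1e-3 * neo_bp) / neo_bp


def test_gene_hits_noiseless_and_noisy_majority():
    # noiseless labels + long scaffolds (many genes): majority vote exact
    cfg = ks.ScenarioConfig(
        n_scaffolds=200, scaffold_length_law=(11.5, 0.2, 50_000), seed=19
    )
    scaffolds, truth = ks.simulate_genome(cfg)
    hits = ks.simulate_gene_hits(scaffolds, truth, cfg)
    assigns = ks.assign_scaffold_elements(ks.filter_hits(hits))
    merged = assigns.merge(
        truth.scaffolds[["scaffold_id", "element"]], on="scaffold_id"
    )
    assert (merged["assigned_element"] == merged["element"]).all()

    # 10% label noise with >= 5 genes/scaffold: >99% of scaffolds correct
    cfg = ks.ScenarioConfig(
        n_scaffolds=300, scaffold_length_law=(11.5, 0.2, 80_000),
        hit_noise_rate=0.1, seed=23,
    )
    scaffolds, truth = ks.simulate_genome(cfg)
    hits = ks.simulate_gene_hits(scaffolds, truth, cfg)
    assigns = ks.assign_scaffold_elements(ks.filter_hits(hits))
    merged = assigns[assigns["n_genes"] >= 5].merge(
        truth.scaffolds[["scaffold_id", "element"]], on="scaffold_id"
    )
    assert (merged["assigned_element"] == merged["element"]).mean() > 0.99

    # a scaffold without genes never appears in the hit table
    assert set(hits["scaffold_id"]) <= set(scaffolds["scaffold_id"])


@pytest.mark.parametrize(
    "mode, expected_male_x", [("male_up", 1.0), ("none", 0.5), ("female_down", 0.5)]
)
def test_expression_planting(mode, expected_male_x):
    cfg = ks.ScenarioConfig(
        n_scaffolds=600, per_element_scenario={"D": ks.ElementScenario("diff_X")},
        compensation_mode=mode, seed=29,
    )
    scaffolds, truth = ks.simulate_genome(cfg)
    ks.simulate_gene_hits(scaffolds, truth, cfg)
    expr, anc, orth = ks.simulate_expression(truth, cfg)

    def med_ca(sex, x):
        cur = expr[(expr["tissue"] == "whole_body") & (expr["sex"] == sex)]
        a = anc[(anc["tissue"] == "whole_body") & (anc["sex"] == sex)]
        pairs = orth.merge(cur, left_on="focal_gene", right_on="gene_id")
        pairs = pairs.merge(a, left_on="ref_gene", right_on="gene_id",
                            suffixes=("_cur", "_anc"))
        sub = pairs[pairs["ref_element"].isin(["D"]) == x]
        return np.median(sub["fpkm_cur"] / sub["fpkm_anc"])

    assert abs(med_ca("male", True) - expected_male_x) < 0.12
    # autosomal control: median C/A = 1 in both sexes, any mode
    assert abs(med_ca("male", False) - 1.0) < 0.1
    assert abs(med_ca("female", False) - 1.0) < 0.1
    expected_female_x = 0.5 if mode == "female_down" else 1.0
    assert abs(med_ca("female", True) - expected_female_x) < 0.12
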