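"""Properties of the synthetic-study generator."""

import numpy as np
import pytest

from recsplice.autozygosity import MISSING
from recsplice.simdata import (SEQ_CASE_IDS, SEQ_CONTROL_IDS, ConfigError,
                               SimConfig, fixture_gene,
                               simulate_junction_reads, simulate_population,
                               simulate_reference, simulate_variant_calls)
from recsplice.varfilter import filter_cascade


def test_same_seed_identical_outputs():
    a = simulate_population(SimConfig(seed=5))
    b = simulate_population(SimConfig(seed=5))
    assert np.array_equal(a.matrix.genotypes, b.matrix.genotypes)
    assert a.matrix.markers.equals(b.matrix.markers)
    ma, sa = simulate_reference(SimConfig(seed=5))
    mb, sb = simulate_reference(SimConfig(seed=5))
    assert sa == sb and ma.exons == mb.exons


def test_different_seed_differs():
    a = simulate_population(SimConfig(seed=5))
    b = simulate_population(SimConfig(seed=6))
    assert not np.array_equal(a.matrix.genotypes, b.matrix.genotypes)


def test_all_cases_homozygous_ibd(default_config, default_population):
    """Every case is homozygous for the founder haplotype across the
    configured interval; no control is."""
    pop = default_population
    lo, hi = default_config.interval_bounds
    pos = pop.matrix.markers["pos"].to_numpy()
    iv = (pos >= lo) & (pos <= hi)
    expected = (2 * pop.hstar[iv]).astype(np.int8)
    for cid in pop.case_ids:
        row = pop.matrix.genotypes[pop.matrix.samples.index(cid)]
        assert np.array_equal(row[iv], expected)
    carries = pop.carries_hstar.set_index("sample")
    for cid in pop.control_ids:
        assert not (carries.loc[cid, "hap0"] and carries.loc[cid, "hap1"])


def test_zero_carrier_frequency_means_no_control_carries():
    cfg = SimConfig(seed=3, carrier_freq_controls=0.0, n_controls=60)
    pop = simulate_population(cfg)
    carries = pop.carries_hstar.set_index("sample")
    assert not carries.loc[pop.control_ids, ["hap0", "hap1"]].any().any()


def test_control_carrier_rate_near_configured(default_config,
                                              default_population):
    pop = default_population
    carries = pop.carries_hstar.set_index("sample")
    frac = carries.loc[pop.control_ids, ["hap0", "hap1"]].any(axis=1).mean()
    p = default_config.carrier_freq_controls
    se = np.sqrt(p * (1 - p) / len(pop.control_ids))
    assert abs(frac - p) <= 4 * se


def test_mendelian_consistency_of_trios(default_population):
    """No child genotype is impossible given its parents' genotypes."""
    pop = default_population
    gm = pop.matrix
    idx = {s: i for i, s in enumerate(gm.samples)}

    def gametes(g):
        return {0: {0}, 1: {0, 1}, 2: {1}, MISSING: {0, 1}}[g]

    trios = pop.pedigree[(pop.pedigree["sire"] != ".")
                         & (pop.pedigree["dam"] != ".")]
    assert len(trios) >= 30  # dams and cases
    for _, row in trios.iterrows():
        child = gm.genotypes[idx[row["id"]]]
        sire = gm.genotypes[idx[row["sire"]]]
        dam = gm.genotypes[idx[row["dam"]]]
        for c, s, d in zip(child, sire, dam):
            assert any(
                c == a + b for a in gametes(s) for b in gametes(d)
            ), f"impossible trio genotype child={c} sire={s} dam={d}"


def test_impossible_configs_rejected():
    with pytest.raises(ConfigError):
        SimConfig(ibd_interval=1.5)
    with pytest.raises(ConfigError):
        SimConfig(n_cases=0)
    with pytest.raises(ConfigError):
        SimConfig(skip_fraction_het=1.2)
    with pytest.raises(ConfigError):
        # interval too small to hold the gene
        SimConfig(region_span=20_000, ibd_interval=0.05)


def test_causal_variant_survives_cascade(default_study):
    study = default_study
    report = filter_cascade(
        study.variants, study.config.interval, SEQ_CASE_IDS,
        SEQ_CONTROL_IDS, known_catalog=study.catalog,
    )
    keys = {v.key for v in report.candidates}
    assert study.variant_truth.causal_key in keys
    assert keys == study.variant_truth.candidate_keys
    assert len(keys) == study.config.n_candidate_decoys + 1


def test_quality_100_decoys_are_excluded(default_study):
    """QUAL exactly 100 fails the strictly-greater quality stage."""
    study = default_study
    at_100 = [v for v in study.variants if v.qual == 100.0]
    assert at_100  # the generator plants a few
    report = filter_cascade(
        study.variants, study.config.interval, SEQ_CASE_IDS,
        SEQ_CONTROL_IDS, known_catalog=study.catalog,
    )
    survivors = {v.key for v in report.candidates}
    assert all(v.key not in survivors for v in at_100)


def test_in_interval_high_quality_count(default_study):
    """Stages 1+2 leave the configured 2,968 records."""
    study = default_study
    cfg = study.config
    n = sum(
        1 for v in study.variants
        if cfg.interval.contains(v.chrom, v.pos) and v.qual > 100
    )
    assert n == cfg.n_decoy_variants + 1 == 2968


def test_no_decoys_gives_single_record(default_config):
    cfg = SimConfig(seed=2, n_decoy_variants=0, n_candidate_decoys=0)
    model, seq = simulate_reference(cfg)
    variants, truth, catalog = simulate_variant_calls(cfg, model, seq)
    assert len(variants) == 1
    assert variants[0].key == truth.causal_key
    assert not catalog


@pytest.mark.parametrize("label,lo,hi", [("wt", 1.0, 1.0),
                                         ("het", 0.25, 0.75),
                                         ("hom", 0.0, 0.0)])
def test_junction_reads_match_genotype(default_config, label, lo, hi, rng):
    model, seq = simulate_reference(default_config)
    jt = simulate_junction_reads(default_config, label, model, "s", rng)
    inc = jt.count("s", model.chrom, *model.junction(0))
    skip = jt.count("s", model.chrom, *model.skip_junction(1))
    total = inc + skip
    if label == "wt":
        assert skip == 0 and inc > 0
    elif label == "hom":
        assert inc == 0
    else:
        assert lo <= inc / total <= hi


def test_unknown_genotype_label_rejected(default_config, rng):
    model, _ = simulate_reference(default_config)
    with pytest.raises(ValueError, match="genotype label"):
        simulate_junction_reads(default_config, "carrier", model, "s", rng)


def test_het_depth45_reproduces_20_of_45_split(default_config):
    """At ~45 junction reads a carrier shows roughly half skipping
    (the 20-skip / 25-inclusion regime), 75/25 skip-only vs cryptic."""
    model, _ = simulate_reference(default_config)
    d_skip, a_skip = model.skip_junction(1)
    cryptic_acc = model.shift_acceptor(model.acceptor_site(1), 3)
    cj = tuple(sorted((model.donor_site(0), cryptic_acc)))
    rng = np.random.default_rng(1)
    aberrant, total, cryptic = 0, 0, 0
    for _ in range(40):
        jt = simulate_junction_reads(default_config, "het", model, "s", rng)
        inc = jt.count("s", model.chrom, *model.junction(0))
        skip = jt.count("s", model.chrom, d_skip, a_skip)
        cry = jt.count("s", model.chrom, *cj)
        aberrant += skip + cry
        cryptic += cry
        total += inc + skip + cry
    assert abs(aberrant / total - 0.5) < 0.05
    assert abs(cryptic / aberrant - 0.25) < 0.07
    assert 35 < total / 40 < 55  # mean coverage near the configured depth


def test_fixture_gene_rejects_bad_strand():
    with pytest.raises(ValueError):
        fixture_gene(strand="x")
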