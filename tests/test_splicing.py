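"""Junction extraction, PSI, event detection and in-silico RT-PCR."""

import io as stdio
import re

import numpy as np
import pandas as pd
import pytest

from recsplice.io import write_junction_sam
from recsplice.simdata import (FWD_PRIMER, REV_PRIMER, SimConfig,
                               simulate_junction_reads, simulate_reference)
from recsplice.splicing import (Isoform, JunctionTable, SpliceEvent,
                                detect_events, exon_psi, extract_junctions,
                                insilico_rtpcr, junctions_from_cigar)


def table_from_counts(model, sample, j12, j23, skip, cryptic=0):
    rows = []
    cj = tuple(sorted((model.donor_site(0),
                       model.shift_acceptor(model.acceptor_site(1), 3))))
    for (d, a), n in [
        (model.junction(0), j12),
        (model.junction(1), j23),
        (model.skip_junction(1), skip),
        (cj, cryptic),
    ]:
        if n:
            rows.append({"chrom": model.chrom, "donor_end": d,
                         "acceptor_start": a, "sample": sample, "count": n})
    return JunctionTable(pd.DataFrame(rows))


class TestCigarWalk:
    def test_worked_example(self):
        assert junctions_from_cigar(100, "20M50N20M") == [(119, 170)]

    def test_no_gap_contributes_nothing(self):
        assert junctions_from_cigar(100, "40M") == []
        assert junctions_from_cigar(100, "10M5I10M3D17M") == []

    def test_double_gap(self):
        # 10M 100N 10M 50N 10M from 1: gaps at (10,111) and (120,171)
        assert junctions_from_cigar(1, "10M100N10M50N10M") == \
            [(10, 111), (120, 171)]

    def test_anchor_filter(self):
        assert junctions_from_cigar(100, "5M50N20M", anchor_min=8) == []
        assert junctions_from_cigar(100, "20M50N5M", anchor_min=8) == []
        assert junctions_from_cigar(100, "8M50N8M", anchor_min=8) == \
            [(107, 158)]

    def test_clips_and_insertions_ignored_on_reference(self):
        # soft clip + insertion do not consume reference
        assert junctions_from_cigar(100, "5S20M2I30N20M") == [(119, 150)]

    def test_malformed_cigar(self):
        with pytest.raises(ValueError):
            junctions_from_cigar(1, "20Q")
        with pytest.raises(ValueError):
            junctions_from_cigar(1, "MM")

    def test_matches_per_base_interpreter(self, rng):
        """Random CIGARs agree with a dumb per-base expansion oracle."""
        ops = ["M", "N", "M", "N", "M"]
        for _ in range(50):
            lens = [int(rng.integers(1, 40)) for _ in ops]
            cigar = "".join(f"{n}{o}" for n, o in zip(lens, ops))
            pos = int(rng.integers(1, 1000))
            # oracle: expand to per-base reference annotation
            track = []
            for n, o in zip(lens, ops):
                track.extend(o * n)
            expected = []
            ref = pos
            i = 0
            while i < len(track):
                if track[i] == "N":
                    j = i
                    while j < len(track) and track[j] == "N":
                        j += 1
                    left = i  # aligned length before gap
                    left_run = 0
                    k = i - 1
                    while k >= 0 and track[k] == "M":
                        left_run += 1
                        k -= 1
                    right_run = 0
                    k = j
                    while k < len(track) and track[k] == "M":
                        right_run += 1
                        k += 1
                    if left_run >= 8 and right_run >= 8:
                        expected.append((ref + i - 1, ref + j))
                    i = j
                else:
                    i += 1
            assert junctions_from_cigar(pos, cigar) == expected


class TestExtraction:
    def test_sam_roundtrip_equals_simulated_counts(self, default_config,
                                                   tmp_path, rng):
        model, _ = simulate_reference(default_config)
        jt = simulate_junction_reads(default_config, "het", model, "s1", rng)
        sam = tmp_path / "reads.sam"
        write_junction_sam(jt, sam, {model.chrom: default_config.region_span})
        back = extract_junctions(sam, sample="s1")
        a = jt.df.sort_values(["donor_end", "acceptor_start"]).reset_index(drop=True)
        b = back.df.sort_values(["donor_end", "acceptor_start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_tsv_roundtrip_identity(self, default_config, tmp_path, rng):
        model, _ = simulate_reference(default_config)
        jt = simulate_junction_reads(default_config, "hom", model, "s2", rng)
        p = tmp_path / "j.tsv"
        jt.to_tsv(p)
        back = extract_junctions(p)
        pd.testing.assert_frame_equal(jt.df, back.df)


class TestPsi:
    def test_worked_example_20_of_45(self, minus_fixture):
        """25 inclusion / 20 skip reads give PSI 25/45 and skip 20/45."""
        model, _ = minus_fixture
        jt = table_from_counts(model, "carrier", j12=25, j23=25, skip=20)
        ev = exon_psi(jt, model, exon=2, sample="carrier")
        assert ev.inclusion_count == 25 and ev.skip_count == 20
        assert ev.psi == pytest.approx(25 / 45)
        assert ev.skip_fraction == pytest.approx(20 / 45)

    def test_inclusion_averages_flanking_junctions(self, minus_fixture):
        model, _ = minus_fixture
        jt = table_from_counts(model, "s", j12=24, j23=27, skip=0)
        ev = exon_psi(jt, model, 2, "s")
        assert ev.inclusion_count == 26  # (24+27)/2 rounded half-up
        assert ev.psi == 1.0

    def test_no_skip_reads_gives_psi_one(self, minus_fixture):
        model, _ = minus_fixture
        jt = table_from_counts(model, "s", j12=30, j23=30, skip=0)
        assert exon_psi(jt, model, 2, "s").psi == 1.0

    def test_terminal_exon_rejected(self, minus_fixture):
        model, _ = minus_fixture
        jt = table_from_counts(model, "s", 1, 1, 0)
        with pytest.raises(ValueError):
            exon_psi(jt, model, 1, "s")
        with pytest.raises(ValueError):
            exon_psi(jt, model, 4, "s")

    def test_hom_simulation_psi_near_zero(self, default_config, rng):
        model, _ = simulate_reference(default_config)
        jt = simulate_junction_reads(default_config, "hom", model, "s", rng)
        ev = exon_psi(jt, model, 2, "s")
        assert ev.psi == 0.0

    def test_psi_in_unit_interval_all_genotypes(self, default_config, rng):
        model, _ = simulate_reference(default_config)
        for label in ("wt", "het", "hom"):
            for _ in range(10):
                jt = simulate_junction_reads(default_config, label, model,
                                             "s", rng)
                psi = exon_psi(jt, model, 2, "s").psi
                assert 0.0 <= psi <= 1.0


class TestDetectEvents:
    def test_case_fixture_yields_skip_and_cryptic(self, minus_fixture):
        model, seq = minus_fixture
        jt = table_from_counts(model, "case", j12=0, j23=0, skip=15,
                               cryptic=5)
        events = detect_events(jt, model, "case", chrom_seq=seq)
        kinds = {e.type for e in events}
        assert kinds == {"exon_skip", "cryptic_acceptor"}
        skip = next(e for e in events if e.type == "exon_skip")
        assert skip.exon == 2
        assert skip.psi == 0.0
        assert skip.isoform_fractions == {"skip_only": 0.75,
                                          "skip_cryptic": 0.25}
        cry = next(e for e in events if e.type == "cryptic_acceptor")
        assert cry.exon == 3
        assert cry.acceptor_shift == 3
        assert cry.ag_upstream is True

    def test_wild_type_fixture_yields_nothing(self, minus_fixture):
        model, seq = minus_fixture
        jt = table_from_counts(model, "wt", j12=30, j23=30, skip=0)
        assert detect_events(jt, model, "wt", chrom_seq=seq) == []

    def test_min_reads_gate(self, minus_fixture):
        model, seq = minus_fixture
        jt = table_from_counts(model, "s", j12=2, j23=2, skip=3)
        assert detect_events(jt, model, "s", min_reads=10,
                             chrom_seq=seq) == []

    def test_strand_mirror_detects_same_events(self, plus_fixture):
        model, seq = plus_fixture
        jt = table_from_counts(model, "case", j12=10, j23=10, skip=15,
                               cryptic=5)
        events = detect_events(jt, model, "case", chrom_seq=seq)
        skip = next(e for e in events if e.type == "exon_skip")
        cry = next(e for e in events if e.type == "cryptic_acceptor")
        assert skip.exon == 2 and cry.acceptor_shift == 3
        assert cry.ag_upstream is True

    def test_psi_monotone_in_planted_skip_fraction(self, default_config):
        """Measured PSI decreases in the planted skip fraction
        (Spearman |rho| > 0.95 over 50 seeded simulations)."""
        from scipy.stats import spearmanr

        model, _ = simulate_reference(default_config)
        rng = np.random.default_rng(77)
        planted, measured = [], []
        for _ in range(50):
            f = float(rng.uniform(0.02, 0.98))
            cfg = SimConfig(seed=int(rng.integers(0, 2**31)),
                            skip_fraction_het=f, read_depth=120)
            jt = simulate_junction_reads(cfg, "het", model, "s", rng)
            ev = exon_psi(jt, model, 2, "s")
            planted.append(f)
            measured.append(ev.psi)
        rho = spearmanr(planted, measured).statistic
        assert rho < -0.95


class TestRtPcr:
    @pytest.mark.parametrize("fx", ["minus_fixture", "plus_fixture"])
    def test_product_lengths(self, request, fx):
        """Wild type 593 nt; exon-2 skip 377; skip + 3-nt cryptic 374."""
        model, seq = request.getfixturevalue(fx)
        cases = [
            (Isoform((1, 2, 3, 4)), 593),
            (Isoform((1, 3, 4)), 377),
            (Isoform((1, 3, 4), {3: 3}), 374),
        ]
        for iso, expected in cases:
            p = insilico_rtpcr(model, seq, FWD_PRIMER, REV_PRIMER, iso)
            assert p is not None and p.length == expected
            assert len(p.sequence) == expected
            assert p.sequence.startswith(FWD_PRIMER)

    def test_primer_in_skipped_exon_gives_no_product(self, minus_fixture):
        model, seq = minus_fixture
        wt = insilico_rtpcr(model, seq, FWD_PRIMER, REV_PRIMER,
                            Isoform((1, 2, 3, 4)))
        # a primer taken from inside exon 2 of the wild-type product
        exon2_start_in_product = 246  # fwd primer starts at transcript 5
        inner = wt.sequence[exon2_start_in_product:
                            exon2_start_in_product + 20]
        p = insilico_rtpcr(model, seq, inner, REV_PRIMER, Isoform((1, 3, 4)))
        assert p is None

    def test_cryptic_product_lacks_first_lys_codon(self, minus_fixture):
        """The minor isoform is the skip product minus the leading AAG of
        exon 3."""
        model, seq = minus_fixture
        skip = insilico_rtpcr(model, seq, FWD_PRIMER, REV_PRIMER,
                              Isoform((1, 3, 4)))
        cryptic = insilico_rtpcr(model, seq, FWD_PRIMER, REV_PRIMER,
                                 Isoform((1, 3, 4), {3: 3}))
        exon1_tail = 250 - 4  # product part from exon 1 (primer at t5)
        assert skip.sequence[exon1_tail:exon1_tail + 3] == "AAG"
        assert cryptic.sequence == (skip.sequence[:exon1_tail]
                                    + skip.sequence[exon1_tail + 3:])


def test_junction_table_validation():
    with pytest.raises(ValueError):
        JunctionTable(pd.DataFrame([{"chrom": "c", "donor_end": 100,
                                     "acceptor_start": 90, "sample": "s",
                                     "count": 1}]))
    with pytest.raises(ValueError):
        JunctionTable(pd.DataFrame([{"chrom": "c", "donor_end": 10,
                                     "acceptor_start": 90, "sample": "s",
                                     "count": -1}]))


def test_splice_event_psi_bounds():
    with pytest.raises(ValueError):
        SpliceEvent(type="exon_skip", gene_id="g", chrom="c", exon=2,
                    sample="s", psi=1.5)
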