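"""Filter cascade, consequence classification and HGVS parsing."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from recsplice.autozygosity import Interval
from recsplice.simdata import SEQ_CASE_IDS, SEQ_CONTROL_IDS
from recsplice.varfilter import (CASCADE_STAGE_ORDER, Consequence,
                                 VariantRecord, classify_consequence,
                                 filter_cascade, parse_hgvs_c)


def mkvar(pos, qual=500.0, cases=2, controls=0, ref="A", alt="T",
          chrom="chr1"):
    genos = {f"c{i}": cases for i in range(4)}
    genos.update({f"k{i}": controls for i in range(4)})
    return VariantRecord(chrom, pos, ref, alt, qual, genos)


CASES = [f"c{i}" for i in range(4)]
CONTROLS = [f"k{i}" for i in range(4)]
IV = Interval("chr1", 100, 1000)


class TestCascade:
    def test_stage_semantics(self):
        variants = [
            mkvar(500),                      # survivor
            mkvar(50),                       # outside interval
            mkvar(501, qual=100.0),          # exactly at threshold: removed
            mkvar(502, cases=1),             # case not hom-alt
            mkvar(503, controls=1),          # seen in a control
            mkvar(504),                      # in catalog
        ]
        catalog = {("chr1", 504, "A", "T")}
        rep = filter_cascade(variants, IV, CASES, CONTROLS, catalog)
        assert rep.stage_counts == [5, 4, 3, 2, 1]
        assert [v.pos for v in rep.candidates] == [500]
        assert variants[5].in_known_catalog

    def test_empty_variant_list(self):
        rep = filter_cascade([], IV, CASES, CONTROLS)
        assert rep.stage_counts == [0, 0, 0, 0, 0]
        assert rep.candidates == []

    def test_unknown_sample_id_raises(self):
        with pytest.raises(KeyError):
            filter_cascade([mkvar(500)], IV, CASES + ["ghost"], CONTROLS)

    def test_counts_monotone_and_order_invariant(self, default_study):
        study = default_study
        base = filter_cascade(
            study.variants, study.config.interval, SEQ_CASE_IDS,
            SEQ_CONTROL_IDS, known_catalog=study.catalog,
        )
        counts = base.stage_counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        base_keys = {v.key for v in base.candidates}
        # permuting stages 2-5 never changes the final candidate set
        for perm in itertools.permutations(CASCADE_STAGE_ORDER[1:]):
            rep = filter_cascade(
                study.variants, study.config.interval, SEQ_CASE_IDS,
                SEQ_CONTROL_IDS, known_catalog=study.catalog,
                stage_order=(CASCADE_STAGE_ORDER[0],) + perm,
            )
            assert {v.key for v in rep.candidates} == base_keys

    def test_missing_case_genotype_fails_homozygosity(self):
        v = mkvar(500)
        v.genotypes["c0"] = -1
        rep = filter_cascade([v], IV, CASES, CONTROLS)
        assert rep.candidates == []


class TestConsequence:
    def test_planted_causal_variant_is_intronic_minus10(self, minus_fixture,
                                                        default_study):
        model, seq = minus_fixture
        g = model.genomic_from_anchor(parse_hgvs_c("c.211-10C>G", model).anchor)
        v = VariantRecord(model.chrom, g, seq[g - 1], "C", 500.0)
        cons = classify_consequence(v, model, seq)
        assert cons.klass == "intronic"
        assert cons.distance_to_junction == -10
        assert cons.affected_exon == 2

    def test_within_three_bp_is_canonical_splice_region(self, minus_fixture):
        model, seq = minus_fixture
        acc = model.acceptor_site(0)
        g = acc + 3 if model.strand == "-" else acc - 3
        ref = seq[g - 1]
        alt = "A" if ref != "A" else "G"
        cons = classify_consequence(
            VariantRecord(model.chrom, g, ref, alt, 500.0), model, seq
        )
        assert cons.klass == "canonical_splice_region"
        assert cons.distance_to_junction == -3

    def test_synonymous_nonsense_missense_by_retranslation(self,
                                                           minus_fixture,
                                                           rng):
        """Codon classification agrees with brute-force re-translation of
        the whole CDS for random exonic substitutions."""
        model, seq = minus_fixture
        cds_positions = [
            model.t2g(t) for t in range(model.cds_start_t, model.cds_end_t + 1)
        ]
        protein_ref = model.protein_seq(seq)
        checked = {"synonymous": 0, "missense": 0, "nonsense": 0}
        for g in rng.choice(cds_positions, size=120, replace=False):
            g = int(g)
            ref = seq[g - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            cons = classify_consequence(
                VariantRecord(model.chrom, g, ref, alt, 500.0), model, seq
            )
            mutated = seq[: g - 1] + alt + seq[g:]
            protein_alt = model.protein_seq(mutated)
            stop_at = protein_alt.find("*")
            if protein_alt == protein_ref:
                expected = "synonymous"
            elif 0 <= stop_at < len(protein_ref) - 1:
                expected = "nonsense"
            else:
                expected = "missense"
            assert cons.klass == expected, (g, ref, alt)
            checked[expected] += 1
        assert all(v > 0 for v in checked.values())

    def test_identity_codon_is_synonymous(self, minus_fixture):
        model, seq = minus_fixture
        # wobble position of a leucine-family codon: find one empirically
        for t in range(model.cds_start_t + 2, model.cds_end_t, 3):
            g = model.t2g(t)
            ref = seq[g - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                cons = classify_consequence(
                    VariantRecord(model.chrom, g, ref, alt, 500.0), model, seq
                )
                if cons.klass == "synonymous":
                    return
        pytest.fail("no synonymous wobble substitution found in fixture")

    def test_utr_intergenic_and_indel(self, minus_fixture):
        model, seq = minus_fixture
        utr_g = model.t2g(1)  # first transcript base, 5' UTR
        v = VariantRecord(model.chrom, utr_g, seq[utr_g - 1], "A"
                          if seq[utr_g - 1] != "A" else "C", 500.0)
        assert classify_consequence(v, model, seq).klass == "utr"
        out = VariantRecord(model.chrom, 10, seq[9], "A"
                            if seq[9] != "A" else "C", 500.0)
        assert classify_consequence(out, model, seq).klass == "intergenic"
        indel = VariantRecord(model.chrom, utr_g, "AT", "A", 500.0)
        assert classify_consequence(indel, model, seq).klass == "indel"

    def test_strand_mirror_gives_same_classes(self, minus_fixture,
                                              plus_fixture, rng):
        """The mirrored fixture yields identical consequence classes and
        junction distances at equivalent positions."""
        m_model, m_seq = minus_fixture
        p_model, p_seq = plus_fixture
        m_lo, m_hi = m_model.span
        p_lo, _ = p_model.span
        for off in rng.integers(0, m_hi - m_lo + 1, size=60):
            off = int(off)
            gm = m_hi - off  # walk minus fixture from its transcript start
            gp = p_lo + off
            ref_m = m_seq[gm - 1]
            ref_p = p_seq[gp - 1]
            assert ref_p == str(Seq(ref_m).complement())
            alt_m = "A" if ref_m != "A" else "G"
            alt_p = str(Seq(alt_m).complement())
            cm = classify_consequence(
                VariantRecord(m_model.chrom, gm, ref_m, alt_m, 9.9), m_model,
                m_seq)
            cp = classify_consequence(
                VariantRecord(p_model.chrom, gp, ref_p, alt_p, 9.9), p_model,
                p_seq)
            assert cm.klass == cp.klass
            if cm.distance_to_junction is not None:
                assert abs(cm.distance_to_junction) == \
                    abs(cp.distance_to_junction)


class TestHgvs:
    def test_causal_notation(self, minus_fixture):
        model, _ = minus_fixture
        h = parse_hgvs_c("c.211-10C>G", model)
        assert h.cds_pos == 211
        assert h.intron_offset == -10
        assert (h.ref, h.alt) == ("C", "G")
        # minus strand: plus-strand alleles are complemented
        assert (h.ref_fwd, h.alt_fwd) == ("G", "C")
        assert model.intron_of_genomic(h.genomic_pos) == 0

    def test_tolerates_missing_dot(self, minus_fixture):
        model, _ = minus_fixture
        assert parse_hgvs_c("c211-10C>G", model) == \
            parse_hgvs_c("c.211-10C>G", model)

    def test_exonic_anchor(self, minus_fixture):
        model, _ = minus_fixture
        h = parse_hgvs_c("c.100A>T", model)
        assert h.intron_offset == 0
        assert model.g2t(h.genomic_pos) == model.cds_start_t + 99

    @pytest.mark.parametrize("bad", ["c.10", "g.100A>T", "c.100A>",
                                     "c.+5A>T", "c.100AA>T"])
    def test_malformed_rejected(self, minus_fixture, bad):
        model, _ = minus_fixture
        with pytest.raises(ValueError):
            parse_hgvs_c(bad, model)

    def test_offset_outside_intron_rejected(self, minus_fixture):
        model, _ = minus_fixture
        with pytest.raises(ValueError, match="intron"):
            parse_hgvs_c("c.211-9999C>G", model)

    def test_roundtrip_on_random_positions(self, minus_fixture, rng):
        """genomic -> HGVS text -> genomic is the identity."""
        model, seq = minus_fixture
        lo, hi = model.span
        done = 0
        for g in rng.integers(lo, hi + 1, size=200):
            g = int(g)
            anchor = model.anchor_from_genomic(g)
            if anchor.base <= 0:  # UTR designations use a different syntax
                continue
            ref = "A"
            text = f"c.{anchor.base}{anchor.offset:+d}A>G" if anchor.offset \
                else f"c.{anchor.base}A>G"
            h = parse_hgvs_c(text, model)
            assert h.genomic_pos == g
            done += 1
        assert done >= 100
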