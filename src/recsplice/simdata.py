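"""Synthetic study generator: every input the pipeline consumes.

Emulates the structure of a recessive-lethal splice-variant study in an
elite-sire cattle population:

* a half-sib pedigree in which one founder haplotype carries the causal
  allele, every case is homozygous identical-by-descent for it across a
  configured interval, and controls carry it only heterozygously;
* SNP-array-like genotypes (15 cases, 275 controls by default);
* a variant-call set over the mapped interval containing one causal
  intronic acceptor variant among thousands of decoys, constructed so the
  case/control filter cascade leaves 31 candidates (the causal variant
  plus 30 non-coding decoys);
* a four-exon gene fixture whose second exon (216 nt) is skipped on mutant
  transcripts, with a minor isoform additionally using a cryptic acceptor
  3 nt into exon 3; RT-PCR primers in exons 1 and 4 give a 593-nt
  wild-type product, 377 on exon-2 skip and 374 on skip-plus-cryptic;
* junction read counts (Poisson depth) per genotype class, and an assay
  genotype table for the population-validation statistics.

Everything derives from a single seed through independent per-component
streams; identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .autozygosity import GenotypeMatrix, Interval
from .model import CdsAnchor, GeneModel
from .prioritize import CdsExonModel
from .splicing import JunctionTable, JUNCTION_COLUMNS
from .varfilter import VariantRecord

__all__ = [
    "SimConfig",
    "ConfigError",
    "PopulationSim",
    "VariantTruth",
    "SimStudy",
    "EXON_LENS",
    "INTRON_LENS",
    "FWD_PRIMER",
    "REV_PRIMER",
    "PROTEIN_DOMAINS",
    "fixture_gene",
    "fixture_reference",
    "fixture_protein_model",
    "conservation_alignment_fixture",
    "simulate_population",
    "simulate_variant_calls",
    "simulate_junction_reads",
    "simulate_assay_table",
    "simulate_study",
]


class ConfigError(ValueError):
    """Raised for impossible simulation configurations."""


# --------------------------------------------------------------------- #
# fixture gene: 4 exons, 216-nt exon 2, engineered splice sites

EXON_LENS = (250, 216, 87, 150)
INTRON_LENS = (400, 350, 300)
UTR5_LEN = 40
CDS_LEN = 567  # 188 codons + stop
TRANSCRIPT_LEN = sum(EXON_LENS)
GENE_LEN = TRANSCRIPT_LEN + sum(INTRON_LENS)

FWD_PRIMER = "TCTCTTTGCGCTCGCTCACC"  # sits in exon 1 (5' UTR)
REV_PRIMER = "GATCCACCACATCCATACTGG"  # sits in exon 4 (CDS)
_FWD_T0 = 4  # 0-based transcript offset of the forward primer
_REV_T0 = 576  # 0-based offset of the reverse primer's sense-strand site

# acceptor tail (transcribed strand, last 20 nt of each intron):
# -20..-17 | polypyrimidine tract -16..-5 (C at -10) | -4..-3 | AG
ACCEPTOR_TAIL = "GAAA" + "TTTTTTCTTTTT" + "CA" + "AG"

PROTEIN_DOMAINS = [
    ("N-terminal cytoplasmic", 1, 37),
    ("TM helix 1", 38, 55),
    ("ER luminal loop", 56, 59),
    ("TM helix 2", 60, 78),
    ("C-terminal cytoplasmic", 79, 188),
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            return c


def _build_transcript(rng: np.random.Generator) -> str:
    """Mature mRNA of the fixture gene (transcribed strand, 703 nt)."""
    utr5 = list(_random_seq(rng, UTR5_LEN))
    utr5[_FWD_T0 : _FWD_T0 + len(FWD_PRIMER)] = FWD_PRIMER
    codons = ["ATG"] + [_random_codon(rng) for _ in range(187)] + ["TAA"]
    codons[142] = "AAG"  # first codon of exon 3: Lys, ends in the AG
    cds = list("".join(codons))
    rev_site = str(Seq(REV_PRIMER).reverse_complement())
    c0 = _REV_T0 - UTR5_LEN  # CDS offset of the reverse-primer site
    cds[c0 : c0 + len(rev_site)] = rev_site
    cds = "".join(cds)
    for k in range(0, CDS_LEN - 3, 3):
        assert cds[k : k + 3] not in _STOPS, "premature stop in fixture CDS"
    utr3 = _random_seq(rng, TRANSCRIPT_LEN - UTR5_LEN - CDS_LEN)
    transcript = "".join(utr5) + cds + utr3
    assert len(transcript) == TRANSCRIPT_LEN
    assert transcript.count(FWD_PRIMER) == 1
    assert transcript.count(rev_site) == 1
    return transcript


def _build_pre_mrna(rng: np.random.Generator) -> str:
    """Unspliced transcript: exons interleaved with GT..AG introns whose
    acceptors carry the engineered polypyrimidine tail."""
    transcript = _build_transcript(rng)
    t_spans = []
    t = 0
    for L in EXON_LENS:
        t_spans.append((t, t + L))
        t += L
    pieces = []
    for i, (a, b) in enumerate(t_spans):
        pieces.append(transcript[a:b])
        if i < len(INTRON_LENS):
            interior = _random_seq(rng, INTRON_LENS[i] - 2 - len(ACCEPTOR_TAIL))
            pieces.append("GT" + interior + ACCEPTOR_TAIL)
    pre = "".join(pieces)
    assert len(pre) == GENE_LEN
    return pre


def fixture_gene(
    strand: str = "-",
    chrom: str = "chrF",
    gene_start: int = 1001,
    seed: int = 0,
) -> tuple[GeneModel, str]:
    """Build the packaged 4-exon gene fixture.

    Returns the gene model and the plus-strand sequence of the gene body
    (``GENE_LEN`` nt starting at genomic position ``gene_start``).  The
    fixture is generated on the minus strand by default, which forces all
    coordinate code through the strand-aware paths.
    """
    rng = np.random.default_rng(seed)
    pre = _build_pre_mrna(rng)

    # pre-mRNA offsets (0-based, transcription direction) of each exon
    offsets = []
    o = 0
    for i, L in enumerate(EXON_LENS):
        offsets.append((o, o + L - 1))
        o += L
        if i < len(INTRON_LENS):
            o += INTRON_LENS[i]

    if strand == "+":
        plus_seq = pre
        exons = [(gene_start + a, gene_start + b) for a, b in offsets]
    elif strand == "-":
        plus_seq = str(Seq(pre).reverse_complement())
        last = GENE_LEN - 1
        exons = [
            (gene_start + (last - b), gene_start + (last - a))
            for a, b in offsets
        ]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    model = GeneModel(
        gene_id="PIGH_like",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_t=UTR5_LEN + 1,
        cds_end_t=UTR5_LEN + CDS_LEN,
    )
    return model, plus_seq


def fixture_reference(
    strand: str = "-",
    chrom: str = "chrF",
    chrom_len: int = 4000,
    gene_start: int = 1001,
    seed: int = 0,
) -> tuple[GeneModel, str]:
    """Gene fixture embedded in a random chromosome of ``chrom_len`` nt."""
    if gene_start + GENE_LEN - 1 > chrom_len:
        raise ConfigError("gene does not fit in the requested chromosome")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    model, gene_seq = fixture_gene(strand, chrom, gene_start, seed)
    left = _random_seq(rng, gene_start - 1)
    right = _random_seq(rng, chrom_len - (gene_start - 1) - GENE_LEN)
    return model, left + gene_seq + right


def causal_anchor() -> CdsAnchor:
    """The planted causal variant: intron-1 position 10 nt upstream of the
    exon-2 acceptor, i.e. c.211-10 (exon 2 starts at c.211)."""
    return CdsAnchor(211, -10)


def causal_variant(model: GeneModel, chrom_seq: str,
                   genotypes: dict[str, int] | None = None,
                   qual: float = 2000.0) -> VariantRecord:
    """The planted c.211-10C>G substitution as a plus-strand VCF record."""
    g = model.genomic_from_anchor(causal_anchor())
    ref = chrom_seq[g - 1]
    alt = "G" if model.strand == "+" else "C"
    expected_ref = "C" if model.strand == "+" else "G"
    assert ref.upper() == expected_ref, "fixture acceptor tail out of register"
    return VariantRecord(
        chrom=model.chrom, pos=g, ref=ref.upper(), alt=alt, qual=qual,
        genotypes=dict(genotypes or {}), vid="causal",
    )


def fixture_protein_model() -> tuple[CdsExonModel, list[tuple[str, int, int]]]:
    """CDS architecture matching the published protein annotation of the
    real gene: 188 residues, exon 2 contributing CDS nucleotides 181-390
    so that skipping it removes amino acids 61-130.

    This is a synthetic stand-in parameterized to the reported protein,
    kept separate from the splice fixture (whose exon 2 is 216 nt and
    starts at c.211, removing codons 71-142 when skipped): the two
    published coordinate systems are not mutually consistent, and this
    model reproduces the protein-level report.
    """
    cds = CdsExonModel(
        protein_length=188,
        exon_cds_spans=((1, 180), (181, 390), (391, 480), (481, 567)),
    )
    return cds, list(PROTEIN_DOMAINS)


def conservation_alignment_fixture(
    n_species: int = 27, seed: int = 0
) -> tuple[list[tuple[str, str]], int]:
    """Synthetic 27-mammal alignment of the intron-1 acceptor window.

    Returns (records, focal_column): aligned 23-nt sequences, one per
    species, and the 0-based column of the -10 tract position.  Exactly
    one species mismatches the reference base at the focal column; other
    columns carry light random divergence away from the splice signals.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    _, gene_seq = fixture_gene(strand="+", gene_start=1, seed=seed)
    # acceptor window of intron 1 on the transcribed strand
    acc_off = EXON_LENS[0] + INTRON_LENS[0]  # 0-based pre-mRNA offset of exon 2
    window = gene_seq[acc_off - 20 : acc_off + 3]
    focal = 10  # column of offset -10 in a -20..+3 window
    frozen = set(range(4, 16)) | {18, 19}  # tract and AG stay put
    records = []
    mismatch_species = int(rng.integers(0, n_species))
    for k in range(n_species):
        s = list(window)
        for col in range(len(s)):
            if col in frozen or col == focal:
                continue
            if rng.random() < 0.10:
                s[col] = "ACGT"[rng.integers(0, 4)]
        if k == mismatch_species:
            s[focal] = "A"
        records.append((f"species_{k + 1:02d}", "".join(s)))
    return records, focal


# --------------------------------------------------------------------- #
# study configuration

@dataclass(frozen=True)
class SimConfig:
    """Study design constants for the synthetic population.

    Defaults mirror the study structure: 15 genotyped cases and 275
    control sires on a shared marker panel, a shared homozygous interval
    covering 22% of the simulated region, ~50% exon skipping in carrier
    transcripts (complete in homozygotes) with a 75/25 split between
    skip-only and skip-plus-cryptic isoforms, 45 junction reads of depth,
    and 2,968 interval variants of quality above 100 of which 31 survive
    the filter cascade.
    """

    n_cases: int = 15
    n_controls: int = 275
    n_markers: int = 324
    region_span: int = 1_000_000
    ibd_interval: float = 0.22
    carrier_freq_controls: float = 0.06
    n_decoy_variants: int = 2967
    skip_fraction_het: float = 0.5
    skip_fraction_hom: float = 1.0
    cryptic_fraction: float = 0.25
    read_depth: float = 45.0
    seed: int = 0
    # decoy-pool structure
    n_candidate_decoys: int = 30
    n_offinterval_decoys: int = 150
    n_lowqual_decoys: int = 150
    strand: str = "-"
    chrom: str = "chr10"

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_markers", "region_span"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "ibd_interval", "carrier_freq_controls", "skip_fraction_het",
            "skip_fraction_hom", "cryptic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.ibd_interval < 1.0:
            raise ConfigError("ibd_interval must be a fraction in (0, 1)")
        if self.read_depth <= 0:
            raise ConfigError("read_depth must be positive")
        if self.n_decoy_variants < 0 or self.n_candidate_decoys < 0:
            raise ConfigError("decoy counts must be non-negative")
        if self.n_candidate_decoys > self.n_decoy_variants and self.n_decoy_variants:
            raise ConfigError("n_candidate_decoys exceeds n_decoy_variants")
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")
        lo, hi = self.interval_bounds
        if hi - lo + 1 < GENE_LEN + 400:
            raise ConfigError("IBD interval too small to contain the gene")

    @property
    def interval_bounds(self) -> tuple[int, int]:
        span = int(self.region_span * self.ibd_interval)
        lo = self.region_span // 2 - span // 2
        return lo, lo + span - 1

    @property
    def interval(self) -> Interval:
        lo, hi = self.interval_bounds
        return Interval(self.chrom, lo, hi)

    @property
    def gene_start(self) -> int:
        return self.region_span // 2 - GENE_LEN // 2

    def streams(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ("population", "reference", "variants", "junctions", "assay")
        children = ss.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# --------------------------------------------------------------------- #
# population

@dataclass
class PopulationSim:
    pedigree: pd.DataFrame  # id, sire, dam, role
    matrix: GenotypeMatrix
    haplotypes: dict[str, np.ndarray]  # sample -> (2, n_markers) 0/1
    carries_hstar: pd.DataFrame  # sample, hap0, hap1 (bool over interval)
    truth_interval: Interval
    case_ids: list[str]
    control_ids: list[str]
    hstar: np.ndarray


def _draw_hap(rng, freqs) -> np.ndarray:
    return (rng.random(freqs.size) < freqs).astype(np.int8)


def simulate_population(config: SimConfig) -> PopulationSim:
    """Simulate the pedigree and SNP genotypes.

    One founder haplotype (H*) carries the causal allele.  The elite sire
    is a carrier; each case is produced by mating the sire to one of his
    own carrier daughters, so every case receives H* through both paths
    and is homozygous IBD across the interval.  Within the interval H* is
    transmitted without recombination; single crossovers are drawn
    uniformly in the flanks.  Controls are unrelated and carry H* at
    ``carrier_freq_controls``, never homozygous.
    """
    rng = config.streams()["population"]
    lo, hi = config.interval_bounds
    pos = np.sort(
        rng.choice(np.arange(1, config.region_span + 1),
                   size=config.n_markers, replace=False)
    )
    in_interval = (pos >= lo) & (pos <= hi)
    if in_interval.sum() < 3:
        raise ConfigError("too few markers fall inside the IBD interval")
    freqs = rng.uniform(0.05, 0.95, config.n_markers)
    hstar = _draw_hap(rng, freqs)
    # recombination confined to a one-marker-spacing zone at each interval
    # boundary: the configured interval IS the breakpoint-delimited shared
    # segment, as a mapped region is reported from real data
    zone = max(1, config.region_span // config.n_markers)

    def _breakpoints() -> tuple[int, int]:
        lb = int(rng.integers(max(1, lo - zone), lo)) if lo > 1 else 1
        rb = int(rng.integers(hi + 1,
                              min(config.region_span, hi + zone) + 1))
        return lb, rb

    def hstar_mosaic() -> np.ndarray:
        """H* across the interval, recombining into background at the edges."""
        bg = _draw_hap(rng, freqs)
        lb, rb = _breakpoints()
        seg = (pos >= lb) & (pos <= rb)
        return np.where(seg, hstar, bg).astype(np.int8)

    def transmit(haps: tuple[np.ndarray, np.ndarray], carry_idx: int | None
                 ) -> np.ndarray:
        if carry_idx is not None:
            keep, other = haps[carry_idx], haps[1 - carry_idx]
            lb, rb = _breakpoints()
            seg = (pos >= lb) & (pos <= rb)
            return np.where(seg, keep, other).astype(np.int8)
        a, b = haps if rng.random() < 0.5 else haps[::-1]
        cx = int(rng.integers(1, config.region_span + 1))
        return np.where(pos < cx, a, b).astype(np.int8)

    haplotypes: dict[str, np.ndarray] = {}
    pedigree_rows = []
    case_ids, control_ids = [], []

    sire = "sire0"
    haplotypes[sire] = np.stack([hstar.copy(), _draw_hap(rng, freqs)])
    pedigree_rows.append((sire, ".", ".", "sire"))

    for i in range(1, config.n_cases + 1):
        fdam, dam, case = f"fdam{i:02d}", f"dam{i:02d}", f"case{i:02d}"
        haplotypes[fdam] = np.stack([_draw_hap(rng, freqs),
                                     _draw_hap(rng, freqs)])
        pedigree_rows.append((fdam, ".", ".", "founder_dam"))
        dam_pat = transmit(tuple(haplotypes[sire]), carry_idx=0)
        dam_mat = transmit(tuple(haplotypes[fdam]), carry_idx=None)
        haplotypes[dam] = np.stack([dam_pat, dam_mat])
        pedigree_rows.append((dam, sire, fdam, "dam"))
        case_pat = transmit(tuple(haplotypes[sire]), carry_idx=0)
        case_mat = transmit(tuple(haplotypes[dam]), carry_idx=0)
        haplotypes[case] = np.stack([case_pat, case_mat])
        pedigree_rows.append((case, sire, dam, "case"))
        case_ids.append(case)

    iv = in_interval
    for j in range(1, config.n_controls + 1):
        ctrl = f"ctrl{j:03d}"
        if rng.random() < config.carrier_freq_controls:
            hap_a = hstar_mosaic()
        else:
            hap_a = _draw_hap(rng, freqs)
        while True:
            hap_b = _draw_hap(rng, freqs)
            if not np.array_equal(hap_b[iv], hstar[iv]):
                break
        haplotypes[ctrl] = np.stack([hap_a, hap_b])
        pedigree_rows.append((ctrl, ".", ".", "control"))
        control_ids.append(ctrl)

    samples = [r[0] for r in pedigree_rows]
    genos = np.stack([haplotypes[s].sum(axis=0) for s in samples]).astype(np.int8)
    markers = pd.DataFrame(
        {
            "id": [f"snp{k + 1:04d}" for k in range(config.n_markers)],
            "chrom": config.chrom,
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "B",
        }
    )
    matrix = GenotypeMatrix(samples, markers, genos)
    carries = pd.DataFrame(
        {
            "sample": samples,
            "hap0": [bool(np.array_equal(haplotypes[s][0][iv], hstar[iv]))
                     for s in samples],
            "hap1": [bool(np.array_equal(haplotypes[s][1][iv], hstar[iv]))
                     for s in samples],
        }
    )
    pedigree = pd.DataFrame(pedigree_rows,
                            columns=["id", "sire", "dam", "role"])
    return PopulationSim(
        pedigree=pedigree,
        matrix=matrix,
        haplotypes=haplotypes,
        carries_hstar=carries,
        truth_interval=config.interval,
        case_ids=case_ids,
        control_ids=control_ids,
        hstar=hstar,
    )


def simulate_null_population(
    n_cases: int,
    n_controls: int,
    n_markers: int,
    region_span: int,
    seed: int,
    chrom: str = "chr10",
) -> tuple[GenotypeMatrix, list[str], list[str]]:
    """Null model: cases and controls drawn from one unstructured
    population (no founder haplotype, no autozygosity).  Used to
    calibrate the sharing scan's false-positive behaviour."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    pos = np.sort(
        rng.choice(np.arange(1, region_span + 1), size=n_markers,
                   replace=False)
    )
    freqs = rng.uniform(0.05, 0.95, n_markers)
    n = n_cases + n_controls
    genos = (
        (rng.random((n, n_markers)) < freqs).astype(np.int8)
        + (rng.random((n, n_markers)) < freqs).astype(np.int8)
    )
    case_ids = [f"ncase{i:02d}" for i in range(1, n_cases + 1)]
    control_ids = [f"nctrl{i:03d}" for i in range(1, n_controls + 1)]
    markers = pd.DataFrame(
        {
            "id": [f"snp{k + 1:04d}" for k in range(n_markers)],
            "chrom": chrom,
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "B",
        }
    )
    matrix = GenotypeMatrix(case_ids + control_ids, markers, genos)
    return matrix, case_ids, control_ids


# --------------------------------------------------------------------- #
# reference and variant calls

def simulate_reference(config: SimConfig) -> tuple[GeneModel, str]:
    """Random chromosome of ``region_span`` nt with the gene fixture
    embedded at the centre of the IBD interval."""
    rng = config.streams()["reference"]
    model, gene_seq = fixture_gene(
        strand=config.strand, chrom=config.chrom,
        gene_start=config.gene_start, seed=config.seed,
    )
    gs = config.gene_start
    left = _random_seq(rng, gs - 1)
    right = _random_seq(rng, config.region_span - (gs - 1) - GENE_LEN)
    return model, left + gene_seq + right


@dataclass
class VariantTruth:
    causal_key: tuple[str, int, str, str]
    causal_vid: str
    candidate_keys: set[tuple[str, int, str, str]]
    case_ids: list[str]
    control_ids: list[str]


SEQ_CASE_IDS = [f"case{i:02d}" for i in range(1, 5)]
SEQ_CONTROL_IDS = [f"seqctl{i:02d}" for i in range(1, 16)]

_OFF_INTERVAL_BUFFER = 20_000


def simulate_variant_calls(
    config: SimConfig,
    model: GeneModel,
    chrom_seq: str,
) -> tuple[list[VariantRecord], VariantTruth, set]:
    """Variant calls for 4 sequenced cases and 15 sequenced controls.

    The in-interval, quality>100 set comprises one causal variant plus
    ``n_decoy_variants`` decoys, of which ``n_candidate_decoys`` survive
    the whole cascade (placed away from the gene so they cannot outrank
    the causal variant on RNA evidence); the rest fail the homozygosity,
    control-absence or known-catalog stage.  Additional pools carry decoys
    of low quality and decoys outside the interval.  Returns the records,
    the truth labels, and the synthetic known-variant catalog.
    """
    rng = config.streams()["variants"]
    lo, hi = config.interval_bounds
    cases, controls = SEQ_CASE_IDS, SEQ_CONTROL_IDS

    def geno(case_code, control_codes) -> dict[str, int]:
        g = {s: case_code if np.isscalar(case_code) else case_code[i]
             for i, s in enumerate(cases)}
        for i, s in enumerate(controls):
            g[s] = control_codes if np.isscalar(control_codes) else control_codes[i]
        return g

    used = set()

    def draw_positions(n, lo_p, hi_p, exclude=()):
        out = []
        forbidden = used.union(exclude)
        while len(out) < n:
            p = int(rng.integers(lo_p, hi_p + 1))
            if p in forbidden:
                continue
            forbidden.add(p)
            used.add(p)
            out.append(p)
        return out

    def alt_for(ref):
        choices = [b for b in "ACGT" if b != ref.upper()]
        return choices[int(rng.integers(0, 3))]

    variants: list[VariantRecord] = []
    catalog: set[tuple[str, int, str, str]] = set()

    causal = causal_variant(model, chrom_seq, genotypes=geno(2, 0),
                            qual=float(rng.uniform(500, 3000)))
    used.add(causal.pos)
    variants.append(causal)

    g_lo, g_hi = model.span
    gene_buffer = 200
    # n_decoy_variants = 0 means a bare causal record: no decoy pools at all
    bare = config.n_decoy_variants == 0
    n_candidates = min(config.n_candidate_decoys, config.n_decoy_variants)
    n_fail = config.n_decoy_variants - n_candidates

    # cascade survivors: non-coding decoys away from the gene, kept clear
    # of the interval edges so the marker-delimited mapped segment (which
    # starts at the outermost qualifying marker, up to a few marker
    # spacings inside the true boundary) always contains them
    margin = 8 * config.region_span // config.n_markers
    cand_lo, cand_hi = lo + margin, hi - margin
    cand_pos = []
    while len(cand_pos) < n_candidates:
        p = int(rng.integers(cand_lo, cand_hi + 1))
        if p in used or (g_lo - gene_buffer) <= p <= (g_hi + gene_buffer):
            continue
        used.add(p)
        cand_pos.append(p)
    candidate_keys = set()
    for k, p in enumerate(cand_pos):
        ref = chrom_seq[p - 1].upper()
        v = VariantRecord(config.chrom, p, ref, alt_for(ref),
                          qual=float(rng.uniform(101, 3000)),
                          genotypes=geno(2, 0), vid=f"cand{k:03d}")
        candidate_keys.add(v.key)
        variants.append(v)

    # in-interval decoys that fail one of stages 3-5
    for k, p in enumerate(draw_positions(n_fail, lo, hi)):
        ref = chrom_seq[p - 1].upper()
        v = VariantRecord(config.chrom, p, ref, alt_for(ref),
                          qual=float(rng.uniform(101, 3000)),
                          genotypes=geno(2, 0), vid=f"fail{k:04d}")
        mode = rng.choice(("case_not_hom", "control_carries", "in_catalog"),
                          p=(0.5, 0.4, 0.1))
        if mode == "case_not_hom":
            v.genotypes[cases[int(rng.integers(0, len(cases)))]] = int(
                rng.integers(0, 2)
            )
        elif mode == "control_carries":
            idx = rng.integers(0, len(controls),
                               size=int(rng.integers(1, 4)))
            for i in set(int(x) for x in idx):
                v.genotypes[controls[i]] = int(rng.integers(1, 3))
            if rng.random() < 0.3:
                catalog.add(v.key)
        else:
            catalog.add(v.key)
        variants.append(v)

    # low-quality decoys inside the interval (first few exactly at 100)
    n_lowqual = 0 if bare else config.n_lowqual_decoys
    for k, p in enumerate(draw_positions(n_lowqual, lo, hi)):
        ref = chrom_seq[p - 1].upper()
        qual = 100.0 if k < 5 else float(rng.uniform(20, 100))
        variants.append(
            VariantRecord(config.chrom, p, ref, alt_for(ref), qual=qual,
                          genotypes=geno(2, 0), vid=f"lowq{k:03d}")
        )

    # decoys outside the interval
    n_off = 0 if bare else config.n_offinterval_decoys
    left_n = n_off // 2
    off_pos = []
    if lo - _OFF_INTERVAL_BUFFER > 2:
        off_pos += draw_positions(left_n, 1, lo - _OFF_INTERVAL_BUFFER)
    if hi + _OFF_INTERVAL_BUFFER < config.region_span - 1:
        off_pos += draw_positions(n_off - len(off_pos),
                                  hi + _OFF_INTERVAL_BUFFER, config.region_span)
    for k, p in enumerate(off_pos):
        ref = chrom_seq[p - 1].upper()
        gt = geno(int(rng.integers(0, 3)), 0)
        variants.append(
            VariantRecord(config.chrom, p, ref, alt_for(ref),
                          qual=float(rng.uniform(50, 3000)),
                          genotypes=gt, vid=f"off{k:03d}")
        )

    # catalog noise: known variants that were not even called here
    for p in draw_positions(0 if bare else 50, lo, hi):
        ref = chrom_seq[p - 1].upper()
        catalog.add((config.chrom, p, ref, alt_for(ref)))

    variants.sort(key=lambda v: (v.chrom, v.pos))
    truth = VariantTruth(
        causal_key=causal.key,
        causal_vid="causal",
        candidate_keys=candidate_keys | {causal.key},
        case_ids=cases,
        control_ids=controls,
    )
    return variants, truth, catalog


# --------------------------------------------------------------------- #
# junction reads

GENOTYPE_LABELS = ("wt", "het", "hom")


def simulate_junction_reads(
    config: SimConfig,
    genotype_at_locus: str,
    model: GeneModel,
    sample: str,
    rng: np.random.Generator | None = None,
    depth: float | None = None,
) -> JunctionTable:
    """Junction read counts for one sample of the given genotype class.

    The number of transcripts observed at the locus is Poisson around
    ``read_depth``; each mutant-allele transcript skips exon 2, and a
    ``cryptic_fraction`` of the aberrant transcripts additionally use the
    cryptic acceptor 3 nt into exon 3.  Each transcript contributes one
    read to every junction it spans.
    """
    if genotype_at_locus not in GENOTYPE_LABELS:
        raise ValueError(
            f"unknown genotype label {genotype_at_locus!r}; "
            f"expected one of {GENOTYPE_LABELS}"
        )
    if rng is None:
        rng = config.streams()["junctions"]
    skip_frac = {
        "wt": 0.0,
        "het": config.skip_fraction_het,
        "hom": config.skip_fraction_hom,
    }[genotype_at_locus]
    n = int(rng.poisson(depth if depth is not None else config.read_depth))
    aberrant = int(rng.binomial(n, skip_frac)) if n else 0
    cryptic = int(rng.binomial(aberrant, config.cryptic_fraction)) if aberrant else 0
    skip_only = aberrant - cryptic
    inclusion = n - aberrant

    j12 = model.junction(0)
    j23 = model.junction(1)
    j34 = model.junction(2)
    skip_j = model.skip_junction(1)
    g_acc3 = model.acceptor_site(1)
    cryptic_acc = model.shift_acceptor(g_acc3, 3)
    d_skip = model.donor_site(0)
    cj = (d_skip, cryptic_acc) if d_skip < cryptic_acc else (cryptic_acc, d_skip)

    rows = []
    for (d, a), count in (
        (j12, inclusion),
        (j23, inclusion),
        (skip_j, skip_only),
        (cj, cryptic),
        (j34, n),
    ):
        if count > 0:
            rows.append({"chrom": model.chrom, "donor_end": d,
                         "acceptor_start": a, "sample": sample,
                         "count": count})
    return JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))


# --------------------------------------------------------------------- #
# assay table

def simulate_assay_table(
    config: SimConfig,
    n_assay_cases: int = 25,
    n_parents: int = 21,
    n_population: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Genotyping-assay table: cases homozygous risk, parents obligate
    heterozygotes, and a healthy population carrying the allele at
    ``carrier_freq_controls`` with no homozygotes (recessive lethal)."""
    if rng is None:
        rng = config.streams()["assay"]
    rows = []
    for i in range(1, n_assay_cases + 1):
        rows.append((f"acase{i:03d}", "case", "AA"))
    for i in range(1, n_parents + 1):
        rows.append((f"parent{i:03d}", "parent", "RA"))
    carrier = rng.random(n_population) < config.carrier_freq_controls
    for i in range(n_population):
        rows.append((f"pop{i + 1:05d}", "population",
                     "RA" if carrier[i] else "RR"))
    return pd.DataFrame(rows, columns=["id", "role", "genotype"])


# --------------------------------------------------------------------- #
# whole study

@dataclass
class SimStudy:
    """Everything one simulated study produces, with truth labels."""

    config: SimConfig
    population: PopulationSim
    model: GeneModel
    chrom_seq: str
    variants: list[VariantRecord]
    variant_truth: VariantTruth
    catalog: set
    junctions: JunctionTable
    rna_samples: dict[str, str]  # sample -> genotype label
    assay: pd.DataFrame


def simulate_study(config: SimConfig,
                   n_population_assay: int = 10_000) -> SimStudy:
    """Run every generator with per-component streams from one seed."""
    population = simulate_population(config)
    model, chrom_seq = simulate_reference(config)
    variants, vtruth, catalog = simulate_variant_calls(config, model, chrom_seq)

    jrng = config.streams()["junctions"]
    rna_samples = {"fetus_carrier": "het", "case_rna": "hom", "control_rna": "wt"}
    frames = []
    for sample, label in rna_samples.items():
        jt = simulate_junction_reads(config, label, model, sample, rng=jrng)
        frames.append(jt.df)
    junctions = JunctionTable(pd.concat(frames, ignore_index=True))

    assay = simulate_assay_table(config, n_population=n_population_assay)
    return SimStudy(
        config=config,
        population=population,
        model=model,
        chrom_seq=chrom_seq,
        variants=variants,
        variant_truth=vtruth,
        catalog=catalog,
        junctions=junctions,
        rna_samples=rna_samples,
        assay=assay,
    )
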