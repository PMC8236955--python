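"""Synthetic panel, sample-evidence and cohort generation with known truth.

Everything downstream of read alignment is testable against this module:
it fabricates a targeted panel (gene models with exons and protein domains,
coverage bins with GC content, ~5,000 SNP loci, 100 microsatellite loci) on
fictional 0-based half-open coordinates, and simulates pileup-level
tumor/normal evidence for cohorts with per-site mutation loads, a
C>T-dominated substitution spectrum, recurrent copy-number events
(an 11q13-like co-amplified CCND1/FGF4/FGF3/FGF19 block, CDKN2A/CDKN2B
deletions), TEX10-NTRK2-style fusions and MSI-H/MSS samples.

Noise model: per-site and per-bin depths are negative binomial around the
configured means (tumor 730x, normal 343x, dispersion 0.1); alt reads are
binomial at the purity- and copy-number-adjusted allele fraction; sequencing
error adds binomial noise at rate 1e-3; bin depths are modulated by a smooth
GC bias curve; het-SNP BAFs are binomial around the allele-specific
expectation; fusions emit discordant read pairs flanking both breakpoints;
unstable microsatellite loci receive left-shifted, widened tumor histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .msi import MSLocusProfile
from .svfusion import Breakend, DiscordantRead
from .variants import PileupSite

__all__ = [
    "GeneModel",
    "PanelDefinition",
    "SomaticVariant",
    "CNSegmentTruth",
    "FusionTruth",
    "SampleTruth",
    "CohortConfig",
    "SNPBafRecord",
    "SampleEvidence",
    "ANATOMIC_SITES",
    "generate_panel",
    "simulate_sample_evidence",
    "simulate_cohort",
    "write_fixtures",
    "read_fixtures",
]

ANATOMIC_SITES = (
    "paranasal_sinus",
    "nasopharynx",
    "larynx",
    "oral_cavity",
    "hypopharynx",
    "oropharynx",
    "unknown",
)

#: Cohort composition of the emulated study (317 tumors).
DEFAULT_SITE_COUNTS = {
    "paranasal_sinus": 4,
    "nasopharynx": 83,
    "larynx": 60,
    "oral_cavity": 111,
    "hypopharynx": 36,
    "oropharynx": 7,
    "unknown": 16,
}

#: Mean non-synonymous mutations per tumor by anatomic site; sites without a
#: reported mean fall back to the cohort-wide 5.5.
DEFAULT_SITE_LOADS = {
    "nasopharynx": 3.6,
    "oral_cavity": 4.5,
    "hypopharynx": 7.3,
    "larynx": 8.3,
}
DEFAULT_MEAN_LOAD = 5.5

#: Per-(gene, site) mutated-sample frequencies for recurrently mutated genes.
DEFAULT_GENE_FREQ = {
    ("TP53", "hypopharynx"): 0.861,
    ("TP53", "larynx"): 0.900,
    ("TP53", "nasopharynx"): 0.241,
    ("TP53", "oral_cavity"): 0.703,
    ("CYLD", "nasopharynx"): 9 / 83,
    ("CYLD", "larynx"): 0.019,
    ("CYLD", "oral_cavity"): 0.019,
    ("CYLD", "hypopharynx"): 0.019,
    ("BAP1", "nasopharynx"): 8 / 83,
    ("BAP1", "larynx"): 0.024,
    ("BAP1", "oral_cavity"): 0.024,
    ("BAP1", "hypopharynx"): 0.024,
    ("KMT2D", "larynx"): 0.333,
    ("KMT2D", "hypopharynx"): 0.139,
    ("KMT2D", "nasopharynx"): 0.096,
    ("KMT2D", "oral_cavity"): 0.072,
}

#: Pyrimidine-normalized substitution spectrum (C>T transitions dominate,
#: then C>A transversions).
DEFAULT_SPECTRUM = {
    "C>A": 0.224,
    "C>G": 0.100,
    "C>T": 0.422,
    "T>A": 0.060,
    "T>C": 0.140,
    "T>G": 0.054,
}

# Recurrently altered genes placed first on the panel, with their fictional
# chromosomes. CCND1/FGF4/FGF3/FGF19 are laid down adjacently to emulate an
# 11q13-like co-amplified block, CDKN2A/CDKN2B likewise.
_SPECIAL_GENES = [
    ("TP53", "chr17"),
    ("CYLD", "chr16"),
    ("BAP1", "chr3"),
    ("PIK3CA", "chr3"),
    ("CDKN2A", "chr9"),
    ("CDKN2B", "chr9"),
    ("CCND1", "chr11"),
    ("FGF4", "chr11"),
    ("FGF3", "chr11"),
    ("FGF19", "chr11"),
    ("TEX10", "chr5"),
    ("NTRK2", "chr9"),
    ("MYC", "chr8"),
    ("KMT2D", "chr12"),
    ("FAT1", "chr4"),
    ("NOTCH1", "chr9"),
    ("CHD4", "chr12"),
    ("LRP1B", "chr2"),
    ("CDKN1B", "chr12"),
    ("EGFR", "chr7"),
    ("ERBB2", "chr17"),
    ("FGFR1", "chr8"),
    ("NFKBIA", "chr14"),
    ("CTNNB1", "chr3"),
    ("TRAF3", "chr14"),
    ("NLRC5", "chr16"),
    ("HRAS", "chr11"),
]

_INTRON_BP = 2000
_GENE_GAP_BP = 50_000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    name: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted
    domains: tuple[tuple[str, int, int], ...] = ()  # (name, start, end)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if not start < end:
                raise ValueError(f"{self.name}: empty exon interval [{start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.name}: exons overlap or are unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class Bin:
    chrom: str
    start: int
    end: int
    gc_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SNPLocus:
    chrom: str
    pos: int
    population_het: bool


@dataclass(frozen=True)
class MSLocus:
    locus_id: str
    chrom: str
    pos: int
    repeat_unit: str
    ref_repeat_length: int


@dataclass(frozen=True)
class PanelDefinition:
    genes: tuple[GeneModel, ...]
    bins: tuple[Bin, ...]
    snp_loci: tuple[SNPLocus, ...]
    ms_loci: tuple[MSLocus, ...]
    target_size_bp: int

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def has_gene(self, name: str) -> bool:
        return any(g.name == name for g in self.genes)

    def gene_at(self, chrom: str, pos: int) -> Optional[GeneModel]:
        for g in self.genes:
            if g.chromosome == chrom and g.start <= pos < g.end:
                return g
        return None


@dataclass(frozen=True)
class SomaticVariant:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float  # fraction of tumor-cell copies carrying the alt allele
    consequence: str  # exonic | splicing
    variant_class: str  # missense | nonsense | frameshift_ins | ... (landscape vocabulary)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class CNSegmentTruth:
    chrom: str
    start: int
    end: int
    copy_number: int


@dataclass(frozen=True)
class FusionTruth:
    gene5: str
    exon5: int  # last exon of the 5' partner retained
    gene3: str
    exon3: int  # first exon of the 3' partner retained


@dataclass(frozen=True)
class SampleTruth:
    sample_id: str
    anatomic_site: str
    purity: float
    ploidy: float
    somatic_variants: tuple[SomaticVariant, ...] = ()
    cn_segments: tuple[CNSegmentTruth, ...] = ()
    fusions: tuple[FusionTruth, ...] = ()
    msi_status: str = "MSS"
    unstable_locus_count: int = 0

    def __post_init__(self) -> None:
        if not 0.2 <= self.purity <= 1.0:
            raise ValueError("tumor purity must lie in [0.2, 1] (cancer cell content >= 20%)")
        if self.anatomic_site not in ANATOMIC_SITES:
            raise ValueError(f"unknown anatomic site {self.anatomic_site!r}")
        if not 0 <= self.unstable_locus_count <= 100:
            raise ValueError("unstable_locus_count must lie in [0, 100]")
        is_high = self.unstable_locus_count >= 75
        if (self.msi_status == "MSI-H") != is_high:
            raise ValueError(
                "msi_status inconsistent with unstable_locus_count under the >=75 rule"
            )


@dataclass
class CohortConfig:
    """Study conditions for cohort simulation.

    Defaults emulate the target study: 317 tumors over seven anatomic-site
    groups, site-specific Poisson mutation loads (larynx highest at 8.3,
    nasopharynx lowest at 3.6), a C>T-dominated spectrum, tumor/normal mean
    depths 730x/343x, purity uniform on [0.2, 1].
    """

    site_counts: dict = field(default_factory=lambda: dict(DEFAULT_SITE_COUNTS))
    site_mean_mutation_load: dict = field(default_factory=lambda: dict(DEFAULT_SITE_LOADS))
    gene_mutation_freq: dict = field(default_factory=lambda: dict(DEFAULT_GENE_FREQ))
    spectrum_weights: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    tumor_mean_depth: float = 730.0
    normal_mean_depth: float = 343.0
    seed: int = 0
    # noise model
    error_rate: float = 1e-3
    nb_dispersion: float = 0.1
    gc_bias_strength: float = 1.5
    # tumor composition
    purity_range: tuple[float, float] = (0.2, 1.0)
    ploidy: float = 2.0
    vaf_range: tuple[float, float] = (0.2, 0.7)
    indel_fraction: float = 292 / 2156
    # recurrent events
    amp11q13_rate: float = 0.256
    cdkn2a_loss_rate: float = 0.243
    fusion_rate: float = 14 / 317
    msi_h_rate: float = 2 / 317
    # panel and nuisance evidence
    n_genes: int = 383
    bins_per_gene: int = 5
    noise_sites: int = 50
    germline_sites: int = 20
    fusion_read_pairs: int = 20
    sv_noise_reads: int = 8

    def validate(self) -> None:
        if not self.site_counts:
            raise ValueError("site_counts must be nonempty")
        for site, n in self.site_counts.items():
            if site not in ANATOMIC_SITES:
                raise ValueError(f"unknown anatomic site {site!r}")
            if n < 0:
                raise ValueError("site counts must be nonnegative")
        for (gene, site), f in self.gene_mutation_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"gene_mutation_freq[{gene},{site}]={f} outside [0, 1]")
        total = sum(self.spectrum_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"spectrum_weights sum to {total}, expected 1")
        if set(self.spectrum_weights) != set(DEFAULT_SPECTRUM):
            raise ValueError("spectrum_weights must cover the six pyrimidine classes")


@dataclass(frozen=True)
class SNPBafRecord:
    chrom: str
    pos: int
    depth: int
    alt_depth: int

    @property
    def baf(self) -> float:
        return self.alt_depth / self.depth if self.depth else float("nan")


@dataclass(frozen=True)
class SampleEvidence:
    sample_id: str
    pileup_sites: tuple[PileupSite, ...] = ()
    depth_bins: tuple[tuple[int, int], ...] = ()  # (bin index, raw depth)
    snp_baf_records: tuple[SNPBafRecord, ...] = ()
    discordant_reads: tuple[DiscordantRead, ...] = ()
    ms_histograms: tuple[MSLocusProfile, ...] = ()
    paired_normal: Optional["SampleEvidence"] = None


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def generate_panel(
    n_genes: int = 383,
    bins_per_gene: int = 5,
    seed: int = 0,
    *,
    snps_per_gene: int = 13,
    n_ms_loci: int = 100,
) -> PanelDefinition:
    """Generate a deterministic fictional targeted panel.

    The first genes are the named recurrent genes of the emulated landscape
    (TP53, CYLD, BAP1, PIK3CA, CDKN2A/B, the CCND1/FGF4/FGF3/FGF19 block,
    TEX10 and NTRK2 with a tyrosine-kinase domain); the rest are generic.
    With the defaults the panel carries 383 genes, ~5,000 SNP loci and 100
    microsatellite loci.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if bins_per_gene < 1:
        raise ValueError("bins_per_gene must be >= 1")
    rng = np.random.default_rng(seed)

    names = [name for name, _ in _SPECIAL_GENES[:n_genes]]
    chroms = {name: chrom for name, chrom in _SPECIAL_GENES}
    for i in range(len(names), n_genes):
        name = f"GENE{i + 1:03d}"
        names.append(name)
        chroms[name] = f"chr{(i % 22) + 1}"

    cursors: dict[str, int] = {}
    genes: list[GeneModel] = []
    for name in names:
        chrom = chroms[name]
        start = cursors.get(chrom, 100_000)
        if name == "NTRK2":
            n_ex = 20
        elif name == "TEX10":
            n_ex = 12
        else:
            n_ex = int(rng.integers(4, 16))
        if name in ("NTRK2", "TEX10"):
            lens = (rng.integers(40, 67, size=n_ex) * 3).astype(int)
        else:
            lens = rng.integers(120, 201, size=n_ex).astype(int)
        exons = []
        pos = start
        for length in lens:
            exons.append((int(pos), int(pos + length)))
            pos += int(length) + _INTRON_BP
        strand = "+" if name in ("NTRK2", "TEX10") or rng.random() > 0.3 else "-"
        domains: tuple = ()
        if name == "NTRK2":
            domains = (
                ("LRR", exons[1][0], exons[4][1]),
                ("tyrosine_kinase", exons[15][0], exons[18][1]),
            )
        elif name == "TEX10":
            domains = (("TEX10_core", exons[1][0], exons[7][1]),)
        genes.append(GeneModel(name, chrom, strand, tuple(exons), domains))
        cursors[chrom] = exons[-1][1] + _GENE_GAP_BP

    bins: list[Bin] = []
    for gene in genes:
        span = gene.end - gene.start
        width = max(1, span // bins_per_gene)
        for b in range(bins_per_gene):
            bstart = gene.start + b * width
            bend = gene.end if b == bins_per_gene - 1 else bstart + width
            # capture bins are exon-anchored, so GC varies bin to bin
            gc = 0.5 + rng.normal(0.0, 0.08)
            bins.append(Bin(gene.chromosome, int(bstart), int(bend),
                            float(np.clip(gc, 0.25, 0.75))))

    snp_loci: list[SNPLocus] = []
    for gene in genes:
        positions = np.sort(
            rng.choice(np.arange(gene.start, gene.end), size=snps_per_gene, replace=False)
        )
        for pos in positions:
            snp_loci.append(SNPLocus(gene.chromosome, int(pos), bool(rng.random() < 0.5)))

    ms_loci: list[MSLocus] = []
    for i in range(n_ms_loci):
        chrom = f"chr{(i % 22) + 1}"
        pos = 50_000_000 + (i // 22) * 10_000 + (i % 22)
        unit = str(rng.choice(["A", "AC", "AGC"]))
        ref_len = int(rng.integers(10, 26))
        ms_loci.append(MSLocus(f"MS{i + 1:03d}", chrom, pos, unit, ref_len))

    target_size = sum(e - s for g in genes for s, e in g.exons)
    return PanelDefinition(
        genes=tuple(genes),
        bins=tuple(bins),
        snp_loci=tuple(snp_loci),
        ms_loci=tuple(ms_loci),
        target_size_bp=int(target_size),
    )


# ---------------------------------------------------------------------------
# Evidence simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial (NB1) with var = (1 + dispersion) * mean.

    The constant-overdispersion parametrization keeps the bin-level
    coefficient of variation realistic for normalized capture depth
    (about 4% at 730x with the default dispersion 0.1).
    """
    if mean <= 0:
        return 0
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return int(rng.negative_binomial(r, p))


def _gc_bias(gc: float, strength: float) -> float:
    return max(0.05, 1.0 - strength * (gc - 0.47) ** 2)


def expected_tumor_vaf(truth_vaf: float, purity: float, copy_number: float = 2.0) -> float:
    """Expected observed alt-read fraction at a spiked site.

    The tumor contributes ``purity * copy_number`` allele copies per cell of
    which a fraction ``truth_vaf`` carry the alt allele; the admixed normal
    contributes ``2 * (1 - purity)`` reference copies. For a copy-neutral
    site this reduces to ``purity * truth_vaf``.
    """
    p = purity
    denom = p * copy_number + 2.0 * (1.0 - p)
    if denom <= 0:  # homozygously deleted in a pure tumor: nothing to observe
        return 0.0
    return min(1.0, (p * truth_vaf * copy_number) / denom)


_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_sample_evidence(
    truth: SampleTruth,
    panel: PanelDefinition,
    config: CohortConfig,
    seed: int,
) -> SampleEvidence:
    """Simulate pileup/bin/BAF/discordant/microsatellite evidence for one sample."""
    rng = np.random.default_rng(seed)
    p = truth.purity
    psi = truth.ploidy
    e = config.error_rate
    d = config.nb_dispersion

    def copy_number_at(chrom: str, pos: int) -> float:
        for seg in truth.cn_segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return float(seg.copy_number)
        return 2.0

    def depth_ratio(C: float) -> float:
        return (p * C + 2.0 * (1.0 - p)) / (p * psi + 2.0 * (1.0 - p))

    # --- pileup sites -------------------------------------------------------
    sites: list[PileupSite] = []
    for v in truth.somatic_variants:
        if not panel.has_gene(v.gene):
            raise ValueError(f"variant outside panel: gene {v.gene} at {v.chrom}:{v.pos}")
        gene = panel.gene(v.gene)
        if not (gene.start - 2 <= v.pos < gene.end + 2):
            raise ValueError(f"variant outside panel: gene {v.gene} at {v.chrom}:{v.pos}")
        C = copy_number_at(v.chrom, v.pos)
        obs_vaf = expected_tumor_vaf(v.vaf, p, C)
        depth_t = max(1, _nb_draw(rng, config.tumor_mean_depth * depth_ratio(C), d))
        alt_true = rng.binomial(depth_t, obs_vaf)
        alt_err = rng.binomial(depth_t - alt_true, e)
        alt = int(alt_true + alt_err)
        ref = depth_t - alt
        depth_n = max(1, _nb_draw(rng, config.normal_mean_depth, d))
        alt_n = int(rng.binomial(depth_n, e))
        sites.append(_make_site(rng, v.chrom, v.pos, v.ref, v.alt, ref, alt,
                                depth_n - alt_n, alt_n))
    # background-noise and germline-het sites on random exons
    sites.extend(_nuisance_sites(rng, panel, config, p, truth))
    sites.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))

    # --- depth bins ---------------------------------------------------------
    tumor_bins: list[tuple[int, int]] = []
    normal_bins: list[tuple[int, int]] = []
    for i, b in enumerate(panel.bins):
        mid = (b.start + b.end) // 2
        C = copy_number_at(b.chrom, mid)
        bias = _gc_bias(b.gc_fraction, config.gc_bias_strength)
        t_mean = config.tumor_mean_depth * bias * depth_ratio(C)
        tumor_bins.append((i, _nb_draw(rng, t_mean, d)))
        normal_bins.append((i, _nb_draw(rng, config.normal_mean_depth * bias, d)))

    # --- SNP BAF records ----------------------------------------------------
    snp_records: list[SNPBafRecord] = []
    normal_snp_records: list[SNPBafRecord] = []
    for locus in panel.snp_loci:
        het = rng.random() < (0.5 if locus.population_het else 0.05)
        C = copy_number_at(locus.chrom, locus.pos)
        depth_t = max(1, _nb_draw(rng, config.tumor_mean_depth * depth_ratio(C), d))
        depth_n = max(1, _nb_draw(rng, config.normal_mean_depth, d))
        if het:
            if C >= 2:
                haps = (1.0, C - 1.0)
            elif C == 1:
                haps = (0.0, 1.0)
            else:
                haps = (0.0, 0.0)
            b_copies = float(rng.choice(haps))
            # denominator is 0 only for a homozygous deletion in a pure tumor,
            # where the handful of residual reads are balanced noise
            denom = p * C + 2.0 * (1.0 - p)
            exp_baf = (p * b_copies + (1.0 - p)) / denom if denom > 0 else 0.5
            exp_normal = 0.5
        else:
            hom_alt = rng.random() < 0.1
            exp_baf = 1.0 - e if hom_alt else e
            exp_normal = exp_baf
        alt_t = int(rng.binomial(depth_t, min(1.0, exp_baf)))
        alt_n = int(rng.binomial(depth_n, min(1.0, exp_normal)))
        snp_records.append(SNPBafRecord(locus.chrom, locus.pos, depth_t, alt_t))
        normal_snp_records.append(SNPBafRecord(locus.chrom, locus.pos, depth_n, alt_n))

    # --- discordant reads ---------------------------------------------------
    reads: list[DiscordantRead] = []
    for k, fus in enumerate(truth.fusions):
        g5 = panel.gene(fus.gene5)
        g3 = panel.gene(fus.gene3)
        bp5 = _intron_after_exon(g5, fus.exon5)
        bp3 = _intron_before_exon(g3, fus.exon3)
        for i in range(config.fusion_read_pairs):
            off5 = int(rng.integers(30, 300))
            off3 = int(rng.integers(30, 300))
            end5 = Breakend(g5.chromosome,
                            bp5 - off5 if g5.strand == "+" else bp5 + off5,
                            g5.strand)
            end3 = Breakend(g3.chromosome,
                            bp3 + off3 if g3.strand == "+" else bp3 - off3,
                            "-" if g3.strand == "+" else "+")
            reads.append(DiscordantRead(f"fus{k}_{i}", end5, end3,
                                        int(rng.integers(0, 30))))
    for i in range(config.sv_noise_reads):
        c1 = f"chr{int(rng.integers(1, 23))}"
        c2 = f"chr{int(rng.integers(1, 23))}"
        reads.append(
            DiscordantRead(
                f"noise{i}",
                Breakend(c1, int(rng.integers(0, 10_000_000)), str(rng.choice(["+", "-"]))),
                Breakend(c2, int(rng.integers(20_000_000, 30_000_000)), str(rng.choice(["+", "-"]))),
                0,
            )
        )

    # --- microsatellite histograms -----------------------------------------
    n_loci = len(panel.ms_loci)
    unstable_idx = set(
        rng.choice(n_loci, size=min(truth.unstable_locus_count, n_loci), replace=False).tolist()
    )
    profiles: list[MSLocusProfile] = []
    stable_offsets = np.array([-2, -1, 0, 1])
    stable_probs = np.array([0.08, 0.17, 0.65, 0.10])
    shifted_offsets = np.array([-6, -5, -4, -3, -2])
    shifted_probs = np.array([0.10, 0.20, 0.30, 0.30, 0.10])
    for idx, locus in enumerate(panel.ms_loci):
        depth_t = max(1, _nb_draw(rng, config.tumor_mean_depth, d))
        depth_n = max(1, _nb_draw(rng, config.normal_mean_depth, d))
        normal_hist = _draw_histogram(rng, depth_n, locus.ref_repeat_length,
                                      stable_offsets, stable_probs)
        if idx in unstable_idx:
            w = 0.9 * p  # unstable fraction scales with tumor content
            probs = np.concatenate([(1 - w) * stable_probs, w * shifted_probs])
            offsets = np.concatenate([stable_offsets, shifted_offsets])
            tumor_hist = _draw_histogram(rng, depth_t, locus.ref_repeat_length,
                                         offsets, probs / probs.sum())
        else:
            tumor_hist = _draw_histogram(rng, depth_t, locus.ref_repeat_length,
                                         stable_offsets, stable_probs)
        profiles.append(MSLocusProfile(locus.locus_id, tumor_hist, normal_hist))

    normal_evidence = SampleEvidence(
        sample_id=truth.sample_id + "_N",
        depth_bins=tuple(normal_bins),
        snp_baf_records=tuple(normal_snp_records),
    )
    return SampleEvidence(
        sample_id=truth.sample_id,
        pileup_sites=tuple(sites),
        depth_bins=tuple(tumor_bins),
        snp_baf_records=tuple(snp_records),
        discordant_reads=tuple(reads),
        ms_histograms=tuple(profiles),
        paired_normal=normal_evidence,
    )


def _make_site(rng, chrom, pos, ref, alt, t_ref, t_alt, n_ref, n_alt) -> PileupSite:
    t_ref_f = int(rng.binomial(t_ref, 0.5))
    t_alt_f = int(rng.binomial(t_alt, 0.5))
    n_ref_f = int(rng.binomial(n_ref, 0.5))
    n_alt_f = int(rng.binomial(n_alt, 0.5))
    return PileupSite(
        chrom=chrom, pos=int(pos), ref=ref, alt=alt,
        t_ref_fwd=t_ref_f, t_ref_rev=int(t_ref - t_ref_f),
        t_alt_fwd=t_alt_f, t_alt_rev=int(t_alt - t_alt_f),
        n_ref_fwd=n_ref_f, n_ref_rev=int(n_ref - n_ref_f),
        n_alt_fwd=n_alt_f, n_alt_rev=int(n_alt - n_alt_f),
        mean_base_quality=float(np.clip(rng.normal(32.0, 2.0), 20.0, 40.0)),
        mean_mapping_quality=float(np.clip(rng.normal(58.0, 2.0), 30.0, 60.0)),
    )


def _nuisance_sites(rng, panel, config, purity, truth) -> list[PileupSite]:
    sites = []
    d = config.nb_dispersion
    e = config.error_rate
    for kind, count, frac in (
        ("noise", config.noise_sites, None),
        ("germline", config.germline_sites, 0.5),
    ):
        for _ in range(count):
            gene = panel.genes[int(rng.integers(0, len(panel.genes)))]
            s, ee = gene.exons[int(rng.integers(0, len(gene.exons)))]
            pos = int(rng.integers(s, ee))
            ref = str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            depth_t = max(1, _nb_draw(rng, config.tumor_mean_depth, d))
            depth_n = max(1, _nb_draw(rng, config.normal_mean_depth, d))
            t_frac = e if frac is None else frac
            n_frac = e if frac is None else frac
            alt_t = int(rng.binomial(depth_t, t_frac))
            alt_n = int(rng.binomial(depth_n, n_frac))
            sites.append(_make_site(rng, gene.chromosome, pos, ref, alt,
                                    depth_t - alt_t, alt_t, depth_n - alt_n, alt_n))
    return sites


def _draw_histogram(rng, depth, ref_len, offsets, probs) -> dict[int, int]:
    counts = rng.multinomial(depth, probs / probs.sum())
    hist: dict[int, int] = {}
    for off, c in zip(offsets, counts):
        if c > 0:
            length = max(1, int(ref_len + off))
            hist[length] = hist.get(length, 0) + int(c)
    return hist


def _intron_after_exon(gene: GeneModel, exon_number: int) -> int:
    """Midpoint of the intron following 1-based ``exon_number`` (tx order)."""
    if gene.strand == "+":
        idx = exon_number - 1
        return (gene.exons[idx][1] + gene.exons[idx + 1][0]) // 2
    idx = len(gene.exons) - exon_number
    return (gene.exons[idx - 1][1] + gene.exons[idx][0]) // 2


def _intron_before_exon(gene: GeneModel, exon_number: int) -> int:
    if gene.strand == "+":
        idx = exon_number - 1
        return (gene.exons[idx - 1][1] + gene.exons[idx][0]) // 2
    idx = len(gene.exons) - exon_number
    return (gene.exons[idx][1] + gene.exons[idx + 1][0]) // 2


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: CohortConfig,
    panel: Optional[PanelDefinition] = None,
) -> list[tuple[SampleTruth, SampleEvidence]]:
    """Simulate a multi-site cohort of (truth, evidence) pairs.

    Per-sample mutation counts are Poisson around the site-specific mean;
    recurrently mutated genes are spiked per their configured Bernoulli
    frequencies; the remaining load is distributed over background genes so
    the configured gene frequencies are preserved.
    """
    config.validate()
    if panel is None:
        panel = generate_panel(config.n_genes, config.bins_per_gene, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    out: list[tuple[SampleTruth, SampleEvidence]] = []
    counter = 0
    for site in sorted(config.site_counts):
        for _ in range(config.site_counts[site]):
            counter += 1
            truth = _simulate_truth(f"S{counter:04d}", site, panel, config, rng)
            ev_seed = int(rng.integers(0, 2**31 - 1))
            evidence = simulate_sample_evidence(truth, panel, config, ev_seed)
            out.append((truth, evidence))
    return out


def _simulate_truth(sample_id, site, panel, config, rng) -> SampleTruth:
    purity = float(rng.uniform(*config.purity_range))
    configured = {g: f for (g, s), f in config.gene_mutation_freq.items()
                  if s == site and panel.has_gene(g)}
    mutated = [g for g, f in configured.items() if rng.random() < f]
    mean_load = config.site_mean_mutation_load.get(site, DEFAULT_MEAN_LOAD)
    extra_mean = max(0.0, mean_load - sum(configured.values()))
    n_extra = int(rng.poisson(extra_mean))
    background = [g.name for g in panel.genes if g.name not in configured]
    if background and n_extra:
        mutated.extend(str(g) for g in rng.choice(background, size=n_extra, replace=True))

    variants = tuple(_simulate_variant(gene, panel, config, rng) for gene in mutated)

    segments: list[CNSegmentTruth] = []
    if panel.has_gene("CCND1") and rng.random() < config.amp11q13_rate:
        block = [panel.gene(n) for n in ("CCND1", "FGF4", "FGF3", "FGF19")
                 if panel.has_gene(n)]
        segments.append(CNSegmentTruth(
            block[0].chromosome,
            min(g.start for g in block) - 1000,
            max(g.end for g in block) + 1000,
            int(rng.choice([4, 5, 6, 7, 8])),
        ))
    if panel.has_gene("CDKN2A") and rng.random() < config.cdkn2a_loss_rate:
        block = [panel.gene(n) for n in ("CDKN2A", "CDKN2B") if panel.has_gene(n)]
        segments.append(CNSegmentTruth(
            block[0].chromosome,
            min(g.start for g in block) - 1000,
            max(g.end for g in block) + 1000,
            int(rng.choice([0, 1])),
        ))

    fusions: tuple[FusionTruth, ...] = ()
    if (panel.has_gene("TEX10") and panel.has_gene("NTRK2")
            and rng.random() < config.fusion_rate):
        fusions = (FusionTruth("TEX10", 9, "NTRK2", 15),)

    if rng.random() < config.msi_h_rate:
        msi_status, unstable = "MSI-H", int(rng.integers(80, 96))
    else:
        msi_status, unstable = "MSS", 0

    return SampleTruth(
        sample_id=sample_id,
        anatomic_site=site,
        purity=purity,
        ploidy=config.ploidy,
        somatic_variants=variants,
        cn_segments=tuple(segments),
        fusions=fusions,
        msi_status=msi_status,
        unstable_locus_count=unstable,
    )


_SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _simulate_variant(gene_name, panel, config, rng) -> SomaticVariant:
    gene = panel.gene(gene_name)
    exon = gene.exons[int(rng.integers(0, len(gene.exons)))]
    splicing = rng.random() < 0.05
    if splicing:
        pos = exon[1]  # first intronic base, inside the splice window
    else:
        pos = int(rng.integers(exon[0], exon[1]))
    if rng.random() < config.indel_fraction:
        length = int(rng.integers(1, 11))
        insertion = rng.random() < 0.5
        filler = "".join(rng.choice(_BASES, size=length))
        if insertion:
            ref, alt = "A", "A" + filler
            vclass = "inframe_indel" if length % 3 == 0 else "frameshift_ins"
        else:
            ref, alt = "A" + filler, "A"
            vclass = "inframe_indel" if length % 3 == 0 else "frameshift_del"
    else:
        probs = np.array([config.spectrum_weights[c] for c in _SPECTRUM_CLASSES])
        cls = _SPECTRUM_CLASSES[int(rng.choice(6, p=probs / probs.sum()))]
        ref, alt = cls.split(">")
        if rng.random() < 0.5:  # purine-strand representation
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        u = rng.random()
        vclass = "missense" if u < 0.75 else ("nonsense" if u < 0.9 else "other")
    consequence = "splicing" if splicing else "exonic"
    if splicing:
        vclass = "splice_site"
    return SomaticVariant(
        gene=gene.name,
        chrom=gene.chromosome,
        pos=int(pos),
        ref=ref,
        alt=alt,
        vaf=float(rng.uniform(*config.vaf_range)),
        consequence=consequence,
        variant_class=vclass,
    )


# ---------------------------------------------------------------------------
# Fixture files (tab-delimited, round-trippable)
# ---------------------------------------------------------------------------

_F = "%.17g"  # float format that round-trips IEEE doubles exactly


def write_fixtures(cohort, outdir, panel: PanelDefinition) -> list[str]:
    """Write a cohort and its panel as documented tab-delimited files.

    Emits the panel as BED plus typed panel tables, per-sample truth tables
    and the full evidence set; :func:`read_fixtures` restores objects that
    compare equal. Returns the list of file names written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def _write(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format=_F)

    with open(out / "panel.bed", "w") as fh:
        for gene in panel.genes:
            for s, e in gene.exons:
                fh.write(f"{gene.chromosome}\t{s}\t{e}\t{gene.name}\n")

    _write("panel_genes.tsv", pd.DataFrame(
        [
            {
                "name": g.name,
                "chromosome": g.chromosome,
                "strand": g.strand,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "domains": "|".join(f"{n}:{s}:{e}" for n, s, e in g.domains),
            }
            for g in panel.genes
        ],
        columns=["name", "chromosome", "strand", "exon_starts", "exon_ends", "domains"],
    ))
    _write("panel_bins.tsv", pd.DataFrame(
        [{"chrom": b.chrom, "start": b.start, "end": b.end, "gc_fraction": b.gc_fraction}
         for b in panel.bins],
        columns=["chrom", "start", "end", "gc_fraction"],
    ))
    _write("panel_snps.tsv", pd.DataFrame(
        [{"chrom": s.chrom, "pos": s.pos, "population_het": int(s.population_het)}
         for s in panel.snp_loci],
        columns=["chrom", "pos", "population_het"],
    ))
    _write("panel_ms.tsv", pd.DataFrame(
        [{"locus_id": m.locus_id, "chrom": m.chrom, "pos": m.pos,
          "repeat_unit": m.repeat_unit, "ref_repeat_length": m.ref_repeat_length}
         for m in panel.ms_loci],
        columns=["locus_id", "chrom", "pos", "repeat_unit", "ref_repeat_length"],
    ))

    samples, t_var, t_cnv, t_fus = [], [], [], []
    pileups, bins_rows, baf_rows, disc_rows, ms_rows = [], [], [], [], []
    for truth, ev in cohort:
        samples.append({
            "sample_id": truth.sample_id,
            "anatomic_site": truth.anatomic_site,
            "purity": truth.purity,
            "ploidy": truth.ploidy,
            "msi_status": truth.msi_status,
            "unstable_locus_count": truth.unstable_locus_count,
        })
        for v in truth.somatic_variants:
            t_var.append({"sample_id": truth.sample_id, "gene": v.gene, "chrom": v.chrom,
                          "pos": v.pos, "ref": v.ref, "alt": v.alt, "vaf": v.vaf,
                          "consequence": v.consequence, "variant_class": v.variant_class})
        for seg in truth.cn_segments:
            t_cnv.append({"sample_id": truth.sample_id, "chrom": seg.chrom,
                          "start": seg.start, "end": seg.end,
                          "copy_number": seg.copy_number})
        for f in truth.fusions:
            t_fus.append({"sample_id": truth.sample_id, "gene5": f.gene5,
                          "exon5": f.exon5, "gene3": f.gene3, "exon3": f.exon3})
        for s in ev.pileup_sites:
            pileups.append({
                "sample_id": truth.sample_id, "chrom": s.chrom, "pos": s.pos,
                "ref": s.ref, "alt": s.alt,
                "t_ref_fwd": s.t_ref_fwd, "t_ref_rev": s.t_ref_rev,
                "t_alt_fwd": s.t_alt_fwd, "t_alt_rev": s.t_alt_rev,
                "n_ref_fwd": s.n_ref_fwd, "n_ref_rev": s.n_ref_rev,
                "n_alt_fwd": s.n_alt_fwd, "n_alt_rev": s.n_alt_rev,
                "mean_base_quality": s.mean_base_quality,
                "mean_mapping_quality": s.mean_mapping_quality,
                "in_str_region": int(s.in_str_region),
            })
        for role, source in (("tumor", ev), ("normal", ev.paired_normal)):
            if source is None:
                continue
            for idx, depth in source.depth_bins:
                bins_rows.append({"sample_id": truth.sample_id, "role": role,
                                  "bin_index": idx, "depth": depth})
            for r in source.snp_baf_records:
                baf_rows.append({"sample_id": truth.sample_id, "role": role,
                                 "chrom": r.chrom, "pos": r.pos,
                                 "depth": r.depth, "alt_depth": r.alt_depth})
        for r in ev.discordant_reads:
            disc_rows.append({
                "sample_id": truth.sample_id, "read_id": r.read_id,
                "chrom1": r.end1.chrom, "pos1": r.end1.pos, "strand1": r.end1.strand,
                "chrom2": r.end2.chrom, "pos2": r.end2.pos, "strand2": r.end2.strand,
                "clip_length": r.clip_length,
            })
        for prof in ev.ms_histograms:
            for role, hist in (("tumor", prof.tumor), ("normal", prof.normal)):
                for length in sorted(hist):
                    ms_rows.append({"sample_id": truth.sample_id, "role": role,
                                    "locus_id": prof.locus_id,
                                    "repeat_length": length, "count": hist[length]})

    _write("samples.tsv", pd.DataFrame(samples, columns=[
        "sample_id", "anatomic_site", "purity", "ploidy",
        "msi_status", "unstable_locus_count"]))
    _write("truth_variants.tsv", pd.DataFrame(t_var, columns=[
        "sample_id", "gene", "chrom", "pos", "ref", "alt", "vaf",
        "consequence", "variant_class"]))
    _write("truth_cnv.tsv", pd.DataFrame(t_cnv, columns=[
        "sample_id", "chrom", "start", "end", "copy_number"]))
    _write("truth_fusions.tsv", pd.DataFrame(t_fus, columns=[
        "sample_id", "gene5", "exon5", "gene3", "exon3"]))
    _write("pileups.tsv", pd.DataFrame(pileups, columns=[
        "sample_id", "chrom", "pos", "ref", "alt",
        "t_ref_fwd", "t_ref_rev", "t_alt_fwd", "t_alt_rev",
        "n_ref_fwd", "n_ref_rev", "n_alt_fwd", "n_alt_rev",
        "mean_base_quality", "mean_mapping_quality", "in_str_region"]))
    _write("bins.tsv", pd.DataFrame(bins_rows, columns=[
        "sample_id", "role", "bin_index", "depth"]))
    _write("baf.tsv", pd.DataFrame(baf_rows, columns=[
        "sample_id", "role", "chrom", "pos", "depth", "alt_depth"]))
    _write("discordant.tsv", pd.DataFrame(disc_rows, columns=[
        "sample_id", "read_id", "chrom1", "pos1", "strand1",
        "chrom2", "pos2", "strand2", "clip_length"]))
    _write("ms_histograms.tsv", pd.DataFrame(ms_rows, columns=[
        "sample_id", "role", "locus_id", "repeat_length", "count"]))

    return ["panel.bed", "panel_genes.tsv", "panel_bins.tsv", "panel_snps.tsv",
            "panel_ms.tsv", "samples.tsv", "truth_variants.tsv", "truth_cnv.tsv",
            "truth_fusions.tsv", "pileups.tsv", "bins.tsv", "baf.tsv",
            "discordant.tsv", "ms_histograms.tsv"]


def _read_tsv(path: Path, name: str) -> pd.DataFrame:
    return pd.read_csv(path / name, sep="\t", float_precision="round_trip",
                       dtype={"chrom": str, "chrom1": str, "chrom2": str})


def read_fixtures(outdir) -> tuple[PanelDefinition, list[tuple[SampleTruth, SampleEvidence]]]:
    """Read fixture files back into in-memory objects equal to the originals."""
    path = Path(outdir)
    genes = []
    for row in _read_tsv(path, "panel_genes.tsv").itertuples():
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        domains = []
        if isinstance(row.domains, str) and row.domains:
            for part in row.domains.split("|"):
                n, s, e = part.split(":")
                domains.append((n, int(s), int(e)))
        genes.append(GeneModel(row.name, row.chromosome, row.strand,
                               tuple(zip(starts, ends)), tuple(domains)))
    bins = tuple(
        Bin(r.chrom, int(r.start), int(r.end), float(r.gc_fraction))
        for r in _read_tsv(path, "panel_bins.tsv").itertuples()
    )
    snps = tuple(
        SNPLocus(r.chrom, int(r.pos), bool(r.population_het))
        for r in _read_tsv(path, "panel_snps.tsv").itertuples()
    )
    ms = tuple(
        MSLocus(r.locus_id, r.chrom, int(r.pos), r.repeat_unit, int(r.ref_repeat_length))
        for r in _read_tsv(path, "panel_ms.tsv").itertuples()
    )
    panel = PanelDefinition(
        genes=tuple(genes), bins=bins, snp_loci=snps, ms_loci=ms,
        target_size_bp=int(sum(e - s for g in genes for s, e in g.exons)),
    )

    samples = _read_tsv(path, "samples.tsv")
    t_var = _read_tsv(path, "truth_variants.tsv")
    t_cnv = _read_tsv(path, "truth_cnv.tsv")
    t_fus = _read_tsv(path, "truth_fusions.tsv")
    pileups = _read_tsv(path, "pileups.tsv")
    bins_df = _read_tsv(path, "bins.tsv")
    baf = _read_tsv(path, "baf.tsv")
    disc = _read_tsv(path, "discordant.tsv")
    ms_df = _read_tsv(path, "ms_histograms.tsv")

    cohort = []
    for srow in samples.itertuples():
        sid = srow.sample_id
        variants = tuple(
            SomaticVariant(r.gene, r.chrom, int(r.pos), r.ref, r.alt, float(r.vaf),
                           r.consequence, r.variant_class)
            for r in t_var[t_var.sample_id == sid].itertuples()
        )
        segs = tuple(
            CNSegmentTruth(r.chrom, int(r.start), int(r.end), int(r.copy_number))
            for r in t_cnv[t_cnv.sample_id == sid].itertuples()
        )
        fus = tuple(
            FusionTruth(r.gene5, int(r.exon5), r.gene3, int(r.exon3))
            for r in t_fus[t_fus.sample_id == sid].itertuples()
        )
        truth = SampleTruth(sid, srow.anatomic_site, float(srow.purity),
                            float(srow.ploidy), variants, segs, fus,
                            srow.msi_status, int(srow.unstable_locus_count))

        sites = tuple(
            PileupSite(r.chrom, int(r.pos), r.ref, r.alt,
                       int(r.t_ref_fwd), int(r.t_ref_rev), int(r.t_alt_fwd),
                       int(r.t_alt_rev), int(r.n_ref_fwd), int(r.n_ref_rev),
                       int(r.n_alt_fwd), int(r.n_alt_rev),
                       float(r.mean_base_quality), float(r.mean_mapping_quality),
                       bool(r.in_str_region))
            for r in pileups[pileups.sample_id == sid].itertuples()
        )
        sb = bins_df[bins_df.sample_id == sid]
        t_bins = tuple((int(r.bin_index), int(r.depth))
                       for r in sb[sb.role == "tumor"].itertuples())
        n_bins = tuple((int(r.bin_index), int(r.depth))
                       for r in sb[sb.role == "normal"].itertuples())
        sbaf = baf[baf.sample_id == sid]
        t_baf = tuple(SNPBafRecord(r.chrom, int(r.pos), int(r.depth), int(r.alt_depth))
                      for r in sbaf[sbaf.role == "tumor"].itertuples())
        n_baf = tuple(SNPBafRecord(r.chrom, int(r.pos), int(r.depth), int(r.alt_depth))
                      for r in sbaf[sbaf.role == "normal"].itertuples())
        reads = tuple(
            DiscordantRead(r.read_id,
                           Breakend(r.chrom1, int(r.pos1), r.strand1),
                           Breakend(r.chrom2, int(r.pos2), r.strand2),
                           int(r.clip_length))
            for r in disc[disc.sample_id == sid].itertuples()
        )
        sms = ms_df[ms_df.sample_id == sid]
        profiles = []
        for locus in panel.ms_loci:
            lrows = sms[sms.locus_id == locus.locus_id]
            if lrows.empty:
                continue
            tumor = {int(r.repeat_length): int(r.count)
                     for r in lrows[lrows.role == "tumor"].itertuples()}
            normal = {int(r.repeat_length): int(r.count)
                      for r in lrows[lrows.role == "normal"].itertuples()}
            profiles.append(MSLocusProfile(locus.locus_id, tumor, normal))
        normal_ev = SampleEvidence(sample_id=sid + "_N", depth_bins=n_bins,
                                   snp_baf_records=n_baf)
        evidence = SampleEvidence(
            sample_id=sid, pileup_sites=sites, depth_bins=t_bins,
            snp_baf_records=t_baf, discordant_reads=reads,
            ms_histograms=tuple(profiles), paired_normal=normal_ev,
        )
        cohort.append((truth, evidence))
    return panel, cohort
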