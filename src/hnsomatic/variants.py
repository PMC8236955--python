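"""Somatic SNV/indel calling from matched tumor/normal pileup evidence.

The caller scores each pileup site with a two-hypothesis binomial model
(background sequencing error vs. a real variant at the observed allele
fraction), vetoes sites whose matched normal carries the allele above the
error rate (germline), and then applies a five-rule somatic filter cascade:

1. alt-supporting reads >= 8 and VAF >= 0.1,
2. exonic or splicing consequence only,
3. strand bias (majority-strand fraction of alt reads) < 0.9,
4. indel length <= 40 bp,
5. population allele frequency <= 0.015 in every bundled population table.

Thresholds are inclusive exactly as stated: >=8 and >=0.1 pass, >=0.9 fails,
>40 fails, >0.015 fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

__all__ = [
    "PileupSite",
    "ErrorModel",
    "VariantCall",
    "PopulationAFTable",
    "score_somatic",
    "compute_strand_bias",
    "annotate_consequence",
    "apply_somatic_filters",
    "call_sample",
    "write_vcf",
    "read_vcf",
    "calls_to_table",
]

#: Names of the five somatic filter rules, in cascade order.
FILTER_RULES = (
    "alt_reads",
    "vaf",
    "consequence",
    "strand_bias",
    "indel_length",
    "population_af",
)

PASSING_CONSEQUENCES = frozenset({"exonic", "splicing"})


@dataclass(frozen=True)
class PileupSite:
    """Per-site tumor/normal allele counts split by strand.

    Coordinates are 0-based. ``ref`` and ``alt`` of unequal length encode an
    indel; the indel length is the absolute length difference.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    t_ref_fwd: int
    t_ref_rev: int
    t_alt_fwd: int
    t_alt_rev: int
    n_ref_fwd: int
    n_ref_rev: int
    n_alt_fwd: int
    n_alt_rev: int
    mean_base_quality: float = 30.0
    mean_mapping_quality: float = 60.0
    in_str_region: bool = False

    def __post_init__(self) -> None:
        for name in (
            "t_ref_fwd", "t_ref_rev", "t_alt_fwd", "t_alt_rev",
            "n_ref_fwd", "n_ref_rev", "n_alt_fwd", "n_alt_rev",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative read count in field {name!r}")

    @property
    def tumor_alt(self) -> int:
        return self.t_alt_fwd + self.t_alt_rev

    @property
    def tumor_ref(self) -> int:
        return self.t_ref_fwd + self.t_ref_rev

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def normal_alt(self) -> int:
        return self.n_alt_fwd + self.n_alt_rev

    @property
    def normal_depth(self) -> int:
        return self.n_ref_fwd + self.n_ref_rev + self.normal_alt

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def is_indel(self) -> bool:
        return self.indel_length > 0


@dataclass(frozen=True)
class ErrorModel:
    """Background-noise model for the Bayesian score.

    error_rate
        Per-read probability of observing a non-reference base by chance
        (sequencing + FFPE background), default 1e-3.
    prior_somatic
        Per-site prior probability of a true somatic variant, default 1e-6.
    germline_alpha
        Significance level of the binomial test used to veto sites whose
        matched normal carries the alternative allele above ``error_rate``.
    """

    error_rate: float = 1e-3
    prior_somatic: float = 1e-6
    germline_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if not 0.0 < self.prior_somatic < 0.5:
            raise ValueError("prior_somatic must lie in (0, 0.5)")


@dataclass(frozen=True)
class VariantCall:
    site: PileupSite
    vaf: float
    alt_reads: int
    strand_bias: float
    posterior_somatic: float
    consequence: str
    population_af: float
    indel_length: int
    filter_verdict: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.filter_verdict

    @property
    def verdict_string(self) -> str:
        return "PASS" if self.passed else ";".join(self.filter_verdict)


class PopulationAFTable:
    """Bundled stand-in for public population allele-frequency databases.

    Holds one or more named tables mapping (chrom, pos, ref, alt) to an
    allele frequency; lookups return the maximum over all tables, because a
    site is removed when it is common in *either* database.
    """

    def __init__(self, tables: Optional[Mapping[str, Mapping[tuple, float]]] = None):
        self.tables: dict[str, dict[tuple, float]] = {
            name: dict(tab) for name, tab in (tables or {}).items()
        }

    @classmethod
    def empty(cls) -> "PopulationAFTable":
        return cls({})

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> float:
        key = (chrom, int(pos), ref, alt)
        best = 0.0
        for tab in self.tables.values():
            best = max(best, tab.get(key, 0.0))
        return best


def score_somatic(site: PileupSite, model: ErrorModel) -> float:
    """Posterior probability that ``site`` carries a somatic variant.

    Two-hypothesis binomial model on the tumor counts: under H0 alt reads
    arise from background error ``e``; under H1 they arise at the observed
    alt fraction (floored at ``e`` so the generalized likelihood ratio is
    monotone in the alt count). Sites whose matched normal rejects the
    background-error hypothesis are treated as germline and score 0.
    """
    depth = site.tumor_depth
    if depth == 0:
        raise ValueError(
            f"undefined somatic score: zero tumor depth at {site.chrom}:{site.pos}"
        )
    e = model.error_rate
    # Germline veto on the matched normal.
    if site.normal_depth > 0 and site.normal_alt > 0:
        p_norm = stats.binom.sf(site.normal_alt - 1, site.normal_depth, e)
        if p_norm < model.germline_alpha:
            return 0.0
    alt = site.tumor_alt
    v = max(alt / depth, e)
    log_l1 = stats.binom.logpmf(alt, depth, v)
    log_l0 = stats.binom.logpmf(alt, depth, e)
    log_prior_odds = math.log(model.prior_somatic) - math.log1p(-model.prior_somatic)
    log_odds = log_prior_odds + (log_l1 - log_l0)
    # posterior = 1 / (1 + exp(-log_odds))
    if log_odds > 700:
        return 1.0
    return 1.0 / (1.0 + math.exp(-log_odds))


def compute_strand_bias(alt_fwd: int, alt_rev: int) -> float:
    """Majority-strand fraction of alt-supporting reads, in [0.5, 1]."""
    total = alt_fwd + alt_rev
    if total < 1:
        raise ValueError("strand bias undefined with zero alt reads")
    return max(alt_fwd, alt_rev) / total


def annotate_consequence(site: PileupSite, panel, splice_window: int = 2) -> str:
    """Classify a site as exonic / splicing / intronic / other against a panel.

    ``panel`` is any object exposing ``genes`` with ``chromosome``, ``exons``
    (sorted half-open intervals) and a genomic span.
    """
    pos = site.pos
    for gene in panel.genes:
        if gene.chromosome != site.chrom:
            continue
        if not (gene.start - splice_window <= pos < gene.end + splice_window):
            continue
        for start, end in gene.exons:
            if start <= pos < end:
                return "exonic"
        for start, end in gene.exons:
            if start - splice_window <= pos < start or end <= pos < end + splice_window:
                return "splicing"
        if gene.start <= pos < gene.end:
            return "intronic"
    return "other"


def apply_somatic_filters(
    call: VariantCall,
    *,
    min_alt_reads: int = 8,
    min_vaf: float = 0.1,
    max_strand_bias: float = 0.9,
    max_indel_length: int = 40,
    max_population_af: float = 0.015,
) -> tuple[str, ...]:
    """Return the tuple of failed somatic-filter rule names (empty = PASS).

    PASS requires alt reads >= 8, VAF >= 0.1, exonic or splicing consequence,
    strand bias < 0.9, indel length <= 40 bp and population AF <= 0.015.
    """
    for field_name in ("consequence", "population_af", "strand_bias", "vaf"):
        if getattr(call, field_name) is None:
            raise ValueError(f"call not fully annotated: missing {field_name!r}")
    failed = []
    if call.alt_reads < min_alt_reads:
        failed.append("alt_reads")
    if call.vaf < min_vaf:
        failed.append("vaf")
    if call.consequence not in PASSING_CONSEQUENCES:
        failed.append("consequence")
    if call.strand_bias >= max_strand_bias:
        failed.append("strand_bias")
    if call.indel_length > max_indel_length:
        failed.append("indel_length")
    if call.population_af > max_population_af:
        failed.append("population_af")
    return tuple(failed)


def call_sample(
    evidence,
    panel,
    model: Optional[ErrorModel] = None,
    *,
    pop_af: Optional[PopulationAFTable] = None,
    keep_rejected: bool = False,
    posterior_threshold: float = 0.99,
    min_base_quality: float = 20.0,
    min_mapping_quality: float = 30.0,
    str_alt_multiplier: float = 2.0,
    min_alt_reads: int = 8,
    min_vaf: float = 0.1,
    max_strand_bias: float = 0.9,
    max_indel_length: int = 40,
    max_population_af: float = 0.015,
) -> list[VariantCall]:
    """Call somatic variants for one tumor/normal pair.

    Mean base quality and mapping quality act as pre-filters; sites flagged as
    short-tandem-repeat regions need ``str_alt_multiplier`` times the usual
    alt-read support. Returns PASS calls sorted by coordinate; with
    ``keep_rejected`` the rejected candidates (with their failed-rule
    verdicts) are included as well.
    """
    model = model or ErrorModel()
    pop_af = pop_af or PopulationAFTable.empty()
    if getattr(evidence, "paired_normal", None) is None:
        raise ValueError("matched normal evidence is required for somatic calling")
    calls: list[VariantCall] = []
    for site in evidence.pileup_sites:
        if site.tumor_depth == 0 or site.tumor_alt == 0:
            continue
        failed_pre: list[str] = []
        if site.mean_base_quality < min_base_quality:
            failed_pre.append("base_quality")
        if site.mean_mapping_quality < min_mapping_quality:
            failed_pre.append("mapping_quality")
        posterior = score_somatic(site, model)
        if posterior < posterior_threshold:
            failed_pre.append("posterior")
        str_min_alt = min_alt_reads * str_alt_multiplier if site.in_str_region else 0
        if site.in_str_region and site.tumor_alt < str_min_alt:
            failed_pre.append("str_alt_reads")
        if failed_pre and not keep_rejected:
            continue
        call = VariantCall(
            site=site,
            vaf=site.tumor_alt / site.tumor_depth,
            alt_reads=site.tumor_alt,
            strand_bias=compute_strand_bias(site.t_alt_fwd, site.t_alt_rev),
            posterior_somatic=posterior,
            consequence=annotate_consequence(site, panel),
            population_af=pop_af.lookup(site.chrom, site.pos, site.ref, site.alt),
            indel_length=site.indel_length,
        )
        failed = list(
            apply_somatic_filters(
                call,
                min_alt_reads=min_alt_reads,
                min_vaf=min_vaf,
                max_strand_bias=max_strand_bias,
                max_indel_length=max_indel_length,
                max_population_af=max_population_af,
            )
        )
        verdict = tuple(failed_pre + failed)
        call = replace(call, filter_verdict=verdict)
        if call.passed or keep_rejected:
            calls.append(call)
    calls.sort(key=lambda c: (c.site.chrom, c.site.pos, c.site.ref, c.site.alt))
    return calls


# ---------------------------------------------------------------------------
# VCF input/output
# ---------------------------------------------------------------------------

# float-valued keys are typed String so that %.17g text round-trips exactly
_INFO_FIELDS = [
    ("VAF", "String", "Variant allele frequency in the tumor"),
    ("SBF", "String", "Majority-strand fraction of alt reads"),
    ("PSOM", "String", "Posterior probability of a somatic variant"),
    ("CSQ", "String", "Consequence class"),
    ("PAF", "String", "Maximum population allele frequency"),
    ("TRF", "Integer", "Tumor ref reads, forward strand"),
    ("TRR", "Integer", "Tumor ref reads, reverse strand"),
    ("TAF", "Integer", "Tumor alt reads, forward strand"),
    ("TAR", "Integer", "Tumor alt reads, reverse strand"),
    ("NRF", "Integer", "Normal ref reads, forward strand"),
    ("NRR", "Integer", "Normal ref reads, reverse strand"),
    ("NAF", "Integer", "Normal alt reads, forward strand"),
    ("NAR", "Integer", "Normal alt reads, reverse strand"),
    ("BQ", "String", "Mean base quality"),
    ("MQ", "String", "Mean mapping quality"),
    ("STR", "Integer", "1 if the site lies in a short tandem repeat region"),
]

_PRE_FILTERS = ("base_quality", "mapping_quality", "posterior", "str_alt_reads")


def write_vcf(calls: Sequence[VariantCall], path, sample_id: str = "TUMOR") -> None:
    """Write calls as an uncompressed VCF 4.2 file.

    The FILTER column carries the failed-rule names; all pileup counts go to
    INFO so that :func:`read_vcf` round-trips calls field-for-field.
    """
    contigs = sorted({c.site.chrom for c in calls})
    lines = ["##fileformat=VCFv4.2", f"##source=hnsomatic sample={sample_id}"]
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    for rule in FILTER_RULES + _PRE_FILTERS:
        lines.append(f'##FILTER=<ID={rule},Description="Failed somatic rule {rule}">')
    for key, typ, desc in _INFO_FIELDS:
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in calls:
        s = call.site
        info = ";".join(
            [
                f"VAF={call.vaf:.17g}",
                f"SBF={call.strand_bias:.17g}",
                f"PSOM={call.posterior_somatic:.17g}",
                f"CSQ={call.consequence}",
                f"PAF={call.population_af:.17g}",
                f"TRF={s.t_ref_fwd}", f"TRR={s.t_ref_rev}",
                f"TAF={s.t_alt_fwd}", f"TAR={s.t_alt_rev}",
                f"NRF={s.n_ref_fwd}", f"NRR={s.n_ref_rev}",
                f"NAF={s.n_alt_fwd}", f"NAR={s.n_alt_rev}",
                f"BQ={s.mean_base_quality:.17g}",
                f"MQ={s.mean_mapping_quality:.17g}",
                f"STR={int(s.in_str_region)}",
            ]
        )
        lines.append(
            f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\t"
            f"{call.verdict_string}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantCall]:
    """Read a VCF written by :func:`write_vcf` back into VariantCall objects."""
    import cyvcf2

    calls = []
    for rec in cyvcf2.VCF(str(path)):
        site = PileupSite(
            chrom=rec.CHROM,
            pos=rec.POS - 1,
            ref=rec.REF,
            alt=rec.ALT[0],
            t_ref_fwd=int(rec.INFO["TRF"]),
            t_ref_rev=int(rec.INFO["TRR"]),
            t_alt_fwd=int(rec.INFO["TAF"]),
            t_alt_rev=int(rec.INFO["TAR"]),
            n_ref_fwd=int(rec.INFO["NRF"]),
            n_ref_rev=int(rec.INFO["NRR"]),
            n_alt_fwd=int(rec.INFO["NAF"]),
            n_alt_rev=int(rec.INFO["NAR"]),
            mean_base_quality=float(rec.INFO["BQ"]),
            mean_mapping_quality=float(rec.INFO["MQ"]),
            in_str_region=bool(int(rec.INFO["STR"])),
        )
        filt = rec.FILTER  # None means PASS in cyvcf2
        verdict = tuple(filt.split(";")) if filt else ()
        calls.append(
            VariantCall(
                site=site,
                vaf=float(rec.INFO["VAF"]),
                alt_reads=site.tumor_alt,
                strand_bias=float(rec.INFO["SBF"]),
                posterior_somatic=float(rec.INFO["PSOM"]),
                consequence=str(rec.INFO["CSQ"]),
                population_af=float(rec.INFO["PAF"]),
                indel_length=site.indel_length,
                filter_verdict=verdict,
            )
        )
    return calls


def calls_to_table(sample_id: str, calls: Iterable[VariantCall], gene_of=None):
    """MAF-like records for the cohort-landscape module.

    ``gene_of`` maps (chrom, pos) to a gene name; when omitted the gene column
    is left empty.
    """
    import pandas as pd

    rows = []
    for call in calls:
        s = call.site
        gene = gene_of(s.chrom, s.pos) if gene_of else ""
        rows.append(
            {
                "sample_id": sample_id,
                "gene": gene,
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "vaf": call.vaf,
                "consequence": call.consequence,
                "filter": call.verdict_string,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "gene", "chrom", "pos", "ref", "alt",
            "vaf", "consequence", "filter",
        ],
    )
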