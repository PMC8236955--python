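"""Cohort-level mutational landscape statistics.

Aggregates per-sample SNV/indel, CNV, fusion and MSI calls into a MAF-like
cohort table keyed by anatomic site and computes the landscape summaries:
per-sample mutation load, pyrimidine-normalized substitution spectrum, gene
and CNV frequencies, continuity-corrected proportion tests with
Benjamini-Hochberg FDR, Wilcoxon rank-sum load comparisons, pairwise
Fisher-exact mutual exclusivity, pathway alteration frequencies, and
knowledge-base actionability tiers (evidence levels 1 > 2 > 3A > 3B > 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortTable",
    "PathwayMap",
    "KnowledgeBase",
    "KBRule",
    "default_pathway_map",
    "default_knowledge_base",
    "summarize_mutation_load",
    "mutation_spectrum",
    "gene_frequency",
    "cnv_frequency",
    "proportion_test_cc",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "mutual_exclusivity",
    "pathway_alteration_frequency",
    "annotate_actionability",
    "export_landscape",
]

VARIANT_CLASSES = frozenset({
    "missense", "nonsense", "frameshift_ins", "frameshift_del",
    "inframe_indel", "splice_site", "other",
})

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

LEVELS = ("1", "2", "3A", "3B", "4")  # 1 is highest priority


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """MAF-like per-sample alteration matrix keyed by anatomic site.

    ``samples``: DataFrame (sample_id, anatomic_site);
    ``variants``: DataFrame (sample_id, gene, variant_class, ref, alt);
    ``cnvs``: DataFrame (sample_id, gene, cnv_type in {gain, loss});
    ``fusions``: DataFrame (sample_id, gene5, gene3);
    ``msi``: mapping sample_id -> MSI-H | MSS / MSI-stable.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    cnvs: pd.DataFrame
    fusions: pd.DataFrame
    msi: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.samples["sample_id"])
        for name, df in (("variants", self.variants), ("cnvs", self.cnvs),
                         ("fusions", self.fusions)):
            if len(df) and not set(df["sample_id"]).issubset(known):
                raise ValueError(f"{name} reference samples missing from the sample list")
        if len(self.variants):
            bad = set(self.variants["variant_class"]) - VARIANT_CLASSES
            if bad:
                raise ValueError(f"unknown variant classes: {sorted(bad)}")

    @classmethod
    def from_truth(cls, cohort: Iterable) -> "CohortTable":
        """Build the cohort table from simulated sample truths."""
        samples, variants, cnvs, fusions, msi = [], [], [], [], {}
        for item in cohort:
            truth = item[0] if isinstance(item, tuple) else item
            samples.append({"sample_id": truth.sample_id,
                            "anatomic_site": truth.anatomic_site})
            for v in truth.somatic_variants:
                variants.append({"sample_id": truth.sample_id, "gene": v.gene,
                                 "variant_class": v.variant_class,
                                 "ref": v.ref, "alt": v.alt})
            for f in truth.fusions:
                fusions.append({"sample_id": truth.sample_id,
                                "gene5": f.gene5, "gene3": f.gene3})
            msi[truth.sample_id] = truth.msi_status
        # per-gene CNV rows need a panel; attach them via with_cnv_truth
        return cls(
            samples=pd.DataFrame(samples, columns=["sample_id", "anatomic_site"]),
            variants=pd.DataFrame(
                variants, columns=["sample_id", "gene", "variant_class", "ref", "alt"]),
            cnvs=pd.DataFrame(columns=["sample_id", "gene", "cnv_type"]),
            fusions=pd.DataFrame(fusions, columns=["sample_id", "gene5", "gene3"]),
            msi=msi,
        )

    def with_cnv_truth(self, cohort: Iterable, panel) -> "CohortTable":
        """Attach per-gene CNV rows derived from truth segments and a panel."""
        rows = []
        for item in cohort:
            truth = item[0] if isinstance(item, tuple) else item
            for seg in truth.cn_segments:
                for gene in panel.genes:
                    if (gene.chromosome == seg.chrom
                            and gene.start < seg.end and gene.end > seg.start):
                        cnv_type = "gain" if seg.copy_number > truth.ploidy else "loss"
                        rows.append({"sample_id": truth.sample_id,
                                     "gene": gene.name, "cnv_type": cnv_type})
        return CohortTable(
            samples=self.samples, variants=self.variants,
            cnvs=pd.DataFrame(rows, columns=["sample_id", "gene", "cnv_type"]),
            fusions=self.fusions, msi=dict(self.msi),
        )

    def site_samples(self, grouping: Union[None, str, Sequence[str]]) -> pd.Series:
        """Sample ids in the requested grouping (site, list of sites, or all)."""
        if grouping is None:
            return self.samples["sample_id"]
        if isinstance(grouping, str):
            grouping = [grouping]
        sel = self.samples["anatomic_site"].isin(list(grouping))
        return self.samples.loc[sel, "sample_id"]


# ---------------------------------------------------------------------------
# Mutation load and spectrum
# ---------------------------------------------------------------------------

def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1


def summarize_mutation_load(table: CohortTable) -> dict:
    """Per-sample mutation counts (SNVs + indels) with per-site summaries.

    Returns a dict with ``per_sample`` (Series indexed by sample_id, zero for
    unmutated samples), ``per_site`` (DataFrame of mean/median/min/max/n),
    and cohort totals ``n_snv``, ``n_indel``, ``n_total``.
    """
    if table.samples.empty:
        raise ValueError("empty cohort table")
    counts = table.variants.groupby("sample_id").size() if len(table.variants) else pd.Series(dtype=int)
    per_sample = counts.reindex(table.samples["sample_id"], fill_value=0).astype(int)
    sites = table.samples.set_index("sample_id")["anatomic_site"]
    frame = pd.DataFrame({"count": per_sample, "site": sites})
    per_site = frame.groupby("site")["count"].agg(
        mean="mean", median="median", min="min", max="max", n="size")
    if len(table.variants):
        snv_mask = [
            _is_snv(r, a) for r, a in zip(table.variants["ref"], table.variants["alt"])
        ]
        n_snv = int(sum(snv_mask))
        n_indel = int(len(table.variants) - n_snv)
    else:
        n_snv = n_indel = 0
    return {
        "per_sample": per_sample,
        "per_site": per_site,
        "n_snv": n_snv,
        "n_indel": n_indel,
        "n_total": n_snv + n_indel,
    }


def mutation_spectrum(table: CohortTable) -> dict[str, float]:
    """Fractions over the six pyrimidine-normalized substitution classes.

    Purine-reference SNVs are complemented (G>A counts as C>T); non-SNV
    records are ignored.
    """
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    for ref, alt in zip(table.variants["ref"], table.variants["alt"]):
        if not _is_snv(ref, alt):
            continue
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        key = f"{ref}>{alt}"
        if key in counts:
            counts[key] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no SNVs to classify")
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Gene / CNV frequencies
# ---------------------------------------------------------------------------

def gene_frequency(
    table: CohortTable,
    gene: str,
    grouping: Union[None, str, Sequence[str]] = None,
) -> tuple[int, int, float]:
    """(mutated sample count, group size, percent rounded to one decimal)."""
    group = table.site_samples(grouping)
    if group.empty:
        raise ValueError("empty grouping")
    mutated = set(table.variants.loc[table.variants["gene"] == gene, "sample_id"])
    count = int(sum(1 for s in group if s in mutated))
    size = int(len(group))
    return count, size, round(100.0 * count / size, 1)


def cnv_frequency(
    table: CohortTable,
    gene: str,
    grouping: Union[None, str, Sequence[str]] = None,
) -> tuple[int, int, int, float]:
    """(altered sample count, gains, losses, percent to one decimal)."""
    group = table.site_samples(grouping)
    if group.empty:
        raise ValueError("empty grouping")
    sub = table.cnvs[table.cnvs["gene"] == gene]
    sub = sub[sub["sample_id"].isin(set(group))]
    gains = int(sub[sub["cnv_type"] == "gain"]["sample_id"].nunique())
    losses = int(sub[sub["cnv_type"] == "loss"]["sample_id"].nunique())
    altered = int(sub["sample_id"].nunique())
    return altered, gains, losses, round(100.0 * altered / len(group), 1)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def proportion_test_cc(successes: Sequence[int], sizes: Sequence[int]) -> float:
    """k-sample test of equal proportions, continuity-corrected for k = 2.

    For two groups this is the chi-square test with Yates continuity
    correction; for k > 2 the k-sample chi-square test of equal proportions
    (no correction). Returns the two-sided p-value.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if len(x) < 2 or len(x) != len(n):
        raise ValueError("need success counts and sizes for k >= 2 groups")
    if np.any(n <= 0):
        raise ValueError("group sizes must be positive")
    if np.any((x < 0) | (x > n)):
        raise ValueError("success counts must lie in [0, size]")
    contingency = np.vstack([x, n - x])
    if np.any(contingency.sum(axis=1) == 0):
        return 1.0  # all groups identically 0% or 100%
    result = stats.chi2_contingency(contingency, correction=(len(x) == 2))
    return float(result[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most 10 observations and no
    ties across the pooled data; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    pooled = a + b
    exact = len(a) <= 10 and len(b) <= 10 and len(set(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method, use_continuity=True).pvalue)


def mutual_exclusivity(
    table: CohortTable,
    gene_a: str,
    gene_b: str,
    grouping: Union[None, str, Sequence[str]] = None,
) -> tuple[int, float]:
    """(overlap count, Fisher exact two-sided p) for two genes' mutation sets."""
    group = list(table.site_samples(grouping))
    if not group:
        raise ValueError("empty grouping")
    in_group = set(group)
    set_a = set(table.variants.loc[table.variants["gene"] == gene_a, "sample_id"]) & in_group
    set_b = set(table.variants.loc[table.variants["gene"] == gene_b, "sample_id"]) & in_group
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    neither = len(in_group) - both - only_a - only_b
    _, p = stats.fisher_exact([[both, only_a], [only_b, neither]],
                              alternative="two-sided")
    return both, float(p)


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------

@dataclass
class PathwayMap:
    """pathway name -> {gene: role}, role in {oncogene, tumor_suppressor}."""

    pathways: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            for gene, role in members.items():
                if role not in ("oncogene", "tumor_suppressor"):
                    raise ValueError(f"unknown role {role!r} for {gene} in {name}")


def default_pathway_map() -> PathwayMap:
    """Deregulated cancer pathways with member genes and roles."""
    return PathwayMap({
        "RTK_RAS_PI3K": {
            "FGFR1": "oncogene", "EGFR": "oncogene", "ERBB2": "oncogene",
            "PIK3CA": "oncogene", "HRAS": "oncogene",
        },
        "cell_cycle": {
            "TP53": "tumor_suppressor", "CDKN2A": "tumor_suppressor",
            "CDKN2B": "tumor_suppressor", "CDKN1B": "tumor_suppressor",
            "CCND1": "oncogene", "MYC": "oncogene",
        },
        "NFKB": {
            "CYLD": "tumor_suppressor", "NFKBIA": "tumor_suppressor",
            "TRAF3": "tumor_suppressor", "NLRC5": "tumor_suppressor",
        },
        "WNT_NOTCH": {
            "NOTCH1": "tumor_suppressor", "FAT1": "tumor_suppressor",
            "CTNNB1": "oncogene",
        },
    })


def _altered_samples(table: CohortTable, gene: str) -> set[str]:
    """Samples with >= 1 SNV/indel, CNV or fusion in ``gene``."""
    out = set(table.variants.loc[table.variants["gene"] == gene, "sample_id"])
    out |= set(table.cnvs.loc[table.cnvs["gene"] == gene, "sample_id"])
    if len(table.fusions):
        hit = (table.fusions["gene5"] == gene) | (table.fusions["gene3"] == gene)
        out |= set(table.fusions.loc[hit, "sample_id"])
    return out


def pathway_alteration_frequency(
    table: CohortTable,
    pathway_map: PathwayMap,
    grouping: Union[None, str, Sequence[str]] = None,
) -> dict[str, dict]:
    """Per-pathway and per-gene altered-sample percentages (integers).

    A sample counts once per pathway regardless of how many member genes are
    altered; SNVs/indels, CNVs and fusions all count.
    """
    group = list(table.site_samples(grouping))
    if not group:
        raise ValueError("empty grouping")
    in_group = set(group)
    out: dict[str, dict] = {}
    for name, members in pathway_map.pathways.items():
        pathway_hit: set[str] = set()
        gene_pct = {}
        for gene in members:
            hit = _altered_samples(table, gene) & in_group
            pathway_hit |= hit
            gene_pct[gene] = round(100.0 * len(hit) / len(group))
        out[name] = {
            "pathway_pct": round(100.0 * len(pathway_hit) / len(group)),
            "altered_samples": len(pathway_hit),
            "n": len(group),
            "genes": gene_pct,
        }
    return out


# ---------------------------------------------------------------------------
# Actionability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KBRule:
    gene: str  # gene symbol, or the special marker "MSI-H"
    alteration_type: str  # snv_indel | deletion | amplification | fusion | msi_h
    level: Optional[str]  # evidence level, None for oncogenic-only rules
    drugs: tuple[str, ...] = ()
    oncogenic: bool = True
    variant_pattern: Optional[str] = None  # optional variant_class filter

    def __post_init__(self) -> None:
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"unknown evidence level {self.level!r}")
        if self.alteration_type not in (
                "snv_indel", "deletion", "amplification", "fusion", "msi_h"):
            raise ValueError(f"unknown alteration type {self.alteration_type!r}")


@dataclass
class KnowledgeBase:
    rules: list[KBRule]

    @classmethod
    def from_yaml(cls, path) -> "KnowledgeBase":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = []
        for entry in raw["rules"]:
            rules.append(KBRule(
                gene=entry["gene"],
                alteration_type=entry["alteration_type"],
                level=entry.get("level"),
                drugs=tuple(entry.get("drugs", [])),
                oncogenic=bool(entry.get("oncogenic", True)),
                variant_pattern=entry.get("variant_pattern"),
            ))
        return cls(rules)


def default_knowledge_base() -> KnowledgeBase:
    """Bundled static therapy-evidence table (no network lookup).

    A curated stand-in for a clinical knowledge base: level-1 entries for
    NTRK fusions (larotrectinib/entrectinib) and MSI-H (pembrolizumab), and
    lower-level entries for the recurrently altered panel genes.
    """
    r = KBRule
    return KnowledgeBase([
        r("NTRK2", "fusion", "1", ("larotrectinib", "entrectinib")),
        r("MSI-H", "msi_h", "1", ("pembrolizumab",)),
        r("ERBB2", "amplification", "3A", ("trastuzumab", "pertuzumab")),
        r("PIK3CA", "snv_indel", "3B", ("alpelisib",)),
        r("PIK3CA", "amplification", "4", ()),
        r("FGFR1", "amplification", "3B", ("erdafitinib",)),
        r("CCND1", "amplification", "4", ("abemaciclib", "palbociclib")),
        r("MYC", "amplification", "4", ()),
        r("CDKN2A", "deletion", "4", ("abemaciclib", "palbociclib")),
        r("CDKN2A", "snv_indel", "4", ("abemaciclib", "palbociclib")),
        r("CDKN2B", "deletion", "4", ()),
        r("EGFR", "amplification", "3B", ("cetuximab",)),
        r("HRAS", "snv_indel", "3A", ("tipifarnib",)),
        # oncogenic but not directly actionable
        r("TP53", "snv_indel", None),
        r("FAT1", "snv_indel", None),
        r("KMT2D", "snv_indel", None),
        r("NOTCH1", "snv_indel", None),
        r("CYLD", "snv_indel", None),
        r("BAP1", "snv_indel", None),
        r("CHD4", "snv_indel", None),
        r("LRP1B", "snv_indel", None),
        r("NFKBIA", "deletion", None),
        r("CTNNB1", "snv_indel", None),
    ])


def _sample_alterations(table: CohortTable, sample: str) -> list[tuple[str, str, Optional[str]]]:
    """(gene, alteration_type, variant_class) triples carried by a sample."""
    alts: list[tuple[str, str, Optional[str]]] = []
    v = table.variants[table.variants["sample_id"] == sample]
    for row in v.itertuples():
        alts.append((row.gene, "snv_indel", row.variant_class))
    c = table.cnvs[table.cnvs["sample_id"] == sample]
    for row in c.itertuples():
        kind = "amplification" if row.cnv_type == "gain" else "deletion"
        alts.append((row.gene, kind, None))
    f = table.fusions[table.fusions["sample_id"] == sample]
    for row in f.itertuples():
        alts.append((row.gene5, "fusion", None))
        alts.append((row.gene3, "fusion", None))
    if table.msi.get(sample) == "MSI-H":
        alts.append(("MSI-H", "msi_h", None))
    return alts


def annotate_actionability(
    table: CohortTable,
    kb: Optional[KnowledgeBase] = None,
) -> dict:
    """Per-sample highest evidence level and cohort actionability summary.

    A sample's level is the highest-priority level among matched rules
    (1 > 2 > 3A > 3B > 4); samples matching any rule (leveled or not) count
    as carrying an oncogenic alteration. The summary reports counts and
    percentages over all samples plus per-(gene, alteration-type) tallies.
    """
    kb = kb or default_knowledge_base()
    priority = {lvl: i for i, lvl in enumerate(LEVELS)}
    per_sample_level: dict[str, Optional[str]] = {}
    oncogenic_samples: set[str] = set()
    kind_tally: dict[tuple[str, str], int] = {}
    for sample in table.samples["sample_id"]:
        best: Optional[str] = None
        matched_kinds: set[tuple[str, str]] = set()
        for gene, kind, vclass in _sample_alterations(table, sample):
            for rule in kb.rules:
                if rule.gene != gene or rule.alteration_type != kind:
                    continue
                if rule.variant_pattern is not None and vclass != rule.variant_pattern:
                    continue
                if rule.oncogenic:
                    oncogenic_samples.add(sample)
                if rule.level is not None:
                    matched_kinds.add((gene, kind))
                    if best is None or priority[rule.level] < priority[best]:
                        best = rule.level
        per_sample_level[sample] = best
        for key in matched_kinds:
            kind_tally[key] = kind_tally.get(key, 0) + 1
    n = len(table.samples)
    actionable = [s for s, lvl in per_sample_level.items() if lvl is not None]
    level_counts = {lvl: sum(1 for v in per_sample_level.values() if v == lvl)
                    for lvl in LEVELS}
    return {
        "per_sample_level": per_sample_level,
        "n_samples": n,
        "n_actionable": len(actionable),
        "actionable_pct": round(100.0 * len(actionable) / n, 1) if n else 0.0,
        "n_oncogenic": len(oncogenic_samples),
        "oncogenic_pct": round(100.0 * len(oncogenic_samples) / n, 1) if n else 0.0,
        "level_counts": level_counts,
        "alteration_kind_counts": dict(sorted(
            kind_tally.items(), key=lambda kv: (-kv[1], kv[0]))),
    }


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_landscape(table: CohortTable, outdir, results: Optional[dict] = None) -> list[str]:
    """Write the MAF-like table, frequency tables, and a sorted sample-by-gene
    alteration matrix (samples grouped by anatomic site, genes by descending
    mutated-sample count, alphabetical tie-break)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.variants.to_csv(out / "variants.maf.tsv", sep="\t", index=False)
    table.cnvs.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)

    genes = sorted(set(table.variants["gene"])) if len(table.variants) else []
    freq_rows = []
    for gene in genes:
        count, size, pct = gene_frequency(table, gene)
        freq_rows.append({"gene": gene, "mutated_samples": count,
                          "n": size, "percent": pct})
    freq = pd.DataFrame(freq_rows, columns=["gene", "mutated_samples", "n", "percent"])
    freq = freq.sort_values(["mutated_samples", "gene"],
                            ascending=[False, True], ignore_index=True)
    freq.to_csv(out / "gene_frequencies.tsv", sep="\t", index=False)

    sample_order = table.samples.sort_values(
        ["anatomic_site", "sample_id"])["sample_id"].tolist()
    matrix = pd.DataFrame("", index=freq["gene"].tolist(), columns=sample_order)
    for row in table.variants.itertuples():
        prev = matrix.at[row.gene, row.sample_id]
        matrix.at[row.gene, row.sample_id] = (
            f"{prev};{row.variant_class}" if prev else row.variant_class)
    matrix.to_csv(out / "oncoprint_matrix.tsv", sep="\t")
    return ["variants.maf.tsv", "cnv_calls.tsv", "gene_frequencies.tsv",
            "oncoprint_matrix.tsv"]
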