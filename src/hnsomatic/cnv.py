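"""Copy-number calling: panel of normals, GC normalization, log2 ratios,
circular binary segmentation, and purity/ploidy-aware absolute copy number.

The normalized tumor depth of each fixed-size bin is divided by a pooled
panel-of-normals reference to give a log2 ratio profile, segmented by CBS
(recursive splitting on the circularized max-|t| arc, accepted by a seeded
permutation test). Tumor purity p and ploidy psi are estimated by a grid
search against het-SNP B-allele frequencies and segment log2 ratios under
the allele-specific mixture model

    observed ratio  2^l = (p*C + 2(1-p)) / (p*psi + 2(1-p))
    het-SNP BAF         = (p*b + (1-p)) / (p*C + 2(1-p))

with C the segment's total copy number and b the copies of the B allele.
Absolute copy number inverts the first relation:

    C = (2^l * (p*psi + 2(1-p)) - 2(1-p)) / p ,  floored at 0.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PanelOfNormals",
    "Segment",
    "PurityPloidyFit",
    "AbsoluteCNSegment",
    "build_pon",
    "normalize_gc",
    "cbs_segment",
    "max_circular_t",
    "expected_log2",
    "expected_baf",
    "absolute_cn",
    "classify_gain_loss",
    "fit_purity_ploidy",
    "call_cnv_sample",
    "segments_to_seg_table",
]


@dataclass(frozen=True)
class PanelOfNormals:
    """Pooled normal-coverage reference: per-bin median of library-size-scaled
    normal profiles, with low-coverage bins masked."""

    reference: np.ndarray  # per-bin reference depth (> 0 where usable)
    variance: np.ndarray
    mask: np.ndarray  # True where the bin is usable

    @property
    def n_bins(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class Segment:
    start: int  # first bin index (inclusive)
    end: int  # past-last bin index
    mean: float
    n_bins: int
    p_value: Optional[float] = None  # permutation p of the split creating it


@dataclass(frozen=True)
class PurityPloidyFit:
    purity: float
    ploidy: float
    score: float
    ambiguous: bool = False
    defaulted: bool = False


@dataclass(frozen=True)
class AbsoluteCNSegment:
    chrom: str
    start: int
    end: int
    bin_start: int
    bin_end: int
    n_bins: int
    mean_log2: float
    copy_number: float
    copy_number_int: int
    call: str  # gain | loss | neutral
    genes: tuple[str, ...] = ()


def build_pon(
    profiles: Sequence[np.ndarray],
    min_median_depth: float = 10.0,
) -> PanelOfNormals:
    """Build a mixed panel of normals from >= 2 per-bin depth profiles.

    Each profile is scaled to the mean library size (median depth), then the
    per-bin median across normals becomes the reference. Bins whose scaled
    median falls below ``min_median_depth`` are masked.
    """
    if len(profiles) < 2:
        raise ValueError("a panel of normals needs at least 2 normal profiles")
    arrays = [np.asarray(p, dtype=float) for p in profiles]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("normal profiles cover different bin sets")
    medians = np.array([np.median(a) for a in arrays])
    if np.any(medians <= 0):
        # profiles that are mostly zero cannot be library-size scaled
        medians = np.where(medians <= 0, 1.0, medians)
    target = medians.mean()
    scaled = np.vstack([a * (target / m) for a, m in zip(arrays, medians)])
    reference = np.median(scaled, axis=0)
    variance = np.var(scaled, axis=0, ddof=0)
    mask = reference >= min_median_depth
    return PanelOfNormals(reference=reference, variance=variance, mask=mask)


def normalize_gc(
    depths: np.ndarray,
    gc_fractions: np.ndarray,
    stratum_width: float = 0.02,
    min_bins_per_stratum: int = 20,
) -> np.ndarray:
    """Rolling-median GC correction.

    Bins are grouped into GC strata of ``stratum_width``; sparse strata are
    merged with their right neighbor until each group holds at least
    ``min_bins_per_stratum`` bins, which keeps the stratum median robust to
    a minority of copy-number-altered bins. Each depth is divided by its
    group's median and rescaled so the overall median depth is preserved;
    groups with a zero median fall back to the global median. The output
    median is invariant to any monotone GC bias applied upstream.
    """
    depths = np.asarray(depths, dtype=float)
    gc = np.asarray(gc_fractions, dtype=float)
    if depths.shape != gc.shape:
        raise ValueError("depths and gc_fractions must have equal length")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc fractions must lie in [0, 1]")
    if len(depths) == 0:
        return depths.copy()
    global_median = float(np.median(depths))
    if global_median <= 0:
        return depths.copy()
    strata = np.floor(gc / stratum_width).astype(int)
    # merge sparse strata rightward (then leftward for the trailing group)
    groups: list[np.ndarray] = []
    pending = np.zeros(0, dtype=int)
    for stratum in np.unique(strata):
        idx = np.where(strata == stratum)[0]
        pending = np.concatenate([pending, idx])
        if len(pending) >= min_bins_per_stratum:
            groups.append(pending)
            pending = np.zeros(0, dtype=int)
    if len(pending):
        if groups:
            groups[-1] = np.concatenate([groups[-1], pending])
        else:
            groups.append(pending)
    corrected = np.empty_like(depths)
    for idx in groups:
        med = float(np.median(depths[idx]))
        if med <= 0:
            med = global_median
        corrected[idx] = depths[idx] / med * global_median
    return corrected


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def max_circular_t(values: np.ndarray) -> tuple[float, int, int]:
    """Maximum |t|-like statistic over all circular arcs of ``values``.

    For the arc [i, j) of length k against the remaining n-k bins,
    t = (mean_in - mean_out) / sqrt(1/k + 1/(n-k)); the scale factor is
    constant over arcs so it does not affect the argmax. Returns
    (|t|_max, i, j). Wrap-around arcs are the complements of linear arcs and
    share the same |t|, so scanning i < j covers the circle.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        return 0.0, 0, n
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    best = (-1.0, 0, n)
    for k in range(1, n):
        s = cs[k:] - cs[:-k]  # arc sums for arcs [i, i+k), i = 0..n-k
        mean_in = s / k
        mean_out = (total - s) / (n - k)
        t = np.abs(mean_in - mean_out) / math.sqrt(1.0 / k + 1.0 / (n - k))
        i = int(np.argmax(t))
        if t[i] > best[0]:
            best = (float(t[i]), i, i + k)
    return best


def _perm_max_t(x: np.ndarray, n_perm: int, rng: np.random.Generator,
                observed: float, alpha: float) -> float:
    """Permutation p-value of the max-|t| statistic, with early stopping once
    the exceedance count can no longer fall below alpha."""
    n = len(x)
    stop_at = math.ceil(alpha * n_perm)
    exceed = 0
    done = 0
    chunk = 50
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.vstack([rng.permutation(x) for _ in range(b)])
        cs = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
        total = cs[:, -1:]
        maxima = np.zeros(b)
        for k in range(1, n):
            s = cs[:, k:] - cs[:, :-k]
            mean_in = s / k
            mean_out = (total - s) / (n - k)
            t = np.abs(mean_in - mean_out) / math.sqrt(1.0 / k + 1.0 / (n - k))
            maxima = np.maximum(maxima, t.max(axis=1))
        exceed += int(np.sum(maxima >= observed))
        done += b
        if exceed >= stop_at:  # split can no longer be accepted
            return exceed / done
    return exceed / n_perm


def cbs_segment(
    values: Sequence[float],
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    min_seg_diff: float = 0.1,
) -> list[Segment]:
    """Circular binary segmentation of an ordered log2-ratio vector.

    Recursively splits at the circularized max-|t| arc while the permutation
    p-value is below ``alpha``; adjacent segments whose means differ by less
    than ``min_seg_diff`` are re-merged. Segments partition the input and
    segment means equal the mean over member bins. Constant input yields one
    segment.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot segment an empty vector")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    boundaries: list[tuple[int, int, Optional[float]]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 4 or float(np.ptp(seg)) < 1e-12:
            boundaries.append((lo, hi, None))
            return
        stat, i, j = max_circular_t(seg)
        if stat <= 0 or (i == 0 and j == n):
            boundaries.append((lo, hi, None))
            return
        p = _perm_max_t(seg, n_permutations, rng, stat, alpha)
        if p >= alpha:
            boundaries.append((lo, hi, p))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, len(x))
    boundaries.sort()
    segments = [
        Segment(lo, hi, float(np.mean(x[lo:hi])), hi - lo, p)
        for lo, hi, p in boundaries
    ]
    # re-merge adjacent segments with near-equal means
    merged: list[Segment] = []
    for seg in segments:
        if merged and abs(merged[-1].mean - seg.mean) < min_seg_diff:
            prev = merged.pop()
            lo, hi = prev.start, seg.end
            merged.append(Segment(lo, hi, float(np.mean(x[lo:hi])), hi - lo,
                                  prev.p_value))
        else:
            merged.append(seg)
    return merged


# ---------------------------------------------------------------------------
# Purity / ploidy and absolute copy number
# ---------------------------------------------------------------------------

def expected_log2(copy_number: float, purity: float, ploidy: float) -> float:
    """Expected log2 ratio of a segment with total copy number C."""
    num = purity * copy_number + 2.0 * (1.0 - purity)
    den = purity * ploidy + 2.0 * (1.0 - purity)
    return math.log2(num / den)


def expected_baf(b_copies: float, copy_number: float, purity: float) -> float:
    """Expected B-allele frequency at a het SNP on a segment with total copy
    number C and ``b_copies`` copies of the B allele in tumor cells."""
    return (purity * b_copies + (1.0 - purity)) / (
        purity * copy_number + 2.0 * (1.0 - purity)
    )


def absolute_cn(mean_log2: float, purity: float, ploidy: float) -> tuple[float, int]:
    """Absolute copy number of a segment from its mean log2 ratio.

    Inverts the expected-ratio model; returns the real-valued copy number
    (floored at 0) and its rounded integer.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    c = (2.0 ** mean_log2 * (purity * ploidy + 2.0 * (1.0 - purity))
         - 2.0 * (1.0 - purity)) / purity
    c = max(c, 0.0)
    return c, int(round(c))


def classify_gain_loss(copy_number_int: int, ploidy: float,
                       gain_offset: int = 1, loss_offset: int = 1) -> str:
    """gain iff C >= round(ploidy)+gain_offset, loss iff C <= round(ploidy)-loss_offset."""
    if copy_number_int < 0:
        raise ValueError("copy number must be nonnegative")
    base = round(ploidy)
    if copy_number_int >= base + gain_offset:
        return "gain"
    if copy_number_int <= base - loss_offset:
        return "loss"
    return "neutral"


def _expected_mirrored_baf(exp_b: np.ndarray, depth: float) -> np.ndarray:
    """Expected value of max(BAF, 1-BAF) for binomial BAF around ``exp_b``.

    max(X, 1-X) = 0.5 + |X - 0.5|; with X approximately normal the folded
    moment is delta*(1 - 2*Phi(-delta/sigma)) + sigma*sqrt(2/pi)*exp(-delta^2
    / (2 sigma^2)). Modeling this expectation removes the upward bias the
    mirroring operation puts on balanced (BAF = 0.5) segments.
    """
    from scipy.special import ndtr

    sigma = np.sqrt(np.clip(exp_b * (1.0 - exp_b), 1e-12, None) / max(depth, 1.0))
    sigma = np.maximum(sigma, 1e-6)
    delta = np.abs(exp_b - 0.5)
    folded = (delta * (1.0 - 2.0 * ndtr(-delta / sigma))
              + sigma * math.sqrt(2.0 / math.pi) * np.exp(-(delta ** 2) / (2 * sigma ** 2)))
    return 0.5 + folded


def fit_purity_ploidy(
    segments: Sequence,
    snp_records: Sequence,
    normal_records: Optional[Sequence] = None,
    *,
    purity_step: float = 0.01,
    ploidy_step: float = 0.05,
    het_band: tuple[float, float] = (0.4, 0.6),
    max_copies: int = 12,
    baf_noise: float = 0.02,
    log2_noise: float = 0.08,
    ploidy_penalty: float = 1.0,
) -> PurityPloidyFit:
    """Grid-search purity and ploidy against het-SNP BAFs and segment log2.

    ``segments`` need ``chrom``/``start``/``end``/``mean_log2``; SNPs are
    matched to their containing segment and summarized by the mean mirrored
    BAF max(b, 1-b), compared against its model expectation. When
    ``normal_records`` are given, only SNPs heterozygous in the normal (BAF
    within ``het_band``) are used; otherwise tumor records with folded BAF
    > 0.02 stand in.

    The grid covers p in [0.2, 1] (step 0.01) and ploidy in [1, 8] (step
    0.05). Residuals are inverse-variance weighted: the BAF residual by
    ``n_snps / baf_noise^2`` (``baf_noise`` is the nominal per-SNP mirrored-
    BAF standard deviation) and the log2 residual by
    ``n_bins / log2_noise^2`` (nominal per-bin log2 noise), so the far more
    precise allelic evidence is not outvoted by segment-mean depth noise.

    Because the genome-doubling transformation (p' = p/(2-p), C' = 2C,
    psi' = 2psi) reproduces log2 ratios and BAFs exactly, the score adds a
    parsimony penalty ``ploidy_penalty * n_segments * ((psi-2)^2 +
    (1-p)^2)`` (about one normalized-residual unit per segment) that selects
    the least-doubled solution on the degeneracy ridge. Residual ties (as
    in the diploid null, where purity is unidentifiable) are flagged
    ``ambiguous`` and resolved toward higher purity, then ploidy nearer 2.
    """
    het_positions = None
    if normal_records is not None:
        het_positions = {
            (r.chrom, r.pos)
            for r in normal_records
            if r.depth > 0 and het_band[0] <= r.alt_depth / r.depth <= het_band[1]
        }

    seg_summaries = []  # (mean_log2, mean mirrored BAF, n SNPs, depth, n bins)
    for seg in segments:
        mirrored = []
        depths = []
        for r in snp_records:
            if r.chrom != seg.chrom or not (seg.start <= r.pos < seg.end):
                continue
            if het_positions is not None and (r.chrom, r.pos) not in het_positions:
                continue
            if r.depth <= 0:
                continue
            baf = r.alt_depth / r.depth
            if het_positions is None and min(baf, 1.0 - baf) <= 0.02:
                continue  # uninformative homozygous SNP
            mirrored.append(max(baf, 1.0 - baf))
            depths.append(r.depth)
        if mirrored:
            n_bins = getattr(seg, "n_bins", None) or len(mirrored)
            seg_summaries.append((seg.mean_log2, float(np.mean(mirrored)),
                                  len(mirrored), float(np.mean(depths)),
                                  int(n_bins)))
    if not seg_summaries:
        raise ValueError(
            "no informative heterozygous SNPs in any segment; "
            "fall back to default purity=1.0, ploidy=2.0"
        )

    purities = np.round(np.arange(0.2, 1.0 + 1e-9, purity_step), 10)
    ploidies = np.round(np.arange(1.0, 8.0 + 1e-9, ploidy_step), 10)
    P = purities[:, None]
    Psi = ploidies[None, :]
    tumor_frac = P * Psi + 2.0 * (1.0 - P)  # diploid-equivalent DNA mass
    residual = np.zeros((len(purities), len(ploidies)))
    for l, m_obs, n_snps, depth, n_bins in seg_summaries:
        c_real = (2.0 ** l * tumor_frac - 2.0 * (1.0 - P)) / P
        c = np.clip(np.rint(c_real), 0, max_copies)
        # epsilon floor keeps the pure-tumor homozygous-deletion cell finite
        denom = np.maximum(P * c + 2.0 * (1.0 - P), 1e-6)
        resid_l = (l - np.log2(denom / tumor_frac)) ** 2
        b_best = np.full_like(residual, np.inf)
        for b in range(0, max_copies // 2 + 1):
            exp_b = (P * b + (1.0 - P)) / denom
            cand = (m_obs - _expected_mirrored_baf(exp_b, depth)) ** 2
            b_best = np.where(b <= c // 2, np.minimum(b_best, cand), b_best)
        residual += (b_best * n_snps / baf_noise ** 2
                     + resid_l * n_bins / log2_noise ** 2)
    penalty = (ploidy_penalty * len(seg_summaries)
               * ((Psi - 2.0) ** 2 + (1.0 - P) ** 2))
    score = residual + penalty
    flat = np.argmin(score)
    ties = np.argwhere(score <= score.flat[flat] + 1e-12)
    order = sorted(
        ties.tolist(),
        key=lambda ij: (-purities[ij[0]], abs(ploidies[ij[1]] - 2.0)),
    )
    pi, pj = order[0]
    res_ties = int(np.sum(residual <= residual.min() + 1e-12))
    return PurityPloidyFit(purity=float(purities[pi]), ploidy=float(ploidies[pj]),
                           score=float(score[pi, pj]), ambiguous=res_ties > 1)


# ---------------------------------------------------------------------------
# End-to-end per-sample CNV calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _GenomicSegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_bins: int = 0


def call_cnv_sample(
    evidence,
    panel,
    pon: PanelOfNormals,
    *,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    min_seg_diff: float = 0.1,
) -> tuple[list[AbsoluteCNSegment], dict[str, str], PurityPloidyFit]:
    """Call absolute copy-number segments and per-gene gain/loss for a sample.

    Pipeline: library-size scaling, GC normalization, division by the PON
    reference, per-chromosome CBS, BAF purity/ploidy fit, absolute copy
    number and classification; each gene is called from the segment with the
    largest overlap. Deterministic for a fixed seed.
    """
    depths = np.zeros(len(panel.bins))
    for idx, depth in evidence.depth_bins:
        if idx >= len(panel.bins):
            raise ValueError("evidence bins do not match the panel bin set")
    if len(evidence.depth_bins) != len(panel.bins) or pon.n_bins != len(panel.bins):
        raise ValueError("evidence bins do not match the panel/PON bin set")
    for idx, depth in evidence.depth_bins:
        depths[idx] = depth
    gc = np.array([b.gc_fraction for b in panel.bins])

    tumor_med = np.median(depths[pon.mask])
    scaled = depths / tumor_med if tumor_med > 0 else depths
    corrected = normalize_gc(scaled, gc)
    ref_corrected = normalize_gc(pon.reference, gc)
    ref_rel = ref_corrected / np.median(ref_corrected[pon.mask])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pon.mask & (ref_rel > 0),
                         corrected / np.median(corrected[pon.mask]) / ref_rel, np.nan)
    log2r = np.log2(np.clip(ratio, 1e-6, None))

    # per-chromosome segmentation over usable bins
    chrom_of = np.array([b.chrom for b in panel.bins])
    genomic_segments: list[_GenomicSegment] = []
    seg_records: list[AbsoluteCNSegment] = []
    raw: list[tuple[str, int, int, float, int]] = []  # chrom, bin lo, bin hi, mean, nbins
    for chrom in dict.fromkeys(chrom_of):  # preserve panel order
        idxs = np.where((chrom_of == chrom) & pon.mask)[0]
        if len(idxs) == 0:
            continue
        values = log2r[idxs]
        chrom_tag = zlib.crc32(chrom.encode()) % 10_000
        segs = cbs_segment(values, alpha=alpha, n_permutations=n_permutations,
                           seed=seed + chrom_tag, min_seg_diff=min_seg_diff)
        for seg in segs:
            members = idxs[seg.start:seg.end]
            raw.append((chrom, int(members[0]), int(members[-1]) + 1,
                        seg.mean, seg.n_bins))
            genomic_segments.append(_GenomicSegment(
                chrom, panel.bins[members[0]].start,
                panel.bins[members[-1]].end, seg.mean, seg.n_bins))

    # purity / ploidy
    normal_records = (evidence.paired_normal.snp_baf_records
                      if evidence.paired_normal is not None else None)
    try:
        fit = fit_purity_ploidy(genomic_segments, evidence.snp_baf_records,
                                normal_records)
    except ValueError:
        fit = PurityPloidyFit(purity=1.0, ploidy=2.0, score=math.nan,
                              ambiguous=True, defaulted=True)

    for (chrom, blo, bhi, mean, nb), gseg in zip(raw, genomic_segments):
        c_real, c_int = absolute_cn(mean, fit.purity, fit.ploidy)
        seg_records.append(AbsoluteCNSegment(
            chrom=chrom, start=gseg.start, end=gseg.end,
            bin_start=blo, bin_end=bhi, n_bins=nb, mean_log2=mean,
            copy_number=c_real, copy_number_int=c_int,
            call=classify_gain_loss(c_int, fit.ploidy),
            genes=tuple(sorted(
                g.name for g in panel.genes
                if g.chromosome == chrom and g.start < gseg.end and g.end > gseg.start
            )),
        ))

    gene_calls: dict[str, str] = {}
    for gene in panel.genes:
        best_overlap = 0
        call = "neutral"
        for seg in seg_records:
            if seg.chrom != gene.chromosome:
                continue
            overlap = min(seg.end, gene.end) - max(seg.start, gene.start)
            if overlap > best_overlap:
                best_overlap = overlap
                call = seg.call
        gene_calls[gene.name] = call
    return seg_records, gene_calls, fit


def segments_to_seg_table(sample_id: str, segments: Sequence[AbsoluteCNSegment]):
    """SEG-format table (sample, chrom, start, end, n_bins, seg.mean)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample": sample_id,
                "chrom": s.chrom,
                "loc.start": s.start,
                "loc.end": s.end,
                "num.mark": s.n_bins,
                "seg.mean": s.mean_log2,
                "copy.number": s.copy_number_int,
                "call": s.call,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "loc.start", "loc.end", "num.mark",
                 "seg.mean", "copy.number", "call"],
    )
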