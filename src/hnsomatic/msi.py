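"""Microsatellite-instability classification from repeat-length histograms.

For each of the (by default) 100 assayed microsatellite loci the tumor and
matched-normal repeat-length histograms are compared with a two-sample
chi-square test on pooled length bins; a locus is unstable when the
difference is significant. A sample is MSI-high when at least 75 of the 100
loci are unstable, otherwise MSI-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MSLocusProfile",
    "MSISampleResult",
    "compare_locus",
    "classify_sample",
    "call_msi_sample",
]

#: Number of microsatellite loci on the panel.
N_MS_LOCI = 100
#: A sample is MSI-H iff at least this many loci are unstable.
MSI_H_LOCUS_THRESHOLD = 75
#: Both histograms need at least this many reads for the locus to be evaluable.
DEFAULT_MIN_DEPTH = 30


@dataclass(frozen=True)
class MSLocusProfile:
    """Tumor and matched-normal repeat-length read-count histograms."""

    locus_id: str
    tumor: dict[int, int]  # repeat length -> read count
    normal: dict[int, int]
    min_depth: int = DEFAULT_MIN_DEPTH

    def __post_init__(self) -> None:
        for hist in (self.tumor, self.normal):
            if any(c < 0 for c in hist.values()):
                raise ValueError("histogram counts must be nonnegative")

    @property
    def tumor_depth(self) -> int:
        return sum(self.tumor.values())

    @property
    def normal_depth(self) -> int:
        return sum(self.normal.values())

    @property
    def evaluable(self) -> bool:
        return self.tumor_depth >= self.min_depth and self.normal_depth >= self.min_depth


@dataclass(frozen=True)
class MSISampleResult:
    per_locus: dict[str, str]  # locus -> MSI-H | MSS | not_evaluable
    unstable_count: int
    evaluable_count: int
    status: str  # MSI-H | MSI-stable
    low_evaluability: bool = False


def _merged_counts(profile: MSLocusProfile, min_expected: float = 5.0):
    """2 x L count table over pooled repeat-length bins.

    Tail bins whose expected count falls below ``min_expected`` are merged
    inward (leftmost/rightmost bin absorbed into its neighbor) until every
    remaining bin is adequate or only two bins remain.
    """
    lengths = sorted(set(profile.tumor) | set(profile.normal))
    t = np.array([profile.tumor.get(l, 0) for l in lengths], dtype=float)
    n = np.array([profile.normal.get(l, 0) for l in lengths], dtype=float)

    def expected(tv, nv):
        col = tv + nv
        total = col.sum()
        out = np.concatenate([tv.sum() * col / total, nv.sum() * col / total])
        return out.reshape(2, -1)

    while len(t) > 2:
        exp = expected(t, n)
        if exp.min() >= min_expected:
            break
        # merge the worse of the two tail bins into its inner neighbor
        left = exp[:, 0].min()
        right = exp[:, -1].min()
        if left <= right:
            t[1] += t[0]
            n[1] += n[0]
            t, n = t[1:], n[1:]
        else:
            t[-2] += t[-1]
            n[-2] += n[-1]
            t, n = t[:-1], n[:-1]
    return np.vstack([t, n])


def compare_locus(
    profile: MSLocusProfile,
    alpha: float = 0.05,
    method: str = "chi2",
) -> tuple[Optional[float], str]:
    """Compare tumor vs. normal repeat-length distributions at one locus.

    Returns ``(p_value, verdict)`` where the verdict is ``"MSI-H"`` when the
    distributions differ at level ``alpha``, ``"MSS"`` otherwise, and
    ``"not_evaluable"`` (with p-value None) when either histogram is below
    the minimum depth. ``method`` is ``"chi2"`` (default) or ``"ks"``.
    """
    if not profile.evaluable:
        return None, "not_evaluable"
    if method == "chi2":
        table = _merged_counts(profile)
        # drop all-zero bins (possible after merging degenerate input)
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            p = 1.0
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
    elif method == "ks":
        t_sample = np.repeat(list(profile.tumor.keys()), list(profile.tumor.values()))
        n_sample = np.repeat(list(profile.normal.keys()), list(profile.normal.values()))
        p = stats.ks_2samp(t_sample, n_sample).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    verdict = "MSI-H" if p < alpha else "MSS"
    return float(p), verdict


def classify_sample(
    verdicts: Mapping[str, str],
    threshold: int = MSI_H_LOCUS_THRESHOLD,
) -> MSISampleResult:
    """Aggregate per-locus verdicts into a sample-level MSI status.

    MSI-H iff the absolute number of unstable loci reaches ``threshold``
    (default 75); non-evaluable loci count toward neither side. When fewer
    than ``threshold`` loci are evaluable the MSI-H status is unreachable and
    the result carries a low-evaluability warning flag.
    """
    if not verdicts:
        raise ValueError("no loci assayed")
    unstable = sum(1 for v in verdicts.values() if v == "MSI-H")
    evaluable = sum(1 for v in verdicts.values() if v != "not_evaluable")
    status = "MSI-H" if unstable >= threshold else "MSI-stable"
    low = evaluable < threshold
    if low and status == "MSI-stable":
        warnings.warn(
            f"only {evaluable} evaluable loci; MSI-H (>= {threshold}) unreachable",
            stacklevel=2,
        )
    return MSISampleResult(
        per_locus=dict(verdicts),
        unstable_count=unstable,
        evaluable_count=evaluable,
        status=status,
        low_evaluability=low,
    )


def call_msi_sample(
    profiles: Sequence[MSLocusProfile],
    alpha: float = 0.05,
    method: str = "chi2",
    threshold: int = MSI_H_LOCUS_THRESHOLD,
) -> MSISampleResult:
    """End-to-end MSI classification for one tumor/normal pair."""
    verdicts = {}
    for profile in profiles:
        _, verdict = compare_locus(profile, alpha=alpha, method=method)
        verdicts[profile.locus_id] = verdict
    return classify_sample(verdicts, threshold=threshold)
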