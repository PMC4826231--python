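"""Copy-number / allelic-imbalance segmentation.

Chromosomes are partitioned by a likelihood-driven variant of circular
binary segmentation: top-down recursive bisection where each region is
scanned exhaustively for the single breakpoint that maximizes the gain in
joint log-likelihood.  The per-locus model is

* Gaussian on the log2 tumor/normal coverage ratio, with a per-chromosome
  noise scale estimated robustly from successive differences (median
  absolute deviation), and
* binomial on variant reads at germline-heterozygous loci, with a
  segment-level allele fraction.

A split is accepted only when the log-likelihood ratio exceeds ``llr_min``
(default 90, natural-log units) AND the two resulting segments differ in
copy-number ratio by more than ``ratio_min`` (default 1.1, orientation-free)
or in minor-allele frequency by more than ``maf_diff_min`` (default 0.05).

Segment copy numbers are placed on an absolute scale per sample by a single
multiplicative factor chosen so the segment-size-weighted 20th percentile of
copy number across allelically balanced segments is 2 (diploid anchor).
Allelic imbalance is a two-sided exact binomial test of the pooled variant /
total reads against 0.5 (threshold p < 0.001); this assumes the variant
allele is consistently phased within a segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

LABELS = ("neutral", "loss", "gain", "cn_loh", "imbalance_only")


@dataclass(frozen=True)
class SegmentationParams:
    llr_min: float = 90.0          # natural-log LLR gate for a split
    ratio_min: float = 1.1         # copy-number ratio gate, orientation-free
    maf_diff_min: float = 0.05     # minor-allele-frequency difference gate
    ai_p_threshold: float = 0.001  # allelic-imbalance call threshold
    min_width: int = 10            # min loci per segment
    delta: float = 0.3             # copies away from 2 for loss/gain labels
    loh_maf_max: float = 0.05      # MAF bound for (copy-neutral) LOH
    arm_fraction: float = 0.8      # arm label when >= this fraction agrees


@dataclass
class LocusObservation:
    """One genomic locus with tumor/normal coverage and optional BAF."""

    chrom: str
    pos: int
    tumor_coverage: float
    normal_coverage: float
    het: bool = False
    alt_reads: int = 0
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.tumor_coverage < 0 or self.normal_coverage < 0:
            raise ValueError("coverages must be >= 0")
        if self.het and self.total_reads <= 0:
            raise ValueError("het locus needs total_reads > 0")
        if self.alt_reads > self.total_reads:
            raise ValueError("alt_reads > total_reads")

    @property
    def baf(self) -> Optional[float]:
        if not self.het:
            return None
        return self.alt_reads / self.total_reads


@dataclass
class GenomicSegment:
    chrom: str
    start: int
    end: int
    n_loci: int
    copy_number: float
    minor_allele_frequency: float
    allelic_imbalance_p: Optional[float] = None
    label: str = "neutral"
    n_het: int = 0
    pooled_alt: int = 0
    pooled_total: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if not -1e-9 <= self.minor_allele_frequency <= 0.5 + 1e-9:
            raise ValueError("minor allele frequency must lie in [0, 0.5]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# --- likelihood machinery ---------------------------------------------------

class _Profile:
    """Prefix-sum sufficient statistics for O(1) segment log-likelihoods."""

    def __init__(self, loci: Sequence[LocusObservation]):
        eps = 0.5  # pseudo-count guards isolated zero-coverage loci
        tc = np.array([l.tumor_coverage for l in loci], float)
        nc = np.array([l.normal_coverage for l in loci], float)
        if nc.sum() == 0:
            raise ValueError("all-zero normal coverage")
        self.r = np.log2((tc + eps) / (nc + eps))
        het = np.array([l.het for l in loci], bool)
        alt = np.array([l.alt_reads if l.het else 0 for l in loci], float)
        tot = np.array([l.total_reads if l.het else 0 for l in loci], float)
        self.n = len(loci)
        self.cs_r = np.concatenate([[0.0], np.cumsum(self.r)])
        self.cs_r2 = np.concatenate([[0.0], np.cumsum(self.r ** 2)])
        self.cs_alt = np.concatenate([[0.0], np.cumsum(alt)])
        self.cs_tot = np.concatenate([[0.0], np.cumsum(tot)])
        self.cs_het = np.concatenate([[0], np.cumsum(het.astype(int))])
        diffs = np.diff(self.r)
        mad = np.median(np.abs(diffs)) if diffs.size else 0.0
        self.sigma = max(1.4826 * mad / math.sqrt(2.0), 1e-3)

    def loglik(self, a: int, b: int) -> float:
        """Profile log-likelihood of loci [a, b) under a single segment
        (constant terms that cancel in any LLR are dropped)."""
        n = b - a
        sse = (self.cs_r2[b] - self.cs_r2[a]
               - (self.cs_r[b] - self.cs_r[a]) ** 2 / n)
        ll = -sse / (2.0 * self.sigma ** 2)
        tot = self.cs_tot[b] - self.cs_tot[a]
        if tot > 0:
            alt = self.cs_alt[b] - self.cs_alt[a]
            p = min(max(alt / tot, 1e-9), 1 - 1e-9)
            ll += alt * math.log(p) + (tot - alt) * math.log(1 - p)
        return ll

    def mean_ratio(self, a: int, b: int) -> float:
        return 2.0 ** ((self.cs_r[b] - self.cs_r[a]) / (b - a))

    def allele_fraction(self, a: int, b: int) -> Optional[float]:
        tot = self.cs_tot[b] - self.cs_tot[a]
        if tot == 0:
            return None
        return (self.cs_alt[b] - self.cs_alt[a]) / tot

    def maf(self, a: int, b: int) -> float:
        af = self.allele_fraction(a, b)
        if af is None:
            return 0.5
        return min(af, 1.0 - af)


def _best_split(profile: _Profile, a: int, b: int,
                min_width: int) -> tuple[Optional[int], float]:
    """Exhaustive single-breakpoint scan of [a, b); returns (index, LLR)."""
    base = profile.loglik(a, b)
    best_k, best_llr = None, -math.inf
    for k in range(a + min_width, b - min_width + 1):
        llr = profile.loglik(a, k) + profile.loglik(k, b) - base
        if llr > best_llr:
            best_k, best_llr = k, llr
    return best_k, best_llr


@dataclass(frozen=True)
class SplitRecord:
    """One accepted breakpoint with the evidence that admitted it."""

    locus_index: int
    llr: float
    copy_ratio: float
    maf_diff: float


def segment_chromosome(loci: Sequence[LocusObservation],
                       params: SegmentationParams = SegmentationParams(),
                       ) -> list[GenomicSegment]:
    """Segment one chromosome's ordered loci.

    Returns segments tiling the input; every accepted breakpoint cleared the
    LLR gate and the copy-ratio/MAF gates against its sibling segment.
    """
    segments, _ = segment_chromosome_with_trace(loci, params)
    return segments


def segment_chromosome_with_trace(loci: Sequence[LocusObservation],
                                  params: SegmentationParams = SegmentationParams(),
                                  ) -> tuple[list[GenomicSegment], list[SplitRecord]]:
    """As :func:`segment_chromosome`, also returning the accepted splits."""
    if not loci:
        raise ValueError("need at least one locus")
    chrom = loci[0].chrom
    pos = [l.pos for l in loci]
    if any(p2 < p1 for p1, p2 in zip(pos, pos[1:])):
        raise ValueError("loci must be sorted by position")
    if any(l.chrom != chrom for l in loci):
        raise ValueError("loci must belong to a single chromosome")
    profile = _Profile(loci)
    trace: list[SplitRecord] = []

    def recurse(a: int, b: int) -> None:
        if b - a < 2 * params.min_width:
            return
        k, llr = _best_split(profile, a, b, params.min_width)
        if k is None or llr <= params.llr_min:
            return
        c1, c2 = profile.mean_ratio(a, k), profile.mean_ratio(k, b)
        ratio = max(c1, c2) / max(min(c1, c2), 1e-9)
        maf_diff = abs(profile.maf(a, k) - profile.maf(k, b))
        if ratio <= params.ratio_min and maf_diff <= params.maf_diff_min:
            return
        trace.append(SplitRecord(locus_index=k, llr=llr,
                                 copy_ratio=ratio, maf_diff=maf_diff))
        recurse(a, k)
        recurse(k, b)

    recurse(0, profile.n)
    cuts = [0] + sorted(r.locus_index for r in trace) + [profile.n]
    segments = []
    for a, b in zip(cuts, cuts[1:]):
        seg_loci = loci[a:b]
        af = profile.allele_fraction(a, b)
        pooled_alt = int(profile.cs_alt[b] - profile.cs_alt[a])
        pooled_tot = int(profile.cs_tot[b] - profile.cs_tot[a])
        ai_p = (test_allelic_imbalance(pooled_alt, pooled_tot)
                if pooled_tot > 0 else None)
        segments.append(GenomicSegment(
            chrom=chrom, start=seg_loci[0].pos, end=seg_loci[-1].pos,
            n_loci=b - a,
            copy_number=2.0 * profile.mean_ratio(a, b),
            minor_allele_frequency=min(af, 1 - af) if af is not None else 0.5,
            allelic_imbalance_p=ai_p,
            n_het=int(profile.cs_het[b] - profile.cs_het[a]),
            pooled_alt=pooled_alt, pooled_total=pooled_tot,
        ))
    return segments, trace


def test_allelic_imbalance(pooled_alt: int, pooled_total: int) -> float:
    """Two-sided exact binomial p-value for pooled BAF deviating from 0.5."""
    if pooled_total < 1:
        raise ValueError("need at least one read at a het locus")
    return float(binomtest(pooled_alt, pooled_total, 0.5,
                           alternative="two-sided").pvalue)


def _is_balanced(seg: GenomicSegment, params: SegmentationParams) -> bool:
    return (seg.allelic_imbalance_p is not None
            and seg.allelic_imbalance_p >= params.ai_p_threshold)


def weighted_percentile_20(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose weighted CDF reaches 20%."""
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cdf = np.cumsum(weights) / weights.sum()
    idx = int(np.searchsorted(cdf, 0.2, side="left"))
    return float(values[min(idx, len(values) - 1)])


def normalize_copy_number(segments: Sequence[GenomicSegment],
                          params: SegmentationParams = SegmentationParams(),
                          manual_factor: Optional[float] = None,
                          ) -> tuple[list[GenomicSegment], float]:
    """Scale one sample's segments onto the diploid-anchored scale.

    A single multiplicative factor is chosen so that the size-weighted 20th
    percentile of copy number over allelically balanced segments equals 2.
    With no balanced segment (e.g. a near-tetraploid genome), a
    ``manual_factor`` must be supplied.
    """
    if manual_factor is None:
        balanced = [s for s in segments if _is_balanced(s, params)]
        if not balanced:
            raise ValueError(
                "no allelically balanced segment to anchor normalization; "
                "specify the ploidy scaling factor manually")
        values = np.array([s.copy_number for s in balanced], float)
        weights = np.array([s.length for s in balanced], float)
        factor = 2.0 / weighted_percentile_20(values, weights)
    else:
        factor = manual_factor
    out = []
    for s in segments:
        out.append(GenomicSegment(
            chrom=s.chrom, start=s.start, end=s.end, n_loci=s.n_loci,
            copy_number=s.copy_number * factor,
            minor_allele_frequency=s.minor_allele_frequency,
            allelic_imbalance_p=s.allelic_imbalance_p, label=s.label,
            n_het=s.n_het, pooled_alt=s.pooled_alt,
            pooled_total=s.pooled_total))
    return out, factor


def call_aberrations(segments: Sequence[GenomicSegment],
                     params: SegmentationParams = SegmentationParams(),
                     arms: Optional[dict[str, list[tuple[str, int, int]]]] = None,
                     ) -> tuple[list[GenomicSegment], pd.DataFrame]:
    """Label normalized segments and summarize per chromosome arm.

    Labels: ``loss`` (copy < 2-delta), ``gain`` (copy > 2+delta), ``cn_loh``
    (copy within delta of 2, imbalanced, MAF < LOH bound), ``imbalance_only``
    (near-diploid, imbalanced, MAF above the LOH bound), else ``neutral``.
    An arm receives a label when segments sharing that (non-neutral) label
    cover >= 80% of its length.  ``arms`` maps chrom -> [(arm_name, start,
    end)]; by default each chromosome is one arm.
    """
    labeled = []
    for s in segments:
        imbalanced = (s.allelic_imbalance_p is not None
                      and s.allelic_imbalance_p < params.ai_p_threshold)
        if s.copy_number < 2 - params.delta:
            label = "loss"
        elif s.copy_number > 2 + params.delta:
            label = "gain"
        elif imbalanced and s.minor_allele_frequency < params.loh_maf_max:
            label = "cn_loh"
        elif imbalanced:
            label = "imbalance_only"
        else:
            label = "neutral"
        labeled.append(GenomicSegment(
            chrom=s.chrom, start=s.start, end=s.end, n_loci=s.n_loci,
            copy_number=s.copy_number,
            minor_allele_frequency=s.minor_allele_frequency,
            allelic_imbalance_p=s.allelic_imbalance_p, label=label,
            n_het=s.n_het, pooled_alt=s.pooled_alt,
            pooled_total=s.pooled_total))
    rows = []
    by_chrom: dict[str, list[GenomicSegment]] = {}
    for s in labeled:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        chrom_arms = (arms or {}).get(
            chrom, [("", min(s.start for s in segs), max(s.end for s in segs))])
        for arm_name, a_start, a_end in chrom_arms:
            arm_len = a_end - a_start + 1
            cover: dict[str, int] = {}
            for s in segs:
                ov = min(s.end, a_end) - max(s.start, a_start) + 1
                if ov > 0:
                    cover[s.label] = cover.get(s.label, 0) + ov
            call = "none"
            for label, covered in sorted(cover.items()):
                if label != "neutral" and covered / arm_len >= params.arm_fraction:
                    call = label
            rows.append({"chrom": chrom, "arm": arm_name, "arm_call": call,
                         **{f"frac_{lab}": cover.get(lab, 0) / arm_len
                            for lab in LABELS}})
    summary = pd.DataFrame(rows)
    return labeled, summary


def segments_to_frame(segments: Sequence[GenomicSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end, "n_loci": s.n_loci,
        "copy_number": s.copy_number,
        "minor_allele_frequency": s.minor_allele_frequency,
        "allelic_imbalance_p": s.allelic_imbalance_p,
        "label": s.label, "n_het": s.n_het,
    } for s in segments])


def read_loci_tsv(path) -> list[LocusObservation]:
    """Read a loci table: chrom, pos, tumor_cov, normal_cov, alt_reads,
    total_reads, het (0/1)."""
    df = pd.read_csv(path, sep="\t")
    return [LocusObservation(
        chrom=str(r.chrom), pos=int(r.pos),
        tumor_coverage=float(r.tumor_cov), normal_coverage=float(r.normal_cov),
        het=bool(r.het), alt_reads=int(r.alt_reads),
        total_reads=int(r.total_reads)) for r in df.itertuples()]
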