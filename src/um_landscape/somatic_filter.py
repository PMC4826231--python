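"""Stringent somatic SNV/indel filtering for tumor/normal pairs.

A deterministic rule engine: each candidate call is checked against every
rule (no short-circuiting) so the rejection reasons are complete.  The rules
encode a conservative post-calling filter for paired tumor/normal data:

``dbsnp_not_cosmic``
    known population variant (dbSNP) not rescued by a somatic database
    (COSMIC) entry;
``normal_contamination``
    any variant-supporting read in the matched normal (the normal must be
    strictly wild-type);
``normal_low_depth``
    fewer than 8 reference reads in the normal;
``low_pl``
    Phred-scaled genotype likelihood of the wild-type genotype in the tumor
    below 60 (weak evidence against wild-type);
``low_alt_support``
    fewer than 4 variant reads in the tumor;
``low_clr``
    constrained log-likelihood ratio (somatic vs non-somatic genotype
    configurations) below 40;
``quality_warning``
    caller warnings: duplication region, tri-allelic site, variant only at
    read tails;
``repeat_context``
    site lies in a trinucleotide expansion/reduction region (short-motif
    repeat), a mechanized proxy for hand-curation of likely mismapping.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .intervals import IntervalMask

#: Quality-warning codes accepted on a candidate.
QUALITY_WARNINGS = frozenset({"duplication_region", "tri_allelic", "tail_of_reads"})

#: All rejection reason codes, in evaluation order.
REASON_CODES = (
    "dbsnp_not_cosmic",
    "normal_contamination",
    "normal_low_depth",
    "low_pl",
    "low_alt_support",
    "low_clr",
    "quality_warning",
    "repeat_context",
)


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the somatic rule engine (defaults are the study's)."""

    normal_alt_max: int = 0
    normal_ref_min: int = 8
    pl_min: float = 60.0
    tumor_alt_min: int = 4
    clr_min: float = 40.0


@dataclass
class SomaticCandidate:
    """One tumor/normal variant call, the unit filtered by the rule engine."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int
    pl_wildtype: float
    clr: float
    in_dbsnp: bool = False
    in_cosmic: bool = False
    quality_warnings: frozenset = frozenset()
    repeat_context: bool = False

    def validate(self) -> None:
        for name in ("tumor_ref_reads", "tumor_alt_reads",
                     "normal_ref_reads", "normal_alt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pl_wildtype < 0:
            raise ValueError(f"pl_wildtype must be >= 0, got {self.pl_wildtype}")
        unknown = set(self.quality_warnings) - QUALITY_WARNINGS
        if unknown:
            raise ValueError(f"unknown quality warnings: {sorted(unknown)}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class FilterDecision:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


def classify_somatic(candidate: SomaticCandidate,
                     thresholds: FilterThresholds = FilterThresholds()
                     ) -> FilterDecision:
    """Apply every filtering rule to one candidate.

    All rules are evaluated so ``reasons`` lists every violated rule, in the
    canonical order of :data:`REASON_CODES`.  Indels and SNVs share the same
    rule set.
    """
    candidate.validate()
    reasons: list[str] = []
    if candidate.in_dbsnp and not candidate.in_cosmic:
        reasons.append("dbsnp_not_cosmic")
    if candidate.normal_alt_reads > thresholds.normal_alt_max:
        reasons.append("normal_contamination")
    if candidate.normal_ref_reads < thresholds.normal_ref_min:
        reasons.append("normal_low_depth")
    if candidate.pl_wildtype < thresholds.pl_min:
        reasons.append("low_pl")
    if candidate.tumor_alt_reads < thresholds.tumor_alt_min:
        reasons.append("low_alt_support")
    if candidate.clr < thresholds.clr_min:
        reasons.append("low_clr")
    if candidate.quality_warnings:
        reasons.append("quality_warning")
    if candidate.repeat_context:
        reasons.append("repeat_context")
    return FilterDecision(passed=not reasons, reasons=reasons)


def detect_repeat_context(sequence: str, offset: int, *, window: int = 20,
                          max_motif: int = 3, min_repeats: int = 4) -> bool:
    """Flag a site inside a short-motif repeat run.

    A site is flagged when a 1-3 bp motif repeats at least ``min_repeats``
    consecutive times within ``window`` bp on either side of ``offset``
    (0-based index into ``sequence``).
    """
    lo = max(0, offset - window)
    hi = min(len(sequence), offset + window + 1)
    region = sequence[lo:hi].upper()
    for motif_len in range(1, max_motif + 1):
        run_len = motif_len * min_repeats
        for start in range(0, len(region) - run_len + 1):
            motif = region[start:start + motif_len]
            if "N" in motif:
                continue
            if region[start:start + run_len] == motif * min_repeats:
                return True
    return False


def mutation_rate_per_mb(n_mutations: int, covered_mb: float) -> float:
    """Mutations per megabase over the callable footprint."""
    if covered_mb <= 0:
        raise ValueError(f"covered_mb must be > 0, got {covered_mb}")
    return n_mutations / covered_mb


# --- VCF boundary -----------------------------------------------------------

def _sample_ad(record: pysam.VariantRecord, sample: str) -> tuple[int, int]:
    fmt = record.samples[sample]
    ad = fmt.get("AD")
    if ad is None or ad[0] is None:
        return 0, 0
    ref_reads = int(ad[0])
    alt_reads = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
    return ref_reads, alt_reads


def candidate_from_record(record: pysam.VariantRecord, tumor: str, normal: str,
                          dbsnp: Optional[IntervalMask] = None,
                          cosmic: Optional[IntervalMask] = None,
                          repeats: Optional[IntervalMask] = None,
                          ) -> SomaticCandidate:
    """Build a :class:`SomaticCandidate` from a VCF record.

    Per-sample read support comes from ``FORMAT/AD``; the tumor wild-type
    genotype likelihood from the first entry of ``FORMAT/PL``; the CLR score
    from ``INFO/CLR``.  dbSNP/COSMIC/repeat membership comes from the interval
    masks when given, otherwise from the ``DB`` / ``COSMIC`` / ``REPEAT``
    INFO flags.  Quality warnings are read from the ``WARN`` INFO key.
    """
    t_ref, t_alt = _sample_ad(record, tumor)
    n_ref, n_alt = _sample_ad(record, normal)
    pl = record.samples[tumor].get("PL")
    pl_wt = float(pl[0]) if pl and pl[0] is not None else 0.0
    clr = float(record.info.get("CLR", 0.0))
    warn = record.info.get("WARN")
    if warn is None:
        warnings: frozenset = frozenset()
    elif isinstance(warn, (tuple, list)):
        warnings = frozenset(warn)
    else:
        warnings = frozenset([warn])
    chrom, pos = record.chrom, record.pos
    in_dbsnp = dbsnp.contains(chrom, pos) if dbsnp is not None \
        else bool(record.info.get("DB", False))
    in_cosmic = cosmic.contains(chrom, pos) if cosmic is not None \
        else bool(record.info.get("COSMIC", False))
    in_repeat = repeats.contains(chrom, pos) if repeats is not None \
        else bool(record.info.get("REPEAT", False))
    return SomaticCandidate(
        chrom=chrom, pos=pos, ref=record.ref, alt=record.alts[0],
        tumor_ref_reads=t_ref, tumor_alt_reads=t_alt,
        normal_ref_reads=n_ref, normal_alt_reads=n_alt,
        pl_wildtype=pl_wt, clr=clr,
        in_dbsnp=in_dbsnp, in_cosmic=in_cosmic,
        quality_warnings=warnings, repeat_context=in_repeat,
    )


def filter_vcf(vcf_path: str | Path, tumor: str, normal: str,
               dbsnp: Optional[IntervalMask] = None,
               cosmic: Optional[IntervalMask] = None,
               repeats: Optional[IntervalMask] = None,
               thresholds: FilterThresholds = FilterThresholds(),
               passed_out: Optional[str | Path] = None,
               ) -> tuple[list[SomaticCandidate], pd.DataFrame]:
    """Filter a paired tumor/normal VCF.

    Returns the passing candidates and a rejection table (chrom, pos, ref,
    alt, reasons semicolon-joined).  Every parseable record lands in exactly
    one of the two.  Optionally writes the passing records to ``passed_out``
    as VCF.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    for name in (tumor, normal):
        if name not in samples:
            raise KeyError(f"sample column {name!r} not in VCF (has {samples})")
    writer = None
    if passed_out is not None:
        writer = pysam.VariantFile(str(passed_out), "w", header=vcf.header)
    passed: list[SomaticCandidate] = []
    rejected_rows: list[dict] = []
    tally: collections.Counter = collections.Counter()
    n_skipped = 0
    for record in vcf:
        try:
            cand = candidate_from_record(record, tumor, normal,
                                         dbsnp, cosmic, repeats)
            decision = classify_somatic(cand, thresholds)
        except (ValueError, KeyError, TypeError):
            n_skipped += 1
            continue
        if decision.passed:
            passed.append(cand)
            if writer is not None:
                writer.write(record)
        else:
            tally.update(decision.reasons)
            rejected_rows.append({
                "chrom": cand.chrom, "pos": cand.pos,
                "ref": cand.ref, "alt": cand.alt,
                "reasons": ";".join(decision.reasons),
            })
    vcf.close()
    if writer is not None:
        writer.close()
    rejection = pd.DataFrame(rejected_rows,
                             columns=["chrom", "pos", "ref", "alt", "reasons"])
    rejection.attrs["reason_tally"] = dict(tally)
    rejection.attrs["n_skipped"] = n_skipped
    return passed, rejection


def filter_candidates(candidates: Iterable[SomaticCandidate],
                      thresholds: FilterThresholds = FilterThresholds(),
                      ) -> tuple[list[SomaticCandidate], pd.DataFrame]:
    """In-memory counterpart of :func:`filter_vcf` for candidate lists."""
    passed: list[SomaticCandidate] = []
    rejected_rows: list[dict] = []
    for cand in candidates:
        decision = classify_somatic(cand, thresholds)
        if decision.passed:
            passed.append(cand)
        else:
            rejected_rows.append({
                "chrom": cand.chrom, "pos": cand.pos,
                "ref": cand.ref, "alt": cand.alt,
                "reasons": ";".join(decision.reasons),
            })
    rejection = pd.DataFrame(rejected_rows,
                             columns=["chrom", "pos", "ref", "alt", "reasons"])
    return passed, rejection
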