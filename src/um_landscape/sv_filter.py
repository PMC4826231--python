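"""Structural-variant breakpoint filtering and classification.

Candidate breakpoint pairs (junctions from a discordant-pair/clipped-read
detector) are filtered by evidence rules; survivors are classified by
chromosome and breakend orientation and annotated for gene-level
consequences (truncation, in-frame/out-of-frame fusion, intronic deletion).

Rejection reason codes:

``min_junction_reads``     fewer than 3 junction-spanning reads
``high_mismatches``        mean mismatches across junction reads > 2
``extreme_coverage``       coverage > 1000x at either end in tumor or normal
``low_normal_coverage``    normal coverage < 2x at either end
``segdup_overlap``         either end inside a segmental-duplication region
``flank_similarity``       the 20 bp flanks of the two ends are >= 90% similar
``multi_sample``           another sample carries a matching breakpoint
``long_insertion``         more than 3 bp inserted at the junction
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .intervals import IntervalMask

SV_REASON_CODES = (
    "min_junction_reads",
    "high_mismatches",
    "extreme_coverage",
    "low_normal_coverage",
    "segdup_overlap",
    "flank_similarity",
    "multi_sample",
    "long_insertion",
)

SV_CLASSES = ("deletion", "inversion", "tandem_duplication", "interchromosomal")

GENE_EFFECTS = ("truncation", "in_frame_fusion", "out_of_frame_fusion",
                "intronic_deletion", "intergenic")


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    orientation: str  # '+' retains the left (lower-coordinate) side

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got "
                             f"{self.orientation!r}")
        if self.pos < 1:
            raise ValueError("breakend position must be >= 1")


@dataclass
class BreakpointPair:
    """Candidate SV junction with its filtering evidence."""

    end1: Breakend
    end2: Breakend
    junction_reads: int
    mean_junction_mismatches: float
    tumor_coverage_end1: float
    tumor_coverage_end2: float
    normal_coverage_end1: float
    normal_coverage_end2: float
    inserted_bases: str = ""
    flank_similarity: float = 0.0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")
        if not 0.0 <= self.flank_similarity <= 1.0:
            raise ValueError("flank_similarity must lie in [0, 1]")
        if self.mean_junction_mismatches < 0:
            raise ValueError("mean_junction_mismatches must be >= 0")


@dataclass(frozen=True)
class SvThresholds:
    min_junction_reads: int = 3
    max_mean_mismatches: float = 2.0
    max_coverage: float = 1000.0
    min_normal_coverage: float = 2.0
    max_flank_similarity: float = 0.90  # inclusive rejection bound
    max_insertion: int = 3
    multi_sample_window: int = 100


@dataclass
class SvCall:
    breakpoint: BreakpointPair
    sv_class: str
    gene_effect: Optional[str] = None
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv class {self.sv_class!r}")
        inter = self.breakpoint.end1.chrom != self.breakpoint.end2.chrom
        if inter != (self.sv_class == "interchromosomal"):
            raise ValueError("interchromosomal class must match chromosomes")


def flank_similarity_from_sequences(flank1: str, flank2: str) -> float:
    """Similarity of the two 20 bp breakend flanks: (20 - edit distance)/20."""
    n = max(len(flank1), len(flank2), 1)
    # classic Levenshtein; flanks are 20 bp so quadratic cost is negligible
    prev = list(range(len(flank2) + 1))
    for i, a in enumerate(flank1.upper(), 1):
        cur = [i]
        for j, b in enumerate(flank2.upper(), 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (a != b)))
        prev = cur
    return max(0.0, (n - prev[-1]) / n)


def _ends_match(a: BreakpointPair, b: BreakpointPair, window: int) -> bool:
    def close(x: Breakend, y: Breakend) -> bool:
        return (x.chrom == y.chrom and abs(x.pos - y.pos) <= window
                and x.orientation == y.orientation)
    return ((close(a.end1, b.end1) and close(a.end2, b.end2))
            or (close(a.end1, b.end2) and close(a.end2, b.end1)))


def breakpoint_reasons(bp: BreakpointPair,
                       segdup: Optional[IntervalMask],
                       cohort: Sequence[BreakpointPair],
                       thresholds: SvThresholds = SvThresholds()) -> list[str]:
    """Evaluate every filter rule for one candidate (no short-circuit)."""
    reasons = []
    if bp.junction_reads < thresholds.min_junction_reads:
        reasons.append("min_junction_reads")
    if bp.mean_junction_mismatches > thresholds.max_mean_mismatches:
        reasons.append("high_mismatches")
    if max(bp.tumor_coverage_end1, bp.tumor_coverage_end2,
           bp.normal_coverage_end1, bp.normal_coverage_end2) > thresholds.max_coverage:
        reasons.append("extreme_coverage")
    if min(bp.normal_coverage_end1, bp.normal_coverage_end2) < thresholds.min_normal_coverage:
        reasons.append("low_normal_coverage")
    if segdup is not None and (segdup.contains(bp.end1.chrom, bp.end1.pos)
                               or segdup.contains(bp.end2.chrom, bp.end2.pos)):
        reasons.append("segdup_overlap")
    if bp.flank_similarity >= thresholds.max_flank_similarity:
        reasons.append("flank_similarity")
    if any(other.sample_id != bp.sample_id
           and _ends_match(bp, other, thresholds.multi_sample_window)
           for other in cohort):
        reasons.append("multi_sample")
    if len(bp.inserted_bases) > thresholds.max_insertion:
        reasons.append("long_insertion")
    return reasons


def filter_breakpoints(candidates: Sequence[BreakpointPair],
                       segdup: Optional[IntervalMask] = None,
                       cohort: Optional[Sequence[BreakpointPair]] = None,
                       thresholds: SvThresholds = SvThresholds(),
                       ) -> tuple[list[BreakpointPair], pd.DataFrame]:
    """Apply every rule to every candidate.

    The multi-sample rule is evaluated against the full ``cohort`` snapshot
    (defaulting to ``candidates`` itself), which makes re-running on the
    survivors idempotent.
    """
    if cohort is None:
        cohort = candidates
    passed: list[BreakpointPair] = []
    rejected_rows = []
    tally: collections.Counter = collections.Counter()
    for bp in candidates:
        reasons = breakpoint_reasons(bp, segdup, cohort, thresholds)
        if reasons:
            tally.update(reasons)
            rejected_rows.append({
                "sample": bp.sample_id,
                "chrom1": bp.end1.chrom, "pos1": bp.end1.pos,
                "chrom2": bp.end2.chrom, "pos2": bp.end2.pos,
                "reasons": ";".join(reasons)})
        else:
            passed.append(bp)
    rejection = pd.DataFrame(
        rejected_rows,
        columns=["sample", "chrom1", "pos1", "chrom2", "pos2", "reasons"])
    rejection.attrs["reason_tally"] = dict(tally)
    return passed, rejection


def classify_sv(bp: BreakpointPair) -> str:
    """Class from chromosomes and breakend orientations.

    Interchromosomal when the ends sit on different chromosomes; otherwise
    (with ends ordered by position) (+,-) is deletion-type, (-,+)
    tandem-duplication-type and (+,+)/(-,-) inversion-type.
    """
    if bp.end1.chrom != bp.end2.chrom:
        return "interchromosomal"
    e1, e2 = bp.end1, bp.end2
    # '+' sorts first at equal positions so zero-length junctions classify
    # deterministically regardless of end order
    if (e1.pos, e1.orientation) > (e2.pos, e2.orientation):
        e1, e2 = e2, e1
    pair = (e1.orientation, e2.orientation)
    if pair == ("+", "-"):
        return "deletion"
    if pair == ("-", "+"):
        return "tandem_duplication"
    return "inversion"


# --- gene-effect annotation -------------------------------------------------

@dataclass
class Transcript:
    """Minimal gene model: exons plus a coding span, 1-based inclusive."""

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]          # sorted, non-overlapping
    cds_start: Optional[int] = None       # genomic bounds of the CDS
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError(f"exons overlap in {self.gene}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def intron_of(self, pos: int) -> Optional[int]:
        """Index of the intron containing pos, or None."""
        for i, ((_, e1), (s2, _)) in enumerate(zip(self.exons, self.exons[1:])):
            if e1 < pos < s2:
                return i
        return None

    def cds_offset(self, pos: int) -> int:
        """Coding bases of the transcript strictly 5' of ``pos`` (on the
        coding strand)."""
        if not self.coding:
            raise ValueError(f"{self.gene} has no CDS annotation")
        total = 0
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs > ce:
                continue
            if self.strand == "+":
                if ce < pos:
                    total += ce - cs + 1
                elif cs < pos:
                    total += pos - cs
            else:
                if cs > pos:
                    total += ce - cs + 1
                elif ce > pos:
                    total += ce - pos
        return total

    def five_prime_retained(self, orientation: str) -> bool:
        """Does a breakend with this orientation retain the 5' part of the
        gene?  '+' retains the lower-coordinate side."""
        return (orientation == "+") == (self.strand == "+")


def _genes_at(transcripts: Sequence[Transcript], chrom: str,
              pos: int) -> list[Transcript]:
    return [t for t in transcripts if t.chrom == chrom and t.contains(pos)]


def annotate_gene_effects(calls: Sequence[SvCall],
                          gene_models: Sequence[Transcript]) -> list[SvCall]:
    """Attach gene-level consequences to classified SV calls.

    A junction fusing the 5' coding part of one gene to the 3' coding part
    of another is a fusion; it is in frame when the coding phases at the two
    junction points agree.  A deletion confined to a single intron is an
    intronic deletion; any other genic hit is a truncation; otherwise the
    call is intergenic.  Transcripts without frame (CDS) annotation cannot
    support a fusion call and yield truncations.
    """
    out = []
    for call in calls:
        bp = call.breakpoint
        hits1 = _genes_at(gene_models, bp.end1.chrom, bp.end1.pos)
        hits2 = _genes_at(gene_models, bp.end2.chrom, bp.end2.pos)
        effect = "intergenic"
        genes = sorted({t.gene for t in hits1} | {t.gene for t in hits2})
        if hits1 and hits2:
            same = [t for t in hits1 if any(u.gene == t.gene for u in hits2)]
            fused = _fusion_effect(bp, hits1, hits2)
            if (call.sv_class == "deletion" and same
                    and _same_intron(same[0], bp)):
                effect = "intronic_deletion"
            elif fused is not None:
                effect = fused
            else:
                effect = "truncation"
        elif hits1 or hits2:
            effect = "truncation"
        out.append(SvCall(breakpoint=bp, sv_class=call.sv_class,
                          gene_effect=effect, genes=genes))
    return out


def _same_intron(t: Transcript, bp: BreakpointPair) -> bool:
    i1 = t.intron_of(bp.end1.pos)
    i2 = t.intron_of(bp.end2.pos)
    return i1 is not None and i1 == i2


def _fusion_effect(bp: BreakpointPair, hits1: Sequence[Transcript],
                   hits2: Sequence[Transcript]) -> Optional[str]:
    for t1 in hits1:
        for t2 in hits2:
            if t1.gene == t2.gene:
                continue
            if not (t1.coding and t2.coding):
                continue
            r1 = t1.five_prime_retained(bp.end1.orientation)
            r2 = t2.five_prime_retained(bp.end2.orientation)
            if r1 == r2:  # need one 5' donor and one 3' acceptor
                continue
            phase1 = t1.cds_offset(bp.end1.pos) % 3
            phase2 = t2.cds_offset(bp.end2.pos) % 3
            return "in_frame_fusion" if phase1 == phase2 \
                else "out_of_frame_fusion"
    return None


def recurrent_sv_genes(calls: Sequence[SvCall]) -> pd.DataFrame:
    """Genes affected by two or more distinct SV events, with counts."""
    counter: collections.Counter = collections.Counter()
    for call in calls:
        for gene in set(call.genes):
            counter[gene] += 1
    rows = [{"gene": g, "n_events": n}
            for g, n in counter.items() if n >= 2]
    rows.sort(key=lambda r: (-r["n_events"], r["gene"]))
    return pd.DataFrame(rows, columns=["gene", "n_events"])


# --- BEDPE boundary (0-based half-open on disk) ------------------------------

def read_bedpe(path) -> list[BreakpointPair]:
    """Read candidates from an extended BEDPE-like TSV.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 junction_reads mean_mismatches tcov1 tcov2 ncov1 ncov2
    inserted_bases flank_similarity sample.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(BreakpointPair(
            end1=Breakend(str(r.chrom1), int(r.start1) + 1, str(r.strand1)),
            end2=Breakend(str(r.chrom2), int(r.start2) + 1, str(r.strand2)),
            junction_reads=int(r.junction_reads),
            mean_junction_mismatches=float(r.mean_mismatches),
            tumor_coverage_end1=float(r.tcov1),
            tumor_coverage_end2=float(r.tcov2),
            normal_coverage_end1=float(r.ncov1),
            normal_coverage_end2=float(r.ncov2),
            inserted_bases="" if pd.isna(r.inserted_bases) else str(r.inserted_bases),
            flank_similarity=float(r.flank_similarity),
            sample_id=str(r.sample)))
    return out


def write_bedpe(pairs: Sequence[BreakpointPair], path) -> None:
    rows = []
    for bp in pairs:
        rows.append({
            "chrom1": bp.end1.chrom, "start1": bp.end1.pos - 1,
            "end1": bp.end1.pos, "chrom2": bp.end2.chrom,
            "start2": bp.end2.pos - 1, "end2": bp.end2.pos,
            "name": ".", "score": bp.junction_reads,
            "strand1": bp.end1.orientation, "strand2": bp.end2.orientation,
            "junction_reads": bp.junction_reads,
            "mean_mismatches": bp.mean_junction_mismatches,
            "tcov1": bp.tumor_coverage_end1, "tcov2": bp.tumor_coverage_end2,
            "ncov1": bp.normal_coverage_end1, "ncov2": bp.normal_coverage_end2,
            "inserted_bases": bp.inserted_bases,
            "flank_similarity": bp.flank_similarity,
            "sample": bp.sample_id})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
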