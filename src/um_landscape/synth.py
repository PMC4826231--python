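"""Seeded synthetic-data generators.

Every generator is a pure function of its parameters and a seed, producing
inputs with the statistical structure the corresponding analysis stage
assumes: mutation catalogues drawn from known signature mixtures, variant
read counts on a duplicated arm under stated purity and copy number,
coverage/BAF profiles with CNV and LOH blocks, SV candidate lists with
planted artifact classes, and driver tables with optional pathway-level
exclusivity.  Defaults match the study conditions the package targets
(WGS-like depth around 60x, tumor content 0.8, arm copy number 3, mutation
burdens of a few hundred per genome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .driver_analysis import DRIVER_GENES, DriverTable
from .segmentation import LocusObservation
from .signature_fit import BASES, CONTEXT_LABELS, MutationCatalogue, SignatureMatrix
from .somatic_filter import SomaticCandidate
from .sv_filter import Breakend, BreakpointPair
from .timing import TimingModel, TimingObservation

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# --- signatures -------------------------------------------------------------

def synthetic_signature_matrix(k: int = 5, seed: int = 2015,
                               concentration: float = 0.3) -> SignatureMatrix:
    """A K-column synthetic signature matrix with distinct sparse profiles.

    Columns are Dirichlet draws sharpened so pairwise cosine similarity is
    low; deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 96, size=k).T
    return SignatureMatrix(names=[f"SynthSig{i + 1}" for i in range(k)],
                           probs=probs)


def simulate_signature_catalogue(signatures: SignatureMatrix,
                                 exposures: Sequence[float],
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None,
                                 sample_id: str = "synthetic",
                                 ) -> MutationCatalogue:
    """Poisson catalogue with bin means (P @ E_true)."""
    exposures = np.asarray(exposures, float)
    if (exposures < 0).any():
        raise ValueError("exposures must be non-negative")
    if exposures.shape != (signatures.k,):
        raise ValueError("exposure length must equal number of signatures")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean = signatures.probs @ exposures
    counts = rng.poisson(mean).astype(float)
    return MutationCatalogue(sample_id=sample_id, counts=counts)


def random_genome(length: int = 10_000, seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  chrom: str = "chrS") -> dict[str, str]:
    """Uniform-composition synthetic contig, as {chrom: sequence}."""
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), size=length))
    return {chrom: seq}


def snvs_for_catalogue(genome: dict[str, str], catalogue: MutationCatalogue,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> list[tuple[str, int, str, str]]:
    """Realize a catalogue as concrete SNVs on a synthetic genome.

    For each non-zero bin, positions whose trinucleotide context matches
    (on either strand) are sampled with replacement; raises if the genome
    lacks a needed context.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    # index genome positions by pyrimidine-centered context
    by_context: dict[str, list[tuple[str, int, bool]]] = {}
    for chrom, seq in genome.items():
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1:i + 2]
            if tri[1] in ("C", "T"):
                key = tri
                flipped = False
            else:
                key = "".join(COMPLEMENT[b] for b in reversed(tri))
                flipped = True
            by_context.setdefault(key, []).append((chrom, i + 1, flipped))
    snvs = []
    for bin_idx, label in enumerate(CONTEXT_LABELS):
        n = int(catalogue.counts[bin_idx])
        if n == 0:
            continue
        f5, ref, _, alt, _, f3 = label[0], label[2], label[3], label[4], label[5], label[6]
        tri = f5 + ref + f3
        sites = by_context.get(tri)
        if not sites:
            raise ValueError(f"synthetic genome lacks context {tri}")
        for j in rng.integers(0, len(sites), size=n):
            chrom, pos, flipped = sites[int(j)]
            if flipped:
                snvs.append((chrom, pos, COMPLEMENT[ref], COMPLEMENT[alt]))
            else:
                snvs.append((chrom, pos, ref, alt))
    snvs.sort(key=lambda v: (v[0], v[1]))
    return snvs


# --- timing -----------------------------------------------------------------

def simulate_timing_observations(model: TimingModel, n: int,
                                 depth_mean: float = 60.0,
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None,
                                 ) -> list[TimingObservation]:
    """Draw variant/total read counts under the duplication-timing mixture.

    Each mutation predates the gain with probability rho; pre-gain mutations
    land on the duplicated haplotype with probability 1/2.  Depths are
    Poisson(depth_mean) truncated at 10.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p_single, p_dup = model.component_means()
    obs = []
    for _ in range(n):
        depth = max(10, int(rng.poisson(depth_mean)))
        pre = rng.random() < model.rho
        duplicated = pre and rng.random() < 0.5
        p = p_dup if duplicated else p_single
        v = int(rng.binomial(depth, p))
        obs.append(TimingObservation(variant_reads=v, total_reads=depth))
    return obs


# --- copy-number profiles ---------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """Planned truth for one block of a simulated chromosome profile."""

    n_loci: int
    copy_number: float        # absolute tumor copy number of the block
    maf: float                # minor-allele fraction in the tumor, [0, 0.5]

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")


def simulate_cn_profile(layout: Sequence[SegmentSpec],
                        purity: float = 0.8,
                        depth: float = 60.0,
                        het_fraction: float = 0.25,
                        locus_spacing: int = 1000,
                        chrom: str = "chrS",
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[list[LocusObservation], list[tuple[int, int]]]:
    """Coverage/BAF profile realizing a planned segment layout.

    Tumor coverage is Poisson around depth x (observed copy number)/2 where
    the observed copy number blends tumor and stromal genomes by ``purity``;
    normal coverage is Poisson(depth).  Het-locus variant reads are binomial
    around the purity-blended minor-allele fraction, with the variant allele
    phased onto the minor haplotype throughout a segment (the orientation
    the allelic-imbalance test assumes).  Returns the loci and the true
    (start, end) bounds of each block.
    """
    if not layout:
        raise ValueError("layout must be non-empty")
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    loci: list[LocusObservation] = []
    bounds = []
    pos = 1
    for spec in layout:
        start = pos
        cn_obs = purity * spec.copy_number + (1 - purity) * 2.0
        minor_copies = spec.maf * spec.copy_number
        af = (purity * minor_copies + (1 - purity) * 1.0) / cn_obs
        for _ in range(spec.n_loci):
            t_cov = rng.poisson(depth * cn_obs / 2.0)
            n_cov = rng.poisson(depth)
            het = rng.random() < het_fraction
            if het:
                total = max(1, int(rng.poisson(depth * cn_obs / 2.0)))
                alt = int(rng.binomial(total, af))
                loci.append(LocusObservation(
                    chrom=chrom, pos=pos, tumor_coverage=float(t_cov),
                    normal_coverage=float(n_cov), het=True,
                    alt_reads=alt, total_reads=total))
            else:
                loci.append(LocusObservation(
                    chrom=chrom, pos=pos, tumor_coverage=float(t_cov),
                    normal_coverage=float(n_cov)))
            pos += locus_spacing
        bounds.append((start, pos - locus_spacing))
    return loci, bounds


# --- somatic candidates -----------------------------------------------------

def _clean_candidate(rng: np.random.Generator, i: int) -> SomaticCandidate:
    ref = str(rng.choice(["A", "C", "G", "T"]))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return SomaticCandidate(
        chrom="chr1", pos=1000 + 37 * i,
        ref=ref,
        alt=alt,
        tumor_ref_reads=int(rng.integers(10, 60)),
        tumor_alt_reads=int(rng.integers(4, 40)),
        normal_ref_reads=int(rng.integers(8, 60)),
        normal_alt_reads=0,
        pl_wildtype=float(rng.integers(60, 250)),
        clr=float(rng.integers(40, 200)),
    )


def simulate_somatic_candidates(n: int, seed: int | None = None,
                                rng: np.random.Generator | None = None,
                                violation_rate: float = 0.5,
                                ) -> list[SomaticCandidate]:
    """Random candidates spanning passing and failing configurations.

    With probability ``violation_rate`` a candidate is perturbed across one
    or more rule boundaries; the draw is unconstrained otherwise, so the
    population covers every reason code and their combinations.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cand = _clean_candidate(rng, i)
        if rng.random() < violation_rate:
            n_viol = 1 + rng.binomial(2, 0.3)
            for which in rng.choice(8, size=n_viol, replace=False):
                if which == 0:
                    cand.in_dbsnp = True
                    cand.in_cosmic = rng.random() < 0.3
                elif which == 1:
                    cand.normal_alt_reads = int(rng.integers(1, 6))
                elif which == 2:
                    cand.normal_ref_reads = int(rng.integers(0, 8))
                elif which == 3:
                    cand.pl_wildtype = float(rng.integers(0, 60))
                elif which == 4:
                    cand.tumor_alt_reads = int(rng.integers(0, 4))
                elif which == 5:
                    cand.clr = float(rng.integers(0, 40))
                elif which == 6:
                    cand.quality_warnings = frozenset(rng.choice(
                        ["duplication_region", "tri_allelic", "tail_of_reads"],
                        size=int(rng.integers(1, 3)), replace=False))
                else:
                    cand.repeat_context = True
        # fuzz threshold-adjacent values on every candidate
        if rng.random() < 0.2:
            cand.tumor_alt_reads = int(rng.integers(3, 6))
        if rng.random() < 0.2:
            cand.normal_ref_reads = int(rng.integers(7, 10))
        out.append(cand)
    return out


# --- SV candidates ----------------------------------------------------------

def _clean_breakpoint(rng: np.random.Generator, sample_id: str,
                      i: int) -> BreakpointPair:
    chrom1 = f"chr{int(rng.integers(1, 23))}"
    intra = rng.random() < 0.6
    chrom2 = chrom1 if intra else f"chr{int(rng.integers(1, 23))}"
    pos1 = int(rng.integers(10_000, 5_000_000))
    pos2 = pos1 + int(rng.integers(10_000, 500_000)) if chrom2 == chrom1 \
        else int(rng.integers(10_000, 5_000_000))
    return BreakpointPair(
        end1=Breakend(chrom1, pos1, str(rng.choice(["+", "-"]))),
        end2=Breakend(chrom2, pos2, str(rng.choice(["+", "-"]))),
        junction_reads=int(rng.integers(3, 40)),
        mean_junction_mismatches=float(rng.uniform(0, 2)),
        tumor_coverage_end1=float(rng.uniform(20, 200)),
        tumor_coverage_end2=float(rng.uniform(20, 200)),
        normal_coverage_end1=float(rng.uniform(10, 200)),
        normal_coverage_end2=float(rng.uniform(10, 200)),
        inserted_bases="".join(rng.choice(list(BASES),
                                          size=int(rng.integers(0, 4)))),
        flank_similarity=float(rng.uniform(0, 0.7)),
        sample_id=sample_id)


#: Planted violation classes understood by :func:`simulate_sv_candidates`.
SV_VIOLATIONS = ("clean", "min_junction_reads", "high_mismatches",
                 "extreme_coverage", "low_normal_coverage", "segdup_overlap",
                 "flank_similarity", "multi_sample", "long_insertion")


def simulate_sv_candidates(plan: dict[str, int], seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           sample_id: str = "S1",
                           segdup_region: tuple[str, int, int] = ("chrSD", 1, 10_000),
                           ) -> tuple[list[BreakpointPair], list[str]]:
    """Candidates each violating exactly the planned rule (or none).

    ``plan`` maps a violation class from :data:`SV_VIOLATIONS` to a count.
    Returns (candidates, truth labels).  ``multi_sample`` plants a matching
    breakpoint in a second sample; ``segdup_overlap`` places an end inside
    ``segdup_region``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    unknown = set(plan) - set(SV_VIOLATIONS)
    if unknown:
        raise ValueError(f"unknown violation classes: {sorted(unknown)}")
    if any(v < 0 for v in plan.values()):
        raise ValueError("plan counts must be non-negative")
    candidates: list[BreakpointPair] = []
    labels: list[str] = []
    i = 0
    for cls in SV_VIOLATIONS:
        for _ in range(plan.get(cls, 0)):
            bp = _clean_breakpoint(rng, sample_id, i)
            i += 1
            if cls == "min_junction_reads":
                bp.junction_reads = int(rng.integers(0, 3))
            elif cls == "high_mismatches":
                bp.mean_junction_mismatches = float(rng.uniform(2.01, 10))
            elif cls == "extreme_coverage":
                bp.tumor_coverage_end1 = float(rng.uniform(1001, 5000))
            elif cls == "low_normal_coverage":
                bp.normal_coverage_end2 = float(rng.uniform(0, 1.99))
            elif cls == "segdup_overlap":
                sd_chrom, sd_start, sd_end = segdup_region
                bp.end1 = Breakend(sd_chrom,
                                   int(rng.integers(sd_start, sd_end + 1)),
                                   bp.end1.orientation)
            elif cls == "flank_similarity":
                bp.flank_similarity = float(rng.uniform(0.90, 1.0))
            elif cls == "multi_sample":
                twin = BreakpointPair(
                    end1=Breakend(bp.end1.chrom,
                                  bp.end1.pos + int(rng.integers(-50, 51)),
                                  bp.end1.orientation),
                    end2=Breakend(bp.end2.chrom,
                                  bp.end2.pos + int(rng.integers(-50, 51)),
                                  bp.end2.orientation),
                    junction_reads=5, mean_junction_mismatches=0.5,
                    tumor_coverage_end1=50, tumor_coverage_end2=50,
                    normal_coverage_end1=50, normal_coverage_end2=50,
                    inserted_bases="", flank_similarity=0.1,
                    sample_id=sample_id + "_other")
                candidates.append(twin)
                labels.append("planted_twin")
            elif cls == "long_insertion":
                bp.inserted_bases = "".join(rng.choice(
                    list(BASES), size=int(rng.integers(4, 12))))
            candidates.append(bp)
            labels.append(cls)
    return candidates, labels


# --- driver tables ----------------------------------------------------------

#: Hotspot changes used when simulating driver tables.
_SIM_CHANGES = {
    "BAP1": ("p.Q684X", "splice", "p.D73Vfs*4"),
    "EIF1AX": ("p.P2L", "p.G6V", "splice"),
    "GNA11": ("p.Q209L",),
    "GNAQ": ("p.Q209P",),
    "PLCB4": ("p.D630Y",),
    "SF3B1": ("p.R625C", "p.R625H", "p.K666T"),
}

#: Genes of the Galpha-q pathway treated as mutually exclusive.
PATHWAY_EXCLUSIVE = ("GNA11", "GNAQ", "PLCB4")


def simulate_driver_table(n_samples: int,
                          frequencies: Optional[dict[str, float]] = None,
                          exclusivity: bool = True,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> DriverTable:
    """Random driver table with per-gene mutation frequencies.

    With ``exclusivity`` each sample carries at most one mutation in the
    Galpha-q pathway group (GNA11/GNAQ/PLCB4), chosen with probabilities
    proportional to their frequencies; other genes are independent
    Bernoulli.
    """
    if frequencies is None:
        frequencies = {"BAP1": 0.39, "EIF1AX": 0.14, "GNA11": 0.50,
                       "GNAQ": 0.29, "PLCB4": 0.07, "SF3B1": 0.11}
    if any(not 0 <= f <= 1 for f in frequencies.values()):
        raise ValueError("frequencies must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = [f"SYN{i:03d}" for i in range(n_samples)]
    table = DriverTable(samples=samples)
    for sample in samples:
        if exclusivity:
            probs = np.array([frequencies.get(g, 0.0)
                              for g in PATHWAY_EXCLUSIVE])
            total = probs.sum()
            if total > 0 and rng.random() < min(total, 1.0):
                gene = PATHWAY_EXCLUSIVE[
                    int(rng.choice(len(PATHWAY_EXCLUSIVE), p=probs / total))]
                table.entries[(sample, gene)] = str(
                    _SIM_CHANGES[gene][int(rng.integers(len(_SIM_CHANGES[gene])))])
            others = [g for g in DRIVER_GENES if g not in PATHWAY_EXCLUSIVE]
        else:
            others = list(DRIVER_GENES)
        for gene in others:
            if rng.random() < frequencies.get(gene, 0.0):
                table.entries[(sample, gene)] = str(
                    _SIM_CHANGES[gene][int(rng.integers(len(_SIM_CHANGES[gene])))])
    return table
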