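"""Mutational-signature exposure refitting.

A sample's 96-bin trinucleotide-context mutation catalogue M is approximated
as M ≈ P·E, where P is a fixed 96 × K matrix of signature probability
distributions (COSMIC layout) and E the sample's non-negative exposures
(mutation counts attributed to each signature).  E is the non-negative
least-squares solution minimizing the mean squared error over the 96 raw
count bins.  Confidence intervals come from a parametric Poisson resample:
each bin count is replaced by a Poisson draw with mean equal to the observed
count, exposures are refit, and the 5th-95th percentiles across replicates
define the interval.

Refitting against a fixed catalogue of signatures (rather than de novo
extraction) is appropriate for small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Canonical 96-context labels, substitution-major then 5' then 3' flank.
CONTEXT_LABELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)

#: Samples with fewer total mutations are flagged low-confidence.
LOW_CONFIDENCE_FLOOR = 10


def context_index(sub: str, f5: str, f3: str) -> int:
    return (SUBSTITUTIONS.index(sub) * 16
            + BASES.index(f5) * 4 + BASES.index(f3))


@dataclass
class MutationCatalogue:
    """Per-sample mutation counts over the 96 trinucleotide contexts."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"catalogue must have 96 bins, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalogue counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def low_confidence(self) -> bool:
        return self.total < LOW_CONFIDENCE_FLOOR


@dataclass
class SignatureMatrix:
    """96 × K matrix of signature probability columns."""

    names: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 96:
            raise ValueError(f"probs must be 96 x K, got {self.probs.shape}")
        if self.probs.shape[1] != len(self.names):
            raise ValueError("number of names must match number of columns")
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {colsums}")
        self._warn_collinear()

    def _warn_collinear(self) -> None:
        norms = np.linalg.norm(self.probs, axis=0)
        safe = np.where(norms == 0, 1.0, norms)
        unit = self.probs / safe
        cos = unit.T @ unit
        np.fill_diagonal(cos, 0.0)
        if (cos > 0.95).any():
            i, j = np.unravel_index(np.argmax(cos), cos.shape)
            warnings.warn(
                f"signatures {self.names[i]!r} and {self.names[j]!r} are nearly "
                f"collinear (cosine {cos[i, j]:.3f}); exposures may be unstable",
                stacklevel=2)

    @property
    def k(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        """Read a COSMIC-layout TSV: context labels in the first column,
        one column per signature, rows in any order of the 96 contexts."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CONTEXT_LABELS) - set(df.index)
        if missing:
            raise ValueError(f"signature TSV missing contexts: {sorted(missing)[:3]}...")
        df = df.loc[list(CONTEXT_LABELS)]
        return cls(names=list(df.columns), probs=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.probs, index=list(CONTEXT_LABELS),
                     columns=self.names).to_csv(path, sep="\t",
                                                index_label="context")


@dataclass
class ExposureEstimate:
    sample_id: str
    signature_names: list[str]
    exposures: np.ndarray
    reconstruction_mse: float
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if (self.exposures < -1e-12).any():
            raise ValueError("exposures must be non-negative")
        if self.ci_low is not None and self.ci_high is not None:
            if not np.all(np.asarray(self.ci_low) <= np.asarray(self.ci_high) + 1e-12):
                raise ValueError("ci_low must be <= ci_high elementwise")

    @property
    def proportions(self) -> np.ndarray:
        total = self.exposures.sum()
        if total == 0:
            return np.zeros_like(self.exposures)
        return self.exposures / total


def count_contexts(snvs: Sequence[tuple[str, int, str, str]],
                   reference) -> MutationCatalogue:
    """Count single-base substitutions into the 96 trinucleotide bins.

    ``reference`` is any mapping of chromosome name to indexable sequence
    (e.g. a ``pyfaidx.Fasta``).  Purine-reference SNVs are reverse
    complemented into the pyrimidine-centered convention, so each SNV
    increments exactly one bin.
    """
    counts = np.zeros(96)
    for chrom, pos, ref, alt in snvs:
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"not a SNV: {chrom}:{pos} {ref}>{alt}")
        seq = reference[chrom]
        if pos < 2 or pos > len(seq) - 1:
            raise ValueError(f"position {chrom}:{pos} too close to contig edge")
        tri = str(seq[pos - 2:pos + 1]).upper()
        if len(tri) != 3:
            raise ValueError(f"position {chrom}:{pos} outside reference")
        if tri[1] != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: VCF says {ref}, "
                f"genome says {tri[1]}")
        f5, center, f3 = tri
        alt_base = alt.upper()
        if center in ("G", "A"):  # fold to pyrimidine-centered strand
            center = COMPLEMENT[center]
            alt_base = COMPLEMENT[alt_base]
            f5, f3 = COMPLEMENT[tri[2]], COMPLEMENT[tri[0]]
        counts[context_index(f"{center}>{alt_base}", f5, f3)] += 1
    sample_id = getattr(reference, "sample_id", "sample")
    return MutationCatalogue(sample_id=sample_id, counts=counts)


def fit_exposures(catalogue: MutationCatalogue,
                  signatures: SignatureMatrix) -> ExposureEstimate:
    """Non-negative least-squares exposure fit.

    Minimizes mean((counts − P·E)²) over E ≥ 0; the active-set NNLS solution
    is deterministic, which resolves ties under collinear signatures.
    """
    if signatures.k == 0:
        raise ValueError("signature matrix has no columns")
    exposures, _ = nnls(signatures.probs, catalogue.counts)
    residual = catalogue.counts - signatures.probs @ exposures
    mse = float(np.mean(residual ** 2))
    return ExposureEstimate(
        sample_id=catalogue.sample_id,
        signature_names=list(signatures.names),
        exposures=exposures,
        reconstruction_mse=mse,
        low_confidence=catalogue.low_confidence,
    )


def exposure_confidence(catalogue: MutationCatalogue,
                        signatures: SignatureMatrix,
                        reps: int = 1000,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> ExposureEstimate:
    """Poisson-resampling confidence intervals for the exposures.

    Each replicate replaces every bin count with a Poisson draw whose mean is
    the observed count, refits, and the per-signature 5th/95th percentiles
    over ``reps`` replicates form [ci_low, ci_high].
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    estimate = fit_exposures(catalogue, signatures)
    draws = rng.poisson(catalogue.counts, size=(reps, 96)).astype(float)
    boot = np.empty((reps, signatures.k))
    for r in range(reps):
        boot[r], _ = nnls(signatures.probs, draws[r])
    estimate.ci_low = np.percentile(boot, 5, axis=0)
    estimate.ci_high = np.percentile(boot, 95, axis=0)
    return estimate


def exposure_report(estimates: Sequence[ExposureEstimate],
                    plot_path: str | Path | None = None) -> pd.DataFrame:
    """Stacked-proportion table (and optional stacked-bar plot).

    One row per sample; proportion columns sum to 1 for samples with any
    mutations, all-zero samples are flagged and excluded from the plot.
    """
    if not estimates:
        raise ValueError("need at least one sample estimate")
    names = estimates[0].signature_names
    rows = []
    for est in estimates:
        if est.signature_names != names:
            raise ValueError("all estimates must share the signature set")
        row = {"sample": est.sample_id,
               "total_exposure": float(est.exposures.sum()),
               "all_zero": bool(est.exposures.sum() == 0),
               "low_confidence": est.low_confidence}
        for name, p in zip(names, est.proportions):
            row[f"prop_{name}"] = float(p)
        rows.append(row)
    table = pd.DataFrame(rows)
    if plot_path is not None:
        _plot_stacked(table, names, plot_path)
    return table


def _plot_stacked(table: pd.DataFrame, names: list[str],
                  plot_path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = table[~table["all_zero"]]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(plotted)), 4))
    bottom = np.zeros(len(plotted))
    for name in names:
        vals = plotted[f"prop_{name}"].to_numpy()
        ax.bar(plotted["sample"], vals, bottom=bottom, label=name)
        bottom += vals
    ax.set_ylabel("exposure proportion")
    ax.legend(fontsize="small", ncol=2)
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(plot_path)
    plt.close(fig)
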