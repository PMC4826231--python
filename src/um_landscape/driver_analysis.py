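"""Driver-mutation recurrence and mutual exclusivity.

Works over a driver-mutation sample table: one row per tumor, one column
per driver gene (BAP1, EIF1AX, GNA11, GNAQ, PLCB4, SF3B1), cells holding
protein-change strings ("p.Q209L", "p.D73Vfs*4", "splice"), blank when
wild-type.  The table transcribed from the study cohort ships with the
package (``um_landscape.data``).

Mutual exclusivity is quantified by a permutation test added by this
package (the source study reports the pattern without a statistic): per-gene
mutation counts are preserved while carrier samples are reshuffled, and the
p-value is the fraction of permutations with no more co-mutated samples
than observed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DRIVER_GENES = ("BAP1", "EIF1AX", "GNA11", "GNAQ", "PLCB4", "SF3B1")


def normalize_change(change: str) -> str:
    """Canonical protein-change string: splice unified case-insensitively,
    other changes compared verbatim apart from surrounding whitespace."""
    change = change.strip()
    if change.lower() == "splice":
        return "splice"
    return change


@dataclass
class DriverTable:
    """Sample-by-gene driver mutation table."""

    samples: list[str]
    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    genes: tuple[str, ...] = DRIVER_GENES

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = [s for s in self.samples if self.samples.count(s) > 1]
            raise ValueError(f"duplicate sample labels: {sorted(set(dupes))}")
        for sample, gene in self.entries:
            if gene not in self.genes:
                raise ValueError(f"unknown gene column {gene!r}")
            if sample not in self.samples:
                raise ValueError(f"entry for unknown sample {sample!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def change(self, sample: str, gene: str) -> Optional[str]:
        return self.entries.get((sample, gene))

    def carriers(self, gene: str) -> list[str]:
        if gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return [s for s in self.samples if (s, gene) in self.entries]


def parse_driver_table(path: str | Path) -> DriverTable:
    """Read a driver table TSV: first column sample label, then the six
    gene columns; blank cells mean wild-type."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = list(df.columns)
    unknown = [c for c in header[1:] if c not in DRIVER_GENES]
    if unknown:
        raise ValueError(f"unknown gene columns: {unknown}")
    missing = [g for g in DRIVER_GENES if g not in header[1:]]
    if missing:
        raise ValueError(f"missing gene columns: {missing}")
    samples = [str(s) for s in df[header[0]]]
    table = DriverTable(samples=samples)
    for _, row in df.iterrows():
        sample = str(row[header[0]])
        for gene in DRIVER_GENES:
            cell = str(row[gene]).strip()
            if cell:
                key = (sample, gene)
                if key in table.entries:
                    raise ValueError(f"duplicate entry for {key}")
                table.entries[key] = normalize_change(cell)
    return table


def load_packaged_driver_table() -> DriverTable:
    """The driver-mutation table of the 28-sample uveal melanoma cohort."""
    ref = importlib.resources.files("um_landscape.data") / "um_cohort_drivers.tsv"
    with importlib.resources.as_file(ref) as path:
        return parse_driver_table(path)


def gene_mutation_count(table: DriverTable, gene: str,
                        protein_change: Optional[str] = None) -> int:
    """Samples mutated in ``gene``, optionally restricted to one change.

    ``protein_change`` may be a full change ("p.D630Y") or a codon prefix
    ending in '*' wildcard is not supported; matching is on the normalized
    string, or on the codon when ``protein_change`` omits the substituted
    residue (e.g. "p.Q209" matches p.Q209L and p.Q209P).
    """
    if gene not in table.genes:
        raise KeyError(f"unknown gene {gene!r}")
    wanted = normalize_change(protein_change) if protein_change else None
    count = 0
    for sample in table.samples:
        change = table.change(sample, gene)
        if change is None:
            continue
        if wanted is None or change == wanted or change.startswith(wanted):
            count += 1
    return count


def recurrent_hotspots(table: DriverTable,
                       genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """(gene, protein_change) pairs shared by >= 2 samples.

    Sorted by count descending, then gene name, then change.
    """
    genes = tuple(genes) if genes is not None else table.genes
    counts: dict[tuple[str, str], int] = {}
    for sample in table.samples:
        for gene in genes:
            change = table.change(sample, gene)
            if change is not None:
                counts[(gene, change)] = counts.get((gene, change), 0) + 1
    rows = [{"gene": g, "protein_change": c, "n_samples": n}
            for (g, c), n in counts.items() if n >= 2]
    rows.sort(key=lambda r: (-r["n_samples"], r["gene"], r["protein_change"]))
    return pd.DataFrame(rows, columns=["gene", "protein_change", "n_samples"])


def mutual_exclusivity(table: DriverTable, gene_set: Sequence[str],
                       n_permutations: int = 10_000,
                       seed: int | None = None,
                       ) -> tuple[int, float, pd.DataFrame]:
    """Co-mutation of a gene set with a permutation null.

    Returns (number of samples mutated in >= 2 genes of the set, permutation
    p-value for exclusivity, gene-by-gene co-occurrence matrix).  The null
    reassigns each gene's carriers uniformly at random without replacement,
    preserving per-gene mutation counts; small p means fewer co-mutated
    samples than expected under independence.
    """
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("need at least two genes")
    n = table.n_samples
    carrier_idx = []
    sample_index = {s: i for i, s in enumerate(table.samples)}
    for gene in gene_set:
        carrier_idx.append(np.array([sample_index[s]
                                     for s in table.carriers(gene)], int))
    mutated = np.zeros((len(gene_set), n), bool)
    for g, idx in enumerate(carrier_idx):
        mutated[g, idx] = True
    observed = int((mutated.sum(axis=0) >= 2).sum())
    co = pd.DataFrame(
        (mutated.astype(int) @ mutated.astype(int).T),
        index=gene_set, columns=gene_set)
    rng = np.random.default_rng(seed)
    at_most = 0
    for _ in range(n_permutations):
        hits = np.zeros(n, int)
        for idx in carrier_idx:
            perm = rng.choice(n, size=idx.size, replace=False)
            hits[perm] += 1
        if int((hits >= 2).sum()) <= observed:
            at_most += 1
    p_value = (at_most + 1) / (n_permutations + 1)
    return observed, float(p_value), co


def driver_counts_table(table: DriverTable) -> pd.DataFrame:
    """Per-gene mutated-sample counts over the whole table."""
    rows = [{"gene": g, "n_mutated": gene_mutation_count(table, g)}
            for g in table.genes]
    return pd.DataFrame(rows)
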