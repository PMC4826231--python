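"""Cohort-level summary tables.

Assembles the per-sample landscape view: mutation burden, base-change
spectrum, top signature exposures, chromosome-arm aberration calls, SV
counts and driver entries.  Missing stages are marked absent, never
silently zero.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signature_fit import COMPLEMENT, SUBSTITUTIONS

ABSENT = "NA"


def base_change_proportions(snvs_by_sample: dict[str, Sequence[tuple[str, str]]]
                            ) -> pd.DataFrame:
    """Per-sample proportions over the six pyrimidine-folded base changes.

    ``snvs_by_sample`` maps sample -> iterable of (ref, alt) single bases.
    Rows with at least one SNV sum to 1; empty samples are flagged absent.
    """
    rows = []
    for sample, snvs in snvs_by_sample.items():
        counts = dict.fromkeys(SUBSTITUTIONS, 0)
        n = 0
        for ref, alt in snvs:
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"not a SNV: {ref}>{alt}")
            if ref in ("G", "A"):
                ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
            counts[f"{ref}>{alt}"] += 1
            n += 1
        row = {"sample": sample, "n_snvs": n, "absent": n == 0}
        for sub in SUBSTITUTIONS:
            row[sub] = counts[sub] / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(samples: Sequence[str],
                   mutation_counts: Optional[dict[str, int]] = None,
                   mutations_per_mb: Optional[dict[str, float]] = None,
                   top_signatures: Optional[dict[str, str]] = None,
                   arm_calls: Optional[dict[str, str]] = None,
                   sv_counts: Optional[dict[str, int]] = None,
                   driver_entries: Optional[dict[str, str]] = None,
                   timing_rho: Optional[dict[str, float]] = None,
                   ) -> pd.DataFrame:
    """One row per sample; stages not run are marked with ``NA``."""

    def cell(mapping, sample, fmt=str):
        if mapping is None or sample not in mapping:
            return ABSENT
        return fmt(mapping[sample])

    rows = []
    for sample in samples:
        rows.append({
            "sample": sample,
            "n_mutations": cell(mutation_counts, sample),
            "mutations_per_mb": cell(mutations_per_mb, sample,
                                     lambda v: f"{v:.4f}"),
            "top_signatures": cell(top_signatures, sample),
            "arm_aberrations": cell(arm_calls, sample),
            "n_svs": cell(sv_counts, sample),
            "driver_mutations": cell(driver_entries, sample),
            "pre_duplication_fraction": cell(timing_rho, sample,
                                             lambda v: f"{v:.3f}"),
        })
    return pd.DataFrame(rows)
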