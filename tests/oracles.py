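"""Independent straight-line re-implementations used as test oracles.

Deliberately naive: plain transcriptions of the filtering rules, the timing
likelihood, exhaustive split scans and direct probability summations,
written separately from the package's engines so agreement is meaningful.
"""

import math


def somatic_oracle(c, *, normal_alt_max=0, normal_ref_min=8, pl_min=60,
                   tumor_alt_min=4, clr_min=40):
    """Rule-by-rule somatic filter decision: (passed, reasons)."""
    reasons = []
    if c.in_dbsnp and not c.in_cosmic:
        reasons.append("dbsnp_not_cosmic")
    if c.normal_alt_reads > normal_alt_max:
        reasons.append("normal_contamination")
    if c.normal_ref_reads < normal_ref_min:
        reasons.append("normal_low_depth")
    if c.pl_wildtype < pl_min:
        reasons.append("low_pl")
    if c.tumor_alt_reads < tumor_alt_min:
        reasons.append("low_alt_support")
    if c.clr < clr_min:
        reasons.append("low_clr")
    if len(c.quality_warnings) > 0:
        reasons.append("quality_warning")
    if c.repeat_context:
        reasons.append("repeat_context")
    return (len(reasons) == 0, reasons)


def sv_oracle(bp, segdup_hits, cohort, *, window=100):
    """Rule-by-rule SV filter decision: (passed, reasons).

    ``segdup_hits`` is a callable (chrom, pos) -> bool.
    """
    reasons = []
    if bp.junction_reads < 3:
        reasons.append("min_junction_reads")
    if bp.mean_junction_mismatches > 2:
        reasons.append("high_mismatches")
    covs = [bp.tumor_coverage_end1, bp.tumor_coverage_end2,
            bp.normal_coverage_end1, bp.normal_coverage_end2]
    if any(c > 1000 for c in covs):
        reasons.append("extreme_coverage")
    if bp.normal_coverage_end1 < 2 or bp.normal_coverage_end2 < 2:
        reasons.append("low_normal_coverage")
    if segdup_hits(bp.end1.chrom, bp.end1.pos) or \
            segdup_hits(bp.end2.chrom, bp.end2.pos):
        reasons.append("segdup_overlap")
    if bp.flank_similarity >= 0.90:
        reasons.append("flank_similarity")
    found = False
    for other in cohort:
        if other.sample_id == bp.sample_id:
            continue
        for e1, e2 in ((other.end1, other.end2), (other.end2, other.end1)):
            if (e1.chrom == bp.end1.chrom and abs(e1.pos - bp.end1.pos) <= window
                    and e1.orientation == bp.end1.orientation
                    and e2.chrom == bp.end2.chrom
                    and abs(e2.pos - bp.end2.pos) <= window
                    and e2.orientation == bp.end2.orientation):
                found = True
    if found:
        reasons.append("multi_sample")
    if len(bp.inserted_bases) > 3:
        reasons.append("long_insertion")
    return (len(reasons) == 0, reasons)


def binom_pmf(v, d, p):
    if p <= 0:
        return 1.0 if v == 0 else 0.0
    if p >= 1:
        return 1.0 if v == d else 0.0
    return math.comb(d, v) * p ** v * (1 - p) ** (d - v)


def timing_loglik_oracle(rho, tc, cn, obs):
    """Literal transcription of the duplication-timing mixture likelihood."""
    total = 0.0
    for o in obs:
        v, d = o.variant_reads, o.total_reads
        b_single = binom_pmf(v, d, tc / cn)
        b_dup = binom_pmf(v, d, tc * (1 - 1 / cn))
        lik = rho * (0.5 * b_single + 0.5 * b_dup) + (1 - rho) * b_single
        total += math.log(max(lik, 1e-300))
    return total


def grid_oracle_best(obs, cn_candidates=(3, 4), step=0.01):
    """Coarse 3-D grid search of the timing mixture likelihood
    (rho, tc at ``step``; cn enumerated).  Vectorized but written
    independently of the estimator's internals."""
    import numpy as np
    from scipy.stats import binom as _binom

    v = np.array([o.variant_reads for o in obs])
    d = np.array([o.total_reads for o in obs])
    rhos = np.arange(0.0, 1.0 + step / 2, step)
    tcs = np.arange(step, 1.0 + step / 2, step)
    best = -np.inf
    for cn in cn_candidates:
        for tc in tcs:
            b1 = _binom.pmf(v, d, tc / cn)
            b2 = _binom.pmf(v, d, tc * (1 - 1 / cn))
            mix = (rhos[:, None] * 0.5 * (b1 + b2)[None, :]
                   + (1 - rhos[:, None]) * b1[None, :])
            ll = np.log(np.maximum(mix, 1e-300)).sum(axis=1).max()
            best = max(best, float(ll))
    return best


def exact_binom_two_sided(k, n, p=0.5):
    """Two-sided exact binomial p-value by direct summation over outcomes
    no more probable than the observed one."""
    obs = binom_pmf(k, n, p)
    total = 0.0
    for x in range(n + 1):
        if binom_pmf(x, n, p) <= obs * (1 + 1e-9):
            total += binom_pmf(x, n, p)
    return min(1.0, total)


def count_contexts_oracle(snvs, genome):
    """Direct string-lookup 96-bin recount (pyrimidine-folded)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    counts = [0] * 96
    for chrom, pos, ref, alt in snvs:
        seq = genome[chrom]
        tri = seq[pos - 2:pos + 1]
        assert tri[1] == ref
        if ref in "GA":
            ref2, alt2 = comp[ref], comp[alt]
            f5, f3 = comp[tri[2]], comp[tri[0]]
        else:
            ref2, alt2 = ref, alt
            f5, f3 = tri[0], tri[2]
        idx = (subs.index(f"{ref2}>{alt2}") * 16
               + bases.index(f5) * 4 + bases.index(f3))
        counts[idx] += 1
    return counts


def nnls_grid_2sig(counts, p1, p2, e_max, step):
    """Coarse non-negative grid search of a 2-signature exposure fit."""
    best = None
    e = 0.0
    grid = []
    while e <= e_max:
        grid.append(e)
        e += step
    for e1 in grid:
        for e2 in grid:
            resid = 0.0
            for j in range(96):
                r = counts[j] - (p1[j] * e1 + p2[j] * e2)
                resid += r * r
            if best is None or resid < best[0]:
                best = (resid, e1, e2)
    return best[1], best[2], best[0] / 96.0


def best_single_split(loci, min_width, loglik_fn):
    """Exhaustive one-breakpoint scan with a caller-supplied segment
    log-likelihood; returns (k, llr)."""
    n = len(loci)
    base = loglik_fn(0, n)
    best_k, best_llr = None, -math.inf
    for k in range(min_width, n - min_width + 1):
        llr = loglik_fn(0, k) + loglik_fn(k, n) - base
        if llr > best_llr:
            best_k, best_llr = k, llr
    return best_k, best_llr
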