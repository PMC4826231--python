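"""Timing chromosome-arm duplications against point mutations.

For mutations on a gained arm, the variant allele frequency separates
mutations that predate the gain (those on the duplicated haplotype sit on
cn-1 of cn copies) from those arising after it (a single copy).  With tumor
content ``tc`` and arm copy number ``cn``, variant reads follow a mixture of
binomials:

    L(v, d) = rho * [ 1/2 B(v; d, tc/cn) + 1/2 B(v; d, tc (1 - 1/cn)) ]
              + (1 - rho) * B(v; d, tc/cn)

where ``rho`` is the fraction of mutations predating the gain: half of those
are not on the duplicated haplotype and stay at the single-copy mean tc/cn,
the other half are duplicated to mean tc(1 - 1/cn).  Mutations after the
gain all sit at tc/cn.  ``rho``, ``tc`` are estimated by maximum likelihood
(dense grid refined by bounded local search) and ``cn`` by enumeration.

These are the literal component means; the fully purity-adjusted form
tc*k/(tc*cn + 2(1-tc)) is available via ``purity_adjusted=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom


@dataclass(frozen=True)
class TimingObservation:
    """Variant/total read counts of one somatic SNV on the gained arm."""

    variant_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if not 0 <= self.variant_reads <= self.total_reads:
            raise ValueError("variant_reads must lie in [0, total_reads]")


@dataclass(frozen=True)
class TimingModel:
    """Mixture parameters: pre-gain fraction, tumor content, copy number."""

    rho: float
    tc: float
    cn: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not 0.0 < self.tc <= 1.0:
            raise ValueError(f"tc must lie in (0, 1], got {self.tc}")
        if self.cn < 3:
            raise ValueError(
                f"cn must be >= 3 for a duplicated arm (components coincide "
                f"at cn=2), got {self.cn}")

    def component_means(self, purity_adjusted: bool = False) -> tuple[float, float]:
        """(single-copy mean, duplicated-copies mean)."""
        if purity_adjusted:
            denom = self.tc * self.cn + 2.0 * (1.0 - self.tc)
            return (self.tc / denom, self.tc * (self.cn - 1) / denom)
        return (self.tc / self.cn, self.tc * (1.0 - 1.0 / self.cn))


def _obs_arrays(obs: Sequence[TimingObservation]) -> tuple[np.ndarray, np.ndarray]:
    if not obs:
        raise ValueError("need at least one observation")
    v = np.array([o.variant_reads for o in obs], int)
    d = np.array([o.total_reads for o in obs], int)
    return v, d


def timing_loglik(model: TimingModel, obs: Sequence[TimingObservation],
                  purity_adjusted: bool = False) -> float:
    """Mixture log-likelihood of the observations under ``model``."""
    v, d = _obs_arrays(obs)
    p_single, p_dup = model.component_means(purity_adjusted)
    b_single = binom.pmf(v, d, p_single)
    b_dup = binom.pmf(v, d, p_dup)
    mix = (model.rho * 0.5 * (b_single + b_dup)
           + (1.0 - model.rho) * b_single)
    return float(np.sum(np.log(np.maximum(mix, 1e-300))))


def _loglik_grid(v: np.ndarray, d: np.ndarray, cn: int,
                 rho_grid: np.ndarray, tc_grid: np.ndarray,
                 purity_adjusted: bool) -> np.ndarray:
    """Log-likelihood surface over (tc, rho), vectorized per tc."""
    surface = np.empty((tc_grid.size, rho_grid.size))
    for i, tc in enumerate(tc_grid):
        model = TimingModel(rho=0.0, tc=tc, cn=cn)
        p_single, p_dup = model.component_means(purity_adjusted)
        b_single = binom.pmf(v, d, p_single)
        b_dup = binom.pmf(v, d, p_dup)
        # rows: rho values; columns: observations
        mix = (rho_grid[:, None] * 0.5 * (b_single + b_dup)[None, :]
               + (1.0 - rho_grid[:, None]) * b_single[None, :])
        surface[i] = np.log(np.maximum(mix, 1e-300)).sum(axis=1)
    return surface


def estimate_timing(obs: Sequence[TimingObservation],
                    cn_candidates: Sequence[int] = (3, 4),
                    rho_step: float = 0.01, tc_step: float = 0.01,
                    purity_adjusted: bool = False,
                    ) -> tuple[TimingModel, float, float]:
    """Joint MLE of (rho, tc, cn).

    Dense grid over rho in [0, 1] and tc in (0, 1], refined by Nelder-Mead
    from the grid optimum; cn by enumeration.  Returns (model, loglik,
    rho_hat); rho_hat is the estimated fraction of mutations predating the
    duplication.
    """
    v, d = _obs_arrays(obs)
    if len(obs) < 20:
        warnings.warn(f"only {len(obs)} observations; timing estimates are "
                      "unstable below ~20 mutations", stacklevel=2)
    if any(cn < 3 for cn in cn_candidates):
        raise ValueError("cn candidates must be >= 3")
    rho_grid = np.arange(0.0, 1.0 + rho_step / 2, rho_step)
    tc_grid = np.arange(tc_step, 1.0 + tc_step / 2, tc_step)
    best: tuple[float, TimingModel] | None = None
    for cn in cn_candidates:
        surface = _loglik_grid(v, d, cn, rho_grid, tc_grid, purity_adjusted)
        i, j = np.unravel_index(np.argmax(surface), surface.shape)
        tc0, rho0 = float(tc_grid[i]), float(rho_grid[j])

        def neg(x, cn=cn):
            rho = min(max(x[0], 0.0), 1.0)
            tc = min(max(x[1], 1e-6), 1.0)
            return -timing_loglik(TimingModel(rho, tc, cn), obs,
                                  purity_adjusted)

        res = minimize(neg, [rho0, tc0], method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7})
        grid_ll = float(surface[i, j])
        if res.success or -res.fun >= grid_ll:
            rho_hat = min(max(float(res.x[0]), 0.0), 1.0)
            tc_hat = min(max(float(res.x[1]), 1e-6), 1.0)
            ll = float(-res.fun)
        else:
            rho_hat, tc_hat, ll = rho0, tc0, grid_ll
        model = TimingModel(rho=rho_hat, tc=tc_hat, cn=cn)
        if best is None or ll > best[0]:
            best = (ll, model)
    assert best is not None
    ll, model = best
    return model, ll, model.rho


def vaf_density(obs: Sequence[TimingObservation],
                grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-mutation-likelihood smoother of the VAF distribution.

    density(f) is proportional to the sum over mutations of the binomial
    likelihood B(v_i; d_i, f), normalized to integrate to 1 by the trapezoid
    rule.  Returns (grid, density).
    """
    v, d = _obs_arrays(obs)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(grid, float)
    if grid.size < 2:
        raise ValueError("grid must have at least two points")
    dens = binom.pmf(v[None, :], d[None, :], grid[:, None]).sum(axis=1)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return grid, dens


def count_density_modes(grid: np.ndarray, density: np.ndarray,
                        min_prominence: float = 0.05) -> int:
    """Number of local maxima of a density curve (simple prominence gate)."""
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(density, prominence=min_prominence * density.max())
    # interior peaks only; a boundary mode at f=0 counts when density is
    # decreasing from the edge
    n = len(peaks)
    if density[0] > density[1]:
        n += 1
    if density[-1] > density[-2]:
        n += 1
    return n


def pre_duplication_fraction_summary(rho_hats: Sequence[float]
                                     ) -> dict[str, float]:
    """Cohort mean and min-max range of per-sample pre-gain fractions."""
    if not rho_hats:
        raise ValueError("need at least one sample estimate")
    arr = np.asarray(rho_hats, float)
    return {"mean": float(arr.mean()),
            "min": float(arr.min()),
            "max": float(arr.max())}
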