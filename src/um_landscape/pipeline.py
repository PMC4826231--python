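"""End-to-end pipeline over a synthetic cohort.

Wires the stages in dependency order — somatic filtering, then signature
refitting and segmentation, then duplication timing, SV filtering, driver
analysis and the cohort report — writing each stage's tables under a
stage-named directory.  Every stage consumes seeded synthetic inputs whose
structure matches what the corresponding analysis assumes, so the whole
pipeline runs without external data and is byte-reproducible for a fixed
configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, report, synth
from .driver_analysis import (driver_counts_table, load_packaged_driver_table,
                              mutual_exclusivity, recurrent_hotspots)
from .segmentation import (SegmentationParams, call_aberrations,
                           normalize_copy_number, segment_chromosome,
                           segments_to_frame)
from .signature_fit import exposure_confidence, exposure_report
from .somatic_filter import FilterThresholds, filter_candidates
from .sv_filter import SvThresholds, classify_sv, filter_breakpoints
from .synth import SegmentSpec
from .timing import TimingModel, estimate_timing, vaf_density

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "n_samples": 6,
    "covered_mb": 3000.0,
    "somatic": {"enabled": True, "n_candidates": 120},
    "signatures": {"enabled": True, "k": 5, "total_mutations": 400,
                   "reps": 200},
    "segmentation": {"enabled": True, "depth": 60.0, "purity": 0.8,
                     "n_loci_per_block": 400},
    "timing": {"enabled": True, "n_obs": 300, "rho": 0.93, "tc": 0.8,
               "cn": 3, "depth": 60.0},
    "sv": {"enabled": True,
           "plan": {"clean": 8, "min_junction_reads": 2, "high_mismatches": 2,
                    "long_insertion": 2}},
    "drivers": {"enabled": True, "source": "packaged", "n_permutations": 2000},
}

#: Per-sample copy-number layouts cycled across the cohort: a diploid
#: baseline plus one aberrant block (monosomy-, gain- or cnLOH-like).
_LAYOUT_POOL = [
    [SegmentSpec(400, 2.0, 0.5), SegmentSpec(400, 1.0, 0.0), SegmentSpec(400, 2.0, 0.5)],
    [SegmentSpec(400, 2.0, 0.5), SegmentSpec(400, 3.0, 1 / 3), SegmentSpec(400, 2.0, 0.5)],
    [SegmentSpec(400, 2.0, 0.5), SegmentSpec(400, 2.0, 0.0), SegmentSpec(400, 2.0, 0.5)],
]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    return config


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Run every enabled stage over the synthetic cohort.

    Returns the cohort summary (one row per sample) and writes per-stage
    artifacts plus a machine-readable run log under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    n_samples = int(config["n_samples"])
    samples = [f"SYN{i:02d}" for i in range(n_samples)]
    seeds = np.random.SeedSequence(seed).spawn(n_samples + 1)
    sample_rngs = {s: np.random.default_rng(seeds[i])
                   for i, s in enumerate(samples)}
    cohort_rng = np.random.default_rng(seeds[-1])

    mutation_counts: dict[str, int] = {}
    per_mb: dict[str, float] = {}
    top_sigs: dict[str, str] = {}
    arm_calls: dict[str, str] = {}
    sv_counts: dict[str, int] = {}
    timing_rho: dict[str, float] = {}
    driver_entries: dict[str, str] = {}

    # --- somatic filtering -------------------------------------------------
    if config["somatic"]["enabled"]:
        stage = out / "somatic_filter"
        all_rejections = []
        for s in samples:
            cands = synth.simulate_somatic_candidates(
                int(config["somatic"]["n_candidates"]), rng=sample_rngs[s])
            passed, rejection = filter_candidates(cands, FilterThresholds())
            rejection.insert(0, "sample", s)
            all_rejections.append(rejection)
            mutation_counts[s] = len(passed)
            per_mb[s] = len(passed) / float(config["covered_mb"])
        _write_tsv(pd.concat(all_rejections, ignore_index=True),
                   stage / "rejections.tsv")
        _write_tsv(pd.DataFrame({"sample": samples,
                                 "n_passed": [mutation_counts[s] for s in samples],
                                 "mutations_per_mb": [per_mb[s] for s in samples]}),
                   stage / "passed_counts.tsv")

    # --- signatures --------------------------------------------------------
    snvs_by_sample: dict[str, list] = {}
    if config["signatures"]["enabled"]:
        stage = out / "signatures"
        sig_cfg = config["signatures"]
        matrix = synth.synthetic_signature_matrix(k=int(sig_cfg["k"]))
        estimates = []
        truth_rows = []
        for s in samples:
            rng = sample_rngs[s]
            weights = rng.dirichlet([1.0] * matrix.k)
            e_true = weights * float(sig_cfg["total_mutations"])
            cat = synth.simulate_signature_catalogue(
                matrix, e_true, rng=rng, sample_id=s)
            genome = synth.random_genome(length=20_000, rng=rng)
            snvs = synth.snvs_for_catalogue(genome, cat, rng=rng)
            snvs_by_sample[s] = [(ref, alt) for _, _, ref, alt in snvs]
            est = exposure_confidence(cat, matrix,
                                      reps=int(sig_cfg["reps"]), rng=rng)
            estimates.append(est)
            order = np.argsort(est.exposures)[::-1]
            top_sigs[s] = ",".join(matrix.names[i] for i in order[:2])
            truth_rows.append({"sample": s,
                               **{f"true_{n}": e for n, e in
                                  zip(matrix.names, e_true)}})
        table = exposure_report(estimates)
        _write_tsv(table, stage / "exposure_proportions.tsv")
        _write_tsv(pd.DataFrame(truth_rows), stage / "true_exposures.tsv")
        exp_rows = []
        for est in estimates:
            row = {"sample": est.sample_id,
                   "reconstruction_mse": est.reconstruction_mse}
            for i, name in enumerate(est.signature_names):
                row[name] = est.exposures[i]
                row[f"{name}_ci_low"] = est.ci_low[i]
                row[f"{name}_ci_high"] = est.ci_high[i]
            exp_rows.append(row)
        _write_tsv(pd.DataFrame(exp_rows), stage / "exposures.tsv")
        _write_tsv(report.base_change_proportions(snvs_by_sample),
                   stage / "base_change_proportions.tsv")

    # --- segmentation ------------------------------------------------------
    if config["segmentation"]["enabled"]:
        stage = out / "segmentation"
        seg_cfg = config["segmentation"]
        params = SegmentationParams()
        frames = []
        arm_frames = []
        for i, s in enumerate(samples):
            layout = _LAYOUT_POOL[i % len(_LAYOUT_POOL)]
            scale = int(seg_cfg["n_loci_per_block"]) / 400
            layout = [SegmentSpec(max(20, int(b.n_loci * scale)),
                                  b.copy_number, b.maf) for b in layout]
            loci, _ = synth.simulate_cn_profile(
                layout, purity=float(seg_cfg["purity"]),
                depth=float(seg_cfg["depth"]), rng=sample_rngs[s])
            segs = segment_chromosome(loci, params)
            segs, factor = normalize_copy_number(segs, params)
            segs, arm_summary = call_aberrations(segs, params)
            frame = segments_to_frame(segs)
            frame.insert(0, "sample", s)
            frames.append(frame)
            arm_summary.insert(0, "sample", s)
            arm_frames.append(arm_summary)
            labels = sorted({seg.label for seg in segs if seg.label != "neutral"})
            arm_calls[s] = ",".join(labels) if labels else "none"
        _write_tsv(pd.concat(frames, ignore_index=True), stage / "segments.tsv")
        _write_tsv(pd.concat(arm_frames, ignore_index=True),
                   stage / "arm_summary.tsv")

    # --- timing ------------------------------------------------------------
    if config["timing"]["enabled"]:
        stage = out / "timing"
        t_cfg = config["timing"]
        truth = TimingModel(rho=float(t_cfg["rho"]), tc=float(t_cfg["tc"]),
                            cn=int(t_cfg["cn"]))
        rows = []
        dens_frames = []
        for s in samples:
            obs = synth.simulate_timing_observations(
                truth, n=int(t_cfg["n_obs"]),
                depth_mean=float(t_cfg["depth"]), rng=sample_rngs[s])
            model, loglik, rho_hat = estimate_timing(obs)
            timing_rho[s] = rho_hat
            rows.append({"sample": s, "rho": model.rho, "tc": model.tc,
                         "cn": model.cn, "loglik": loglik})
            grid, dens = vaf_density(obs)
            dens_frames.append(pd.DataFrame(
                {"sample": s, "vaf": grid, "density": dens}))
        _write_tsv(pd.DataFrame(rows), stage / "timing_estimates.tsv")
        _write_tsv(pd.concat(dens_frames, ignore_index=True),
                   stage / "vaf_density.tsv")

    # --- structural variants ------------------------------------------------
    if config["sv"]["enabled"]:
        stage = out / "sv"
        plan = {k: int(v) for k, v in config["sv"]["plan"].items()}
        all_cands = []
        per_sample: dict[str, list] = {}
        for s in samples:
            cands, _ = synth.simulate_sv_candidates(
                plan, rng=sample_rngs[s], sample_id=s)
            per_sample[s] = cands
            all_cands.extend(cands)
        rows = []
        rejections = []
        for s in samples:
            passed, rejection = filter_breakpoints(
                per_sample[s], cohort=all_cands, thresholds=SvThresholds())
            sv_counts[s] = len(passed)
            rejections.append(rejection)
            for bp in passed:
                rows.append({
                    "sample": s, "chrom1": bp.end1.chrom, "pos1": bp.end1.pos,
                    "strand1": bp.end1.orientation, "chrom2": bp.end2.chrom,
                    "pos2": bp.end2.pos, "strand2": bp.end2.orientation,
                    "junction_reads": bp.junction_reads,
                    "sv_class": classify_sv(bp)})
        _write_tsv(pd.DataFrame(rows, columns=[
            "sample", "chrom1", "pos1", "strand1", "chrom2", "pos2",
            "strand2", "junction_reads", "sv_class"]), stage / "sv_calls.tsv")
        _write_tsv(pd.concat(rejections, ignore_index=True),
                   stage / "rejections.tsv")

    # --- drivers -----------------------------------------------------------
    driver_stats = {}
    if config["drivers"]["enabled"]:
        stage = out / "drivers"
        if config["drivers"]["source"] == "packaged":
            table = load_packaged_driver_table()
        else:
            table = synth.simulate_driver_table(n_samples, rng=cohort_rng)
        _write_tsv(driver_counts_table(table), stage / "gene_counts.tsv")
        _write_tsv(recurrent_hotspots(table), stage / "hotspots.tsv")
        excl = {}
        for name, genes in (("galpha_pathway", ("GNA11", "GNAQ", "PLCB4")),
                            ("bap1_eif1ax", ("BAP1", "EIF1AX"))):
            overlap, p, _ = mutual_exclusivity(
                table, genes,
                n_permutations=int(config["drivers"]["n_permutations"]),
                seed=seed)
            excl[name] = {"genes": list(genes), "overlapping_samples": overlap,
                          "permutation_p": p,
                          "note": "permutation test is repository-defined"}
        with open(stage / "mutual_exclusivity.json", "w") as fh:
            json.dump(excl, fh, indent=2, sort_keys=True)
        driver_stats = excl
        for s in samples:
            if s in table.samples:
                entries = [f"{g}:{table.change(s, g)}" for g in table.genes
                           if table.change(s, g)]
                driver_entries[s] = ";".join(entries) if entries else "none"

    # --- report ------------------------------------------------------------
    summary = report.cohort_summary(
        samples,
        mutation_counts=mutation_counts or None,
        mutations_per_mb=per_mb or None,
        top_signatures=top_sigs or None,
        arm_calls=arm_calls or None,
        sv_counts=sv_counts or None,
        driver_entries=driver_entries or None,
        timing_rho=timing_rho or None)
    _write_tsv(summary, out / "cohort_summary.tsv")
    run_log = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "thresholds": {
            "somatic": FilterThresholds().__dict__,
            "sv": SvThresholds().__dict__,
            "segmentation": SegmentationParams().__dict__,
        },
        "driver_exclusivity": driver_stats,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True, default=str)
    return summary
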