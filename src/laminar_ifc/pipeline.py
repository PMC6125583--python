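"""End-to-end orchestration: generate -> map -> tune -> parcellate ->
variability -> iFC -> group statistics, reproducible from a config + seed.

A single master seed fans out to per-stage child seeds through
``numpy.random.SeedSequence``; subjects are re-simulated deterministically
from their child seed whenever a stage needs the raw series again, so no
stage has to hold the whole cohort in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from laminar_ifc import io as lio
from laminar_ifc.group_stats import (
    DEPTH_PAIR_FAMILY,
    adjust_bonferroni,
    adjust_fdr,
    one_tailed_t,
    one_way_anova,
)
from laminar_ifc.ifc import (
    DELTA_BIN_EDGES,
    bandpass,
    bin_curve,
    block_basis,
    fit_selectivity,
    pairwise_ifc,
    pages_trend_test,
    regress_out,
    stimulus_design,
)
from laminar_ifc.phase_mapping import debias_latency, map_subject
from laminar_ifc.regions import RegionLabels, define_core, functional_roi, snr_matched_roi
from laminar_ifc.stimulus_surface import ChirpStimulus, smooth_on_sheet
from laminar_ifc.synthetic_data import (
    GroundTruth,
    SynthConfig,
    make_ground_truth,
    simulate_subject,
)
from laminar_ifc.tuning import estimate_tuning
from laminar_ifc.variability import inter_subject_sd, intra_subject_sd

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "config_from_yaml"]

log = logging.getLogger("laminar_ifc")

LN2 = np.log(2.0)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    z_threshold: float = 1.65
    roi_fdr_q: float = 0.01
    core_threshold_oct: float = 1.7
    smoothing_fwhm_mm: float = 0.0   # surface smoothing of the mapping series
    latency_debias: bool = True      # remove the clipped-bump phase bias
    preproc: str = "none"            # 'none' or 'bandpass_confounds'
    evoked_removal: str = "model"    # 'model' (sinusoid) or 'block' (mean block)
    n_model_harmonics: int = 1
    x_mode: str = "midpoint"         # bin representative for the decay fit
    features: tuple = ("frequency", "tuning")
    bin_edges: tuple = DELTA_BIN_EDGES
    compute_variability: bool = False
    variability_repeats: int = 20
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def config_from_yaml(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synth = SynthConfig(**{k: _coerce(k, v) for k, v in (raw.pop("synth", {}) or {}).items()})
    cfg = RunConfig(synth=synth, **{k: _coerce(k, v) for k, v in raw.items()})
    return cfg


def _coerce(key: str, value):
    if isinstance(value, list):
        return tuple(value)
    if key == "lambda_table" and isinstance(value, dict):
        return {float(d): dict(t) for d, t in value.items()}
    return value


@dataclass
class PipelineResult:
    config: RunConfig
    gt: GroundTruth
    stim: ChirpStimulus
    roi: np.ndarray
    regions: RegionLabels
    snr_matched: np.ndarray
    maps: dict                 # subject -> depth -> ActivationMap
    tuning: dict               # subject -> depth -> TuningMap
    curves: list               # IFCCurve per subject x depth x region x feature
    lambda_table: pd.DataFrame
    stats: pd.DataFrame
    variability: dict
    recovery: dict

    def lambda_values(self, feature: str, region: str, depth: float) -> np.ndarray:
        df = self.lambda_table
        sel = ((df.feature == feature) & (df.region == region)
               & (np.isclose(df.depth, depth)))
        return df.loc[sel].sort_values("subject")["lam"].to_numpy()


def _subject_seeds(cfg: RunConfig) -> tuple:
    state = np.random.SeedSequence(cfg.seed).generate_state(
        cfg.synth.n_subjects + 2, dtype=np.uint64)
    return int(state[0]), [int(s) for s in state[1:-1]], int(state[-1])


def _smooth_runs(runs, cfg: RunConfig, sheet):
    if cfg.smoothing_fwhm_mm <= 0:
        return runs
    out = []
    for r in runs:
        smoothed = smooth_on_sheet(r.data.T, cfg.smoothing_fwhm_mm, sheet).T
        out.append(dataclasses.replace(r, data=smoothed))
    return out


def subject_feature_maps(runs, stim: ChirpStimulus, cfg: RunConfig, sheet):
    """Activation and tuning maps per depth for one subject's runs."""
    mruns = _smooth_runs(runs, cfg, sheet)
    maps = map_subject(mruns, stim, z_threshold=cfg.z_threshold)
    tuning = {d: estimate_tuning(mruns, stim, depth=d) for d in sorted({r.depth for r in mruns})}
    if cfg.latency_debias:
        for d, amap in maps.items():
            debias_latency(amap, tuning[d].width_oct, stim)
    return maps, tuning


def subject_residuals(runs_at_depth, stim: ChirpStimulus, cfg: RunConfig) -> np.ndarray:
    """Per-run regression of the stimulus-locked model (+ optional
    preprocessing), residuals concatenated across runs.

    ``evoked_removal='model'`` regresses the sinusoidal activation model
    (plus ``n_model_harmonics - 1`` extra harmonics); ``'block'`` projects
    out the full block-periodic subspace (the per-vertex mean block).
    ``preproc='bandpass_confounds'`` bandpass-filters data and confounds (0.01-0.1 Hz,
    6th-order zero-phase Butterworth) and adds the six motion and the
    white-matter regressors to the design.  No spatial smoothing is ever
    applied on this path.
    """
    pieces = []
    for run in sorted(runs_at_depth, key=lambda r: r.run_id):
        ts = run.data
        n_t = ts.shape[1]
        if cfg.evoked_removal == "model":
            X = stimulus_design(n_t, run.tr, stim.presentation_freq,
                                n_harmonics=cfg.n_model_harmonics)
        elif cfg.evoked_removal == "block":
            X = block_basis(n_t, stim.samples_per_block)
        else:
            raise ValueError(f"unknown evoked_removal {cfg.evoked_removal!r}")
        res = regress_out(ts, X)

        if cfg.preproc == "bandpass_confounds":
            # activation model is removed *before* filtering: the zero-phase
            # filter's edge transients of the strong evoked component are not
            # block-periodic and would otherwise leak into every correlation
            res = bandpass(res, 0.01, 0.1, order=6, tr=run.tr)
            confounds = bandpass(run.nuisance, 0.01, 0.1, order=6, tr=run.tr)
            design = np.column_stack([np.ones(n_t), confounds.T])
            res = regress_out(res, design)
        elif cfg.preproc != "none":
            raise ValueError(f"unknown preproc mode {cfg.preproc!r}")
        pieces.append(res)
    return np.concatenate(pieces, axis=1)


def subject_curves(runs, maps, tuning, regions: RegionLabels,
                   stim: ChirpStimulus, cfg: RunConfig, subject: int) -> list:
    """Binned and fitted iFC curves for one subject, all depths x regions x features."""
    curves = []
    by_depth: dict = {}
    for r in runs:
        by_depth.setdefault(r.depth, []).append(r)
    for depth, depth_runs in sorted(by_depth.items()):
        res = subject_residuals(depth_runs, stim, cfg)
        amap, tmap = maps[depth], tuning[depth]
        features = {}
        if "frequency" in cfg.features:
            features["frequency"] = np.where(amap.valid, amap.logf / LN2, np.nan)
        if "tuning" in cfg.features:
            tw = np.where(amap.valid & tmap.valid, tmap.width_oct, np.nan)
            features["tuning"] = np.log2(tw)
        for feature, values in features.items():
            for region in ("core", "noncore"):
                mask = regions.mask(region)
                try:
                    delta, r_pairs = pairwise_ifc(res, mask, values,
                                                  max_delta=cfg.bin_edges[-1])
                    curve = bin_curve(delta, r_pairs, edges=cfg.bin_edges,
                                      subject=subject, depth=depth,
                                      region=region, feature=feature)
                    fit_selectivity(curve, x_mode=cfg.x_mode)
                except (ValueError, RuntimeError) as err:
                    log.warning("iFC skipped (subject %s depth %s %s %s): %s",
                                subject, depth, region, feature, err)
                    continue
                curves.append(curve)
    return curves


def _page_table(curves: list) -> np.ndarray | None:
    """Subject x bin matrix keeping only bins populated for every subject."""
    subjects = sorted({c.subject for c in curves})
    rows = [next(c for c in curves if c.subject == s) for s in subjects]
    mat = np.stack([c.r_mean for c in rows])
    keep = np.all(np.isfinite(mat), axis=0)
    if keep.sum() < 3:
        return None
    return mat[:, keep]


def group_statistics(result_curves: list, lambda_df: pd.DataFrame,
                     cfg: RunConfig) -> pd.DataFrame:
    """Page trend tests, depth ANOVAs, and region/depth-pair t-tests on lambda."""
    rows = []
    depths = sorted(lambda_df.depth.unique())
    features = sorted(lambda_df.feature.unique())

    for feature in features:
        for region in ("core", "noncore"):
            for depth in depths:
                sel = [c for c in result_curves
                       if c.feature == feature and c.region == region
                       and np.isclose(c.depth, depth)]
                table = _page_table(sel) if sel else None
                if table is None:
                    continue
                page = pages_trend_test(table, order="decreasing")
                rows.append(dict(test="page", feature=feature, region=region,
                                 depth_a=depth, depth_b=np.nan,
                                 statistic=page.L, df=table.shape,
                                 p=page.p, p_adj=np.nan, family=1))

            # lambda profile across depths (subjects as observations)
            base = (lambda_df.feature == feature) & (lambda_df.region == region)
            groups = [lambda_df.loc[base & np.isclose(lambda_df.depth, d), "lam"].to_numpy()
                      for d in depths]
            if len(depths) >= 2 and all(g.size >= 2 for g in groups):
                res = one_way_anova(groups)
                rows.append(dict(test="anova_depth", feature=feature,
                                 region=region, depth_a=np.nan, depth_b=np.nan,
                                 statistic=res.statistic, df=res.df, p=res.p,
                                 p_adj=np.nan, family=1))
                # post-hoc one-tailed deep > superficial over the fixed family
                fam, fam_p = [], []
                for da, db in DEPTH_PAIR_FAMILY:
                    if da not in depths or db not in depths:
                        continue
                    a = lambda_df.loc[base & np.isclose(lambda_df.depth, da)]
                    b = lambda_df.loc[base & np.isclose(lambda_df.depth, db)]
                    ab = a.merge(b, on="subject", suffixes=("_a", "_b"))
                    if len(ab) < 2:
                        continue
                    t = one_tailed_t(ab["lam_a"].to_numpy(), ab["lam_b"].to_numpy(),
                                     paired=True, direction="greater")
                    fam.append((da, db, t))
                    fam_p.append(t.p)
                if fam:
                    adj = adjust_fdr(fam_p)
                    for (da, db, t), p_adj in zip(fam, adj):
                        rows.append(dict(test="t_depth_pair", feature=feature,
                                         region=region, depth_a=da, depth_b=db,
                                         statistic=t.statistic, df=t.df, p=t.p,
                                         p_adj=p_adj, family=len(fam)))

        # core vs noncore per depth, Bonferroni over depths
        fam, fam_p = [], []
        for depth in depths:
            feat_depth = (lambda_df.feature == feature) & np.isclose(lambda_df.depth, depth)
            a = lambda_df.loc[feat_depth & (lambda_df.region == "core")]
            b = lambda_df.loc[feat_depth & (lambda_df.region == "noncore")]
            merged = a.merge(b, on="subject", suffixes=("_core", "_noncore"))
            if len(merged) < 2:
                continue
            t = one_tailed_t(merged["lam_core"].to_numpy(),
                             merged["lam_noncore"].to_numpy(),
                             paired=True, direction="greater")
            fam.append((depth, t))
            fam_p.append(t.p)
        if fam:
            adj = adjust_bonferroni(fam_p, m=len(fam))
            for (depth, t), p_adj in zip(fam, adj):
                rows.append(dict(test="t_core_gt_noncore", feature=feature,
                                 region="core-noncore", depth_a=depth,
                                 depth_b=np.nan, statistic=t.statistic,
                                 df=t.df, p=t.p, p_adj=p_adj, family=len(fam)))
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis on a synthetic cohort described by ``cfg``."""
    stim = ChirpStimulus()
    sheet = cfg.synth.sheet()
    gt_seed, subj_seeds, misc_seed = _subject_seeds(cfg)
    gt = make_ground_truth(sheet, cfg.synth, gt_seed)
    n_sub = cfg.synth.n_subjects
    log.info("pipeline start: %d subjects, grid %dx%d, hash %s",
             n_sub, sheet.n_rows, sheet.n_cols, cfg.config_hash())

    # stage 1: per-subject feature maps (simulate, map, discard the series)
    maps, tuning = {}, {}
    for s in range(n_sub):
        runs = simulate_subject(gt, stim, cfg.synth, s, subj_seeds[s])
        maps[s], tuning[s] = subject_feature_maps(runs, stim, cfg, sheet)
        log.info("mapped subject %d", s)

    depths = sorted(cfg.synth.depths)
    z_stack = np.stack([maps[s][d].z for s in range(n_sub) for d in depths])
    roi = functional_roi(z_stack, q=cfg.roi_fdr_q)

    tw_stack = np.stack([np.where(tuning[s][d].valid, tuning[s][d].width_oct, np.nan)
                         for s in range(n_sub) for d in depths])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_tw = np.nanmean(tw_stack, axis=0)
    regions = define_core(mean_tw, sheet, roi_mask=roi,
                          threshold=cfg.core_threshold_oct)
    snr_matched = (snr_matched_roi(regions.noncore, gt.snr, regions.core)
                   if regions.noncore.sum() >= regions.core.sum()
                   else np.zeros_like(regions.core))

    variability: dict = {}
    if n_sub >= 2:
        for d in depths:
            logf_stack = np.stack([maps[s][d].logf for s in range(n_sub)])
            tw_d = np.stack([np.where(tuning[s][d].valid, tuning[s][d].width_oct,
                                      np.nan) for s in range(n_sub)])
            variability[("inter", "logf", d)] = inter_subject_sd(logf_stack)
            variability[("inter", "tw", d)] = inter_subject_sd(tw_d)
    elif n_sub == 1:
        warnings.warn("single subject: group statistics will be skipped")

    if cfg.compute_variability:
        for s in range(n_sub):
            runs = simulate_subject(gt, stim, cfg.synth, s, subj_seeds[s])
            for d in depths:
                intra = intra_subject_sd([r for r in runs if r.depth == d], stim,
                                         n_repeats=cfg.variability_repeats,
                                         seed=misc_seed + s)
                variability[("intra", "logf", d, s)] = intra["logf"]
                variability[("intra", "tw", d, s)] = intra["tw"]

    # stage 2: iFC (re-simulate each subject deterministically)
    curves = []
    for s in range(n_sub):
        runs = simulate_subject(gt, stim, cfg.synth, s, subj_seeds[s])
        curves.extend(subject_curves(runs, maps[s], tuning[s], regions,
                                     stim, cfg, subject=s))
        log.info("iFC subject %d", s)

    lambda_df = pd.DataFrame([
        dict(subject=c.subject, depth=c.depth, region=c.region,
             feature=c.feature, r0=c.r0, lam=c.lam,
             n_bins=int(np.sum(c.n_pairs > 0)))
        for c in curves])

    stats_df = (group_statistics(curves, lambda_df, cfg)
                if n_sub >= 2 and not lambda_df.empty else pd.DataFrame())

    recovery = _recovery_diagnostics(gt, maps, tuning, lambda_df, regions, roi)
    result = PipelineResult(config=cfg, gt=gt, stim=stim, roi=roi,
                            regions=regions, snr_matched=snr_matched,
                            maps=maps, tuning=tuning, curves=curves,
                            lambda_table=lambda_df, stats=stats_df,
                            variability=variability, recovery=recovery)
    if cfg.outdir:
        _write_outputs(result)
    return result


def _recovery_diagnostics(gt: GroundTruth, maps: dict, tuning: dict,
                          lambda_df: pd.DataFrame, regions: RegionLabels,
                          roi: np.ndarray) -> dict:
    """Truth-vs-estimate summaries used by the acceptance checks."""
    pref_err, tw_rel_err = [], []
    for s, smaps in maps.items():
        for d, amap in smaps.items():
            sel = amap.valid & roi
            if sel.any():
                pref_err.append(np.abs(amap.logf[sel] - gt.logf[sel]) / LN2)
            tmap = tuning[s][d]
            tsel = tmap.valid & roi
            if tsel.any():
                tw_rel_err.append(np.abs(tmap.width_oct[tsel] - gt.tuning_width_oct[tsel])
                                  / gt.tuning_width_oct[tsel])
    out = {
        "pref_abs_err_oct_median": float(np.median(np.concatenate(pref_err)))
        if pref_err else np.nan,
        "tw_rel_err_median": float(np.median(np.concatenate(tw_rel_err)))
        if tw_rel_err else np.nan,
    }
    inter = np.intersect1d(np.flatnonzero(regions.core), np.flatnonzero(gt.core_mask))
    union = np.union1d(np.flatnonzero(regions.core), np.flatnonzero(gt.core_mask))
    out["core_jaccard"] = float(inter.size / union.size) if union.size else np.nan
    if not lambda_df.empty:
        rec = lambda_df.groupby(["feature", "region", "depth"])["lam"].mean()
        out["lambda_mean"] = {f"{f}/{r}/{d}": float(v)
                              for (f, r, d), v in rec.items()}
        out["lambda_true"] = {f"{d}/{r}": gt.lam(d, r)
                              for d in gt.lambda_table for r in ("core", "noncore")}
    return out


def _write_outputs(result: PipelineResult) -> None:
    cfg = result.config
    outdir = lio.ensure_dir(cfg.outdir)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    lio.write_maps(f"{outdir}/maps.h5", result.maps, result.tuning, attrs=meta)
    lio.maps_to_frame(result.maps).to_csv(f"{outdir}/maps.csv", index=False)
    lio.tuning_to_frame(result.tuning).to_csv(f"{outdir}/tuning.csv", index=False)

    sheet = result.gt.sheet
    rows, cols = sheet.row_col(np.arange(sheet.n_vertices))
    label = np.where(result.regions.core, "core",
                     np.where(result.regions.noncore, "noncore", "outside"))
    pd.DataFrame({"vertex": np.arange(sheet.n_vertices), "row": rows,
                  "col": cols, "label": label}).to_csv(
        f"{outdir}/regions.tsv", sep="\t", index=False)

    curve_rows = []
    for c in result.curves:
        for b in range(c.r_mean.size):
            curve_rows.append(dict(subject=c.subject, depth=c.depth,
                                   region=c.region, feature=c.feature, bin=b,
                                   x_mid=c.x_mid[b], x_mean=c.x_mean[b],
                                   r=c.r_mean[b], n_pairs=int(c.n_pairs[b]),
                                   r0=c.r0, **{"lambda": c.lam}))
    pd.DataFrame(curve_rows).to_csv(f"{outdir}/ifc_curves.csv", index=False)
    result.lambda_table.to_csv(f"{outdir}/lambda.csv", index=False)
    if not result.stats.empty:
        result.stats.to_csv(f"{outdir}/stats.csv", index=False)
    with open(f"{outdir}/summary.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg.to_dict(), **meta,
                        "recovery": result.recovery}, fh,
                       default_flow_style=False, sort_keys=False)
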