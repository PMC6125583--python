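"""Inter- and intra-subject variability of preference and tuning width.

Intra-subject variability follows the split-half scheme: the pooled blocks
of one subject are randomly partitioned into two complementary halves (each
holding 15 rising and 15 falling blocks), preference and tuning are
estimated in each half, the process is repeated ``n_repeats`` times, and the
SD is taken across the 2 x n_repeats estimates.
"""

from __future__ import annotations

import warnings

import numpy as np

from laminar_ifc.phase_mapping import average_phase, fourier_component, phase_to_latency
from laminar_ifc.stimulus_surface import ChirpStimulus, latency_to_log_frequency
from laminar_ifc.tuning import (
    _reorient_falling,
    extract_blocks,
    fit_gaussian_fwhm,
    fwhm_to_octaves,
)

__all__ = ["inter_subject_sd", "intra_subject_sd", "split_half_estimate"]

TWO_PI = 2.0 * np.pi


def inter_subject_sd(maps: np.ndarray) -> np.ndarray:
    """Vertex-wise SD across subjects (NaN-aware, sample SD with ddof=1).

    ``maps``: (n_subjects, n_vertices) with NaN marking invalid entries.
    Vertices with fewer than 2 valid subjects are NaN.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_vertices) array")
    n_valid = np.sum(np.isfinite(maps), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(maps, axis=0, ddof=1)
    sd[n_valid < 2] = np.nan
    return sd


def split_half_estimate(rising_blocks: np.ndarray, falling_blocks: np.ndarray,
                        stim: ChirpStimulus) -> tuple:
    """Preference (ln Hz) and tuning width (oct) from one set of blocks.

    ``*_blocks``: (n_vertices, n_blocks, samples_per_block).  Phase is taken
    from the single-block Fourier fundamental of the block mean; tuning from
    per-direction Gaussian fits, widths averaged.  Silent-tail latencies and
    failed fits return NaN.
    """
    f_p = stim.presentation_freq
    avg = {"rising": rising_blocks.mean(axis=1), "falling": falling_blocks.mean(axis=1)}
    phi_lag = {}
    for d, series in avg.items():
        comp = fourier_component(series, f_p, stim.tr)
        phi_lag[d] = (-comp.phase) % TWO_PI
    phi_avg = average_phase(phi_lag["rising"], phi_lag["falling"])
    latency = (phase_to_latency(phi_avg, f_p)
               - stim.silence_duration / 2.0) % stim.block_duration
    logf = latency_to_log_frequency(latency, stim)

    n_v = avg["rising"].shape[0]
    widths = np.full((2, n_v), np.nan)
    for i, d in enumerate(("rising", "falling")):
        block = avg[d] if d == "rising" else _reorient_falling(avg[d], stim)
        for v in range(n_v):
            fit = fit_gaussian_fwhm(block[v], stim.tr, stim.block_duration)
            if fit.ok:
                widths[i, v] = fwhm_to_octaves(fit.fwhm_s, stim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tw = np.nanmean(widths, axis=0)
    return logf, tw


def intra_subject_sd(runs, stim: ChirpStimulus, n_repeats: int = 20,
                     seed: int = 0, min_valid: int = 30) -> dict:
    """Split-half intra-subject variability maps for one subject at one depth.

    Pools the blocks of all runs per direction, then repeats ``n_repeats``
    times: a uniform random partition into two complementary halves (each
    with half the rising and half the falling blocks), estimates per half,
    and finally the SD across the 2 x n_repeats estimates per vertex.
    Vertices with fewer than ``min_valid`` valid estimates are NaN.

    Returns ``{"logf": sd_lnHz, "tw": sd_oct}``.
    """
    depths = {r.depth for r in runs}
    if len(depths) != 1:
        raise ValueError("runs span multiple depths")
    blocks = {"rising": [], "falling": []}
    for r in runs:
        blocks[r.direction].append(extract_blocks(r.data, stim))
    for d in blocks:
        if not blocks[d]:
            raise ValueError(f"no {d} blocks available")
        blocks[d] = np.concatenate(blocks[d], axis=1)
    n_half = {d: blocks[d].shape[1] // 2 for d in blocks}
    if any(blocks[d].shape[1] < 2 for d in blocks):
        raise ValueError("insufficient blocks for a split-half estimate")

    rng = np.random.default_rng(seed)
    ests = {"logf": [], "tw": []}
    for _ in range(n_repeats):
        perm = {d: rng.permutation(blocks[d].shape[1]) for d in blocks}
        for half in (0, 1):
            sel = {d: perm[d][: n_half[d]] if half == 0 else perm[d][n_half[d]:]
                   for d in blocks}
            logf, tw = split_half_estimate(blocks["rising"][:, sel["rising"]],
                                           blocks["falling"][:, sel["falling"]],
                                           stim)
            ests["logf"].append(logf)
            ests["tw"].append(tw)

    out = {}
    for key, stack in ests.items():
        arr = np.stack(stack)  # (2 * n_repeats, n_vertices)
        n_valid = np.sum(np.isfinite(arr), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(arr, axis=0, ddof=1)
        sd[n_valid < min(min_valid, arr.shape[0])] = np.nan
        out[key] = sd
    return out
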