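"""Spectral tuning width: Gaussian FWHM of the block-averaged response.

The averaged response to one chirp block is fitted by a four-parameter
Gaussian (baseline + amplitude * exp(-(t - mu)^2 / 2 sigma^2)); the FWHM in
seconds converts to octaves through the constant sweep rate (0.2 oct/s for
the default paradigm).
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.optimize import curve_fit

from laminar_ifc.stimulus_surface import ChirpStimulus

__all__ = [
    "TuningMap",
    "GaussianFit",
    "extract_blocks",
    "block_average",
    "fit_gaussian_fwhm",
    "fwhm_to_octaves",
    "estimate_tuning",
]

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class TuningMap:
    """Per-vertex tuning width (octaves), Gaussian center, and fit quality."""

    width_oct: np.ndarray
    center_s: np.ndarray
    r2: np.ndarray
    valid: np.ndarray
    depth: float = np.nan


@dataclass
class GaussianFit:
    center: float
    fwhm_s: float
    r2: float
    ok: bool


def extract_blocks(ts: np.ndarray, stim: ChirpStimulus) -> np.ndarray:
    """Segment a (vertices, time) series into (vertices, n_blocks, samples)."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    spb = stim.samples_per_block
    if ts.shape[-1] % spb != 0:
        raise ValueError("series length not divisible by block length")
    return ts.reshape(ts.shape[0], -1, spb)


def _reorient_falling(block: np.ndarray, stim: ChirpStimulus) -> np.ndarray:
    """Map a falling-direction block onto the rising time axis.

    Sample at time t of the falling sweep corresponds to rising time
    (chirp_duration - t) mod block_duration; with the default paradigm both
    grids coincide, so this is a circular index permutation.
    """
    spb = stim.samples_per_block
    c = stim.chirp_duration / stim.tr
    if abs(c - round(c)) > 1e-9:
        raise ValueError("chirp_duration must be a multiple of tr to reorient")
    k = np.arange(spb)
    j = (int(round(c)) - k) % spb
    out = np.empty_like(block)
    out[..., j] = block[..., k]
    return out


def block_average(ts: np.ndarray, stim: ChirpStimulus, direction: str) -> np.ndarray:
    """Mean over blocks for one direction, reoriented to the rising axis.

    Falling-direction blocks are time-reversed (about the chirp) onto the
    rising time axis so the two directions can be averaged without axis
    mismatch.  Returns (vertices, samples_per_block); 1-D input stays 1-D.
    """
    one_d = np.asarray(ts).ndim == 1
    blocks = extract_blocks(ts, stim)
    avg = blocks.mean(axis=1)
    if direction == "falling":
        avg = _reorient_falling(avg, stim)
    elif direction != "rising":
        raise ValueError(f"bad direction {direction!r}")
    return avg[0] if one_d else avg


def _gauss(t, baseline, amp, mu, sigma):
    return baseline + amp * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def _fit_gauss_points(t: np.ndarray, y: np.ndarray, sigma_max: float) -> GaussianFit:
    """Unconstrained LM fit of baseline + Gaussian to scattered (t, y) points."""
    if np.ptp(y) == 0:
        return GaussianFit(np.nan, np.nan, np.nan, False)
    p0 = [float(y.min()), float(np.ptp(y)), float(t[np.argmax(y)]), 5.0]
    try:
        popt, _ = curve_fit(_gauss, t, y, p0=p0, method="lm", maxfev=4000)
    except RuntimeError:
        return GaussianFit(np.nan, np.nan, np.nan, False)
    sigma = abs(float(popt[3]))
    if not (0 < sigma <= sigma_max) or popt[1] <= 0:
        return GaussianFit(np.nan, np.nan, np.nan, False)
    resid = y - _gauss(t, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return GaussianFit(center=float(popt[2]), fwhm_s=float(GAUSS_FWHM * sigma),
                       r2=float(r2), ok=True)


def fit_gaussian_fwhm(block: np.ndarray, tr: float,
                      block_duration: float | None = None) -> GaussianFit:
    """Least-squares Gaussian fit of one averaged block.

    The block is circularly rotated so its maximum sits mid-window before
    fitting (the hemodynamic delay can push the bump across the block
    boundary); the fitted center is mapped back modulo the block duration.
    Initialization: mu0 = argmax, sigma0 = 5 s, amp0 = max - min,
    baseline0 = min; fits with |sigma| > block_duration are flagged invalid.
    """
    block = np.asarray(block, dtype=float)
    n = block.size
    if n < 6:
        raise ValueError("need at least 6 samples to fit")
    if block_duration is None:
        block_duration = n * tr
    shift = n // 2 - int(np.argmax(block))
    rolled = np.roll(block, shift)
    t = np.arange(n) * tr
    fit = _fit_gauss_points(t, rolled, sigma_max=block_duration)
    if not fit.ok:
        return fit
    fit.center = (fit.center - shift * tr) % block_duration
    return fit


def fwhm_to_octaves(fwhm_seconds: float, stim: ChirpStimulus) -> float:
    """Temporal FWHM -> octaves via the constant sweep rate (0.2 oct/s)."""
    if np.any(np.asarray(fwhm_seconds) < 0):
        raise ValueError("fwhm_seconds must be >= 0")
    return fwhm_seconds * stim.chirp_rate_oct_per_s


def estimate_hemodynamic_delay(avg_blocks: dict, stim: ChirpStimulus) -> float:
    """Subject hemodynamic delay from the rising/falling phase lags.

    The rising-direction fundamental lag is (latency + delay); the falling
    lag is (chirp_duration - latency + delay); their sum isolates the delay.
    Amplitude-weighted circular mean across vertices.
    """
    from laminar_ifc.phase_mapping import fourier_component  # cycle-free import

    f_p = stim.presentation_freq
    lag, amp = {}, {}
    for d, series in avg_blocks.items():
        comp = fourier_component(series, f_p, stim.tr)
        lag[d] = ((-comp.phase) % (2 * np.pi)) / (2 * np.pi * f_p)
        amp[d] = comp.amplitude
    d_v = (lag["rising"] + lag["falling"] - stim.chirp_duration) / 2.0
    theta = 2 * np.pi * d_v / stim.block_duration
    w = amp["rising"] * amp["falling"]
    if w.sum() == 0:
        return 0.0
    mean_vec = np.sum(w * np.exp(1j * theta)) / w.sum()
    return float((np.angle(mean_vec) / (2 * np.pi) * stim.block_duration)
                 % stim.block_duration)


def estimate_tuning(runs, stim: ChirpStimulus, combine: str = "mean_fwhm",
                    depth: float | None = None) -> TuningMap:
    """Tuning-width map for one subject at one depth.

    The subject's hemodynamic delay is first estimated from the fundamental
    phase lags of the two directions; sample times are then unwrapped into
    stimulus coordinates (``u = (t - delay) mod block``), samples falling in
    the silent period are excluded, and a baseline + Gaussian model is
    fitted to the remaining in-chirp samples of each direction's block
    average.  This avoids the downward width bias that clipping the bump at
    the silence boundary would otherwise cause.  ``combine='mean_fwhm'``
    (default) averages the two per-direction FWHMs; ``combine='joint'``
    pools the in-chirp samples of both directions into a single fit.
    """
    if depth is not None:
        runs = [r for r in runs if r.depth == depth]
    else:
        depths = {r.depth for r in runs}
        if len(depths) != 1:
            raise ValueError("runs span multiple depths; pass depth=")
        depth = depths.pop()
    avg_run = {}
    for d in ("rising", "falling"):
        mats = [r.data for r in runs if r.direction == d]
        if not mats:
            raise ValueError(f"no {d} run at depth {depth}")
        avg_run[d] = np.mean(mats, axis=0)
    blocks = {d: block_average(avg_run[d], stim, "rising")  # no reorientation
              for d in avg_run}

    delay = estimate_hemodynamic_delay(avg_run, stim)
    spb = stim.samples_per_block
    t_block = np.arange(spb) * stim.tr
    u = (t_block - delay) % stim.block_duration
    in_chirp = u < stim.chirp_duration
    if in_chirp.sum() < 6:
        raise ValueError("too few in-chirp samples to fit")
    # map falling-direction stimulus time onto the rising axis
    coords = {"rising": u[in_chirp],
              "falling": stim.chirp_duration - u[in_chirp]}

    n_v = blocks["rising"].shape[0]
    sigma_max = stim.block_duration

    def _fit_points(t_pts, y_rows):
        fits = [_fit_gauss_points(t_pts, y_rows[v], sigma_max) for v in range(n_v)]
        w = np.array([fwhm_to_octaves(f.fwhm_s, stim) if f.ok else np.nan for f in fits])
        c = np.array([f.center if f.ok else np.nan for f in fits])
        q = np.array([f.r2 if f.ok else np.nan for f in fits])
        return w, c, q

    if combine == "joint":
        t_pts = np.concatenate([coords["rising"], coords["falling"]])
        y = np.concatenate([blocks["rising"][:, in_chirp],
                            blocks["falling"][:, in_chirp]], axis=1)
        width, center, r2 = _fit_points(t_pts, y)
    elif combine == "mean_fwhm":
        w_r, c_r, q_r = _fit_points(coords["rising"], blocks["rising"][:, in_chirp])
        w_f, _, q_f = _fit_points(coords["falling"], blocks["falling"][:, in_chirp])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            width = np.nanmean(np.stack([w_r, w_f]), axis=0)
            r2 = np.nanmean(np.stack([q_r, q_f]), axis=0)
        center = c_r
    else:
        raise ValueError(f"unknown combine mode {combine!r}")

    valid = np.isfinite(width) & (width > 0)
    return TuningMap(width_oct=np.where(valid, width, np.nan),
                     center_s=center, r2=r2, valid=valid, depth=depth)
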