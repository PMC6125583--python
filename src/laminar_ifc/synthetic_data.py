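"""Synthetic multi-subject, multi-depth, multi-run BOLD generator.

Forward model: each vertex responds to the chirp with a Gaussian spectral
profile in log2-frequency centered on its preferred frequency (FWHM = its
tuning width in octaves).  Under the constant sweep rate this is exactly a
Gaussian bump in time within each block.  The evoked component is shifted by
a subject-specific hemodynamic delay; residual noise is drawn from a
zero-mean multivariate normal whose within-region correlation decays
exponentially with the pairwise difference in log2 preferred frequency,
with depth- and region-specific decay constants.  All ground-truth
quantities are retained so downstream stages can be tested by parameter
recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from laminar_ifc.stimulus_surface import ChirpStimulus, CorticalSheet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "DepthRunSeries",
    "make_ground_truth",
    "simulate_run",
    "simulate_subject",
    "make_nuisance",
    "evoked_block",
]

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM / sigma for a Gaussian

RUN_DIRECTIONS = ("rising", "rising", "falling", "falling")


def _default_lambda_table() -> dict:
    # Core selectivity increases toward the deep depths; noncore is flat.
    return {
        0.1: {"core": 2.0, "noncore": 1.0},
        0.3: {"core": 1.8, "noncore": 1.0},
        0.5: {"core": 1.4, "noncore": 1.0},
        0.7: {"core": 1.2, "noncore": 1.0},
        0.9: {"core": 1.0, "noncore": 1.0},
    }


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort.

    The tonotopic gradient is mirror-symmetric along ``gradient_axis``: the
    preferred frequency runs from ``f_end`` at the sheet edge down to
    ``f_start`` at the midline and back up, spanning the full four octaves.
    The core is a contiguous strip of narrowly tuned vertices.
    """

    n_subjects: int = 5
    n_rows: int = 20
    n_cols: int = 33
    spacing_mm: float = 1.5
    depths: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    gradient_axis: str = "cols"
    gradient_f_low: float = 250.0   # preferred frequency at the midline
    gradient_f_high: float = 4000.0  # preferred frequency at the sheet edges
    core_rows: tuple = (7, 13)   # half-open [start, stop)
    core_cols: tuple = (9, 25)
    tw_core_oct: float = 1.4
    tw_noncore_oct: float = 1.9
    tw_row_spread_oct: float = 0.0  # within-region tuning-width gradient across rows
    amplitude: float = 1.0
    amplitude_row_slope: float = 0.0  # relative amplitude change per row (SNR gradient)
    noise_sd: float = 0.1
    rho0: float = 0.8
    lambda_table: dict = field(default_factory=_default_lambda_table)
    delay_range: tuple = (3.0, 7.0)
    drift_amplitude: float = 0.0
    confound_coupling: float = 0.0
    temporal_ar: float = 0.0  # optional AR(1) coefficient for the noise
    hrf_mode: str = "shift"   # 'shift' (default) or 'gamma'

    def sheet(self) -> CorticalSheet:
        return CorticalSheet(self.n_rows, self.n_cols, self.spacing_mm, tuple(self.depths))


@dataclass
class GroundTruth:
    """Generative truth for one synthetic cohort (shared across subjects)."""

    sheet: CorticalSheet
    logf: np.ndarray            # per-vertex true preference, ln Hz
    tuning_width_oct: np.ndarray
    core_mask: np.ndarray       # bool per vertex
    lambda_table: dict          # depth -> {'core': lam, 'noncore': lam}
    rho0: float
    noise_sd: float
    amplitude: np.ndarray       # per-vertex evoked peak amplitude
    delays: np.ndarray          # per-subject hemodynamic delay, seconds
    snr: np.ndarray             # per-vertex mean(evoked)/noise SD
    _chol_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.rho0 > 1:
            raise ValueError("need 0 < rho0 <= 1")
        if np.any(self.tuning_width_oct <= 0):
            raise ValueError("tuning widths must be positive")
        for d, t in self.lambda_table.items():
            for region, lam in t.items():
                if lam <= 0:
                    raise ValueError(f"lambda_table[{d}][{region}] must be > 0")

    @property
    def log2f(self) -> np.ndarray:
        return self.logf / np.log(2.0)

    def lam(self, depth: float, region: str) -> float:
        return float(self.lambda_table[depth][region])

    def noise_cholesky(self, depth: float) -> np.ndarray:
        """Cholesky factor of the unit-variance residual correlation matrix.

        Within each region Corr(v, w) = rho0 * exp(-lam * |dlog2f|) for
        v != w, 1 on the diagonal; zero across regions.  Cached per depth.
        """
        if depth in self._chol_cache:
            return self._chol_cache[depth]
        n = self.sheet.n_vertices
        corr = np.eye(n)
        x = self.log2f
        for region, mask in (("core", self.core_mask), ("noncore", ~self.core_mask)):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            lam = self.lam(depth, region)
            dx = np.abs(x[idx, None] - x[None, idx])
            block = self.rho0 * np.exp(-lam * dx)
            np.fill_diagonal(block, 1.0)
            corr[np.ix_(idx, idx)] = block
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            warnings.warn("residual correlation not positive definite; jittering diagonal")
            chol = np.linalg.cholesky(corr + 1e-8 * np.eye(n))
        self._chol_cache[depth] = chol
        return chol


@dataclass
class DepthRunSeries:
    """One run of one subject at one cortical depth: vertex x time BOLD."""

    subject: int
    depth: float
    run_id: str
    direction: str
    data: np.ndarray      # (n_vertices, n_timepoints)
    tr: float
    nuisance: np.ndarray  # (7, n_timepoints): 6 motion + 1 white-matter series

    def __post_init__(self) -> None:
        if self.direction not in ("rising", "falling"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be (vertices, timepoints)")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def make_ground_truth(sheet: CorticalSheet, cfg: SynthConfig, seed: int) -> GroundTruth:
    """Build the generative truth: tonotopy, tuning widths, core strip, delays.

    Deterministic given ``seed`` (only the per-subject delays are random).
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.divmod(np.arange(sheet.n_vertices), sheet.n_cols)

    n_oct = np.log2(cfg.gradient_f_high / cfg.gradient_f_low)
    if cfg.gradient_axis == "cols":
        axis_pos, axis_len = cols, sheet.n_cols
    elif cfg.gradient_axis == "rows":
        axis_pos, axis_len = rows, sheet.n_rows
    else:
        raise ValueError("gradient_axis must be 'cols' or 'rows'")
    mid = (axis_len - 1) / 2.0
    # mirror-symmetric: low frequency at the midline, high at both edges
    log2f = np.log2(cfg.gradient_f_low) + n_oct * np.abs(axis_pos - mid) / mid

    r0, r1 = cfg.core_rows
    c0, c1 = cfg.core_cols
    if not (0 <= r0 < r1 <= sheet.n_rows and 0 <= c0 < c1 <= sheet.n_cols):
        raise ValueError("core strip does not fit on the sheet")
    core_mask = (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)

    if cfg.tw_core_oct >= cfg.tw_noncore_oct:
        raise ValueError("core tuning width must be narrower than noncore")
    tw = np.where(core_mask, cfg.tw_core_oct, cfg.tw_noncore_oct).astype(float)
    if cfg.tw_row_spread_oct:
        # smooth within-region width variation, orthogonal to the tonotopic axis
        ramp = (rows - rows.min()) / max(rows.max() - rows.min(), 1) - 0.5
        tw = tw + cfg.tw_row_spread_oct * ramp
        if np.any(tw <= 0):
            raise ValueError("tw_row_spread_oct drives widths non-positive")

    amplitude = cfg.amplitude * (1.0 + cfg.amplitude_row_slope * (rows - rows.mean()))
    if np.any(amplitude <= 0):
        raise ValueError("amplitude_row_slope drives amplitudes non-positive")

    delays = rng.uniform(*cfg.delay_range, size=cfg.n_subjects)

    lambda_table = {float(d): dict(t) for d, t in cfg.lambda_table.items()}
    missing = set(cfg.depths) - set(lambda_table)
    if missing:
        raise ValueError(f"lambda_table missing depths {sorted(missing)}")

    gt = GroundTruth(
        sheet=sheet,
        logf=log2f * np.log(2.0),
        tuning_width_oct=tw.astype(float),
        core_mask=core_mask,
        lambda_table=lambda_table,
        rho0=cfg.rho0,
        noise_sd=cfg.noise_sd,
        amplitude=amplitude.astype(float),
        delays=delays,
        snr=np.zeros(sheet.n_vertices),
    )
    stim = ChirpStimulus()
    block = evoked_block(gt, stim, "rising", delay=0.0)
    with np.errstate(divide="ignore"):
        gt.snr = np.where(cfg.noise_sd > 0, block.mean(axis=1) / max(cfg.noise_sd, 1e-300),
                          np.inf)
    return gt


def _gamma_hrf(tr: float, duration: float = 25.0) -> np.ndarray:
    """Simple single-gamma HRF sampled at TR, unit area."""
    t = np.arange(0, duration, tr)
    shape, scale = 6.0, 0.9
    h = t ** (shape - 1) * np.exp(-t / scale)
    return h / h.sum()


def evoked_block(gt: GroundTruth, stim: ChirpStimulus, direction: str,
                 delay: float, hrf_mode: str = "shift") -> np.ndarray:
    """Noise-free evoked response over one block, sampled at TR.

    Returns (n_vertices, samples_per_block).  The Gaussian-in-time bump is
    centered at the moment the chirp sweeps each vertex's preferred
    frequency, zero during silence, then circularly shifted by ``delay``
    (the stimulus is block-periodic, so the delayed response wraps).
    """
    rate = stim.chirp_rate_oct_per_s
    latency = (gt.log2f - np.log2(stim.f_start)) / rate  # rising sweep time
    if direction == "falling":
        latency = stim.chirp_duration - latency
    elif direction != "rising":
        raise ValueError(f"bad direction {direction!r}")
    sigma_t = gt.tuning_width_oct / GAUSS_FWHM / rate

    if hrf_mode == "shift":
        t = (np.arange(stim.samples_per_block) * stim.tr - delay) % stim.block_duration
        bump = np.exp(-((t[None, :] - latency[:, None]) ** 2) / (2.0 * sigma_t[:, None] ** 2))
        bump[:, t >= stim.chirp_duration] = 0.0
        return gt.amplitude[:, None] * bump
    if hrf_mode == "gamma":
        # convolve the undelayed block-periodic response with a gamma HRF
        t = (np.arange(stim.samples_per_block) * stim.tr) % stim.block_duration
        bump = np.exp(-((t[None, :] - latency[:, None]) ** 2) / (2.0 * sigma_t[:, None] ** 2))
        bump[:, t >= stim.chirp_duration] = 0.0
        bump = gt.amplitude[:, None] * bump
        h = _gamma_hrf(stim.tr)
        spb = stim.samples_per_block
        # circular convolution (periodic stimulation)
        fb = np.fft.rfft(bump, axis=1)
        fh = np.fft.rfft(np.resize(h, spb))
        return np.fft.irfft(fb * fh, n=spb, axis=1)
    raise ValueError(f"unknown hrf_mode {hrf_mode!r}")


def make_nuisance(rng: np.random.Generator, n_timepoints: int) -> np.ndarray:
    """Six motion-like slow random walks plus one AR(1) white-matter series.

    Each series is standardized to zero mean, unit SD: (7, T).
    """
    series = np.empty((7, n_timepoints))
    for i in range(6):
        w = np.cumsum(rng.standard_normal(n_timepoints))
        series[i] = w
    wm = np.empty(n_timepoints)
    wm[0] = rng.standard_normal()
    for t in range(1, n_timepoints):
        wm[t] = 0.5 * wm[t - 1] + rng.standard_normal()
    series[6] = wm
    series -= series.mean(axis=1, keepdims=True)
    series /= series.std(axis=1, keepdims=True)
    return series


def simulate_run(gt: GroundTruth, stim: ChirpStimulus, cfg: SynthConfig,
                 direction: str, subject: int, depth: float,
                 rng: np.random.Generator, run_id: str = "run-1",
                 nuisance: Optional[np.ndarray] = None) -> DepthRunSeries:
    """Simulate one run at one depth for one subject.

    Evoked bump + exponential-structured multivariate-normal noise
    (+ optional drift and nuisance-coupled components).
    """
    n_t = stim.samples_per_run
    block = evoked_block(gt, stim, direction, gt.delays[subject], cfg.hrf_mode)
    data = np.tile(block, (1, stim.n_blocks_per_run)).astype(float)

    if gt.noise_sd > 0:
        chol = gt.noise_cholesky(depth)
        eps = rng.standard_normal((gt.sheet.n_vertices, n_t))
        if cfg.temporal_ar > 0:
            a = cfg.temporal_ar
            for t in range(1, n_t):
                eps[:, t] = a * eps[:, t - 1] + np.sqrt(1 - a * a) * eps[:, t]
        data += gt.noise_sd * (chol @ eps)

    t_sec = np.arange(n_t) * stim.tr
    if cfg.drift_amplitude > 0:
        f_drift = rng.uniform(0.001, 0.004, size=gt.sheet.n_vertices)
        phase = rng.uniform(0, 2 * np.pi, size=gt.sheet.n_vertices)
        slope = rng.uniform(-1, 1, size=gt.sheet.n_vertices)
        drift = np.sin(2 * np.pi * f_drift[:, None] * t_sec[None, :] + phase[:, None])
        drift += slope[:, None] * (t_sec[None, :] / t_sec[-1] - 0.5)
        data += cfg.drift_amplitude * drift

    if nuisance is None:
        nuisance = make_nuisance(rng, n_t)
    if cfg.confound_coupling > 0:
        weights = rng.standard_normal((gt.sheet.n_vertices, nuisance.shape[0]))
        data += cfg.confound_coupling * (weights @ nuisance)

    return DepthRunSeries(subject=subject, depth=depth, run_id=run_id,
                          direction=direction, data=data, tr=stim.tr,
                          nuisance=nuisance)


def simulate_subject(gt: GroundTruth, stim: ChirpStimulus, cfg: SynthConfig,
                     subject: int, seed: int) -> list:
    """Simulate the full 4-run (2 rising, 2 falling) session at every depth.

    Nuisance series are shared across depths of the same run (they model
    whole-head confounds); noise draws are independent per depth.  Two calls
    with the same seed produce identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    runs = []
    for i, direction in enumerate(RUN_DIRECTIONS):
        nuis = make_nuisance(rng, stim.samples_per_run)
        for depth in cfg.depths:
            runs.append(simulate_run(gt, stim, cfg, direction, subject, depth,
                                     rng, run_id=f"run-{i + 1}", nuisance=nuis))
    return runs
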