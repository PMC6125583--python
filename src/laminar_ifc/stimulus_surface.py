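"""Stimulus paradigm, frequency/latency coordinate system, and sheet geometry.

The stimulus is a logarithmic tone chirp (250 -> 4000 Hz over 20 s, i.e. four
octaves at a constant 0.2 oct/s) followed by 10 s of silence, repeated in
30-s blocks.  The cortical "surface" used throughout is a regular 2-D vertex
grid replicated at five normalized cortical depths; it is a geometric
stand-in with columnar vertex correspondence across depths, not a mesh
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ChirpStimulus",
    "CorticalSheet",
    "chirp_frequency_at",
    "latency_to_log_frequency",
    "smooth_on_sheet",
    "SILENCE",
]

#: Sentinel returned by :func:`chirp_frequency_at` during the silent period.
SILENCE = -1.0

DEFAULT_DEPTHS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class ChirpStimulus:
    """Parameters of the chirp/silence block paradigm.

    Defaults encode the 20-s four-octave chirp (250-4000 Hz) plus 10-s
    silence, 15 blocks per run, sampled at TR = 2.5 s.
    """

    f_start: float = 250.0
    f_end: float = 4000.0
    chirp_duration: float = 20.0
    silence_duration: float = 10.0
    n_blocks_per_run: int = 15
    tr: float = 2.5

    def __post_init__(self) -> None:
        if self.f_start <= 0 or self.f_end <= self.f_start:
            raise ValueError("need 0 < f_start < f_end")
        if self.chirp_duration <= 0 or self.silence_duration < 0:
            raise ValueError("durations must be positive")
        if self.tr <= 0 or self.n_blocks_per_run < 1:
            raise ValueError("tr must be > 0 and n_blocks_per_run >= 1")

    @property
    def block_duration(self) -> float:
        """Length of one stimulation block in seconds (chirp + silence)."""
        return self.chirp_duration + self.silence_duration

    @property
    def presentation_freq(self) -> float:
        """Stimulus repetition rate, 1 / block duration (Hz)."""
        return 1.0 / self.block_duration

    @property
    def n_octaves(self) -> float:
        return float(np.log2(self.f_end / self.f_start))

    @property
    def chirp_rate_oct_per_s(self) -> float:
        """Constant sweep rate in octaves per second (4 oct / 20 s = 0.2)."""
        return self.n_octaves / self.chirp_duration

    @property
    def samples_per_block(self) -> int:
        spb = self.block_duration / self.tr
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("block_duration must be a multiple of tr")
        return int(round(spb))

    @property
    def samples_per_run(self) -> int:
        return self.samples_per_block * self.n_blocks_per_run

    @property
    def run_duration(self) -> float:
        return self.block_duration * self.n_blocks_per_run


@dataclass(frozen=True)
class CorticalSheet:
    """Regular 2-D vertex grid replicated at each cortical depth.

    Vertices are indexed row-major (``v = row * n_cols + col``) and the same
    indexing applies at every depth (columnar correspondence).  Neighborhood
    structure is the 4-neighborhood of the grid.
    """

    n_rows: int
    n_cols: int
    spacing_mm: float = 1.5
    depths: tuple = field(default=DEFAULT_DEPTHS)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if len(set(self.depths)) != len(self.depths):
            raise ValueError("duplicate depth labels")
        object.__setattr__(self, "depths", tuple(float(d) for d in self.depths))

    @property
    def n_vertices(self) -> int:
        return self.n_rows * self.n_cols

    def vertex_id(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def row_col(self, vertex):
        v = np.asarray(vertex)
        return v // self.n_cols, v % self.n_cols

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a vertex-indexed vector to the (n_rows, n_cols) grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_vertices:
            raise ValueError("vertex vector length != n_vertices")
        return values.reshape(values.shape[:-1] + (self.n_rows, self.n_cols))

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid)
        return grid.reshape(grid.shape[:-2] + (self.n_vertices,))

    def adjacency_edges(self) -> np.ndarray:
        """Symmetric 4-neighborhood as an (n_edges, 2) array, i < j, no self-edges."""
        r = np.arange(self.n_rows)
        c = np.arange(self.n_cols)
        rr, cc = np.meshgrid(r, c, indexing="ij")
        v = self.vertex_id(rr, cc)
        right = np.stack([v[:, :-1].ravel(), v[:, 1:].ravel()], axis=1)
        down = np.stack([v[:-1, :].ravel(), v[1:, :].ravel()], axis=1)
        return np.concatenate([right, down], axis=0)


def chirp_frequency_at(t, direction: str, stim: ChirpStimulus):
    """Instantaneous chirp frequency (Hz) at time ``t`` within a block.

    Rising: ``f(t) = f_start * (f_end/f_start)**(t/chirp_duration)``; falling
    is the time reverse within the chirp.  Times in the silent tail return
    the :data:`SILENCE` sentinel.  ``t`` outside ``[0, block_duration)``
    raises ``ValueError``.
    """
    if direction not in ("rising", "falling"):
        raise ValueError(f"unknown direction {direction!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= stim.block_duration):
        raise ValueError("t outside [0, block_duration)")
    tau = t_arr if direction == "rising" else stim.chirp_duration - t_arr
    ratio = stim.f_end / stim.f_start
    freq = stim.f_start * ratio ** (tau / stim.chirp_duration)
    out = np.where(t_arr < stim.chirp_duration, freq, SILENCE)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def latency_to_log_frequency(latency, stim: ChirpStimulus):
    """Natural log of the rising-chirp frequency at a response latency.

    Latencies in the silent tail (``chirp_duration <= latency <
    block_duration``) have no stimulus frequency; they are returned as NaN
    (flagged invalid) rather than raising.
    """
    lat = np.asarray(latency, dtype=float)
    if np.any(lat < 0) or np.any(lat >= stim.block_duration):
        raise ValueError("latency outside [0, block_duration)")
    ln_fs = np.log(stim.f_start)
    ln_ratio = np.log(stim.f_end / stim.f_start)
    logf = ln_fs + ln_ratio * lat / stim.chirp_duration
    out = np.where(lat < stim.chirp_duration, logf, np.nan)
    if np.isscalar(latency) or lat.ndim == 0:
        return float(out)
    return out


def gaussian_kernel_2d(fwhm_mm: float, spacing_mm: float) -> np.ndarray:
    """Truncated, normalized 2-D Gaussian kernel on the grid.

    sigma = fwhm / (2 sqrt(2 ln 2)); truncated at ceil(4 sigma) grid steps.
    """
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing_mm
    radius = int(np.ceil(4.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    dx, dy = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth_on_sheet(values: np.ndarray, fwhm_mm: float, sheet: CorticalSheet) -> np.ndarray:
    """Gaussian smoothing of a vertex map along the sheet.

    Uses reflective boundaries (mass preserving for NaN-free maps) and
    normalized convolution for NaN vertices: NaNs carry no kernel mass and
    stay NaN in the output.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != sheet.n_vertices:
        raise ValueError("map length != vertex count")
    if fwhm_mm == 0:
        return values.copy()
    kernel = gaussian_kernel_2d(fwhm_mm, sheet.spacing_mm)

    def _smooth_one(vec: np.ndarray) -> np.ndarray:
        grid = sheet.to_grid(vec)
        nan = np.isnan(grid)
        if nan.any():
            filled = np.where(nan, 0.0, grid)
            mass = ndimage.convolve((~nan).astype(float), kernel, mode="reflect")
            num = ndimage.convolve(filled, kernel, mode="reflect")
            with np.errstate(invalid="ignore", divide="ignore"):
                out = num / mass
            out[nan] = np.nan
        else:
            out = ndimage.convolve(grid, kernel, mode="reflect")
        return sheet.from_grid(out)

    if values.ndim == 1:
        return _smooth_one(values)
    flat = values.reshape(-1, sheet.n_vertices)
    return np.stack([_smooth_one(v) for v in flat]).reshape(values.shape)
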