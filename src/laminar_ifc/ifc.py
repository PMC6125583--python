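"""Residual intrinsic functional connectivity (iFC) and selectivity fitting.

After the stimulus-locked activation model (and optional confounds) are
regressed out, iFC is the Pearson correlation of residual series between
vertex pairs within a region at one depth.  Pairs are binned by their
feature difference (octaves), per-bin correlations are Fisher-z averaged,
and selectivity is the decay constant of ``y = R0 * exp(-lambda * x)``
fitted to the binned curve.  Includes the robustness preprocessing
(Butterworth bandpass + motion/white-matter regression) and Page's trend
test for monotonically decreasing curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal, stats
from scipy.optimize import curve_fit

__all__ = [
    "DELTA_BIN_EDGES",
    "IFCCurve",
    "PageResult",
    "stimulus_design",
    "block_basis",
    "regress_out",
    "bandpass",
    "pairwise_ifc",
    "bin_curve",
    "fit_selectivity",
    "pages_trend_test",
]

#: Feature-difference bin edges in octaves (half-open bins, [0, 3) covered).
DELTA_BIN_EDGES = (0.0, 0.1875, 0.375, 0.75, 1.5, 3.0)

TWO_PI = 2.0 * np.pi
_R_CAP = 1.0 - 1e-12


@dataclass
class IFCCurve:
    """Binned feature-difference vs iFC curve with its exponential fit."""

    edges: np.ndarray
    r_mean: np.ndarray   # per-bin Fisher-z-averaged correlation (NaN if empty)
    n_pairs: np.ndarray
    x_mid: np.ndarray
    x_mean: np.ndarray   # mean pair delta per bin
    r0: float = np.nan
    lam: float = np.nan
    subject: int = -1
    depth: float = np.nan
    region: str = ""
    feature: str = "frequency"

    def x(self, mode: str = "midpoint") -> np.ndarray:
        if mode == "midpoint":
            return self.x_mid
        if mode == "pair_mean":
            return self.x_mean
        raise ValueError(f"unknown x mode {mode!r}")


def stimulus_design(n_timepoints: int, tr: float, f_p: float,
                    n_harmonics: int = 1) -> np.ndarray:
    """Design matrix spanning the activation model: intercept + cos/sin pairs.

    A per-vertex sinusoid ``a cos(2 pi f_p t + phi)`` is a linear
    combination of the shared cosine and sine columns, so OLS against this
    design removes the activation model with vertex-specific amplitude and
    phase.  ``n_harmonics > 1`` additionally spans harmonics of ``f_p``.
    """
    t = np.arange(n_timepoints) * tr
    cols = [np.ones(n_timepoints)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(TWO_PI * k * f_p * t))
        cols.append(np.sin(TWO_PI * k * f_p * t))
    return np.column_stack(cols)


def block_basis(n_timepoints: int, samples_per_block: int) -> np.ndarray:
    """Block-phase indicator basis spanning every block-periodic signal.

    Regressing against it is equivalent to subtracting each vertex's mean
    block, i.e. complete removal of the stimulus-locked (evoked) component.
    The intercept lies in its span.
    """
    if n_timepoints % samples_per_block != 0:
        raise ValueError("series length not divisible by block length")
    phase = np.arange(n_timepoints) % samples_per_block
    return (phase[:, None] == np.arange(samples_per_block)[None, :]).astype(float)


def regress_out(ts: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of each vertex series against the design matrix.

    ``ts``: (n_vertices, T); ``regressors``: (T, p), full rank, with the
    intercept in its column span.  Residuals are orthogonal to every
    regressor.  Rank deficiency raises, naming the offending columns.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    X = np.asarray(regressors, dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.shape[1]:
        raise ValueError("regressors must be (n_timepoints, p)")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, rank)
        raise ValueError(f"rank-deficient design: columns {bad} are collinear")
    ones = np.ones(X.shape[0])
    beta0, res0, *_ = np.linalg.lstsq(X, ones, rcond=None)
    if res0.size and res0[0] > 1e-8 * X.shape[0]:
        raise ValueError("design must contain the intercept in its span")
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def _collinear_columns(X: np.ndarray, rank: int) -> list:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [int(i) for i in np.flatnonzero(diag <= tol)] or list(range(rank, X.shape[1]))


def bandpass(ts: np.ndarray, low: float = 0.01, high: float = 0.1,
             order: int = 6, tr: float = 2.5) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the time axis.

    Forward-backward (``sosfiltfilt``) application of an ``order``-th order
    design, so the effective magnitude order is doubled.  The band must lie
    strictly inside (0, Nyquist).
    """
    nyq = 0.5 / tr
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) outside (0, Nyquist={nyq})")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


def pairwise_ifc(residuals: np.ndarray, region_mask: np.ndarray,
                 feature_oct: np.ndarray, max_delta: float = 3.0) -> tuple:
    """All unordered within-region vertex pairs: (delta octaves, Pearson r).

    ``feature_oct`` is the per-vertex feature on an octave scale (log2
    frequency preference, or log2 tuning width); NaN entries are excluded.
    Pairs with ``delta >= max_delta`` are dropped.
    """
    residuals = np.asarray(residuals, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    feature_oct = np.asarray(feature_oct, dtype=float)
    keep = region_mask & np.isfinite(feature_oct)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError("fewer than 2 valid vertices in region")
    corr = np.corrcoef(residuals[idx])
    f = feature_oct[idx]
    iu, ju = np.triu_indices(idx.size, k=1)
    delta = np.abs(f[iu] - f[ju])
    r = corr[iu, ju]
    sel = delta < max_delta
    return delta[sel], r[sel]


def bin_curve(delta: np.ndarray, r: np.ndarray,
              edges=DELTA_BIN_EDGES, **meta) -> IFCCurve:
    """Bin pair correlations into half-open delta bins, Fisher-z averaged.

    Per bin the correlations are atanh-transformed, averaged, and
    tanh-transformed back.  Empty bins are NaN with ``n_pairs = 0`` and are
    excluded from any subsequent fit.
    """
    delta = np.asarray(delta, dtype=float)
    r = np.asarray(r, dtype=float)
    if delta.size == 0:
        raise ValueError("no pairs to bin")
    edges = np.asarray(edges, dtype=float)
    k = edges.size - 1
    which = np.digitize(delta, edges) - 1
    r_mean = np.full(k, np.nan)
    x_mean = np.full(k, np.nan)
    n_pairs = np.zeros(k, dtype=int)
    z = np.arctanh(np.clip(r, -_R_CAP, _R_CAP))
    for b in range(k):
        sel = which == b
        n_pairs[b] = int(sel.sum())
        if n_pairs[b]:
            r_mean[b] = np.tanh(z[sel].mean())
            x_mean[b] = delta[sel].mean()
    return IFCCurve(edges=edges, r_mean=r_mean, n_pairs=n_pairs,
                    x_mid=0.5 * (edges[:-1] + edges[1:]), x_mean=x_mean, **meta)


def _exp_decay(x, r0, lam):
    return r0 * np.exp(-lam * x)


def fit_selectivity(curve: IFCCurve, x_mode: str = "midpoint") -> tuple:
    """Nonlinear least squares of ``y = R0 exp(-lambda x)`` on the binned curve.

    ``lambda`` is constrained to be >= 0.  Initialization is log-linear on
    the positive bins; on failure the fit retries from a unit-decay start.
    Requires at least 3 non-empty bins.  Returns ``(R0, lambda)`` and stores
    them on the curve.
    """
    good = np.isfinite(curve.r_mean) & (curve.n_pairs > 0)
    if good.sum() < 3:
        raise ValueError("need at least 3 non-empty bins to fit")
    x = curve.x(x_mode)[good]
    y = curve.r_mean[good]

    inits = []
    if np.all(y > 0):
        slope, intercept = np.polyfit(x, np.log(y), 1)
        inits.append((np.exp(intercept), max(-slope, 0.0)))
    inits.append((y[0], 1.0))
    inits.append((y[0] if y[0] != 0 else 0.1, 0.0))

    last_err: Optional[Exception] = None
    for r0_0, lam_0 in inits:
        try:
            popt, _ = curve_fit(_exp_decay, x, y, p0=[r0_0, lam_0],
                                bounds=([-np.inf, 0.0], [np.inf, np.inf]),
                                maxfev=5000)
            curve.r0, curve.lam = float(popt[0]), float(popt[1])
            return curve.r0, curve.lam
        except RuntimeError as err:  # pragma: no cover - rare
            last_err = err
    raise RuntimeError(f"exponential fit failed to converge: {last_err}")


@dataclass
class PageResult:
    L: float
    p: float
    method: str
    z: float = np.nan


def _page_L(table: np.ndarray, coef: np.ndarray) -> float:
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    return float(np.sum(ranks * coef[None, :]))


def _exact_page_distribution(n_subjects: int, k: int, coef: np.ndarray):
    """Exact null distribution of L by convolving per-subject score counts."""
    scores = [int(np.dot(coef, perm)) for perm in itertools.permutations(range(1, k + 1))]
    lo, hi = min(scores), max(scores)
    base = np.zeros(hi - lo + 1)
    for s in scores:
        base[s - lo] += 1
    base /= base.sum()
    dist = base.copy()
    for _ in range(n_subjects - 1):
        dist = np.convolve(dist, base)
    offset = n_subjects * lo
    return dist, offset


def pages_trend_test(table: np.ndarray, order: str = "decreasing",
                     method: str = "auto", n_perm: int = 20000,
                     seed: int = 0) -> PageResult:
    """Page's trend test for a hypothesized monotone ordering of k conditions.

    ``table``: (n_subjects, k) with no missing cells.  Within-subject ranks
    (average ranks on ties) are weighted by the hypothesized rank of each
    column (``k..1`` for ``order='decreasing'``, ``1..k`` for increasing);
    ``L`` is the summed product.  One-sided p-value: normal approximation
    for N >= 12 (or ``method='asymptotic'``), exact convolution of the
    per-subject score distribution for small tie-free tables, Monte-Carlo
    permutation otherwise.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 3:
        raise ValueError("need an (n_subjects, k >= 3) table")
    if np.any(~np.isfinite(table)):
        raise ValueError("missing cells are not allowed")
    n, k = table.shape
    if order == "decreasing":
        coef = np.arange(k, 0, -1, dtype=float)
    elif order == "increasing":
        coef = np.arange(1, k + 1, dtype=float)
    else:
        raise ValueError("order must be 'decreasing' or 'increasing'")

    L = _page_L(table, coef)
    has_ties = any(np.unique(row).size < k for row in table)

    if method == "auto":
        if n >= 12:
            method = "asymptotic"
        elif not has_ties and k <= 8:
            method = "exact"
        else:
            method = "permutation"

    if method == "asymptotic":
        mean = n * k * (k + 1) ** 2 / 4.0
        var = n * k**2 * (k + 1) ** 2 * (k - 1) / 144.0
        z = (L - mean) / np.sqrt(var)
        return PageResult(L=L, p=float(stats.norm.sf(z)), method=method, z=z)
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free rows")
        dist, offset = _exact_page_distribution(n, k, coef)
        idx = int(np.ceil(L)) - offset
        p = float(dist[max(idx, 0):].sum()) if idx < dist.size else 0.0
        return PageResult(L=L, p=min(p, 1.0), method=method)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = np.stack([rng.permutation(row) for row in table])
            if _page_L(perm, coef) >= L:
                count += 1
        return PageResult(L=L, p=(count + 1) / (n_perm + 1), method=method)
    raise ValueError(f"unknown method {method!r}")
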