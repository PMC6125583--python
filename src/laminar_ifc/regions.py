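"""Functional ROI, core/noncore parcellation, and the SNR-matched control ROI.

The core is defined once at the group level — a spatially continuous,
narrowly tuned patch (tuning width below 1.7 octaves) in the across-subject,
across-depth mean tuning map — and applied identically at every depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from laminar_ifc.stimulus_surface import CorticalSheet

__all__ = ["RegionLabels", "functional_roi", "define_core", "snr_matched_roi",
           "CORE_TW_THRESHOLD_OCT"]

#: Tuning-width threshold (octaves) separating core from noncore.
CORE_TW_THRESHOLD_OCT = 1.7


@dataclass
class RegionLabels:
    """Per-vertex parcellation: core / noncore / outside (same at all depths)."""

    core: np.ndarray     # bool per vertex
    noncore: np.ndarray  # bool per vertex
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.core & self.noncore):
            raise ValueError("core and noncore overlap")

    @property
    def outside(self) -> np.ndarray:
        return ~(self.core | self.noncore)

    def mask(self, region: str) -> np.ndarray:
        if region not in ("core", "noncore"):
            raise ValueError(f"unknown region {region!r}")
        return self.core if region == "core" else self.noncore


def functional_roi(z_maps: np.ndarray, q: float = 0.01,
                   anatomical_mask: np.ndarray | None = None) -> np.ndarray:
    """Group functional ROI by Benjamini-Hochberg FDR on mean activation z.

    ``z_maps``: (n_subjects, n_vertices) calibrated z scores (or a single
    map).  One-tailed p = normal upper tail of the across-subject mean z;
    BH step-up at level ``q`` over the vertices inside ``anatomical_mask``
    (the multiple-testing family).  Returns a boolean vertex mask.
    """
    z_maps = np.atleast_2d(np.asarray(z_maps, dtype=float))
    mean_z = z_maps.mean(axis=0)
    n_vertices = mean_z.size
    if anatomical_mask is None:
        anatomical_mask = np.ones(n_vertices, dtype=bool)
    anatomical_mask = np.asarray(anatomical_mask, dtype=bool)

    idx = np.flatnonzero(anatomical_mask)
    p = stats.norm.sf(mean_z[idx])
    reject = stats.false_discovery_control(p, method="bh") <= q
    out = np.zeros(n_vertices, dtype=bool)
    out[idx[reject]] = True
    if not out.any():
        warnings.warn("functional ROI is empty at the requested FDR level")
    return out


def define_core(mean_tuning: np.ndarray, sheet: CorticalSheet,
                roi_mask: np.ndarray | None = None,
                threshold: float = CORE_TW_THRESHOLD_OCT) -> RegionLabels:
    """Parcellate the ROI into core and noncore.

    Vertices with mean tuning width strictly below ``threshold`` are
    candidates; the largest 4-connected component is the core (ties broken
    by the component found first in row-major order).  The remainder of the
    ROI is noncore.  Raises if no vertex is below threshold.
    """
    mean_tuning = np.asarray(mean_tuning, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(sheet.n_vertices, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)

    narrow = roi_mask & np.isfinite(mean_tuning) & (mean_tuning < threshold)
    if not narrow.any():
        raise ValueError("no vertex below the tuning-width threshold; "
                         "parcellation unusable")
    grid = sheet.to_grid(narrow.astype(np.int8))
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n_comp = ndimage.label(grid, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1))
    best = 1 + int(np.argmax(sizes))  # argmax -> first maximal label (row-major)
    core = sheet.from_grid(labels == best).astype(bool)
    noncore = roi_mask & ~core
    return RegionLabels(core=core, noncore=noncore,
                        provenance={"threshold_oct": threshold,
                                    "component_size": int(core.sum()),
                                    "n_components": int(n_comp)})


def snr_matched_roi(noncore_mask: np.ndarray, snr: np.ndarray,
                    core_mask: np.ndarray) -> np.ndarray:
    """Noncore control ROI with SNR matched to the core, same vertex count.

    Greedy selection of the |core| noncore vertices whose SNR is nearest the
    core-mean SNR; ties broken by vertex index.
    """
    noncore_mask = np.asarray(noncore_mask, dtype=bool)
    core_mask = np.asarray(core_mask, dtype=bool)
    snr = np.asarray(snr, dtype=float)
    if np.any(np.isnan(snr[noncore_mask | core_mask])):
        raise ValueError("SNR missing for some vertices")
    n_core = int(core_mask.sum())
    if int(noncore_mask.sum()) < n_core:
        raise ValueError("noncore smaller than core; cannot match")
    target = snr[core_mask].mean()
    cand = np.flatnonzero(noncore_mask)
    order = np.lexsort((cand, np.abs(snr[cand] - target)))
    chosen = cand[order[:n_core]]
    out = np.zeros_like(noncore_mask)
    out[chosen] = True
    return out
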