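"""Cell-level protein abundance quantification from multiplexed channel images.

Multiplexed fluorescence channels suffer from salt-and-pepper noise, channel-
to-channel intensity differences and regional illumination gradients, so no
single global threshold separates signal from background.  Each channel is
therefore binarized adaptively: a pixel is positive iff its intensity strictly
exceeds the Gaussian-weighted mean of its local window plus a per-channel
constant (by default the channel's global intensity standard deviation).  The
abundance A(c, p) of protein p in cell c is then the fraction of positive
pixels of channel p inside segment c.

Membrane completion handles nuclei for which no cell membrane was segmented:
the mean ratio rho of cell to nucleus equivalent radii over the matched pairs
is estimated, and each orphan nucleus receives a disc of radius
rho * r_nucleus around its centroid, never overwriting existing segments;
pixels contested by two discs go to the nearer nucleus centroid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 201


def gaussian_window_kernel(window: int, sigma: float | None = None) -> np.ndarray:
    """Normalized 1-D Gaussian kernel spanning a window of odd width.

    When *sigma* is omitted, the width-dependent convention
    ``sigma = 0.3 * ((window - 1) * 0.5 - 1) + 0.8`` is used, the standard
    choice for deriving a Gaussian bandwidth from a kernel size.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if sigma is None:
        sigma = 0.3 * ((window - 1) * 0.5 - 1) + 0.8
    half = window // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def adaptive_binarize(
    channel: np.ndarray,
    window: int = DEFAULT_WINDOW,
    offset: float | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Binarize a channel against its local Gaussian-weighted mean.

    Pixel -> 1 iff intensity > (Gaussian-weighted mean of the window
    neighborhood) + *offset*.  Borders use reflected (symmetric) padding.
    *offset* defaults to the channel's global intensity standard deviation,
    recomputed per channel.  A constant-valued channel yields all zeros
    (std = 0 and the strict inequality fails at equality).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("channel must be a 2-D intensity grid")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    if offset is None:
        offset = float(channel.std())
    kernel = gaussian_window_kernel(window, sigma)
    local_mean = ndimage.correlate1d(channel, kernel, axis=0, mode="reflect")
    local_mean = ndimage.correlate1d(local_mean, kernel, axis=1, mode="reflect")
    return (channel > local_mean + offset).astype(np.uint8)


def equivalent_radius(area: float) -> float:
    """Equivalent-area radius sqrt(area / pi) of an irregular pixel region."""
    return float(np.sqrt(area / np.pi))


def _centroids_and_areas(mask: np.ndarray) -> pd.DataFrame:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if len(labels) == 0:
        return pd.DataFrame(columns=["label", "area", "cy", "cx"]).set_index("label")
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=np.float64), mask, index=labels)
    centroids = ndimage.center_of_mass(np.ones_like(mask, dtype=np.float64), mask, index=labels)
    cy, cx = zip(*centroids)
    return pd.DataFrame({"label": labels, "area": areas, "cy": cy, "cx": cx}).set_index("label")


class MembraneCompletionError(ValueError):
    """Raised when nucleus/cell masks violate completion preconditions."""


def complete_membranes(
    nuclei: np.ndarray, detected_cells: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Complete the cell segmentation for nuclei without a detected membrane.

    Returns ``(completed_mask, info)`` where the completed mask keeps every
    detected cell verbatim and adds one disc segment per orphan nucleus, and
    *info* maps orphan nucleus labels to their new cell labels and records
    the estimated radius ratio ``rho``.

    Raises
    ------
    MembraneCompletionError
        If a nucleus overlaps two or more detected cells, or no nucleus is
        matched to a detected cell (the ratio would be undefined).
    """
    nuclei = np.asarray(nuclei)
    detected_cells = np.asarray(detected_cells)
    if nuclei.shape != detected_cells.shape:
        raise MembraneCompletionError("nucleus and cell masks must share one shape")
    nuc_stats = _centroids_and_areas(nuclei)
    cell_stats = _centroids_and_areas(detected_cells)

    matched, orphans = {}, []
    for nuc_label in nuc_stats.index:
        covering = np.unique(detected_cells[nuclei == nuc_label])
        covering = covering[covering > 0]
        if len(covering) > 1:
            raise MembraneCompletionError(
                f"nucleus {nuc_label} overlaps multiple detected cells: {covering.tolist()}"
            )
        if len(covering) == 1:
            matched[nuc_label] = int(covering[0])
        else:
            orphans.append(nuc_label)
    if not matched:
        raise MembraneCompletionError(
            "no nucleus is matched to a detected cell; radius ratio is undefined"
        )
    ratios = [
        equivalent_radius(cell_stats.loc[c, "area"]) / equivalent_radius(nuc_stats.loc[n, "area"])
        for n, c in matched.items()
    ]
    rho = float(np.mean(ratios))

    completed = detected_cells.copy()
    next_label = int(detected_cells.max()) + 1
    new_labels = {}
    # claim[i,j]: squared distance to the centroid of the disc currently
    # holding pixel (i,j); contested pixels go to the nearer nucleus centroid,
    # exact ties to the lower nucleus label (deterministic).
    claim_dist = np.full(nuclei.shape, np.inf)
    rows, cols = np.indices(nuclei.shape)
    n_ties = 0
    for nuc_label in sorted(orphans):
        radius = rho * equivalent_radius(nuc_stats.loc[nuc_label, "area"])
        cy, cx = nuc_stats.loc[nuc_label, "cy"], nuc_stats.loc[nuc_label, "cx"]
        y0, y1 = int(np.floor(cy - radius)) - 1, int(np.ceil(cy + radius)) + 2
        x0, x1 = int(np.floor(cx - radius)) - 1, int(np.ceil(cx + radius)) + 2
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, nuclei.shape[0]), min(x1, nuclei.shape[1])
        d2 = (rows[y0:y1, x0:x1] - cy) ** 2 + (cols[y0:y1, x0:x1] - cx) ** 2
        in_disc = d2 <= radius ** 2
        free = detected_cells[y0:y1, x0:x1] == 0
        closer = d2 < claim_dist[y0:y1, x0:x1]
        n_ties += int(np.sum(in_disc & free & (d2 == claim_dist[y0:y1, x0:x1])))
        take = in_disc & free & closer
        completed[y0:y1, x0:x1][take] = next_label
        claim_dist[y0:y1, x0:x1][take] = d2[take]
        new_labels[int(nuc_label)] = next_label
        next_label += 1
    if n_ties:
        logger.info("%d contested disc pixels resolved by lower-label tie-break", n_ties)
    return completed, {"rho": rho, "new_labels": new_labels, "matched": matched}


def abundance_matrix(binary_channels: dict, segmentation: np.ndarray) -> pd.DataFrame:
    """Fraction of positive pixels per (cell, protein): A(c, p) in [0, 1].

    *binary_channels* maps protein name -> binary grid (same shape as the
    segmentation).  Rows are indexed by segment label, columns by protein.
    """
    segmentation = np.asarray(segmentation)
    labels = np.unique(segmentation)
    labels = labels[labels > 0]
    if len(labels) == 0:
        raise ValueError("segmentation contains no cells")
    areas = ndimage.sum_labels(np.ones(segmentation.shape), segmentation, index=labels)
    data = {}
    for protein, grid in binary_channels.items():
        grid = np.asarray(grid)
        if grid.shape != segmentation.shape:
            raise ValueError(
                f"channel {protein!r} shape {grid.shape} != segmentation shape {segmentation.shape}"
            )
        positives = ndimage.sum_labels(grid.astype(np.float64), segmentation, index=labels)
        data[protein] = positives / areas
    out = pd.DataFrame(data, index=pd.Index(labels, name="cell_id"))
    return out
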