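"""Seeded synthetic cohorts, channel images and reference tables.

The generator emulates the three inputs of the pipeline so that every module
is testable without real data:

* ``simulate_tissue`` -- a cohort of spatial point patterns with planted
  type-mixing differences between conditions.  Cell centroids sit on a
  jittered grid; labels come from a cluster-center interaction process whose
  mixing parameter beta interpolates between fully random labels (beta = 0)
  and near-total segregation into single-type territories (large beta).  A
  condition may additionally carry focal "lesions": disc regions enriched for
  a focal cell type whose non-focal occupants are uniformly mixed, so focal
  cells simultaneously cluster together and sit in mixed surroundings -- the
  tissue signature the heterogeneity scores are designed to pick up.
* ``simulate_channels`` -- noisy marker channel images consistent with a
  known segmentation (disc cells with contained disc nuclei, one marker per
  type, salt-and-pepper noise, and a configured fraction of cells whose
  membrane is withheld to exercise membrane completion).
* ``simulate_reference`` -- a cluster-level reference expression table with
  designed marker structure (each type has one exclusive high gene).

All randomness flows from one master seed through ``numpy``'s SeedSequence
spawning, so cohorts are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .celltypes import ReferenceExpression
from .graph import UNKNOWN_LABEL

DEFAULT_TYPES = {
    "T-cell": 0.15,
    "basal-keratinocyte": 0.35,
    "fibroblast": 0.20,
    "endothelial": 0.18,
    "macrophage": 0.12,
}


@dataclass
class TissueSimConfig:
    """Configuration of one synthetic cohort.

    Defaults emulate the cohort shape of a three-condition skin study:
    three conditions of ~20 samples with ~3000 cells each, one lymphoma-like
    condition carrying focal lesions of the focal type.  Tests use reduced
    sizes via explicit arguments.
    """

    conditions: tuple = ("CTCL", "AD", "PSO")
    samples_per_condition: int = 20
    cells_per_sample: int = 3000
    type_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_TYPES))
    beta: dict | float = 3.0  # mixing parameter per condition (0 = random labels)
    cells_per_cluster: int = 60
    focal_type: str = "T-cell"
    # the focal type occurs diffusely (never forms background territories);
    # in lesion-bearing conditions it concentrates inside lesions whose other
    # occupants are uniformly mixed, so focal cells cluster together AND sit
    # in mixed surroundings
    focal_diffuse: bool = True
    lesion_count: dict | int = field(default_factory=lambda: {"CTCL": 3, "AD": 0, "PSO": 0})
    lesion_focal_frac: float = 0.6
    lesion_radius_frac: float = 0.12  # lesion radius as fraction of domain side
    grid_spacing: float = 14.0  # px between grid rows/columns
    jitter_frac: float = 0.15  # uniform jitter, fraction of spacing
    # marker panel / imaging
    foreground_abundance: float = 0.9  # mean bright-pixel fraction inside own-type cells
    # per-cell positive fraction is uniform in abundance +- jitter: a bounded
    # high mode whose 1.96-sigma gate (see celltypes) captures every cell,
    # unlike a Gaussian mode whose 2.5% left tail would always be cut; the
    # gate margin 1.96*sigma - halfwidth grows with the width, so a wider
    # mode is MORE robust to fit noise
    foreground_jitter: float = 0.08
    background_rate: float = 0.02  # P(bright pixel) elsewhere
    salt_pepper_rate: float = 0.002
    foreground_level: float = 200.0
    background_level: float = 10.0
    cell_radius: float = 4.0
    nucleus_radius: float = 2.0
    orphan_fraction: float = 0.0  # cells rendered without a membrane label
    markerless_fraction: float = 0.0  # planted cells expressing no marker
    # types present in the reference but not in the tissue (their markers are
    # not measured); the assignment loop ends with them remaining, like the
    # unassignable trailing type of a real reference
    reference_only_types: tuple = ("mast-cell",)
    seed: int = 0

    def __post_init__(self):
        freqs = np.array(list(self.type_frequencies.values()), dtype=float)
        if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("type frequencies must be non-negative and sum to 1")
        if self._beta_for_checks() < 0:
            raise ValueError("beta must be non-negative")
        for rate in (self.background_rate, self.salt_pepper_rate, self.foreground_abundance):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def _beta_for_checks(self) -> float:
        if isinstance(self.beta, dict):
            return min(self.beta.values(), default=0.0)
        return float(self.beta)

    def beta_of(self, condition) -> float:
        if isinstance(self.beta, dict):
            return float(self.beta.get(condition, 0.0))
        return float(self.beta)

    def lesions_of(self, condition) -> int:
        if isinstance(self.lesion_count, dict):
            return int(self.lesion_count.get(condition, 0))
        return int(self.lesion_count)

    @property
    def types(self) -> list:
        return list(self.type_frequencies)

    def marker_of(self, cell_type) -> str:
        return f"MARK-{cell_type}"


def _simulate_sample(config: TissueSimConfig, condition, sample_id, rng) -> pd.DataFrame:
    n = config.cells_per_sample
    side = int(np.ceil(np.sqrt(n)))
    spacing = config.grid_spacing
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    order = rng.permutation(side * side)[:n]
    jitter = config.jitter_frac * spacing
    x = (gx.ravel()[order] + 0.5) * spacing + rng.uniform(-jitter, jitter, n)
    y = (gy.ravel()[order] + 0.5) * spacing + rng.uniform(-jitter, jitter, n)
    domain = side * spacing

    types = config.types
    freqs = np.array([config.type_frequencies[t] for t in types])
    beta = config.beta_of(condition)

    focal_idx = types.index(config.focal_type) if config.focal_type in types else None
    n_centers = max(len(types), n // config.cells_per_cluster)
    centers = rng.uniform(0, domain, size=(n_centers, 2))
    if focal_idx is not None and config.focal_diffuse:
        center_freqs = freqs.copy()
        center_freqs[focal_idx] = 0.0
        center_freqs /= center_freqs.sum()
    else:
        center_freqs = freqs
    center_types = rng.choice(len(types), size=n_centers, p=center_freqs)
    d = np.hypot(x[:, None] - centers[None, :, 0], y[:, None] - centers[None, :, 1])
    nearest = d.argmin(axis=1)
    d_near = d[np.arange(n), nearest]
    scale = domain / np.sqrt(n_centers)
    keep = np.zeros(n, dtype=bool)
    if beta > 0:
        keep = rng.random(n) < np.exp(-d_near / (beta * scale))
    labels = np.where(keep, center_types[nearest], rng.choice(len(types), size=n, p=freqs))

    for _ in range(config.lesions_of(condition)):
        if focal_idx is None:
            break
        radius = config.lesion_radius_frac * domain
        cx, cy = rng.uniform(radius, domain - radius, size=2)
        inside = np.flatnonzero(np.hypot(x - cx, y - cy) <= radius)
        take_focal = rng.random(len(inside)) < config.lesion_focal_frac
        labels[inside[take_focal]] = focal_idx
        others = inside[~take_focal]
        non_focal = [i for i in range(len(types)) if i != focal_idx]
        labels[others] = rng.choice(non_focal, size=len(others))

    cell_type = np.array(types, dtype=object)[labels]
    if config.markerless_fraction > 0:
        blank = rng.random(n) < config.markerless_fraction
        cell_type = cell_type.copy()
        cell_type[blank] = UNKNOWN_LABEL
    return pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i:05d}" for i in range(n)],
            "x": x,
            "y": y,
            "sample_id": sample_id,
            "condition": condition,
            "cell_type": cell_type,
        }
    )


def simulate_tissue(config: TissueSimConfig) -> pd.DataFrame:
    """Generate a full cohort cell table (all conditions, all samples)."""
    master = np.random.SeedSequence(config.seed)
    n_samples = len(config.conditions) * config.samples_per_condition
    children = master.spawn(n_samples)
    frames = []
    i = 0
    for condition in config.conditions:
        for s in range(config.samples_per_condition):
            rng = np.random.default_rng(children[i])
            sample_id = f"{condition}_s{s:02d}"
            frames.append(_simulate_sample(config, condition, sample_id, rng))
            i += 1
    return pd.concat(frames, ignore_index=True)


def _disc_mask(shape, cy, cx, radius):
    y0, y1 = max(int(cy - radius) - 1, 0), min(int(cy + radius) + 2, shape[0])
    x0, x1 = max(int(cx - radius) - 1, 0), min(int(cx + radius) + 2, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def simulate_channels(cells: pd.DataFrame, config: TissueSimConfig, seed: int | None = None):
    """Render marker channels plus nucleus/cell label masks for one sample.

    Returns ``(channels, nuclei, detected_cells, truth)`` where *channels*
    maps marker name -> float image, the masks are integer label grids
    (cell label = row order + 1), and *truth* is the input cell table with an
    added integer ``segment`` column and an ``orphan`` flag for cells whose
    membrane was withheld from *detected_cells*.

    The grid layout of :func:`simulate_tissue` guarantees non-overlapping
    discs when ``cell_radius + jitter < spacing / 2``; violations are an
    error.
    """
    min_gap = config.grid_spacing - 2 * config.jitter_frac * config.grid_spacing
    if 2 * config.cell_radius >= min_gap:
        raise ValueError(
            f"cell discs of radius {config.cell_radius} can overlap at spacing "
            f"{config.grid_spacing} with jitter {config.jitter_frac}"
        )
    if cells["sample_id"].nunique() != 1:
        raise ValueError("simulate_channels renders a single sample")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed).spawn(1)[0]
    )
    n = len(cells)
    pad = int(np.ceil(config.cell_radius)) + 2
    shape = (
        int(np.ceil(cells["y"].max())) + pad,
        int(np.ceil(cells["x"].max())) + pad,
    )
    nuclei = np.zeros(shape, dtype=np.int32)
    cell_mask = np.zeros(shape, dtype=np.int32)
    truth = cells.reset_index(drop=True).copy()
    truth["segment"] = np.arange(1, n + 1)
    truth["orphan"] = rng.random(n) < config.orphan_fraction

    channels = {
        config.marker_of(t): np.full(shape, config.background_level) for t in config.types
    }
    for row in truth.itertuples():
        label = row.segment
        (sl, disc) = _disc_mask(shape, row.y, row.x, config.cell_radius)
        (sln, discn) = _disc_mask(shape, row.y, row.x, config.nucleus_radius)
        nuclei[sln][discn] = label
        if not row.orphan:
            cell_mask[sl][disc] = label
        marker = config.marker_of(row.cell_type)
        if marker in channels:
            q = float(
                np.clip(
                    config.foreground_abundance
                    + rng.uniform(-config.foreground_jitter, config.foreground_jitter),
                    0.0,
                    1.0,
                )
            )
            disc_flat = np.flatnonzero(disc)
            # ceil keeps the realized fraction at or above the drawn one, so
            # the rendered mode never leaks below its lower bound
            n_bright = min(int(np.ceil(q * len(disc_flat))), len(disc_flat))
            chosen = rng.choice(disc_flat, size=n_bright, replace=False)
            bright = np.zeros(disc.shape, dtype=bool)
            bright.ravel()[chosen] = True
            channels[marker][sl][bright] = config.foreground_level
    for marker, img in channels.items():
        bg = rng.random(shape) < config.background_rate
        img[bg & (img <= config.background_level)] = config.foreground_level
        salt = rng.random(shape) < config.salt_pepper_rate
        pepper = rng.random(shape) < config.salt_pepper_rate
        img[salt] = 255.0
        img[pepper] = 0.0
        img += rng.normal(0, 1.0, shape)
    return channels, nuclei, cell_mask, truth


def simulate_reference(config: TissueSimConfig, seed: int | None = None) -> ReferenceExpression:
    """Reference table with one exclusive high-expression marker per type.

    Each type gets 1-3 clusters of random size; its own marker gene is
    expressed around 8, all other genes around 0.3, so the spread score of
    (type, own marker) dominates by construction.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed).spawn(2)[-1]
    )
    all_types = config.types + list(config.reference_only_types)
    genes = [config.marker_of(t) for t in all_types]
    rows, ann = [], []
    cluster_idx = 0
    for t in all_types:
        for _ in range(int(rng.integers(1, 4))):
            name = f"c-{cluster_idx}"
            cluster_idx += 1
            size = int(rng.integers(50, 500))
            ann.append({"cluster": name, "cell_type": t, "size": size})
            for g in genes:
                base = 8.0 + rng.normal(0, 0.5) if g == config.marker_of(t) else 0.3 + rng.uniform(0, 0.2)
                rows.append({"cluster": name, "gene": g, "expression": max(base, 0.0)})
    return ReferenceExpression(clusters=pd.DataFrame(rows), annotations=pd.DataFrame(ann))


def reference_to_hpa_frames(ref: ReferenceExpression, tissue: str = "skin"):
    """Export a reference as the two HPA-dialect TSV frames (expression, description)."""
    expr = ref.clusters.rename(
        columns={"cluster": "Cluster", "gene": "Gene name", "expression": "nTPM"}
    )
    expr.insert(0, "Tissue", tissue)
    desc = ref.annotations.rename(
        columns={"cluster": "Cluster", "cell_type": "Cell type", "size": "Cell count"}
    )
    desc.insert(0, "Tissue", tissue)
    return expr, desc
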