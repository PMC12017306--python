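"""ROI segmentation of imaging movies.

Pixels responding to the dense-noise stimulus are found by thresholding a
per-pixel SD image at twice the field-mean SD; the 100 highest-SD
dendritic pixels are cross-correlated (Pearson, zero lag) and grouped
into ROIs by agglomerating neighbors within 3 um whose correlation with
the growing ROI exceeds the mean of all pairwise coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiRecord", "sd_image", "extract_rois", "make_field_roi"]


@dataclass
class RoiRecord:
    """One ROI: member pixels, extracted trace and morphology attachment."""

    pixel_set: list[tuple[int, int]]
    trace_raw: np.ndarray
    field_id: int = 0
    attachment_node: int | None = None
    dendritic_distance: float | None = None   # um to soma along the arbor
    is_field_roi: bool = False
    is_proximal: bool = False
    meta: dict = field(default_factory=dict)


def sd_image(movie: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel temporal SD of a (T, H, W) movie.

    With a boolean ``mask`` (glutamate mode: hand-drawn dendrite mask),
    pixels outside the mask get SD 0 and are excluded from all downstream
    statistics.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (T, H, W) with at least 2 frames")
    sd = movie.std(axis=0)
    if mask is not None:
        sd = np.where(np.asarray(mask, dtype=bool), sd, 0.0)
    return sd


def extract_rois(movie: np.ndarray, pixel_um: float,
                 mask: np.ndarray | None = None,
                 neighbor_um: float = 3.0, top_n: int = 100,
                 field_id: int = 0) -> list[RoiRecord]:
    """Segment ROIs from a dense-noise response movie.

    1. SD image; pixels with SD >= 2 x mean SD (over the mask, if given)
       are dendritic.
    2. The ``top_n`` highest-SD dendritic pixels are extracted and their
       pairwise Pearson correlations computed; the grouping threshold is
       the mean of these coefficients.
    3. ROIs grow by seeded agglomeration in descending-SD order: a pixel
       joins if it lies within ``neighbor_um`` of a current member and its
       correlation with that member exceeds the threshold.  Ties in SD are
       broken by raster order.

    Deterministic; disjoint ROIs; every ROI pixel is dendritic.
    """
    sd = sd_image(movie, mask)
    valid = sd > 0 if mask is not None else np.ones_like(sd, dtype=bool)
    mean_sd = sd[valid].mean() if valid.any() else 0.0
    dendritic = valid & (sd >= 2.0 * mean_sd) & (sd > 0)
    coords = np.argwhere(dendritic)
    if len(coords) < 2:
        warnings.warn("fewer than 2 dendritic pixels; no ROIs extracted")
        return []

    # top-N by SD, raster order breaking ties (stable sort on -SD)
    sds = sd[coords[:, 0], coords[:, 1]]
    order = np.argsort(-sds, kind="stable")[:top_n]
    coords = coords[order]
    traces = movie[:, coords[:, 0], coords[:, 1]].T  # (n, T)
    rho = np.corrcoef(traces)
    n = len(coords)
    off_diag = rho[~np.eye(n, dtype=bool)]
    rho_threshold = off_diag.mean()

    radius_px = neighbor_um / pixel_um
    assigned = np.full(n, -1)
    rois: list[list[int]] = []
    for seed_idx in range(n):
        if assigned[seed_idx] != -1:
            continue
        label = len(rois)
        members = [seed_idx]
        assigned[seed_idx] = label
        frontier = [seed_idx]
        while frontier:
            cur = frontier.pop(0)
            d = np.linalg.norm(coords - coords[cur], axis=1)
            for j in np.where((d <= radius_px) & (assigned == -1))[0]:
                if rho[cur, j] > rho_threshold:
                    assigned[j] = label
                    members.append(int(j))
                    frontier.append(int(j))
        rois.append(members)

    out = []
    for members in rois:
        pix = [tuple(map(int, coords[m])) for m in members]
        tr = movie[:, [p[0] for p in pix], [p[1] for p in pix]].mean(axis=1)
        out.append(RoiRecord(pix, tr, field_id=field_id,
                             meta={"rho_threshold": float(rho_threshold)}))
    return out


def make_field_roi(rois: list[RoiRecord], movie: np.ndarray | None = None,
                   proximal_um: float = 50.0) -> RoiRecord:
    """Combine all ROIs of one field into a field ROI.

    The field ROI is proximal if the median dendritic distance to the soma
    of the member ROIs is below ``proximal_um``.  (For cells with several
    proximal fields, the caller keeps the one with the largest downstream
    RF estimate.)
    """
    if not rois:
        raise ValueError("cannot build a field ROI from no ROIs")
    pixels = sorted({p for r in rois for p in r.pixel_set})
    if movie is not None:
        tr = movie[:, [p[0] for p in pixels], [p[1] for p in pixels]].mean(axis=1)
    else:
        tr = np.mean([r.trace_raw for r in rois], axis=0)
    distances = [r.dendritic_distance for r in rois
                 if r.dendritic_distance is not None]
    proximal = bool(distances) and float(np.median(distances)) < proximal_um
    return RoiRecord(list(pixels), tr, field_id=rois[0].field_id,
                     is_field_roi=True, is_proximal=proximal)
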