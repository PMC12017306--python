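"""File exchange helpers: HDF5 containers and CSV summary tables.

Movies, recordings and ROI label maps travel as HDF5; scalar summaries
(ROI metrics, response indices, cluster labels, density profiles) as CSV
via pandas.  Dendrograms serialize as nested lists in JSON.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .roi import RoiRecord

__all__ = [
    "save_roi_labels",
    "load_roi_labels",
    "roi_summary_table",
    "index_table",
    "labels_table",
    "dendrogram_to_json",
]


def save_roi_labels(path: str, rois: list[RoiRecord], shape: tuple[int, int],
                    group: str = "rois") -> None:
    """Write ROI membership as a labeled-integer map (-1 = background)."""
    labels = np.full(shape, -1, dtype=np.int32)
    for i, r in enumerate(rois):
        for y, x in r.pixel_set:
            labels[y, x] = i
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("labels", data=labels)
        g.create_dataset("traces", data=np.stack([r.trace_raw for r in rois]))


def load_roi_labels(path: str, group: str = "rois") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[group]["labels"][()]


def roi_summary_table(rois: list[RoiRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "roi_id": range(len(rois)),
        "n_pixels": [len(r.pixel_set) for r in rois],
        "field_id": [r.field_id for r in rois],
        "distance_to_soma": [r.dendritic_distance for r in rois],
        "is_proximal": [r.is_proximal for r in rois],
    })


def index_table(rows: list[dict]) -> pd.DataFrame:
    """Response-index table: (roi_id, stimulus, SI, TRi, n_repeats, flags)."""
    return pd.DataFrame(rows, columns=["roi_id", "stimulus", "SI", "TRi",
                                       "n_repeats", "flags"])


def labels_table(labels: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"roi_id": range(len(labels)), "cluster": labels})


def dendrogram_to_json(linkage_matrix: np.ndarray) -> str:
    """Serialize a scipy linkage matrix as nested [left, right, height] lists."""
    n = len(linkage_matrix) + 1
    nodes: dict[int, object] = {i: i for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage_matrix):
        nodes[n + k] = [nodes[int(a)], nodes[int(b)], float(h)]
    return json.dumps(nodes[n + len(linkage_matrix) - 1])
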