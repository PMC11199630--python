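"""File-format glue: TIFF volumes, colour-vector/cluster CSV, reference YAML."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
import yaml

from .colour_space import ColourVector
from .spectral import ChannelImage, SpectralReference

__all__ = [
    "read_tiff",
    "write_tiff",
    "save_reference",
    "load_reference",
    "save_colour_vectors",
    "load_colour_vectors",
    "save_clusters",
    "load_labels",
]


def read_tiff(path, voxel_size_um=(1.0, 1.0, 1.0)) -> ChannelImage:
    """Read a multichannel TIFF hyperstack as (channels, z, y, x).

    Accepts CZYX or ZCYX axis orders (channel axis inferred as the smaller
    of the first two dimensions) and single-channel ZYX stacks.
    """
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim == 4:
        if arr.shape[0] > arr.shape[1]:  # ZCYX -> CZYX
            arr = np.swapaxes(arr, 0, 1)
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")
    return ChannelImage(arr, voxel_size_um)


def write_tiff(img: ChannelImage, path) -> None:
    tifffile.imwrite(path, img.voxels.astype(np.float32))


def save_reference(ref: SpectralReference, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ref.to_dict(), fh, sort_keys=False)


def load_reference(path) -> SpectralReference:
    with open(path) as fh:
        return SpectralReference.from_dict(yaml.safe_load(fh))


def save_colour_vectors(vectors, path, lengths=None) -> None:
    """Colour-vector table: fragment_id, ch_1..ch_N, magnitude[, length_um]."""
    rows = []
    for i, v in enumerate(vectors):
        row = {"fragment_id": v.fragment_id if v.fragment_id is not None else i}
        row.update({f"ch_{c+1}": v.values[c] for c in range(v.n_channels)})
        row["magnitude"] = v.magnitude
        if lengths is not None:
            row["length_um"] = lengths[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_colour_vectors(path):
    df = pd.read_csv(path)
    chans = sorted(
        (c for c in df.columns if c.startswith("ch_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = []
    for _, row in df.iterrows():
        vals = row[chans].to_numpy(dtype=float)
        out.append(
            ColourVector(vals, float(row["magnitude"]), fragment_id=row["fragment_id"])
        )
    return out


def save_clusters(cluster_set, vectors, path, centroid_path=None) -> None:
    rows = []
    for v, cid in zip(vectors, cluster_set.assignments):
        d = (
            float(np.linalg.norm(v.values - cluster_set.centroids[cid]))
            if cid >= 0
            else np.nan
        )
        rows.append(
            {"fragment_id": v.fragment_id, "cluster_id": int(cid), "d_to_centroid": d}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    if centroid_path is not None:
        cent = pd.DataFrame(
            cluster_set.centroids,
            columns=[f"ch_{c+1}" for c in range(cluster_set.centroids.shape[1])],
        )
        cent.insert(0, "cluster_id", range(len(cent)))
        cent.to_csv(centroid_path, index=False)


def load_labels(path) -> dict:
    """fragment -> neuron map from a two-column CSV (fragment_id, neuron_id)."""
    df = pd.read_csv(path)
    return dict(zip(df["fragment_id"], df["neuron_id"]))
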