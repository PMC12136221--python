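"""Readers and writers for the package's file formats.

The canonical on-disk representation of a :class:`~hemiasym.containers.ContrastDataset`
is a single HDF5 container::

    /left            float64 (n_subjects, n_epochs, n_vertices)
    /right           float64 (n_subjects, n_epochs, n_vertices)
    /coords/left     float64 (n_vertices, 3)
    /coords/right    float64 (n_vertices, 3)
    /meta/subject_ids, /meta/epoch_names   UTF-8 string datasets

Vertex indexing is 0-based; readers never reorder vertices or epochs
relative to the stored manifest. CIFTI-2 dscalar files (one per epoch,
left and right cortical surface models present) are supported as an
optional *input* path only — they are converted to the container layout
on read and are never the internal representation.

Subject tables, network summaries and all result matrices are
tab-separated text with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    NETWORKS,
    ContrastDataset,
    NetworkPartition,
    SchemaError,
    partition_from_names,
    validate_subject_table,
)

_STR = h5py.string_dtype(encoding="utf-8")


# ---------------------------------------------------------------------------
# native HDF5 container
# ---------------------------------------------------------------------------

def write_dataset(dataset: ContrastDataset, path: str | Path) -> Path:
    """Write a ContrastDataset to the native HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("left", data=dataset.left_values)
        f.create_dataset("right", data=dataset.right_values)
        g = f.create_group("coords")
        g.create_dataset("left", data=dataset.left_coords)
        g.create_dataset("right", data=dataset.right_coords)
        m = f.create_group("meta")
        m.create_dataset("subject_ids", data=np.array(
            dataset.subject_ids, dtype=_STR))
        m.create_dataset("epoch_names", data=np.array(
            dataset.epoch_names, dtype=_STR))
        m.attrs["format"] = "hemiasym-contrast-container"
        m.attrs["vertex_indexing"] = "0-based"
    return path


def _read_container(path: Path) -> ContrastDataset:
    with h5py.File(path, "r") as f:
        for key in ("left", "right"):
            if key not in f:
                raise SchemaError(f"container missing /{key} hemisphere data")
        subject_ids = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["meta/subject_ids"][()]]
        epoch_names = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["meta/epoch_names"][()]]
        left = f["left"][()]
        right = f["right"][()]
        if right.shape[-1] != left.shape[-1]:
            raise SchemaError(
                f"hemisphere vertex counts differ: left {left.shape[-1]}, "
                f"right {right.shape[-1]}")
        if left.shape[1] != len(epoch_names):
            raise SchemaError(
                f"epoch count {left.shape[1]} does not match manifest "
                f"({len(epoch_names)} names)")
        return ContrastDataset(
            subject_ids=subject_ids,
            epoch_names=epoch_names,
            left_values=left,
            right_values=right,
            left_coords=f["coords/left"][()],
            right_coords=f["coords/right"][()],
        )


def read_dataset(path: str | Path, format: str = "container",
                 **kwargs) -> ContrastDataset:
    """Read a ContrastDataset.

    Parameters
    ----------
    path : str or Path
        HDF5 container file, or (for ``format="cifti_pair"``) a JSON
        manifest listing one dscalar per epoch.
    format : {"container", "cifti_pair"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container":
        return _read_container(path)
    if format == "cifti_pair":
        return read_cifti_manifest(path, **kwargs)
    raise ValueError(f"unknown format {format!r}")


def write_maps(maps: dict[str, np.ndarray], subject_ids: list[str],
               epoch_names: list[str], path: str | Path) -> Path:
    """Write named (n_subjects, n_epochs, n_vertices) maps (e.g. delta and
    amplitude) to an HDF5 container sharing the dataset manifest layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for name, arr in maps.items():
            f.create_dataset(name, data=np.asarray(arr, dtype=float))
        m = f.create_group("meta")
        m.create_dataset("subject_ids", data=np.array(subject_ids, dtype=_STR))
        m.create_dataset("epoch_names", data=np.array(epoch_names, dtype=_STR))
        m.attrs["format"] = "hemiasym-map-container"
    return path


def read_maps(path: str | Path) -> tuple[dict[str, np.ndarray],
                                         list[str], list[str]]:
    with h5py.File(path, "r") as f:
        subject_ids = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["meta/subject_ids"][()]]
        epoch_names = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["meta/epoch_names"][()]]
        maps = {k: f[k][()] for k in f if k != "meta"}
    return maps, subject_ids, epoch_names


# ---------------------------------------------------------------------------
# optional CIFTI-2 input path
# ---------------------------------------------------------------------------

def _cifti_hemi_data(img, structure: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (n_maps, n_vertices) data and vertex indices for one cortical
    surface structure from a dscalar image."""
    import nibabel as nib  # deferred: nibabel only needed on this path

    ax = img.header.get_axis(1)
    if not isinstance(ax, nib.cifti2.cifti2_axes.BrainModelAxis):
        raise SchemaError("dscalar axis 1 is not a brain-model axis")
    data = np.asarray(img.get_fdata())
    for name, slc, bm in ax.iter_structures():
        if name == structure:
            return data[:, slc], bm.vertex
    raise SchemaError(f"dscalar missing structure {structure}")


def read_cifti_pair(paths: dict[str, str | Path],
                    coords: tuple[np.ndarray, np.ndarray] | None = None,
                    subject_ids: list[str] | None = None) -> ContrastDataset:
    """Read per-epoch dscalar files into a ContrastDataset.

    Parameters
    ----------
    paths : mapping epoch name -> dscalar path
        Each file must contain both CORTEX_LEFT and CORTEX_RIGHT surface
        models, with one scalar map per subject (rows = subjects).
    coords : optional (left_coords, right_coords)
        Vertex coordinates; dscalar files carry none, so identity-matched
        placeholder coordinates are synthesized when omitted.
    """
    import nibabel as nib

    epoch_names = list(paths)
    lefts, rights = [], []
    n_rows = None
    for epoch in epoch_names:
        img = nib.load(str(paths[epoch]))
        lval, _ = _cifti_hemi_data(img, "CIFTI_STRUCTURE_CORTEX_LEFT")
        rval, _ = _cifti_hemi_data(img, "CIFTI_STRUCTURE_CORTEX_RIGHT")
        if lval.shape[1] != rval.shape[1]:
            raise SchemaError(
                "left/right cortical models have different vertex counts")
        if n_rows is None:
            n_rows = lval.shape[0]
        elif lval.shape[0] != n_rows:
            raise SchemaError(
                f"epoch {epoch!r} has {lval.shape[0]} maps, expected {n_rows}")
        lefts.append(lval)
        rights.append(rval)
    left = np.stack(lefts, axis=1)   # subjects x epochs x vertices
    right = np.stack(rights, axis=1)
    n_vertices = left.shape[2]
    if coords is None:
        # Placeholder mirrored geometry: identity correspondence.
        rng = np.random.default_rng(0)
        lc = rng.standard_normal((n_vertices, 3)) * 50.0
        lc[:, 0] = -np.abs(lc[:, 0]) - 1.0
        rc = lc.copy()
        rc[:, 0] = -rc[:, 0]
        coords = (lc, rc)
    if subject_ids is None:
        subject_ids = [f"sub{i:04d}" for i in range(left.shape[0])]
    return ContrastDataset(
        subject_ids=subject_ids, epoch_names=epoch_names,
        left_values=left, right_values=right,
        left_coords=coords[0], right_coords=coords[1])


def read_cifti_manifest(path: str | Path, **kwargs) -> ContrastDataset:
    """Read a JSON manifest {"epochs": {name: dscalar_path, ...}} whose paths
    are resolved relative to the manifest location."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    paths = {e: path.parent / p for e, p in manifest["epochs"].items()}
    return read_cifti_pair(paths, subject_ids=manifest.get("subject_ids"),
                           **kwargs)


# ---------------------------------------------------------------------------
# network partition
# ---------------------------------------------------------------------------

def read_partition(path: str | Path, n_vertices: int | None = None
                   ) -> NetworkPartition:
    """Read a vertex -> network labeling.

    Accepts two-column whitespace/tab-separated text ``vertex_index
    network_name`` (header optional). Vertices absent from the file get the
    background code. Names outside the canonical 12 are appended with a
    warning.
    """
    path = Path(path)
    rows: list[tuple[int, str]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0].lower() in ("vertex", "vertex_index"):
            continue
        rows.append((int(parts[0]), parts[1]))
    if not rows:
        raise SchemaError(f"empty partition file {path}")
    max_v = max(v for v, _ in rows)
    n = n_vertices if n_vertices is not None else max_v + 1
    if max_v >= n:
        raise SchemaError(
            f"vertex index {max_v} out of range for {n} vertices")
    names: list[str | None] = [None] * n
    for v, name in rows:
        names[v] = name
    return partition_from_names(names)


def write_partition(partition: NetworkPartition, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as f:
        f.write("vertex_index\tnetwork\n")
        for v, lab in enumerate(partition.labels):
            if lab >= 0:
                f.write(f"{v}\t{partition.network_names[lab]}\n")
    return path


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated subject/covariate table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return validate_subject_table(df)


def write_subject_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = table.reset_index() if table.index.name == "subject_id" else table
    out.to_csv(path, sep="\t", index=False)
    return path


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
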