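"""Core data containers for bilateral cortical contrast data.

The package works on per-subject, per-task-epoch contrast maps sampled on
matched left/right cortical surface meshes. Three containers carry the data
through the pipeline:

``ContrastDataset``
    subjects x epochs x vertices contrast estimates for each hemisphere,
    plus the vertex coordinates needed to establish left-right
    correspondence.
``NetworkPartition``
    a vertex -> functional-network labeling (canonical 12-network scheme).
``SubjectTable``
    covariates (age, sex, race, BMI, handedness, head motion) and task
    accuracy for the scored epochs, one row per subject.

Vertex indexing is 0-based everywhere.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical 17 task epochs (emotion, gambling, language, motor, relational,
#: social, working-memory conditions of the HCP-style task battery).
EPOCHS: tuple[str, ...] = (
    "faces", "shapes", "reward", "punish", "story", "math",
    "lh", "rh", "lf", "rf", "t",
    "rel", "match", "social", "random", "0bk", "2bk",
)

#: The 12 epochs with behavioral accuracy scores (motor epochs are unscored).
SCORED_EPOCHS: tuple[str, ...] = (
    "faces", "shapes", "reward", "punish", "story", "math",
    "rel", "match", "social", "random", "0bk", "2bk",
)

#: Canonical 12-network cortical parcellation order.
NETWORKS: tuple[str, ...] = (
    "VIS1", "VIS2", "SMM", "CON", "DAN", "LAN",
    "FPN", "AUD", "DMN", "PMM", "VMM", "ORA",
)

#: The 9 major networks retained for PLS prediction (ORA, VMM and PMM are
#: excluded: small, diffuse, weakly task-specific).
PLS_NETWORKS: tuple[str, ...] = (
    "VIS1", "VIS2", "SMM", "CON", "DAN", "LAN", "FPN", "AUD", "DMN",
)

#: Label code for vertices not assigned to any network.
BACKGROUND: int = -1

#: Numeric covariate columns expected in a subject table.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "age", "sex", "race", "bmi", "handedness", "rms_motion",
)


class SchemaError(ValueError):
    """An input violates the documented container schema."""


class EmptyCohortError(ValueError):
    """An operation removed every subject from the cohort."""


@dataclass
class ContrastDataset:
    """Bilateral contrast estimates for a cohort.

    Parameters
    ----------
    subject_ids : list of str
        Unique opaque subject identifiers.
    epoch_names : list of str
        Unique epoch labels, typically the canonical 17.
    left_values, right_values : ndarray, shape (n_subjects, n_epochs, n_vertices)
        Contrast estimates in arbitrary BOLD-contrast units. Hemispheres
        must have identical vertex counts.
    left_coords, right_coords : ndarray, shape (n_vertices, 3)
        Cartesian vertex coordinates in mm. Used only to establish
        left-right vertex correspondence.
    """

    subject_ids: list[str]
    epoch_names: list[str]
    left_values: np.ndarray
    right_values: np.ndarray
    left_coords: np.ndarray
    right_coords: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.epoch_names = [str(e) for e in self.epoch_names]
        self.left_values = np.asarray(self.left_values, dtype=float)
        self.right_values = np.asarray(self.right_values, dtype=float)
        self.left_coords = np.asarray(self.left_coords, dtype=float)
        self.right_coords = np.asarray(self.right_coords, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        ns, ne = len(self.subject_ids), len(self.epoch_names)
        if len(set(self.subject_ids)) != ns:
            raise SchemaError("duplicate subject ids")
        if len(set(self.epoch_names)) != ne:
            raise SchemaError("duplicate epoch names")
        expect = (ns, ne, self.n_vertices)
        if self.left_values.shape != expect:
            raise SchemaError(
                f"left_values shape {self.left_values.shape} != {expect}")
        if self.right_values.shape != expect:
            raise SchemaError(
                f"right hemisphere shape {self.right_values.shape} does not "
                f"match left {expect}")
        for name, coords in (("left", self.left_coords),
                             ("right", self.right_coords)):
            if coords.shape != (self.n_vertices, 3):
                raise SchemaError(
                    f"{name}_coords shape {coords.shape} != "
                    f"({self.n_vertices}, 3)")
            if not np.all(np.isfinite(coords)):
                raise SchemaError(f"{name}_coords contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_names)

    @property
    def n_vertices(self) -> int:
        return self.left_values.shape[2] if self.left_values.ndim == 3 else 0

    def subset_subjects(self, keep: np.ndarray) -> "ContrastDataset":
        """Return a dataset restricted to subjects where ``keep`` is True,
        order preserved."""
        keep = np.asarray(keep, dtype=bool)
        ids = [s for s, k in zip(self.subject_ids, keep) if k]
        if not ids:
            raise EmptyCohortError("subject subset is empty")
        return ContrastDataset(
            subject_ids=ids,
            epoch_names=list(self.epoch_names),
            left_values=self.left_values[keep],
            right_values=self.right_values[keep],
            left_coords=self.left_coords,
            right_coords=self.right_coords,
        )


@dataclass
class NetworkPartition:
    """Vertex -> network labeling.

    ``labels[v]`` indexes into ``network_names``; ``BACKGROUND`` (-1) marks
    unassigned vertices, which are excluded from all network means.
    Unknown network names encountered on read are appended after the
    canonical 12 with a warning.
    """

    labels: np.ndarray
    network_names: list[str] = field(default_factory=lambda: list(NETWORKS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.network_names = list(self.network_names)
        bad = (self.labels < BACKGROUND) | (
            self.labels >= len(self.network_names))
        if np.any(bad):
            raise SchemaError(
                f"{int(bad.sum())} labels outside "
                f"[-1, {len(self.network_names) - 1}]")

    @property
    def n_vertices(self) -> int:
        return self.labels.size

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def vertex_counts(self) -> pd.Series:
        """Vertices per network (0 for empty networks)."""
        counts = np.bincount(self.labels[self.labels >= 0],
                             minlength=self.n_networks)
        return pd.Series(counts, index=self.network_names, name="n_vertices")

    def empty_networks(self) -> list[str]:
        c = self.vertex_counts()
        return list(c.index[c == 0])


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject/covariate table and return it indexed by subject_id.

    Expected columns: ``subject_id``, the covariates in
    :data:`COVARIATE_COLUMNS`, and ``acc_<epoch>`` for scored epochs
    (missing accuracy cells may be NaN).
    """
    df = table.copy()
    if "subject_id" in df.columns:
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            raise SchemaError("duplicate subject_id in subject table")
        df = df.set_index("subject_id")
    df.index = df.index.astype(str)
    if "age" in df.columns and (pd.to_numeric(df["age"]) <= 0).any():
        raise SchemaError("non-positive age")
    if "rms_motion" in df.columns and (
            pd.to_numeric(df["rms_motion"]) < 0).any():
        raise SchemaError("negative rms_motion")
    acc_cols = [c for c in df.columns if c.startswith("acc_")]
    for c in acc_cols:
        vals = pd.to_numeric(df[c])
        if ((vals < 0) | (vals > 100)).any():
            raise SchemaError(f"accuracy column {c} outside [0, 100]")
    return df


def accuracy_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("acc_")]


def filter_by_motion(
    table: pd.DataFrame,
    dataset: ContrastDataset,
    threshold: float = 2.0,
) -> tuple[pd.DataFrame, ContrastDataset]:
    """Retain subjects with RMS head motion strictly below ``threshold`` mm.

    The inclusion rule is a strict inequality: a subject with motion exactly
    equal to the threshold is excluded. Subject order is preserved in both
    outputs. Idempotent.
    """
    if threshold <= 0:
        raise ValueError("motion threshold must be positive")
    table = validate_subject_table(table)
    motion = table["rms_motion"].reindex(dataset.subject_ids)
    if motion.isna().any():
        missing = list(motion.index[motion.isna()])
        raise SchemaError(f"subjects missing from table: {missing[:5]}")
    keep = (motion < threshold).to_numpy()
    if not keep.any():
        raise EmptyCohortError(
            f"no subject has rms_motion < {threshold} mm")
    kept_ids = [s for s, k in zip(dataset.subject_ids, keep) if k]
    return table.loc[kept_ids], dataset.subset_subjects(keep)


def partition_from_names(
    names_per_vertex: list[str | None],
    canonical: tuple[str, ...] = NETWORKS,
) -> NetworkPartition:
    """Build a partition from per-vertex network names.

    ``None`` entries become background. Names outside the canonical list
    are appended after it, with a warning.
    """
    network_names = list(canonical)
    index = {n: i for i, n in enumerate(network_names)}
    labels = np.full(len(names_per_vertex), BACKGROUND, dtype=int)
    extras: list[str] = []
    for v, name in enumerate(names_per_vertex):
        if name is None:
            continue
        if name not in index:
            extras.append(name)
            index[name] = len(network_names)
            network_names.append(name)
        labels[v] = index[name]
    if extras:
        warnings.warn(
            f"non-canonical network names appended: {sorted(set(extras))}",
            stacklevel=2)
    return NetworkPartition(labels=labels, network_names=network_names)


def asdict_shallow(obj) -> dict:
    """dataclass -> dict without deep-copying arrays (unlike dataclasses.asdict)."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
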