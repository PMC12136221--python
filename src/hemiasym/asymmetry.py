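"""Vertex-wise laterality index and left-right vertex correspondence.

For matched left/right contrast estimates L and R the package computes a
normalized, threshold-independent asymmetry index

    delta = (L - R) / (|L| + |R|)          in [-1, 1]

and the bilateral amplitude

    A = (|L| + |R|) / 2                    >= 0.

Positive delta means greater left-hemisphere activity (leftward
lateralization); negative delta means rightward. The index is undefined
where |L| + |R| = 0; those cells are masked rather than zero-filled, since
a 0/0 cell carries no lateralization information. No epsilon
regularization is applied to near-zero denominators — instabilities are
handled downstream by network averaging, preserving the
threshold-independent character of the index.

Left-right correspondence between the two hemisphere meshes is established
geometrically: right-hemisphere coordinates are mirrored across the
midsagittal plane (x -> -x) after centering each mesh on its bounding box,
then each left vertex is matched to the nearest mirrored right vertex. The
match is accepted only if the Pearson correlation of matched coordinates
exceeds a quality threshold (default R > 0.995).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .containers import ContrastDataset


class CorrespondenceError(ValueError):
    """Left-right vertex matching failed (non-bijective or low quality)."""


@dataclass
class VertexCorrespondence:
    """Pairing of each left vertex with its mirror-symmetric right vertex.

    Attributes
    ----------
    permutation : ndarray of int
        ``permutation[v]`` is the right-hemisphere vertex matched to left
        vertex ``v``; a bijection on ``0..n_vertices-1``.
    fit_quality : float
        Pearson correlation of the matched coordinate vectors (all three
        axes concatenated, right x mirrored), in [-1, 1].
    """

    permutation: np.ndarray
    fit_quality: float

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=int)
        n = self.permutation.size
        if not np.array_equal(np.sort(self.permutation), np.arange(n)):
            raise CorrespondenceError("permutation is not a bijection")


@dataclass
class AsymmetryResult:
    """Vertex-wise asymmetry index and bilateral amplitude.

    ``delta`` and ``amplitude`` have shape (n_subjects, n_epochs,
    n_vertices); ``mask`` is True exactly where |L|+|R| = 0 and the index
    is undefined. Masked cells hold NaN.
    """

    delta: np.ndarray
    amplitude: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    epoch_names: list[str]


def _center_on_bounding_box(coords: np.ndarray) -> np.ndarray:
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    return coords - (lo + hi) / 2.0


def match_vertices(
    left_coords: np.ndarray,
    right_coords: np.ndarray,
    min_fit: float = 0.995,
) -> VertexCorrespondence:
    """Establish left-right vertex correspondence from mesh geometry.

    Both coordinate sets are centered on their bounding boxes, the right
    x-axis is negated (mirror across the midsagittal plane), and each left
    vertex is assigned its nearest right vertex by Euclidean distance. The
    assignment must be a bijection, and the Pearson correlation of matched
    coordinates (fit quality) must exceed ``min_fit``.

    Raises
    ------
    CorrespondenceError
        If the nearest-neighbor assignment collides (two left vertices
        claiming one right vertex) or the fit quality is at or below
        ``min_fit``.
    """
    left_coords = np.asarray(left_coords, dtype=float)
    right_coords = np.asarray(right_coords, dtype=float)
    if left_coords.shape != right_coords.shape:
        raise CorrespondenceError(
            f"coordinate shapes differ: {left_coords.shape} vs "
            f"{right_coords.shape}")
    lc = _center_on_bounding_box(left_coords)
    rc = _center_on_bounding_box(right_coords)
    rc_mirror = rc.copy()
    rc_mirror[:, 0] = -rc_mirror[:, 0]

    tree = cKDTree(rc_mirror)
    _, perm = tree.query(lc, k=1)
    perm = np.asarray(perm, dtype=int)
    counts = np.bincount(perm, minlength=lc.shape[0])
    n_collisions = int(np.sum(counts > 1))
    if n_collisions:
        raise CorrespondenceError(
            f"nearest-neighbor matching is not a bijection: "
            f"{n_collisions} right vertices claimed more than once")

    matched = rc_mirror[perm]
    fit_quality = float(np.corrcoef(lc.ravel(), matched.ravel())[0, 1])
    if not fit_quality > min_fit:
        raise CorrespondenceError(
            f"correspondence fit quality {fit_quality:.6f} <= "
            f"required {min_fit}")
    return VertexCorrespondence(permutation=perm, fit_quality=fit_quality)


def compute_asymmetry(
    dataset: ContrastDataset,
    correspondence: VertexCorrespondence | None = None,
) -> AsymmetryResult:
    """Compute the asymmetry index and bilateral amplitude per cell.

    ``correspondence`` reorders the right hemisphere so that right vertex
    ``permutation[v]`` is compared against left vertex ``v``. When omitted,
    it is derived from the dataset's vertex coordinates.
    """
    if correspondence is None:
        correspondence = match_vertices(dataset.left_coords,
                                        dataset.right_coords)
    if correspondence.permutation.size != dataset.n_vertices:
        raise ValueError(
            f"correspondence covers {correspondence.permutation.size} "
            f"vertices, dataset has {dataset.n_vertices}")
    L = dataset.left_values
    R = dataset.right_values[:, :, correspondence.permutation]
    denom = np.abs(L) + np.abs(R)
    mask = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(mask, np.nan, (L - R) / np.where(mask, 1.0, denom))
    amplitude = np.where(mask, np.nan, denom / 2.0)
    return AsymmetryResult(
        delta=delta, amplitude=amplitude, mask=mask,
        subject_ids=list(dataset.subject_ids),
        epoch_names=list(dataset.epoch_names))
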