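"""Network-level aggregation of vertex maps and asymmetry rankings.

Vertex-wise asymmetry and amplitude maps are averaged within functional
network partitions, per participant and task epoch (vertex-first: the
index is averaged, never recomputed from averaged hemisphere signals).
Networks are then ranked by the root-mean-square of their cohort-mean
asymmetry across epochs, and epochs by their mean asymmetry across
networks.

Motor epochs can optionally be re-expressed relative to the overall
asymmetry induced by the motor task (epoch-minus-task-mean centering)
before ranking; the default leaves epochs raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asymmetry import AsymmetryResult, VertexCorrespondence
from .containers import BACKGROUND, ContrastDataset, NetworkPartition

#: Epochs belonging to the motor task (used by task-mean centering).
MOTOR_EPOCHS: tuple[str, ...] = ("lh", "rh", "lf", "rf", "t")


class AggregationError(ValueError):
    pass


@dataclass
class NetworkSummary:
    """Subject x epoch x network means of asymmetry and amplitude.

    All arrays have shape (n_subjects, n_epochs, n_networks). ``left_mean``
    and ``right_mean`` are per-hemisphere mean absolute amplitudes (contrast
    units); entries for empty or fully masked networks are NaN.
    """

    delta_mean: np.ndarray
    amplitude_mean: np.ndarray
    left_mean: np.ndarray
    right_mean: np.ndarray
    subject_ids: list[str]
    epoch_names: list[str]
    network_names: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject, epoch, network, delta, amplitude,
        left, right."""
        idx = pd.MultiIndex.from_product(
            [self.subject_ids, self.epoch_names, self.network_names],
            names=["subject", "epoch", "network"])
        return pd.DataFrame({
            "delta": self.delta_mean.ravel(),
            "amplitude": self.amplitude_mean.ravel(),
            "left": self.left_mean.ravel(),
            "right": self.right_mean.ravel(),
        }, index=idx).reset_index()

    def cohort_mean_delta(self) -> pd.DataFrame:
        """Cohort-mean asymmetry, epochs x networks."""
        return pd.DataFrame(
            np.nanmean(self.delta_mean, axis=0),
            index=self.epoch_names, columns=self.network_names)


def summary_from_frame(df: pd.DataFrame) -> NetworkSummary:
    """Rebuild a NetworkSummary from its long-format table (the inverse of
    :meth:`NetworkSummary.to_frame`); first-appearance order of subjects,
    epochs and networks is preserved."""
    subjects = list(pd.unique(df["subject"].astype(str)))
    epochs = list(pd.unique(df["epoch"].astype(str)))
    networks = list(pd.unique(df["network"].astype(str)))
    shape = (len(subjects), len(epochs), len(networks))
    arrays = {}
    pivot = df.set_index(["subject", "epoch", "network"])
    idx = pd.MultiIndex.from_product([subjects, epochs, networks])
    for col in ("delta", "amplitude", "left", "right"):
        arrays[col] = pivot[col].reindex(idx).to_numpy().reshape(shape)
    return NetworkSummary(
        delta_mean=arrays["delta"], amplitude_mean=arrays["amplitude"],
        left_mean=arrays["left"], right_mean=arrays["right"],
        subject_ids=subjects, epoch_names=epochs, network_names=networks)


@dataclass
class RankingResult:
    """Networks ordered by RMS asymmetry, epochs by mean asymmetry."""

    network_order: list[str] = field(default_factory=list)
    network_scores: dict[str, float] = field(default_factory=dict)
    epoch_order: list[str] = field(default_factory=list)
    epoch_scores: dict[str, float] = field(default_factory=dict)


def _network_means(values: np.ndarray, partition: NetworkPartition
                   ) -> np.ndarray:
    """nanmean of (subjects, epochs, vertices) within each network ->
    (subjects, epochs, networks)."""
    out = np.full(values.shape[:2] + (partition.n_networks,), np.nan)
    for k in range(partition.n_networks):
        sel = partition.labels == k
        if not sel.any():
            continue
        block = values[:, :, sel]
        valid = np.isfinite(block).any(axis=2)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(block, axis=2)
        out[:, :, k] = np.where(valid, m, np.nan)
    return out


def aggregate_by_network(
    result: AsymmetryResult,
    partition: NetworkPartition,
    dataset: ContrastDataset | None = None,
    correspondence: VertexCorrespondence | None = None,
) -> NetworkSummary:
    """Average vertex-wise asymmetry and amplitude within each network.

    Means are unweighted over a network's unmasked vertices, per subject
    and epoch. Background vertices (label -1) and masked cells are
    excluded. When ``dataset`` is given, per-hemisphere mean absolute
    amplitudes are also computed (right hemisphere reordered through
    ``correspondence`` when provided); otherwise they fall back to the
    bilateral amplitude.

    Raises
    ------
    AggregationError
        If every network is empty.
    """
    if partition.n_vertices != result.delta.shape[2]:
        raise AggregationError(
            f"partition covers {partition.n_vertices} vertices, maps have "
            f"{result.delta.shape[2]}")
    if np.all(partition.labels == BACKGROUND):
        raise AggregationError("all networks are empty")
    delta_mean = _network_means(result.delta, partition)
    amplitude_mean = _network_means(result.amplitude, partition)
    if dataset is not None:
        right = dataset.right_values
        if correspondence is not None:
            right = right[:, :, correspondence.permutation]
        left_mean = _network_means(np.abs(dataset.left_values), partition)
        right_mean = _network_means(np.abs(right), partition)
    else:
        left_mean = amplitude_mean.copy()
        right_mean = amplitude_mean.copy()
    return NetworkSummary(
        delta_mean=delta_mean, amplitude_mean=amplitude_mean,
        left_mean=left_mean, right_mean=right_mean,
        subject_ids=list(result.subject_ids),
        epoch_names=list(result.epoch_names),
        network_names=list(partition.network_names))


def center_motor_epochs(summary: NetworkSummary,
                        motor_epochs: tuple[str, ...] = MOTOR_EPOCHS
                        ) -> NetworkSummary:
    """Re-express motor-task epochs relative to the motor-task mean.

    Subtracts, per subject and network, the mean asymmetry over the motor
    epochs from each motor epoch, leaving other epochs unchanged. Useful
    for rankings where the contralateral motor pattern should be read
    relative to the overall asymmetry induced by the motor task.
    """
    sel = np.array([e in motor_epochs for e in summary.epoch_names])
    delta = summary.delta_mean.copy()
    if sel.any():
        task_mean = np.nanmean(delta[:, sel, :], axis=1, keepdims=True)
        delta[:, sel, :] = delta[:, sel, :] - task_mean
    return NetworkSummary(
        delta_mean=delta,
        amplitude_mean=summary.amplitude_mean,
        left_mean=summary.left_mean, right_mean=summary.right_mean,
        subject_ids=summary.subject_ids, epoch_names=summary.epoch_names,
        network_names=summary.network_names)


def _ordered(scores: dict[str, float], canonical: list[str]) -> list[str]:
    # Descending score; canonical input order breaks ties.
    pos = {n: i for i, n in enumerate(canonical)}
    return sorted(scores, key=lambda n: (-scores[n], pos[n]))


def rank_networks(summary: NetworkSummary) -> RankingResult:
    """Rank networks by RMS of cohort-mean asymmetry across epochs
    (descending; canonical order breaks ties)."""
    table = summary.cohort_mean_delta()  # epochs x networks
    if table.empty:
        raise AggregationError("empty summary")
    rms = np.sqrt(np.nanmean(np.square(table.to_numpy()), axis=0))
    scores = {n: float(s) for n, s in zip(summary.network_names, rms)}
    return RankingResult(
        network_order=_ordered(scores, summary.network_names),
        network_scores=scores)


def rank_epochs(summary: NetworkSummary) -> RankingResult:
    """Rank epochs by mean cohort-mean asymmetry across networks
    (descending; canonical order breaks ties)."""
    table = summary.cohort_mean_delta()
    if table.empty:
        raise AggregationError("empty summary")
    means = np.nanmean(table.to_numpy(), axis=1)
    scores = {e: float(s) for e, s in zip(summary.epoch_names, means)}
    return RankingResult(
        epoch_order=_ordered(scores, summary.epoch_names),
        epoch_scores=scores)
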