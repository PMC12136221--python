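"""Synthetic cohort generator with planted, recoverable structure.

Real task-fMRI cohorts of the kind this package analyzes are
access-restricted, so validation runs on synthetic cohorts that emulate
the statistical structure the analysis assumes:

* mirrored left/right vertex geometry (right = left with x negated,
  stored in a recorded pseudo-random permutation),
* network-structured activation: each network is block-constant in its
  planted mean asymmetry and bilateral amplitude per epoch, plus
  independent vertex noise,
* a subject-level latent factor f_i coupling amplitude to asymmetry,
* task accuracy generated as a linear function of (standardized)
  noiseless network measures plus noise, clipped to [0, 100],
* covariates with planted age/sex effects on the latent factor.

Generative model, per subject i, network k, epoch e::

    f_i       ~ Normal(beta_age * z(age_i) + beta_sex * sex_i, 1)
    A_ike     = true_amplitude[k,e] * (1 + s * f_i)            (floored > 0)
    Delta_ike = true_delta[k,e] + coupling[k,e] * (s * f_i) + s * eps_ike
    L_v       = A_ike * (1 + Delta_ike) + vertex noise
    R_v       = A_ike * (1 - Delta_ike) + vertex noise

with s = ``subject_noise_sd``. With L, R >= 0 this construction is
exactly inverted by the asymmetry index: (L-R)/(|L|+|R|) = Delta and
(|L|+|R|)/2 = A at zero noise, which is what makes the planted values
recoverable. Delta is clipped to (-0.999, 0.999) so hemisphere signals
stay non-negative at zero vertex noise.

The within-subject correlation structure across epochs is carried
entirely by the single latent factor — an explicit modeling assumption,
not an empirical claim about real cohorts.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    EPOCHS,
    NETWORKS,
    SCORED_EPOCHS,
    ContrastDataset,
    NetworkPartition,
)


class ConfigError(ValueError):
    pass


def _effect_table(base: float, overrides: dict[tuple[str, str], float],
                  networks=NETWORKS, epochs=EPOCHS) -> pd.DataFrame:
    table = pd.DataFrame(base, index=list(networks), columns=list(epochs),
                         dtype=float)
    for (net, ep), val in overrides.items():
        table.loc[net, ep] = val
    return table


def default_true_delta() -> pd.DataFrame:
    """Planted mean asymmetry (networks x epochs), chosen to mirror the
    qualitative pattern of task lateralization: contralateral motor
    responses in somatomotor cortex, leftward story-listening asymmetry
    in language/frontoparietal/default-mode networks, rightward asymmetry
    for face matching in dorsal-attention cortex."""
    overrides = {
        # contralateral motor pattern in SMM (and echoes in DAN/AUD)
        ("SMM", "lh"): -0.35, ("SMM", "rh"): 0.35,
        ("SMM", "lf"): -0.30, ("SMM", "rf"): 0.30, ("SMM", "t"): 0.05,
        ("DAN", "lh"): -0.10, ("DAN", "rh"): 0.10,
        ("AUD", "lh"): -0.08, ("AUD", "rh"): 0.08,
        # language task: story strongly leftward in LAN/FPN/DMN/AUD
        ("LAN", "story"): 0.35, ("LAN", "math"): 0.12,
        ("FPN", "story"): 0.20, ("DMN", "story"): 0.10,
        ("AUD", "story"): 0.15, ("VIS1", "story"): -0.08,
        ("VIS2", "story"): -0.08, ("SMM", "story"): -0.10,
        # emotion task: rightward in DAN/FPN/PMM
        ("DAN", "faces"): -0.15, ("FPN", "faces"): -0.10,
        ("PMM", "faces"): -0.10, ("DAN", "shapes"): -0.08,
        # working memory: slight leftward visual, rightward DMN
        ("VIS1", "2bk"): 0.08, ("VIS2", "2bk"): 0.08,
        ("DMN", "2bk"): -0.10, ("DMN", "0bk"): -0.06,
        # social / relational: mild rightward LAN/FPN
        ("LAN", "social"): -0.08, ("LAN", "random"): -0.08,
        ("FPN", "rel"): -0.06, ("LAN", "rel"): -0.05,
    }
    table = _effect_table(0.02, overrides)
    table.loc["DMN"] = table.loc["DMN"].where(
        table.loc["DMN"] != 0.02, -0.05)  # DMN mildly rightward elsewhere
    return table


def default_true_amplitude() -> pd.DataFrame:
    """Planted bilateral amplitude (contrast units), higher in
    task-relevant networks."""
    overrides = {
        ("SMM", "lh"): 1.6, ("SMM", "rh"): 1.6, ("SMM", "lf"): 1.5,
        ("SMM", "rf"): 1.5, ("SMM", "t"): 1.5,
        ("LAN", "story"): 1.7, ("LAN", "math"): 1.3,
        ("AUD", "story"): 1.5, ("AUD", "math"): 1.3,
        ("VIS1", "faces"): 1.5, ("VIS2", "faces"): 1.5,
        ("VIS1", "shapes"): 1.4, ("VIS2", "shapes"): 1.4,
        ("DAN", "2bk"): 1.4, ("FPN", "2bk"): 1.4, ("FPN", "0bk"): 1.2,
        ("FPN", "rel"): 1.3, ("DAN", "rel"): 1.3,
    }
    return _effect_table(1.0, overrides)


def default_coupling() -> pd.DataFrame:
    """Amplitude-asymmetry coupling coefficients, strongest in language,
    frontoparietal and dorsal-attention networks."""
    table = _effect_table(0.05, {})
    for net in ("LAN", "FPN", "DAN"):
        table.loc[net] = 0.20
    table.loc["VIS1"], table.loc["VIS2"] = 0.12, 0.12
    table.loc["DMN"] = 0.03
    return table


def default_accuracy_weights() -> dict[str, list[tuple[str, str, float]]]:
    """Linear weights (percent per SD of the network measure) generating
    accuracy for a subset of scored epochs; unlisted epochs get noise
    only around the baseline."""
    return {
        "story": [("LAN", "delta", 4.0), ("LAN", "amplitude", 3.0)],
        "math": [("LAN", "amplitude", 2.5)],
        "2bk": [("FPN", "amplitude", 4.0), ("DAN", "amplitude", 3.0)],
        "0bk": [("FPN", "amplitude", 2.5)],
        "rel": [("FPN", "delta", 3.0), ("DAN", "amplitude", 2.5)],
        "match": [("DAN", "amplitude", 2.0)],
        "faces": [("VIS1", "amplitude", 3.0), ("DAN", "delta", -2.0)],
        "social": [("LAN", "delta", 2.0)],
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give a 200-subject, 2,000-vertex, 17-epoch, 12-network
    cohort with the planted lateralization, coupling and accuracy
    structure described in the module docstring.
    """

    n_subjects: int = 200
    n_vertices: int = 2000
    network_names: tuple[str, ...] = NETWORKS
    epoch_names: tuple[str, ...] = EPOCHS
    true_delta: pd.DataFrame = field(default_factory=default_true_delta)
    true_amplitude: pd.DataFrame = field(
        default_factory=default_true_amplitude)
    coupling: pd.DataFrame = field(default_factory=default_coupling)
    accuracy_weights: dict = field(default_factory=default_accuracy_weights)
    accuracy_baseline: float = 80.0
    vertex_noise_sd: float = 0.15
    subject_noise_sd: float = 0.10
    accuracy_noise_sd: float = 5.0
    age_effect: float = -0.3
    sex_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        nets, eps = list(self.network_names), list(self.epoch_names)
        if len(nets) > 12:
            raise ConfigError("at most 12 networks supported")
        for name in ("true_delta", "true_amplitude", "coupling"):
            tab = getattr(self, name)
            tab = tab.loc[nets, eps]
            setattr(self, name, tab)
        if (self.true_delta.abs() >= 1).any().any():
            raise ConfigError("|true_delta| must be < 1")
        if (self.true_amplitude <= 0).any().any():
            raise ConfigError(
                "true_amplitude must be > 0 (non-positive bilateral "
                "signal at zero noise)")
        for sd in (self.vertex_noise_sd, self.subject_noise_sd,
                   self.accuracy_noise_sd):
            if sd < 0:
                raise ConfigError("noise SDs must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            setattr(new, k, v)
        new.__post_init__()
        return new


@dataclass
class GroundTruth:
    """Planted parameters plus realized latent state, for recovery tests."""

    config: SimulationConfig
    latent: np.ndarray                  # (n_subjects,)
    true_network_delta: np.ndarray      # (n_subjects, n_epochs, n_networks)
    true_network_amplitude: np.ndarray  # same shape
    right_permutation: np.ndarray       # left vertex v <-> right vertex perm[v]
    labels: np.ndarray                  # vertex -> network index

    def partition(self) -> NetworkPartition:
        return NetworkPartition(labels=self.labels,
                                network_names=list(self.config.network_names))

    def to_jsonable(self) -> dict:
        cfg = self.config
        return {
            "n_subjects": cfg.n_subjects,
            "n_vertices": cfg.n_vertices,
            "seed": cfg.seed,
            "network_names": list(cfg.network_names),
            "epoch_names": list(cfg.epoch_names),
            "true_delta": cfg.true_delta.to_dict(),
            "true_amplitude": cfg.true_amplitude.to_dict(),
            "coupling": cfg.coupling.to_dict(),
            "accuracy_weights": cfg.accuracy_weights,
            "noise": {
                "vertex_noise_sd": cfg.vertex_noise_sd,
                "subject_noise_sd": cfg.subject_noise_sd,
                "accuracy_noise_sd": cfg.accuracy_noise_sd,
            },
            "latent": self.latent.tolist(),
            "right_permutation": self.right_permutation.tolist(),
        }


def generate_geometry(n_vertices: int, seed: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate mirrored left/right vertex coordinates.

    Left coordinates are pseudo-random points in a hemispheric slab
    (x < 0); right coordinates are the left ones mirrored across the
    midsagittal plane (x -> -x) and stored in a random permuted order.
    Returns (left_coords, right_coords, permutation) with
    ``right_coords[permutation[v]]`` mirroring left vertex ``v``.
    """
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    rng = np.random.default_rng(seed)
    # Near-regular mesh: surface meshes have roughly uniform vertex
    # spacing, so sample a jittered grid with a guaranteed minimum
    # separation (0.7 x grid spacing) rather than fully random points.
    m = max(int(np.ceil(n_vertices ** (1.0 / 3.0))), 1)
    extents = np.array([(-140.0, -10.0),     # x strictly left of midline
                        (-65.0, 65.0),
                        (-65.0, 65.0)])
    axes = [np.linspace(lo, hi, m + 1)[:-1] + (hi - lo) / (2 * m)
            for lo, hi in extents]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    cells = rng.choice(grid.shape[0], size=n_vertices, replace=False)
    spacing = (extents[:, 1] - extents[:, 0]) / m
    left = grid[cells] + rng.uniform(-0.15, 0.15, (n_vertices, 3)) * spacing
    mirrored = left.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    perm = rng.permutation(n_vertices)
    right = np.empty_like(mirrored)
    right[perm] = mirrored          # right vertex perm[v] mirrors left v
    return left, right, perm


def _assign_networks(n_vertices: int, n_networks: int) -> np.ndarray:
    """Contiguous, near-equal blocks of vertices per network."""
    return np.minimum((np.arange(n_vertices) * n_networks) // n_vertices,
                      n_networks - 1)


def generate_cohort(config: SimulationConfig, seed: int | None = None
                    ) -> tuple[ContrastDataset, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns the bilateral contrast dataset, the subject/covariate/accuracy
    table, and the ground-truth record (which also carries the network
    partition used).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n, v = config.n_subjects, config.n_vertices
    nets = list(config.network_names)
    eps = list(config.epoch_names)
    n_nets, n_eps = len(nets), len(eps)

    left_coords, right_coords, perm = generate_geometry(
        v, seed=int(rng.integers(2 ** 31)))
    labels = _assign_networks(v, n_nets)

    # covariates
    age = rng.uniform(22.0, 36.0, n)
    sex01 = rng.integers(0, 2, n)
    race = rng.choice(["white", "black", "asian", "other"], size=n,
                      p=[0.65, 0.15, 0.10, 0.10])
    bmi = np.clip(rng.normal(26.5, 4.5, n), 16.0, 50.0)
    handedness = np.clip(rng.normal(65.0, 40.0, n), -100.0, 100.0)
    rms_motion = np.abs(rng.normal(0.6, 0.4, n))

    z_age = (age - age.mean()) / age.std()
    latent = rng.normal(config.age_effect * z_age
                        + config.sex_effect * sex01, 1.0)

    # network-level noiseless measures
    amp0 = config.true_amplitude.to_numpy().T       # epochs x networks
    delta0 = config.true_delta.to_numpy().T
    coup = config.coupling.to_numpy().T
    s = config.subject_noise_sd
    A = amp0[None] * (1.0 + s * latent[:, None, None])
    A = np.maximum(A, 1e-6)
    eps_delta = rng.standard_normal((n, n_eps, n_nets))
    # coupling links the amplitude *deviation* (s * f) to asymmetry, so
    # zero subject noise implies both constant amplitude and no
    # coupling-driven asymmetry spread — the zero-noise cohort inverts to
    # the planted tables exactly for any coupling coefficient
    delta = (delta0[None] + coup[None] * (s * latent[:, None, None])
             + s * eps_delta)
    delta = np.clip(delta, -0.999, 0.999)

    # vertex values: block-constant network signal + independent noise
    A_vert = A[:, :, labels]                         # subj x epochs x vertices
    D_vert = delta[:, :, labels]
    left = A_vert * (1.0 + D_vert)
    right_matched = A_vert * (1.0 - D_vert)
    if config.vertex_noise_sd > 0:
        left = left + rng.normal(0.0, config.vertex_noise_sd, left.shape)
        right_matched = right_matched + rng.normal(
            0.0, config.vertex_noise_sd, right_matched.shape)
    right = np.empty_like(right_matched)
    right[:, :, perm] = right_matched   # store right hemisphere permuted

    dataset = ContrastDataset(
        subject_ids=[f"sub{i:04d}" for i in range(n)],
        epoch_names=eps,
        left_values=left, right_values=right,
        left_coords=left_coords, right_coords=right_coords)

    # accuracy from standardized noiseless network measures
    table = pd.DataFrame({
        "subject_id": dataset.subject_ids,
        "age": age, "sex": np.where(sex01 == 1, "M", "F"),
        "race": race, "bmi": bmi, "handedness": handedness,
        "rms_motion": rms_motion,
    })
    measures = {"delta": delta, "amplitude": A}
    for ep in SCORED_EPOCHS:
        if ep not in eps:
            continue
        e = eps.index(ep)
        acc = np.full(n, config.accuracy_baseline)
        for net, measure, weight in config.accuracy_weights.get(ep, []):
            if net not in nets:
                continue
            k = nets.index(net)
            x = measures[measure][:, e, k]
            sd = x.std()
            zx = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            acc = acc + weight * zx
        if config.accuracy_noise_sd > 0:
            acc = acc + rng.normal(0.0, config.accuracy_noise_sd, n)
        table[f"acc_{ep}"] = np.clip(acc, 0.0, 100.0)

    truth = GroundTruth(
        config=config, latent=latent,
        true_network_delta=delta, true_network_amplitude=A,
        right_permutation=perm, labels=labels)
    return dataset, table.set_index("subject_id"), truth
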