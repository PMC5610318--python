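"""Seeded generator of synthetic multiplexed Exchange-PAINT acquisitions.

The receptor field is a Thomas-type cluster process: cluster centres
("parents") follow a homogeneous Poisson process, each parent hosts a set of
receptor species, and receptors scatter isotropically around their parent.
Pairwise co-clustering between species is injected at the hosting step: for
a coupled pair, with the configured probability the two species' hosting
decisions at a parent are a single shared Bernoulli draw (they co-occupy or
co-avoid that cluster), otherwise they are independent.  This raises the
joint hosting probability from q^2 to c*q + (1-c)*q^2 while leaving each
species' marginal hosting rate — and hence its expected receptor total —
unchanged, so a coupling difference between two conditions changes only the
co-occupancy structure, not single-channel densities.

Imaging emulates DNA-PAINT statistics: each receptor is labelled by an
antibody-DNA conjugate with probability ``p_label``; a conjugate carries
``strands_per_conjugate`` docking strands and each strand yields a Poisson
number of localizations per imaging round (mean ``per_strand_rate``).  Every
localization is displaced by a per-antibody linkage offset (uniform in a
disk, the worst-case antibody/streptavidin/oligo geometry) plus isotropic
Gaussian fit noise, assigned a uniformly random frame within its channel's
imaging round, and shifted by the global drift at that frame.  Imaging
rounds are sequential per channel (Exchange-PAINT) with one global frame
index, so a single drift trace spans all rounds.  Fiducial markers emit one
localization per frame in every round under a reserved channel label.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locdata import FIDUCIAL_CHANNEL, LocalizationTable

DEFAULT_CHANNELS = ("EGFR", "ErbB2", "ErbB3", "IGF1R", "Met")

_MAX_RECEPTORS = 10**7


@dataclasses.dataclass
class SceneConfig:
    """Parameters of one synthetic cell / acquisition.

    Units: nm for lengths, parents per µm² for ``parent_intensity``,
    localizations per strand per imaging round for ``per_strand_rate``.
    """

    fov_width: float = 20_000.0
    fov_height: float = 20_000.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    receptors_per_channel: float = 2950.0
    parent_intensity: float = 7.0  # clusters per µm²
    mean_per_cluster: float = 2.0  # expected receptors per hosted channel
    cluster_sigma: float = 25.0  # nm scatter of receptors about their parent
    background_fraction: float = 0.05
    coupling: Mapping[tuple[str, str], float] | None = None
    p_label: float = 0.6
    strands_per_conjugate: int = 6
    poisson_strands: bool = False  # draw strand count ~ Poisson(6) per conjugate
    per_strand_rate: float = 7.2
    sigma_loc: float = 3.9
    linkage_radius: float = 20.0
    frames_per_round: int = 1500
    drift_total: tuple[float, float] = (0.0, 0.0)  # linear drift over the movie, nm
    n_fiducials: int = 0
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frames_per_round * len(self.channels)

    @property
    def area_um2(self) -> float:
        return self.fov_width * self.fov_height / 1e6

    def coupling_value(self, a: str, b: str) -> float:
        if not self.coupling:
            return 0.0
        return float(self.coupling.get((a, b), self.coupling.get((b, a), 0.0)))

    def validate(self) -> None:
        if self.fov_width <= 0 or self.fov_height <= 0:
            raise ValueError("field of view must have positive extent")
        if len(self.channels) != len(set(self.channels)):
            raise ValueError("channel labels must be unique")
        if FIDUCIAL_CHANNEL in self.channels:
            raise ValueError(f"channel label {FIDUCIAL_CHANNEL!r} is reserved")
        for name in ("receptors_per_channel", "parent_intensity", "mean_per_cluster",
                     "cluster_sigma", "per_strand_rate", "sigma_loc", "linkage_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("background_fraction", "p_label"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.strands_per_conjugate < 0 or self.frames_per_round < 1 or self.n_fiducials < 0:
            raise ValueError("counts must be valid non-negative integers")
        if self.coupling:
            for (a, b), p in self.coupling.items():
                if a not in self.channels or b not in self.channels or a == b:
                    raise ValueError(f"invalid coupling pair ({a}, {b})")
                if not 0.0 <= p <= 1.0:
                    raise ValueError("coupling probabilities must be in [0, 1]")
        if self.receptors_per_channel * len(self.channels) > _MAX_RECEPTORS:
            raise ValueError("configuration would generate more than 10^7 receptors")

    def base_host_probability(self) -> float:
        """Per-channel probability that a parent hosts the channel.

        Chosen so the expected clustered receptor count per channel equals
        (1 - background_fraction) * receptors_per_channel, before any extra
        hosting induced by pair coupling.
        """
        expected_parents = self.parent_intensity * self.area_um2
        denom = expected_parents * self.mean_per_cluster
        if denom <= 0:
            return 0.0
        q = (1.0 - self.background_fraction) * self.receptors_per_channel / denom
        if q > 1.0:
            raise ValueError(
                "receptors_per_channel is unreachable: raise parent_intensity or mean_per_cluster"
            )
        return q


@dataclasses.dataclass
class GroundTruth:
    """Known truth underlying one synthetic acquisition."""

    channels: tuple[str, ...]
    positions: dict[str, np.ndarray]  # channel -> (n, 2) nm
    parent_index: dict[str, np.ndarray]  # channel -> (n,) int, -1 for background
    parents: np.ndarray  # (P, 2) nm
    host: np.ndarray  # (P, C) bool hosting matrix
    fiducials: np.ndarray  # (F, 2) nm
    drift: np.ndarray  # (n_frames, 2) nm

    def validate(self, config: SceneConfig) -> None:
        for ch in self.channels:
            pos, par = self.positions[ch], self.parent_index[ch]
            if len(pos) != len(par):
                raise ValueError("positions and parent assignments disagree in length")
            clustered = par >= 0
            if clustered.any() and par[clustered].max() >= len(self.parents):
                raise ValueError("clustered receptor references a non-existent parent")
            if len(pos) and (
                (pos < 0).any()
                or (pos[:, 0] > config.fov_width).any()
                or (pos[:, 1] > config.fov_height).any()
            ):
                raise ValueError("receptor positions outside the field of view")


def linear_drift_trace(n_frames: int, total: tuple[float, float]) -> np.ndarray:
    """Linear per-frame drift from (0, 0) at frame 0 to ``total`` at the last frame."""
    if n_frames < 1:
        return np.zeros((0, 2))
    t = np.linspace(0.0, 1.0, n_frames)
    return np.outer(t, np.asarray(total, float))


def simulate_receptor_field(config: SceneConfig, seed=None) -> GroundTruth:
    """Draw receptor positions for every channel from the cluster process."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    C = len(config.channels)
    n_parents = rng.poisson(config.parent_intensity * config.area_um2)
    parents = rng.uniform(0, [config.fov_width, config.fov_height], size=(n_parents, 2))

    q = config.base_host_probability()
    host = rng.random((n_parents, C)) < q
    # coupled pairs share one hosting draw with probability c (processed in
    # canonical channel order; marginal hosting rates stay q)
    for ia, ib in itertools.combinations(range(C), 2):
        p = config.coupling_value(config.channels[ia], config.channels[ib])
        if p > 0:
            shared = rng.random(n_parents) < p
            host[shared, ib] = host[shared, ia]

    positions: dict[str, np.ndarray] = {}
    parent_index: dict[str, np.ndarray] = {}
    total = 0
    for ic, ch in enumerate(config.channels):
        hosts = np.flatnonzero(host[:, ic])
        counts = rng.poisson(config.mean_per_cluster, size=len(hosts))
        par = np.repeat(hosts, counts)
        scatter = rng.normal(0.0, config.cluster_sigma, size=(len(par), 2))
        clustered = parents[par] + scatter
        n_bg = rng.poisson(config.background_fraction * config.receptors_per_channel)
        bg = rng.uniform(0, [config.fov_width, config.fov_height], size=(n_bg, 2))
        pos = np.vstack([clustered, bg])
        np.clip(pos[:, 0], 0.0, config.fov_width, out=pos[:, 0])
        np.clip(pos[:, 1], 0.0, config.fov_height, out=pos[:, 1])
        positions[ch] = pos
        parent_index[ch] = np.concatenate([par, np.full(n_bg, -1, dtype=np.int64)])
        total += len(pos)
        if total > _MAX_RECEPTORS:
            raise ValueError("simulation would exceed 10^7 receptors")

    fiducials = rng.uniform(0, [config.fov_width, config.fov_height], size=(config.n_fiducials, 2))
    drift = linear_drift_trace(config.n_frames, config.drift_total)
    truth = GroundTruth(
        config.channels, positions, parent_index, parents, host, fiducials, drift
    )
    truth.validate(config)
    return truth


def simulate_imaging(truth: GroundTruth, config: SceneConfig, seed=None) -> LocalizationTable:
    """Turn a receptor field into a localization table (all imaging rounds)."""
    config.validate()
    if tuple(truth.channels) != tuple(config.channels):
        raise ValueError("ground truth and config disagree on channels")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    F = config.frames_per_round
    drift = truth.drift
    frames_all, xs, ys, chans = [], [], [], []

    for ic, ch in enumerate(config.channels):
        pos = truth.positions[ch]
        labelled = rng.random(len(pos)) < config.p_label
        anchors = pos[labelled]
        n_ab = len(anchors)
        # fixed per-antibody linkage displacement, uniform in a disk
        theta = rng.uniform(0.0, 2 * np.pi, n_ab)
        rad = config.linkage_radius * np.sqrt(rng.random(n_ab))
        anchors = anchors + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
        if config.poisson_strands:
            strands = rng.poisson(config.strands_per_conjugate, n_ab)
        else:
            strands = np.full(n_ab, config.strands_per_conjugate)
        # sum of per-strand Poisson draws == Poisson(rate * n_strands)
        n_loc = rng.poisson(config.per_strand_rate * strands)
        rep = np.repeat(np.arange(n_ab), n_loc)
        xy = anchors[rep] + rng.normal(0.0, config.sigma_loc, size=(len(rep), 2))
        frames = rng.integers(ic * F, (ic + 1) * F, size=len(rep))
        xy = xy + drift[frames]
        frames_all.append(frames)
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
        chans.extend([ch] * len(rep))

    if len(truth.fiducials):
        n_frames = config.n_frames
        fid = np.repeat(truth.fiducials, n_frames, axis=0)
        frames = np.tile(np.arange(n_frames), len(truth.fiducials))
        xy = fid + rng.normal(0.0, config.sigma_loc, size=fid.shape) + drift[frames]
        frames_all.append(frames)
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
        chans.extend([FIDUCIAL_CHANNEL] * len(frames))

    frame = np.concatenate(frames_all) if frames_all else np.zeros(0, dtype=np.int64)
    x = np.concatenate(xs) if xs else np.zeros(0)
    y = np.concatenate(ys) if ys else np.zeros(0)
    order = np.argsort(frame, kind="stable")
    chan_arr = np.asarray(chans, dtype=object)
    table = LocalizationTable.from_arrays(
        frame[order],
        x[order],
        y[order],
        chan_arr[order] if len(order) else [],
        sigma=np.full(len(order), config.sigma_loc),
        fov=(config.fov_width, config.fov_height),
        n_frames=config.n_frames,
    )
    return table


def simulate_scene(config: SceneConfig, seed=None) -> tuple[LocalizationTable, GroundTruth]:
    """Field + imaging in one call, both stages fed from one seed sequence."""
    seed = config.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_field, s_img = ss.spawn(2)
    truth = simulate_receptor_field(config, s_field)
    table = simulate_imaging(truth, config, s_img)
    return table, truth


def simulate_experiment(
    config_unstim: SceneConfig,
    config_stim: SceneConfig,
    n_cells_per_condition: int,
    seed=None,
) -> list[tuple[LocalizationTable, int, GroundTruth]]:
    """Simulate a two-condition experiment; labels 0 (unstim) / 1 (stim)."""
    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be at least 1")
    if tuple(config_unstim.channels) != tuple(config_stim.channels):
        raise ValueError("conditions must share the channel set")
    if (config_unstim.fov_width, config_unstim.fov_height) != (
        config_stim.fov_width,
        config_stim.fov_height,
    ):
        raise ValueError("conditions must share the field of view")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_cells_per_condition)
    out = []
    for i in range(n_cells_per_condition):
        table, truth = simulate_scene(config_unstim, children[i])
        out.append((table, 0, truth))
    for i in range(n_cells_per_condition):
        table, truth = simulate_scene(config_stim, children[n_cells_per_condition + i])
        out.append((table, 1, truth))
    return out
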