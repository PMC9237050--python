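"""Synthetic cohort generation: parcellations, connectomes, lesions, behavior.

All generators are deterministic for a fixed seed and produce symmetric,
zero-diagonal, nonnegative-integer streamline-count matrices.  Default
calibration targets a healthy cohort with mean binary degree ~18 and
structural-entropy (connectivity disorder) ~0.059 after the <=3-streamline
threshold, matching the statistical regime the downstream analysis assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RSN_NAMES",
    "Parcellation",
    "LesionSpec",
    "SubjectRecord",
    "HealthyCalibration",
    "generate_parcellation",
    "generate_healthy_connectome",
    "apply_lesion",
    "contiguous_lesion",
    "remodel_recovery",
    "generate_behavior",
]

#: Resting-state network labels used for default parcellations.
RSN_NAMES = ("VIS", "DMN", "SMM", "AUD", "COP", "SAL", "VAT", "DAN", "FPN", "CPA")

# Default layout mirrors a 324-node cortical parcellation with 159 left- and
# 165 right-hemisphere parcels; the left share below reproduces that split.
_LEFT_SHARE = 159.0 / 324.0


@dataclass
class Parcellation:
    """Node metadata: hemisphere, network label, homotopic partner, position."""

    node_id: np.ndarray          # (N,) int
    hemisphere: np.ndarray       # (N,) str, 'L' or 'R'
    network: np.ndarray          # (N,) str
    homotope: np.ndarray         # (N,) int, -1 when unpaired
    position: np.ndarray         # (N, 3) float

    @property
    def n_nodes(self) -> int:
        return len(self.node_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_id,
                "hemisphere": self.hemisphere,
                "network": self.network,
                "homotope": self.homotope,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "z": self.position[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        return cls(
            node_id=df["node_id"].to_numpy(int),
            hemisphere=df["hemisphere"].to_numpy(str),
            network=df["network"].to_numpy(str),
            homotope=df["homotope"].to_numpy(int),
            position=df[["x", "y", "z"]].to_numpy(float),
        )

    def homotopic_pairs(self) -> np.ndarray:
        """Return (n_pairs, 2) array of homotopic (i, j) pairs with i < j."""
        pairs = []
        for i, h in enumerate(self.homotope):
            if h >= 0 and i < h:
                pairs.append((i, h))
        return np.asarray(pairs, dtype=int).reshape(-1, 2)

    def validate(self) -> None:
        n = self.n_nodes
        for i, h in enumerate(self.homotope):
            if h < 0:
                continue
            if not (0 <= h < n):
                raise ValueError(f"homotope index {h} out of range")
            if self.homotope[h] != i:
                raise ValueError("homotope relation is not symmetric")
            if self.hemisphere[h] == self.hemisphere[i]:
                raise ValueError("homotopic pair within a single hemisphere")


@dataclass
class LesionSpec:
    """Specification of a focal lesion applied to a connectome."""

    lesioned_nodes: Sequence[int] = ()
    interhemispheric_scale: float = 1.0
    edge_dropout: float = 0.0
    seed: int = 0

    def validate(self, n_nodes: int) -> None:
        if not 0.0 <= self.interhemispheric_scale <= 1.0:
            raise ValueError("interhemispheric_scale must lie in [0, 1]")
        if not 0.0 <= self.edge_dropout <= 1.0:
            raise ValueError("edge_dropout must lie in [0, 1]")
        nodes = np.asarray(list(self.lesioned_nodes), dtype=int)
        if nodes.size and (nodes.min() < 0 or nodes.max() >= n_nodes):
            raise ValueError("lesioned node outside the parcellation")


@dataclass
class SubjectRecord:
    """One subject at one timepoint, with its connectome and behavior score."""

    subject_id: str
    group: str                    # 'control' | 'patient'
    timepoint: str                # 't1' | 't2'
    connectome: "object" = None   # RawConnectome (import cycle avoided)
    behavior: Optional[float] = None


@dataclass
class HealthyCalibration:
    """Generator parameters for healthy connectomes.

    Streamline counts follow a three-tier law: a near-regular backbone of
    *strong* bundles (rounded-normal counts carrying most of each node's
    normalized input), a thin layer of *medium* rounded-lognormal
    connections, and *weak* connections that mostly fall at or below the
    <=3-streamline threshold.  A per-row share cap keeps any single bundle
    from dominating its node's normalized input.  Defaults are calibrated
    so that, after thresholding, the cohort-mean binary degree falls in the
    18 +/- 3 band, the structural entropy in 0.059 +/- 0.004, and the
    simulated critical threshold near 0.122.
    """

    strong_degree: float = 17.0           # target per-node strong-bundle degree
    medium_degree: float = 2.0            # mean per-node medium-edge degree (raw)
    weak_degree: float = 5.0              # mean per-node weak-edge degree (raw)
    distance_scale: float = 35.0          # mm, exponential decay of edge prob
    strong_mean: float = 85.0             # mean strong streamline count
    strong_sd: float = 6.0                # sd of strong streamline count
    medium_log_mean: float = 2.3          # lognormal log-mean of medium counts
    medium_log_sd: float = 0.9
    weak_log_mean: float = 0.3            # lognormal log-mean of weak counts
    weak_log_sd: float = 1.0              # mostly at or below the threshold
    cap_share: float = 0.11               # max share of an edge in its row sum
    homotopic_edge_prob: float = 0.90
    homotopic_weight_mult: float = 1.2    # applied to (always strong) homotopic edges


def _hemisphere_sizes(n_nodes: int) -> tuple[int, int]:
    n_left = int(round(n_nodes * _LEFT_SHARE))
    n_left = min(max(n_left, 1), n_nodes - 1) if n_nodes >= 2 else n_nodes
    return n_left, n_nodes - n_left


def generate_parcellation(
    n_nodes: int = 324, n_networks: int = 10, seed: int = 0
) -> Parcellation:
    """Generate a bilateral parcellation with mirrored homotopic pairs.

    Nodes 0..n_left-1 are left hemisphere, the rest right.  The first
    min(n_left, n_right) nodes of each hemisphere form homotopic pairs at
    mirrored positions; leftover right-hemisphere nodes are unpaired.
    Networks are assigned per homotopic pair so every network (when
    n_networks <= number of pairs) has members in both hemispheres.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if n_networks > n_nodes:
        raise ValueError("n_networks may not exceed n_nodes")

    rng = np.random.default_rng(seed)
    n_left, n_right = _hemisphere_sizes(n_nodes)
    n_pairs = min(n_left, n_right)

    # Mirrored positions: lateral coordinate flips sign across the midline.
    base = np.column_stack(
        [
            rng.uniform(12.0, 70.0, n_pairs),
            rng.uniform(0.0, 160.0, n_pairs),
            rng.uniform(0.0, 100.0, n_pairs),
        ]
    )
    position = np.zeros((n_nodes, 3))
    position[:n_pairs] = base * np.array([-1.0, 1.0, 1.0])
    position[n_left : n_left + n_pairs] = base
    n_extra = n_nodes - 2 * n_pairs
    if n_extra > 0:
        extra = np.column_stack(
            [
                rng.uniform(12.0, 70.0, n_extra),
                rng.uniform(0.0, 160.0, n_extra),
                rng.uniform(0.0, 100.0, n_extra),
            ]
        )
        # Unpaired nodes sit in whichever hemisphere has the surplus.
        sign = -1.0 if n_left > n_pairs else 1.0
        lo = n_pairs if n_left > n_pairs else n_left + n_pairs
        position[lo : lo + n_extra] = extra * np.array([sign, 1.0, 1.0])

    hemisphere = np.array(["L"] * n_left + ["R"] * n_right)
    homotope = np.full(n_nodes, -1, dtype=int)
    homotope[:n_pairs] = np.arange(n_left, n_left + n_pairs)
    homotope[n_left : n_left + n_pairs] = np.arange(n_pairs)

    if n_networks <= len(RSN_NAMES):
        names = list(RSN_NAMES[:n_networks])
    else:
        names = list(RSN_NAMES) + [
            f"NET{k}" for k in range(len(RSN_NAMES), n_networks)
        ]
    pair_nets = np.empty(n_pairs, dtype=object)
    head = min(n_networks, n_pairs)
    pair_nets[:head] = names[:head]            # guarantee full coverage
    if n_pairs > head:
        pair_nets[head:] = rng.choice(names, size=n_pairs - head)
    network = np.empty(n_nodes, dtype=object)
    network[:n_pairs] = pair_nets
    network[n_left : n_left + n_pairs] = pair_nets
    unassigned = network == None  # noqa: E711 - object array sentinel
    if unassigned.any():
        network[unassigned] = rng.choice(names, size=int(unassigned.sum()))

    parc = Parcellation(
        node_id=np.arange(n_nodes),
        hemisphere=hemisphere,
        network=network.astype(str),
        homotope=homotope,
        position=position,
    )
    parc.validate()
    return parc


def generate_healthy_connectome(
    parcellation: Parcellation,
    calibration: Optional[HealthyCalibration] = None,
    seed: int = 0,
    subject_id: str = "synth",
    timepoint: str = "t1",
):
    """Generate a healthy streamline-count matrix on the given parcellation.

    Edge probability decays exponentially with inter-node distance (many
    short-range, few long-range connections); homotopic pairs receive
    elevated connection probability and weight.  Streamline counts are
    rounded-lognormal, producing entries below and above the downstream
    <=3-streamline threshold.
    """
    from neurocrit.connectome import RawConnectome

    cal = calibration or HealthyCalibration()
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    if cal.strong_degree + cal.medium_degree + cal.weak_degree > n - 1:
        raise ValueError(
            "infeasible calibration: requested density exceeds complete graph"
        )

    pos = parcellation.position
    dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    kernel = np.exp(-dist / cal.distance_scale)
    np.fill_diagonal(kernel, 0.0)

    # Strong backbone: each node picks ~strong_degree/2 partners with
    # probability proportional to the distance kernel, keeping the strong
    # degree nearly regular so that row-normalized backbone weights cluster
    # around 1/K.
    strong = np.zeros((n, n), dtype=bool)
    m = max(1, int(round(cal.strong_degree / 2.0)))
    for i in range(n):
        p = kernel[i] / kernel[i].sum()
        picks = rng.choice(n, size=min(m, n - 1), replace=False, p=p)
        strong[i, picks] = True
    strong |= strong.T

    homotope = parcellation.homotope
    for i in range(n):
        h = homotope[i]
        if h > i and rng.random() < cal.homotopic_edge_prob:
            strong[i, h] = strong[h, i] = True

    # Degree repair: top up nodes far below the target and trim nodes far
    # above it so the backbone degree distribution stays narrow.
    target = int(round(cal.strong_degree))
    for _ in range(3):
        deg = strong.sum(axis=1)
        for i in np.flatnonzero(deg < target - 1):
            deficit = target - 1 - int(strong[i].sum())
            if deficit <= 0:
                continue
            p = kernel[i].copy()
            p[strong[i]] = 0.0
            p[i] = 0.0
            p /= p.sum()
            picks = rng.choice(n, size=deficit, replace=False, p=p)
            strong[i, picks] = True
            strong[picks, i] = True
        deg = strong.sum(axis=1)
        for i in np.flatnonzero(deg > target + 1):
            excess = int(strong[i].sum()) - (target + 1)
            if excess <= 0:
                continue
            nbrs = np.flatnonzero(strong[i])
            # only drop edges whose other endpoint stays above the floor
            droppable = nbrs[(strong[nbrs].sum(axis=1) > target - 1)
                             & (parcellation.homotope[nbrs] != i)]
            if droppable.size:
                drop = rng.choice(droppable, size=min(excess, droppable.size),
                                  replace=False)
                strong[i, drop] = False
                strong[drop, i] = False

    # Medium and weak connections: Bernoulli with distance-decaying
    # probability; medium counts survive the streamline threshold with small
    # normalized shares, weak counts mostly fall at or below it.
    iu, ju = np.triu_indices(n, k=1)
    kvals = kernel[iu, ju]
    ksum = kernel.sum()
    p_med = np.clip(cal.medium_degree * n / ksum * kvals, 0.0, 1.0)
    p_weak = np.clip(cal.weak_degree * n / ksum * kvals, 0.0, 1.0)
    s_mask = strong[iu, ju]
    medium = (rng.random(iu.size) < p_med) & ~s_mask
    weak = (rng.random(iu.size) < p_weak) & ~s_mask & ~medium

    counts = np.zeros(iu.size, dtype=np.int64)
    w_weak = rng.lognormal(cal.weak_log_mean, cal.weak_log_sd, iu.size)
    counts[weak] = np.maximum(1, np.round(w_weak[weak])).astype(np.int64)
    w_med = rng.lognormal(cal.medium_log_mean, cal.medium_log_sd, iu.size)
    counts[medium] = np.maximum(1, np.round(w_med[medium])).astype(np.int64)
    w_strong = rng.normal(cal.strong_mean, cal.strong_sd, iu.size)
    w_strong *= np.where(homotope[iu] == ju, cal.homotopic_weight_mult, 1.0)
    counts[s_mask] = np.maximum(1, np.round(w_strong[s_mask])).astype(np.int64)

    W = np.zeros((n, n), dtype=np.int64)
    W[iu, ju] = counts
    W[ju, iu] = counts

    # Share cap: no edge may exceed cap_share of either endpoint's total
    # count, keeping the strongest homeostatically normalized weights from
    # dominating their row.
    Wf = W.astype(float)
    for _ in range(4):
        sums = Wf.sum(axis=1)
        cap = cal.cap_share * np.minimum(sums[:, None], sums[None, :])
        Wf = np.minimum(Wf, cap)
    W = np.where(W > 0, np.maximum(np.round(Wf), 1.0), 0.0).astype(np.int64)
    return RawConnectome(
        W=W, parcellation=parcellation, subject_id=subject_id, timepoint=timepoint
    )


def contiguous_lesion(
    parcellation: Parcellation,
    size: int,
    seed: int = 0,
    hemisphere: Optional[str] = None,
) -> np.ndarray:
    """Pick a spatially contiguous node set within one hemisphere.

    A random seed node is drawn in the chosen hemisphere and its
    ``size - 1`` nearest same-hemisphere neighbours are added, emulating a
    focal lesion.
    """
    rng = np.random.default_rng(seed)
    hemi = hemisphere or rng.choice(["L", "R"])
    candidates = np.flatnonzero(parcellation.hemisphere == hemi)
    if size > candidates.size:
        raise ValueError("lesion larger than the hemisphere")
    center = rng.choice(candidates)
    d = np.linalg.norm(
        parcellation.position[candidates] - parcellation.position[center], axis=1
    )
    return candidates[np.argsort(d)[:size]]


def apply_lesion(connectome, spec: LesionSpec):
    """Apply a focal lesion: node deletion, inter-hemispheric scaling, dropout."""
    parc = connectome.parcellation
    spec.validate(parc.n_nodes)
    rng = np.random.default_rng(spec.seed)

    W = connectome.W.copy()
    nodes = np.asarray(list(spec.lesioned_nodes), dtype=int)
    if nodes.size:
        W[nodes, :] = 0
        W[:, nodes] = 0

    if spec.interhemispheric_scale < 1.0:
        left = parc.hemisphere == "L"
        cross = left[:, None] != left[None, :]
        W = np.where(
            cross, np.round(W * spec.interhemispheric_scale).astype(W.dtype), W
        )

    if spec.edge_dropout > 0.0:
        iu, ju = np.triu_indices(parc.n_nodes, k=1)
        alive = np.flatnonzero(W[iu, ju] > 0)
        n_drop = int(round(spec.edge_dropout * alive.size))
        if n_drop:
            drop = rng.choice(alive, size=n_drop, replace=False)
            W[iu[drop], ju[drop]] = 0
            W[ju[drop], iu[drop]] = 0

    return dataclasses.replace(connectome, W=W)


def remodel_recovery(
    lesioned,
    healthy_template,
    recovery_fraction: float,
    rewire_fraction: float = 0.0,
    seed: int = 0,
):
    """Partially restore a lesioned connectome toward a healthy template.

    Surviving-node edges move a fraction of the way back to the template's
    values; ``rewire_fraction`` additionally creates new edges absent from
    the template (weights resampled from the template's surviving edges).
    Nodes with all-zero rows in the lesioned input are treated as destroyed
    and stay disconnected.
    """
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must lie in [0, 1]")
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError("rewire_fraction must lie in [0, 1]")
    if lesioned.parcellation.n_nodes != healthy_template.parcellation.n_nodes:
        raise ValueError("connectomes must share a parcellation")

    rng = np.random.default_rng(seed)
    n = lesioned.parcellation.n_nodes
    L = lesioned.W
    Tm = healthy_template.W
    dead = np.flatnonzero(L.sum(axis=1) == 0)
    alive_mask = np.ones(n, dtype=bool)
    alive_mask[dead] = False

    iu, ju = np.triu_indices(n, k=1)
    both_alive = alive_mask[iu] & alive_mask[ju]
    vals = L[iu, ju].astype(np.int64)
    delta = np.round(recovery_fraction * (Tm[iu, ju] - L[iu, ju])).astype(np.int64)
    vals = np.where(both_alive, vals + delta, vals)

    if rewire_fraction > 0.0:
        tmpl_vals = Tm[iu, ju]
        tmpl_edges = both_alive & (tmpl_vals > 0)
        candidates = np.flatnonzero(both_alive & (tmpl_vals == 0) & (vals == 0))
        n_new = min(int(round(rewire_fraction * tmpl_edges.sum())), candidates.size)
        if n_new and tmpl_edges.any():
            pick = rng.choice(candidates, size=n_new, replace=False)
            pool = tmpl_vals[tmpl_edges]
            vals[pick] = rng.choice(pool, size=n_new)

    W = np.zeros((n, n), dtype=np.int64)
    W[iu, ju] = np.maximum(vals, 0)
    W[ju, iu] = W[iu, ju]
    return dataclasses.replace(lesioned, W=W)


def generate_behavior(
    I1: np.ndarray,
    I2: np.ndarray,
    coefficients: tuple[float, float, float] = (0.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    control_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Linear-Gaussian composite behavior score driven by (I1, I2).

    B = intercept + c1*I1 - c2*I2 + noise, then standardized to mean 0 and
    SD 1 on the control subset (all subjects when no mask is given).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if not (np.all(np.isfinite(I1)) and np.all(np.isfinite(I2))):
        raise ValueError("criticality integrals must be finite")
    c0, c1, c2 = coefficients
    rng = np.random.default_rng(seed)
    raw = c0 + c1 * I1 - c2 * I2 + rng.normal(0.0, noise_sd, size=I1.shape)
    ref = raw if control_mask is None else raw[np.asarray(control_mask, bool)]
    mu = float(np.mean(ref))
    sd = float(np.std(ref))
    if sd == 0.0:
        return raw - mu
    return (raw - mu) / sd
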