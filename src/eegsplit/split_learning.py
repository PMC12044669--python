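"""Split-learning simulation: client encoders, a server head, and the
activation/gradient packet exchange across the cut layer.

The composed model is f(x; θ, φ) = f_server(f_client(x; θ); φ). Each client
holds its own encoder parameters θ_i and its local feature partition; the
server holds φ. Only latent activations z (with labels — the label-sharing
variant, since the server computes the loss) travel client → server, and
only dL/dz travels back. Raw features never enter a packet: the packet
schema has exactly the fields (client_id, z, labels, batch_index) and is
audited as such in the tests.

Training is two-phase, reconciling gradient-based split training with a
tree-ensemble server head (which is not gradient-trainable):

* Phase A — for each epoch, clients take turns round-robin; per batch the
  client sends an activation packet, the server computes softmax
  cross-entropy, takes one Adam step on φ, and returns dL/dz; the client
  backpropagates through its encoder and takes one Adam step on θ_i.
* Phase B — all θ_i freeze; clients stream latents for their full
  partitions and the server fits a random forest on the pooled latents and
  labels. Inference then routes z through the forest.

Transport is in-process message passing with explicit JSON serialization,
so packet audits and transfer timing are meaningful without sockets.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .errors import ConfigError, InputError, StateError
from .preprocessing import FeatureMatrix

# ---------------------------------------------------------------------------
# Packets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationPacket:
    """Client → server message. Carries latents and labels only."""

    client_id: int
    z: np.ndarray
    labels: np.ndarray
    batch_index: int

    def payload(self) -> dict:
        """The exact over-the-wire content; no other fields exist."""
        return {
            "client_id": int(self.client_id),
            "z": np.asarray(self.z, dtype=np.float64).tolist(),
            "labels": np.asarray(self.labels, dtype=np.int64).tolist(),
            "batch_index": int(self.batch_index),
        }

    def serialize(self) -> bytes:
        return json.dumps(self.payload()).encode()


@dataclass(frozen=True)
class GradientPacket:
    """Server → client message: dL/dz shaped like the triggering z."""

    client_id: int
    dl_dz: np.ndarray
    batch_index: int

    def payload(self) -> dict:
        return {
            "client_id": int(self.client_id),
            "dl_dz": np.asarray(self.dl_dz, dtype=np.float64).tolist(),
            "batch_index": int(self.batch_index),
        }

    def serialize(self) -> bytes:
        return json.dumps(self.payload()).encode()


# ---------------------------------------------------------------------------
# Client / server state
# ---------------------------------------------------------------------------


class FeatureTokenEncoder(nn.Module):
    """Client-side encoder: standardize → channel tokens → transformer.

    Wraps a :class:`~eegsplit.nn.TransformerBackbone` with a fixed
    (non-trainable) standardization learned from the client's local data,
    taking flat ``(batch, n_features)`` rows.
    """

    def __init__(
        self,
        n_features: int,
        mean: np.ndarray,
        scale: np.ndarray,
        token_dim: int = 6,
        d_model: int = 32,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 64,
        rng: np.random.Generator | None = None,
    ):
        if n_features % token_dim != 0:
            raise ConfigError(
                f"n_features={n_features} is not a multiple of token_dim={token_dim}"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        self.n_features = n_features
        self.token_dim = token_dim
        self.mean = np.asarray(mean, dtype=np.float64)
        self.scale = np.where(np.asarray(scale, dtype=np.float64) > 0, scale, 1.0)
        self.backbone = nn.TransformerBackbone(
            n_features // token_dim, token_dim, d_model, n_heads, n_layers, d_ff, rng
        )
        self.latent_dim = d_model

    def parameters(self) -> list[nn.Parameter]:
        return self.backbone.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise InputError(f"expected (batch, {self.n_features}) input, got {x.shape}")
        xs = (x - self.mean) / self.scale
        tokens = xs.reshape(x.shape[0], -1, self.token_dim)
        return self.backbone.forward(tokens)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.backbone.backward(dout)


class ClientState:
    """One client: encoder parameters θ_i plus its local data partition.

    The local feature matrix is never serialized into any outbound packet;
    only encoder outputs leave this object.
    """

    def __init__(
        self,
        client_id: int,
        encoder: nn.Module,
        data: FeatureMatrix,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.client_id = int(client_id)
        self.encoder = encoder
        self.data = data
        self.optimizer = nn.Adam(encoder.parameters(), lr=lr)
        self.seed = seed
        self._batch_counter = 0

    @property
    def n_samples(self) -> int:
        return self.data.n_epochs


class ServerState:
    """The server: head parameters φ, loss, and the Phase-B forest."""

    def __init__(
        self,
        latent_dim: int,
        n_classes: int = 2,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.n_classes = n_classes
        self.head = nn.Linear(latent_dim, n_classes, rng)
        self.optimizer = nn.Adam(self.head.parameters(), lr=lr)
        self.head_mode = "softmax"
        self.forest_: RandomForestClassifier | None = None
        self.seed = seed


def make_transformer_client(
    client_id: int,
    data: FeatureMatrix,
    token_dim: int = 6,
    d_model: int = 32,
    n_heads: int = 4,
    n_layers: int = 2,
    d_ff: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> ClientState:
    """Build a client whose θ_i is a channel-token transformer encoder.

    Standardization statistics come from the client's own partition
    (local preprocessing stays local).
    """
    mean = data.values.mean(axis=0)
    scale = data.values.std(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(client_id,)))
    encoder = FeatureTokenEncoder(
        data.n_features, mean, scale, token_dim, d_model, n_heads, n_layers, d_ff, rng
    )
    return ClientState(client_id, encoder, data, lr=lr, seed=seed)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def partition_clients(
    features: FeatureMatrix,
    k: int,
    mode: str = "subject",
    seed: int = 0,
) -> list[FeatureMatrix]:
    """Split a feature matrix into k disjoint, exhaustive client partitions.

    ``subject`` mode deals whole subjects to clients (a subject's epochs
    never straddle two clients), per class round-robin after a seeded
    shuffle so every client receives both classes. ``epoch`` mode deals
    individual rows the same way.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if mode not in ("subject", "epoch"):
        raise InputError("mode must be 'subject' or 'epoch'")
    rng = np.random.default_rng(seed)
    assignment = np.empty(features.n_epochs, dtype=np.int64)

    if mode == "subject":
        # class of each subject = class of its epochs (constant per subject)
        subj_label: dict = {}
        for s, lab in zip(features.groups, features.labels):
            subj_label.setdefault(s, int(lab))
        for cls in (0, 1):
            subjects = sorted(s for s, lab in subj_label.items() if lab == cls)
            if len(subjects) < k:
                raise InputError(
                    f"need at least k={k} subjects of class {cls} for a "
                    f"subject-level partition, got {len(subjects)}"
                )
            order = rng.permutation(len(subjects))
            for pos, si in enumerate(order):
                assignment[np.asarray(features.groups == subjects[si])] = pos % k
    else:
        for cls in (0, 1):
            rows = np.flatnonzero(features.labels == cls)
            if len(rows) < k:
                raise InputError(
                    f"need at least k={k} epochs of class {cls} for an "
                    f"epoch-level partition, got {len(rows)}"
                )
            order = rng.permutation(rows)
            for pos, ri in enumerate(order):
                assignment[ri] = pos % k

    return [features.subset(np.flatnonzero(assignment == i)) for i in range(k)]


# ---------------------------------------------------------------------------
# Protocol steps
# ---------------------------------------------------------------------------


def client_forward(
    client: ClientState, batch_indices: np.ndarray
) -> ActivationPacket:
    """Forward the batch through f_client and wrap the latents in a packet."""
    batch_indices = np.asarray(batch_indices)
    if batch_indices.size == 0:
        raise InputError("batch must be non-empty")
    z = client.encoder.forward(client.data.values[batch_indices])
    packet = ActivationPacket(
        client_id=client.client_id,
        z=z,
        labels=client.data.labels[batch_indices],
        batch_index=client._batch_counter,
    )
    client._batch_counter += 1
    return packet


def server_step(
    server: ServerState, packet: ActivationPacket
) -> tuple[float, GradientPacket]:
    """Cross-entropy on f_server(z; φ), one Adam step on φ, return dL/dz.

    dL/dz is computed at the pre-update φ (the same parameters the loss was
    evaluated with), so the gradient the client receives is exact.
    """
    if server.head_mode != "softmax":
        raise StateError(
            "server_step requires the softmax training head; the server is "
            f"in {server.head_mode!r} mode"
        )
    z = np.asarray(packet.z, dtype=np.float64)
    y = np.asarray(packet.labels, dtype=np.int64)
    if z.ndim != 2 or z.shape[1] != server.latent_dim:
        raise InputError(f"expected latents of width {server.latent_dim}, got {z.shape}")
    server.optimizer.zero_grad()
    logits = server.head.forward(z)
    loss, dlogits = nn.softmax_cross_entropy(logits, y)
    dz = server.head.backward(dlogits)
    server.optimizer.step()
    return loss, GradientPacket(packet.client_id, dz, packet.batch_index)


def client_apply_gradient(client: ClientState, packet: GradientPacket) -> None:
    """Backpropagate the server's dL/dz through θ_i and take one Adam step."""
    client.optimizer.zero_grad()
    client.encoder.backward(np.asarray(packet.dl_dz, dtype=np.float64))
    client.optimizer.step()


def train_step(
    client: ClientState, server: ServerState, batch_indices: np.ndarray
) -> float:
    """One full exchange: client forward → server step → client update."""
    packet = client_forward(client, batch_indices)
    loss, gpacket = server_step(server, packet)
    client_apply_gradient(client, gpacket)
    return loss


def fit_split(
    clients: list[ClientState],
    server: ServerState,
    n_epochs: int = 10,
    batch_size: int = 64,
    seed: int = 0,
    schedule: str = "round_robin",
    rf_params: dict | None = None,
    fit_forest: bool = True,
    packet_log: list | None = None,
) -> dict:
    """Run Phase A (gradient exchange) then Phase B (server forest refit).

    ``n_epochs = 0`` is a legal no-op for Phase A. With ``packet_log`` a
    list, every outbound activation packet's serialized payload is
    appended (the privacy-audit hook). Returns a history dict with the
    per-step losses.
    """
    if schedule != "round_robin":
        raise ConfigError(f"unknown schedule {schedule!r}")
    if not clients:
        raise InputError("need at least one client")
    losses: list[float] = []

    rng = np.random.default_rng(seed)
    for _ in range(n_epochs):
        # per-epoch shuffled batch queues, one per client
        queues = []
        for c in clients:
            order = rng.permutation(c.n_samples)
            queues.append(
                [order[s : s + batch_size] for s in range(0, c.n_samples, batch_size)]
            )
        round_ = 0
        while any(round_ < len(q) for q in queues):
            for c, q in zip(clients, queues):
                if round_ < len(q):
                    packet = client_forward(c, q[round_])
                    if packet_log is not None:
                        packet_log.append(packet.serialize())
                    loss, gpacket = server_step(server, packet)
                    client_apply_gradient(c, gpacket)
                    losses.append(loss)
            round_ += 1

    if fit_forest:
        zs, ys = [], []
        for c in clients:
            packet = client_forward(c, np.arange(c.n_samples))
            if packet_log is not None:
                packet_log.append(packet.serialize())
            zs.append(np.asarray(packet.z))
            ys.append(np.asarray(packet.labels))
        z_all = np.vstack(zs)
        y_all = np.concatenate(ys)
        if len(np.unique(y_all)) < 2:
            raise InputError("server forest needs both classes in pooled labels")
        params = {"n_estimators": 100, **(rf_params or {})}
        forest = RandomForestClassifier(random_state=server.seed, **params)
        forest.fit(z_all, y_all)
        server.forest_ = forest
        server.head_mode = "random_forest"

    return {"losses": losses}


def split_predict(
    clients: list[ClientState],
    server: ServerState,
    features_per_client: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Per-client predictions through the trained cut: z → server forest."""
    if server.head_mode != "random_forest" or server.forest_ is None:
        raise StateError("split_predict requires Phase B (forest fit) to have run")
    out = []
    for i, c in enumerate(clients):
        x = (
            features_per_client[i]
            if features_per_client is not None
            else c.data.values
        )
        z = c.encoder.forward(np.asarray(x, dtype=np.float64))
        out.append(server.forest_.predict(z).astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# Inference-time accounting
# ---------------------------------------------------------------------------


@dataclass
class TimingRecord:
    """Wall-clock inference decomposition across the k clients.

    ``t_inference[i] = t_local[i] + t_transfer[i] + t_server`` holds
    exactly by construction; ``average`` is the arithmetic mean over
    clients.
    """

    t_local: np.ndarray
    t_transfer: np.ndarray
    t_server: float
    k: int

    @property
    def t_inference(self) -> np.ndarray:
        return self.t_local + self.t_transfer + self.t_server

    @property
    def average(self) -> float:
        return float(np.mean(self.t_inference))


def measure_inference(
    clients: list[ClientState],
    server: ServerState,
    samples_per_client: int = 1,
) -> TimingRecord:
    """Time one inference round: local forward, packet transfer, server head.

    Transfer time covers explicit serialization plus in-process hand-off
    (deserialization); the server component is the forest prediction time,
    averaged over clients and shared in each client's total.
    """
    if server.head_mode != "random_forest" or server.forest_ is None:
        raise StateError("measure_inference requires a trained system (Phase B)")
    t_local = np.zeros(len(clients))
    t_transfer = np.zeros(len(clients))
    server_times = np.zeros(len(clients))
    for i, c in enumerate(clients):
        x = c.data.values[:samples_per_client]
        t0 = time.perf_counter()
        z = c.encoder.forward(x)
        t1 = time.perf_counter()
        packet = ActivationPacket(c.client_id, z, c.data.labels[:samples_per_client], 0)
        wire = packet.serialize()
        received = json.loads(wire.decode())
        z_srv = np.asarray(received["z"], dtype=np.float64)
        t2 = time.perf_counter()
        server.forest_.predict(z_srv)
        t3 = time.perf_counter()
        t_local[i] = t1 - t0
        t_transfer[i] = t2 - t1
        server_times[i] = t3 - t2
    return TimingRecord(
        t_local=t_local,
        t_transfer=t_transfer,
        t_server=float(server_times.mean()),
        k=len(clients),
    )
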