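"""Split-learning protocol: partitions, packets, gradients, two phases."""

import json

import numpy as np
import pytest

import eegsplit as es
from eegsplit import nn
from eegsplit.errors import InputError, StateError
from eegsplit.preprocessing import FeatureMatrix
from eegsplit.split_learning import (
    ActivationPacket,
    client_apply_gradient,
    client_forward,
    fit_split,
    make_transformer_client,
    measure_inference,
    partition_clients,
    server_step,
    split_predict,
    train_step,
)


def _toy_features(n_subjects=6, per_subject=8, width=12, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for s in range(n_subjects):
        lab = s % 2
        center = 3.0 * lab
        rows.append(rng.normal(center, 1.0, size=(per_subject, width)))
        labels += [lab] * per_subject
        groups += [f"S{s}"] * per_subject
    return FeatureMatrix(
        np.vstack(rows), [f"f{i}" for i in range(width)],
        np.array(labels), np.array(groups, dtype=object),
    )


class _MLPClientEncoder(nn.Module):
    """Toy two-layer client model used for protocol-level checks."""

    def __init__(self, d_in, d_hidden, d_out, rng):
        self.net = nn.Sequential(
            nn.Linear(d_in, d_hidden, rng), nn.ReLU(),
            nn.Linear(d_hidden, d_out, rng),
        )
        self.latent_dim = d_out

    def parameters(self):
        return self.net.parameters()

    def forward(self, x):
        return self.net.forward(np.asarray(x, dtype=np.float64))

    def backward(self, dout):
        return self.net.backward(dout)


def _toy_client(features, d_latent=6, seed=0, lr=1e-3, client_id=0):
    rng = np.random.default_rng(seed)
    enc = _MLPClientEncoder(features.n_features, 10, d_latent, rng)
    return es.ClientState(client_id, enc, features, lr=lr, seed=seed)


class TestPartitionClients:
    def test_k1_identity(self):
        fm = _toy_features()
        (part,) = partition_clients(fm, 1, mode="subject", seed=0)
        assert np.array_equal(np.sort(part.values, axis=0), np.sort(fm.values, axis=0))
        assert part.n_epochs == fm.n_epochs

    @pytest.mark.parametrize("mode", ["subject", "epoch"])
    def test_disjoint_exhaustive_both_classes(self, mode):
        fm = _toy_features(n_subjects=6)
        parts = partition_clients(fm, 3, mode=mode, seed=1)
        assert sum(p.n_epochs for p in parts) == fm.n_epochs
        for p in parts:
            assert set(np.unique(p.labels)) == {0, 1}
        if mode == "subject":
            seen = [set(p.groups) for p in parts]
            for i in range(3):
                for j in range(i + 1, 3):
                    assert not (seen[i] & seen[j])
        # set equality oracle on row identities
        all_rows = np.vstack([p.values for p in parts])
        assert np.array_equal(
            np.sort(all_rows, axis=0), np.sort(fm.values, axis=0)
        )

    def test_same_seed_same_partition(self):
        fm = _toy_features()
        a = partition_clients(fm, 3, seed=5)
        b = partition_clients(fm, 3, seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.values, pb.values)

    def test_infeasible_partition_rejected(self):
        fm = _toy_features(n_subjects=4)  # 2 subjects per class
        with pytest.raises(InputError):
            partition_clients(fm, 3, mode="subject", seed=0)


class TestPackets:
    def test_activation_packet_schema_is_exactly_four_fields(self):
        fm = _toy_features()
        client = _toy_client(fm)
        packet = client_forward(client, np.arange(5))
        payload = json.loads(packet.serialize().decode())
        assert set(payload) == {"client_id", "z", "labels", "batch_index"}
        # latents, not raw features: width is the latent dim, not 12
        assert len(payload["z"][0]) == client.encoder.latent_dim
        assert len(payload["z"]) == 5
        assert payload["labels"] == list(fm.labels[:5])

    def test_z_matches_direct_encoder_evaluation(self):
        fm = _toy_features()
        client = _toy_client(fm, seed=3)
        batch = np.array([2, 7, 11])
        packet = client_forward(client, batch)
        direct = client.encoder.forward(fm.values[batch])
        assert np.array_equal(packet.z, direct)

    def test_empty_batch_rejected(self):
        client = _toy_client(_toy_features())
        with pytest.raises(InputError):
            client_forward(client, np.array([], dtype=int))


class TestServerStep:
    def test_confident_correct_logits_near_zero_loss(self):
        server = es.ServerState(latent_dim=2, seed=0)
        # head = identity map with large margin: z rows are +-20 one-hots
        server.head.W.value[...] = np.eye(2)
        server.head.b.value[...] = 0.0
        y = np.array([0, 1, 0, 1])
        z = 20.0 * np.eye(2)[y]
        loss, gp = server_step(server, ActivationPacket(0, z, y, 0))
        assert loss < 1e-3
        assert gp.dl_dz.shape == z.shape

    def test_uniform_logits_loss_is_ln2(self):
        server = es.ServerState(latent_dim=4, seed=0)
        server.head.W.value[...] = 0.0
        server.head.b.value[...] = 0.0
        z = np.random.default_rng(0).normal(size=(6, 4))
        y = np.array([0, 1] * 3)
        loss, _ = server_step(server, ActivationPacket(0, z, y, 0))
        assert loss == pytest.approx(np.log(2.0))

    def test_returned_gradient_passes_finite_differences(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            server = es.ServerState(latent_dim=5, seed=int(rng.integers(1000)))
            z = rng.normal(size=(4, 5))
            y = rng.integers(0, 2, size=4)
            snap = server.head.snapshot()
            _, gp = server_step(server, ActivationPacket(0, z.copy(), y, 0))
            head = nn.Linear(5, 2, np.random.default_rng(0))
            head.load(snap)

            def loss_at(zz):
                return nn.softmax_cross_entropy(head.forward(zz), y)[0]

            eps = 1e-6
            for i, j in [(0, 0), (1, 3), (3, 4)]:
                zp = z.copy(); zp[i, j] += eps
                zm = z.copy(); zm[i, j] -= eps
                num = (loss_at(zp) - loss_at(zm)) / (2 * eps)
                assert gp.dl_dz[i, j] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_forest_mode_rejects_gradient_training(self):
        fm = _toy_features()
        client = _toy_client(fm)
        server = es.ServerState(latent_dim=client.encoder.latent_dim, seed=0)
        fit_split([client], server, n_epochs=0, seed=0)  # Phase B only
        with pytest.raises(StateError):
            server_step(server, client_forward(client, np.arange(4)))


class TestFitSplit:
    def test_zero_epochs_is_parameter_noop(self):
        fm = _toy_features()
        client = _toy_client(fm)
        server = es.ServerState(latent_dim=client.encoder.latent_dim, seed=0)
        theta0 = client.encoder.net.snapshot()
        phi0 = server.head.snapshot()
        fit_split([client], server, n_epochs=0, seed=0, fit_forest=False)
        assert all(np.array_equal(a, b)
                   for a, b in zip(client.encoder.net.snapshot(), theta0))
        assert all(np.array_equal(a, b)
                   for a, b in zip(server.head.snapshot(), phi0))

    def test_single_client_matches_centralized_training(self):
        # oracle: train the composed model directly with the same batches
        fm = _toy_features(seed=2)
        client = _toy_client(fm, seed=9, lr=1e-3)
        server = es.ServerState(latent_dim=6, lr=1e-3, seed=9)

        rng = np.random.default_rng(0)
        cenc = _MLPClientEncoder(fm.n_features, 10, 6, np.random.default_rng(1))
        cenc.net.load(client.encoder.net.snapshot())
        chead = nn.Linear(6, 2, np.random.default_rng(1))
        chead.load(server.head.snapshot())
        opt_enc = nn.Adam(cenc.parameters(), lr=1e-3)
        opt_head = nn.Adam(chead.parameters(), lr=1e-3)

        batches = [rng.choice(fm.n_epochs, size=16, replace=False)
                   for _ in range(50)]
        split_losses, central_losses = [], []
        for batch in batches:
            split_losses.append(train_step(client, server, batch))
            opt_enc.zero_grad(); opt_head.zero_grad()
            z = cenc.forward(fm.values[batch])
            loss, dlogits = nn.softmax_cross_entropy(
                chead.forward(z), fm.labels[batch]
            )
            cenc.backward(chead.backward(dlogits))
            opt_head.step(); opt_enc.step()
            central_losses.append(loss)
        diffs = np.abs(np.array(split_losses) - np.array(central_losses))
        assert diffs.max() < 1e-6

    def test_phase_a_reduces_loss(self):
        fm = _toy_features(n_subjects=8, per_subject=10, seed=5)
        client = _toy_client(fm, seed=0, lr=3e-3)
        server = es.ServerState(latent_dim=6, lr=3e-3, seed=0)
        hist = fit_split([client], server, n_epochs=20, batch_size=16,
                         seed=0, fit_forest=False)
        first = np.mean(hist["losses"][:3])
        last = np.mean(hist["losses"][-3:])
        assert last < first

    def test_round_robin_interleaves_all_clients(self):
        fm = _toy_features(n_subjects=6)
        parts = partition_clients(fm, 3, seed=0)
        clients = [_toy_client(p, seed=i, client_id=i)
                   for i, p in enumerate(parts)]
        server = es.ServerState(latent_dim=6, seed=0)
        log = []
        fit_split(clients, server, n_epochs=1, batch_size=8, seed=0,
                  fit_forest=False, packet_log=log)
        origin = [json.loads(p.decode())["client_id"] for p in log]
        assert set(origin) == {0, 1, 2}


class TestSplitPredictAndTiming:
    @pytest.fixture(scope="class")
    def trained(self):
        fm = _toy_features(n_subjects=6, per_subject=12, seed=7)
        parts = partition_clients(fm, 3, seed=0)
        clients = [_toy_client(p, seed=i, client_id=i)
                   for i, p in enumerate(parts)]
        server = es.ServerState(latent_dim=6, seed=0)
        fit_split(clients, server, n_epochs=5, seed=0)
        return clients, server

    def test_predict_before_phase_b_rejected(self):
        fm = _toy_features()
        client = _toy_client(fm)
        server = es.ServerState(latent_dim=6, seed=0)
        with pytest.raises(StateError):
            split_predict([client], server)

    def test_outputs_match_per_client_inputs(self, trained):
        clients, server = trained
        preds = split_predict(clients, server)
        for c, p in zip(clients, preds):
            assert len(p) == c.n_samples
            assert set(np.unique(p)) <= {0, 1}

    def test_deterministic_and_equal_to_manual_pipeline(self, trained):
        clients, server = trained
        a = split_predict(clients, server)
        b = split_predict(clients, server)
        for pa, pb, c in zip(a, b, clients):
            assert np.array_equal(pa, pb)
            manual = server.forest_.predict(c.encoder.forward(c.data.values))
            assert np.array_equal(pa, manual)

    def test_timing_identities(self, trained):
        clients, server = trained
        rec = measure_inference(clients, server)
        assert rec.k == 3
        assert np.all(rec.t_local >= 0) and np.all(rec.t_transfer >= 0)
        assert rec.t_server >= 0
        assert np.allclose(
            rec.t_inference, rec.t_local + rec.t_transfer + rec.t_server
        )
        assert rec.average == pytest.approx(float(rec.t_inference.mean()))

    def test_transformer_client_factory(self):
        fm = _toy_features(width=12)
        client = make_transformer_client(0, fm, token_dim=3, d_model=8,
                                         n_heads=2, n_layers=1, seed=0)
        packet = client_forward(client, np.arange(4))
        assert np.asarray(packet.z).shape == (4, 8)
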