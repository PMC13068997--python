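"""Simulated cross-silo federation.

Synchronous, full-participation rounds over a small set of institutional
clients: the server broadcasts the global parameter vector, every client
runs a few epochs of local gradient descent, and the server aggregates the
returned :class:`~fedhetero.aggregation.ClientReport` payloads under one of
four strategies:

* ``fedavg``   — sample-size weights;
* ``feddisco`` — label-discrepancy weighting (``gamma = 0``);
* ``ours``    — label + representation discrepancy weighting;
* ``fedbn``   — sample-size weights, but normalization segments stay local
  to each client and the global copy is never overwritten.

Only parameter vectors, sample counts and label histograms cross the
client/server boundary; features and labels never appear in a report.
Everything is deterministic given ``FederationConfig.seed``: client batch
schedules are keyed by (seed, round, client), independent of the strategy,
so strategies that produce the same weights produce bit-identical
parameter trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aggregation import (
    AggregationWeights,
    ClientReport,
    DiscoConfig,
    LabelDistribution,
    aggregate_params,
    disco_weights,
    fedavg_weights,
)
from .metrics import MetricReport, evaluate_predictions
from .models import ModelSpec, init_model, predict_scores, train_local
from .params import ParamVector
from .synthetic import FederatedDataset

__all__ = [
    "STRATEGIES",
    "FederationConfig",
    "ClientState",
    "RoundLog",
    "FederationResult",
    "clients_from_dataset",
    "run_round",
    "run_federation",
]

STRATEGIES = ("fedavg", "feddisco", "fedbn", "ours")


@dataclass(frozen=True)
class FederationConfig:
    """Experiment configuration for one federated run.

    Defaults follow the cross-silo regime of the motivating setting:
    30 communication rounds of 2 local epochs (midpoints of the 20-40 /
    1-3 ranges), learning rate 1e-3 with cosine decay over rounds, and
    decoupled weight decay 0.01.
    """

    rounds: int = 30
    local_epochs: int = 2
    strategy: str = "ours"
    disco: DiscoConfig = field(default_factory=DiscoConfig.validation_selected)
    seed: int = 0
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 4
    cosine_lr_decay: bool = True

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; known: {', '.join(STRATEGIES)}"
            )

    def lr_at(self, round_index: int) -> float:
        if not self.cosine_lr_decay or self.rounds == 1:
            return self.learning_rate
        return self.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * round_index / (self.rounds - 1))
        )


@dataclass
class ClientState:
    """Client-local view: its dataset splits and its personalized parameters
    (used by FedBN, whose normalization segments never leave the client)."""

    client_id: str
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    local_params: ParamVector | None = None

    @property
    def n_train(self) -> int:
        return int(self.y_train.size)


@dataclass(frozen=True)
class RoundLog:
    round_index: int
    weights: AggregationWeights
    train_losses: dict[str, float]
    lr: float
    val_metrics: MetricReport | None = None


@dataclass
class FederationResult:
    final_params: ParamVector
    round_logs: list[RoundLog]
    pooled_test: MetricReport
    per_client_test: dict[str, MetricReport]
    pooled_test_global_norm: MetricReport | None = None
    best_val_round: int | None = None


def clients_from_dataset(dataset: FederatedDataset) -> list[ClientState]:
    out = []
    for c in dataset.clients:
        Xtr, ytr = c.subset("train")
        Xv, yv = c.subset("val")
        Xte, yte = c.subset("test")
        out.append(ClientState(c.name, Xtr, ytr, Xv, yv, Xte, yte))
    return out


def _client_seed(config_seed: int, round_index: int, client_index: int) -> int:
    ss = np.random.SeedSequence([int(config_seed), int(round_index), int(client_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _receive(
    global_params: ParamVector, client: ClientState, strategy: str
) -> ParamVector:
    """Broadcast: FedBN clients keep their own normalization segments."""
    if (
        strategy == "fedbn"
        and client.local_params is not None
        and global_params.has_segment("norm")
    ):
        return global_params.replace_segment("norm", client.local_params.segment("norm"))
    return global_params


def run_round(
    global_params: ParamVector,
    clients: list[ClientState],
    config: FederationConfig,
    spec: ModelSpec,
    round_index: int = 0,
) -> tuple[ParamVector, RoundLog]:
    """One synchronous communication round; mutates client local state."""
    if not clients:
        raise ValueError("a federation needs at least one client")
    lr = config.lr_at(round_index)
    reports: list[ClientReport] = []
    losses: dict[str, float] = {}
    for ci, client in enumerate(clients):
        received = _receive(global_params, client, config.strategy)
        updated, loss = train_local(
            spec,
            received,
            client.X_train,
            client.y_train,
            epochs=config.local_epochs,
            lr=lr,
            weight_decay=config.weight_decay,
            seed=_client_seed(config.seed, round_index, ci),
            batch_size=config.batch_size,
        )
        client.local_params = updated
        losses[client.client_id] = loss
        reports.append(
            ClientReport(
                client_id=client.client_id,
                params=updated,
                n_train=client.n_train,
                label_dist=LabelDistribution.from_labels(client.y_train),
            )
        )

    theta_ref = global_params.segment("head")
    if config.strategy == "fedavg":
        weights = fedavg_weights(reports)
    elif config.strategy == "feddisco":
        weights = disco_weights(reports, theta_ref, replace(config.disco, gamma=0.0))
    elif config.strategy == "ours":
        weights = disco_weights(reports, theta_ref, config.disco)
    else:  # fedbn
        weights = fedavg_weights(reports)

    exclude = ("norm",) if config.strategy == "fedbn" and global_params.has_segment("norm") else ()
    new_global = aggregate_params(reports, weights, exclude, reference=global_params)
    return new_global, RoundLog(round_index, weights, losses, lr)


def _evaluate(
    params: ParamVector,
    clients: list[ClientState],
    spec: ModelSpec,
    which: str,
    strategy: str,
    norm_mode: str = "local",
) -> tuple[MetricReport, dict[str, MetricReport]]:
    """Pooled + per-client metrics on one split.

    For FedBN with ``norm_mode='local'`` each client's samples are scored
    with that client's personalized normalization parameters; otherwise the
    plain global vector is used everywhere.
    """
    all_y, all_s = [], []
    per_client: dict[str, MetricReport] = {}
    for client in clients:
        p = params
        if (
            strategy == "fedbn"
            and norm_mode == "local"
            and client.local_params is not None
            and params.has_segment("norm")
        ):
            p = params.replace_segment("norm", client.local_params.segment("norm"))
        X, y = getattr(client, f"X_{which}"), getattr(client, f"y_{which}")
        if y.size == 0:
            continue
        s = predict_scores(spec, p, X)
        per_client[client.client_id] = evaluate_predictions(y, s)
        all_y.append(y)
        all_s.append(s)
    pooled = evaluate_predictions(np.concatenate(all_y), np.concatenate(all_s))
    return pooled, per_client


def run_federation(
    dataset: FederatedDataset,
    config: FederationConfig,
    spec: ModelSpec | None = None,
) -> FederationResult:
    """Run a full federated experiment on a dataset.

    Initializes the global model from ``config.seed``, runs
    ``config.rounds`` rounds, logs per-round weights/losses/validation
    metrics, and evaluates the final global model on the pooled test split
    (union of client test sets) and per client.
    """
    if spec is None:
        spec = ModelSpec(input_dim=dataset.feature_dim, use_norm_layers=True)
    clients = clients_from_dataset(dataset)
    global_params = init_model(spec, seed=config.seed)

    logs: list[RoundLog] = []
    best_val = -np.inf
    best_round = None
    for t in range(config.rounds):
        global_params, log = run_round(global_params, clients, config, spec, t)
        val_pooled, _ = _evaluate(global_params, clients, spec, "val", config.strategy)
        log = replace(log, val_metrics=val_pooled)
        logs.append(log)
        ba = val_pooled.balanced_accuracy
        if np.isfinite(ba) and ba > best_val:
            best_val, best_round = ba, t

    pooled, per_client = _evaluate(global_params, clients, spec, "test", config.strategy)
    pooled_global = None
    if config.strategy == "fedbn":
        pooled_global, _ = _evaluate(
            global_params, clients, spec, "test", config.strategy, norm_mode="global"
        )
    return FederationResult(
        final_params=global_params,
        round_logs=logs,
        pooled_test=pooled,
        per_client_test=per_client,
        pooled_test_global_norm=pooled_global,
        best_val_round=best_round,
    )
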