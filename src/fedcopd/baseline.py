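"""The comparison arm: each simulated hospital trains the identical network on
its own shard alone, with no parameter exchange.

The study calls this arm "CML"; in its usage the term denotes per-site
isolated training — each client sees only its own records.  To keep the
comparison about data pooling rather than optimisation budget, each baseline
client runs ``total_epochs = r·E`` epochs, exactly the number of gradient
passes a federated client performs across all rounds, consumed in blocks of E
epochs with the same derived per-(client, round) seeds.  With K=1 the two
arms are therefore parameter-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ClientShard, ID_COL, feature_cols
from .federation import (
    FLConfig,
    _STREAM_CLIENT,
    client_update,
    derive_rng,
    init_seed,
)
from .network import (
    NetworkArchitecture,
    NetworkParams,
    TrainConfig,
    forward,
    init_params,
)


@dataclass
class BaselineClientResult:
    """One isolated client's final parameters, test predictions, loss trace."""

    client_id: int
    params: NetworkParams
    predictions: pd.DataFrame  # columns: client, record_id, label, prob
    epoch_losses: list[float]


@dataclass
class BaselineResult:
    """Per-client isolated-training results, schema-compatible with the
    federated RES for symmetric evaluation."""

    clients: dict[int, BaselineClientResult]

    @property
    def res(self) -> pd.DataFrame:
        return pd.concat(
            [c.predictions for c in self.clients.values()], ignore_index=True
        )

    def final_round_predictions(self) -> pd.DataFrame:
        """Alias matching :class:`FederationResult`'s accessor."""
        return self.res


def train_local(
    shard: ClientShard,
    cfg: TrainConfig,
    total_epochs: int,
    master_seed: int,
    initial_params: NetworkParams,
    activation: str = "relu",
) -> BaselineClientResult:
    """Train one client in isolation for ``total_epochs`` epochs of minibatch SGD.

    Epochs are consumed in blocks of ``cfg.epochs`` with seeds derived per
    (client, block), matching the randomness schedule of a federated client.
    """
    Xtr, ytr, Xte, yte = shard.arrays()
    if len(ytr) == 0:
        raise ValueError(f"client {shard.client_id} has an empty training set")
    params = initial_params.copy()
    losses: list[float] = []
    block = 0
    remaining = total_epochs
    while remaining > 0:
        rng = derive_rng(master_seed, _STREAM_CLIENT, shard.client_id, block)
        n_epochs = min(cfg.epochs, remaining) if cfg.epochs > 0 else remaining
        block_cfg = TrainConfig(
            eta=cfg.eta, epochs=n_epochs, batch_size=cfg.batch_size
        )
        params, block_losses = client_update(
            params, (Xtr, ytr), block_cfg, rng, activation
        )
        losses.extend(block_losses)
        remaining -= n_epochs
        block += 1
    probs = forward(params, Xte, activation)
    predictions = pd.DataFrame(
        {
            "client": shard.client_id,
            ID_COL: shard.test[ID_COL].to_numpy(),
            "label": yte.astype(int),
            "prob": probs,
        }
    )
    return BaselineClientResult(
        client_id=shard.client_id,
        params=params,
        predictions=predictions,
        epoch_losses=losses,
    )


def run_baseline(
    shards: list[ClientShard],
    cfg: FLConfig,
    initial_params: NetworkParams | None = None,
) -> BaselineResult:
    """Train every client independently with the federated gradient budget.

    Each client runs ``rounds · epochs`` local epochs from the same seeded
    initialisation a federated run would use; no parameters are ever mixed, so
    deleting one client's data cannot affect another's result.
    """
    shards = sorted(shards, key=lambda s: s.client_id)
    if initial_params is None:
        width = len(feature_cols(shards[0].train))
        arch = NetworkArchitecture(
            input_width=width, hidden=cfg.hidden, activation=cfg.activation
        )
        initial_params = init_params(arch, init_seed(cfg.seed).integers(2**31))
    total_epochs = cfg.rounds * cfg.train.epochs
    clients: dict[int, BaselineClientResult] = {}
    for shard in shards:
        try:
            clients[shard.client_id] = train_local(
                shard,
                cfg.train,
                total_epochs,
                cfg.seed,
                initial_params,
                cfg.activation,
            )
        except Exception as exc:
            raise RuntimeError(
                f"baseline client {shard.client_id} failed: {exc}"
            ) from exc
    return BaselineResult(clients=clients)
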