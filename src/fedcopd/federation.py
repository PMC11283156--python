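"""The federated-averaging loop: client updates, server aggregation, rounds.

Federation is simulated in-process.  Each communication round, every client
(simulated hospital) receives a copy of the current global parameters, runs E
local epochs of minibatch SGD on its private training shard, and uploads the
result; the server replaces the global model with the elementwise arithmetic
mean of the uploads (θ^{r+1} = (1/K)Σ_k θ_k^r).  Raw records never cross the
client boundary — only parameter vectors do — which is the privacy premise of
the design.  After each aggregation every client scores its local test set
with the new global model; those per-round prediction records (``RES``) drive
all downstream evaluation.

Determinism: every source of randomness is derived from the master seed via
``numpy.random.SeedSequence([master, stream, client, round])``, so a run is
reproducible bit-for-bit and clients are mutually independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ClientShard, ID_COL
from .network import (
    NetworkArchitecture,
    NetworkParams,
    TrainConfig,
    forward,
    init_params,
    run_epochs,
)

logger = logging.getLogger(__name__)

# seed-stream tags: keep derived entropy words distinct per purpose
_STREAM_INIT = 0
_STREAM_CLIENT = 1


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """A reproducible generator for one (purpose, client, round, ...) slot."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


def init_seed(master_seed: int) -> np.random.Generator:
    return derive_rng(master_seed, _STREAM_INIT)


@dataclass(frozen=True)
class FLConfig:
    """Federation hyperparameters: K clients, r rounds, local (E, B, η), split T.

    Defaults are the published operating point: K=3, r=350, E=5, B=10,
    η=0.001, T=7:3.
    """

    n_clients: int = 3
    rounds: int = 350
    train: TrainConfig = field(default_factory=TrainConfig)
    split: tuple[float, float] = (7.0, 3.0)
    hidden: tuple[int, ...] = (32, 16)
    activation: str = "relu"
    weighted: bool = False  # sample-size-weighted aggregation (off: plain mean)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 1:
            raise ValueError("need at least one client")
        if self.rounds < 0:
            raise ValueError("rounds must be nonnegative")


@dataclass
class FederationResult:
    """Outcome of a federated run: final global parameters, per-round per-client
    training-loss trace, and RES — the per-round test-set predictions."""

    final_params: NetworkParams
    initial_params: NetworkParams
    loss_trace: pd.DataFrame  # columns: round, client, loss
    res: pd.DataFrame  # columns: round, client, record_id, label, prob

    def final_round_predictions(self) -> pd.DataFrame:
        """RES restricted to the last communication round (headline metrics)."""
        if self.res.empty:
            return self.res
        return self.res[self.res["round"] == self.res["round"].max()]


def client_update(
    params: NetworkParams,
    shard_arrays: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    rng: np.random.Generator,
    activation: str = "relu",
) -> tuple[NetworkParams, list[float]]:
    """E local epochs of minibatch SGD from a copy of the broadcast parameters.

    The input parameters are never modified: clients exchange copies, mirroring
    a transport boundary.  Returns the updated parameters and per-epoch losses.
    """
    X, y = shard_arrays
    if len(y) == 0:
        raise ValueError("client has an empty training set")
    return run_epochs(params.copy(), X, y, cfg, rng, activation=activation)


def server_aggregate(
    client_params: list[NetworkParams], weights: list[float] | None = None
) -> NetworkParams:
    """Elementwise arithmetic mean of the uploaded parameters (optionally a
    sample-size-weighted mean when ``weights`` is given)."""
    if not client_params:
        raise ValueError("no client parameters to aggregate")
    shapes = [tuple(W.shape for W in p.weights) for p in client_params]
    if any(s != shapes[0] for s in shapes[1:]):
        raise ValueError("client parameter shapes differ")
    n_layers = client_params[0].n_layers
    agg_W = []
    agg_b = []
    if weights is None:
        # left-fold sum then divide: deterministic summation order
        k = len(client_params)
        for i in range(n_layers):
            agg_W.append(sum(p.weights[i] for p in client_params) / k)
            agg_b.append(sum(p.biases[i] for p in client_params) / k)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(client_params) or w.sum() <= 0:
            raise ValueError("invalid aggregation weights")
        w = w / w.sum()
        for i in range(n_layers):
            agg_W.append(sum(w[j] * p.weights[i] for j, p in enumerate(client_params)))
            agg_b.append(sum(w[j] * p.biases[i] for j, p in enumerate(client_params)))
    return NetworkParams(agg_W, agg_b)


def predict_with_params(
    shards: list[ClientShard], params: NetworkParams, activation: str = "relu"
) -> pd.DataFrame:
    """Score every client's local test set with one parameter vector."""
    rows = []
    for shard in sorted(shards, key=lambda s: s.client_id):
        _, _, Xte, yte = shard.arrays()
        rows.append(
            pd.DataFrame(
                {
                    "client": shard.client_id,
                    ID_COL: shard.test[ID_COL].to_numpy(),
                    "label": yte.astype(int),
                    "prob": forward(params, Xte, activation),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_federation(
    shards: list[ClientShard],
    cfg: FLConfig,
    initial_params: NetworkParams | None = None,
) -> FederationResult:
    """Run r communication rounds of federated averaging over the given shards.

    Per round: every client updates from the freshly broadcast global
    parameters (never from its previous local state), the server averages the
    uploads over clients sorted by identifier (a fixed summation order, so the
    result is exactly invariant to client permutation), and each client then
    scores its local test set with the new global model.
    """
    if len(shards) != cfg.n_clients:
        raise ValueError(
            f"expected {cfg.n_clients} shards, got {len(shards)}"
        )
    shards = sorted(shards, key=lambda s: s.client_id)
    arrays = {s.client_id: s.arrays() for s in shards}

    if initial_params is None:
        arch = NetworkArchitecture(
            input_width=arrays[shards[0].client_id][0].shape[1],
            hidden=cfg.hidden,
            activation=cfg.activation,
        )
        initial_params = init_params(
            arch, init_seed(cfg.seed).integers(2**31)
        )

    theta_cur = initial_params.copy()
    loss_rows: list[dict] = []
    res_rows: list[pd.DataFrame] = []
    agg_weights = (
        [len(arrays[s.client_id][1]) for s in shards] if cfg.weighted else None
    )

    for rnd in range(cfg.rounds):
        uploads = []
        for shard in shards:
            Xtr, ytr, _, _ = arrays[shard.client_id]
            rng = derive_rng(cfg.seed, _STREAM_CLIENT, shard.client_id, rnd)
            try:
                upd, losses = client_update(
                    theta_cur, (Xtr, ytr), cfg.train, rng, cfg.activation
                )
            except Exception as exc:  # identify the failing client
                raise RuntimeError(
                    f"client {shard.client_id} failed in round {rnd}: {exc}"
                ) from exc
            uploads.append(upd)
            loss_rows.append(
                {
                    "round": rnd,
                    "client": shard.client_id,
                    "loss": float(np.mean(losses)) if losses else np.nan,
                }
            )
        theta_cur = server_aggregate(uploads, agg_weights)

        for shard in shards:
            _, _, Xte, yte = arrays[shard.client_id]
            probs = forward(theta_cur, Xte, cfg.activation)
            res_rows.append(
                pd.DataFrame(
                    {
                        "round": rnd,
                        "client": shard.client_id,
                        ID_COL: shard.test[ID_COL].to_numpy(),
                        "label": yte.astype(int),
                        "prob": probs,
                    }
                )
            )
        logger.debug("round %d aggregated over %d clients", rnd, len(shards))

    loss_trace = pd.DataFrame(loss_rows, columns=["round", "client", "loss"])
    res = (
        pd.concat(res_rows, ignore_index=True)
        if res_rows
        else pd.DataFrame(columns=["round", "client", ID_COL, "label", "prob"])
    )
    return FederationResult(
        final_params=theta_cur,
        initial_params=initial_params,
        loss_trace=loss_trace,
        res=res,
    )
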