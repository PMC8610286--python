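"""Relational graph convolutional link predictor.

The encoder is the standard relational graph convolution: per layer,

    h_i^(l+1) = ReLU( sum_{r in R} sum_{j in N_i^r} (1/C_{i,r}) W_r^(l) h_j^(l)
                      + W_O^(l) h_i^(l) )

where ``N_i^r`` is the set of neighbours sending a message to node ``i``
under relation ``r`` (the graph is pre-augmented with inverse relations and
self-loops, so both edge directions carry messages), and the normalisation
constant ``C_{i,r}`` is the degree of the receiving node under ``r``.
Each relation keeps its own full weight matrix — no basis decomposition —
which is fine at the relation-vocabulary sizes this package targets.

The pairwise decoder scores an *ordered* pair (upstream, downstream):

    logit(a, b) = u·h_a + v·h_b + w·(h_a ⊙ h_b) + bias,   p = sigmoid(logit)

The two linear terms keep the score direction-aware (u ≠ v in general);
the elementwise-product term gives the head a multiplicative channel,
without which no additive read-out could express neighbourhood-similarity
rules at all.

Everything is plain numpy: the forward pass is a handful of sparse
matrix products per relation and the gradients are derived by hand, so
training is exactly reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .graph import KnowledgeGraph, LinkDataset, NodeFeatureTable, augment_graph


@dataclass
class TrainConfig:
    """Hyperparameters of the encoder/decoder fit.

    ``hidden_dim`` is used for every layer output; ``patience`` counts
    validation evaluations (one per epoch) without MCC improvement before
    stopping.  ``l2`` is the coefficient of the squared-norm penalty on all
    weight matrices.
    """

    hidden_dim: int = 64
    n_layers: int = 2
    learning_rate: float = 0.005
    max_epochs: int = 800
    patience: int = 80
    l2: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.n_layers <= 0 or self.max_epochs < 0:
            raise ValueError("hidden_dim, n_layers positive; max_epochs >= 0")


@dataclass
class LayerParams:
    """One relational convolution layer: per-relation W_r plus self W_O."""

    W: np.ndarray  # (n_relations, d_out, d_in)
    W_self: np.ndarray  # (d_out, d_in)

    def __post_init__(self) -> None:
        if self.W.ndim != 3 or self.W_self.shape != self.W.shape[1:]:
            raise ValueError("inconsistent layer parameter shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.W_self))):
            raise ValueError("non-finite layer parameters")


@dataclass
class HeadParams:
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    bias: float


@dataclass
class RGCNModel:
    """Trained encoder + decoder, tied to a relation vocabulary."""

    layers: list[LayerParams]
    head: HeadParams
    relations: tuple[str, ...]  # augmented vocabulary the weights index
    config: TrainConfig
    input_dim: int


@dataclass
class PredictionRecord:
    """One scored ordered gene pair.

    ``ri`` is the reliability index, ``round(100 * (2p - 1))`` in
    [-100, 100]; negative values flag confident non-interaction.  The
    predicted label is positive iff ``ri >= 0``.  ``ok`` is False when a
    gene was unknown to the model (such pairs are flagged, never dropped).
    """

    gene_a: str
    gene_b: str
    p: float
    ri: int
    label: int
    ok: bool = True
    note: str = ""

    @staticmethod
    def reliability_index(p: float) -> int:
        # round-half-up so the mapping is platform independent
        return int(np.floor(200.0 * p - 100.0 + 0.5))

    @classmethod
    def from_probability(cls, a: str, b: str, p: float) -> "PredictionRecord":
        if not np.isfinite(p):
            raise ValueError(f"non-finite probability for pair ({a}, {b})")
        ri = cls.reliability_index(float(p))
        return cls(gene_a=a, gene_b=b, p=float(p), ri=ri, label=int(ri >= 0))


# ---------------------------------------------------------------------------
# message-passing operators


def relation_operators(graph: KnowledgeGraph) -> list[sp.csr_matrix]:
    """One sparse operator per relation: ``(A_r x)_i`` averages the states
    of the neighbours sending to ``i`` under ``r`` (entries ``1/C_{i,r}``)."""
    if not graph.is_augmented:
        raise ValueError("relation operators require an augmented graph")
    idx = graph.node_index()
    n = graph.n_nodes
    rel_idx = {r: k for k, r in enumerate(graph.relations)}
    rows: list[list[int]] = [[] for _ in graph.relations]
    cols: list[list[int]] = [[] for _ in graph.relations]
    for s, r, t in graph.edges:
        k = rel_idx[r]
        rows[k].append(idx[t])  # message flows source -> target
        cols[k].append(idx[s])
    ops = []
    for k in range(len(graph.relations)):
        if rows[k]:
            data = np.ones(len(rows[k]))
            A = sp.csr_matrix((data, (rows[k], cols[k])), shape=(n, n))
            indeg = np.asarray(A.sum(axis=1)).ravel()
            scale = np.divide(1.0, indeg, out=np.zeros_like(indeg), where=indeg > 0)
            A = sp.diags(scale) @ A
        else:
            A = sp.csr_matrix((n, n))
        ops.append(A.tocsr())
    return ops


def init_params(
    input_dim: int, config: TrainConfig, n_relations: int, rng: np.random.Generator
) -> tuple[list[LayerParams], HeadParams]:
    """Symmetric-uniform initialisation scaled by fan-in."""
    layers = []
    d_in = input_dim
    for _ in range(config.n_layers):
        a = 1.0 / np.sqrt(d_in)
        layers.append(
            LayerParams(
                W=rng.uniform(-a, a, size=(n_relations, config.hidden_dim, d_in)),
                W_self=rng.uniform(-a, a, size=(config.hidden_dim, d_in)),
            )
        )
        d_in = config.hidden_dim
    a = 1.0 / np.sqrt(config.hidden_dim)
    head = HeadParams(
        u=rng.uniform(-a, a, size=config.hidden_dim),
        v=rng.uniform(-a, a, size=config.hidden_dim),
        w=rng.uniform(-a, a, size=config.hidden_dim),
        bias=0.0,
    )
    return layers, head


# ---------------------------------------------------------------------------
# forward / backward


def _forward(
    ops: Sequence[sp.csr_matrix], X: np.ndarray, layers: Sequence[LayerParams]
):
    """Return (H_list, cache); H_list[l] is the activation after layer l."""
    H = X
    H_list = [X]
    cache = []
    for lp in layers:
        AX = [A @ H for A in ops]  # per-relation aggregated inputs
        Z = H @ lp.W_self.T
        for k, ax in enumerate(AX):
            Z += ax @ lp.W[k].T
        Hn = np.maximum(Z, 0.0)
        cache.append((H, AX, Z))
        H = Hn
        H_list.append(H)
    return H_list, cache


def _backward(
    ops: Sequence[sp.csr_matrix],
    layers: Sequence[LayerParams],
    cache,
    dH_out: np.ndarray,
):
    """Gradients of all layer parameters given d(loss)/d(final activation)."""
    grads: list[dict[str, np.ndarray]] = [None] * len(layers)  # type: ignore
    dH = dH_out
    for l in range(len(layers) - 1, -1, -1):
        H_in, AX, Z = cache[l]
        dZ = dH * (Z > 0)
        gW = np.empty_like(layers[l].W)
        dH_in = dZ @ layers[l].W_self
        for k, A in enumerate(ops):
            gW[k] = dZ.T @ AX[k]
            dH_in += (A.T @ dZ) @ layers[l].W[k]
        grads[l] = {"W": gW, "W_self": dZ.T @ H_in}
        dH = dH_in
    return grads


def score_pair(emb_a: np.ndarray, emb_b: np.ndarray, head: HeadParams) -> float:
    """Interaction probability for an ordered pair of final-layer embeddings."""
    emb_a = np.asarray(emb_a, dtype=float)
    emb_b = np.asarray(emb_b, dtype=float)
    if emb_a.shape != emb_b.shape or emb_a.shape != head.u.shape:
        raise ValueError(
            f"embedding dims {emb_a.shape}/{emb_b.shape} do not match head dim "
            f"{head.u.shape}"
        )
    logit = head.u @ emb_a + head.v @ emb_b + head.w @ (emb_a * emb_b) + head.bias
    return float(1.0 / (1.0 + np.exp(-logit)))


def _pair_logits(H: np.ndarray, ia: np.ndarray, ib: np.ndarray, head: HeadParams):
    Ha, Hb = H[ia], H[ib]
    return Ha @ head.u + Hb @ head.v + (Ha * Hb) @ head.w + head.bias


def rgcn_layer_forward(
    graph: KnowledgeGraph, H: dict[str, np.ndarray] | np.ndarray, layer: LayerParams
):
    """Single-layer forward pass on an augmented graph.

    ``H`` maps every node to its current state (or is a matrix in node
    order); returns the updated states in the same form.
    """
    as_dict = isinstance(H, dict)
    if as_dict:
        missing = [g for g in graph.nodes if g not in H]
        if missing:
            raise KeyError(f"nodes missing from embedding: {missing[:5]}")
        X = np.array([np.asarray(H[g], dtype=float) for g in graph.nodes])
    else:
        X = np.asarray(H, dtype=float)
    ops = relation_operators(graph)
    if layer.W.shape[0] != len(ops):
        raise ValueError(
            f"layer has {layer.W.shape[0]} relation matrices but graph has "
            f"{len(ops)} relations"
        )
    H_list, _ = _forward(ops, X, [layer])
    out = H_list[-1]
    if as_dict:
        return {g: out[i] for i, g in enumerate(graph.nodes)}
    return out


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _flatten_params(layers: list[LayerParams], head: HeadParams):
    arrs = []
    for lp in layers:
        arrs.extend([lp.W, lp.W_self])
    bias = np.array([head.bias])
    arrs.extend([head.u, head.v, head.w, bias])
    return arrs, bias


def _link_indices(links: LinkDataset, node_idx: dict[str, int]):
    missing = sorted({g for g in links.genes() if g not in node_idx})
    if missing:
        raise ValueError(f"link genes absent from graph: {missing[:10]}")
    ia = np.array([node_idx[a] for a, _, _ in links.records])
    ib = np.array([node_idx[b] for _, b, _ in links.records])
    y = links.labels().astype(float)
    return ia, ib, y


def train(
    graph: KnowledgeGraph,
    features: NodeFeatureTable,
    train_links: LinkDataset,
    val_links: LinkDataset,
    config: TrainConfig,
) -> tuple[RGCNModel, list[dict]]:
    """Fit encoder + head by full-batch Adam on binary cross-entropy.

    Early stopping monitors validation MCC (positive = RI >= 0); the
    checkpoint with the best validation MCC is returned together with the
    per-epoch training log.  Bit-reproducible given ``config.seed``.
    """
    from .evaluation import ConfusionCounts, metrics as _metrics, auc as _auc

    if not train_links.records:
        raise ValueError("empty training link set")
    overlap = set(train_links.pairs()) & set(val_links.pairs())
    if overlap:
        raise ValueError(f"train/val link sets overlap: {sorted(overlap)[:5]}")

    agraph = graph if graph.is_augmented else augment_graph(graph)
    ops = relation_operators(agraph)
    node_idx = agraph.node_index()
    X = features.matrix(agraph.nodes)
    ia, ib, y = _link_indices(train_links, node_idx)
    via, vib, vy = _link_indices(val_links, node_idx) if val_links.records else (None,) * 3

    rng = np.random.default_rng(config.seed)
    layers, head = init_params(X.shape[1], config, len(agraph.relations), rng)
    params, bias_arr = _flatten_params(layers, head)
    opt = _Adam(params, config.learning_rate)

    def val_metrics() -> tuple[float, float]:
        if via is None:
            return float("nan"), float("nan")
        H_list, _ = _forward(ops, X, layers)
        logits = _pair_logits(H_list[-1], via, vib, head)
        p = 1.0 / (1.0 + np.exp(-logits))
        pred = (p >= 0.5).astype(int)
        c = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (vy == 1))),
            fp=int(np.sum((pred == 1) & (vy == 0))),
            tn=int(np.sum((pred == 0) & (vy == 0))),
            fn=int(np.sum((pred == 0) & (vy == 1))),
        )
        rep = _metrics(c)
        a = _auc(p, vy) if 0 < vy.sum() < len(vy) else float("nan")
        return rep.mcc, a

    log: list[dict] = []
    best = {"mcc": -np.inf, "epoch": -1, "params": None}
    stale = 0
    n = len(y)
    for epoch in range(config.max_epochs):
        head.bias = float(bias_arr[0])
        H_list, cache = _forward(ops, X, layers)
        H = H_list[-1]
        logits = _pair_logits(H, ia, ib, head)
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        l2_loss = config.l2 * sum(
            float(np.sum(lp.W**2) + np.sum(lp.W_self**2)) for lp in layers
        )
        g = (p - y) / n
        Ha, Hb = H[ia], H[ib]
        gu = Ha.T @ g
        gv = Hb.T @ g
        gw = (Ha * Hb).T @ g
        gb = np.array([g.sum()])
        dH = np.zeros_like(H)
        np.add.at(dH, ia, g[:, None] * (head.u + head.w * Hb))
        np.add.at(dH, ib, g[:, None] * (head.v + head.w * Ha))
        layer_grads = _backward(ops, layers, cache, dH)
        grad_list: list[np.ndarray] = []
        for lp, lg in zip(layers, layer_grads):
            grad_list.extend(
                [lg["W"] + 2 * config.l2 * lp.W, lg["W_self"] + 2 * config.l2 * lp.W_self]
            )
        grad_list.extend([gu, gv, gw, gb])
        opt.step(params, grad_list)
        head.bias = float(bias_arr[0])

        mcc, vauc = val_metrics()
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(loss),
                "l2_loss": float(l2_loss),
                "val_mcc": float(mcc),
                "val_auc": float(vauc),
            }
        )
        if via is not None:
            if mcc > best["mcc"]:
                best = {
                    "mcc": mcc,
                    "epoch": epoch,
                    "params": [a.copy() for a in params],
                }
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    if best["params"] is not None:
        for p_arr, b_arr in zip(params, best["params"]):
            p_arr[...] = b_arr
    head.bias = float(bias_arr[0])
    model = RGCNModel(
        layers=layers,
        head=head,
        relations=agraph.relations,
        config=config,
        input_dim=X.shape[1],
    )
    return model, log


def embed(
    model: RGCNModel, graph: KnowledgeGraph, features: NodeFeatureTable
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Final-layer node embeddings under the trained encoder."""
    agraph = graph if graph.is_augmented else augment_graph(graph)
    if agraph.relations != model.relations:
        raise ValueError("graph relation vocabulary differs from the model's")
    ops = relation_operators(agraph)
    X = features.matrix(agraph.nodes)
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dim {X.shape[1]} != model input dim {model.input_dim}"
        )
    H_list, _ = _forward(ops, X, model.layers)
    return H_list[-1], agraph.nodes


def predict(
    model: RGCNModel,
    pairs: Sequence[tuple[str, str]],
    graph: KnowledgeGraph,
    features: NodeFeatureTable,
) -> list[PredictionRecord]:
    """Score ordered gene pairs; unknown genes yield flagged records."""
    H, nodes = embed(model, graph, features)
    idx = {g: i for i, g in enumerate(nodes)}
    out = []
    for a, b in pairs:
        if a not in idx or b not in idx:
            bad = [g for g in (a, b) if g not in idx]
            out.append(
                PredictionRecord(
                    gene_a=a, gene_b=b, p=float("nan"), ri=0, label=0,
                    ok=False, note=f"unknown gene(s): {','.join(bad)}",
                )
            )
            continue
        p = score_pair(H[idx[a]], H[idx[b]], model.head)
        out.append(PredictionRecord.from_probability(a, b, p))
    return out


# ---------------------------------------------------------------------------
# prediction / checkpoint I/O


def write_predictions(records: Sequence[PredictionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tp\tri\tlabel\n")
        for r in records:
            p = "NA" if not r.ok else repr(r.p)
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{p}\t{r.ri}\t{r.label}\n")


def read_predictions(path) -> list[PredictionRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["gene_a", "gene_b", "p", "ri", "label"]:
            raise ValueError(f"{path}: not a predictions TSV")
        for line in fh:
            a, b, p, ri, label = line.rstrip("\n").split("\t")[:5]
            if p == "NA":
                out.append(
                    PredictionRecord(a, b, float("nan"), 0, 0, ok=False, note="unscored")
                )
            else:
                out.append(PredictionRecord(a, b, float(p), int(ri), int(label)))
    return out


def _zip_writestr(zf: zipfile.ZipFile, name: str, data) -> None:
    # fixed timestamp so identical models produce byte-identical checkpoints
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    zf.writestr(info, data)


def save_model(model: RGCNModel, path) -> None:
    """Single-file checkpoint: parameter tensors + config + relation vocab.

    A zip archive of ``.npy`` members plus a JSON manifest; byte-identical
    for identical models (fixed member timestamps), so re-training with the
    same seed reproduces the checkpoint exactly.
    """
    arrays = {}
    for l, lp in enumerate(model.layers):
        arrays[f"layer{l}_W"] = lp.W
        arrays[f"layer{l}_W_self"] = lp.W_self
    arrays["head_u"] = model.head.u
    arrays["head_v"] = model.head.v
    arrays["head_w"] = model.head.w
    meta = {
        "config": asdict(model.config),
        "relations": list(model.relations),
        "input_dim": model.input_dim,
        "n_layers": len(model.layers),
        "head_bias": model.head.bias,
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        _zip_writestr(zf, "meta.json", json.dumps(meta, indent=1, sort_keys=True))
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, arrays[name])
            _zip_writestr(zf, name + ".npy", buf.getvalue())


def load_model(path) -> RGCNModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))

        def arr(name: str) -> np.ndarray:
            return np.load(io.BytesIO(zf.read(name + ".npy")))

        layers = [
            LayerParams(W=arr(f"layer{l}_W"), W_self=arr(f"layer{l}_W_self"))
            for l in range(meta["n_layers"])
        ]
        head = HeadParams(
            u=arr("head_u"), v=arr("head_v"), w=arr("head_w"), bias=meta["head_bias"]
        )
    return RGCNModel(
        layers=layers,
        head=head,
        relations=tuple(meta["relations"]),
        config=TrainConfig(**meta["config"]),
        input_dim=int(meta["input_dim"]),
    )
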