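"""Seeded generators for every input the pipeline consumes.

The generators emulate the *statistical structure* each analysis stage
assumes, so the whole tool is testable without any external downloads:

* a typed, directed knowledge graph with latent communities whose
  community pairs prefer different relation labels;
* node features that are noisy linear images of community membership,
  split into ontology / expression / mutation blocks;
* labeled links planted by a relation-specific rule — a pair interacts
  iff the two genes share enough common out-neighbours *under one
  designated relation* — so a relation-aware encoder holds a genuine
  advantage over a relation-blind one;
* a perturbed (cancer) network with planted hub genes gaining and/or
  losing links at a configurable multiple of the background rate;
* a survival cohort with per-gene mutation indicators and exponential
  survival times whose hazard is scaled by planted per-gene effects.

All randomness flows from ``SimConfig.seed`` through fixed, per-generator
substreams (``numpy.random.SeedSequence`` spawn keys), so adding or
re-running one generator never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import KnowledgeGraph, LinkDataset, NodeFeatureTable
from .perturbation import Edge, normalize_edge
from .survival import SurvivalCohort

# fixed substream keys: adding a generator never shifts another's draws
_STREAM_GRAPH = 0
_STREAM_FEATURES = 1
_STREAM_LINKS = 2
_STREAM_PERTURB = 3
_STREAM_SURVIVAL = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(3, len(str(max(n - 1, 0))))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Graph: ``n_nodes`` genes in ``n_communities`` latent communities;
    an ordered pair carries an edge of relation r with probability
    ``edge_density * multiplier * n_relations * pi[c_u, c_v, r]`` where the
    multiplier prefers within-community pairs and ``pi`` blends (weight
    ``node_mixing``) the source gene's own relation-usage profile — each
    gene commits to a preferred outgoing relation, Dirichlet concentration
    ``node_relation_concentration`` — with a per community-pair Dirichlet
    preference (concentration ``relation_concentration``).  Expected edge
    count is exactly ``edge_density * n_nodes * (n_nodes - 1) *
    n_relations``.

    Links: positive iff the pair shares >= ``overlap_threshold`` common
    out-neighbours under relation index ``designated_relation``; observed
    labels carry ``label_flip_rate`` label noise (flips are stratified so
    the requested class counts stay exact and each class contains the
    nominal flip fraction).  A fraction ``community_match_frac`` of the
    true negatives is drawn community-matched to the sampled positives so
    that community membership alone cannot separate the classes.

    Perturbation: hub universe of ``n_hub_genes`` genes with
    ``n_reference_edges`` directed reference links; every gene gains
    (loses) links at per-gene rate ``background_gain_rate``
    (``background_loss_rate``), planted hubs at ``hub_gain_multiplier``
    times that rate.

    Survival: ``n_patients`` patients, per-gene mutation prevalence uniform
    in ``mutation_prevalence``, exponential survival with baseline mean
    ``baseline_mean_days`` scaled down by each mutated gene's hazard ratio
    in ``planted_gene_effects``, independent exponential censoring tuned to
    censor ``censoring_rate`` of patients.
    """

    # knowledge graph
    n_nodes: int = 300
    n_relations: int = 3
    n_communities: int = 6
    edge_density: float = 0.05
    within_multiplier: float = 4.0
    relation_concentration: float = 0.3
    node_relation_concentration: float = 0.02
    node_mixing: float = 0.98
    # features
    latent_dim: int = 64
    feature_block_dims: tuple[int, int, int] = (32, 16, 16)
    feature_noise_sd: float = 1.0
    # links
    n_pos_links: int = 400
    n_neg_links: int = 400
    label_flip_rate: float = 0.05
    overlap_threshold: int = 3
    designated_relation: int = 0
    community_match_frac: float = 0.9
    # perturbation / hubs
    n_hub_genes: int = 200
    n_reference_edges: int = 15000
    background_gain_rate: float = 20.0
    background_loss_rate: float = 20.0
    hub_gain_multiplier: float = 5.0
    planted_hub_ids: tuple[str, ...] = ()
    planted_hub_types: tuple[str, ...] = ()
    # survival
    n_patients: int = 500
    n_survival_genes: int = 20
    planted_gene_effects: dict = field(
        default_factory=lambda: {"G000": 3.0, "G001": 1.0 / 3.0}
    )
    mutation_prevalence: tuple[float, float] = (0.1, 0.4)
    baseline_mean_days: float = 1500.0
    censoring_rate: float = 0.25
    # master seed (mandatory; every generator derives a substream from it)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nodes, self.n_relations, self.n_communities) <= 0:
            raise ValueError("counts must be positive")
        for name in ("edge_density", "label_flip_rate", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if sum(self.feature_block_dims) != self.latent_dim:
            raise ValueError("feature_block_dims must sum to latent_dim")
        if len(self.planted_hub_ids) != len(self.planted_hub_types):
            raise ValueError("planted_hub_ids and planted_hub_types must be parallel")
        for t in self.planted_hub_types:
            if t not in ("gain", "loss", "both"):
                raise ValueError(f"unknown planted hub type {t!r}")


def default_hub_plan(cfg: SimConfig, n_planted: int = 10) -> SimConfig:
    """Fill in a standard planted-hub layout: first genes of the hub
    universe, 40% gain-only, 40% loss-only, 20% both."""
    from dataclasses import replace

    ids = tuple(gene_names(cfg.n_hub_genes)[:n_planted])
    n_gain = max(1, int(round(0.4 * n_planted)))
    n_loss = max(1, int(round(0.4 * n_planted)))
    types = ("gain",) * n_gain + ("loss",) * n_loss + ("both",) * (
        n_planted - n_gain - n_loss
    )
    return replace(cfg, planted_hub_ids=ids, planted_hub_types=types)


# ---------------------------------------------------------------------------
# knowledge graph


def communities(cfg: SimConfig) -> np.ndarray:
    """Community assignment: contiguous, near-equal blocks."""
    return (np.arange(cfg.n_nodes) * cfg.n_communities) // cfg.n_nodes


def gen_graph(cfg: SimConfig) -> KnowledgeGraph:
    """Typed multigraph with community structure and community-pair
    relation preferences; deterministic per seed."""
    rng = _rng(cfg.seed, _STREAM_GRAPH)
    n, R = cfg.n_nodes, cfg.n_relations
    comm = communities(cfg)
    names = gene_names(n)

    same = comm[:, None] == comm[None, :]
    f_in = (same.sum() - n) / (n * (n - 1))
    a_in = cfg.within_multiplier
    if a_in * f_in >= 1.0:
        raise ValueError("within_multiplier too large for this community layout")
    a_out = (1.0 - a_in * f_in) / (1.0 - f_in)
    mult = np.where(same, a_in, a_out)

    pi = rng.dirichlet(
        np.full(R, cfg.relation_concentration),
        size=(cfg.n_communities, cfg.n_communities),
    )  # (C, C, R): community pairs commit to different relation mixes
    # per-node relation usage: each gene commits to a preferred relation for
    # its outgoing edges (kinases phosphorylate, TFs regulate expression...),
    # independently of its community
    usage = rng.dirichlet(np.full(R, cfg.node_relation_concentration), size=n)
    mix = (
        cfg.node_mixing * usage[:, None, :]
        + (1.0 - cfg.node_mixing) * pi[comm[:, None], comm[None, :], :]
    )  # (n, n, R), sums to 1 over relations
    q = cfg.edge_density * mult[:, :, None] * R * mix
    q[np.arange(n), np.arange(n), :] = 0.0
    if q.max() > 1.0:
        raise ValueError(
            f"edge probability {q.max():.3f} > 1: density/multiplier imply more "
            "than a complete multigraph"
        )
    draws = rng.random((n, n, R)) < q
    src, dst, rel = np.nonzero(draws)
    rel_names = [f"rel{r}" for r in range(R)]
    edges = [(names[s], rel_names[r], names[t]) for s, t, r in zip(src, dst, rel)]
    return KnowledgeGraph(
        nodes=tuple(names),
        edges=edges,
        relations=tuple(rel_names),
        meta={"communities": {g: int(c) for g, c in zip(names, comm)}},
    )


def expected_edge_count(cfg: SimConfig) -> float:
    return cfg.edge_density * cfg.n_nodes * (cfg.n_nodes - 1) * cfg.n_relations


# ---------------------------------------------------------------------------
# features


def gen_features(graph: KnowledgeGraph, cfg: SimConfig) -> NodeFeatureTable:
    """Community one-hot through a random linear map plus Gaussian noise.

    With ``feature_noise_sd = 0`` same-community nodes are identical; the
    default noise gives every node an individually distinctive signature
    on top of its community centroid (standing in for the fact that real
    ontology embeddings are gene-specific, not community-specific).
    """
    rng = _rng(cfg.seed, _STREAM_FEATURES)
    comm_of = graph.meta.get("communities")
    if comm_of is None:
        raise ValueError("graph lacks community metadata (not a synthetic graph?)")
    centroids = rng.normal(size=(cfg.n_communities, cfg.latent_dim))
    noise = rng.normal(scale=1.0, size=(graph.n_nodes, cfg.latent_dim))
    X = np.empty((graph.n_nodes, cfg.latent_dim))
    for i, g in enumerate(graph.nodes):
        X[i] = centroids[comm_of[g]] + cfg.feature_noise_sd * noise[i]
    return NodeFeatureTable(
        genes=graph.nodes, X=X, block_dims=cfg.feature_block_dims
    )


# ---------------------------------------------------------------------------
# labeled links


def _overlap_matrix(graph: KnowledgeGraph, relation: str) -> np.ndarray:
    idx = graph.node_index()
    n = graph.n_nodes
    A = np.zeros((n, n), dtype=np.int32)
    for s, r, t in graph.edges:
        if r == relation:
            A[idx[s], idx[t]] = 1
    return A @ A.T  # common out-neighbour counts


def rule_scores(graph: KnowledgeGraph, cfg: SimConfig) -> np.ndarray:
    """The planted rule's raw statistic (common out-neighbour counts under
    the designated relation) for every ordered pair; the generator's own
    oracle for label recoverability checks."""
    relation = graph.relations[cfg.designated_relation]
    return _overlap_matrix(graph, relation)


def gen_links(graph: KnowledgeGraph, cfg: SimConfig) -> LinkDataset:
    """Labeled ordered pairs under the planted typed-overlap rule.

    A pair's true label is positive iff its common out-neighbour count
    under the designated relation reaches ``overlap_threshold``.  The
    observed dataset has exact class counts with ``label_flip_rate`` of
    each observed class carrying the wrong true label (stratified flips:
    uniform subsampling after flipping the whole pair matrix would let
    the much larger negative class swamp the positives, inflating the
    effective noise far beyond the nominal rate).  True negatives are
    drawn community-pair-matched to the sampled positives (fraction
    ``community_match_frac``; remainder uniform), so the classes cannot
    be separated by community membership alone — only by the typed
    neighbourhood structure itself.
    """
    rng = _rng(cfg.seed, _STREAM_LINKS)
    n = graph.n_nodes
    names = graph.nodes
    O = rule_scores(graph, cfg)
    label = O >= cfg.overlap_threshold
    np.fill_diagonal(label, False)
    offdiag = ~np.eye(n, dtype=bool)
    pos_pool = np.argwhere(label & offdiag)
    neg_mask = ~label & offdiag

    n_flip_pos = int(round(cfg.label_flip_rate * cfg.n_pos_links))
    n_flip_neg = int(round(cfg.label_flip_rate * cfg.n_neg_links))
    n_true_pos = cfg.n_pos_links - n_flip_pos
    n_true_neg = cfg.n_neg_links - n_flip_neg
    if len(pos_pool) < n_true_pos + n_flip_neg:
        raise ValueError(
            f"only {len(pos_pool)} rule-positive pairs available; need "
            f"{n_true_pos + n_flip_neg} (raise density or lower the threshold)"
        )

    take = rng.choice(len(pos_pool), size=n_true_pos + n_flip_neg, replace=False)
    true_pos = [tuple(p) for p in pos_pool[take[:n_true_pos]]]
    neg_from_pos = [tuple(p) for p in pos_pool[take[n_true_pos:]]]

    comm = np.array([graph.meta["communities"][g] for g in names])
    by_cpair: dict[tuple[int, int], np.ndarray] = {}
    used: set[tuple[int, int]] = set(true_pos) | set(neg_from_pos)

    def draw_negative(cpair: tuple[int, int] | None) -> tuple[int, int]:
        if cpair is not None:
            pool = by_cpair.get(cpair)
            if pool is None:
                sel = (comm[:, None] == cpair[0]) & (comm[None, :] == cpair[1])
                pool = np.argwhere(neg_mask & sel)
                by_cpair[cpair] = pool
            if len(pool):
                for _ in range(50):
                    cand = tuple(pool[rng.integers(len(pool))])
                    if cand not in used:
                        return cand
        while True:  # uniform fallback
            a, b = rng.integers(n), rng.integers(n)
            if a != b and neg_mask[a, b] and (a, b) not in used:
                return (a, b)

    def matched_cpair() -> tuple[int, int] | None:
        if rng.random() < cfg.community_match_frac and true_pos:
            ref = true_pos[rng.integers(len(true_pos))]
            return (int(comm[ref[0]]), int(comm[ref[1]]))
        return None

    true_neg: list[tuple[int, int]] = []
    for _ in range(n_true_neg):
        cand = draw_negative(matched_cpair())
        true_neg.append(cand)
        used.add(cand)

    # flipped-in positives follow the same sampling law as the negatives,
    # so label noise carries no community signature of its own
    pos_from_neg: list[tuple[int, int]] = []
    for _ in range(n_flip_pos):
        cand = draw_negative(matched_cpair())
        pos_from_neg.append(cand)
        used.add(cand)

    records = [(names[a], names[b], 1) for a, b in true_pos + pos_from_neg]
    records += [(names[a], names[b], 0) for a, b in true_neg + neg_from_pos]
    perm = rng.permutation(len(records))
    return LinkDataset([records[i] for i in perm])


# ---------------------------------------------------------------------------
# perturbed network with planted hubs


def gen_reference_net(cfg: SimConfig) -> set[Edge]:
    """Uniform directed reference interactome over the hub universe.

    Directed, matching the link predictor's ordered-pair output; the hub
    statistics downstream count links incident to a gene in either
    direction.
    """
    rng = _rng(cfg.seed, _STREAM_PERTURB)
    names = gene_names(cfg.n_hub_genes)
    max_edges = cfg.n_hub_genes * (cfg.n_hub_genes - 1)
    if cfg.n_reference_edges > max_edges:
        raise ValueError("n_reference_edges exceeds the complete directed graph")
    edges: set[Edge] = set()
    while len(edges) < cfg.n_reference_edges:
        need = cfg.n_reference_edges - len(edges)
        u = rng.integers(0, cfg.n_hub_genes, size=2 * need + 10)
        v = rng.integers(0, cfg.n_hub_genes, size=2 * need + 10)
        for a, b in zip(u, v):
            if a == b:
                continue
            edges.add((names[a], names[b]))
            if len(edges) >= cfg.n_reference_edges:
                break
    return edges


def _hub_rate_multipliers(cfg: SimConfig, names: list[str]):
    planted = dict(zip(cfg.planted_hub_ids, cfg.planted_hub_types))
    for g in planted:
        if g not in names:
            raise ValueError(f"planted hub {g!r} outside the hub universe")
    m_gain = np.ones(len(names))
    m_loss = np.ones(len(names))
    idx = {g: i for i, g in enumerate(names)}
    for g, t in planted.items():
        if t in ("gain", "both"):
            m_gain[idx[g]] = cfg.hub_gain_multiplier
        if t in ("loss", "both"):
            m_loss[idx[g]] = cfg.hub_gain_multiplier
    return planted, m_gain, m_loss


def gen_perturbed_network(
    reference: Iterable[Edge], cfg: SimConfig
) -> tuple[set[Edge], dict[str, str]]:
    """Cancer network = reference - lost + gained, with planted hubs.

    Per-gene perturbation counts are Poisson with rate
    ``background_gain_rate`` (``background_loss_rate``), multiplied by
    ``hub_gain_multiplier`` for planted genes — so planted hubs carry
    exactly the configured multiple of the background link rate.  Gained
    links are realised by configuration-model stub pairing over novel
    ordered pairs (each gene receives its drawn number of link endpoints,
    so planted and background genes never compete for link mass); lost
    links are a per-gene subset of each gene's incident reference edges.
    Returns the cancer edge set and the ground-truth table mapping each
    planted gene to its type (Type1 = gained, Type2 = lost, Type3 = both).
    """
    rng = _rng(cfg.seed, _STREAM_PERTURB + 10)
    ref_set = {(a, b) for a, b in reference}
    names = gene_names(cfg.n_hub_genes)
    n = len(names)
    planted, m_gain, m_loss = _hub_rate_multipliers(cfg, names)

    # --- gained: stub pairing -------------------------------------------
    targets = rng.poisson(cfg.background_gain_rate * m_gain)
    stubs = np.repeat(np.arange(n), targets)
    if len(stubs) % 2:
        stubs = stubs[:-1]
    rng.shuffle(stubs)
    gained: set[Edge] = set()
    leftovers: list[int] = []
    for a, b in zip(stubs[0::2], stubs[1::2]):
        e = (names[a], names[b])
        if a == b or e in ref_set or e in gained:
            leftovers.extend((a, b))
            continue
        gained.add(e)
    # re-pair rejected stubs a few times so realised counts track targets
    for _ in range(20):
        if len(leftovers) < 2:
            break
        stubs = np.array(leftovers)
        rng.shuffle(stubs)
        leftovers = []
        for a, b in zip(stubs[0::2], stubs[1::2]):
            e = (names[a], names[b])
            if a == b or e in ref_set or e in gained:
                leftovers.extend((int(a), int(b)))
                continue
            gained.add(e)

    # --- lost: per-gene subset of incident reference edges --------------
    incident: dict[int, list[Edge]] = {i: [] for i in range(n)}
    name_idx = {g: i for i, g in enumerate(names)}
    for a, b in sorted(ref_set):
        incident[name_idx[a]].append((a, b))
        incident[name_idx[b]].append((a, b))
    lost: set[Edge] = set()
    loss_targets = rng.poisson(cfg.background_loss_rate * m_loss)
    # planted genes first: their incident edges are removed at the full
    # planted rate; background genes then top up to their own rate,
    # counting losses already inflicted by planted partners
    order = sorted(range(n), key=lambda i: -m_loss[i])
    for i in order:
        have = sum(1 for e in incident[i] if e in lost)
        need = int(loss_targets[i]) - have
        if need <= 0:
            continue
        avail = [e for e in incident[i] if e not in lost]
        take = rng.choice(len(avail), size=min(need, len(avail)), replace=False)
        lost.update(avail[j] for j in take)

    cancer = (ref_set - lost) | gained
    truth = {
        g: {"gain": "Type1", "loss": "Type2", "both": "Type3"}[t]
        for g, t in planted.items()
    }
    return cancer, truth


# ---------------------------------------------------------------------------
# survival cohort


def gen_survival(cfg: SimConfig) -> SurvivalCohort:
    """Exponential survival with planted per-gene hazard-ratio effects.

    Each gene is mutated independently per patient at a prevalence drawn
    uniformly from ``mutation_prevalence``; a patient's hazard is the
    baseline times the product of the hazard ratios of their mutated
    genes.  Censoring is an independent exponential clock whose rate is
    tuned so roughly ``censoring_rate`` of patients are censored
    (``censoring_rate = 0`` disables it: every event is observed).
    """
    rng = _rng(cfg.seed, _STREAM_SURVIVAL)
    genes = gene_names(cfg.n_survival_genes)
    effects = dict(cfg.planted_gene_effects)
    for g in effects:
        if g not in genes:
            raise ValueError(f"planted effect gene {g!r} outside the gene panel")
    lo, hi = cfg.mutation_prevalence
    prevalence = rng.uniform(lo, hi, size=cfg.n_survival_genes)
    M = (rng.random((cfg.n_patients, cfg.n_survival_genes)) < prevalence).astype(int)

    lam0 = 1.0 / cfg.baseline_mean_days
    log_hr = np.array([np.log(effects.get(g, 1.0)) for g in genes])
    lam = lam0 * np.exp(M @ log_hr)
    t_event = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        lam_c = lam0 * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=cfg.n_patients)
    else:
        t_cens = np.full(cfg.n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "patient": [f"P{i:04d}" for i in range(cfg.n_patients)],
            "time_days": np.maximum(time, 1.0).round(1),
            "event": event,
        }
    )
    for j, g in enumerate(genes):
        df[g] = M[:, j]
    return SurvivalCohort(df)
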