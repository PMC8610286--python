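"""Interactome perturbation: network diffing, binomial hub-gene tests,
and random-walk eigenvector centrality.

A cancer network is read off the link predictor's high-confidence band
(|RI| >= cutoff, default 80) and compared against a reference interactome.
Edges confidently predicted present but absent from the reference are
*gained*; reference edges confidently predicted non-interacting are *lost*.
A gene carrying more gained (or lost) links than expected if links attached
to genes uniformly at random is a hub gene:

    P(m >= k) = sum_{i=k..n} C(n, i) p^i (1-p)^(n-i)

with n = 2 x (total links of that class) and per-trial probability
p = 2/L over the L unique genes of the analysis universe, Bonferroni
adjusted across the genes tested.  Type 1 hubs are enriched in gained
links only, Type 2 in lost links only, Type 3 in both.

Note the doubled per-trial probability: under the plain uniform-endpoint
model one would take p = 1/L (each of the n = 2E endpoint draws hits a
given gene with probability 1/L).  The doubled form sets the null mean to
twice the actual mean degree and is therefore conservative; it is the
package default, with ``null_model="standard"`` switching to p = 1/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .rgcn import PredictionRecord

Edge = tuple[str, str]


def normalize_edge(a: str, b: str, directed: bool) -> Edge:
    if directed or a <= b:
        return (a, b)
    return (b, a)


@dataclass
class NetworkDiff:
    """Gained and lost edges between a reference and a cancer network."""

    gained: dict[str, set[Edge]]  # per gene, gained edges touching it
    lost: dict[str, set[Edge]]
    gained_edges: set[Edge]
    lost_edges: set[Edge]
    nodes: tuple[str, ...]  # analysis universe, sorted
    directed: bool = False

    def k_gained(self, gene: str) -> int:
        return len(self.gained.get(gene, ()))

    def k_lost(self, gene: str) -> int:
        return len(self.lost.get(gene, ()))


def _per_gene(edges: Iterable[Edge]) -> dict[str, set[Edge]]:
    out: dict[str, set[Edge]] = {}
    for e in edges:
        for g in set(e):
            out.setdefault(g, set()).add(e)
    return out


def diff_edge_sets(
    reference: Iterable[Edge],
    cancer: Iterable[Edge],
    directed: bool = False,
    nodes: Iterable[str] | None = None,
) -> NetworkDiff:
    """Diff two explicit edge sets (used for synthetic ground-truth nets)."""
    ref = {normalize_edge(*e, directed) for e in reference}
    can = {normalize_edge(*e, directed) for e in cancer}
    gained = can - ref
    lost = ref - can
    if nodes is None:
        universe = {g for e in ref | can for g in e}
    else:
        universe = set(nodes)
    return NetworkDiff(
        gained=_per_gene(gained),
        lost=_per_gene(lost),
        gained_edges=gained,
        lost_edges=lost,
        nodes=tuple(sorted(universe)),
        directed=directed,
    )


def diff_networks(
    cancer_preds: Sequence[PredictionRecord],
    reference_net: Iterable[Edge],
    ri_cutoff: int = 80,
    directed: bool = False,
) -> NetworkDiff:
    """Diff the predicted cancer interactome against a reference edge set.

    Pairs with RI >= cutoff form the cancer network; a reference edge
    counts as lost only when confidently predicted non-interacting
    (RI <= -cutoff) — the abstain band |RI| < cutoff contributes to
    neither side.
    """
    if not 0 < ri_cutoff <= 100:
        raise ValueError(f"ri_cutoff must be in (0, 100], got {ri_cutoff}")
    ref = {normalize_edge(*e, directed) for e in reference_net}
    cancer_edges: set[Edge] = set()
    confident_neg: set[Edge] = set()
    pred_genes: set[str] = set()
    for r in cancer_preds:
        if not r.ok:
            continue
        e = normalize_edge(r.gene_a, r.gene_b, directed)
        pred_genes.update(e)
        if r.ri >= ri_cutoff:
            cancer_edges.add(e)
        elif r.ri <= -ri_cutoff:
            confident_neg.add(e)
    gained = cancer_edges - ref
    lost = ref & confident_neg
    universe = pred_genes | {g for e in ref for g in e}
    return NetworkDiff(
        gained=_per_gene(gained),
        lost=_per_gene(lost),
        gained_edges=gained,
        lost_edges=lost,
        nodes=tuple(sorted(universe)),
        directed=directed,
    )


# ---------------------------------------------------------------------------
# binomial hub test


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper tail P(m >= k) of Binomial(n, p), stable via the survival
    function; exactly 1 at k = 0."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


@dataclass
class HubResult:
    gene: str
    k_gained: int
    k_lost: int
    p_gained: float
    p_lost: float
    p_adj_gained: float
    p_adj_lost: float
    hub_type: str  # "Type1" | "Type2" | "Type3" | "none"


def hub_test(
    diff: NetworkDiff,
    alpha: float = 0.05,
    null_model: str = "doubled",
) -> list[HubResult]:
    """Binomial enrichment test per gene, separately for gained and lost
    links, Bonferroni-adjusted within each class over all genes tested."""
    if not diff.gained_edges and not diff.lost_edges:
        raise ValueError("empty diff: nothing to test")
    L = len(diff.nodes)
    if L < 2:
        raise ValueError("need at least 2 genes in the universe")
    if null_model == "doubled":
        p = 2.0 / L
    elif null_model == "standard":
        p = 1.0 / L
    else:
        raise ValueError(f"unknown null_model {null_model!r}")
    p = min(p, 1.0)
    n_gained = 2 * len(diff.gained_edges)
    n_lost = 2 * len(diff.lost_edges)
    results = []
    for gene in diff.nodes:
        kg = diff.k_gained(gene)
        kl = diff.k_lost(gene)
        pg = binomial_tail(kg, n_gained, p) if n_gained else 1.0
        pl = binomial_tail(kl, n_lost, p) if n_lost else 1.0
        ag = min(1.0, pg * L)
        al = min(1.0, pl * L)
        sig_g = ag < alpha
        sig_l = al < alpha
        if sig_g and sig_l:
            htype = "Type3"
        elif sig_g:
            htype = "Type1"
        elif sig_l:
            htype = "Type2"
        else:
            htype = "none"
        results.append(
            HubResult(
                gene=gene,
                k_gained=kg,
                k_lost=kl,
                p_gained=pg,
                p_lost=pl,
                p_adj_gained=ag,
                p_adj_lost=al,
                hub_type=htype,
            )
        )
    return results


def write_hubs(
    results: Sequence[HubResult],
    path,
    centrality_ref: dict[str, float] | None = None,
    centrality_cancer: dict[str, float] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tk_gained\tk_lost\tp_gained\tp_lost\tp_adj_gained\tp_adj_lost"
            "\thub_type\tcentrality_ref\tcentrality_cancer\n"
        )
        for r in results:
            cr = centrality_ref.get(r.gene, float("nan")) if centrality_ref else float("nan")
            cc = (
                centrality_cancer.get(r.gene, float("nan"))
                if centrality_cancer
                else float("nan")
            )
            fh.write(
                f"{r.gene}\t{r.k_gained}\t{r.k_lost}\t{r.p_gained:.6g}\t"
                f"{r.p_lost:.6g}\t{r.p_adj_gained:.6g}\t{r.p_adj_lost:.6g}\t"
                f"{r.hub_type}\t{cr:.6g}\t{cc:.6g}\n"
            )


# ---------------------------------------------------------------------------
# centrality


def centrality_softmax(
    edges: Iterable[Edge],
    nodes: Iterable[str] | None = None,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    directed: bool = False,
) -> dict[str, float]:
    """Damped random-walk eigenvector centrality, softmax-normalised.

    Power iteration on M = damping * S + (1-damping)/N * 1 1^T, with S the
    column-stochastic adjacency (dangling columns spread uniformly);
    damping keeps disconnected graphs irreducible.  The stationary vector
    is passed through a softmax so the per-network centralities form a
    probability distribution: the chance that a random walker, started at
    a random gene, is found at each gene.
    """
    edge_list = [normalize_edge(*e, directed) for e in edges]
    if not edge_list:
        raise ValueError("centrality needs at least one edge")
    if nodes is None:
        universe = sorted({g for e in edge_list for g in e})
    else:
        universe = sorted(set(nodes))
    idx = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    rows, cols = [], []
    for a, b in edge_list:
        rows.append(idx[b])
        cols.append(idx[a])
        if not directed:
            rows.append(idx[a])
            cols.append(idx[b])
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    out_deg = np.asarray(A.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        inv = np.where(out_deg > 0, 1.0 / np.maximum(out_deg, 1), 0.0)
    S = A @ sp.diags(inv)
    dangling = out_deg == 0
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (S @ x + x[dangling].sum() / n) + (1 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(
            f"centrality power iteration did not converge; residual "
            f"{np.abs(x_new - x).sum():.3g} after {max_iter} iterations"
        )
    ex = np.exp(x - x.max())
    soft = ex / ex.sum()
    return {g: float(soft[idx[g]]) for g in universe}
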