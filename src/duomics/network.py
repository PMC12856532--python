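"""Multi-block discriminative integration and relevance networks.

A block sparse PLS-DA: each omics block gets per-component sparse unit-norm
loading vectors maximizing covariance between block scores, their cross-block
partners (weighted by a design matrix) and a dummy-coded outcome block.
Relevance similarity between features i and j from different blocks on a
chosen component is cor(x_i, z) * cor(x_j, z) with z the mean of the two
blocks' score vectors; edges with |similarity| above a threshold (0.85 by
default, component 1 for liver and component 2 for muscle) form the
relevance network, which is partitioned by greedy modularity maximization,
with hubs defined as nodes in the top decile of within-community degree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ValidationError

log = logging.getLogger("duomics")


def _center_scale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _soft_threshold_keep(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold a loading to its ``keep`` largest absolute entries."""
    if keep >= len(a):
        return a.copy()
    absa = np.abs(a)
    lam = np.sort(absa)[::-1][keep]
    out = np.sign(a) * np.maximum(absa - lam, 0.0)
    return out


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return v if v[i] >= 0 else -v


@dataclass
class BlockModel:
    """Fitted multi-block sparse PLS-DA."""

    block_names: list
    loadings: dict               # block -> (features x ncomp)
    scores: dict                 # block -> (samples x ncomp), incl. "outcome"
    keepX: dict                  # block -> per-component retained counts
    ncomp: int
    design: pd.DataFrame
    scaled: dict                 # block -> standardized data (pre-deflation)
    component_data: dict         # comp index -> block -> data the component was fit on
    feature_index: dict          # block -> feature ids
    converged: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for b in self.block_names:
            for h in range(self.ncomp):
                nz = int(np.sum(self.loadings[b][:, h] != 0))
                rows.append(dict(block=b, component=h + 1, nonzero_loadings=nz,
                                 keepX=self.keepX[b][h],
                                 converged=self.converged.get((b, h), True)))
        return pd.DataFrame(rows)


class BlockSPLSDA:
    """Model object for the multi-block sparse PLS-DA.

    Parameters
    ----------
    blocks : dict of DataFrame
        Samples x features per omics block; all blocks share the sample
        index.
    outcome : Series
        Class label per sample (dummy-coded internally as its own block).
    design : float or DataFrame
        Off-diagonal block-connection weight (the outcome block is always
        fully connected) or an explicit symmetric design matrix.
    """

    def __init__(self, blocks: dict, outcome: pd.Series, design: float | pd.DataFrame = 0.1):
        names = list(blocks)
        samples = blocks[names[0]].index
        for b in names[1:]:
            if not blocks[b].index.equals(samples):
                raise ValidationError("blocks must share samples")
        self.block_names = names
        self.blocks = blocks
        self.outcome = outcome.loc[samples]
        levels = sorted(self.outcome.unique())
        Y = pd.get_dummies(self.outcome).astype(float)[levels]
        self.Y = Y
        all_names = names + ["outcome"]
        if isinstance(design, pd.DataFrame):
            self.design = design.loc[all_names, all_names]
        else:
            D = pd.DataFrame(float(design), index=all_names, columns=all_names)
            D.loc["outcome", :] = 1.0
            D.loc[:, "outcome"] = 1.0
            np.fill_diagonal(D.values, 0.0)
            self.design = D

    def fit(self, ncomp: int = 2, keepX: dict | None = None,
            tol: float = 1e-6, max_iter: int = 500) -> BlockModel:
        names = self.block_names
        X = {b: _center_scale(self.blocks[b].to_numpy(dtype=float)) for b in names}
        X["outcome"] = _center_scale(self.Y.to_numpy(dtype=float))
        scaled = {b: X[b].copy() for b in X}
        widths = {b: X[b].shape[1] for b in X}
        if keepX is None:
            keepX = {b: [max(1, int(round(0.1 * widths[b])))] * ncomp for b in names}
        for b in names:
            kx = keepX[b]
            if isinstance(kx, int):
                keepX[b] = [kx] * ncomp
            for k in keepX[b]:
                if k > widths[b]:
                    raise ValidationError(f"keepX {k} exceeds block {b} width {widths[b]}")
        keepX = dict(keepX)
        keepX["outcome"] = [widths["outcome"]] * ncomp

        all_names = names + ["outcome"]
        loadings = {b: np.zeros((widths[b], ncomp)) for b in all_names}
        scores = {b: np.zeros((X[b].shape[0], ncomp)) for b in all_names}
        converged = {}
        component_data = {}
        D = self.design

        for h in range(ncomp):
            component_data[h] = {b: X[b].copy() for b in all_names}
            a = {}
            t = {}
            for b in all_names:
                # initialize from the dominant singular direction of the
                # covariance with the concatenated connected blocks
                others = [X[c] * D.loc[b, c] for c in all_names if c != b and D.loc[b, c] != 0]
                M = X[b].T @ np.hstack(others) if others else X[b].T
                u, _, _ = np.linalg.svd(M, full_matrices=False)
                a[b] = _fix_sign(u[:, 0])
                t[b] = X[b] @ a[b]
            ok = False
            for it in range(max_iter):
                max_delta = 0.0
                for b in all_names:
                    grad = np.zeros(widths[b])
                    for c in all_names:
                        if c == b or D.loc[b, c] == 0:
                            continue
                        grad += D.loc[b, c] * (X[b].T @ t[c])
                    new = _soft_threshold_keep(grad, keepX[b][h])
                    nrm = np.linalg.norm(new)
                    if nrm == 0:
                        new = grad
                        nrm = np.linalg.norm(new)
                    new = _fix_sign(new / nrm)
                    max_delta = max(max_delta, float(np.max(np.abs(new - a[b]))))
                    a[b] = new
                    t[b] = X[b] @ new
                if max_delta < tol:
                    ok = True
                    break
            for b in all_names:
                converged[(b, h)] = ok
                if not ok:
                    warnings.warn(f"component {h+1} not converged after {max_iter} iterations")
                loadings[b][:, h] = a[b]
                scores[b][:, h] = t[b]
                # deflate each block by its own score
                tb = t[b]
                denom = float(tb @ tb)
                if denom > 0:
                    X[b] = X[b] - np.outer(tb, tb @ X[b]) / denom
        return BlockModel(
            block_names=names,
            loadings={b: loadings[b] for b in all_names},
            scores={b: scores[b] for b in all_names},
            keepX=keepX, ncomp=ncomp, design=D,
            scaled={b: scaled[b] for b in all_names},
            component_data=component_data,
            feature_index={b: list(self.blocks[b].columns) for b in names},
            converged=converged,
        )


def relevance_similarity(model: BlockModel, component: int,
                         blocks: list | None = None) -> dict:
    """Pairwise cross-block relevance similarity on one component (1-based).

    For blocks q, r the similarity of features i, j is
    cor(x_i, z) * cor(x_j, z) with z = (t_q + t_r) / 2; because both
    correlations are against the same z, the pairwise matrix is the outer
    product of per-feature correlation vectors computed against z.  The
    correlations use each block's data as it stood when the component was
    extracted (earlier components deflated out), so the similarity reflects
    that component's structure only.
    """
    h = component - 1
    if h < 0 or h >= model.ncomp:
        raise ValidationError(f"component {component} out of range")
    blocks = blocks or model.block_names
    sims = {}
    for qi, q in enumerate(blocks):
        for r in blocks[qi + 1:]:
            z = (model.scores[q][:, h] + model.scores[r][:, h]) / 2.0
            cq = _feature_correlations_with(model, q, z, h)
            cr = _feature_correlations_with(model, r, z, h)
            sims[(q, r)] = pd.DataFrame(
                np.outer(cq.to_numpy(), cr.to_numpy()), index=cq.index, columns=cr.index
            )
    return sims


def _feature_correlations_with(model: BlockModel, block: str, z: np.ndarray,
                               component: int = 0) -> pd.Series:
    X = model.component_data[component][block]
    zc = z - z.mean()
    dz = np.sqrt((zc ** 2).sum())
    Xc = X - X.mean(axis=0)
    dx = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = (Xc.T @ zc) / (dx * dz)
    out = pd.Series(cors, index=model.feature_index[block])
    return out[np.isfinite(out.to_numpy())]


def build_network(similarities: dict, threshold: float = 0.85,
                  directions: dict | None = None) -> nx.Graph:
    """Relevance network from cross-block similarity matrices.

    Edges where |similarity| is strictly above the threshold; isolated
    features are excluded (every node has at least one edge).  Node
    attributes carry the block and, when provided, the feature's
    differential direction.
    """
    G = nx.Graph()
    for (q, r), sim in sorted(similarities.items()):
        arr = sim.to_numpy()
        ii, jj = np.nonzero(np.abs(arr) > threshold)
        for i, j in zip(ii, jj):
            fi, fj = sim.index[i], sim.columns[j]
            G.add_node(fi, block=q)
            G.add_node(fj, block=r)
            G.add_edge(fi, fj, similarity=float(arr[i, j]))
    if directions:
        for n in G.nodes:
            G.nodes[n]["direction"] = directions.get(n, "ns")
    if G.number_of_edges() == 0:
        log.warning("no edge survives threshold %.2f: empty network", threshold)
    return G


def communities_and_hubs(G: nx.Graph, percentile: float = 90.0):
    """Greedy-modularity communities and top-decile within-community hubs.

    Deterministic: nodes are processed in sorted order.  Hubs are nodes
    whose within-community degree reaches the community's given percentile
    (ties included), so every community has at least one hub.
    """
    if G.number_of_nodes() == 0:
        return {}, pd.DataFrame(columns=["feature_id", "community", "within_degree", "hub"])
    H = nx.Graph()
    H.add_nodes_from(sorted(G.nodes(data=True)))
    H.add_edges_from(sorted(G.edges(data=True)))
    comms = nx.community.greedy_modularity_communities(H)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    membership = {}
    rows = []
    for ci, members in enumerate(comms, start=1):
        mset = set(members)
        degs = {n: sum(1 for nb in G.neighbors(n) if nb in mset) for n in members}
        cut = np.percentile(list(degs.values()), percentile)
        for n in members:
            membership[n] = ci
            rows.append(dict(feature_id=n, community=ci, within_degree=degs[n],
                             hub=degs[n] >= cut))
    table = pd.DataFrame(rows).sort_values(["community", "feature_id"]).reset_index(drop=True)
    return membership, table
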