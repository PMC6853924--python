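"""Per-tumor clonal-architecture summaries.

Two complementary views of a tumor's clonal structure:

* from the CCF distribution — the Shannon entropy (in nats) of the 10-bin
  CCF histogram (a diversity index: low entropy means lineages have
  collapsed onto few frequency classes, the footprint of a hard sweep) and
  the median CCF;
* from clone trees — the linearity and branching indices: the proportions of
  cross-clone mutation pairs whose clones sit in ancestor-descendant versus
  incomparable (sibling-branch) relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .data_io import CloneTree

logger = logging.getLogger(__name__)

N_BINS = 10
_BIN_EDGES = np.linspace(0.0, 1.0, N_BINS + 1)


@dataclass
class ArchitectureMetrics:
    sample_id: str
    median_ccf: float
    diversity_h: float
    bin_counts: np.ndarray
    n_mutations: int


@dataclass
class TreeIndices:
    linearity: float
    branching: float
    n_trees_averaged: int = 1
    degenerate: bool = False


@dataclass
class AssociationFit:
    slope: float
    intercept: float
    p_nonzero_slope: float
    degenerate: bool = False


def diversity_index(ccfs: Sequence[float] | np.ndarray) -> tuple[float, np.ndarray]:
    """Shannon entropy H = -sum p_i ln p_i of the 10-bin CCF histogram.

    Bins are [0, 0.1), ..., [0.9, 1.0] with the last bin closed so clonal
    mutations (CCF = 1) occupy the top bin; values are clipped to [0, 1]
    first and 0 ln 0 is taken as 0.  Returns ``(H, bin_counts)``.
    """
    ccfs = np.asarray(ccfs, dtype=float)
    if ccfs.size == 0:
        raise ValueError("diversity_index requires at least one CCF")
    counts, _ = np.histogram(np.clip(ccfs, 0.0, 1.0), bins=_BIN_EDGES)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum()), counts


def median_ccf(ccfs: Sequence[float] | np.ndarray) -> float:
    """Median CCF (mean of the middle two for even n)."""
    ccfs = np.asarray(ccfs, dtype=float)
    if ccfs.size == 0:
        raise ValueError("median_ccf requires at least one CCF")
    return float(np.median(ccfs))


def summarize_sample(sample_id: str, ccfs: Sequence[float] | np.ndarray) -> ArchitectureMetrics:
    h, counts = diversity_index(ccfs)
    return ArchitectureMetrics(
        sample_id=sample_id,
        median_ccf=median_ccf(ccfs),
        diversity_h=h,
        bin_counts=counts,
        n_mutations=int(counts.sum()),
    )


def best_tree(trees: Sequence[CloneTree], best: str = "lowest") -> CloneTree:
    """Select the best-ranked tree by normalized log likelihood.

    The default takes the tree with the *lowest* normalized log-likelihood
    value; ``best="highest"`` selects the conventional maximum instead.  Ties
    break toward fewer nodes, then first occurrence.  Trees without
    likelihoods fall back to the first tree with a warning.
    """
    if not trees:
        raise ValueError("no trees given")
    scored = [(t.log_likelihood, i, t) for i, t in enumerate(trees) if t.log_likelihood is not None]
    if not scored:
        logger.warning("no tree carries a log likelihood; falling back to the first tree")
        return trees[0]
    sign = 1.0 if best == "lowest" else -1.0
    return min(scored, key=lambda x: (sign * x[0], len(x[2].nodes), x[1]))[2]


def tree_indices(tree: CloneTree) -> TreeIndices:
    """Linearity and branching of one clone tree over cross-node mutation pairs.

    Every unordered pair of mutations sitting in two *distinct* nodes is
    LINEAR when one node is an ancestor of the other and BRANCHED when the
    nodes are incomparable; same-node pairs are excluded.  The indices are
    the two proportions (they sum to 1 over cross-node pairs).  A tree with
    fewer than two mutation-bearing nodes has both indices 0 and is flagged
    degenerate.
    """
    nodes = [n for n in tree.nodes if n.n_mutations > 0]
    if len(nodes) < 2:
        return TreeIndices(linearity=0.0, branching=0.0, degenerate=True)
    anc = {n.node_id: set(tree.ancestors(n.node_id)) for n in tree.nodes}
    linear = 0
    branched = 0
    for a_idx in range(len(nodes)):
        for b_idx in range(a_idx + 1, len(nodes)):
            a, b = nodes[a_idx], nodes[b_idx]
            pairs = a.n_mutations * b.n_mutations
            if a.node_id in anc[b.node_id] or b.node_id in anc[a.node_id]:
                linear += pairs
            else:
                branched += pairs
    total = linear + branched
    return TreeIndices(linearity=linear / total, branching=branched / total)


def averaged_tree_indices(
    trees: Sequence[CloneTree], top_k: int | None = None, best: str = "lowest"
) -> TreeIndices:
    """Unweighted mean of per-tree indices over the ``top_k`` best-ranked trees."""
    if not trees:
        raise ValueError("no trees given")
    sign = 1.0 if best == "lowest" else -1.0
    order = sorted(
        range(len(trees)),
        key=lambda i: (
            (sign * trees[i].log_likelihood) if trees[i].log_likelihood is not None else np.inf,
            len(trees[i].nodes),
            i,
        ),
    )
    chosen = order if top_k is None else order[: max(1, top_k)]
    per = [tree_indices(trees[i]) for i in chosen]
    return TreeIndices(
        linearity=float(np.mean([p.linearity for p in per])),
        branching=float(np.mean([p.branching for p in per])),
        n_trees_averaged=len(per),
        degenerate=all(p.degenerate for p in per),
    )


def architecture_association(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> AssociationFit:
    """Ordinary least-squares fit of y on x with a non-zero-slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0:
        return AssociationFit(slope=0.0, intercept=float(np.mean(y)), p_nonzero_slope=1.0, degenerate=True)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_nonzero_slope=float(model.pvalues[1]),
    )
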