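"""Up/down expression-signature construction, single-sample scoring, and the
information coefficient.

The signature workflow mirrors how pathway-activity scores are built from a
perturbation panel: normalize each gene to standard deviations from its
median across samples, rank genes by median absolute deviation, prune the
candidate list for compactness (mean absolute inter-gene correlation) and
first-principal-component variance share, and split the surviving genes into
"up" and "down" sets by the sign of their PC1 loading.  A sample's score is
the difference between its mean up-gene and mean down-gene expression,
relative to the within-sample variation of the signature genes — so the
score is exactly antisymmetric under swapping the up and down sets.

The information coefficient (IC) is a nonlinear association measure between
a binary genomic feature and a continuous response profile: the mutual
information between label and profile, estimated from Gaussian kernel
density estimates of the class-conditional profiles, rescaled to
``sqrt(1 - exp(-2 I))`` so it runs from 0 (no association) to 1 (perfect
association).  Significance comes from an empirical permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, norm

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    up_genes: list[str]
    down_genes: list[str]
    per_gene_center: dict[str, float] = field(default_factory=dict)
    per_gene_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.up_genes or not self.down_genes:
            raise ValueError("up and down gene sets must both be non-empty")
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene sets must be disjoint")

    def swapped(self) -> "GeneSignature":
        return GeneSignature(
            up_genes=list(self.down_genes),
            down_genes=list(self.up_genes),
            per_gene_center=dict(self.per_gene_center),
            per_gene_scale=dict(self.per_gene_scale),
        )


@dataclass
class AssociationResult:
    ic: float
    p_value: float
    n_permutations: int


def normalize_expression(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Normalize each gene to standard deviations from its median across samples.

    Returns the normalized matrix and the list of zero-variance genes, whose
    rows are set to 0.  Requires at least 3 samples.
    """
    if len(matrix.sample_ids) < 3:
        raise ValueError("need >= 3 samples to normalize")
    vals = matrix.values
    med = np.median(vals, axis=1, keepdims=True)
    sd = np.std(vals, axis=1, ddof=1, keepdims=True)
    flagged = [g for g, s in zip(matrix.gene_ids, sd.ravel()) if s == 0.0]
    if flagged:
        logger.warning("%d zero-variance genes set to 0", len(flagged))
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    out = np.where(sd == 0.0, 0.0, (vals - med) / safe_sd)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out), flagged


def select_variable_genes(matrix: ExpressionMatrix, n_genes: int) -> list[str]:
    """Top genes by median absolute deviation across samples (ties lexicographic)."""
    mad = np.median(
        np.abs(matrix.values - np.median(matrix.values, axis=1, keepdims=True)), axis=1
    )
    if n_genes > len(matrix.gene_ids):
        logger.warning("requested %d genes of %d; returning all", n_genes, len(matrix.gene_ids))
        n_genes = len(matrix.gene_ids)
    order = sorted(zip(matrix.gene_ids, mad), key=lambda gm: (-gm[1], gm[0]))
    return [g for g, _ in order[:n_genes]]


def _pc1_share_and_loadings(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Variance share of PC1 and gene loadings for a genes-x-samples block."""
    centered = x - x.mean(axis=1, keepdims=True)
    # SVD over samples: rows are genes (variables), columns samples (observations)
    u, s2, _ = np.linalg.svd(centered, full_matrices=False)
    var = s2**2
    share = float(var[0] / var.sum()) if var.sum() > 0 else 0.0
    return share, u[:, 0]


def _mean_abs_corr(x: np.ndarray) -> float:
    c = np.corrcoef(x)
    n = c.shape[0]
    off = np.abs(c[~np.eye(n, dtype=bool)])
    return float(np.mean(off))


def prune_signature(
    matrix: ExpressionMatrix,
    candidate_genes: list[str],
    target_size: int | None = None,
) -> GeneSignature:
    """Prune candidates for compactness and split into up/down sets.

    Greedy backward elimination: at each step, drop the gene whose removal
    most increases the mean absolute inter-gene correlation (compactness);
    stop when the removal no longer improves the variance share of the first
    principal component, or when ``target_size`` is reached.  Up/down
    assignment follows the sign of the PC1 loading, oriented so the "up" set
    correlates positively with the first component.
    """
    if len(candidate_genes) < 10:
        raise ValueError("need >= 10 candidate genes")
    df = matrix.to_frame()
    genes = [g for g in candidate_genes if g in df.index]
    x = df.loc[genes].to_numpy(dtype=float)
    if np.any(np.std(x, axis=1) == 0):
        logger.warning("degenerate (constant) candidate genes; returning unpruned split")
    floor = target_size if target_size is not None else 10
    current = list(range(len(genes)))
    share, _ = _pc1_share_and_loadings(x)
    # dropping the gene with the smallest summed |corr| to the others maximizes
    # the remaining mean absolute inter-gene correlation, so the greedy step
    # reduces to a row-sum argmin that can be maintained incrementally
    with np.errstate(invalid="ignore"):
        absc = np.abs(np.nan_to_num(np.corrcoef(x), nan=0.0))
    np.fill_diagonal(absc, 0.0)
    row_sums = absc.sum(axis=1)
    alive = np.ones(len(genes), dtype=bool)
    while len(current) > floor:
        sub = np.array(current)
        j = sub[np.argmin(row_sums[sub])]
        reduced = [i for i in current if i != j]
        new_share, _ = _pc1_share_and_loadings(x[reduced])
        if target_size is None and new_share <= share:
            break
        alive[j] = False
        row_sums -= absc[:, j]
        current, share = reduced, new_share
    kept = [genes[i] for i in current]
    xk = x[current]
    _, loadings = _pc1_share_and_loadings(xk)
    # orient PC1 so that positive loadings mean positively-scoring genes
    if np.sum(loadings) < 0:
        loadings = -loadings
    up = [g for g, l in zip(kept, loadings) if l >= 0]
    down = [g for g, l in zip(kept, loadings) if l < 0]
    if not up or not down:
        # one-sided structure: split at the median loading instead
        med = np.median(loadings)
        up = [g for g, l in zip(kept, loadings) if l >= med]
        down = [g for g, l in zip(kept, loadings) if l < med]
    center = {g: float(np.median(df.loc[g])) for g in kept}
    scale = {g: float(np.std(df.loc[g], ddof=1)) for g in kept}
    return GeneSignature(up_genes=up, down_genes=down, per_gene_center=center, per_gene_scale=scale)


def score_samples(matrix: ExpressionMatrix, signature: GeneSignature) -> dict[str, float]:
    """Per-sample signature activity score.

    ``score = (mean(up) - mean(down)) / SD(all signature genes)`` computed
    within each sample.  Signature genes missing from the matrix are dropped
    with a warning; a within-sample SD of 0 yields NaN (flagged undefined).
    """
    df = matrix.to_frame()
    up = [g for g in signature.up_genes if g in df.index]
    down = [g for g in signature.down_genes if g in df.index]
    missing = (set(signature.up_genes) | set(signature.down_genes)) - set(df.index)
    if missing:
        logger.warning("%d signature genes missing from matrix", len(missing))
    if not up or not down:
        raise ValueError("no signature genes present in the matrix")
    all_genes = sorted(up + down)  # fixed order: the score is exactly
    scores: dict[str, float] = {}  # antisymmetric under swapping up/down
    for sample in matrix.sample_ids:
        col = df[sample]
        sd = float(np.std(col.loc[all_genes], ddof=1))
        if sd == 0.0:
            logger.warning("sample %s has zero within-sample SD; score undefined", sample)
            scores[sample] = float("nan")
            continue
        scores[sample] = float((col.loc[up].mean() - col.loc[down].mean()) / sd)
    return scores


# ---------------------------------------------------------------------------
# information coefficient
# ---------------------------------------------------------------------------


def _class_kdes(feature: np.ndarray, profile: np.ndarray):
    kdes, weights = [], []
    for cls in (0, 1):
        vals = profile[feature == cls]
        if vals.size == 0:
            raise ValueError("both feature classes must be non-empty")
        spread = np.std(vals)
        if spread == 0 or vals.size < 2:
            # degenerate class: a Gaussian bump at the class value, with a
            # bandwidth borrowed from the pooled spread
            pooled = np.std(profile)
            bw = (pooled if pooled > 0 else 1.0) * 0.1
            loc = float(np.mean(vals))
            kdes.append(lambda g, loc=loc, bw=bw: norm.pdf(g, loc=loc, scale=bw))
        else:
            kdes.append(gaussian_kde(vals))
        weights.append(vals.size / profile.size)
    return kdes, np.array(weights)


def differential_information(feature, profile, grid_size: int = 2048) -> float:
    """Differential information (nats) carried by a binary feature about a profile.

    The profile's class-conditional densities ``p_0`` and ``p_1`` are
    estimated by Gaussian KDE (Scott plug-in bandwidth) and compared with the
    symmetrized Kullback-Leibler divergence
    ``I = (KL(p_0 || p_1) + KL(p_1 || p_0)) / 2``, integrated by the
    trapezoid rule on a padded grid.  Unlike the label-profile mutual
    information (which is capped at ln 2 for a binary label), this divergence
    is unbounded, so the rescaled coefficient spans the full [0, 1) range:
    0 when the classes share a distribution, approaching 1 for perfectly
    separated classes.  Invariant under affine transforms of the profile.
    """
    feature = np.asarray(feature, dtype=int)
    profile = np.asarray(profile, dtype=float)
    if feature.size != profile.size or feature.size < 5:
        raise ValueError("need >= 5 paired samples")
    if set(np.unique(feature)) - {0, 1}:
        raise ValueError("feature must be binary 0/1")
    kdes, _ = _class_kdes(feature, profile)
    lo, hi = profile.min(), profile.max()
    pad = 3.0 * max(np.std(profile), 1e-6)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = np.vstack([k(grid) for k in kdes])
    eps = 1e-300
    log_ratio = np.log(dens[0] + eps) - np.log(dens[1] + eps)
    jeffreys = 0.5 * np.trapezoid((dens[0] - dens[1]) * log_ratio, grid)
    return float(max(jeffreys, 0.0))


def information_coefficient(feature, profile) -> float:
    """IC = sqrt(1 - exp(-2 I)): differential information rescaled to [0, 1)."""
    i_val = differential_information(feature, profile)
    return float(np.sqrt(1.0 - np.exp(-2.0 * i_val)))


def permutation_pvalue(
    feature, profile, n_perm: int = 999, seed: int | None = None
) -> AssociationResult:
    """Empirical permutation test of the IC with the add-one estimator.

    Labels are permuted, the profile stays fixed;
    ``p = (1 + #{permuted >= observed}) / (1 + n_perm)`` so p is never 0.
    Permutations are compared on the divergence scale (monotone in the IC),
    which does not saturate in floating point the way the IC does near 1.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    feature = np.asarray(feature, dtype=int)
    profile = np.asarray(profile, dtype=float)
    rng = np.random.default_rng(seed)
    observed_i = differential_information(feature, profile)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(feature)
        if differential_information(perm, profile) >= observed_i:
            hits += 1
    return AssociationResult(
        ic=float(np.sqrt(1.0 - np.exp(-2.0 * observed_i))),
        p_value=(1 + hits) / (1 + n_perm),
        n_permutations=n_perm,
    )
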