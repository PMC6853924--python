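"""Synthetic bulk tumors, cohorts, clone trees and expression matrices.

Every generator is a pure function of its seed and emits exactly the objects
and file formats the analysis consumes, so the whole pipeline runs with no
external data.  The tumor generator plants known truth (per-mutation CCF,
multiplicity, local copy number; tumor-level fitness and regime) and then
pushes it through the same observation model the analysis assumes:

    expected VAF = purity * ccf * m / (purity * cn + 2 * (1 - purity))
    depth ~ Poisson(mean_depth),  alt_count ~ Binomial(depth, expected VAF)

Regimes
-------
HARD / SOFT
    The driver sweeps to a clonal CCF with fitness ``s`` (2.0 / 1.1 by
    default); hitch-hiker CCFs follow the analytic sweep spectrum at the
    configured (s, mu).
NEUTRAL
    No selected driver; subclonal CCFs are drawn from a 1/f-shaped spectrum
    (log-uniform) truncated at a detection floor of 0.05, giving the
    low-frequency tail that swept tumors lack.
SUBCLONAL_DRIVER
    The driver CCF is drawn uniformly in (0.1, 0.6).

Each tumor also carries clonal truncal mutations (CCF 1) so swept and
neutral tumors have comparable mutation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CloneTree,
    CloneTreeNode,
    CopyNumberSegment,
    MutationRecord,
    ROOT_PARENT,
    TumorSample,
)
from .sweeps import SweepParams, simulate_sweep_spectrum

DETECTION_FLOOR = 0.05
DRIVER_CHROM = "7"
DRIVER_POS = 140_453_136  # BRAF V600E hotspot coordinate (hg19), for flavor
BACKGROUND_CHROM = "1"
BACKGROUND_START = 1_000_000
BACKGROUND_SPACING = 10_000


class TumorRegime(str, Enum):
    HARD = "HARD"
    SOFT = "SOFT"
    NEUTRAL = "NEUTRAL"
    SUBCLONAL_DRIVER = "SUBCLONAL_DRIVER"


_DEFAULT_S = {
    TumorRegime.HARD: 2.0,
    TumorRegime.SOFT: 1.1,
    TumorRegime.NEUTRAL: 1.0,
    TumorRegime.SUBCLONAL_DRIVER: 1.0,
}


@dataclass
class SimTumorConfig:
    """Study conditions for one synthetic tumor."""

    regime: TumorRegime = TumorRegime.HARD
    s: float | None = None  # default depends on regime
    mu: float = 0.001
    N: float = 1e6
    purity: float = 0.8
    mean_depth: float = 200.0
    n_background_mutations: int = 100
    n_clonal_mutations: int = 30
    driver_multiplicity: int = 1
    local_cn_at_driver: int = 2
    driver_ccf: float = 0.98  # sweep stop / clonal CCF for HARD and SOFT
    seed: int = 0
    overdispersion: float | None = None  # beta-binomial rho, if set

    def resolved_s(self) -> float:
        return self.s if self.s is not None else _DEFAULT_S[TumorRegime(self.regime)]


@dataclass
class MutationTruth:
    chrom: str
    pos: int
    ccf: float
    multiplicity: float
    local_cn: float
    is_driver: bool


@dataclass
class SimTruth:
    sample_id: str
    regime: TumorRegime
    s: float
    purity: float
    mutations: list[MutationTruth] = field(default_factory=list)


def expected_vaf(purity: float, ccf: float, m: float, cn: float) -> float:
    """Expected allele fraction of a variant with the given cell and copy state."""
    v = purity * ccf * m / (purity * cn + 2.0 * (1.0 - purity))
    if v > 1.0 + 1e-12:
        raise ValueError(
            f"inconsistent configuration: expected VAF {v:.3f} > 1 "
            f"(purity={purity}, ccf={ccf}, m={m}, cn={cn})"
        )
    return min(v, 1.0)


def _draw_alt(rng: np.random.Generator, depth: int, vaf: float, rho: float | None) -> int:
    if depth == 0:
        return 0
    if rho is None or vaf in (0.0, 1.0):
        return int(rng.binomial(depth, vaf))
    # beta-binomial overdispersion with intraclass correlation rho
    conc = (1.0 - rho) / rho
    p = rng.beta(vaf * conc, (1.0 - vaf) * conc)
    return int(rng.binomial(depth, p))


def _neutral_ccfs(rng: np.random.Generator, n: int, floor: float = DETECTION_FLOOR) -> np.ndarray:
    """1/f-shaped subclonal CCFs: log-uniform on [floor, 1)."""
    u = rng.random(n)
    return floor * (1.0 / floor) ** u * (1.0 - 1e-9)


def simulate_tumor(config: SimTumorConfig) -> tuple[TumorSample, SimTruth]:
    """One synthetic tumor with planted truth, observed through read counts."""
    cfg = config
    regime = TumorRegime(cfg.regime)
    rng = np.random.default_rng(cfg.seed)
    s = cfg.resolved_s()
    sample_id = f"SIM_{regime.value}_{cfg.seed}"

    # --- plant true CCFs ---------------------------------------------------
    if regime in (TumorRegime.HARD, TumorRegime.SOFT):
        driver_ccf = cfg.driver_ccf
        spectrum = simulate_sweep_spectrum(
            SweepParams(s=s, N=cfg.N, mu=cfg.mu),
            n_passengers=cfg.n_background_mutations,
            stop_at_driver_ccf=driver_ccf,
        )
        background_ccfs = np.asarray(spectrum.passenger_freqs)
    elif regime is TumorRegime.NEUTRAL:
        driver_ccf = float(_neutral_ccfs(rng, 1)[0])
        background_ccfs = _neutral_ccfs(rng, cfg.n_background_mutations)
    elif regime is TumorRegime.SUBCLONAL_DRIVER:
        driver_ccf = float(rng.uniform(0.1, 0.6))
        background_ccfs = _neutral_ccfs(rng, cfg.n_background_mutations)
    else:  # pragma: no cover
        raise ValueError(f"unknown regime {regime}")

    truths: list[MutationTruth] = [
        MutationTruth(
            chrom=DRIVER_CHROM,
            pos=DRIVER_POS,
            ccf=driver_ccf,
            multiplicity=float(cfg.driver_multiplicity),
            local_cn=float(cfg.local_cn_at_driver),
            is_driver=True,
        )
    ]
    pos = BACKGROUND_START
    for ccf in background_ccfs:
        truths.append(
            MutationTruth(
                chrom=BACKGROUND_CHROM, pos=pos, ccf=float(ccf),
                multiplicity=1.0, local_cn=2.0, is_driver=False,
            )
        )
        pos += BACKGROUND_SPACING
    for _ in range(cfg.n_clonal_mutations):
        truths.append(
            MutationTruth(
                chrom=BACKGROUND_CHROM, pos=pos, ccf=1.0,
                multiplicity=1.0, local_cn=2.0, is_driver=False,
            )
        )
        pos += BACKGROUND_SPACING

    # --- observe through reads ---------------------------------------------
    mutations: list[MutationRecord] = []
    for t in truths:
        v = expected_vaf(cfg.purity, t.ccf, t.multiplicity, t.local_cn)
        depth = int(rng.poisson(cfg.mean_depth))
        alt = _draw_alt(rng, depth, v, cfg.overdispersion)
        if depth == 0:
            continue
        mutations.append(
            MutationRecord(
                sample_id=sample_id,
                chrom=t.chrom,
                pos=t.pos,
                ref="A",
                alt="T",
                alt_count=alt,
                ref_count=depth - alt,
                gene="BRAF" if t.is_driver else None,
            )
        )

    segments = [
        CopyNumberSegment(
            sample_id=sample_id,
            chrom=DRIVER_CHROM,
            start=DRIVER_POS - 500_000,
            end=DRIVER_POS + 500_000,
            seg_mean=math.log2(cfg.local_cn_at_driver / 2.0),
        ),
        CopyNumberSegment(
            sample_id=sample_id,
            chrom=BACKGROUND_CHROM,
            start=BACKGROUND_START - 1,
            end=pos + BACKGROUND_SPACING,
            seg_mean=0.0,
        ),
    ]
    sample = TumorSample(
        sample_id=sample_id, purity=cfg.purity, mutations=mutations, segments=segments
    )
    truth = SimTruth(
        sample_id=sample_id, regime=regime, s=s, purity=cfg.purity, mutations=truths
    )
    return sample, truth


def simulate_cohort(
    n_per_regime: dict[TumorRegime | str, int],
    base_config: SimTumorConfig | None = None,
    seed: int = 0,
) -> list[tuple[TumorSample, SimTruth]]:
    """Independent tumors with per-tumor seeds split from a master seed.

    ``n_per_regime`` maps regime -> count.  Child seeds come from
    ``numpy.random.SeedSequence.spawn`` so cohorts are reproducible
    byte-for-byte and stable under partial regeneration.
    """
    base = base_config or SimTumorConfig()
    ss = np.random.SeedSequence(seed)
    total = sum(n_per_regime.values())
    children = ss.spawn(total)
    out: list[tuple[TumorSample, SimTruth]] = []
    k = 0
    for regime, n in n_per_regime.items():
        if n < 1:
            raise ValueError("n_per_regime counts must be >= 1")
        for _ in range(n):
            child_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
            cfg = replace(base, regime=TumorRegime(regime), seed=child_seed, s=base.s)
            out.append(simulate_tumor(cfg))
            k += 1
    return out


class TreeTopology(str, Enum):
    CHAIN = "CHAIN"
    STAR = "STAR"
    RANDOM = "RANDOM"


def simulate_clone_trees(
    topology: TreeTopology | str,
    n_nodes: int,
    mutation_counts: Sequence[int] | None = None,
    seed: int = 0,
    n_trees: int = 1,
) -> list[CloneTree]:
    """Clone trees with prevalences consistent with parent >= child.

    CHAIN stacks each node under the previous one; STAR hangs all non-root
    nodes off the root; RANDOM draws each node's parent uniformly among the
    earlier nodes.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    topology = TreeTopology(topology)
    rng = np.random.default_rng(seed)
    trees: list[CloneTree] = []
    for _ in range(n_trees):
        if mutation_counts is None:
            counts = rng.integers(1, 10, size=n_nodes).tolist()
        else:
            if len(mutation_counts) != n_nodes:
                raise ValueError("mutation_counts length must equal n_nodes")
            counts = list(mutation_counts)
        parents = [ROOT_PARENT]
        for i in range(1, n_nodes):
            if topology is TreeTopology.CHAIN:
                parents.append(i - 1)
            elif topology is TreeTopology.STAR:
                parents.append(0)
            else:
                parents.append(int(rng.integers(0, i)))
        # assign prevalences by depth so every child is below its parent
        prevalence = [1.0] * n_nodes
        for i in range(1, n_nodes):
            prevalence[i] = prevalence[parents[i]] * float(rng.uniform(0.3, 0.95))
        nodes = [
            CloneTreeNode(
                node_id=i, parent_id=parents[i], n_mutations=int(counts[i]),
                prevalence=prevalence[i],
            )
            for i in range(n_nodes)
        ]
        trees.append(CloneTree(nodes=nodes, log_likelihood=float(rng.normal(-10.0, 1.0))))
    return trees


def simulate_expression(
    n_up: int,
    n_down: int,
    n_noise: int,
    n_samples_per_class: int,
    effect_size: float = 2.0,
    seed: int = 0,
):
    """Expression matrix with planted up/down signature structure.

    Log-scale expression is standard normal noise; in the "high" class, up
    genes are shifted by ``+effect_size`` SD and down genes by
    ``-effect_size`` SD.  Noise genes are exchangeable across classes.
    Returns ``(matrix, truth)`` where truth records the planted gene sets
    and class labels.
    """
    if min(n_up, n_down, n_noise, n_samples_per_class) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes = (
        [f"UP{i:03d}" for i in range(n_up)]
        + [f"DN{i:03d}" for i in range(n_down)]
        + [f"NS{i:03d}" for i in range(n_noise)]
    )
    samples = [f"HI{i:03d}" for i in range(n_samples_per_class)] + [
        f"LO{i:03d}" for i in range(n_samples_per_class)
    ]
    vals = rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    vals[:n_up, :n_samples_per_class] += effect_size
    vals[n_up : n_up + n_down, :n_samples_per_class] -= effect_size
    from .data_io import ExpressionMatrix

    matrix = ExpressionMatrix(genes, samples, vals)
    truth = {
        "up_genes": genes[:n_up],
        "down_genes": genes[n_up : n_up + n_down],
        "noise_genes": genes[n_up + n_down :],
        "high_samples": samples[:n_samples_per_class],
        "low_samples": samples[n_samples_per_class:],
        "effect_size": effect_size,
    }
    return matrix, truth


def write_truth_table(truths: Sequence[SimTruth], path: str | Path) -> None:
    rows = []
    for t in truths:
        for m in t.mutations:
            rows.append(
                {
                    "sample": t.sample_id,
                    "regime": t.regime.value,
                    "s": t.s,
                    "purity": t.purity,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "true_ccf": m.ccf,
                    "true_multiplicity": m.multiplicity,
                    "true_local_cn": m.local_cn,
                    "is_driver": m.is_driver,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
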