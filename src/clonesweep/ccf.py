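"""Cancer cell fraction, multiplicity and mutation-vs-gain ordering.

The central quantity is the cancer cell fraction (CCF): the proportion of
cancer cells carrying a single-nucleotide variant, obtained by rescaling the
variant-allele fraction (VAF) for sample purity and the local copy state,

    CCF = VAF * (2 + (ploidy_CNV - 2) * CCF_CNV) / purity

where ploidy_CNV is the total copy number at the locus and CCF_CNV the
fraction of cancer cells bearing that copy-number variant.  This assumes the
variant sits on a single copy; when amplification placed extra copies of the
variant allele in each cell, the raw value overshoots 1 and a multiplicity
correction is applied (``apply_ccf_heuristics``).

The purity-only corrected allele fraction (cVAF = VAF / purity) carries
timing information: under a copy gain it exceeds 0.5 only when the point
mutation preceded the gain and the gained copies carry the variant allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import MutationRecord, TumorSample

CLONAL_THRESHOLD = 0.95
"""Default CCF above which (strictly) a mutation is called clonal."""


class GainOrder(str, Enum):
    """Phylogenetic ordering call between a point mutation and a copy gain."""

    MUTATION_BEFORE_GAIN_VARIANT_ALLELE = "MUTATION_BEFORE_GAIN_VARIANT_ALLELE"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class CCFRecord:
    """Per-mutation clonality summary: CCF, multiplicity, cVAF and gain order."""

    mutation: MutationRecord
    local_cn: float
    multiplicity: float | None
    ccf: float | None
    clonal: bool | None
    cvaf: float
    order_call: GainOrder
    inconsistent: bool = False


def abs_cn_from_segmean(seg_mean: float, round_to_int: bool = True) -> float:
    """Total copy number from a log2 copy-ratio segment mean (diploid baseline).

    ``abs_cn = 2 * 2**seg_mean``; rounded to the nearest integer by default so
    that multiplicity enumeration has an integer ceiling.
    """
    if not math.isfinite(seg_mean):
        raise ValueError(f"non-finite seg_mean {seg_mean}")
    cn = 2.0 * 2.0 ** seg_mean
    return float(round(cn)) if round_to_int else cn


def compute_ccf(vaf: float, purity: float, ploidy_cnv: float, ccf_cnv: float = 1.0) -> float:
    """Raw (unclipped) cancer cell fraction of an SNV.

    Returns ``vaf * (2 + (ploidy_cnv - 2) * ccf_cnv) / purity``; can exceed 1
    when the variant is present on multiple copies per cell.
    """
    if purity <= 0:
        raise ValueError(f"purity must be positive, got {purity}")
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if not (0.0 <= ccf_cnv <= 1.0):
        raise ValueError(f"ccf_cnv {ccf_cnv} outside [0, 1]")
    if ploidy_cnv < 0:
        raise ValueError(f"ploidy_cnv {ploidy_cnv} negative")
    return vaf * (2.0 + (ploidy_cnv - 2.0) * ccf_cnv) / purity


def multiplicity(vaf: float, purity: float, local_cn: float) -> float:
    """Average variant copies per cancer cell (continuous, not rounded).

    ``m = vaf * (purity * local_cn + 2 * (1 - purity)) / purity`` — the total
    variant copies implied by the allele fraction, expressed per cancer cell.
    """
    if purity <= 0:
        raise ValueError(f"purity must be positive, got {purity}")
    return vaf * (purity * local_cn + 2.0 * (1.0 - purity)) / purity


def apply_ccf_heuristics(
    raw_ccf: float,
    vaf: float,
    purity: float,
    local_cn: float,
) -> tuple[float | None, int | None]:
    """Multiplicity-aware CCF correction.

    The allele fraction implies a continuous multiplicity
    ``m_cont = vaf * (purity*local_cn + 2(1-purity)) / purity`` (total variant
    copies per cancer cell).  The integer multiplicity is the nearest integer
    to ``m_cont``, clamped to {1, ..., max(1, round(local_cn))}, and the
    corrected CCF is ``m_cont / m`` clipped to [0, 1].  With ``m = 1`` this
    reduces to the raw formula; rounding (rather than picking the smallest m
    whose CCF is feasible) keeps a clonal heterozygous locus whose noisy raw
    CCF lands marginally above 1 from being halved.

    Returns ``(ccf, m)``; ``(None, None)`` when ``local_cn == 0`` with
    ``vaf > 0`` (an inconsistent locus).
    """
    if local_cn == 0:
        if vaf > 0:
            return None, None
        return 0.0, 0
    max_m = max(1, int(round(local_cn)))
    m_cont = multiplicity(vaf, purity, local_cn)
    m = min(max(1, int(round(m_cont))), max_m)
    ccf = float(np.clip(m_cont / m, 0.0, 1.0))
    return ccf, m


def classify_clonality(ccf: float | None, threshold: float = CLONAL_THRESHOLD) -> bool | None:
    """Clonal iff CCF strictly exceeds the threshold; None propagates missing."""
    if ccf is None:
        return None
    return ccf > threshold


def corrected_vaf(vaf: float, purity: float) -> float:
    """VAF corrected for purity only (cVAF), clipped to [0, 1]."""
    if purity <= 0:
        raise ValueError(f"purity must be positive, got {purity}")
    return min(vaf / purity, 1.0)


def infer_gain_order(cvaf: float, local_cn: float) -> GainOrder:
    """Order a point mutation against a copy gain at the same locus.

    cVAF strictly above 0.5 at a gained locus (total CN > 2) is only possible
    when the mutation preceded the gain and the gain amplified the variant
    allele; anything else is indeterminate.
    """
    if cvaf > 0.5 and local_cn > 2:
        return GainOrder.MUTATION_BEFORE_GAIN_VARIANT_ALLELE
    return GainOrder.INDETERMINATE


def annotate_sample(
    sample: TumorSample, clonal_threshold: float = CLONAL_THRESHOLD
) -> list[CCFRecord]:
    """Compute a :class:`CCFRecord` for every mutation in a tumor sample.

    Mutations must already carry ``local_cn`` (see
    :func:`clonesweep.data_io.assemble_tumor_sample`).
    """
    records: list[CCFRecord] = []
    for m in sample.mutations:
        cn = m.local_cn if m.local_cn is not None else 2.0
        assert m.vaf is not None
        raw = compute_ccf(m.vaf, sample.purity, cn, m.ccf_cnv)
        ccf, mult = apply_ccf_heuristics(raw, m.vaf, sample.purity, cn)
        cvaf = corrected_vaf(m.vaf, sample.purity)
        records.append(
            CCFRecord(
                mutation=m,
                local_cn=cn,
                multiplicity=float(mult) if mult is not None else None,
                ccf=ccf,
                clonal=classify_clonality(ccf, clonal_threshold),
                cvaf=cvaf,
                order_call=infer_gain_order(cvaf, cn),
                inconsistent=ccf is None,
            )
        )
    return records


def ccf_table(records: Sequence[CCFRecord], purity: float) -> pd.DataFrame:
    """Flatten CCF records into the per-sample output table."""
    rows = [
        {
            "sample": r.mutation.sample_id,
            "chrom": r.mutation.chrom,
            "pos": r.mutation.pos,
            "ref": r.mutation.ref,
            "alt": r.mutation.alt,
            "vaf": r.mutation.vaf,
            "purity": purity,
            "local_cn": r.local_cn,
            "multiplicity": r.multiplicity,
            "ccf": r.ccf,
            "clonal": r.clonal,
            "cvaf": r.cvaf,
            "order_call": r.order_call.value,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_ccf_table(records: Sequence[CCFRecord], purity: float, path: str | Path) -> None:
    ccf_table(records, purity).to_csv(path, sep="\t", index=False)
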