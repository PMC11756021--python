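"""Mutant-Allele Tumor Heterogeneity (MATH) from somatic variant records.

MATH summarizes genetic intratumoral heterogeneity as the spread of the
per-variant mutant-allele fraction (VAF) distribution within a sample::

    vaf  = t_alt_count / (t_alt_count + t_ref_count)
    MATH = 100 * MAD(vafs) / median(vafs)

where MAD is the median absolute deviation scaled by the 1.4826
normal-consistency constant — the maftools/Mroz convention.  Both the
constant and the x100 scaling are configurable (and recorded in output),
since published definitions frequently omit them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MehegError, ValidationError, VariantRecord

logger = logging.getLogger("meheg")

MAD_CONSTANT = 1.4826
MATH_SCALE = 100.0


class MathScoreError(MehegError):
    """Raised when MATH is undefined for a VAF set."""


@dataclass
class MathResult:
    sample: str
    n_variants: int
    median_vaf: float
    mad_vaf: float
    math: float


def vaf(record: VariantRecord) -> float:
    """Mutant-allele fraction of one variant; requires nonzero depth."""
    if record.depth == 0:
        raise MathScoreError(
            f"zero-depth variant at {record.chromosome}:{record.position}"
        )
    return record.t_alt_count / record.depth


def math_from_vafs(
    vafs: Sequence[float],
    mad_constant: float = MAD_CONSTANT,
    scale: float = MATH_SCALE,
    sample: str = "",
) -> MathResult:
    """MATH score of a VAF vector (>= 2 values, positive median)."""
    v = np.asarray(list(vafs), dtype=float)
    if v.size < 2:
        raise MathScoreError(f"need >= 2 VAFs, got {v.size}")
    med = float(np.median(v))
    if med <= 0:
        raise MathScoreError("undefined MATH: median VAF is zero")
    mad = mad_constant * float(np.median(np.abs(v - med)))
    return MathResult(
        sample=sample,
        n_variants=int(v.size),
        median_vaf=med,
        mad_vaf=mad,
        math=scale * mad / med,
    )


def math_per_sample(
    maf: Sequence[VariantRecord],
    min_depth: int = 0,
    mad_constant: float = MAD_CONSTANT,
    scale: float = MATH_SCALE,
) -> pd.DataFrame:
    """Group variants by sample and score each one.

    Depth-filtered (``depth >= min_depth`` and usable); samples with fewer
    than two usable variants are flagged instead of scored.
    """
    if not maf:
        raise ValidationError("empty MAF")
    by_sample: dict[str, list[float]] = {}
    order: list[str] = []
    for rec in maf:
        if rec.sample not in by_sample:
            by_sample[rec.sample] = []
            order.append(rec.sample)
        if rec.usable and rec.depth >= min_depth:
            by_sample[rec.sample].append(vaf(rec))
    rows = []
    for sample in order:
        vals = by_sample[sample]
        try:
            res = math_from_vafs(vals, mad_constant, scale, sample=sample)
            rows.append(
                {
                    "sample": sample,
                    "n_variants": res.n_variants,
                    "median_vaf": res.median_vaf,
                    "mad_vaf": res.mad_vaf,
                    "math": res.math,
                    "status": "ok",
                }
            )
        except MathScoreError as exc:
            rows.append(
                {
                    "sample": sample,
                    "n_variants": len(vals),
                    "median_vaf": np.nan,
                    "mad_vaf": np.nan,
                    "math": np.nan,
                    "status": f"failed: {exc}",
                }
            )
    return pd.DataFrame(rows).set_index("sample")
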