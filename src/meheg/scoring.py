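"""Panel training and the intratumoral epigenetic-heterogeneity (MeHEG) score.

The score for a sample with panel betas ``beta_i`` and probes-x-regions
weights ``w_{i,j}`` is the coefficient of variation of the region-specific
weighted sums::

    S_j   = sum_i beta_i * w_{i,j}
    S_bar = (1/R) * sum_j S_j
    score = sqrt((1/R) * sum_j (S_j - S_bar)^2) / S_bar

with the *population* variance (divide by R) inside the root.  The score is
zero iff all regional scores are equal, invariant to positive rescaling of
betas or weights, and undefined (an error) when any regional score is
negative or the mean is non-positive — a CV over sign-mixed scores is
meaningless and is surfaced rather than masked.

Two weight-derivation strategies are provided:

``svr-primal``
    For each region, fit a linear nu-SVR of the region-membership indicator
    on the probe betas across training samples and read the primal weight
    vector off the support-vector expansion.  Discriminative, but the signed
    weights frequently produce negative regional sums, which the score
    rejects; use for probe ranking rather than scoring.
``signature``
    Region-mean betas of the panel probes (the signature restricted to the
    panel).  Nonnegative by construction, hence always score-compatible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .io import (
    BetaMatrix,
    MehegError,
    SampleAnnotation,
    ValidationError,
    WeightMatrix,
)

logger = logging.getLogger("meheg")

DEFAULT_PANEL_SIZE = 7
DEFAULT_UPPER_Q = 0.75
DEFAULT_LOWER_Q = 0.25
WEIGHT_NU = 0.5


class ScoringError(MehegError):
    """Raised when the heterogeneity score is undefined for a sample."""


@dataclass
class MehegResult:
    """Per-sample score decomposition."""

    sample: str
    regional_scores: pd.Series  # S_j per region
    mean_score: float  # S_bar
    score: float  # the CV


# ---------------------------------------------------------------------------
# Weight derivation and panel selection
# ---------------------------------------------------------------------------


def derive_weights(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    probes: Sequence[str],
    strategy: str = "svr-primal",
    nu: float = WEIGHT_NU,
) -> WeightMatrix:
    """Derive per-probe-per-region weights on training data.

    See the module docstring for the two strategies.  Requires >= 2 samples
    per region.
    """
    probes = list(probes)
    missing = [p for p in probes if p not in set(beta.probes)]
    if missing:
        raise ValidationError(f"probe {missing[0]!r} not in beta matrix")
    regions = list(annot.region_set)
    for r in regions:
        if len(annot.samples_of(r)) < 2:
            raise ValidationError(f"region {r!r} needs >= 2 samples")

    if strategy == "signature":
        cols = {
            r: beta.values.loc[probes, annot.samples_of(r)].mean(axis=1)
            for r in regions
        }
        w = pd.DataFrame(cols, index=probes)
        if w.isna().any().any():
            raise ValidationError("missing betas among panel probes")
        return WeightMatrix(w, strategy="signature")
    if strategy != "svr-primal":
        raise ValidationError(f"unknown weight strategy {strategy!r}")

    samples = annot.samples
    x = beta.values.loc[probes, samples].to_numpy(dtype=float).T
    if np.isnan(x).any():
        raise ValidationError("missing betas among training samples")
    cols = {}
    for r in regions:
        y = np.array(
            [1.0 if annot.table.loc[s, "region"] == r else 0.0 for s in samples]
        )
        model = NuSVR(nu=nu, C=1.0, kernel="linear", tol=1e-4)
        model.fit(x, y)
        cols[r] = model.coef_[0]
    w = pd.DataFrame(cols, index=probes)
    return WeightMatrix(w, strategy="svr-primal")


def select_model_probes(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    dmps: Sequence[str],
    panel_size: int = DEFAULT_PANEL_SIZE,
    strategy: str = "svr-primal",
    nu: float = WEIGHT_NU,
) -> list[str]:
    """Shrink a DMP set to a scoring panel by recursive weight elimination.

    Each round fits per-region weight models on the current probe set,
    scores every probe by the maximum over regions of |w_{i,j}| after
    per-column L2 normalization, and drops the lowest-scoring half (at least
    one probe, never past *panel_size*).  Deterministic given its inputs;
    score ties are broken lexicographically by probe ID.
    """
    current = list(dmps)
    if panel_size >= len(current):
        raise ValidationError(
            f"panel_size {panel_size} must be smaller than the DMP set "
            f"({len(current)} probes)"
        )
    if panel_size < 1:
        raise ValidationError("panel_size must be >= 1")
    while len(current) > panel_size:
        w = derive_weights(beta, annot, current, strategy=strategy, nu=nu)
        arr = np.abs(w.values.to_numpy(dtype=float))
        norms = np.linalg.norm(arr, axis=0)
        norms[norms == 0] = 1.0
        score = (arr / norms).max(axis=1)
        n_drop = min(len(current) - panel_size, max(1, len(current) // 2))
        order = sorted(range(len(current)), key=lambda i: (score[i], current[i]))
        dropped = {current[i] for i in order[:n_drop]}
        current = [p for p in current if p not in dropped]
    return current


# ---------------------------------------------------------------------------
# The score
# ---------------------------------------------------------------------------


def meheg_score(
    sample_betas: pd.Series | Mapping[str, float],
    weights: WeightMatrix,
    sample: str = "",
) -> MehegResult:
    """Compute the CV-of-regional-scores heterogeneity score for one sample."""
    betas = pd.Series(sample_betas, dtype=float)
    missing = [p for p in weights.probes if p not in betas.index]
    if missing:
        raise ScoringError(f"missing panel probe {missing[0]!r}")
    b = betas[weights.probes]
    if b.isna().any():
        raise ScoringError(
            f"missing beta for panel probe {b.index[b.isna()][0]!r}"
        )
    s = b.to_numpy(dtype=float) @ weights.values.to_numpy(dtype=float)
    s_series = pd.Series(s, index=weights.regions)
    if (s < 0).any():
        raise ScoringError(
            f"negative regional score for region "
            f"{s_series.index[s_series < 0][0]!r}: CV undefined for "
            "sign-mixed scores"
        )
    s_bar = float(s.mean())
    if s_bar <= 0:
        raise ScoringError("non-positive mean regional score: CV undefined")
    score = float(np.sqrt(np.mean((s - s_bar) ** 2)) / s_bar)
    return MehegResult(sample=sample, regional_scores=s_series,
                       mean_score=s_bar, score=score)


def meheg_cohort(beta: BetaMatrix, weights: WeightMatrix) -> pd.DataFrame:
    """Score every sample of a cohort; per-sample failures are flagged.

    Returns a DataFrame indexed by sample with one ``S_<region>`` column per
    region, ``S_bar``, ``meheg`` and ``status``.
    """
    overlap = [p for p in weights.probes if p in set(beta.probes)]
    if not overlap:
        raise ValidationError("no overlap between panel and beta probes")
    rows = []
    for sample in beta.samples:
        row: dict[str, object] = {"sample": sample}
        try:
            res = meheg_score(beta.values[sample], weights, sample=sample)
            row.update(
                {f"S_{r}": res.regional_scores[r] for r in weights.regions}
            )
            row.update({"S_bar": res.mean_score, "meheg": res.score,
                        "status": "ok"})
        except MehegError as exc:
            row.update({f"S_{r}": np.nan for r in weights.regions})
            row.update({"S_bar": np.nan, "meheg": np.nan,
                        "status": f"failed: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def stratify(
    scores: pd.Series,
    upper_q: float = DEFAULT_UPPER_Q,
) -> pd.Series:
    """Label samples H/L by an upper-quantile cut-off on their scores.

    The threshold is the linear-interpolation quantile; the comparison is a
    strict ``>``, so ties at the threshold fall to L.
    """
    vals = scores.astype(float)
    finite = vals[np.isfinite(vals)]
    if len(finite) < 2:
        raise ValidationError("need >= 2 finite scores to stratify")
    if not 0 <= upper_q <= 1:
        raise ValidationError("upper_q must lie in [0, 1]")
    threshold = float(np.quantile(finite, upper_q))
    if finite.nunique() == 1:
        logger.warning("stratify: all scores identical; H group is empty")
    labels = pd.Series(
        np.where(vals > threshold, "H", "L"), index=scores.index
    )
    labels[~np.isfinite(vals)] = "NA"
    return labels


def classify_dual(
    meheg_scores: pd.Series,
    metil_scores: pd.Series,
    upper_q: float = DEFAULT_UPPER_Q,
    lower_q: float = DEFAULT_LOWER_Q,
) -> pd.Series:
    """Four-type grouping by the heterogeneity score and an external
    immune-infiltration (MeTIL) score.

    The heterogeneity score is cut at its upper quantile (H above, strict
    ``>``); the MeTIL score at its lower quantile (L below, strict ``<``,
    lower MeTIL = denser CD8+ infiltration).  Types: 1 = H/MeTIL-L,
    2 = H/MeTIL-H, 3 = L/MeTIL-L, 4 = L/MeTIL-H.
    """
    common = meheg_scores.index.intersection(metil_scores.index)
    if len(common) < 2:
        raise ValidationError("need >= 2 samples scored by both measures")
    heheg = stratify(meheg_scores[common], upper_q)
    metil_vals = metil_scores[common].astype(float)
    t_low = float(np.quantile(metil_vals[np.isfinite(metil_vals)], lower_q))
    metil_low = metil_vals < t_low
    mapping = {
        ("H", True): 1,
        ("H", False): 2,
        ("L", True): 3,
        ("L", False): 4,
    }
    return pd.Series(
        [mapping[(heheg[s], bool(metil_low[s]))] for s in common],
        index=common,
        name="type",
    )
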