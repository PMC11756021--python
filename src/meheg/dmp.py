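"""Differentially methylated position (DMP) ranking across tumor regions.

Probes are scored with a per-probe one-way F test across region groups
(the standard array DMP protocol), computed on the beta scale by default or
on the variance-stabilized M scale (``m = log2(beta / (1 - beta))``).  An
optional patient-blocked two-way decomposition removes between-patient
variation for multiregional designs.  Benjamini-Hochberg q values are
reported, but selection is by top-n rank.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import (
    BetaMatrix,
    SampleAnnotation,
    SignatureMatrix,
    ValidationError,
)

logger = logging.getLogger("meheg")

M_VALUE_EPS = 1e-6


def _to_mvalues(arr: np.ndarray) -> np.ndarray:
    clipped = np.clip(arr, M_VALUE_EPS, 1.0 - M_VALUE_EPS)
    return np.log2(clipped / (1.0 - clipped))


def _oneway_f(arr: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, int, int]:
    """Vectorized one-way ANOVA F over probes (rows of *arr*).

    Returns (F, df_between, df_within).  Probes with zero within-group
    variance but nonzero between-group variance get F = inf.
    """
    n_total = sum(g.size for g in groups)
    n_groups = len(groups)
    grand = arr.mean(axis=1, keepdims=True)
    ss_between = np.zeros(arr.shape[0])
    ss_within = np.zeros(arr.shape[0])
    for idx in groups:
        sub = arr[:, idx]
        gm = sub.mean(axis=1, keepdims=True)
        ss_between += idx.size * (gm[:, 0] - grand[:, 0]) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=1)
    df_b = n_groups - 1
    df_w = n_total - n_groups
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_within > 0, ms_between / ms_within,
                     np.where(ms_between > 0, np.inf, np.nan))
    return f, df_b, df_w


def _blocked_f(
    arr: np.ndarray,
    region_groups: list[np.ndarray],
    patient_groups: list[np.ndarray],
) -> tuple[np.ndarray, int, int]:
    """Two-way additive decomposition (region + patient block), balanced design.

    F for the region effect uses the residual mean square after removing
    both main effects; requires each patient to contribute one sample per
    region (a complete multiregional layout).
    """
    n_total = arr.shape[1]
    grand = arr.mean(axis=1, keepdims=True)
    ss_total = ((arr - grand) ** 2).sum(axis=1)
    ss_region = np.zeros(arr.shape[0])
    for idx in region_groups:
        gm = arr[:, idx].mean(axis=1)
        ss_region += idx.size * (gm - grand[:, 0]) ** 2
    ss_patient = np.zeros(arr.shape[0])
    for idx in patient_groups:
        gm = arr[:, idx].mean(axis=1)
        ss_patient += idx.size * (gm - grand[:, 0]) ** 2
    ss_resid = ss_total - ss_region - ss_patient
    df_region = len(region_groups) - 1
    df_resid = n_total - len(region_groups) - len(patient_groups) + 1
    if df_resid < 1:
        raise ValidationError("not enough samples for a patient-blocked test")
    ms_region = ss_region / df_region
    ms_resid = np.maximum(ss_resid, 0.0) / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_resid > 0, ms_region / ms_resid,
                     np.where(ms_region > 0, np.inf, np.nan))
    return f, df_region, df_resid


def rank_dmps(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    scale: str = "beta",
    blocked: bool = False,
) -> pd.DataFrame:
    """Rank probes by differential methylation across region groups.

    Parameters
    ----------
    beta
        Probe x sample beta matrix; probes with missing values among the
        annotated samples are dropped (logged), as are probes whose values
        are identical across all samples (F undefined).
    annot
        Sample annotation; every region must have >= 2 samples.
    scale
        ``"beta"`` (default) or ``"mvalue"``.
    blocked
        If True, use the patient-blocked two-way decomposition instead of
        the default unpaired one-way test.

    Returns
    -------
    DataFrame indexed by probe with columns ``F``, ``p``, ``q``, one
    ``mean_<region>`` per region, and ``rank`` (1 = most significant; ties
    broken by descending F, then probe ID).
    """
    if scale not in ("beta", "mvalue"):
        raise ValidationError(f"unknown scale {scale!r}")
    samples = [s for s in annot.samples if s in set(beta.samples)]
    if len(samples) < len(annot.samples):
        raise ValidationError("annotation refers to samples absent from the beta matrix")
    regions = list(annot.region_set)
    region_samples = {r: annot.samples_of(r) for r in regions}
    for r, ss in region_samples.items():
        if len(ss) < 2:
            raise ValidationError(f"region {r!r} has {len(ss)} samples; need >= 2")

    complete = beta.drop_incomplete(samples)
    df = complete.values[samples]
    arr = df.to_numpy(dtype=float)

    # exclude probes constant across all samples: F undefined
    nonconst = ~(np.all(arr == arr[:, :1], axis=1))
    n_const = int((~nonconst).sum())
    if n_const:
        logger.info("rank_dmps: excluding %d all-identical probes", n_const)
    arr = arr[nonconst]
    probes = df.index[nonconst]

    pos = {s: k for k, s in enumerate(samples)}
    region_idx = [np.array([pos[s] for s in region_samples[r]]) for r in regions]

    work = _to_mvalues(arr) if scale == "mvalue" else arr
    if blocked:
        patients = sorted(set(annot.table.loc[samples, "patient"]))
        patient_idx = [
            np.array([pos[s] for s in samples
                      if annot.table.loc[s, "patient"] == p])
            for p in patients
        ]
        f, df_b, df_w = _blocked_f(work, region_idx, patient_idx)
    else:
        f, df_b, df_w = _oneway_f(work, region_idx)

    with np.errstate(invalid="ignore"):
        p = stats.f.sf(f, df_b, df_w)
    p = np.where(np.isinf(f), 0.0, p)
    p = np.where(np.isnan(f), 1.0, p)
    f = np.where(np.isnan(f), 0.0, f)
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({"F": f, "p": p, "q": q}, index=probes)
    for r, idx in zip(regions, region_idx):
        out[f"mean_{r}"] = arr[:, idx].mean(axis=1)
    order = sorted(
        range(len(out)), key=lambda i: (p[i], -f[i], str(probes[i]))
    )
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out.sort_values("rank")


def select_top(dmps: pd.DataFrame, n: int) -> list[str]:
    """Return the *n* most significant probes by rank (deterministic)."""
    if n < 0:
        raise ValidationError("n must be nonnegative")
    if n > len(dmps):
        raise ValidationError(
            f"requested {n} probes but only {len(dmps)} are ranked"
        )
    return list(dmps.sort_values("rank").index[:n])


def build_signature(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    probes: Sequence[str],
) -> SignatureMatrix:
    """Region-mean signature matrix B over the given probes.

    Entry (i, j) is the arithmetic mean beta of probe i over the samples of
    region j.  The probe count must exceed the region count so that the
    mixture system stays overdetermined.
    """
    probes = list(probes)
    missing = [p for p in probes if p not in set(beta.probes)]
    if missing:
        raise ValidationError(f"probe {missing[0]!r} not present in beta matrix")
    regions = list(annot.region_set)
    if len(probes) <= len(regions):
        raise ValidationError(
            f"{len(probes)} probes for {len(regions)} regions: the signature "
            "must contain more marker probes than content types"
        )
    cols = {}
    for r in regions:
        ss = annot.samples_of(r)
        if not ss:
            raise ValidationError(f"region {r!r} has no samples")
        cols[r] = beta.values.loc[probes, ss].mean(axis=1)
    sig = pd.DataFrame(cols, index=probes)
    if sig.isna().any().any():
        raise ValidationError("missing betas among signature probes; drop or complete them first")
    return SignatureMatrix(sig)
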