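"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be produced here: a probes-x-regions
reference (signature), multiregional cohorts of bulk beta profiles with true
mixing fractions, dual-channel qPCR CT tables, and MAF variant tables with a
planted clonal structure.  All generators are pure functions of
``(seed, parameters)``; the ground truth is returned as a
:class:`SimTruth` and can be serialized next to the data.

The reference emulates a multiregional tumor design with an ordered
methylation-progression gradient: planted differential probes start from a
low baseline in the first region (the digestive-tract surface) and *gain*
methylation monotonically toward the last region (the invasive front), with
the final inter-region gap larger than the earlier ones (an accelerating
gradient).  Bulk samples from each region are Dirichlet mixtures of the
region profiles, most concentrated for the surface and flattest — most
admixed — for the invasive front.  Under this design the region-weighted
score sums are monotone in the sample's progression load, so the
invasive-front samples carry the highest heterogeneity scores; see
docs/methods.md for the derivation and for what this generator deliberately
does not model (batch effects, probe cross-hybridization, FFPE artifacts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    CtRecord,
    DEFAULT_REGIONS,
    SampleAnnotation,
    SignatureMatrix,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("meheg")

# Frozen study-condition defaults (rationale in docs/methods.md).
DEFAULT_SEPARATION = 0.1
BASELINE_RANGE = (0.05, 0.30)
FIRST_GAP_JITTER = (1.0, 1.25)  # multiples of `separation`
LAST_GAP_ACCEL = (2.4, 3.6)  # multiples of `separation`
BETA_RANGE = (0.05, 0.95)
DEFAULT_DOMINANCE = (5.0, 3.5, 2.0)  # Dirichlet own-region concentration
DEFAULT_NOISE_SD = 0.02


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    seed: int
    params: dict
    planted_probes: list[str] = field(default_factory=list)
    reference: SignatureMatrix | None = None
    fractions: pd.DataFrame | None = None  # sample x region true fractions
    entropy: pd.Series | None = None  # per-sample admixture entropy

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": self.seed, "params": self.params,
                    "planted_probes": self.planted_probes}
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        if self.reference is not None:
            self.reference.values.to_csv(
                directory / "true_reference.tsv", sep="\t", index_label="probe"
            )
        if self.fractions is not None:
            self.fractions.to_csv(
                directory / "true_fractions.tsv", sep="\t", index_label="sample"
            )
        if self.entropy is not None:
            self.entropy.to_frame("entropy").to_csv(
                directory / "true_entropy.tsv", sep="\t", index_label="sample"
            )


def _gap_ranges(separation: float, n_regions: int) -> tuple[tuple[float, float], tuple[float, float]]:
    """Jitter ranges (as multiples of separation) for early and final gaps,
    shrunk when the beta range cannot hold the maximal span."""
    lo, hi = BETA_RANGE
    budget = hi - lo  # room for the whole gradient span
    early_hi = FIRST_GAP_JITTER[1]
    accel_lo, accel_hi = LAST_GAP_ACCEL
    max_last = budget / separation - early_hi * (n_regions - 2)
    if max_last < 1.0:
        raise ValidationError(
            f"infeasible separation {separation} for {n_regions} regions in "
            f"[{lo}, {hi}]"
        )
    accel_hi = min(accel_hi, max_last)
    accel_lo = max(1.0, min(accel_lo, accel_hi))
    return FIRST_GAP_JITTER, (accel_lo, accel_hi)


def simulate_reference(
    n_probes: int,
    n_dmp: int,
    separation: float = DEFAULT_SEPARATION,
    n_regions: int = 3,
    seed: int = 0,
    region_names: Sequence[str] | None = None,
    mode: str = "progression",
) -> tuple[SignatureMatrix, SimTruth]:
    """Simulate a probes-x-regions reference with planted differential probes.

    Two planted-probe layouts are available.  ``mode="progression"``
    (default) follows the gradient described in the module docstring: a
    baseline drawn from ``[0.05, 0.30]`` in the first region and monotone
    gains toward the last, every inter-region gap at least *separation* (the
    final gap 2.4-3.6x larger, shrunk if the beta range cannot hold the
    span).  ``mode="independent"`` assigns spaced levels (gaps 1-1.5x
    *separation*) to the regions in a random per-probe order — an
    unstructured, well-conditioned reference suited to deconvolution
    benchmarks.  Null probes share one mean across regions.
    ``separation = 0`` plants no signal.
    """
    if mode not in ("progression", "independent"):
        raise ValidationError(f"unknown reference mode {mode!r}")
    if region_names is None:
        region_names = (
            DEFAULT_REGIONS if n_regions == 3
            else tuple(f"R{k + 1}" for k in range(n_regions))
        )
    region_names = tuple(region_names)
    if len(region_names) != n_regions or n_regions < 2:
        raise ValidationError("need >= 2 uniquely named regions")
    if not 0 <= n_dmp <= n_probes:
        raise ValidationError("n_dmp must lie in [0, n_probes]")
    if separation < 0:
        raise ValidationError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    lo, hi = BETA_RANGE
    probes = [f"cg{k:08d}" for k in range(n_probes)]
    values = np.empty((n_probes, n_regions))
    planted_idx = np.sort(rng.choice(n_probes, size=n_dmp, replace=False))
    is_planted = np.zeros(n_probes, dtype=bool)
    is_planted[planted_idx] = True

    if separation > 0 and n_dmp > 0:
        if mode == "progression":
            early_rng, last_rng = _gap_ranges(separation, n_regions)
        elif separation * 1.5 * (n_regions - 1) > hi - lo:
            raise ValidationError(
                f"infeasible separation {separation} for {n_regions} regions "
                f"in [{lo}, {hi}]"
            )
    for i in range(n_probes):
        if is_planted[i] and separation > 0:
            if mode == "progression":
                gaps = separation * np.concatenate(
                    [
                        rng.uniform(*early_rng, size=n_regions - 2),
                        [rng.uniform(*last_rng)],
                    ]
                )
                span = gaps.sum()
                b_hi = min(BASELINE_RANGE[1], hi - span)
                base = rng.uniform(BASELINE_RANGE[0],
                                   max(b_hi, BASELINE_RANGE[0]))
                values[i] = base + np.concatenate([[0.0], np.cumsum(gaps)])
            else:
                gaps = separation * rng.uniform(1.0, 1.5, size=n_regions - 1)
                span = gaps.sum()
                base = rng.uniform(lo, hi - span)
                levels = base + np.concatenate([[0.0], np.cumsum(gaps)])
                values[i] = levels[rng.permutation(n_regions)]
        else:
            values[i] = rng.uniform(lo, hi)
    sig = SignatureMatrix(
        pd.DataFrame(values, index=probes, columns=list(region_names))
    )
    truth = SimTruth(
        seed=seed,
        params={
            "n_probes": n_probes,
            "n_dmp": n_dmp,
            "separation": separation,
            "n_regions": n_regions,
            "region_names": list(region_names),
            "mode": mode,
        },
        planted_probes=[probes[i] for i in planted_idx],
        reference=sig,
    )
    return sig, truth


def default_concentrations(
    region_names: Sequence[str],
    dominance: Sequence[float] = DEFAULT_DOMINANCE,
) -> dict[str, np.ndarray]:
    """Per-region Dirichlet concentration vectors.

    Each region's own concentration dominates; the dominance declines along
    the region order (surface samples near-pure, invasive-front samples the
    most admixed).  For other region counts the dominance is interpolated
    linearly between the first and last default values.
    """
    n = len(region_names)
    if n == len(dominance):
        doms = list(dominance)
    else:
        doms = list(np.linspace(dominance[0], dominance[-1], n))
    out = {}
    for j, r in enumerate(region_names):
        alpha = np.ones(n)
        alpha[j] = doms[j]
        out[r] = alpha
    return out


def simulate_cohort(
    reference: SignatureMatrix,
    n_patients: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    concentrations: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> tuple[BetaMatrix, SampleAnnotation, SimTruth]:
    """Simulate a multiregional cohort of bulk beta profiles.

    For each patient and region a true fraction vector is drawn from that
    region's Dirichlet; the bulk profile is ``B @ f`` plus truncated Gaussian
    noise clipped to [0, 1] (clipping above 1% of entries is logged).  One
    sample per patient per region, named ``P<patient>_<region>``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_patients < 1:
        raise ValidationError("need >= 1 patient")
    regions = reference.regions
    conc = (
        {r: np.asarray(v, dtype=float) for r, v in concentrations.items()}
        if concentrations is not None
        else default_concentrations(regions)
    )
    for r in regions:
        if r not in conc:
            raise ValidationError(f"no Dirichlet concentration for region {r!r}")
        if (conc[r] <= 0).any():
            raise ValidationError("Dirichlet concentrations must be positive")
    rng = np.random.default_rng(seed)
    b = reference.values.to_numpy(dtype=float)
    names, rows_annot, fracs, cols = [], [], [], []
    for p in range(1, n_patients + 1):
        patient = f"P{p:03d}"
        for j, region in enumerate(regions):
            f = rng.dirichlet(conc[region])
            profile = b @ f
            if noise_sd > 0:
                profile = profile + rng.normal(0.0, noise_sd, size=b.shape[0])
            cols.append(np.clip(profile, 0.0, 1.0))
            name = f"{patient}_{region}"
            names.append(name)
            rows_annot.append({"sample": name, "patient": patient,
                               "region": region})
            fracs.append(f)
    arr = np.column_stack(cols)
    clip_frac = float(np.mean((arr == 0.0) | (arr == 1.0)))
    if clip_frac > 0.01:
        logger.warning(
            "simulate_cohort: %.1f%% of beta entries clipped to [0, 1]",
            100 * clip_frac,
        )
    beta = BetaMatrix(
        pd.DataFrame(arr, index=reference.probes, columns=names)
    )
    annot = SampleAnnotation(
        pd.DataFrame(rows_annot).set_index("sample")[["patient", "region"]],
        region_set=tuple(regions),
    )
    frac_df = pd.DataFrame(fracs, index=names, columns=regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(
            np.where(frac_df.values > 0,
                     frac_df.values * np.log(frac_df.values), 0.0),
            axis=1,
        )
    truth = SimTruth(
        seed=seed,
        params={
            "n_patients": n_patients,
            "noise_sd": noise_sd,
            "concentrations": {r: list(map(float, conc[r])) for r in regions},
        },
        reference=reference,
        fractions=frac_df,
        entropy=pd.Series(ent, index=names),
    )
    return beta, annot, truth


def simulate_ct(
    beta: BetaMatrix,
    base_ct: float = 30.0,
    replicate_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> list[CtRecord]:
    """Invert the dual-probe qPCR model to generate CT records.

    ``delta_ct = log2((1 - beta) / beta)``; the unmethylated channel sits at
    *base_ct* and the methylated channel at ``base_ct + delta_ct``, each
    replicate jittered with Gaussian noise of SD *replicate_sd*.  Betas of
    exactly 0 or 1 are rejected (infinite delta CT).
    """
    arr = beta.values.to_numpy(dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValidationError("betas must lie strictly in (0, 1) for CT simulation")
    if replicate_sd < 0 or n_replicates < 1:
        raise ValidationError("bad replicate settings")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for j, sample in enumerate(beta.samples):
        for i, locus in enumerate(beta.probes):
            delta = float(np.log2((1.0 - arr[i, j]) / arr[i, j]))
            for rep in range(1, n_replicates + 1):
                jm = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                ju = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                records.append(
                    CtRecord(sample, locus, "methylated", rep,
                             base_ct + delta + jm)
                )
                records.append(
                    CtRecord(sample, locus, "unmethylated", rep, base_ct + ju)
                )
    return records


DEFAULT_CLONES: tuple[tuple[float, float, float], ...] = (
    (0.25, 0.02, 0.5),
    (0.50, 0.02, 0.5),
)


def simulate_maf(
    n_samples: int,
    n_variants: int,
    clonal_structure: Sequence[tuple[float, float, float]] = DEFAULT_CLONES,
    depth: int = 100,
    seed: int = 0,
) -> tuple[list[VariantRecord], SimTruth]:
    """Simulate MAF variant records with a planted clonal structure.

    *clonal_structure* is a list of ``(vaf_center, dispersion, weight)``
    clones; per variant a clone is drawn by weight, the true VAF from a Beta
    distribution with mean *vaf_center* and concentration ``1/dispersion``,
    and the alt count binomially at the stated depth.
    """
    if not clonal_structure:
        raise ValidationError("empty clonal structure")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    centers = np.array([c[0] for c in clonal_structure])
    disps = np.array([c[1] for c in clonal_structure])
    weights = np.array([c[2] for c in clonal_structure])
    if not np.isclose(weights.sum(), 1.0):
        raise ValidationError("clone weights must sum to 1")
    if ((centers <= 0) | (centers >= 1)).any() or (disps <= 0).any():
        raise ValidationError("clone centers must be in (0,1), dispersions > 0")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    true_vafs = []
    for s in range(1, n_samples + 1):
        sample = f"S{s:03d}"
        for v in range(n_variants):
            clone = rng.choice(len(clonal_structure), p=weights)
            kappa = 1.0 / disps[clone]
            a = centers[clone] * kappa
            bshape = (1.0 - centers[clone]) * kappa
            true_vaf = rng.beta(a, bshape)
            alt = int(rng.binomial(depth, true_vaf))
            records.append(
                VariantRecord(
                    sample=sample,
                    chromosome=str(1 + v % 22),
                    position=1_000_000 + v,
                    t_ref_count=depth - alt,
                    t_alt_count=alt,
                )
            )
            true_vafs.append({"sample": sample, "variant": v, "vaf": true_vaf})
    truth = SimTruth(
        seed=seed,
        params={
            "n_samples": n_samples,
            "n_variants": n_variants,
            "clonal_structure": [list(map(float, c)) for c in clonal_structure],
            "depth": depth,
        },
        fractions=pd.DataFrame(true_vafs).set_index("sample"),
    )
    return records, truth


def write_maf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write variant records as a minimal MAF file."""
    df = pd.DataFrame(
        [
            {
                "Tumor_Sample_Barcode": r.sample,
                "Chromosome": r.chromosome,
                "Start_Position": r.position,
                "t_ref_count": r.t_ref_count,
                "t_alt_count": r.t_alt_count,
            }
            for r in records
        ]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
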