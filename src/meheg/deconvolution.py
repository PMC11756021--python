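"""nu-SVR reference-based deconvolution of bulk methylation profiles.

Solves the linear mixture model ``m = f x B``: a bulk beta profile *m* is
regressed on the columns of a probes-x-regions signature *B* with
nu-support-vector regression (linear kernel).  The nu parameter bounds the
training-error fraction from above and the support-vector fraction from
below; a small nu grid is fitted and the fit with the lowest RMSE between
fitted and observed (standardized) mixture wins.  Negative regression
coefficients are truncated to zero and the remainder normalized to sum to
one, yielding relative region fractions.

Both the mixture and the signature columns are z-scored with the pooled
mean/SD of the signature sub-matrix before fitting.  Because the true
fractions sum to one, this standardization maps the mixture onto the same
linear combination of standardized columns, so the raw coefficients estimate
the fractions directly (up to the truncation/normalization step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .io import (
    BetaMatrix,
    FractionVector,
    MehegError,
    SignatureMatrix,
    ValidationError,
)

logger = logging.getLogger("meheg")

DEFAULT_NU_GRID: tuple[float, ...] = (0.25, 0.50, 0.75)
SVR_C = 1.0
SVR_TOL = 1e-4
COLLINEARITY_R = 0.9999


class DeconvolutionError(MehegError):
    """Raised when a mixture admits no valid region composition."""


@dataclass
class NuSvrFit:
    """One nu-SVR fit of a standardized mixture on standardized signature columns."""

    nu: float
    raw_coefficients: pd.Series  # per region, possibly negative, untruncated
    intercept: float
    fitted_mixture: np.ndarray  # standardized scale, per probe
    rmse: float
    support_mask: np.ndarray  # per-probe support-vector flags
    collinear: bool = False


def _standardize(signature: SignatureMatrix, mixture: np.ndarray):
    b = signature.values.to_numpy(dtype=float)
    mu = b.mean()
    sd = b.std(ddof=0)
    if sd == 0:
        raise ValidationError("degenerate signature: all entries identical")
    bs = (b - mu) / sd
    col_sd = bs.std(axis=0, ddof=0)
    dead = np.flatnonzero(col_sd == 0)
    if dead.size:
        raise ValidationError(
            f"degenerate signature: region column "
            f"{signature.regions[dead[0]]!r} is constant across probes"
        )
    ms = (mixture - mu) / sd
    return bs, ms


def fit_nusvr(
    mixture: pd.Series | np.ndarray,
    signature: SignatureMatrix,
    nu: float,
) -> NuSvrFit:
    """Fit a linear-kernel nu-SVR of the mixture on the signature columns.

    The mixture must be order-aligned with the signature probes and contain
    no missing values.  Raw per-region coefficients are returned untruncated
    (they may be negative); RMSE is computed on the standardized scale.
    Near-perfectly collinear signature columns are flagged, not fatal.
    """
    if not 0 < nu <= 1:
        raise ValidationError(f"nu must lie in (0, 1], got {nu}")
    if isinstance(mixture, pd.Series):
        if list(mixture.index) != signature.probes:
            raise ValidationError("mixture probes do not match signature probes")
        m = mixture.to_numpy(dtype=float)
    else:
        m = np.asarray(mixture, dtype=float)
        if m.shape != (len(signature.probes),):
            raise ValidationError("mixture length does not match signature probes")
    if np.isnan(m).any():
        raise ValidationError("mixture contains missing values")

    bs, ms = _standardize(signature, m)
    collinear = False
    if bs.shape[1] > 1:
        cc = np.corrcoef(bs.T)
        iu = np.triu_indices_from(cc, k=1)
        if np.any(np.abs(cc[iu]) > COLLINEARITY_R):
            collinear = True
            logger.warning("fit_nusvr: near-collinear signature columns")

    model = NuSVR(nu=nu, C=SVR_C, kernel="linear", tol=SVR_TOL)
    model.fit(bs, ms)
    fitted = model.predict(bs)
    rmse = float(np.sqrt(np.mean((fitted - ms) ** 2)))
    support = np.zeros(bs.shape[0], dtype=bool)
    support[model.support_] = True
    return NuSvrFit(
        nu=nu,
        raw_coefficients=pd.Series(model.coef_[0], index=signature.regions),
        intercept=float(model.intercept_[0]),
        fitted_mixture=fitted,
        rmse=rmse,
        support_mask=support,
        collinear=collinear,
    )


def truncate_and_normalize(raw: pd.Series) -> FractionVector:
    """Set negative coefficients to zero and normalize the rest to sum to 1."""
    f = raw.to_numpy(dtype=float).copy()
    f[f < 0] = 0.0
    total = f.sum()
    if total <= 0:
        raise DeconvolutionError(
            "no admissible composition: all regression coefficients were "
            "non-positive (mixture inconsistent with the reference)"
        )
    return FractionVector(pd.Series(f / total, index=raw.index))


def deconvolve(
    mixture: pd.Series | np.ndarray,
    signature: SignatureMatrix,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
) -> tuple[FractionVector, NuSvrFit]:
    """Estimate region fractions for one bulk profile.

    Fits one nu-SVR per nu in *nu_grid*, keeps the fit with the lowest RMSE
    (ties go to the smaller nu), truncates negative coefficients to zero and
    normalizes the remainder to sum to one.
    """
    if not nu_grid:
        raise ValidationError("nu_grid must be non-empty")
    best: NuSvrFit | None = None
    for nu in sorted(nu_grid):
        fit = fit_nusvr(mixture, signature, nu)
        if best is None or fit.rmse < best.rmse:
            best = fit
    assert best is not None
    fractions = truncate_and_normalize(best.raw_coefficients)
    return fractions, best


def deconvolve_cohort(
    beta: BetaMatrix,
    signature: SignatureMatrix,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
) -> pd.DataFrame:
    """Deconvolve every sample of a cohort against the signature.

    Returns one row per sample with the region fractions, chosen nu and
    RMSE, and a ``status`` column: samples whose deconvolution fails (for
    example all-missing panel betas, or no admissible composition) carry an
    explicit failure marker rather than silent zeros.

    Probes of the signature absent from the beta matrix are dropped from the
    fit with a log entry; zero overlap is a hard error.
    """
    probes = [p for p in signature.probes if p in set(beta.probes)]
    if not probes:
        raise ValidationError("no overlap between signature and beta probes")
    if len(probes) < len(signature.probes):
        logger.warning(
            "deconvolve_cohort: %d signature probes absent from beta matrix",
            len(signature.probes) - len(probes),
        )
    sub_sig_df = signature.values.loc[probes]
    rows = []
    for sample in beta.samples:
        col = beta.values.loc[probes, sample]
        ok = col.notna()
        row: dict[str, object] = {"sample": sample}
        try:
            use = list(col.index[ok])
            if len(use) <= len(signature.regions):
                raise DeconvolutionError(
                    f"sample {sample!r}: only {len(use)} usable probes"
                )
            sig = SignatureMatrix(sub_sig_df.loc[use])
            frac, fit = deconvolve(col[use], sig, nu_grid)
            row.update({r: frac.fractions[r] for r in frac.regions})
            row.update({"nu": fit.nu, "rmse": fit.rmse, "status": "ok"})
        except MehegError as exc:
            row.update({r: np.nan for r in signature.regions})
            row.update({"nu": np.nan, "rmse": np.nan,
                        "status": f"failed: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
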