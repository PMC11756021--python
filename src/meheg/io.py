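"""Domain types and delimited-text I/O for methylation heterogeneity analysis.

Carriers for the objects the pipeline moves around: beta-value matrices
(probes x samples, values in [0, 1]), sample annotations mapping samples to
patients and tumor regions, probes-x-regions signature and weight matrices,
per-region fraction vectors, qPCR CT records, and MAF somatic-variant
records.  Every reader validates exhaustively: malformed input raises a
diagnostic :class:`ValidationError`, never a silently truncated object.

Tabular formats are tab-delimited UTF-8 with a single header row (the GEO
series-matrix convention: probes in rows, samples in columns).  MAF files
follow the Mutation Annotation Format standard (tab-delimited, 1-based
coordinates, ``#`` comment lines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("meheg")

#: Default ordered tumor-region labels: digestive tract surface, central
#: bulk, invasive front.
DEFAULT_REGIONS: tuple[str, ...] = ("DTS", "CB", "IF")

#: The published 7-probe scoring panel.  Panel *weights* are deliberately not
#: shipped: they must be derived from training data or supplied by the user.
DEFAULT_PANEL: tuple[str, ...] = (
    "cg06436185",
    "cg20060598",
    "cg08668790",
    "cg19169932",
    "cg24923516",
    "cg26974214",
    "cg21001441",
)

NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}


class MehegError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MehegError, ValueError):
    """Raised when an input object or file violates its contract."""


def _check_unique(labels: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {kind} ID: {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# Matrix-like containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta values in [0, 1]; NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index.astype(str), "probe")
        _check_unique(df.columns.astype(str), "sample")
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere(~np.isnan(arr) & ((arr < 0) | (arr > 1)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_incomplete(self, samples: Sequence[str] | None = None) -> "BetaMatrix":
        """Drop probes with any missing value among *samples* (default all).

        No imputation is attempted; the dropped-probe count is logged.
        """
        sub = self.values if samples is None else self.values[list(samples)]
        keep = ~sub.isna().any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d probes with missing values", n_drop)
        return BetaMatrix(self.values.loc[keep])


@dataclass
class SignatureMatrix:
    """Probes x regions reference profile B (region-mean betas)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index.astype(str), "probe")
        _check_unique(df.columns.astype(str), "region")
        if df.shape[0] <= df.shape[1]:
            raise ValidationError(
                "signature must contain more marker probes than regions "
                f"(got {df.shape[0]} probes for {df.shape[1]} regions): "
                "the mixture system m = f x B must be overdetermined"
            )
        arr = df.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("signature matrix contains missing values")
        if ((arr < 0) | (arr > 1)).any():
            raise ValidationError("signature entries must lie in [0, 1]")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class WeightMatrix:
    """Probes x regions scoring weights w_{i,j} (the trained panel model)."""

    values: pd.DataFrame
    strategy: str = "unspecified"

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index.astype(str), "probe")
        _check_unique(df.columns.astype(str), "region")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("weight matrix entries must be finite")
        dead = [c for c, col in zip(df.columns, arr.T) if not np.any(col != 0)]
        if dead:
            raise ValidationError(f"all-zero weight column for region {dead[0]!r}")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FractionVector:
    """Nonnegative per-region content fractions summing to 1."""

    fractions: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy(dtype=float)
        if (f < 0).any():
            raise ValidationError("fractions must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions must sum to 1 within 1e-9 (got {f.sum()!r})"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.fractions.index)


@dataclass
class SampleAnnotation:
    """Mapping sample ID -> (patient ID, tumor region)."""

    table: pd.DataFrame  # index: sample; columns: patient, region
    region_set: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        if len(self.region_set) < 2:
            raise ValidationError("need at least 2 region labels")
        _check_unique(self.table.index.astype(str), "sample")
        unknown = set(self.table["region"]) - set(self.region_set)
        if unknown:
            raise ValidationError(
                f"unknown region label(s) {sorted(unknown)}; allowed: "
                f"{list(self.region_set)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def samples_of(self, region: str) -> list[str]:
        return list(self.table.index[self.table["region"] == region])

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

CHANNELS = ("methylated", "unmethylated")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR cycle-threshold measurement.

    ``ct`` is None when the reaction did not amplify ("Undetermined") and the
    undetermined policy maps it to missing.
    """

    sample: str
    locus: str
    channel: str  # "methylated" | "unmethylated"
    replicate: int
    ct: float | None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with tumor ref/alt read counts (MAF convention)."""

    sample: str
    chromosome: str
    position: int  # 1-based
    t_ref_count: int
    t_alt_count: int

    def __post_init__(self) -> None:
        if self.t_ref_count < 0 or self.t_alt_count < 0:
            raise ValidationError("read counts must be nonnegative")

    @property
    def depth(self) -> int:
        return self.t_ref_count + self.t_alt_count

    @property
    def usable(self) -> bool:
        """Whether the record can contribute a mutant-allele fraction."""
        return self.depth > 0


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    return pd.read_csv(path, sep=sep, comment="#", dtype=str,
                       keep_default_na=False)


def read_beta_matrix(
    path: str | Path,
    sep: str = "\t",
    probes_in_rows: bool = True,
) -> BetaMatrix:
    """Read a beta-value matrix from delimited text.

    First column holds probe IDs, header row holds sample IDs (array-export
    convention); ``probes_in_rows=False`` transposes.  NA tokens become
    missing values, with the missing count logged.
    """
    raw = _read_table(path, sep=sep)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected probe-ID column plus samples")
    raw = raw.set_index(raw.columns[0])
    if not probes_in_rows:
        raw = raw.T
    _check_unique(raw.index, "probe")
    _check_unique(raw.columns, "sample")

    def parse(cell: str, probe: str, sample: str) -> float:
        if cell.strip() in NA_TOKENS:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise ValidationError(
                f"non-numeric beta {cell!r} at probe {probe!r}, sample {sample!r}"
            ) from None

    values = pd.DataFrame(
        [
            [parse(raw.iat[i, j], raw.index[i], raw.columns[j])
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
    )
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.info("read_beta_matrix: %d missing entries in %s", n_missing, path)
    return BetaMatrix(values)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    _write_df(beta.values, path, index_label="probe", header_lines=header_lines)


def read_sample_annotation(
    path: str | Path,
    region_set: Sequence[str] = DEFAULT_REGIONS,
    sep: str = "\t",
) -> SampleAnnotation:
    """Read a sample annotation table with columns sample, patient, region."""
    df = _read_table(path, sep=sep)
    required = ["sample", "patient", "region"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column {missing[0]!r}")
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    table = df[required].set_index("sample")
    return SampleAnnotation(table, tuple(region_set))


def write_sample_annotation(
    annot: SampleAnnotation, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    _write_df(annot.table, path, index_label="sample", header_lines=header_lines)


def read_signature_matrix(path: str | Path, sep: str = "\t") -> SignatureMatrix:
    raw = _read_table(path, sep=sep)
    raw = raw.set_index(raw.columns[0])
    return SignatureMatrix(raw.astype(float))


def write_signature_matrix(
    sig: SignatureMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    _write_df(sig.values, path, index_label="probe", header_lines=header_lines)


def read_weight_matrix(
    path: str | Path, sep: str = "\t", strategy: str = "file"
) -> WeightMatrix:
    raw = _read_table(path, sep=sep)
    raw = raw.set_index(raw.columns[0])
    return WeightMatrix(raw.astype(float), strategy=strategy)


def write_weight_matrix(
    weights: WeightMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    _write_df(weights.values, path, index_label="probe", header_lines=header_lines)


MAF_REQUIRED = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "t_ref_count",
    "t_alt_count",
)


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a Mutation Annotation Format file into variant records.

    Only the sample barcode, coordinates, and tumor read counts are
    consumed.  Rows with zero total depth are retained but flagged unusable
    via :attr:`VariantRecord.usable`.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column {missing[0]}")
    records: list[VariantRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        counts = {}
        for col in ("t_ref_count", "t_alt_count", "Start_Position"):
            try:
                counts[col] = int(row_d[col])
            except ValueError:
                raise ValidationError(
                    f"{path}: non-integer {col} {row_d[col]!r} on line {lineno}"
                ) from None
        records.append(
            VariantRecord(
                sample=row_d["Tumor_Sample_Barcode"],
                chromosome=row_d["Chromosome"],
                position=counts["Start_Position"],
                t_ref_count=counts["t_ref_count"],
                t_alt_count=counts["t_alt_count"],
            )
        )
    n_unusable = sum(not r.usable for r in records)
    if n_unusable:
        logger.info("read_maf: %d zero-depth records flagged unusable", n_unusable)
    return records


def read_ct_table(
    path: str | Path,
    max_cycles: float = 40.0,
    undetermined: str = "max_cycles",
    channel_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[CtRecord]:
    """Read a qPCR CT table with columns sample, locus, channel, replicate, ct.

    Channel tokens are normalized case-insensitively; dye names can be mapped
    via *channel_map* (e.g. ``{"FAM": "methylated", "VIC": "unmethylated"}``,
    the dual-probe dye convention).  ``Undetermined``/NA CT values follow the
    *undetermined* policy: ``"max_cycles"`` treats no-amplification as the
    limit cycle; ``"missing"`` drops the replicate value.
    """
    if undetermined not in ("max_cycles", "missing"):
        raise ValidationError(
            f"unknown undetermined policy {undetermined!r}"
        )
    df = _read_table(path, sep=sep)
    required = ["sample", "locus", "channel", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column {missing[0]!r}")
    cmap = {c.lower(): c for c in CHANNELS}
    if channel_map:
        cmap.update({k.lower(): v for k, v in channel_map.items()})
    records: list[CtRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        chan = cmap.get(str(d["channel"]).strip().lower())
        if chan is None:
            raise ValidationError(
                f"{path}: unknown channel {d['channel']!r} on line {lineno}; "
                f"known tokens: {sorted(cmap)}"
            )
        token = str(d["ct"]).strip()
        ct: float | None
        if token in NA_TOKENS or token.lower() == "undetermined":
            ct = max_cycles if undetermined == "max_cycles" else None
        else:
            try:
                ct = float(token)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric ct {token!r} on line {lineno}"
                ) from None
            if not 0 < ct <= max_cycles:
                raise ValidationError(
                    f"{path}: ct {ct} outside (0, {max_cycles}] on line {lineno}"
                )
        records.append(
            CtRecord(
                sample=str(d["sample"]),
                locus=str(d["locus"]),
                channel=chan,
                replicate=int(d["replicate"]),
                ct=ct,
            )
        )
    return records


def write_ct_table(
    records: Sequence[CtRecord], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "locus": r.locus,
                "channel": r.channel,
                "replicate": r.replicate,
                "ct": "Undetermined" if r.ct is None else repr(r.ct),
            }
            for r in records
        ]
    )
    _write_df(df.set_index("sample"), path, index_label="sample",
              header_lines=header_lines)


def _write_df(
    df: pd.DataFrame,
    path: str | Path,
    index_label: str,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a DataFrame as tab-delimited UTF-8 with optional # metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n",
                  float_format=None)
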