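"""Dual-probe qPCR methylation quantification (QASM).

One qPCR reaction carries two fluorescent probes — one binding the
bisulfite-converted methylated allele (FAM), one the unmethylated allele
(VIC) — amplified with a single primer pair.  The per-locus methylation
percentage follows from the cycle-threshold difference::

    delta_ct = CT_methylated - CT_unmethylated
    percent  = 100 / (1 + 2 ** delta_ct)

which is strictly decreasing in delta_ct: fewer cycles on the methylated
channel means more methylated template.  Replicates are collapsed by
averaging CT values (CT is the measured quantity) before the ratio is
formed; discordant replicates are flagged, not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, CtRecord, MehegError, ValidationError

DEFAULT_SPREAD_LIMIT = 0.5  # cycles


class QasmError(MehegError):
    """Raised when CT data cannot be converted to a methylation level."""


@dataclass
class QasmMeasurement:
    """One (sample, locus) methylation measurement with QC flags."""

    sample: str
    locus: str
    ct_meth: float
    ct_unmeth: float
    qc_flags: frozenset[str] = frozenset()

    @property
    def delta_ct(self) -> float:
        return self.ct_meth - self.ct_unmeth

    @property
    def methylation_percent(self) -> float:
        return methylation_percentage(self.delta_ct)


def methylation_percentage(delta_ct: float) -> float:
    """Map a CT difference to a methylation percentage in (0, 100)."""
    if not math.isfinite(delta_ct):
        raise QasmError(f"non-finite delta_ct: {delta_ct!r}")
    return 100.0 / (1.0 + 2.0 ** delta_ct)


def delta_ct_from_percent(percent: float) -> float:
    """Inverse of :func:`methylation_percentage` on (0, 100)."""
    if not 0 < percent < 100:
        raise QasmError("percent must lie strictly between 0 and 100")
    return math.log2(100.0 / percent - 1.0)


def collapse_replicates(
    records: Sequence[CtRecord],
    spread_limit: float = DEFAULT_SPREAD_LIMIT,
) -> pd.DataFrame:
    """Average replicate CTs per (sample, locus, channel).

    Returns a DataFrame with columns sample, locus, channel, ct, n_replicates
    and flags; the ``replicate_spread`` flag marks groups whose max-min CT
    exceeds *spread_limit* cycles.  A group with no usable (numeric)
    replicate raises :class:`QasmError`.
    """
    groups: dict[tuple[str, str, str], list[float]] = {}
    seen: list[tuple[str, str, str]] = []
    for r in records:
        key = (r.sample, r.locus, r.channel)
        if key not in groups:
            groups[key] = []
            seen.append(key)
        if r.ct is not None:
            groups[key].append(r.ct)
    rows = []
    for key in seen:
        cts = groups[key]
        if not cts:
            raise QasmError(
                f"no usable replicate for sample {key[0]!r}, locus "
                f"{key[1]!r}, channel {key[2]!r}"
            )
        flags = []
        if max(cts) - min(cts) > spread_limit:
            flags.append("replicate_spread")
        rows.append(
            {
                "sample": key[0],
                "locus": key[1],
                "channel": key[2],
                "ct": float(np.mean(cts)),
                "n_replicates": len(cts),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def qasm_measurements(
    records: Sequence[CtRecord],
    spread_limit: float = DEFAULT_SPREAD_LIMIT,
) -> list[QasmMeasurement]:
    """Collapse replicates and pair channels into per-locus measurements."""
    collapsed = collapse_replicates(records, spread_limit)
    out = []
    for (sample, locus), grp in collapsed.groupby(["sample", "locus"], sort=False):
        chans = dict(zip(grp["channel"], grp["ct"]))
        if "methylated" not in chans or "unmethylated" not in chans:
            continue  # handled by qasm_beta_table as a flagged missing cell
        flags = set()
        for f in grp["flags"]:
            flags.update(t for t in f.split(";") if t)
        out.append(
            QasmMeasurement(
                sample=sample,
                locus=locus,
                ct_meth=chans["methylated"],
                ct_unmeth=chans["unmethylated"],
                qc_flags=frozenset(flags),
            )
        )
    return out


def qasm_beta_table(
    records: Sequence[CtRecord],
    panel: Sequence[str],
    spread_limit: float = DEFAULT_SPREAD_LIMIT,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Convert CT records into a panel beta matrix plus a QC sidecar table.

    Cells whose methylated or unmethylated channel cannot be collapsed are
    left missing and flagged ``missing_channel`` — never zero-filled.
    """
    panel = list(panel)
    if not panel:
        raise ValidationError("empty panel")
    collapsed = collapse_replicates(records, spread_limit)
    samples = list(dict.fromkeys(collapsed["sample"]))
    values = pd.DataFrame(np.nan, index=panel, columns=samples, dtype=float)
    qc_rows = []
    by_key = {
        (r.sample, r.locus, r.channel): (r.ct, r.flags)
        for r in collapsed.itertuples(index=False)
    }
    for sample in samples:
        for locus in panel:
            meth = by_key.get((sample, locus, "methylated"))
            unmeth = by_key.get((sample, locus, "unmethylated"))
            flags = set()
            if meth is None or unmeth is None:
                flags.add("missing_channel")
            else:
                for f in (meth[1], unmeth[1]):
                    flags.update(t for t in f.split(";") if t)
                delta = meth[0] - unmeth[0]
                values.loc[locus, sample] = methylation_percentage(delta) / 100.0
            qc_rows.append(
                {"sample": sample, "locus": locus, "flags": ";".join(sorted(flags))}
            )
    return BetaMatrix(values), pd.DataFrame(qc_rows)
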