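"""Lineage-acceleration statistics: Identity Ratio, Extended Identity Ratio,
Tukey-fence outlier screening over a gene panel.

The Identity Ratio (IR) for a gene is

    IR = pid(reference, focal) / pid(reference, baseline)

with defaults reference=human, focal=house_mouse, baseline=bovine. Under a
constant evolutionary rate and a topology where the focal species is closer
to the reference than the baseline is, IR is expected above 1; values well
below 1 indicate focal-lineage sequence acceleration.

The Extended Identity Ratio (EIR) compares the focal species against a trio
of reference species:

    EIR = sum_t pid(focal, t) / sum_{t<u} pid(t, u),   t, u in trio

Outliers are flagged with the Tukey lower fence Q1 - 1.5*IQR computed over
the screened gene panel; quartiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .errors import UndefinedRatioError
from .pairwise import IdentityMatrix, identity_matrix
from .seqio import OrthologGroup

logger = logging.getLogger(__name__)

DEFAULT_REF = "human"
DEFAULT_FOCAL = "house_mouse"
DEFAULT_BASE = "bovine"
DEFAULT_TRIO = ("human", "bovine", "rabbit")
DEFAULT_PANEL = ("human", "house_mouse", "bovine", "rabbit")


def identity_ratio(
    m: IdentityMatrix,
    focal: str = DEFAULT_FOCAL,
    ref: str = DEFAULT_REF,
    base: str = DEFAULT_BASE,
) -> float:
    """pid(ref, focal) / pid(ref, base); full precision, round at reporting."""
    denom = m.get(ref, base)
    if denom == 0:
        raise UndefinedRatioError(
            f"identity ratio undefined: pid({ref}, {base}) = 0"
        )
    return m.get(ref, focal) / denom


def extended_identity_ratio(
    m: IdentityMatrix,
    focal: str = DEFAULT_FOCAL,
    trio: Sequence[str] = DEFAULT_TRIO,
) -> float:
    """Sum of focal-to-trio identities over the sum of within-trio identities."""
    trio = tuple(trio)
    if len(trio) != 3 or len(set(trio)) != 3 or focal in trio:
        raise ValueError("trio must be three distinct species excluding focal")
    denom = sum(m.get(t, u) for t, u in combinations(trio, 2))
    if denom == 0:
        raise UndefinedRatioError("extended identity ratio undefined: trio sum 0")
    return sum(m.get(focal, t) for t in trio) / denom


@dataclass(frozen=True)
class TukeySummary:
    """Five-number-style summary used for lower-outlier fencing."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float


def tukey_summary(values: Iterable[float]) -> TukeySummary:
    """Median/quartiles (linear interpolation) and the Q1 - 1.5*IQR fence."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4 or not np.all(np.isfinite(arr)):
        raise ValueError(
            "Tukey summary requires at least 4 finite values "
            f"(got {arr.size} values)"
        )
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    iqr = q3 - q1
    return TukeySummary(
        n=int(arr.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(q1 - 1.5 * iqr),
    )


@dataclass(frozen=True)
class RatioRecord:
    """Per-gene screen result; ratios are full precision and never silently 0."""

    gene_symbol: str
    ir: float
    eir: float
    n_species_used: int

    def __post_init__(self) -> None:
        for name, value in (("ir", self.ir), ("eir", self.eir)):
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value}")


@dataclass(frozen=True)
class ScreenReport:
    """Ranked screen results with the fence summary and outlier flags."""

    records: tuple[RatioRecord, ...]  # ascending by the chosen ratio
    ratio_choice: str  # "ir" or "eir"
    summary: TukeySummary
    outlier_flags: dict  # gene_symbol -> bool (ratio < lower fence)
    skipped: tuple[str, ...]  # genes missing panel species

    def ratio_of(self, record: RatioRecord) -> float:
        return record.ir if self.ratio_choice == "ir" else record.eir

    def flagged(self) -> tuple[str, ...]:
        return tuple(g for g, f in self.outlier_flags.items() if f)


def run_screen(
    groups: Iterable[OrthologGroup],
    panel: Sequence[str] = DEFAULT_PANEL,
    ratio_choice: str = "eir",
    focal: str = DEFAULT_FOCAL,
    ref: str = DEFAULT_REF,
    base: str = DEFAULT_BASE,
    trio: Sequence[str] = DEFAULT_TRIO,
    **scoring,
) -> ScreenReport:
    """Screen a gene panel for focal-lineage acceleration.

    Groups missing any panel species are skipped (logged and reported, never
    silently dropped). At least four complete groups are required for the
    fence to be meaningful. Extra keyword arguments (matrix, gap_open,
    gap_extend, denominator) are forwarded to the aligner.
    """
    if ratio_choice not in ("ir", "eir"):
        raise ValueError("ratio_choice must be 'ir' or 'eir'")
    records: list[RatioRecord] = []
    skipped: list[str] = []
    for group in groups:
        if not group.has_panel(panel):
            missing = [sp for sp in panel if sp not in group.members]
            logger.warning(
                "skipping gene %s: missing species %s", group.gene_symbol, missing
            )
            skipped.append(group.gene_symbol)
            continue
        m = identity_matrix(group, panel, **scoring)
        records.append(
            RatioRecord(
                gene_symbol=group.gene_symbol,
                ir=identity_ratio(m, focal=focal, ref=ref, base=base),
                eir=extended_identity_ratio(m, focal=focal, trio=trio),
                n_species_used=len(panel),
            )
        )
    if not records:
        raise ValueError("no ortholog group has a complete species panel")
    if len(records) < 4:
        raise ValueError(
            f"screen needs at least 4 complete groups, got {len(records)}"
        )

    def key(r: RatioRecord):
        return (r.ir if ratio_choice == "ir" else r.eir, r.gene_symbol)

    records.sort(key=key)
    values = [r.ir if ratio_choice == "ir" else r.eir for r in records]
    summary = tukey_summary(values)
    flags = {
        r.gene_symbol: v < summary.lower_fence for r, v in zip(records, values)
    }
    return ScreenReport(
        records=tuple(records),
        ratio_choice=ratio_choice,
        summary=summary,
        outlier_flags=flags,
        skipped=tuple(skipped),
    )


def write_screen_report(report: ScreenReport, path, provenance: dict | None = None):
    """Report TSV: commented summary header, then gene/ir/eir/rank/outlier rows."""
    s = report.summary
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(
            f"# ratio: {report.ratio_choice} n: {s.n} median: {s.median:.2f} "
            f"q1: {s.q1:.2f} q3: {s.q3:.2f} lower_fence: {s.lower_fence:.2f} "
            f"skipped: {len(report.skipped)}\n"
        )
        fh.write("gene\tir\teir\trank\toutlier\n")
        for rank, rec in enumerate(report.records, start=1):
            fh.write(
                f"{rec.gene_symbol}\t{rec.ir:.2f}\t{rec.eir:.2f}\t{rank}\t"
                f"{int(report.outlier_flags[rec.gene_symbol])}\n"
            )
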