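"""Runs-of-homozygosity (ROH) metrics and consanguinity classification.

Per individual: NROH counts autosomal ROH segments at least 1 Mb long, SROH
is their summed length in Mb, and FROH is SROH over the autosomal genome
length (2,881 Mb for GRCh38 by default — a configurable denominator chosen so
that a mean SROH of ~30 Mb corresponds to a mean FROH of ~1%).

SROH thresholds classify consanguinity evidence: >123 Mb evidence; 79-123 Mb
probable; <79 Mb probable non-consanguinity, except that <=22 Mb takes
precedence as no evidence. X-chromosome segments are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

CONSANGUINITY_CLASSES = ("evidence", "probable", "probable_non", "no_evidence")

#: GRCh38 autosomal genome length in Mb, the default FROH denominator.
AUTOSOME_LENGTH_MB = 2881.0

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


class RohError(ValueError):
    """Raised on malformed ROH input."""


@dataclass(frozen=True)
class RohSegment:
    """One ROH segment, BED convention (0-based half-open)."""

    sample_id: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RohError(
                f"non-positive segment length {self.contig}:{self.start}-{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RohMetrics:
    sample_id: str
    nroh: int
    sroh_mb: float
    froh: float

    @property
    def consanguinity_class(self) -> str:
        return classify_consanguinity(self.sroh_mb)


def read_roh_bed(path: str | Path) -> dict[str, list[RohSegment]]:
    """Read ROH segments from a BED file with sample id in the 4th column."""
    by_sample: dict[str, list[RohSegment]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise RohError(f"{path} line {line_no}: expected 4 BED columns")
            seg = RohSegment(parts[3], parts[0], int(parts[1]), int(parts[2]))
            by_sample.setdefault(seg.sample_id, []).append(seg)
    return by_sample


def roh_metrics(
    segments: Iterable[RohSegment],
    sample_id: str | None = None,
    min_len_bp: int = 1_000_000,
    autosome_length_mb: float = AUTOSOME_LENGTH_MB,
) -> RohMetrics:
    """NROH / SROH / FROH for one sample's segments.

    Only autosomal segments with length >= ``min_len_bp`` qualify; order of
    input segments is irrelevant.
    """
    segments = list(segments)
    ids = {s.sample_id for s in segments}
    if sample_id is None:
        if len(ids) > 1:
            raise RohError(f"segments from multiple samples: {sorted(ids)}")
        sample_id = next(iter(ids)) if ids else ""
    elif ids - {sample_id}:
        raise RohError(f"segments from other samples: {sorted(ids - {sample_id})}")
    qualifying = [
        s for s in segments if s.contig in AUTOSOMES and s.length_bp >= min_len_bp
    ]
    sroh_mb = sum(s.length_bp for s in qualifying) / 1e6
    return RohMetrics(
        sample_id=sample_id,
        nroh=len(qualifying),
        sroh_mb=sroh_mb,
        froh=sroh_mb / autosome_length_mb,
    )


def classify_consanguinity(sroh_mb: float) -> str:
    """SROH-threshold consanguinity class.

    >123 Mb: evidence; 79-123 Mb inclusive: probable; below that,
    probable non-consanguinity, with <=22 Mb taking precedence as no
    evidence.
    """
    if sroh_mb < 0:
        raise RohError(f"negative SROH {sroh_mb}")
    if sroh_mb > 123.0:
        return "evidence"
    if sroh_mb >= 79.0:
        return "probable"
    if sroh_mb > 22.0:
        return "probable_non"
    return "no_evidence"


def reconcile_self_report(
    metrics: Iterable[RohMetrics],
    self_reports: Mapping[str, str],
) -> tuple[list[tuple[str, str, str]], float]:
    """Compare SROH classes against self-reported consanguinity.

    A mismatch is self-report "yes" with class probable_non/no_evidence, or
    "no" with class evidence/probable. Unknown self-reports are excluded from
    the denominator. Returns (mismatch rows, mismatch rate); the rate is 0
    when no informative self-reports exist.
    """
    mismatches: list[tuple[str, str, str]] = []
    informative = 0
    for m in metrics:
        report = self_reports.get(m.sample_id, "unknown")
        if report not in ("yes", "no"):
            continue
        informative += 1
        cls = m.consanguinity_class
        if (report == "yes" and cls in ("probable_non", "no_evidence")) or (
            report == "no" and cls in ("evidence", "probable")
        ):
            mismatches.append((m.sample_id, report, cls))
    rate = len(mismatches) / informative if informative else 0.0
    return mismatches, rate
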