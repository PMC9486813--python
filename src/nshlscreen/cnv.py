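"""Copy-number and small unbalanced structural-variant screening.

Events (deletions/duplications with 1-based inclusive coordinates) pass three
automatic filters before analyst curation:

* coding overlap — at least one base pair inside a coding exon; events
  confined to noncoding sequence are never preselected;
* size — events larger than 1 Mb are excluded as likely syndromic;
* syndromic regions — events touching a critical region for a known
  contiguous-gene microdeletion/microduplication syndrome are excluded.

Events from a dedicated CNV caller and small unbalanced SVs from an SV caller
flow through the same type; exact-coordinate duplicates are deduplicated in
favor of the CNV-caller record. Recurrence across samples is defined by exact
(contig, start, end, svtype) identity — no reciprocal-overlap clustering.

Interval arithmetic converts the 1-based inclusive event coordinates to
0-based half-open internally (intervaltree semantics); size_bp is
end - start + 1 under the inclusive convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

SVTYPES = ("DEL", "DUP")
SOURCES = ("cnv_caller", "sv_caller")

CnvKey = tuple[str, int, int, str]


class CnvError(ValueError):
    """Raised on malformed CNV input or contract violations."""


@dataclass(frozen=True)
class CnvEvent:
    """One sample's copy-number event, 1-based inclusive coordinates."""

    sample_id: str
    contig: str
    start: int
    end: int
    svtype: str
    source: str = "cnv_caller"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CnvError(f"start {self.start} > end {self.end}")
        if self.svtype not in SVTYPES:
            raise CnvError(f"unknown svtype {self.svtype!r}")
        if self.source not in SOURCES:
            raise CnvError(f"unknown source {self.source!r}")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> CnvKey:
        """Recurrence identity: exact coordinates + type, across samples."""
        return (self.contig, self.start, self.end, self.svtype)


@dataclass
class RegionMap:
    """Named genomic intervals with interval-tree overlap lookup.

    Intervals are stored 0-based half-open (BED convention). Labels are free
    strings; the exon map uses "gene|exon_number", the syndromic map a
    syndrome label.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, contig: str, start0: int, end0: int, label: str) -> None:
        if end0 <= start0:
            raise CnvError(f"empty interval {contig}:{start0}-{end0}")
        self.trees.setdefault(contig, IntervalTree()).addi(start0, end0, label)

    def overlapping(self, contig: str, start0: int, end0: int) -> list[tuple[int, int, str]]:
        """All (start0, end0, label) intervals overlapping the query."""
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start0, end0))

    def overlaps(self, contig: str, start0: int, end0: int) -> bool:
        tree = self.trees.get(contig)
        return bool(tree is not None and tree.overlap(start0, end0))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionMap":
        """Load a BED file (0-based half-open; 4th column is the label)."""
        rm = cls()
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise CnvError(f"{path} line {line_no}: expected 4 BED columns")
                rm.add(parts[0], int(parts[1]), int(parts[2]), parts[3])
        return rm


def event_interval0(event: CnvEvent) -> tuple[int, int]:
    """1-based inclusive event coordinates as 0-based half-open."""
    return event.start - 1, event.end


def read_cnv_table(path: str | Path) -> list[CnvEvent]:
    """Read events from a TSV (sample_id, contig, start_1based, end_1based, svtype, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CnvEvent(
            sample_id=r.sample_id,
            contig=r.contig,
            start=int(r.start_1based),
            end=int(r.end_1based),
            svtype=r.svtype.strip().upper(),
            source=getattr(r, "source", "cnv_caller") or "cnv_caller",
        )
        for r in df.itertuples(index=False)
    ]


def merge_sources(events: Iterable[CnvEvent]) -> list[CnvEvent]:
    """Merge CNV-caller and SV-caller events per sample.

    Exact-coordinate duplicates within a sample collapse to one event,
    keeping the cnv_caller record when the sources disagree.
    """
    chosen: dict[tuple[str, CnvKey], CnvEvent] = {}
    order: list[tuple[str, CnvKey]] = []
    for e in events:
        k = (e.sample_id, e.key)
        if k not in chosen:
            chosen[k] = e
            order.append(k)
        elif chosen[k].source == "sv_caller" and e.source == "cnv_caller":
            chosen[k] = e
    return [chosen[k] for k in order]


def coding_overlap_filter(
    events: Iterable[CnvEvent], exons: RegionMap
) -> list[CnvEvent]:
    """Keep events overlapping >=1 bp of any coding interval."""
    if len(exons) == 0:
        raise CnvError("empty coding-exon map")
    return [e for e in events if exons.overlaps(e.contig, *event_interval0(e))]


def syndromic_size_filter(
    events: Iterable[CnvEvent],
    syndromic: RegionMap,
    max_size_bp: int = 1_000_000,
) -> tuple[list[CnvEvent], list[tuple[CnvEvent, str]]]:
    """Drop oversize events and events touching syndromic critical regions.

    Returns (retained, excluded_log) where each log entry carries the reason
    ("size" checked first, then "syndromic").
    """
    retained: list[CnvEvent] = []
    log: list[tuple[CnvEvent, str]] = []
    for e in events:
        if e.size_bp > max_size_bp:
            log.append((e, "size"))
        elif syndromic.overlaps(e.contig, *event_interval0(e)):
            log.append((e, "syndromic"))
        else:
            retained.append(e)
    return retained, log


def annotate_cnv_genes(
    event: CnvEvent,
    panel_genes: Iterable[str],
    exons: RegionMap,
) -> tuple[list[str], dict[str, tuple[int, int]]]:
    """Panel genes hit by an event and, per gene, the exon-number span.

    Exon labels in the map are "gene|exon_number"; numbering follows the
    map's transcript, so minus-strand genes may number exons against the
    coordinate direction. Returns ([], {}) when no panel gene is touched.
    """
    panel = set(panel_genes)
    hit_exons: dict[str, list[int]] = {}
    for _, _, label in exons.overlapping(event.contig, *event_interval0(event)):
        try:
            gene, exon_no = label.rsplit("|", 1)
            exon = int(exon_no)
        except ValueError as exc:
            raise CnvError(f"exon label {label!r} is not gene|exon_number") from exc
        if gene in panel:
            hit_exons.setdefault(gene, []).append(exon)
    genes = sorted(hit_exons)
    spans = {g: (min(ns), max(ns)) for g, ns in hit_exons.items()}
    return genes, spans


def apply_cnv_curation(
    events: Iterable[CnvEvent],
    decisions: dict[CnvKey, str],
) -> list[CnvEvent]:
    """Keep events whose curated class (keyed by exact coordinates) is P or LP."""
    kept = []
    for e in events:
        cls = decisions.get(e.key)
        if cls is None:
            raise CnvError(f"no curation decision for CNV {e.key}")
        if cls in ("P", "LP"):
            kept.append(e)
    return kept


def group_recurrent(events: Iterable[CnvEvent]) -> dict[CnvKey, list[str]]:
    """Group events into distinct CNVs by exact coordinates.

    Returns {cnv key: [carrier sample ids]}; a deletion planted at identical
    coordinates in 38 samples aggregates to one distinct CNV with 38 carriers.
    """
    groups: dict[CnvKey, list[str]] = {}
    for e in events:
        groups.setdefault(e.key, []).append(e.sample_id)
    return groups


def distinct_count(events: Iterable[CnvEvent]) -> int:
    """Number of distinct CNVs (exact-coordinate identity)."""
    return len(Counter(e.key for e in events))
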