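"""Gene panel model for nonsyndromic hearing loss (NSHL) screening.

A panel is a table of gene x inheritance-mode associations, each carrying a
gene-disease validity label (ClinGen-style: definitive/strong/moderate/
limited/disputed/refuted), clinical attributes (onset, type, severity,
progression, predominant sound frequency) and a genomic interval. Validity
labels are curated inputs, never computed here: gene-disease evidence scoring
is expert judgement upstream of this package.

Filtering removes associations with contradictory evidence (disputed or
refuted) and genes flagged as having no valid transcript or a non-Mendelian
disease relationship. A gene survives as long as at least one of its modes
survives, which is how a gene with a refuted recessive form can remain on the
panel through its dominant form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

INHERITANCE_MODES = ("AD", "AR", "XL")
VALIDITIES = ("definitive", "strong", "moderate", "limited", "disputed", "refuted")
ONSETS = ("prelingual", "postlingual", "unknown")
HL_TYPES = ("sensorineural", "conductive", "mixed", "central", "unknown")
SEVERITIES = ("mild", "moderate", "severe", "profound", "range", "unknown")
PROGRESSIONS = ("progressive", "stable", "variable", "unknown")
FREQUENCY_BANDS = ("low", "low-middle", "middle", "middle-high", "high", "all", "unknown")

#: Inheritance classes used in panel summaries. A gene carrying both an AD and
#: an AR association is counted once, in the AD/AR class.
INHERITANCE_CLASSES = ("AD", "AR", "AD/AR", "XL")

PANEL_COLUMNS = [
    "gene_symbol",
    "inheritance_mode",
    "validity",
    "onset",
    "hl_type",
    "severity",
    "progression",
    "frequency_band",
    "transcript_id",
    "contig",
    "start_1based",
    "end_1based",
    "no_valid_transcript",
    "non_mendelian",
]


class PanelError(ValueError):
    """Raised for malformed or invalid panel tables."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PanelError(
                f"interval start {self.start} > end {self.end} on {self.contig}"
            )

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene x inheritance-mode association with validity and clinical attributes."""

    gene_symbol: str
    inheritance_mode: str
    validity: str
    onset: str = "unknown"
    hl_type: str = "unknown"
    severity: str = "unknown"
    progression: str = "unknown"
    frequency_band: str = "unknown"
    transcript_id: str = ""
    interval: GenomicInterval | None = None
    no_valid_transcript: bool = False
    non_mendelian: bool = False


@dataclass
class PanelSummary:
    """Cross-tabulated panel composition.

    ``class_gene_counts`` counts unique genes per inheritance class (a dual
    AD+AR gene counts once in "AD/AR"); ``crosstab`` counts gene-mode
    associations per (inheritance class, frequency_band, onset) cell.
    """

    class_gene_counts: dict[str, int] = field(default_factory=dict)
    crosstab: Counter = field(default_factory=Counter)
    n_unique_genes: int = 0
    n_associations: int = 0

    def cell(self, inh_class: str, frequency_band: str, onset: str) -> int:
        return self.crosstab.get((inh_class, frequency_band, onset), 0)


def _norm_enum(raw: str, allowed: tuple[str, ...], column: str, line: int) -> str:
    value = str(raw).strip().lower()
    if value not in allowed:
        raise PanelError(
            f"line {line}: unknown {column} label {raw!r} (allowed: {', '.join(allowed)})"
        )
    return value


def _norm_mode(raw: str, line: int) -> str:
    value = str(raw).strip().upper()
    if value not in INHERITANCE_MODES:
        raise PanelError(f"line {line}: unknown inheritance_mode {raw!r}")
    return value


def load_panel(path: str | Path) -> list[GenePanelEntry]:
    """Load a tab-separated panel table into validated entries.

    Enumeration labels are matched case-insensitively after whitespace
    stripping; duplicate (gene, mode) rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel table missing columns: {', '.join(missing)}")

    entries: list[GenePanelEntry] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        gene = str(row.gene_symbol).strip()
        if not gene:
            raise PanelError(f"line {idx}: empty gene_symbol")
        mode = _norm_mode(row.inheritance_mode, idx)
        key = (gene, mode)
        if key in seen:
            raise PanelError(f"line {idx}: duplicate (gene, mode) row {key}")
        seen.add(key)
        try:
            start, end = int(row.start_1based), int(row.end_1based)
        except ValueError as exc:
            raise PanelError(f"line {idx}: malformed interval coordinates") from exc
        entries.append(
            GenePanelEntry(
                gene_symbol=gene,
                inheritance_mode=mode,
                validity=_norm_enum(row.validity, VALIDITIES, "validity", idx),
                onset=_norm_enum(row.onset, ONSETS, "onset", idx),
                hl_type=_norm_enum(row.hl_type, HL_TYPES, "hl_type", idx),
                severity=_norm_enum(row.severity, SEVERITIES, "severity", idx),
                progression=_norm_enum(
                    row.progression, PROGRESSIONS, "progression", idx
                ),
                frequency_band=_norm_enum(
                    row.frequency_band, FREQUENCY_BANDS, "frequency_band", idx
                ),
                transcript_id=str(row.transcript_id).strip(),
                interval=GenomicInterval(str(row.contig).strip(), start, end),
                no_valid_transcript=str(row.no_valid_transcript).strip() in ("1", "true", "True"),
                non_mendelian=str(row.non_mendelian).strip() in ("1", "true", "True"),
            )
        )
    return entries


def filter_panel(
    entries: Iterable[GenePanelEntry],
) -> tuple[list[GenePanelEntry], list[tuple[str, str, str]]]:
    """Drop disputed/refuted associations and flagged genes.

    Returns the retained entries (in input order) and an exclusion log of
    (gene, mode, reason) tuples, one per removed association. A gene is off
    the panel only when none of its modes survive.
    """
    retained: list[GenePanelEntry] = []
    log: list[tuple[str, str, str]] = []
    for e in entries:
        if e.no_valid_transcript:
            log.append((e.gene_symbol, e.inheritance_mode, "no_valid_transcript"))
        elif e.non_mendelian:
            log.append((e.gene_symbol, e.inheritance_mode, "non_mendelian"))
        elif e.validity in ("disputed", "refuted"):
            log.append((e.gene_symbol, e.inheritance_mode, e.validity))
        else:
            retained.append(e)
    return retained, log


def inheritance_class(modes: set[str]) -> str:
    """Collapse a gene's surviving modes into one inheritance class."""
    if "AD" in modes and "AR" in modes:
        return "AD/AR"
    if "XL" in modes:
        return "XL"
    if "AD" in modes:
        return "AD"
    if "AR" in modes:
        return "AR"
    raise PanelError(f"cannot classify modes {modes}")


def gene_modes(entries: Iterable[GenePanelEntry]) -> dict[str, set[str]]:
    """Map each gene to its set of (retained) inheritance modes."""
    modes: dict[str, set[str]] = {}
    for e in entries:
        modes.setdefault(e.gene_symbol, set()).add(e.inheritance_mode)
    return modes


def summarize_panel(retained: Iterable[GenePanelEntry]) -> PanelSummary:
    """Cross-tabulate a filtered panel by inheritance class, frequency and onset.

    Gene counts per class are unique genes (a dual-mode gene counts once under
    AD/AR); the crosstab counts associations, so a dual gene contributes one
    AD/AR-class cell per mode. Unknown clinical attributes form their own
    category rather than being dropped.
    """
    retained = list(retained)
    modes = gene_modes(retained)
    classes = {g: inheritance_class(m) for g, m in modes.items()}

    class_counts: Counter = Counter(classes.values())
    crosstab: Counter = Counter()
    for e in retained:
        crosstab[(classes[e.gene_symbol], e.frequency_band, e.onset)] += 1

    return PanelSummary(
        class_gene_counts={c: class_counts.get(c, 0) for c in INHERITANCE_CLASSES},
        crosstab=crosstab,
        n_unique_genes=len(modes),
        n_associations=len(retained),
    )


def write_panel(entries: Iterable[GenePanelEntry], path: str | Path) -> None:
    """Write entries back to the tab-separated panel format."""
    rows = []
    for e in entries:
        iv = e.interval or GenomicInterval("chrUn", 1, 1)
        rows.append(
            {
                "gene_symbol": e.gene_symbol,
                "inheritance_mode": e.inheritance_mode,
                "validity": e.validity,
                "onset": e.onset,
                "hl_type": e.hl_type,
                "severity": e.severity,
                "progression": e.progression,
                "frequency_band": e.frequency_band,
                "transcript_id": e.transcript_id,
                "contig": iv.contig,
                "start_1based": iv.start,
                "end_1based": iv.end,
                "no_valid_transcript": int(e.no_valid_transcript),
                "non_mendelian": int(e.non_mendelian),
            }
        )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)
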