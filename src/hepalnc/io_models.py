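"""Domain containers and readers/writers for the pipeline's interchange formats.

The pipeline starts downstream of alignment and assembly: its inputs are
transcript models (GTF), a genes x samples FPKM matrix (TSV with a header of
sample ids), and a per-transcript coding-potential score table (two-column
TSV, negative scores meaning predicted noncoding).  All genomic coordinates
are 1-based inclusive, the GTF convention; transcript "length" always means
spliced length (the sum of exon widths, i.e. the mature transcript), not the
genomic span.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, GtfParseError, ValidationError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
BIOTYPES = ("coding", "known_lncRNA", "novel_lncRNA", "undefined")
GROUP_LABELS = ("control", "case")


def merge_exons(exons: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort exons by start and merge any that overlap or touch.

    Assemblers occasionally emit overlapping exons within one transcript;
    these are merged (with a warning left to the caller) rather than rejected.
    """
    ordered = sorted((int(s), int(e)) for s, e in exons)
    merged: list[list[int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled or reference transcript: an exon chain on a strand.

    Exons are ``(start, end)`` pairs, 1-based inclusive, sorted by start and
    non-overlapping.  Use :func:`merge_exons` (or ``from_exons``) first if the
    source may contain overlapping exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"transcript {self.transcript_id}: strand {self.strand!r} not one of {STRANDS}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: empty exon list")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon start {s} > end {e}"
                )
            if s < 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon start {s} < 1"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[tuple[int, int]],
    ) -> "TranscriptRecord":
        """Build a record, sorting exons and merging overlaps with a warning."""
        raw = list(exons)
        merged = merge_exons(raw)
        if len(merged) != len(raw):
            logger.warning(
                "transcript %s: merged %d overlapping exon(s)",
                transcript_id,
                len(raw) - len(merged),
            )
        return cls(transcript_id, gene_id, chrom, strand, merged)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        """Mature transcript length: sum of exon widths."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class GeneLocus:
    """Per-gene genomic interval (union span of its transcripts) with a biotype."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "undefined"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.gene_id}: bad biotype {self.biotype!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id}: bad interval {self.start}-{self.end}"
            )

    @property
    def location(self) -> str:
        """``chrN:start-end`` display form."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values plus a two-level sample -> group map.

    ``values`` is a pandas DataFrame indexed by gene_id with sample-id columns;
    ``groups`` maps every sample id to ``"control"`` or ``"case"``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="gene_id", columns=None)
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicated gene_id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicated sample_id {dup!r}")
        arr = df.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        missing = [s for s in df.columns if s not in self.groups]
        if missing:
            raise ConfigurationError(f"samples missing from group map: {missing}")
        bad = {g for g in self.groups.values() if g not in GROUP_LABELS}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        for label in GROUP_LABELS:
            if not any(self.groups[s] == label for s in df.columns):
                raise ValidationError(f"group {label!r} has no samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path, attribute_dialect: str = "ensembl-like") -> list[TranscriptRecord]:
    """Read transcript models from a GTF file.

    Only ``exon`` features are used; one :class:`TranscriptRecord` is returned
    per distinct ``transcript_id``, exons sorted by start (overlapping exons
    within a transcript are merged with a warning).  Records come back grouped
    in first-appearance order of their transcript ids.
    """
    if attribute_dialect != "ensembl-like":
        raise ConfigurationError(f"unknown attribute dialect {attribute_dialect!r}")
    path = Path(path)
    # transcript_id -> [gene_id, chrom, strand, [exons]]
    acc: dict[str, list] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path.name} line {lineno}: expected >=9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name} line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start > end:
                raise GtfParseError(f"{path.name} line {lineno}: start {start} > end {end}")
            if strand not in STRANDS:
                raise GtfParseError(f"{path.name} line {lineno}: bad strand {strand!r}")
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            gid = attributes.get("gene_id")
            if not tid:
                raise GtfParseError(f"{path.name} line {lineno}: exon missing transcript_id")
            if not gid:
                raise GtfParseError(f"{path.name} line {lineno}: exon missing gene_id")
            if tid not in acc:
                acc[tid] = [gid, chrom, strand, []]
            else:
                prev = acc[tid]
                if prev[0] != gid or prev[1] != chrom or prev[2] != strand:
                    raise GtfParseError(
                        f"{path.name} line {lineno}: transcript {tid} has conflicting "
                        "gene_id/chrom/strand across exon rows"
                    )
            acc[tid][3].append((start, end))
    return [
        TranscriptRecord.from_exons(tid, gid, chrom, strand, exons)
        for tid, (gid, chrom, strand, exons) in acc.items()
    ]


def write_gtf(records: Sequence[TranscriptRecord], path: str | Path, source: str = "hepalnc") -> None:
    """Write transcripts as exon rows; inverse of :func:`read_gtf`."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            for s, e in rec.exons:
                attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
                fh.write(
                    f"{rec.chrom}\t{source}\texon\t{s}\t{e}\t.\t{rec.strand}\t.\t{attrs}\n"
                )


def genes_from_transcripts(
    transcripts: Sequence[TranscriptRecord],
    biotypes: Mapping[str, str] | None = None,
) -> list[GeneLocus]:
    """Collapse transcripts to per-gene union-span loci.

    A gene's interval is (min transcript start, max transcript end).  Genes
    whose transcripts sit on different chromosomes are rejected; conflicting
    strands collapse to ``"."`` with a warning.  ``biotypes`` may be partial;
    unlisted genes get ``"undefined"``.  Output is sorted by (chrom, start,
    gene_id) for determinism.
    """
    biotypes = dict(biotypes or {})
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    loci = []
    for gid, ts in by_gene.items():
        chroms = {t.chrom for t in ts}
        if len(chroms) > 1:
            raise ConsistencyError(f"gene {gid} spans chromosomes {sorted(chroms)}")
        strands = {t.strand for t in ts}
        if len(strands) == 1:
            strand = strands.pop()
        else:
            logger.warning("gene %s: conflicting strands %s; using '.'", gid, sorted(strands))
            strand = "."
        loci.append(
            GeneLocus(
                gene_id=gid,
                chrom=chroms.pop(),
                strand=strand,
                start=min(t.start for t in ts),
                end=max(t.end for t in ts),
                biotype=biotypes.get(gid, "undefined"),
            )
        )
    loci.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return loci


# ---------------------------------------------------------------------------
# Expression matrices and score tables
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV (first column gene_id, header of sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValidationError(f"non-numeric cell at gene {row!r}, sample {col!r}")
    return ExpressionMatrix(values=df.astype(float), groups=dict(group_map))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(Path(path), sep="\t", index_label="gene_id")


def read_coding_scores(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of transcript_id and coding-potential score."""
    scores: dict[str, float] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path.name} line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0] in ("transcript_id", "id"):
                continue
            try:
                value = float(parts[1])
            except ValueError:
                raise ValidationError(
                    f"{path.name} line {lineno}: non-numeric score {parts[1]!r}"
                ) from None
            if not math.isfinite(value):
                raise ValidationError(f"{path.name} line {lineno}: non-finite score")
            scores[parts[0]] = value
    return scores


def write_coding_scores(scores: Mapping[str, float], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("transcript_id\tscore\n")
        for tid, value in scores.items():
            fh.write(f"{tid}\t{value:.6g}\n")
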