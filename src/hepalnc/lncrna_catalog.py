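"""Transcript classification against reference annotation and the novel-lncRNA filter.

Assembled transcripts are split into known coding / known noncoding / novel /
undefined by a same-strand exonic-overlap rule (a documented simplification of
assembler class codes): a transcript sharing at least one same-strand exonic
base with a reference coding transcript is ``known_coding``; failing that, the
same rule against the reference noncoding set gives ``known_noncoding``; a
transcript overlapping no reference exon and no reference transcript span is
``novel``; anything else (antisense-only or intron-only overlap) is
``undefined``.

Novel transcripts then pass a three-rule lncRNA filter: spliced length >= 200
nt, exon count >= 2 (both inclusive), and coding-potential score strictly < 0.
Fail reasons are recorded in that fixed order, one per transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import ValidationError
from .io_models import TranscriptRecord

CATEGORIES = ("known_coding", "known_noncoding", "novel", "undefined")
VERDICTS = ("pass", "fail_length", "fail_exons", "fail_score", "fail_no_score")


@dataclass(frozen=True)
class ClassifiedTranscript:
    record: TranscriptRecord
    category: str
    filter_verdict: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"bad category {self.category!r}")
        if self.filter_verdict is not None:
            if self.category != "novel":
                raise ValidationError("filter_verdict only applies to novel transcripts")
            if self.filter_verdict not in VERDICTS:
                raise ValidationError(f"bad verdict {self.filter_verdict!r}")


@dataclass
class StructureSummary:
    """Histograms of transcripts per gene and exons per transcript."""

    transcripts_per_gene: dict[int, int]
    exons_per_transcript: dict[int, int]
    n_unique_isoform: int
    n_alternative_splicing: int

    @property
    def n_genes(self) -> int:
        return sum(self.transcripts_per_gene.values())

    @property
    def n_transcripts(self) -> int:
        return sum(self.exons_per_transcript.values())

    def to_dict(self) -> dict:
        return {
            "transcripts_per_gene": {str(k): v for k, v in sorted(self.transcripts_per_gene.items())},
            "exons_per_transcript": {str(k): v for k, v in sorted(self.exons_per_transcript.items())},
            "n_genes": self.n_genes,
            "n_transcripts": self.n_transcripts,
            "n_unique_isoform": self.n_unique_isoform,
            "n_alternative_splicing": self.n_alternative_splicing,
        }


class _ReferenceIndex:
    """Interval trees over reference exons (per strand) and transcript spans."""

    def __init__(self, refs: Iterable[TranscriptRecord]):
        self.exons: dict[tuple[str, str], IntervalTree] = {}
        self.any_exons: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        for t in refs:
            strands = ("+", "-") if t.strand == "." else (t.strand,)
            for s, e in t.exons:
                for st in strands:
                    self.exons.setdefault((t.chrom, st), IntervalTree()).addi(s, e + 1)
                self.any_exons.setdefault(t.chrom, IntervalTree()).addi(s, e + 1)
            self.spans.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end + 1)

    def same_strand_exonic(self, t: TranscriptRecord) -> bool:
        strands = ("+", "-") if t.strand == "." else (t.strand,)
        for st in strands:
            tree = self.exons.get((t.chrom, st))
            if tree is None:
                continue
            for s, e in t.exons:
                if tree.overlaps(s, e + 1):
                    return True
        return False

    def any_exonic(self, t: TranscriptRecord) -> bool:
        tree = self.any_exons.get(t.chrom)
        return tree is not None and any(tree.overlaps(s, e + 1) for s, e in t.exons)

    def span_overlap(self, t: TranscriptRecord) -> bool:
        tree = self.spans.get(t.chrom)
        return tree is not None and tree.overlaps(t.start, t.end + 1)


def classify_transcripts(
    assembled: Sequence[TranscriptRecord],
    ref_coding: Sequence[TranscriptRecord],
    ref_noncoding: Sequence[TranscriptRecord],
) -> list[ClassifiedTranscript]:
    """Assign each assembled transcript exactly one category.

    Strand ``"."`` on either side is treated as compatible with both strands.
    Deterministic and order-independent; duplicating reference transcripts
    cannot change the outcome.
    """
    coding_idx = _ReferenceIndex(ref_coding)
    noncoding_idx = _ReferenceIndex(ref_noncoding)
    out = []
    for t in assembled:
        if coding_idx.same_strand_exonic(t):
            category = "known_coding"
        elif noncoding_idx.same_strand_exonic(t):
            category = "known_noncoding"
        elif (
            coding_idx.any_exonic(t)
            or noncoding_idx.any_exonic(t)
            or coding_idx.span_overlap(t)
            or noncoding_idx.span_overlap(t)
        ):
            category = "undefined"
        else:
            category = "novel"
        out.append(ClassifiedTranscript(record=t, category=category))
    return out


def filter_novel_lncrnas(
    novel: Sequence[TranscriptRecord],
    scores: Mapping[str, float],
    min_length: int = 200,
    min_exons: int = 2,
    max_score_exclusive: float = 0.0,
) -> list[ClassifiedTranscript]:
    """Apply the three-rule novel-lncRNA filter and record per-transcript verdicts.

    Pass requires spliced_length >= ``min_length`` AND exon_count >=
    ``min_exons`` (inclusive) AND score strictly < ``max_score_exclusive``.
    Transcripts without a score fail with ``fail_no_score``.  The first failing
    rule in the order length -> exons -> score is the one recorded.
    """
    out = []
    for t in novel:
        if t.spliced_length < min_length:
            verdict = "fail_length"
        elif t.exon_count < min_exons:
            verdict = "fail_exons"
        elif t.transcript_id not in scores:
            verdict = "fail_no_score"
        elif not scores[t.transcript_id] < max_score_exclusive:
            verdict = "fail_score"
        else:
            verdict = "pass"
        out.append(ClassifiedTranscript(record=t, category="novel", filter_verdict=verdict))
    return out


def summarize_structure(transcripts: Sequence[TranscriptRecord]) -> StructureSummary:
    """Histogram transcript multiplicity per gene and exon count per transcript."""
    if not transcripts:
        raise ValidationError("summarize_structure: empty transcript list")
    per_gene = Counter(t.gene_id for t in transcripts)
    tpg = Counter(per_gene.values())
    ept = Counter(t.exon_count for t in transcripts)
    n_unique = sum(1 for n in per_gene.values() if n == 1)
    return StructureSummary(
        transcripts_per_gene=dict(tpg),
        exons_per_transcript=dict(ept),
        n_unique_isoform=n_unique,
        n_alternative_splicing=len(per_gene) - n_unique,
    )
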