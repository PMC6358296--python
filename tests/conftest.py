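"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import strategies as st

from hepalnc.io_models import ExpressionMatrix, GeneLocus, TranscriptRecord


@st.composite
def exon_chains(draw, max_exons: int = 5):
    """Non-overlapping, non-touching exon chains (gaps >= 2 so no merging occurs)."""
    n = draw(st.integers(1, max_exons))
    start = draw(st.integers(1, 1000))
    exons = []
    pos = start
    for _ in range(n):
        width = draw(st.integers(1, 500))
        exons.append((pos, pos + width - 1))
        pos += width + draw(st.integers(2, 300))
    return tuple(exons)


@st.composite
def transcript_records(draw, transcript_id: str | None = None, gene_id: str | None = None):
    tid = transcript_id or draw(st.from_regex(r"T[0-9]{1,6}", fullmatch=True))
    gid = gene_id or draw(st.from_regex(r"G[0-9]{1,4}", fullmatch=True))
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gid,
        chrom=draw(st.sampled_from(["chr1", "chr2", "chrX"])),
        strand=draw(st.sampled_from(["+", "-", "."])),
        exons=draw(exon_chains()),
    )


@st.composite
def gene_loci(draw, chrom: str | None = None):
    start = draw(st.integers(1, 10_000_000))
    length = draw(st.integers(1, 100_000))
    return GeneLocus(
        gene_id=draw(st.from_regex(r"G[0-9]{1,5}", fullmatch=True)),
        chrom=chrom or draw(st.sampled_from(["chr1", "chr2"])),
        strand=draw(st.sampled_from(["+", "-", "."])),
        start=start,
        end=start + length - 1,
    )


def make_matrix(values: np.ndarray, n_control: int = 3, n_case: int = 3, gene_ids=None) -> ExpressionMatrix:
    """Wrap an array (genes x samples) in a validated ExpressionMatrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"ctrl_{i + 1}" for i in range(n_control)] + [f"case_{i + 1}" for i in range(n_case)]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=gene_ids, columns=samples)
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}
    return ExpressionMatrix(values=df, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20180930)
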