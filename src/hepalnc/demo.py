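"""Bundled worked example: published mouse-liver cis pair coordinates (mm9).

Six lncRNA / protein-coding cis pairs reported from a high-fat-diet mouse
liver RNA-seq screen, over five lncRNAs and five coding genes: one lncRNA is
flanked by two coding partners (G0s2 upstream, Lamb3 downstream) and two
lncRNAs share the coding partner Elovl5.  Every nearest-edge distance is
within the 100 kb juxtaposition window, which makes the set a compact
end-to-end exercise for the distance and pairing operations.

The expression side of the example is synthetic (:func:`monotone_expression`
builds a matrix in which every gene pair is perfectly rank-correlated); only
the coordinates are real.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_models import ExpressionMatrix, GeneLocus

DEMO_LNCRNAS = ("NONMMUG002873", "NONMMUG027912", "XLOC_015129", "NONMMUG043402", "NONMMUG043404")
DEMO_CODING = ("G0s2", "Lamb3", "Elovl6", "Mgll", "Elovl5")

DEMO_LOCI: tuple[GeneLocus, ...] = (
    GeneLocus("NONMMUG002873", "chr1", ".", 195_107_465, 195_110_037),
    GeneLocus("G0s2", "chr1", ".", 195_098_354, 195_099_382),
    GeneLocus("Lamb3", "chr1", ".", 195_128_188, 195_170_072),
    GeneLocus("NONMMUG027912", "chr3", ".", 129_227_397, 129_235_123),
    GeneLocus("Elovl6", "chr3", ".", 129_235_304, 129_341_411),
    GeneLocus("XLOC_015129", "chr6", ".", 88_666_181, 88_672_200),
    GeneLocus("Mgll", "chr6", ".", 88_674_406, 88_778_354),
    GeneLocus("NONMMUG043402", "chr9", ".", 77_654_220, 77_678_796),
    GeneLocus("Elovl5", "chr9", ".", 77_765_172, 77_832_326),
    GeneLocus("NONMMUG043404", "chr9", ".", 77_690_504, 77_699_685),
)

# (lncRNA, coding gene) members of the six reported pairs
DEMO_PAIRS: tuple[tuple[str, str], ...] = (
    ("NONMMUG002873", "G0s2"),
    ("NONMMUG002873", "Lamb3"),
    ("NONMMUG027912", "Elovl6"),
    ("XLOC_015129", "Mgll"),
    ("NONMMUG043402", "Elovl5"),
    ("NONMMUG043404", "Elovl5"),
)


def demo_loci() -> list[GeneLocus]:
    return list(DEMO_LOCI)


def monotone_expression(seed: int = 0, n_control: int = 3, n_case: int = 3) -> ExpressionMatrix:
    """Synthetic 3-vs-3 FPKM matrix over the demo genes with all-pairs rho = 1.

    Every gene's profile is a different strictly increasing transform of one
    shared strictly increasing sample profile, so every Spearman correlation
    is exactly 1 while the FPKM values themselves vary by gene.
    """
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    base = np.cumsum(rng.uniform(0.5, 2.0, size=n))  # strictly increasing
    gene_ids = [g.gene_id for g in DEMO_LOCI]
    rows = []
    for _ in gene_ids:
        scale = rng.uniform(1.0, 20.0)
        offset = rng.uniform(0.0, 5.0)
        rows.append(offset + scale * base)
    samples = [f"ctrl_{i + 1}" for i in range(n_control)] + [f"case_{i + 1}" for i in range(n_case)]
    values = pd.DataFrame(np.array(rows), index=gene_ids, columns=samples)
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}
    return ExpressionMatrix(values=values, groups=groups)
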