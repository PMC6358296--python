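"""Self-contained synthetic datasets with planted signals and truth tables.

The generator emulates the statistical structure the downstream inference
assumes: a small two-group design (3 vs 3 liver samples by default), log-scale
FPKM expression (normal on log2, i.e. log-normal on the natural scale),
group fold-change shifts planted on chosen genes, and lncRNA-mRNA pairs whose
members (a) sit within a configurable genomic distance of each other and
(b) share a per-pair latent factor that induces monotone coexpression.

For each gene g and sample s:

    log2 FPKM = mu_g + shift_g * [s is case] + sum_pairs w_p * z_{p,s} + N(0, sd)

with mu_g uniform over a baseline range, one standard-normal latent draw
z_{p,s} per planted pair per sample, and iid noise.  It does not model
counts, library-size effects, or real genome coordinates.

Gene structure (which genes are lncRNAs, which lncRNAs are already annotated
vs novel candidates) is a deterministic function of the gene index, so preset
builders can reference gene ids before any random draw; randomness drives
only geometry (lengths, gaps, exon chains) and expression.  All randomness
flows from the single config seed through named generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io_models import (
    ExpressionMatrix,
    GeneLocus,
    TranscriptRecord,
    write_coding_scores,
    write_expression_matrix,
    write_gtf,
)

MIN_EXON_BP = 100
MIN_INTRON_BP = 30
MAX_EXONS = 8

PRESETS = ("null", "paper_like", "stress")


@dataclass(frozen=True)
class PlantedPair:
    """A lncRNA-coding gene pair to plant: genomic gap and coexpression strength."""

    lncrna_id: str
    coding_id: str
    target_gap_bp: int
    latent_weight: float = 1.0
    lncrna_known: bool = True  # False: the lncRNA is a novel candidate with a score

    def __post_init__(self) -> None:
        if self.target_gap_bp < 0:
            raise ConfigurationError("target_gap_bp must be >= 0")
        if not 0.0 <= self.latent_weight <= 1.0:
            raise ConfigurationError("latent_weight must be in [0, 1]")


@dataclass
class SimulationConfig:
    n_chromosomes: int = 3
    genes_per_chromosome: int = 50
    n_control: int = 3
    n_case: int = 3
    baseline_log2_mean_range: tuple[float, float] = (2.0, 6.0)
    noise_sd: float = 0.25
    planted_degs: list[tuple[str, float]] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    gene_length_range: tuple[int, int] = (2_000, 30_000)
    intergenic_gap_range: tuple[int, int] = (5_000, 50_000)
    lncrna_every: int = 8  # every k-th background gene is a lncRNA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ConfigurationError("need at least 2 samples per group")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gene_length_range[0] < MAX_EXONS * MIN_EXON_BP + (MAX_EXONS - 1) * MIN_INTRON_BP:
            raise ConfigurationError("minimum gene length too small for the exon model")
        if self.lncrna_every < 2:
            raise ConfigurationError("lncrna_every must be >= 2")
        seen: set[str] = set()
        for p in self.planted_pairs:
            seen.update((p.lncrna_id, p.coding_id))


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests."""

    degs: pd.DataFrame  # gene_id, log2_fc
    pairs: pd.DataFrame  # lncrna_id, coding_id, target_gap_bp, latent_weight
    gene_meta: pd.DataFrame  # gene_id, biotype (lncRNA/coding), known

    def biotype_classes(self) -> dict[str, str]:
        """gene_id -> lncRNA/coding map for stratification."""
        return dict(zip(self.gene_meta["gene_id"], self.gene_meta["biotype"]))


@dataclass
class Annotation:
    """Generated transcript models, gene loci, and reference/score side tables."""

    transcripts: list[TranscriptRecord]
    loci: list[GeneLocus]
    gene_meta: pd.DataFrame  # gene_id, chrom, biotype, known
    coding_scores: dict[str, float]  # novel transcripts only (negative = noncoding)

    def reference_coding(self) -> list[TranscriptRecord]:
        known_coding = set(
            self.gene_meta.loc[
                (self.gene_meta.biotype == "coding") & self.gene_meta.known, "gene_id"
            ]
        )
        return [t for t in self.transcripts if t.gene_id in known_coding]

    def reference_noncoding(self) -> list[TranscriptRecord]:
        known_nc = set(
            self.gene_meta.loc[
                (self.gene_meta.biotype == "lncRNA") & self.gene_meta.known, "gene_id"
            ]
        )
        return [t for t in self.transcripts if t.gene_id in known_nc]


def _background_meta(config: SimulationConfig) -> list[tuple[str, int, str, bool]]:
    """Deterministic (gene_id, chrom_index, biotype, known) for background genes."""
    out = []
    for c in range(1, config.n_chromosomes + 1):
        for i in range(config.genes_per_chromosome):
            gid = f"G{c:02d}_{i:03d}"
            if i % config.lncrna_every == 0:
                biotype = "lncRNA"
                known = (i // config.lncrna_every) % 2 == 0
            else:
                biotype, known = "coding", True
            out.append((gid, c, biotype, known))
    return out


def background_gene_ids(config: SimulationConfig, biotype: str) -> list[str]:
    """Background gene ids of one biotype, in layout order (for preset building)."""
    return [gid for gid, _c, b, _k in _background_meta(config) if b == biotype]


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------


def _pair_components(pairs: Sequence[PlantedPair]) -> list[list[PlantedPair]]:
    """Group pairs sharing a member into components (stars only)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        parent[find(p.lncrna_id)] = find(p.coding_id)
    comps: dict[str, list[PlantedPair]] = {}
    for p in pairs:
        comps.setdefault(find(p.lncrna_id), []).append(p)
    return list(comps.values())


def _place_component(
    comp: Sequence[PlantedPair], lengths: dict[str, int]
) -> dict[str, tuple[int, int]]:
    """Relative 0-based offsets for a pair component.

    Simple pairs anchor on the coding gene with the lncRNA downstream.  Star
    components (one shared member, as when one lncRNA flanks two coding genes)
    alternate partners upstream/downstream of the center.  Longer chains of
    sharing are not supported.
    """

    def rel(anchor: tuple[int, int], length: int, gap: int, downstream: bool) -> tuple[int, int]:
        if downstream:
            start = anchor[1] + gap if gap > 0 else anchor[1]  # gap 0: overlap by 1 bp
            return start, start + length - 1
        end = anchor[0] - gap if gap > 0 else anchor[0]
        return end - length + 1, end

    placed: dict[str, tuple[int, int]] = {}
    if len(comp) == 1:
        p = comp[0]
        placed[p.coding_id] = (0, lengths[p.coding_id] - 1)
        placed[p.lncrna_id] = rel(placed[p.coding_id], lengths[p.lncrna_id], p.target_gap_bp, True)
    else:
        from collections import Counter

        degree = Counter()
        for p in comp:
            degree[p.lncrna_id] += 1
            degree[p.coding_id] += 1
        centers = [g for g, d in degree.items() if d > 1]
        if len(centers) != 1:
            raise ConfigurationError(
                "planted pair components must be stars (exactly one shared gene); "
                f"got shared genes {centers}"
            )
        center = centers[0]
        placed[center] = (0, lengths[center] - 1)
        for k, p in enumerate(comp):
            partner = p.coding_id if p.lncrna_id == center else p.lncrna_id
            placed[partner] = rel(placed[center], lengths[partner], p.target_gap_bp, k % 2 == 1)
    # reject overlapping placements among distinct genes of the component
    items = sorted(placed.items(), key=lambda kv: kv[1])
    for (ga, (sa, ea)), (gb, (sb, eb)) in zip(items, items[1:]):
        if sb <= ea and sa <= eb and not _pair_exists(comp, ga, gb):
            raise ConfigurationError(
                f"layout infeasible: planted genes {ga} and {gb} would overlap"
            )
    return placed


def _pair_exists(comp: Sequence[PlantedPair], a: str, b: str) -> bool:
    return any({p.lncrna_id, p.coding_id} == {a, b} for p in comp)


def _make_exons(rng: np.random.Generator, start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    """Partition [start, end] into n_exons exons separated by introns.

    The first exon begins at ``start`` and the last ends at ``end`` so the
    transcript spans the interval exactly.  Minimum exon width 100 bp keeps
    every multi-exon transcript above the 200 nt spliced-length floor.
    """
    span = end - start + 1
    n_seg = 2 * n_exons - 1
    base = np.empty(n_seg, dtype=int)
    base[0::2] = MIN_EXON_BP
    base[1::2] = MIN_INTRON_BP
    slack = span - int(base.sum())
    if slack < 0:
        raise ConfigurationError(f"span {span} too small for {n_exons} exons")
    extra = rng.multinomial(slack, np.full(n_seg, 1.0 / n_seg)) if slack else np.zeros(n_seg, int)
    widths = base + extra
    exons = []
    pos = start
    for k, w in enumerate(widths):
        if k % 2 == 0:
            exons.append((pos, pos + w - 1))
        pos += w
    return exons


def _max_exons(span: int) -> int:
    return min(MAX_EXONS, (span + MIN_INTRON_BP) // (MIN_EXON_BP + MIN_INTRON_BP))


def _gene_transcripts(
    rng: np.random.Generator, gene_id: str, chrom: str, strand: str, start: int, end: int, is_lncrna: bool
) -> list[TranscriptRecord]:
    """1-3 transcripts; the first spans the gene exactly (locus span == placement)."""
    span = end - start + 1
    min_exons = 2 if is_lncrna else 1
    n_transcripts = int(rng.integers(1, 4))
    records = []
    for j in range(n_transcripts):
        if j == 0:
            s, e = start, end
        else:
            trim = max(span // 4, 1)
            s = start + int(rng.integers(0, trim))
            e = end - int(rng.integers(0, trim))
        hi = _max_exons(e - s + 1)
        lo = min(min_exons, hi)
        m = int(rng.integers(lo, hi + 1))
        records.append(
            TranscriptRecord(
                transcript_id=f"{gene_id}.t{j + 1}",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(_make_exons(rng, s, e, m)),
            )
        )
    return records


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out genes left-to-right per chromosome and emit transcript models.

    Planted pairs are placed first on round-robin chromosomes with their
    requested nearest-edge gap reproduced exactly (the first transcript of
    every gene spans its full locus); background genes follow with uniform
    intergenic gaps.  Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    glo, ghi = config.gene_length_range
    ilo, ihi = config.intergenic_gap_range

    pair_meta: dict[str, tuple[str, bool]] = {}  # gene_id -> (biotype, known)
    for p in config.planted_pairs:
        pair_meta[p.lncrna_id] = ("lncRNA", p.lncrna_known)
        pair_meta[p.coding_id] = ("coding", True)

    cursors = {c: 1 for c in range(1, config.n_chromosomes + 1)}
    placements: list[tuple[str, int, int, int]] = []  # gene_id, chrom_idx, start, end

    for k, comp in enumerate(_pair_components(config.planted_pairs)):
        c = (k % config.n_chromosomes) + 1
        comp_lengths = {}
        for p in comp:
            for gid in (p.lncrna_id, p.coding_id):
                if gid not in comp_lengths:
                    comp_lengths[gid] = int(rng.integers(glo, ghi + 1))
        rel = _place_component(comp, comp_lengths)
        shift = cursors[c] - min(s for s, _e in rel.values())
        for gid, (s, e) in rel.items():
            placements.append((gid, c, s + shift, e + shift))
        cursors[c] = max(e for _s, e in rel.values()) + shift + int(rng.integers(ilo, ihi + 1))

    background = _background_meta(config)
    for gid, c, biotype, known in background:
        length = int(rng.integers(glo, ghi + 1))
        start = cursors[c]
        placements.append((gid, c, start, start + length - 1))
        cursors[c] = start + length + int(rng.integers(ilo, ihi + 1))

    meta_rows = []
    transcripts: list[TranscriptRecord] = []
    loci: list[GeneLocus] = []
    scores: dict[str, float] = {}
    background_meta = {gid: (b, k) for gid, _c, b, k in background}
    for gid, c, start, end in placements:
        biotype, known = pair_meta.get(gid) or background_meta[gid]
        strand = str(rng.choice(["+", "-"]))
        chrom = f"chr{c}"
        recs = _gene_transcripts(rng, gid, chrom, strand, start, end, biotype == "lncRNA")
        transcripts.extend(recs)
        if biotype == "lncRNA" and not known:
            for t in recs:
                scores[t.transcript_id] = float(-0.1 - abs(rng.normal(1.0, 0.5)))
        locus_biotype = (
            "coding"
            if biotype == "coding"
            else ("known_lncRNA" if known else "novel_lncRNA")
        )
        loci.append(
            GeneLocus(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end, biotype=locus_biotype)
        )
        meta_rows.append({"gene_id": gid, "chrom": chrom, "biotype": biotype, "known": known})

    gene_meta = pd.DataFrame(meta_rows)
    return Annotation(transcripts=transcripts, loci=loci, gene_meta=gene_meta, coding_scores=scores)


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------


def generate_expression(
    config: SimulationConfig, annotation: Annotation
) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw the FPKM matrix from the latent-factor log-normal model."""
    gene_ids = list(annotation.gene_meta["gene_id"])
    id_to_row = {g: i for i, g in enumerate(gene_ids)}
    for gid, _fc in config.planted_degs:
        if gid not in id_to_row:
            raise ConfigurationError(f"planted DEG {gid!r} not in annotation")
    for p in config.planted_pairs:
        for gid in (p.lncrna_id, p.coding_id):
            if gid not in id_to_row:
                raise ConfigurationError(f"planted pair gene {gid!r} not in annotation")

    rng = np.random.default_rng([config.seed, 1])
    n_genes = len(gene_ids)
    samples = [f"ctrl_{i + 1}" for i in range(config.n_control)] + [
        f"case_{i + 1}" for i in range(config.n_case)
    ]
    n_samples = len(samples)
    case_ind = np.array([0] * config.n_control + [1] * config.n_case, dtype=float)

    lo, hi = config.baseline_log2_mean_range
    mu = rng.uniform(lo, hi, size=n_genes)
    log2x = np.tile(mu[:, None], (1, n_samples))
    for gid, fc in config.planted_degs:
        log2x[id_to_row[gid]] += fc * case_ind
    # One latent factor per connected component of the pair graph: for
    # disjoint pairs this is exactly one factor per pair; when pairs share a
    # member (one lncRNA with two coding partners or vice versa) the shared
    # gene would otherwise accumulate several factors and decorrelate from
    # each partner even at zero noise.  A gene's loading is the largest
    # latent_weight over its pairs.
    for comp in _pair_components(config.planted_pairs):
        z = rng.standard_normal(n_samples)
        weights: dict[str, float] = {}
        for p in comp:
            for gid in (p.lncrna_id, p.coding_id):
                weights[gid] = max(weights.get(gid, 0.0), p.latent_weight)
        for gid, w in weights.items():
            log2x[id_to_row[gid]] += w * z
    if config.noise_sd > 0:
        log2x += rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    values = pd.DataFrame(np.power(2.0, log2x), index=gene_ids, columns=samples)
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}
    matrix = ExpressionMatrix(values=values, groups=groups)

    truth = TruthTable(
        degs=pd.DataFrame(config.planted_degs, columns=["gene_id", "log2_fc"]),
        pairs=pd.DataFrame(
            [
                {
                    "lncrna_id": p.lncrna_id,
                    "coding_id": p.coding_id,
                    "target_gap_bp": p.target_gap_bp,
                    "latent_weight": p.latent_weight,
                }
                for p in config.planted_pairs
            ],
            columns=["lncrna_id", "coding_id", "target_gap_bp", "latent_weight"],
        ),
        gene_meta=annotation.gene_meta.copy(),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Planted gaps for the paper_like preset echo the geometry of published mouse
# liver cis pairs: two coding partners flanking one lncRNA, two lncRNAs
# sharing one coding partner, gaps from 181 bp to 86 kb (all within 100 kb).
_PAPER_LIKE_GAPS = [
    ("PL_LNC1", "PL_COD1", 8_083, True),
    ("PL_LNC1", "PL_COD2", 18_151, True),
    ("PL_LNC2", "PL_COD3", 181, True),
    ("PL_LNC3", "PL_COD4", 2_206, False),
    ("PL_LNC4", "PL_COD5", 86_376, True),
    ("PL_LNC5", "PL_COD5", 65_487, False),
]


def scenario_presets(name: str) -> SimulationConfig:
    """Named study-shaped configurations with fixed, documented seeds.

    ``null``: no planted signal, for calibration checks.  ``paper_like``: a
    ~2,000-gene transcriptome (a scaled-down stand-in for a genome-wide mouse
    liver assembly), 3 vs 3 samples, 30 planted lncRNA DEGs and 250 planted
    coding DEGs, and 6 planted cis pairs over 5 lncRNAs and 5 coding genes
    (one lncRNA with two coding partners, one coding gene with two lncRNA
    partners).  ``stress``: pairs straddling the 100 kb boundary.
    """
    if name == "null":
        return SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=100, noise_sd=0.5, seed=101
        )
    if name == "paper_like":
        config = SimulationConfig(
            n_chromosomes=8,
            genes_per_chromosome=250,
            noise_sd=0.25,
            lncrna_every=16,
            seed=2018,
        )
        pairs = [
            PlantedPair(l, c, gap, latent_weight=0.9, lncrna_known=known)
            for l, c, gap, known in _PAPER_LIKE_GAPS
        ]
        degs: list[tuple[str, float]] = []
        pair_genes: list[str] = []
        for p in pairs:
            for gid in (p.lncrna_id, p.coding_id):
                if gid not in pair_genes:
                    pair_genes.append(gid)
        # pair genes strongly induced, like the validated liver pairs
        degs.extend((gid, 5.0) for gid in pair_genes)
        lnc_ids = background_gene_ids(config, "lncRNA")[:25]
        cod_ids = background_gene_ids(config, "coding")[:245]
        magnitudes = (1.5, 2.0, 3.0)
        for idx, gid in enumerate(lnc_ids + cod_ids):
            sign = -1.0 if idx % 3 == 2 else 1.0
            degs.append((gid, sign * magnitudes[idx % len(magnitudes)]))
        config.planted_pairs = pairs
        config.planted_degs = degs
        return config
    if name == "stress":
        config = SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=50, noise_sd=0.25, seed=7
        )
        config.planted_pairs = [
            PlantedPair("ST_LNC1", "ST_COD1", 99_999, latent_weight=1.0),
            PlantedPair("ST_LNC2", "ST_COD2", 100_001, latent_weight=1.0),
        ]
        config.planted_degs = [
            ("ST_LNC1", 4.0),
            ("ST_COD1", 4.0),
            ("ST_LNC2", 4.0),
            ("ST_COD2", 4.0),
        ]
        return config
    raise ConfigurationError(f"unknown preset {name!r}; available: {PRESETS}")


# ---------------------------------------------------------------------------
# Config and dataset serialization
# ---------------------------------------------------------------------------


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["planted_pairs"] = [asdict(p) for p in config.planted_pairs]
    data["planted_degs"] = [[g, float(fc)] for g, fc in config.planted_degs]
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    data["planted_pairs"] = [PlantedPair(**p) for p in data.get("planted_pairs", [])]
    data["planted_degs"] = [(g, float(fc)) for g, fc in data.get("planted_degs", [])]
    for key in ("baseline_log2_mean_range", "gene_length_range", "intergenic_gap_range"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a full dataset in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    matrix, truth = generate_expression(config, annotation)
    paths = {
        "assembled_gtf": out / "assembled.gtf",
        "ref_coding_gtf": out / "ref_coding.gtf",
        "ref_noncoding_gtf": out / "ref_noncoding.gtf",
        "matrix": out / "expression.tsv",
        "scores": out / "coding_scores.tsv",
        "truth_degs": out / "truth_degs.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
        "gene_meta": out / "gene_meta.tsv",
        "config": out / "config.yaml",
    }
    write_gtf(annotation.transcripts, paths["assembled_gtf"])
    write_gtf(annotation.reference_coding(), paths["ref_coding_gtf"])
    write_gtf(annotation.reference_noncoding(), paths["ref_noncoding_gtf"])
    write_expression_matrix(matrix, paths["matrix"])
    write_coding_scores(annotation.coding_scores, paths["scores"])
    truth.degs.to_csv(paths["truth_degs"], sep="\t", index=False)
    truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    truth.gene_meta.to_csv(paths["gene_meta"], sep="\t", index=False)
    save_config(config, paths["config"])
    return paths
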