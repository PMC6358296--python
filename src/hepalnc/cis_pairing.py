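"""Coexpression plus genomic juxtaposition: pairing lncRNAs with coding genes.

Guilt-by-association annotation for lncRNAs: a differentially expressed
lncRNA is paired with a differentially expressed protein-coding gene when the
two are coexpressed (Spearman rho >= 0.8 with p < 0.05 across all samples,
rho >= 0.9 marking "strong" pairs) and genomically juxtaposed (nearest-edge
distance <= 100 kb on the same chromosome, strand-agnostic).

With only a handful of samples the t-approximation to Spearman's p is badly
off, so for n <= 8 the two-sided p-value is computed exactly by enumerating
all n! rank permutations: p = #{perm : |rho_perm| >= |rho_obs|} / n!.  Ties
are handled with average ranks, and the enumeration permutes the actual
(possibly tied) rank vector, so the exact p remains valid under ties.

Distances are printed in kb truncated toward zero: two decimals below 1 kb,
one decimal otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .io_models import ExpressionMatrix, GeneLocus

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 8
_FLOAT_SLACK = 1e-12


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    coding_id: str
    rho: float
    p_value: float
    distance_bp: int
    strength: str  # "strong" (rho >= 0.9) or "coexpressed" (0.8 <= rho < 0.9)


def genomic_distance(a: GeneLocus, b: GeneLocus) -> int | None:
    """Nearest-edge separation in bp; 0 for overlapping intervals, None across chromosomes.

    Symmetric, strand-agnostic, no +/-1 adjustment: for disjoint loci the
    distance is start of the downstream locus minus end of the upstream one.
    """
    if a.chrom != b.chrom:
        return None
    if a.start <= b.end and b.start <= a.end:
        return 0
    if a.end < b.start:
        return b.start - a.end
    return a.start - b.end


def format_distance_kb(distance_bp: int) -> str:
    """Display a bp distance in kb, truncated toward zero.

    Below 1 kb two decimals are kept, otherwise one (181 bp -> "0.18",
    86376 bp -> "86.3").  Truncation, not rounding.
    """
    if distance_bp < 0:
        raise ValidationError(f"negative distance {distance_bp}")
    if distance_bp < 1000:
        return f"{(distance_bp // 10) / 100:.2f}"
    return f"{(distance_bp // 100) / 10:.1f}"


# ---------------------------------------------------------------------------
# Correlation with exact small-n permutation p-values
# ---------------------------------------------------------------------------

_PERM_CACHE: dict[int, np.ndarray] = {}
_NULL_ABS_RHO_CACHE: dict[int, np.ndarray] = {}


def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n), identity first (lexicographic)."""
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(permutations(range(n))), dtype=np.intp)
    return _PERM_CACHE[n]


def _standardize(r: np.ndarray) -> np.ndarray | None:
    c = r - r.mean()
    norm = np.linalg.norm(c)
    if norm == 0:
        return None
    return c / norm


def exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Two-sided exact permutation p for the Spearman rho of two rank vectors.

    Enumerates all n! orderings of ``rank_y`` against the fixed ``rank_x``;
    valid for tied (average) ranks since the actual rank multiset is permuted.
    """
    n = len(rank_x)
    zx = _standardize(np.asarray(rank_x, dtype=float))
    cy = np.asarray(rank_y, dtype=float)
    zy = _standardize(cy)
    if zx is None or zy is None:
        raise ValidationError("constant vector: rho undefined")
    perms = _perm_matrix(n)
    rho_perm = (cy[perms] - cy.mean()) @ zx / np.linalg.norm(cy - cy.mean())
    rho_obs = float(zy @ zx)
    count = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - _FLOAT_SLACK))
    return count / factorial(n)


def _null_abs_rho(n: int) -> np.ndarray:
    """|rho| over all permutations for tie-free ranks of length n (sorted)."""
    if n not in _NULL_ABS_RHO_CACHE:
        ranks = np.arange(1, n + 1, dtype=float)
        z = _standardize(ranks)
        perms = _perm_matrix(n)
        rho = (ranks[perms] - ranks.mean()) @ z / np.linalg.norm(ranks - ranks.mean())
        _NULL_ABS_RHO_CACHE[n] = np.sort(np.abs(rho))
    return _NULL_ABS_RHO_CACHE[n]


def _exact_p_from_rho(rho_obs: float, n: int) -> float:
    """Exact two-sided p from the tie-free null distribution (lookup path)."""
    null = _null_abs_rho(n)
    count = len(null) - np.searchsorted(null, abs(rho_obs) - _FLOAT_SLACK, side="left")
    return float(count) / factorial(n)


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value for one gene pair.

    Spearman uses average ranks; for n <= 8 samples the p-value is exact by
    full permutation enumeration, beyond that the usual t-approximation is
    used.  Pearson p always comes from the t-approximation.  A constant
    vector makes rho undefined: the pair is reported as (nan, nan) with a
    warning so callers can skip it (not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need n >= 3 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: rho undefined; returning nan")
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method != "spearman":
        raise ConfigurationError(f"unknown correlation method {method!r}")
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    zx = _standardize(rank_x)
    zy = _standardize(rank_y)
    rho = float(zx @ zy)
    if n <= EXACT_P_MAX_N:
        p = exact_spearman_p(rank_x, rank_y)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# Pair finding
# ---------------------------------------------------------------------------


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def find_cis_pairs(
    de_lncrnas: Sequence[str],
    de_coding: Sequence[str],
    matrix: ExpressionMatrix,
    loci: Sequence[GeneLocus],
    r_coexpressed: float = 0.8,
    r_strong: float = 0.9,
    alpha: float = 0.05,
    max_distance: int = 100_000,
    method: str = "spearman",
) -> list[CisPair]:
    """Emit lncRNA-coding cis pairs passing correlation, significance and distance.

    The full lncRNA x coding correlation matrix is computed across all samples
    (both groups pooled); a pair is kept iff rho >= ``r_coexpressed``, p <
    ``alpha``, both loci share a chromosome, and their nearest-edge distance
    is <= ``max_distance``.  One lncRNA may pair with several coding genes and
    vice versa.  Genes whose expression is constant across samples are skipped
    with a warning.  Output is sorted by (chrom, lncRNA start, coding start).
    """
    de_lncrnas = list(dict.fromkeys(de_lncrnas))
    de_coding = list(dict.fromkeys(de_coding))
    if not de_lncrnas or not de_coding:
        return []
    locus_by_id = {g.gene_id: g for g in loci}
    for gid in list(de_lncrnas) + list(de_coding):
        if gid not in locus_by_id:
            raise ConfigurationError(f"gene {gid!r} has no locus")
        if gid not in matrix.values.index:
            raise ConfigurationError(f"gene {gid!r} missing from expression matrix")

    n = len(matrix.sample_ids)
    lnc_vals = matrix.values.loc[de_lncrnas].to_numpy(dtype=float)
    cod_vals = matrix.values.loc[de_coding].to_numpy(dtype=float)

    def usable(vals: np.ndarray, ids: list[str]) -> np.ndarray:
        ok = np.ptp(vals, axis=1) > 0
        for gid in np.asarray(ids)[~ok]:
            logger.warning("gene %s has constant expression; skipped in pairing", gid)
        return ok

    lnc_ok = usable(lnc_vals, de_lncrnas)
    cod_ok = usable(cod_vals, de_coding)

    if method == "pearson":
        base_l, base_c = lnc_vals, cod_vals
    elif method == "spearman":
        base_l, base_c = _rank_matrix(lnc_vals), _rank_matrix(cod_vals)
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")

    def standardize_rows(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(c, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return c / norms

    rho_mat = standardize_rows(base_l) @ standardize_rows(base_c).T

    lnc_ranks = _rank_matrix(lnc_vals) if method == "spearman" else None
    cod_ranks = _rank_matrix(cod_vals) if method == "spearman" else None
    tiefree_l = (
        np.array([len(np.unique(r)) == n for r in lnc_ranks]) if lnc_ranks is not None else None
    )
    tiefree_c = (
        np.array([len(np.unique(r)) == n for r in cod_ranks]) if cod_ranks is not None else None
    )

    pairs: list[CisPair] = []
    for i, lnc_id in enumerate(de_lncrnas):
        if not lnc_ok[i]:
            continue
        lnc_locus = locus_by_id[lnc_id]
        for j, cod_id in enumerate(de_coding):
            if not cod_ok[j]:
                continue
            rho = float(rho_mat[i, j])
            if rho < r_coexpressed:
                continue
            dist = genomic_distance(lnc_locus, locus_by_id[cod_id])
            if dist is None or dist > max_distance:
                continue
            if method == "pearson":
                _, p = stats.pearsonr(lnc_vals[i], cod_vals[j])
                p = float(p)
            elif n <= EXACT_P_MAX_N:
                if tiefree_l[i] and tiefree_c[j]:
                    p = _exact_p_from_rho(rho, n)
                else:
                    p = exact_spearman_p(lnc_ranks[i], cod_ranks[j])
            else:
                p = float(stats.spearmanr(lnc_vals[i], cod_vals[j]).pvalue)
            if not p < alpha:
                continue
            strength = "strong" if rho >= r_strong else "coexpressed"
            pairs.append(
                CisPair(
                    lncrna_id=lnc_id,
                    coding_id=cod_id,
                    rho=rho,
                    p_value=p,
                    distance_bp=int(dist),
                    strength=strength,
                )
            )
    pairs.sort(
        key=lambda pr: (
            locus_by_id[pr.lncrna_id].chrom,
            locus_by_id[pr.lncrna_id].start,
            locus_by_id[pr.coding_id].start,
        )
    )
    return pairs


def pairs_frame(pairs: Sequence[CisPair], loci: Sequence[GeneLocus]):
    """Tabular pair report: members, locations, distance (kb string and bp), rho, p."""
    import pandas as pd

    locus_by_id = {g.gene_id: g for g in loci}
    rows = []
    for p in pairs:
        rows.append(
            {
                "lncrna_id": p.lncrna_id,
                "lncrna_location": locus_by_id[p.lncrna_id].location,
                "coding_id": p.coding_id,
                "coding_location": locus_by_id[p.coding_id].location,
                "distance_kb": format_distance_kb(p.distance_bp),
                "distance_bp": p.distance_bp,
                "rho": p.rho,
                "p_value": p.p_value,
                "strength": p.strength,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            "lncrna_location",
            "coding_id",
            "coding_location",
            "distance_kb",
            "distance_bp",
            "rho",
            "p_value",
            "strength",
        ],
    )
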