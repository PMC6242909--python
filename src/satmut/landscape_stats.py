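"""Distribution-level statistics over a scored saturation scan.

Implements the threshold-band decomposition of the score distribution,
class-conditional score extraction against residue annotations, two-tailed
Wilcoxon rank-sum comparisons (normal approximation with midrank ties;
exact permutation enumeration below a size cutoff), Pearson correlation,
normalised positional profiles, and the codon-degeneracy analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import CODON_DEGENERACY, STANDARD_AAS
from .proteome_io import BACKGROUND, AnnotationSet, ValidationError
from .saturation_scan import ScoredScan

__all__ = [
    "ScoreDistributionSummary",
    "ComparisonResult",
    "PositionalProfile",
    "CodonDegeneracyResult",
    "band_fractions",
    "class_variant_mask",
    "class_scores",
    "ranksum_compare",
    "pearson_r",
    "positional_profile",
    "codon_degeneracy_analysis",
    "class_comparison_table",
]

#: p-values below this are reported via the underflow flag, never as 0.
P_UNDERFLOW = 1e-300


@dataclass(frozen=True)
class ScoreDistributionSummary:
    """Summary of a score distribution against ordered thresholds.

    ``partition`` is the full four-band decomposition
    (< t1, [t1, t2], (t2, t3], > t3) and always sums to 1; the three named
    fractions are the conventional neutral / likely-deleterious / extreme
    read-outs (scores < t1, > t2 and > t3 respectively).
    """

    class_label: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    thresholds: tuple[float, float, float]
    frac_below_t1: float
    frac_above_t2: float
    frac_above_t3: float
    partition: tuple[float, float, float, float]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-tailed rank-sum comparison between two score samples.

    ``statistic`` is the tie-corrected rank-sum z-statistic of sample *a*
    (antisymmetric under swapping); ``p`` is the two-tailed p-value, with
    ``p_underflow`` flagging values below 1e-300. ``direction`` is the sign
    of median(a) − median(b).
    """

    class_a: str
    class_b: str
    n_a: int
    n_b: int
    statistic: float
    p: float
    p_underflow: bool
    direction: int
    method: str

    @property
    def p_label(self) -> str:
        return "< 1e-300" if self.p_underflow else format(self.p, ".6g")


@dataclass(frozen=True)
class PositionalProfile:
    """Mean score binned by relative sequence position in [0, 1]."""

    n_bins: int
    edges: np.ndarray
    counts: np.ndarray
    means: np.ndarray


@dataclass(frozen=True)
class CodonDegeneracyResult:
    """Per-mutant-amino-acid mean scores vs genetic-code degeneracy."""

    mean_by_aa: dict[str, float]
    codon_count: dict[str, int]
    r: float
    p: float


def band_fractions(
    scores: Iterable[float],
    thresholds: Sequence[float] = (0.3, 0.6, 0.9),
    class_label: str = "all",
) -> ScoreDistributionSummary:
    """Decompose a score collection into threshold bands.

    Reports the fractions of scores strictly below ``t1`` and strictly
    above ``t2`` and ``t3``, plus a full partition that sums to 1.
    """
    values = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores,
                        dtype=float)
    if values.size == 0:
        raise ValidationError("band_fractions: empty score collection")
    t1, t2, t3 = thresholds
    if not (0 < t1 < t2 < t3 < 1):
        raise ValidationError(
            f"thresholds must be strictly increasing within (0, 1); got {thresholds}"
        )
    n = values.size
    below_t1 = float((values < t1).sum()) / n
    above_t2 = float((values > t2).sum()) / n
    above_t3 = float((values > t3).sum()) / n
    mid = float(((values >= t1) & (values <= t2)).sum()) / n
    high = float(((values > t2) & (values <= t3)).sum()) / n
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return ScoreDistributionSummary(
        class_label=class_label,
        n=int(n),
        mean=float(values.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        thresholds=(float(t1), float(t2), float(t3)),
        frac_below_t1=below_t1,
        frac_above_t2=above_t2,
        frac_above_t3=above_t3,
        partition=(below_t1, mid, high, above_t3),
    )


def class_variant_mask(
    scan: ScoredScan,
    annotations: AnnotationSet,
    category: str,
    class_label: str | None,
) -> np.ndarray:
    """Boolean row mask over ``scan.variants`` for an annotation class.

    A variant belongs to a class iff its wild-type position is covered by a
    record of that (category, class). ``class_label=None`` selects the
    category-level union (each variant counted once); ``"background"``
    selects positions covered by no record of the category.
    """
    out = np.zeros(len(scan), dtype=bool)
    background = class_label == BACKGROUND
    label = None if (background or class_label is None) else class_label
    for acc, view in scan.by_protein().items():
        mask = annotations.position_mask(acc, category, label)
        if background:
            mask = ~mask
        out[view.rows] = mask[view.positions - 1]
    return out


def class_scores(
    scan: ScoredScan,
    annotations: AnnotationSet,
    category: str,
    class_label: str | None,
) -> np.ndarray:
    """Scores of variants whose position carries (or, for ``"background"``,
    does not carry) an annotation class.

    A variant at a multiply-annotated residue contributes to every class
    covering its position; the category-level aggregate
    (``class_label=None``) is the union, without double counting.
    """
    return scan.scores[class_variant_mask(scan, annotations, category, class_label)]


def _exact_two_tailed_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact permutation two-tailed p for the rank-sum of sample a.

    Enumerates all assignments of the pooled midranks to group a;
    p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
    """
    eps = 1e-9
    n_le = 0
    n_ge = 0
    total = 0
    for combo in combinations(ranks.tolist(), n_a):
        w = sum(combo)
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def ranksum_compare(
    a: Iterable[float],
    b: Iterable[float],
    *,
    class_a: str = "a",
    class_b: str = "b",
    exact_cutoff: int = 12,
) -> ComparisonResult:
    """Two-tailed Wilcoxon rank-sum comparison of two samples.

    Large samples use the normal approximation with midrank ties and tie-
    corrected variance (no continuity correction). When the pooled size is
    at most ``exact_cutoff``, the p-value comes from exact permutation
    enumeration instead; the z-statistic is reported either way.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("ranksum_compare: both samples must be nonempty")
    n_a, n_b = int(a.size), int(b.size)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts.astype(float) ** 3 - tie_counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    z = 0.0 if var <= 0 else (w - mu) / math.sqrt(var)

    underflow = False
    if n <= exact_cutoff:
        p = _exact_two_tailed_p(ranks, n_a, w)
        method = "exact"
    else:
        method = "normal"
        log_p = math.log(2.0) + stats.norm.logsf(abs(z))
        if log_p < math.log(P_UNDERFLOW):
            underflow = True
            p = 0.0
        else:
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    diff = float(np.median(a) - np.median(b))
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return ComparisonResult(
        class_a=class_a,
        class_b=class_b,
        n_a=n_a,
        n_b=n_b,
        statistic=float(z),
        p=float(p),
        p_underflow=underflow,
        direction=direction,
        method=method,
    )


def pearson_r(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t-transform.

    Requires equal lengths ≥ 3 and nonzero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("pearson_r: length mismatch")
    if x.size < 3:
        raise ValidationError("pearson_r: need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_r: constant input")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def positional_profile(scan: ScoredScan, n_bins: int = 100) -> PositionalProfile:
    """Bin variant scores by relative sequence position.

    Relative position is (position − 1)/(L − 1), so the N-terminus maps to 0
    and the C-terminus to 1; length-1 proteins are excluded. Bins are
    half-open [i/n, (i+1)/n) with the last bin closed.
    """
    if n_bins < 2:
        raise ValidationError("positional_profile: n_bins must be >= 2")
    if len(scan) == 0:
        raise ValidationError("positional_profile: empty scan")
    bin_idx_parts: list[np.ndarray] = []
    score_parts: list[np.ndarray] = []
    for acc, view in scan.by_protein().items():
        length = scan.proteome[acc].length
        if length < 2:
            continue
        rel = (view.positions - 1) / (length - 1)
        idx = np.minimum(np.floor(rel * n_bins).astype(np.int64), n_bins - 1)
        bin_idx_parts.append(idx)
        score_parts.append(view.scores)
    if not bin_idx_parts:
        raise ValidationError("positional_profile: no proteins of length >= 2")
    bin_idx = np.concatenate(bin_idx_parts)
    scores = np.concatenate(score_parts)
    counts = np.bincount(bin_idx, minlength=n_bins)
    sums = np.bincount(bin_idx, weights=scores, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PositionalProfile(
        n_bins=n_bins,
        edges=np.linspace(0.0, 1.0, n_bins + 1),
        counts=counts,
        means=means,
    )


def codon_degeneracy_analysis(scan: ScoredScan) -> CodonDegeneracyResult:
    """Correlate per-mutant-amino-acid mean scores with codon degeneracy.

    The mean is the grand mean over all variants whose mutant is a given
    amino acid; degeneracy is the standard-code sense-codon count (Leu/Ser/
    Arg 6 … Met/Trp 1). Pearson r is computed over the 20 pairs.
    """
    mut_idx = scan.mut_idx
    scores = scan.scores
    counts = np.bincount(mut_idx, minlength=20)
    missing = [STANDARD_AAS[i] for i in range(20) if counts[i] == 0]
    if missing:
        raise ValidationError(
            f"codon_degeneracy_analysis: no variants into {', '.join(missing)}"
        )
    sums = np.bincount(mut_idx, weights=scores, minlength=20)
    means = sums / counts
    degeneracy = np.array([CODON_DEGENERACY[aa] for aa in STANDARD_AAS], dtype=float)
    r, p = pearson_r(means, degeneracy)
    return CodonDegeneracyResult(
        mean_by_aa={aa: float(means[i]) for i, aa in enumerate(STANDARD_AAS)},
        codon_count=dict(CODON_DEGENERACY),
        r=r,
        p=p,
    )


def class_comparison_table(
    scan: ScoredScan,
    annotations: AnnotationSet,
    categories: Sequence[str] | None = None,
    *,
    thresholds: Sequence[float] = (0.3, 0.6, 0.9),
    bh: bool = False,
) -> pd.DataFrame:
    """Per-class summaries and class-vs-background rank-sum comparisons.

    One row per (category, class) with at least one variant on each side.
    ``bh=True`` appends a Benjamini–Hochberg-adjusted column ``p_bh``
    (an extra convenience; the primary read-out is the raw p-value).
    """
    rows = []
    for category in categories or annotations.categories():
        bg = class_scores(scan, annotations, category, BACKGROUND)
        for label in annotations.class_labels(category):
            cls = class_scores(scan, annotations, category, label)
            if cls.size == 0 or bg.size == 0:
                continue
            comp = ranksum_compare(cls, bg, class_a=label, class_b=BACKGROUND)
            summary = band_fractions(cls, thresholds, class_label=label)
            rows.append(
                {
                    "category": category,
                    "class": label,
                    "n": comp.n_a,
                    "n_background": comp.n_b,
                    "mean": summary.mean,
                    "median": summary.median,
                    "frac_below_t1": summary.frac_below_t1,
                    "frac_above_t2": summary.frac_above_t2,
                    "frac_above_t3": summary.frac_above_t3,
                    "z": comp.statistic,
                    "p": comp.p,
                    "p_label": comp.p_label,
                    "direction": comp.direction,
                }
            )
    table = pd.DataFrame(rows)
    if bh and len(table):
        table["p_bh"] = stats.false_discovery_control(table["p"].to_numpy())
    return table
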