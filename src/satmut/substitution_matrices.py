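"""Class-conditional 20×20 substitution matrices and derived profiles.

A substitution matrix holds, for every (wild-type, mutant) pair, the mean
deleteriousness score of the variants observed at positions carrying an
annotation class, together with per-cell counts and an occurrence mask that
suppresses weakly-supported cells (default: cells with count ≤ 100 are
masked, i.e. only pairs occurring more than 100 times are shown).
Rows are wild-type, columns mutant, both alphabetical by one-letter code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import STANDARD_AAS
from .landscape_stats import class_variant_mask, pearson_r
from .proteome_io import BACKGROUND, AnnotationSet, ValidationError
from .saturation_scan import ScoredScan

__all__ = [
    "SubstitutionMatrix",
    "DifferentialProfile",
    "BiophysicalScale",
    "build_matrix",
    "ss_differential",
    "scale_correlation",
    "read_scale",
]

AA_LIST = list(STANDARD_AAS)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Mean-score substitution matrix conditioned on an annotation class.

    ``mask[i, j]`` is True where the cell has too few occurrences
    (count ≤ min_count) — including the structurally empty diagonal.
    """

    category: str
    class_label: str
    mean: np.ndarray  # (20, 20) float, NaN where count == 0
    count: np.ndarray  # (20, 20) int
    mask: np.ndarray  # (20, 20) bool
    min_count: int

    def __post_init__(self) -> None:
        if np.diag(self.count).any():
            raise ValidationError("diagonal counts must be zero")
        if not np.diag(self.mask).all():
            raise ValidationError("diagonal must be masked")

    @property
    def n_variants(self) -> int:
        return int(self.count.sum())

    def to_frame(self, masked_value: str = "NA") -> pd.DataFrame:
        """Mean matrix as a frame with masked cells replaced by ``masked_value``."""
        frame = pd.DataFrame(self.mean, index=AA_LIST, columns=AA_LIST, dtype=object)
        frame = frame.mask(self.mask, masked_value)
        frame.index.name = "wt"
        return frame

    def count_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.count, index=AA_LIST, columns=AA_LIST)
        frame.index.name = "wt"
        return frame

    def to_tsv(self, path) -> None:
        """Write the mean matrix (21 columns: wt + 20 mutants, masked = NA)."""
        with open(path, "w") as fh:
            fh.write(
                f"# substitution matrix: category={self.category} "
                f"class={self.class_label} min_count={self.min_count}\n"
                "# rows = wild-type amino acid, columns = mutant amino acid\n"
            )
            self.to_frame().to_csv(fh, sep="\t")

    def plot(self, ax=None, **imshow_kwargs):
        """Heatmap of the unmasked means (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        shown = np.where(self.mask, np.nan, self.mean)
        im = ax.imshow(shown, vmin=0, vmax=1, cmap="coolwarm", **imshow_kwargs)
        ax.set_xticks(range(20), AA_LIST)
        ax.set_yticks(range(20), AA_LIST)
        ax.set_xlabel("mutant")
        ax.set_ylabel("wild-type")
        ax.set_title(f"{self.category}: {self.class_label}")
        plt.colorbar(im, ax=ax, label="mean deleteriousness")
        return ax


@dataclass(frozen=True)
class DifferentialProfile:
    """Per-mutant-amino-acid mean-score difference, class minus background."""

    ss_class: str
    delta: np.ndarray  # (20,) float, NaN where either side has no variants
    n_class: int
    n_background: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.delta, index=AA_LIST, name=self.ss_class)


@dataclass(frozen=True)
class BiophysicalScale:
    """A per-amino-acid numeric scale (e.g. a free-energy propensity)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AAS):
            raise ValidationError(
                f"scale {self.name!r} must cover exactly the 20 standard amino acids"
            )

    @property
    def vector(self) -> np.ndarray:
        """Values in alphabetical amino-acid order."""
        return np.array([self.values[aa] for aa in STANDARD_AAS], dtype=float)


def _group_stats(
    wt_idx: np.ndarray, mut_idx: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(wt, mut) cell sums and counts via flat bincount."""
    flat = wt_idx.astype(np.int64) * 20 + mut_idx
    counts = np.bincount(flat, minlength=400).reshape(20, 20)
    sums = np.bincount(flat, weights=scores, minlength=400).reshape(20, 20)
    return sums, counts


def build_matrix(
    scan: ScoredScan,
    annotations: AnnotationSet,
    category: str,
    class_label: str | None = BACKGROUND,
    *,
    min_count: int = 100,
) -> SubstitutionMatrix:
    """Build the class-conditional mean-score substitution matrix.

    ``mean[i, j]`` averages the scores of variants with wild-type i and
    mutant j at positions carrying the class; cells supported by at most
    ``min_count`` variants are masked (strict "more than min_count" filter).
    """
    rows = class_variant_mask(scan, annotations, category, class_label)
    wt_idx = scan.wt_idx[rows]
    mut_idx = scan.mut_idx[rows]
    scores = scan.scores[rows]
    sums, counts = _group_stats(wt_idx, mut_idx, scores)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mask = counts <= min_count
    np.fill_diagonal(mask, True)
    return SubstitutionMatrix(
        category=category,
        class_label=BACKGROUND if class_label == BACKGROUND else str(class_label),
        mean=mean,
        count=counts.astype(np.int64),
        mask=mask,
        min_count=int(min_count),
    )


def ss_differential(
    scan: ScoredScan,
    annotations: AnnotationSet,
    *,
    category: str = "secondary_structure",
    by: str = "mut",
) -> list[DifferentialProfile]:
    """Differential deleteriousness profiles per secondary-structure class.

    For each SS class, the per-mutant-amino-acid mean score among variants
    inside the class minus the same mean over SS-unassigned residues
    (positions covered by no record of the category). Classes without a
    single covered residue are omitted with a warning. ``by="wt"`` gives the
    wild-type-marginal counterpart (an extra view, not the canonical one).
    """
    if by not in ("mut", "wt"):
        raise ValueError("by must be 'mut' or 'wt'")
    axis_idx = scan.mut_idx if by == "mut" else scan.wt_idx
    scores = scan.scores
    bg_rows = class_variant_mask(scan, annotations, category, BACKGROUND)
    bg_counts = np.bincount(axis_idx[bg_rows], minlength=20)
    bg_sums = np.bincount(axis_idx[bg_rows], weights=scores[bg_rows], minlength=20)
    with np.errstate(invalid="ignore"):
        bg_means = np.where(bg_counts > 0, bg_sums / np.maximum(bg_counts, 1), np.nan)
    profiles: list[DifferentialProfile] = []
    for label in annotations.class_labels(category):
        rows = class_variant_mask(scan, annotations, category, label)
        if not rows.any():
            warnings.warn(
                f"ss_differential: class {label!r} covers no residues; omitted",
                stacklevel=2,
            )
            continue
        counts = np.bincount(axis_idx[rows], minlength=20)
        sums = np.bincount(axis_idx[rows], weights=scores[rows], minlength=20)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        profiles.append(
            DifferentialProfile(
                ss_class=label,
                delta=means - bg_means,
                n_class=int(rows.sum()),
                n_background=int(bg_rows.sum()),
            )
        )
    return profiles


def scale_correlation(
    values: dict[str, float] | np.ndarray, scale: BiophysicalScale
) -> tuple[float, float]:
    """Pearson correlation between 20 per-amino-acid values and a scale.

    ``values`` is either a dict keyed by one-letter code or a length-20
    vector in alphabetical order.
    """
    if isinstance(values, dict):
        if set(values) != set(STANDARD_AAS):
            raise ValidationError("values must cover exactly the 20 standard amino acids")
        vec = np.array([values[aa] for aa in STANDARD_AAS], dtype=float)
    else:
        vec = np.asarray(values, dtype=float)
        if vec.shape != (20,):
            raise ValidationError("values vector must have length 20")
    return pearson_r(vec, scale.vector)


def read_scale(path, name: str | None = None) -> BiophysicalScale:
    """Read a two-column TSV scale: ``aa<TAB>value``, ``#`` comments."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "aa":
                continue
            aa, value = fields[0], float(fields[1])
            values[aa] = value
    return BiophysicalScale(name=name or str(path), values=values)
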