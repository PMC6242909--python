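"""Per-protein deleteriousness landscapes and blind-test procedures.

A landscape is the L×20 matrix of scores for every substitution across one
protein — the standard deep-mutational-scanning heatmap view. The blind-test
procedures mirror how a predictor is checked against experimentally labelled
variants: a minimum-score check over a single-label set, a two-class
rank-sum discrimination test, and cross-predictor score agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, STANDARD_AAS, aa_indices
from .landscape_stats import (
    ComparisonResult,
    ScoreDistributionSummary,
    band_fractions,
    pearson_r,
    ranksum_compare,
)
from .proteome_io import ValidationError, _format_score
from .saturation_scan import ScoredScan

__all__ = [
    "LandscapeMatrix",
    "LabelledVariantSet",
    "MinScoreCheck",
    "DiscriminationResult",
    "AgreementResult",
    "protein_landscape",
    "min_score_check",
    "discrimination_test",
    "cross_predictor_agreement",
    "read_labelled_variants",
]

AA_LIST = list(STANDARD_AAS)

#: Reserved marker for the wild-type cell in landscape TSVs.
WT_MARKER = "WT"


@dataclass(frozen=True)
class LandscapeMatrix:
    """L×20 deleteriousness landscape of one protein.

    ``scores[i, j]`` is the score of mutating position i+1 into the j-th
    amino acid (alphabetical); the wild-type cell of each row is NaN in
    memory and rendered as ``WT`` in TSV. Rows at non-standard residues
    (B/U/X/Z) carry no scores and no wild-type marker.
    """

    accession: str
    wt_sequence: str
    scores: np.ndarray  # (L, 20)

    @property
    def length(self) -> int:
        return len(self.wt_sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandscapeMatrix):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.wt_sequence == other.wt_sequence
            and np.array_equal(self.scores, other.scores, equal_nan=True)
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# deleteriousness landscape of {self.accession}\n")
            fh.write("position\twt\t" + "\t".join(AA_LIST) + "\n")
            for i, wt in enumerate(self.wt_sequence):
                cells = []
                for j, mut in enumerate(AA_LIST):
                    if mut == wt:
                        cells.append(WT_MARKER)
                    elif np.isnan(self.scores[i, j]):
                        cells.append("NA")
                    else:
                        cells.append(_format_score(float(self.scores[i, j])))
                fh.write(f"{i + 1}\t{wt}\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path, accession: str | None = None) -> "LandscapeMatrix":
        wt_chars: list[str] = []
        rows: list[list[float]] = []
        acc = accession
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if acc is None and "landscape of" in line:
                        acc = line.rsplit(" ", 1)[-1]
                    continue
                fields = line.split("\t")
                if fields[0] == "position":
                    continue
                wt_chars.append(fields[1])
                row = [
                    np.nan if cell in (WT_MARKER, "NA") else float(cell)
                    for cell in fields[2:]
                ]
                rows.append(row)
        return cls(
            accession=acc or "unknown",
            wt_sequence="".join(wt_chars),
            scores=np.array(rows, dtype=float),
        )

    def to_scan_frame(self) -> pd.DataFrame:
        """Rebuild the scan-frame subset (lossless view of the scored cells)."""
        records = []
        for i, wt in enumerate(self.wt_sequence):
            for j, mut in enumerate(AA_LIST):
                if mut == wt or np.isnan(self.scores[i, j]):
                    continue
                records.append((self.accession, i + 1, wt, mut, self.scores[i, j]))
        return pd.DataFrame(
            records, columns=["accession", "position", "wt", "mut", "score"]
        )

    def plot(self, ax=None):
        """Heatmap with wild-type cells in a distinct colour (matplotlib)."""
        import matplotlib.pyplot as plt
        from matplotlib import colors

        if ax is None:
            _, ax = plt.subplots(figsize=(8, max(3, self.length / 12)))
        cmap = plt.get_cmap("coolwarm").copy()
        cmap.set_bad("#1f2d7a")  # wild-type / missing cells
        shown = np.ma.masked_invalid(self.scores)
        ax.imshow(shown, aspect="auto", cmap=cmap, norm=colors.Normalize(0, 1))
        ax.set_xticks(range(20), AA_LIST)
        ax.set_xlabel("mutant amino acid")
        ax.set_ylabel("position")
        ax.set_title(f"deleteriousness landscape: {self.accession}")
        return ax


def protein_landscape(scan: ScoredScan, accession: str) -> LandscapeMatrix:
    """Extract the complete L×20 landscape of one protein from a scan.

    The scan must be complete for the protein: missing cells are an error
    listing the first ten (position, mutant) gaps.
    """
    protein = scan.proteome[accession]
    views = scan.by_protein()
    if accession not in views:
        raise ValidationError(f"scan holds no variants for {accession!r}")
    view = views[accession]
    length = protein.length
    scores = np.full((length, 20), np.nan)
    scores[view.positions - 1, view.mut_idx.astype(np.intp)] = view.scores
    idx = aa_indices(protein.sequence)
    expected = np.zeros((length, 20), dtype=bool)
    std = idx >= 0
    expected[std, :] = True
    expected[np.flatnonzero(std), idx[std].astype(np.intp)] = False
    missing = expected & np.isnan(scores)
    if missing.any():
        where = np.argwhere(missing)[:10]
        cells = ", ".join(f"({pos + 1}, {AA_LIST[j]})" for pos, j in where)
        raise ValidationError(
            f"incomplete scan for {accession}: {int(missing.sum())} missing "
            f"cells; first: {cells}"
        )
    return LandscapeMatrix(accession=accession, wt_sequence=protein.sequence, scores=scores)


LABEL_COLUMNS = ["accession", "position", "wt", "mut", "label"]


class LabelledVariantSet:
    """Variants with binary experimental labels and attached scores.

    ``labels`` declares the binary vocabulary (e.g. ``("change",
    "no_change")`` or ``("deleterious", "neutral")``); duplicate variant
    keys are rejected.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        labels: tuple[str, str] = ("change", "no_change"),
    ) -> None:
        required = LABEL_COLUMNS + ["score"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"labelled variant frame missing columns {missing}")
        if len(set(labels)) != 2:
            raise ValidationError("label vocabulary must hold two distinct labels")
        bad = ~frame["label"].isin(labels)
        if bad.any():
            raise ValidationError(
                f"label {frame.loc[bad, 'label'].iloc[0]!r} outside vocabulary {labels}"
            )
        dup = frame.duplicated(subset=["accession", "position", "wt", "mut"])
        if dup.any():
            row = frame.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate labelled variant {row['accession']} "
                f"{row['position']} {row['wt']}>{row['mut']}"
            )
        scores = frame["score"].to_numpy(dtype=float)
        if len(scores) and (scores.min() < 0 or scores.max() > 1):
            raise ValidationError("labelled variant scores must lie in [0, 1]")
        self.labels = tuple(labels)
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def scores_for(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise ValidationError(f"unknown label {label!r}; vocabulary {self.labels}")
        return self.frame.loc[self.frame["label"] == label, "score"].to_numpy(dtype=float)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(LABEL_COLUMNS) + "\n")
            for row in self.frame.itertuples(index=False):
                fh.write(
                    f"{row.accession}\t{row.position}\t{row.wt}\t{row.mut}\t{row.label}\n"
                )


def read_labelled_variants(
    path,
    scan: ScoredScan,
    labels: tuple[str, str] = ("change", "no_change"),
) -> LabelledVariantSet:
    """Read ``labelled_variants.tsv`` and join scores from a scan.

    Variants absent from the scan are a hard error (a blind test needs a
    prediction for every labelled variant).
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"accession": str})
    missing = [c for c in LABEL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    merged = frame.merge(
        scan.variants, on=["accession", "position", "wt", "mut"], how="left"
    )
    unscored = merged["score"].isna()
    if unscored.any():
        row = merged.loc[unscored].iloc[0]
        raise ValidationError(
            f"{path}: no score for {row['accession']} {row['position']} "
            f"{row['wt']}>{row['mut']}"
        )
    return LabelledVariantSet(merged, labels=labels)


@dataclass(frozen=True)
class MinScoreCheck:
    """Outcome of the minimum-score blind check on one label class."""

    n: int
    min_score: float
    threshold: float
    strict: bool
    all_above: bool


def min_score_check(
    variants: LabelledVariantSet,
    *,
    label: str | None = None,
    threshold: float = 0.5,
    strict: bool = True,
) -> MinScoreCheck:
    """Report the minimum score of a (optionally label-filtered) variant set
    and whether every score clears the threshold.

    ``strict=True`` requires score > threshold; ``strict=False`` allows
    equality (both boundary conventions are exposed).
    """
    scores = (
        variants.frame["score"].to_numpy(dtype=float)
        if label is None
        else variants.scores_for(label)
    )
    if scores.size == 0:
        raise ValidationError("min_score_check: empty variant set")
    min_score = float(scores.min())
    all_above = min_score > threshold if strict else min_score >= threshold
    return MinScoreCheck(
        n=int(scores.size),
        min_score=min_score,
        threshold=float(threshold),
        strict=strict,
        all_above=bool(all_above),
    )


@dataclass(frozen=True)
class DiscriminationResult:
    """Two-class discrimination outcome plus per-label summaries."""

    comparison: ComparisonResult
    summary_by_label: dict[str, ScoreDistributionSummary]


def discrimination_test(variants: LabelledVariantSet) -> DiscriminationResult:
    """Rank-sum discrimination between the two label classes of a blind set.

    Both labels must be represented; the comparison is
    first-declared-label vs second (direction +1 means the first label's
    scores are higher).
    """
    label_a, label_b = variants.labels
    a = variants.scores_for(label_a)
    b = variants.scores_for(label_b)
    if a.size == 0 or b.size == 0:
        raise ValidationError(
            f"discrimination_test: both labels must be represented "
            f"(n[{label_a}]={a.size}, n[{label_b}]={b.size})"
        )
    comparison = ranksum_compare(a, b, class_a=label_a, class_b=label_b)
    summaries = {
        label_a: band_fractions(a, class_label=label_a),
        label_b: band_fractions(b, class_label=label_b),
    }
    return DiscriminationResult(comparison=comparison, summary_by_label=summaries)


@dataclass(frozen=True)
class AgreementResult:
    """Cross-predictor score agreement over matched variant keys."""

    r: float
    p: float
    n_matched: int


def cross_predictor_agreement(scan_a: ScoredScan, scan_b: ScoredScan) -> AgreementResult:
    """Pearson agreement between two scans over their shared variant keys."""
    merged = scan_a.variants.merge(
        scan_b.variants,
        on=["accession", "position", "wt", "mut"],
        suffixes=("_a", "_b"),
    )
    if len(merged) < 3:
        raise ValidationError(
            f"cross_predictor_agreement: only {len(merged)} matched variants (need >= 3)"
        )
    r, p = pearson_r(merged["score_a"].to_numpy(), merged["score_b"].to_numpy())
    return AgreementResult(r=r, p=p, n_matched=len(merged))
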