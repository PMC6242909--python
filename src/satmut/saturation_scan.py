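"""Exhaustive enumeration of single amino-acid variants and score binding.

For every residue over the 20 standard amino acids, exactly 19 substitutions
exist; non-standard residues (B, U, X, Z) are skipped. Enumeration order is
total and reproducible: proteins in input order, positions ascending,
mutant amino acids alphabetical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, MUT_INDEX, STANDARD_AA_ARRAY, STANDARD_AAS, aa_indices
from .proteome_io import (
    SCORE_COLUMNS,
    Protein,
    ProteinSet,
    ScoreTable,
    ValidationError,
    VariantKey,
)

__all__ = [
    "enumerate_savs",
    "count_savs",
    "enumeration_frame",
    "ScoredScan",
    "score_scan",
    "attach_scores",
]

logger = logging.getLogger(__name__)

#: A scorer maps (protein, 1-based position, mutant letter) to a score in
#: [0, 1] and must be deterministic for fixed inputs. This is the seam where
#: any external variant-effect predictor plugs in.
ScorerContract = Callable[[Protein, int, str], float]


def enumerate_savs(proteome: ProteinSet) -> Iterator[VariantKey]:
    """Lazily yield all single amino-acid variants of a proteome.

    Yields exactly 19 keys per standard residue, zero for non-standard
    residues, in deterministic order (accession, position, alphabetical
    mutant). Streaming: proteome-scale enumerations never materialise.
    """
    for protein in proteome:
        accession = protein.accession
        for pos0, wt in enumerate(protein.sequence):
            if wt not in AA_INDEX:
                continue
            position = pos0 + 1
            for mut in STANDARD_AAS:
                if mut != wt:
                    yield VariantKey(accession, position, wt, mut)


def count_savs(proteome: ProteinSet) -> int:
    """Closed-form variant count: 19 × (number of standard residues)."""
    return 19 * proteome.total_standard_residues


def enumeration_frame(proteome: ProteinSet) -> pd.DataFrame:
    """Vectorised enumeration as a frame (accession/position/wt/mut).

    Same order as :func:`enumerate_savs`; intended for table joins and the
    synthetic generator, where per-key Python iteration would dominate.
    """
    accs: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    muts: list[np.ndarray] = []
    for protein in proteome:
        idx = aa_indices(protein.sequence)
        std = idx >= 0
        n = int(std.sum())
        if n == 0:
            continue
        positions = np.flatnonzero(std) + 1
        wt_idx = idx[std].astype(np.intp)
        mut_idx = MUT_INDEX[wt_idx]  # (n, 19)
        accs.append(np.repeat(protein.accession, n * 19))
        poss.append(np.repeat(positions, 19))
        wts.append(np.repeat(STANDARD_AA_ARRAY[wt_idx], 19))
        muts.append(STANDARD_AA_ARRAY[mut_idx.ravel()])
    if not accs:
        return pd.DataFrame(
            {"accession": [], "position": [], "wt": [], "mut": []}
        ).astype({"position": np.int64})
    return pd.DataFrame(
        {
            "accession": np.concatenate(accs),
            "position": np.concatenate(poss).astype(np.int64),
            "wt": np.concatenate(wts),
            "mut": np.concatenate(muts),
        }
    )


@dataclass
class _ProteinView:
    """Per-protein numeric view of a scan (row indices are into the scan)."""

    rows: np.ndarray
    positions: np.ndarray
    wt_idx: np.ndarray
    mut_idx: np.ndarray
    scores: np.ndarray


@dataclass
class ScoredScan:
    """A saturation scan with one deleteriousness score per variant.

    ``variants`` holds columns accession/position/wt/mut/score in canonical
    enumeration order. ``complete`` is True when every enumerable variant of
    the proteome is present (partial score binding produces sub-scans).
    """

    proteome: ProteinSet
    variants: pd.DataFrame
    complete: bool = True
    _views: dict[str, _ProteinView] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValidationError(f"scan frame missing columns {missing}")
        scores = self.variants["score"].to_numpy()
        if len(scores) and (
            np.nanmin(scores) < 0 or np.nanmax(scores) > 1 or not np.isfinite(scores).all()
        ):
            raise ValidationError("scan contains scores outside [0, 1]")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def scores(self) -> np.ndarray:
        return self.variants["score"].to_numpy()

    @property
    def wt_idx(self) -> np.ndarray:
        return self.variants["wt"].map(AA_INDEX).to_numpy(dtype=np.int8)

    @property
    def mut_idx(self) -> np.ndarray:
        return self.variants["mut"].map(AA_INDEX).to_numpy(dtype=np.int8)

    def by_protein(self) -> dict[str, _ProteinView]:
        """Cached per-accession numeric views (fast path for statistics)."""
        if self._views is None:
            frame = self.variants
            wt_idx = self.wt_idx
            mut_idx = self.mut_idx
            positions = frame["position"].to_numpy()
            scores = frame["score"].to_numpy()
            views: dict[str, _ProteinView] = {}
            groups = frame.groupby("accession", sort=False).indices
            for acc, rows in groups.items():
                views[str(acc)] = _ProteinView(
                    rows=rows,
                    positions=positions[rows],
                    wt_idx=wt_idx[rows],
                    mut_idx=mut_idx[rows],
                    scores=scores[rows],
                )
            self._views = views
        return self._views

    def to_score_table(self, validate: bool = False) -> ScoreTable:
        return ScoreTable(self.variants, self.proteome, validate=validate)


def score_scan(
    proteome: ProteinSet,
    scorer: ScorerContract,
    *,
    log_progress: bool = False,
) -> ScoredScan:
    """Run a scorer over the full enumeration of a proteome.

    A scorer returning a value outside [0, 1] is a hard error identifying
    the offending variant.
    """
    rows: list[tuple[str, int, str, str, float]] = []
    for protein in proteome:
        for pos0, wt in enumerate(protein.sequence):
            if wt not in AA_INDEX:
                continue
            position = pos0 + 1
            for mut in STANDARD_AAS:
                if mut == wt:
                    continue
                score = float(scorer(protein, position, mut))
                if not 0.0 <= score <= 1.0:
                    raise ValidationError(
                        f"scorer returned {score} outside [0, 1] for "
                        f"{protein.accession} {position} {wt}>{mut}"
                    )
                rows.append((protein.accession, position, wt, mut, score))
        if log_progress:
            logger.info("scored %s (%d residues)", protein.accession, protein.length)
    frame = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return ScoredScan(proteome, frame, complete=True)


def attach_scores(
    proteome: ProteinSet, table: ScoreTable, policy: str = "strict"
) -> ScoredScan:
    """Bind a precomputed :class:`ScoreTable` to the enumeration.

    ``strict`` requires every enumerated variant to be present (error
    reporting the first 10 missing keys); ``partial`` drops missing keys
    with a logged count.
    """
    if policy not in ("strict", "partial"):
        raise ValueError("policy must be 'strict' or 'partial'")
    enum = enumeration_frame(proteome)
    merged = enum.merge(
        table.frame, on=["accession", "position", "wt", "mut"], how="left"
    )
    missing = merged["score"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        if policy == "strict":
            first = merged.loc[missing].head(10)
            keys = [
                f"{r.accession} {r.position} {r.wt}>{r.mut}"
                for r in first.itertuples(index=False)
            ]
            raise ValidationError(
                f"{n_missing} enumerated variants missing from score table; "
                f"first {len(keys)}: " + "; ".join(keys)
            )
        logger.warning("attach_scores: dropped %d unscored variants", n_missing)
        merged = merged.loc[~missing].reset_index(drop=True)
    return ScoredScan(proteome, merged, complete=(n_missing == 0))
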