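"""Data model and readers/writers for proteins, residue annotations and
per-variant deleteriousness scores.

Three on-disk formats are supported, all plain text:

* FASTA for protein sequences (standard dialect, wrapping tolerated; the
  accession is the first whitespace-delimited token of the header).
* ``annotations.tsv`` — one residue-interval feature per row with header
  ``accession<TAB>start<TAB>end<TAB>category<TAB>class``; ``#`` comments.
  Coordinates are 1-based and inclusive on both ends, following UniProt
  feature conventions.
* ``scores.tsv`` — one single-amino-acid variant per row with header
  ``accession<TAB>position<TAB>wt<TAB>mut<TAB>score``; scores in [0, 1],
  printed with at least six decimal places and losslessly round-trippable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import ALLOWED_AAS, NONSTANDARD_AAS, STANDARD_AAS

__all__ = [
    "ValidationError",
    "Protein",
    "ProteinSet",
    "ResidueAnnotation",
    "AnnotationSet",
    "VariantKey",
    "ScoreTable",
    "CATEGORY_VOCAB",
    "BACKGROUND",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "read_score_table",
    "write_score_table",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


#: Label used throughout the package for the computed "no annotation" class
#: of a category. Background is never stored as records: a residue is
#: background for a category iff no record of that category covers it.
BACKGROUND = "background"

#: Controlled vocabulary of annotation classes per category. Extensible by
#: passing a custom vocabulary to :func:`read_annotations` /
#: :class:`AnnotationSet`.
CATEGORY_VOCAB: dict[str, tuple[str, ...]] = {
    "functional": (
        "Active site",
        "Binding site",
        "DNA binding",
        "Calcium binding",
        "Metal binding",
        "Nucleotide binding",
        "Site",
    ),
    "ptm": ("Disulfide bond", "Glycosylation", "Lipidation", "Other"),
    "secondary_structure": ("Helix", "Beta strand", "Turn"),
    "domain": ("Domain",),
    "ppi": ("Interaction patch",),
    "topology": (
        "Transmembrane",
        "Intramembrane",
        "Cytoplasmic",
        "Extracellular",
        "Other topological",
    ),
}

_NONSTANDARD_SET = frozenset(NONSTANDARD_AAS)
_STANDARD_SET = frozenset(STANDARD_AAS)


@dataclass(frozen=True)
class Protein:
    """An accessioned amino-acid sequence.

    The sequence must be upper-case over the 20 standard one-letter codes
    plus the tolerated non-standard letters B, U, X, Z.
    """

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        if not set(self.sequence) <= ALLOWED_AAS:
            for pos, ch in enumerate(self.sequence, start=1):
                if ch not in ALLOWED_AAS:
                    raise ValidationError(
                        f"{self.accession}: illegal residue {ch!r} at position {pos}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @cached_property
    def n_standard_residues(self) -> int:
        """Number of residues over the 20 standard amino acids."""
        nonstd = sum(self.sequence.count(ch) for ch in NONSTANDARD_AAS)
        return self.length - nonstd


class ProteinSet:
    """Ordered, accession-keyed collection of :class:`Protein`."""

    def __init__(self, proteins: Iterable[Protein] = ()) -> None:
        self._proteins: dict[str, Protein] = {}
        for protein in proteins:
            if protein.accession in self._proteins:
                raise ValidationError(f"duplicate accession {protein.accession!r}")
            self._proteins[protein.accession] = protein

    @classmethod
    def from_sequences(cls, pairs: Iterable[tuple[str, str]]) -> "ProteinSet":
        return cls(Protein(acc, seq) for acc, seq in pairs)

    def __iter__(self) -> Iterator[Protein]:
        return iter(self._proteins.values())

    def __len__(self) -> int:
        return len(self._proteins)

    def __contains__(self, accession: str) -> bool:
        return accession in self._proteins

    def __getitem__(self, accession: str) -> Protein:
        try:
            return self._proteins[accession]
        except KeyError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinSet):
            return NotImplemented
        return list(self._proteins.items()) == list(other._proteins.items())

    def __repr__(self) -> str:
        return f"ProteinSet(n={len(self)}, total_residues={self.total_residues})"

    @property
    def accessions(self) -> list[str]:
        return list(self._proteins)

    @property
    def total_residues(self) -> int:
        return sum(p.length for p in self)

    @property
    def total_standard_residues(self) -> int:
        return sum(p.n_standard_residues for p in self)


def read_fasta(path) -> ProteinSet:
    """Read a FASTA file into a :class:`ProteinSet`, preserving order.

    The accession is the first whitespace-delimited token after ``>``.
    Duplicate accessions and illegal residue letters are hard errors; an
    empty file yields an empty set.
    """
    proteins: list[Protein] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise ValidationError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        proteins.append(Protein(accession, str(record.seq).upper()))
    return ProteinSet(proteins)


def write_fasta(proteome: ProteinSet, path, line_width: int = 60) -> None:
    """Write a :class:`ProteinSet` as wrapped FASTA."""
    with open(path, "w") as fh:
        for protein in proteome:
            fh.write(f">{protein.accession}\n")
            seq = protein.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


@dataclass(frozen=True)
class ResidueAnnotation:
    """A residue-interval class label; 1-based inclusive coordinates."""

    accession: str
    start: int
    end: int
    category: str
    class_label: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.accession}: invalid interval {self.start}..{self.end}"
            )

    def positions(self) -> range:
        return range(self.start, self.end + 1)


class AnnotationSet:
    """Validated collection of residue annotations over a proteome.

    Provides per-protein boolean coverage masks (the fast path used by the
    statistics modules) and a per-position index (the brute-force-verifiable
    view used on small instances).
    """

    def __init__(
        self,
        records: Iterable[ResidueAnnotation],
        proteome: ProteinSet,
        vocab: Mapping[str, tuple[str, ...]] | None = None,
    ) -> None:
        self.vocab: dict[str, tuple[str, ...]] = dict(
            CATEGORY_VOCAB if vocab is None else vocab
        )
        self._lengths = {p.accession: p.length for p in proteome}
        recs = tuple(records)
        for rec in recs:
            if rec.category not in self.vocab:
                raise ValidationError(f"unknown annotation category {rec.category!r}")
            if rec.class_label not in self.vocab[rec.category]:
                raise ValidationError(
                    f"unknown class {rec.class_label!r} for category {rec.category!r}"
                )
            if rec.accession not in self._lengths:
                raise ValidationError(f"unknown accession {rec.accession!r}")
            if rec.end > self._lengths[rec.accession]:
                raise ValidationError(
                    f"{rec.accession}: interval {rec.start}..{rec.end} exceeds "
                    f"protein length {self._lengths[rec.accession]}"
                )
        self._records = recs
        # (accession, category, class_label) -> [(start, end), ...]
        self._by_class: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
        # (accession, category) -> [(start, end), ...]
        self._by_category: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for rec in recs:
            self._by_class.setdefault(
                (rec.accession, rec.category, rec.class_label), []
            ).append((rec.start, rec.end))
            self._by_category.setdefault((rec.accession, rec.category), []).append(
                (rec.start, rec.end)
            )

    @property
    def records(self) -> tuple[ResidueAnnotation, ...]:
        return self._records

    def __len__(self) -> int:
        return len(self._records)

    def categories(self) -> list[str]:
        return list(self.vocab)

    def class_labels(self, category: str) -> tuple[str, ...]:
        try:
            return self.vocab[category]
        except KeyError:
            raise ValidationError(f"unknown annotation category {category!r}") from None

    def active_classes(self, accession: str) -> list[tuple[str, str]]:
        """Distinct (category, class_label) pairs with ≥1 record on a protein."""
        return [
            (cat, label)
            for (acc, cat, label) in self._by_class
            if acc == accession
        ]

    def position_mask(
        self, accession: str, category: str, class_label: str | None = None
    ) -> np.ndarray:
        """Boolean per-residue coverage mask for a protein.

        ``class_label=None`` gives the category-level union (any class of
        the category); the background mask is its negation.
        """
        if category not in self.vocab:
            raise ValidationError(f"unknown annotation category {category!r}")
        if class_label is not None and class_label not in self.vocab[category]:
            raise ValidationError(
                f"unknown class {class_label!r} for category {category!r}"
            )
        length = self._lengths[accession]
        mask = np.zeros(length, dtype=bool)
        if class_label is None:
            intervals = self._by_category.get((accession, category), ())
        else:
            intervals = self._by_class.get((accession, category, class_label), ())
        for start, end in intervals:
            mask[start - 1 : end] = True
        return mask

    def covering(self, accession: str, position: int) -> frozenset[tuple[str, str]]:
        """All (category, class_label) pairs covering a residue."""
        out = set()
        for (acc, cat, label), intervals in self._by_class.items():
            if acc != accession:
                continue
            if any(start <= position <= end for start, end in intervals):
                out.add((cat, label))
        return frozenset(out)

    def build_index(self) -> dict[tuple[str, int], frozenset[tuple[str, str]]]:
        """Materialise the (accession, position) -> labels index.

        Intended for small instances (tests, inspection); equals the
        brute-force union of interval expansions of the records.
        """
        index: dict[tuple[str, int], set[tuple[str, str]]] = {}
        for rec in self._records:
            for pos in rec.positions():
                index.setdefault((rec.accession, pos), set()).add(
                    (rec.category, rec.class_label)
                )
        return {key: frozenset(val) for key, val in index.items()}


_ANNOTATION_HEADER = ["accession", "start", "end", "category", "class"]


def read_annotations(
    path,
    proteome: ProteinSet,
    *,
    vocab: Mapping[str, tuple[str, ...]] | None = None,
    on_unknown_accession: str = "skip",
) -> AnnotationSet:
    """Read the annotation TSV, validating against a proteome.

    Out-of-bounds intervals and unknown categories/classes are hard errors
    with line numbers. Rows referencing an accession absent from the
    proteome are skipped with a warning by default
    (``on_unknown_accession="strict"`` turns them into errors).
    """
    if on_unknown_accession not in ("skip", "strict"):
        raise ValueError("on_unknown_accession must be 'skip' or 'strict'")
    effective_vocab = dict(CATEGORY_VOCAB if vocab is None else vocab)
    records: list[ResidueAnnotation] = []
    n_skipped = 0
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _ANNOTATION_HEADER:
                    raise ValidationError(
                        f"{path}:{lineno}: expected header "
                        f"{chr(9).join(_ANNOTATION_HEADER)!r}, got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 5:
                raise ValidationError(f"{path}:{lineno}: expected 5 fields")
            acc, start_s, end_s, category, class_label = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer interval bounds"
                ) from None
            if acc not in proteome:
                if on_unknown_accession == "strict":
                    raise ValidationError(
                        f"{path}:{lineno}: unknown accession {acc!r}"
                    )
                n_skipped += 1
                continue
            try:
                rec = ResidueAnnotation(acc, start, end, category, class_label)
                if category not in effective_vocab:
                    raise ValidationError(f"unknown annotation category {category!r}")
                if class_label not in effective_vocab[category]:
                    raise ValidationError(
                        f"unknown class {class_label!r} for category {category!r}"
                    )
                if end > proteome[acc].length:
                    raise ValidationError(
                        f"interval {start}..{end} exceeds protein length "
                        f"{proteome[acc].length}"
                    )
            except ValidationError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
            records.append(rec)
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} annotation rows with unknown accessions",
            stacklevel=2,
        )
    return AnnotationSet(records, proteome, vocab=effective_vocab)


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOTATION_HEADER) + "\n")
        for rec in annotations.records:
            fh.write(
                f"{rec.accession}\t{rec.start}\t{rec.end}\t{rec.category}\t"
                f"{rec.class_label}\n"
            )


class VariantKey(NamedTuple):
    """Identity of a single amino-acid variant (1-based position)."""

    accession: str
    position: int
    wt: str
    mut: str


SCORE_COLUMNS = ["accession", "position", "wt", "mut", "score"]


def _format_score(score: float) -> str:
    """≥6 decimal places, lossless on re-parse."""
    fixed = f"{score:.6f}"
    return fixed if float(fixed) == score else repr(float(score))


def _validate_score_frame(frame: pd.DataFrame, proteome: ProteinSet | None) -> None:
    if len(frame) == 0:
        return
    scores = frame["score"].to_numpy()
    bad = np.flatnonzero((scores < 0) | (scores > 1) | ~np.isfinite(scores))
    if bad.size:
        row = frame.iloc[bad[0]]
        raise ValidationError(
            f"score {row['score']} outside [0, 1] for "
            f"{row['accession']} {row['position']} {row['wt']}>{row['mut']}"
        )
    for col in ("wt", "mut"):
        ok = frame[col].isin(list(_STANDARD_SET))
        if not ok.all():
            row = frame.loc[~ok].iloc[0]
            raise ValidationError(
                f"non-standard {col} letter {row[col]!r} at "
                f"{row['accession']} position {row['position']}"
            )
    same = frame["wt"] == frame["mut"]
    if same.any():
        row = frame.loc[same].iloc[0]
        raise ValidationError(
            f"self-substitution {row['wt']}>{row['mut']} at "
            f"{row['accession']} position {row['position']}"
        )
    dup = frame.duplicated(subset=["accession", "position", "wt", "mut"])
    if dup.any():
        row = frame.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate variant key {row['accession']} {row['position']} "
            f"{row['wt']}>{row['mut']}"
        )
    if proteome is None:
        return
    for acc, group in frame.groupby("accession", sort=False):
        if acc not in proteome:
            raise ValidationError(f"unknown accession {acc!r} in score table")
        seq = proteome[acc].sequence
        positions = group["position"].to_numpy()
        if positions.min() < 1 or positions.max() > len(seq):
            bad_pos = positions[(positions < 1) | (positions > len(seq))][0]
            raise ValidationError(
                f"{acc}: position {bad_pos} outside 1..{len(seq)}"
            )
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        wt_arr = group["wt"].to_numpy().astype("S1")
        mismatch = seq_arr[positions - 1] != wt_arr
        if mismatch.any():
            i = int(np.flatnonzero(mismatch)[0])
            raise ValidationError(
                f"{acc}: wild-type mismatch at position {positions[i]} "
                f"(sequence has {seq[positions[i] - 1]!r}, table says "
                f"{group['wt'].iloc[i]!r})"
            )


class ScoreTable:
    """Map from :class:`VariantKey` to a deleteriousness score in [0, 1].

    Backed by a pandas frame with columns accession/position/wt/mut/score.
    Equality is order-insensitive.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        proteome: ProteinSet | None = None,
        validate: bool = True,
    ) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"score frame missing columns {missing}")
        frame = frame.loc[:, SCORE_COLUMNS].reset_index(drop=True)
        frame["position"] = frame["position"].astype(np.int64)
        frame["score"] = frame["score"].astype(np.float64)
        if validate:
            _validate_score_frame(frame, proteome)
        self._frame = frame
        self._lookup: dict[VariantKey, float] | None = None

    @classmethod
    def from_entries(
        cls,
        entries: Mapping[VariantKey, float] | Iterable[tuple[VariantKey, float]],
        proteome: ProteinSet | None = None,
    ) -> "ScoreTable":
        items = entries.items() if isinstance(entries, Mapping) else entries
        rows = [(k.accession, k.position, k.wt, k.mut, s) for k, s in items]
        frame = pd.DataFrame(rows, columns=SCORE_COLUMNS)
        return cls(frame, proteome)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying frame (read-only by convention)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def _ensure_lookup(self) -> dict[VariantKey, float]:
        if self._lookup is None:
            self._lookup = {
                VariantKey(acc, int(pos), wt, mut): float(score)
                for acc, pos, wt, mut, score in self._frame.itertuples(index=False)
            }
        return self._lookup

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._ensure_lookup()

    def __getitem__(self, key: VariantKey) -> float:
        return self._ensure_lookup()[key]

    def items(self) -> Iterator[tuple[VariantKey, float]]:
        return iter(self._ensure_lookup().items())

    def _canonical(self) -> pd.DataFrame:
        return self._frame.sort_values(
            ["accession", "position", "wt", "mut"], kind="mergesort"
        ).reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return self._canonical().equals(other._canonical())


def read_score_table(path, proteome: ProteinSet | None = None) -> ScoreTable:
    """Read ``scores.tsv``; every validation failure is a hard error."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"accession": str, "wt": str, "mut": str},
        float_precision="round_trip",
    )
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return ScoreTable(frame, proteome)


def write_score_table(table: ScoreTable, path) -> None:
    """Write ``scores.tsv`` with lossless ≥6-decimal score formatting."""
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        frame = table.frame
        for acc, pos, wt, mut, score in frame.itertuples(index=False):
            fh.write(f"{acc}\t{pos}\t{wt}\t{mut}\t{_format_score(score)}\n")
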