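"""Synthetic proteomes, annotation tracks and scores with planted effects.

The generator emulates the *product* of a curated proteome study: a set of
protein sequences, six residue-interval annotation tracks (functional sites,
PTMs, secondary structure, domains, interaction patches, membrane topology)
and a deleteriousness score for every possible single amino-acid variant.

Scores follow a logit-additive effect model,

    score = logistic(beta0 + Σ_active beta_class + gamma[wt, mut] + ε),
    ε ~ Normal(0, sigma²),

where the sum runs over the *distinct* (category, class) labels covering the
variant's position (a position covered twice by the same class gets the
shift once). The model makes class shifts and substitution-pair effects
separable and recoverable by the downstream statistics, which is what a
ground-truthed test bed needs; it does not claim to mimic any real
predictor's score distribution.

Reproducibility: one global seed is threaded through all sampling, split
into independent streams keyed as ``[seed, 0, protein]`` (sequence),
``[seed, 1, crc32(category), protein]`` (annotations) and ``[seed, 2,
protein]`` (score noise), so adding a category never perturbs other draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .alphabet import MUT_INDEX, STANDARD_AA_ARRAY, STANDARD_AAS, aa_indices
from .proteome_io import (
    CATEGORY_VOCAB,
    AnnotationSet,
    Protein,
    ProteinSet,
    ResidueAnnotation,
    ScoreTable,
    ValidationError,
)
from .saturation_scan import ScoredScan, enumeration_frame

__all__ = [
    "CategoryPlan",
    "GeneratorConfig",
    "EffectModel",
    "generate_proteome",
    "generate_scan",
    "generate_scores",
    "generate_blind_set",
    "truth_report",
    "simulate_study",
    "SimulatedStudy",
    "write_study",
]


@dataclass(frozen=True)
class CategoryPlan:
    """Annotation plan for one category: target residue coverage and
    interval-length range (labels default to the category vocabulary)."""

    density: float
    length_range: tuple[int, int]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValidationError(f"density {self.density} outside [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid interval length range {self.length_range}")


#: Default per-category annotation plans: coverage fractions and interval
#: lengths chosen to echo the granularity of real residue-level features
#: (functional sites and PTMs are short and sparse, domains long and broad,
#: membrane topology covers much of a membrane protein).
DEFAULT_CATEGORY_PLANS: dict[str, CategoryPlan] = {
    "functional": CategoryPlan(0.05, (1, 3)),
    "ptm": CategoryPlan(0.05, (1, 1)),
    "secondary_structure": CategoryPlan(0.30, (4, 12)),
    "domain": CategoryPlan(0.35, (40, 120)),
    "ppi": CategoryPlan(0.06, (5, 15)),
    "topology": CategoryPlan(0.45, (20, 60)),
}

#: Default planted logit shifts per annotation class. Values are arbitrary
#: effect-size knobs whose ordering qualitatively echoes the known biology
#: (oxidised cysteines and intramembrane stretches most intolerant, domains
#: mildest, plain topological compartments at baseline); they are never
#: asserted as real-data values.
DEFAULT_CLASS_SHIFTS: dict[str, float] = {
    **{label: 1.5 for label in CATEGORY_VOCAB["functional"]},
    "Disulfide bond": 2.0,
    "Glycosylation": 0.8,
    "Lipidation": 0.8,
    "Other": 0.3,
    "Helix": 0.5,
    "Beta strand": 0.5,
    "Turn": 0.5,
    "Domain": 0.4,
    "Interaction patch": 0.7,
    "Transmembrane": 0.6,
    "Intramembrane": 1.2,
    "Cytoplasmic": 0.0,
    "Extracellular": 0.0,
    "Other topological": 0.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape of the synthetic proteome and its annotation tracks."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (300, 300)
    composition: tuple[float, ...] | None = None  # 20 probs, alphabetical
    nonstandard_rate: float = 0.0  # per-residue probability of an X
    category_plans: Mapping[str, CategoryPlan] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PLANS)
    )
    vocab: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CATEGORY_VOCAB)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid length range {self.length_range}")
        if self.composition is not None:
            comp = np.asarray(self.composition, dtype=float)
            if comp.shape != (20,):
                raise ValidationError("composition must have 20 entries")
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValidationError("composition must sum to 1 within 1e-9")
            if (comp < 0).any():
                raise ValidationError("composition entries must be non-negative")
        if not 0.0 <= self.nonstandard_rate <= 1.0:
            raise ValidationError("nonstandard_rate outside [0, 1]")
        for category in self.category_plans:
            if category not in self.vocab:
                raise ValidationError(f"plan for unknown category {category!r}")


@dataclass(frozen=True)
class EffectModel:
    """Planted logit-additive effect model (see module docstring)."""

    beta0: float = -0.8
    beta_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SHIFTS)
    )
    gamma: np.ndarray | None = None  # (20, 20) substitution-pair logit effects
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if self.gamma is not None:
            gamma = np.asarray(self.gamma, dtype=float)
            if gamma.shape != (20, 20):
                raise ValidationError("gamma must be a 20x20 array")
            object.__setattr__(self, "gamma", gamma)

    @classmethod
    def null(cls, sigma: float = 0.5) -> "EffectModel":
        """All class and substitution effects zero (type-I-error setting)."""
        return cls(beta_class={}, gamma=None, sigma=sigma)

    def class_shift(self, class_label: str) -> float:
        return float(self.beta_class.get(class_label, 0.0))

    def gamma_matrix(self) -> np.ndarray:
        return np.zeros((20, 20)) if self.gamma is None else self.gamma

    def expected_mean(self, extra_logit: float = 0.0, n_nodes: int = 80) -> float:
        """E[logistic(beta0 + extra_logit + σε)] by Gauss–Hermite quadrature."""
        if self.sigma == 0:
            return float(expit(self.beta0 + extra_logit))
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        mu = self.beta0 + extra_logit
        vals = expit(mu + self.sigma * np.sqrt(2.0) * nodes)
        return float((weights @ vals) / np.sqrt(np.pi))


def _category_stream(category: str) -> int:
    # stable per-category stream key, independent of the other categories
    return zlib.crc32(category.encode("utf-8"))


def generate_proteome(config: GeneratorConfig) -> tuple[ProteinSet, AnnotationSet]:
    """Sample a proteome and its annotation tracks; fully seed-reproducible.

    Interval placement is independent per protein (no cross-protein
    leakage) and non-overlapping *within* a category — secondary-structure
    elements, topology segments or PTM sites of one track never stack on the
    same residue, while tracks of different categories overlap freely. The
    per-category density is a target coverage approached by rejection
    sampling; a plan whose minimum interval length exceeds a protein's
    length with nonzero density is an error (the intervals cannot fit).
    """
    lo, hi = config.length_range
    comp = None if config.composition is None else np.asarray(config.composition)
    proteins: list[Protein] = []
    for i in range(config.n_proteins):
        rng = np.random.default_rng([config.seed, 0, i])
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        idx = rng.choice(20, size=length, p=comp)
        letters = STANDARD_AA_ARRAY[idx]
        if config.nonstandard_rate > 0:
            letters = letters.copy()
            letters[rng.random(length) < config.nonstandard_rate] = "X"
        proteins.append(Protein(f"SYN{i + 1:05d}", "".join(letters)))
    proteome = ProteinSet(proteins)

    records: list[ResidueAnnotation] = []
    for category in sorted(config.category_plans):
        plan = config.category_plans[category]
        labels = plan.labels or tuple(config.vocab[category])
        if plan.density == 0.0:
            continue
        l_lo, l_hi = plan.length_range
        mean_len = (l_lo + l_hi) / 2.0
        stream = _category_stream(category)
        for i, protein in enumerate(proteins):
            length = protein.length
            if l_lo > length:
                raise ValidationError(
                    f"category {category!r}: intervals of length >= {l_lo} cannot "
                    f"fit in {protein.accession} (length {length})"
                )
            rng = np.random.default_rng([config.seed, 1, stream, i])
            n_intervals = int(round(plan.density * length / mean_len))
            occupied = np.zeros(length, dtype=bool)
            placed = 0
            attempts = 0
            max_attempts = 20 * n_intervals + 20
            while placed < n_intervals and attempts < max_attempts:
                attempts += 1
                iv_len = int(rng.integers(l_lo, min(l_hi, length) + 1))
                start = int(rng.integers(1, length - iv_len + 2))
                if occupied[start - 1 : start - 1 + iv_len].any():
                    continue
                occupied[start - 1 : start - 1 + iv_len] = True
                label = labels[int(rng.integers(len(labels)))]
                records.append(
                    ResidueAnnotation(
                        protein.accession, start, start + iv_len - 1, category, label
                    )
                )
                placed += 1
    annotations = AnnotationSet(records, proteome, vocab=dict(config.vocab))
    return proteome, annotations


def _position_logits(
    protein: Protein, annotations: AnnotationSet, model: EffectModel
) -> np.ndarray:
    """Per-residue baseline + class logit, with set semantics over classes."""
    logits = np.full(protein.length, model.beta0, dtype=float)
    for category, label in annotations.active_classes(protein.accession):
        beta = model.class_shift(label)
        if beta == 0.0:
            continue
        mask = annotations.position_mask(protein.accession, category, label)
        logits[mask] += beta
    return logits


def generate_scan(
    proteome: ProteinSet,
    annotations: AnnotationSet,
    model: EffectModel,
    seed: int,
) -> ScoredScan:
    """Draw one score per enumerable variant from the effect model.

    Vectorised per protein; the output frame is in canonical enumeration
    order and byte-stable for a fixed seed.
    """
    gamma = model.gamma_matrix()
    accs: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    muts: list[np.ndarray] = []
    scores: list[np.ndarray] = []
    for i, protein in enumerate(proteome):
        idx = aa_indices(protein.sequence)
        std = idx >= 0
        n = int(std.sum())
        if n == 0:
            continue
        pos_logit = _position_logits(protein, annotations, model)
        rng = np.random.default_rng([seed, 2, i])
        logit_matrix = pos_logit[:, None] + gamma[np.clip(idx, 0, None), :]
        if model.sigma > 0:
            logit_matrix = logit_matrix + model.sigma * rng.standard_normal(
                (protein.length, 20)
            )
        score_matrix = expit(logit_matrix)
        std_rows = np.flatnonzero(std)
        wt_idx = idx[std].astype(np.intp)
        mut_idx = MUT_INDEX[wt_idx]  # (n, 19)
        accs.append(np.repeat(protein.accession, n * 19))
        poss.append(np.repeat(std_rows + 1, 19))
        wts.append(np.repeat(STANDARD_AA_ARRAY[wt_idx], 19))
        muts.append(STANDARD_AA_ARRAY[mut_idx.ravel()])
        scores.append(score_matrix[std_rows[:, None], mut_idx].ravel())
    frame = pd.DataFrame(
        {
            "accession": np.concatenate(accs),
            "position": np.concatenate(poss).astype(np.int64),
            "wt": np.concatenate(wts),
            "mut": np.concatenate(muts),
            "score": np.concatenate(scores),
        }
    )
    return ScoredScan(proteome, frame, complete=True)


def generate_scores(
    proteome: ProteinSet,
    annotations: AnnotationSet,
    model: EffectModel,
    seed: int,
) -> ScoreTable:
    """Effect-model scores as a :class:`ScoreTable` (one per enumerable SAV)."""
    scan = generate_scan(proteome, annotations, model, seed)
    return ScoreTable(scan.variants, proteome, validate=False)


def truth_report(config: GeneratorConfig, model: EffectModel) -> pd.DataFrame:
    """Planted ground truth: per-class logit shift and expected score mean.

    The expected mean integrates the logistic over the noise (Gauss–Hermite)
    for a variant whose position carries exactly that class and nothing
    else; with overlapping tracks the realised class means sit above these
    values, but the planted *ordering* of classes is preserved whenever
    coverage is balanced across categories. A ``background`` row per
    category gives the no-annotation expectation.
    """
    rows = []
    for category in sorted(config.category_plans):
        labels = config.category_plans[category].labels or tuple(
            config.vocab[category]
        )
        for label in labels:
            beta = model.class_shift(label)
            rows.append(
                {
                    "category": category,
                    "class": label,
                    "logit_shift": beta,
                    "expected_mean": model.expected_mean(beta),
                }
            )
        rows.append(
            {
                "category": category,
                "class": "background",
                "logit_shift": 0.0,
                "expected_mean": model.expected_mean(0.0),
            }
        )
    return pd.DataFrame(rows)


def generate_blind_set(
    scan: ScoredScan,
    annotations: AnnotationSet,
    *,
    category: str,
    class_label: str,
    n_positive: int,
    n_negative: int,
    labels: tuple[str, str] = ("change", "no_change"),
    seed: int = 0,
):
    """Synthetic labelled blind-test set: positives sampled from a class,
    negatives from its background.

    Emulates an experimentally annotated variant list where functional
    consequences concentrate on annotated residues. Returns a
    :class:`~satmut.case_study.LabelledVariantSet`.
    """
    from .case_study import LabelledVariantSet
    from .landscape_stats import class_variant_mask

    rng = np.random.default_rng([seed, 4])
    pos_rows = np.flatnonzero(class_variant_mask(scan, annotations, category, class_label))
    neg_rows = np.flatnonzero(
        class_variant_mask(scan, annotations, category, "background")
    )
    if pos_rows.size < n_positive or neg_rows.size < n_negative:
        raise ValidationError(
            "generate_blind_set: not enough variants in class or background"
        )
    chosen_pos = rng.choice(pos_rows, size=n_positive, replace=False)
    chosen_neg = rng.choice(neg_rows, size=n_negative, replace=False)
    frame = scan.variants.iloc[np.concatenate([chosen_pos, chosen_neg])].copy()
    frame["label"] = [labels[0]] * n_positive + [labels[1]] * n_negative
    return LabelledVariantSet(frame.reset_index(drop=True), labels=labels)


def evaluate_recovery(study: "SimulatedStudy") -> dict:
    """Check that the pipeline recovers the planted effects of a study.

    Two read-outs, both computed per annotation category (contamination by
    the *other* tracks is equal in expectation within a category, so the
    planted order is only identified there):

    * ``ordering_ok`` — for every category, the empirical means of its
      classes plus the category background rank exactly as the planted
      expected means do; pairs with equal planted means carry no order and
      are skipped.
    * ``signs_ok`` — every class with a nonzero planted logit shift shows
      the matching class-vs-background rank-sum direction.
    """
    from itertools import combinations

    from .landscape_stats import class_comparison_table, class_scores

    table = class_comparison_table(study.scan, study.annotations)
    truth = study.truth.set_index(["category", "class"])
    ordering_ok = True
    signs_ok = True
    n_ordered_pairs = 0
    for category in table["category"].unique():
        sub = table[table["category"] == category].set_index("class")
        emp = {label: sub.loc[label, "mean"] for label in sub.index}
        exp = {
            label: truth.loc[(category, label), "expected_mean"]
            for label in sub.index
        }
        bg = class_scores(study.scan, study.annotations, category, "background")
        if bg.size:
            emp["background"] = float(bg.mean())
            exp["background"] = truth.loc[(category, "background"), "expected_mean"]
        for a, b in combinations(emp, 2):
            if abs(exp[a] - exp[b]) < 1e-12:
                continue
            n_ordered_pairs += 1
            if (emp[a] - emp[b]) * (exp[a] - exp[b]) <= 0:
                ordering_ok = False
        for label in sub.index:
            beta = truth.loc[(category, label), "logit_shift"]
            if beta != 0 and np.sign(beta) != sub.loc[label, "direction"]:
                signs_ok = False
    return {
        "ordering_ok": ordering_ok,
        "signs_ok": signs_ok,
        "n_ordered_pairs": n_ordered_pairs,
        "comparisons": table,
    }


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produces."""

    config: GeneratorConfig
    model: EffectModel
    proteome: ProteinSet
    annotations: AnnotationSet
    scan: ScoredScan
    truth: pd.DataFrame


def simulate_study(
    config: GeneratorConfig | None = None, model: EffectModel | None = None
) -> SimulatedStudy:
    """Generate proteome + annotations + full scored scan + truth table."""
    config = config or GeneratorConfig()
    model = model or EffectModel()
    proteome, annotations = generate_proteome(config)
    scan = generate_scan(proteome, annotations, model, config.seed)
    return SimulatedStudy(
        config=config,
        model=model,
        proteome=proteome,
        annotations=annotations,
        scan=scan,
        truth=truth_report(config, model),
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write FASTA + annotations.tsv + scores.tsv + truth.tsv for a study."""
    from pathlib import Path

    from .proteome_io import write_annotations, write_fasta, write_score_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.proteome, outdir / "proteome.fasta")
    write_annotations(study.annotations, outdir / "annotations.tsv")
    write_score_table(study.scan.to_score_table(), outdir / "scores.tsv")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
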