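"""Per-term binary classification datasets from GO annotations.

Implements the labeling convention used throughout the pipeline: for a
target term, proteins directly annotated to it are positives, proteins
annotated only to its ancestors or descendants are excluded (their status
is genuinely uncertain), and every other protein in the featurized
universe is a negative.  Also provides the evidence-code filter (curated
and experimental codes only, no electronic IEA annotations), the minimum
term-size selection, the three size categories and the balanced
under-sampled bags that feed the base classifiers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ontology import OntologyDag

logger = logging.getLogger(__name__)

#: Annotations inferred by a curator.
CURATED_EVIDENCE_CODES = frozenset(
    {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA", "TAS", "NAS", "IC"}
)
#: Annotations supported by direct experimental evidence.
EXPERIMENTAL_EVIDENCE_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
#: Accepted codes: curated or experimental, never electronic (IEA).
ACCEPTED_EVIDENCE_CODES = CURATED_EVIDENCE_CODES | EXPERIMENTAL_EVIDENCE_CODES

#: Default minimum number of positives for a term to enter the study.
DEFAULT_MIN_POSITIVES = 200

SIZE_CATEGORIES = ("small", "medium", "large")


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein -> GO term annotation with its evidence code."""

    protein_id: str
    term_id: str
    evidence_code: str

    def __post_init__(self) -> None:
        if not (self.protein_id and self.term_id and self.evidence_code):
            raise ValueError(f"annotation fields must be non-empty: {self}")


@dataclass(frozen=True)
class LabeledTermDataset:
    """Positives, negatives and excluded proteins for one GO term."""

    term_id: str
    positives: frozenset[str]
    negatives: frozenset[str]
    excluded: frozenset[str]

    def __post_init__(self) -> None:
        overlap = (
            (self.positives & self.negatives)
            | (self.positives & self.excluded)
            | (self.negatives & self.excluded)
        )
        if overlap:
            raise ValueError(f"term {self.term_id}: overlapping label sets: {sorted(overlap)[:5]}")

    @property
    def n_positives(self) -> int:
        return len(self.positives)


@dataclass(frozen=True)
class BagSet:
    """Balanced under-sampled bags for one term.

    Every bag contains all positives plus an equal-size without-replacement
    sample of negatives; bags differ only in their negative samples.
    """

    term_id: str
    bags: tuple[tuple[str, ...], ...]
    seed: int


def filter_annotations(
    records: Iterable[AnnotationRecord],
    policy: str = "lenient",
) -> list[AnnotationRecord]:
    """Keep curated/experimental annotations, drop electronic (IEA) ones.

    Duplicate (protein, term) pairs are collapsed to the first accepted
    record.  Unknown codes raise under ``policy="strict"`` and are dropped
    with a logged count under ``policy="lenient"``.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"policy must be 'strict' or 'lenient', got {policy!r}")
    kept: list[AnnotationRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    n_unknown = 0
    for rec in records:
        code = rec.evidence_code
        if code in ACCEPTED_EVIDENCE_CODES:
            pair = (rec.protein_id, rec.term_id)
            if pair not in seen_pairs:
                seen_pairs.add(pair)
                kept.append(rec)
        elif code == "IEA":
            continue
        else:
            if policy == "strict":
                raise ValueError(f"unknown evidence code {code!r} on {rec.protein_id} -> {rec.term_id}")
            n_unknown += 1
    if n_unknown:
        logger.warning("dropped %d annotations with unknown evidence codes", n_unknown)
    return kept


def label_term(
    term: str,
    annotations: Sequence[AnnotationRecord],
    dag: OntologyDag,
    universe: Iterable[str],
) -> LabeledTermDataset:
    """Apply the positive/excluded/negative rule for one term.

    positives  -- proteins directly annotated to ``term``
    excluded   -- proteins (not positive) annotated to any ancestor or
                  descendant of ``term``
    negatives  -- the rest of the universe

    ``annotations`` are assumed to be evidence-filtered already.
    """
    if term not in dag:
        raise KeyError(f"term {term!r} not present in the ontology")
    universe = frozenset(universe)
    relatives = dag.ancestors(term) | dag.descendants(term)
    positives: set[str] = set()
    related: set[str] = set()
    for rec in annotations:
        if rec.protein_id not in universe:
            continue
        if rec.term_id == term:
            positives.add(rec.protein_id)
        elif rec.term_id in relatives:
            related.add(rec.protein_id)
    excluded = related - positives
    negatives = universe - positives - excluded
    return LabeledTermDataset(
        term_id=term,
        positives=frozenset(positives),
        negatives=frozenset(negatives),
        excluded=frozenset(excluded),
    )


def select_terms(
    datasets: Iterable[LabeledTermDataset],
    min_pos: int = DEFAULT_MIN_POSITIVES,
) -> list[LabeledTermDataset]:
    """Keep terms with strictly more than ``min_pos`` positives."""
    return [d for d in datasets if d.n_positives > min_pos]


def size_category(dataset: LabeledTermDataset) -> str:
    """Classify a selected term by positive count.

    Half-open intervals keep the categories disjoint:
    small (200, 500], medium (500, 1000], large (1000, inf).
    """
    n = dataset.n_positives
    if n < 200:
        raise ValueError(
            f"term {dataset.term_id} has {n} positives (< 200); it should not have been selected"
        )
    if n <= 500:
        return "small"
    if n <= 1000:
        return "medium"
    return "large"


def make_bags(dataset: LabeledTermDataset, n_bags: int = 10, seed: int = 0) -> BagSet:
    """Build balanced bags: all positives + sampled negatives, per bag.

    Sampling is without replacement within a bag and is a deterministic
    function of ``(seed, bag_index)``: bag i uses its own RNG stream, so
    any bag can be regenerated independently.
    """
    pos = sorted(dataset.positives)
    neg = sorted(dataset.negatives)
    if len(pos) < 1:
        raise ValueError(f"term {dataset.term_id}: no positives to bag")
    if len(neg) < len(pos):
        raise ValueError(
            f"term {dataset.term_id}: fewer negatives ({len(neg)}) than positives "
            f"({len(pos)}); consider under-sampling the positive class instead"
        )
    bags = []
    for i in range(n_bags):
        rng = np.random.default_rng([seed, i])
        sampled = rng.choice(len(neg), size=len(pos), replace=False)
        bag = tuple(pos) + tuple(neg[j] for j in sorted(sampled))
        bags.append(bag)
    return BagSet(term_id=dataset.term_id, bags=tuple(bags), seed=seed)


# -- IO ----------------------------------------------------------------


def read_annotation_tsv(path: str | Path) -> list[AnnotationRecord]:
    """Read the three-column TSV dialect: protein_id, term_id, evidence_code.

    A header line is detected (and skipped) if its first field is
    ``protein_id``.
    """
    records: list[AnnotationRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("!"):
                continue
            if i == 0 and row[0] == "protein_id":
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: line {i + 1} has fewer than 3 columns")
            records.append(AnnotationRecord(row[0], row[1], row[2]))
    return records


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "term_id", "evidence_code"])
        for rec in records:
            writer.writerow([rec.protein_id, rec.term_id, rec.evidence_code])


def read_gaf(path: str | Path) -> list[AnnotationRecord]:
    """Read a GAF 2.x file, projecting onto (protein, term, evidence code).

    Uses GAF columns 2 (DB object id), 5 (GO id) and 7 (evidence code);
    comment lines start with ``!``.
    """
    records: list[AnnotationRecord] = []
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise ValueError(f"{path}: line {lineno} has fewer than 7 GAF columns")
            records.append(AnnotationRecord(cols[1], cols[4], cols[6]))
    return records


def write_labels_tsv(dataset: LabeledTermDataset, path: str | Path) -> None:
    """Serialize one term's labels: protein_id, label in {1, 0, NA-excluded}."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "label"])
        for pid in sorted(dataset.positives):
            writer.writerow([pid, "1"])
        for pid in sorted(dataset.negatives):
            writer.writerow([pid, "0"])
        for pid in sorted(dataset.excluded):
            writer.writerow([pid, "NA-excluded"])
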