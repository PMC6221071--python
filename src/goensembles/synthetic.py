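"""Self-contained synthetic fixtures: toy ontology, sequences, annotations.

The generator emulates the *structure* of a real GO-annotation study —
a small is_a DAG with one namespace root, proteins as random amino-acid
sequences, and per-term annotation tables spanning the small/medium/large
term-size categories — while keeping the predictive signal fully under
control: each annotated term owns a set of planted 3-mer motifs that are
written into its positive sequences with probability ``rho``, and a
fraction ``epsilon`` of term memberships is flipped as label noise.
Signals live directly in 3-mer space (planted motifs, or a residue
composition tilt for complementary subgroups) because that is exactly
what the pipeline's feature representation sees, which makes end-to-end
checks sharp.

All randomness flows from one seed through named substreams (sequences,
assignment, planting, noise), so any part of a fixture can be regenerated
independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import AnnotationRecord, write_annotation_tsv
from .features import STANDARD_AMINO_ACIDS, ProteinRecord
from .ontology import OntologyDag, write_obo

_NAMESPACE = "biological_process"
_EVIDENCE_CYCLE = ("IDA", "TAS", "IMP", "ISS")


@dataclass(frozen=True)
class SubgroupSignal:
    """The planted signal carried by one complementary subgroup.

    Either a pool of 3-mer motifs (each member carries one pool motif,
    planted with the fixture's planting rate — a sparse signal that
    split-selecting learners pick up) or a residue-composition tilt
    (members' sequences are drawn with the given letters' frequencies
    multiplied by ``composition_strength`` — a dense signal spread over
    thousands of k-mer features that linear and distribution-based
    learners pick up but single splits cannot).
    """

    motifs: tuple[str, ...] = ()
    composition_letters: str = ""
    composition_strength: float = 1.0

    def __post_init__(self) -> None:
        if bool(self.motifs) == bool(self.composition_letters):
            raise ValueError("a subgroup carries either motifs or a composition tilt")
        if self.composition_letters and self.composition_strength <= 1.0:
            raise ValueError("composition_strength must exceed 1 for a tilt group")


@dataclass(frozen=True)
class FixtureConfig:
    """Conditions under which a synthetic study is generated.

    ``term_positive_counts`` gives the intended number of positives of
    each annotated term; terms are placed at cycling depths in the toy
    DAG so levels 1..depth are populated, on branches chosen so that no
    two annotated terms are ancestor/descendant of each other.
    """

    n_proteins: int = 2500
    length_range: tuple[int, int] = (120, 240)
    depth: int = 4
    branching: int = 2
    term_positive_counts: tuple[int, ...] = (250, 600, 1100)
    motifs_per_term: int = 1
    planting_rate: float = 0.9
    label_noise: float = 0.05
    subgroup_motifs: tuple[tuple[str, ...], ...] | None = None
    subgroup_signals: tuple[SubgroupSignal, ...] | None = None
    n_iea_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planting_rate <= 1.0):
            raise ValueError(f"planting_rate must be in [0, 1], got {self.planting_rate}")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError(f"label_noise must be in [0, 1], got {self.label_noise}")
        if sum(self.term_positive_counts) > self.n_proteins:
            raise ValueError(
                f"term positive counts {self.term_positive_counts} exceed "
                f"n_proteins={self.n_proteins} (terms use disjoint positives)"
            )
        if self.length_range[0] < 3 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"invalid length range {self.length_range}")


@dataclass
class Fixture:
    """An in-memory synthetic study plus its ground-truth manifest."""

    config: FixtureConfig
    dag: OntologyDag
    records: list[ProteinRecord]
    annotations: list[AnnotationRecord]
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write fixture.fasta / fixture.obo / annotations.tsv / manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "fixture.fasta",
            "obo": outdir / "fixture.obo",
            "annotations": outdir / "annotations.tsv",
            "manifest": outdir / "manifest.json",
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i:i + 60] + "\n")
        write_obo(self.dag, paths["obo"])
        write_annotation_tsv(self.annotations, paths["annotations"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return paths


def _toy_dag(depth: int, branching: int) -> tuple[OntologyDag, dict[int, list[str]]]:
    """A rooted is_a DAG: a b-ary tree plus extra diamond edges.

    Returns the DAG and the terms grouped by level.
    """
    def tid(i: int) -> str:
        return f"GO:{i:07d}"

    edges: list[tuple[str, str]] = []
    by_level: dict[int, list[str]] = {0: [tid(0)]}
    next_id = 1
    for level in range(1, depth + 1):
        parents = by_level[level - 1]
        children: list[str] = []
        for p_i, parent in enumerate(parents):
            for _ in range(branching):
                child = tid(next_id)
                next_id += 1
                edges.append((child, parent))
                # every third child of a multi-parent level also hangs off the
                # next parent over, so the graph is a genuine DAG, not a tree
                if len(parents) > 1 and next_id % 3 == 0:
                    edges.append((child, parents[(p_i + 1) % len(parents)]))
                children.append(child)
        by_level[level] = children
    dag = OntologyDag.from_edges(edges, namespace=_NAMESPACE)
    return dag, by_level


def _pick_annotated_terms(
    dag: OntologyDag,
    by_level: dict[int, list[str]],
    n_terms: int,
    depth: int,
) -> list[str]:
    """Choose terms at cycling levels, none an ancestor/descendant of another."""
    chosen: list[str] = []
    taboo: set[str] = set()
    for i in range(n_terms):
        # deepest levels first: a deep term's ancestor chain plus (empty)
        # descendant set is a much smaller exclusion zone than a shallow
        # term's subtree, so mutually unrelated picks stay feasible
        level = depth - (i % depth)
        candidates = [t for t in by_level[level] if t not in taboo and t not in chosen]
        # fall back to any level if this one is exhausted
        if not candidates:
            candidates = [
                t for lv in range(1, depth + 1) for t in by_level[lv]
                if t not in taboo and t not in chosen
            ]
        if not candidates:
            raise ValueError(
                f"toy DAG (depth={depth}) too small for {n_terms} mutually "
                f"unrelated annotated terms; increase depth or branching"
            )
        term = candidates[0]
        chosen.append(term)
        taboo |= dag.ancestors(term) | dag.descendants(term) | {term}
    return chosen


def _random_motifs(rng: np.random.Generator, n: int, exclude: set[str]) -> list[str]:
    motifs: list[str] = []
    alphabet = list(STANDARD_AMINO_ACIDS)
    while len(motifs) < n:
        motif = "".join(rng.choice(alphabet, size=3))
        if motif not in exclude and motif not in motifs:
            motifs.append(motif)
    return motifs


def _tilted_sequence(
    length: int,
    letters: str,
    strength: float,
    rng: np.random.Generator,
) -> str:
    """Draw a sequence whose given letters are ``strength`` times enriched."""
    weights = np.ones(len(STANDARD_AMINO_ACIDS))
    for i, aa in enumerate(STANDARD_AMINO_ACIDS):
        if aa in letters:
            weights[i] = strength
    probs = weights / weights.sum()
    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    return "".join(rng.choice(alphabet, size=length, p=probs))


def _plant(sequence: str, motif: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(sequence) - len(motif) + 1))
    return sequence[:pos] + motif + sequence[pos + len(motif):]


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Generate a complete toy study: DAG, sequences, annotations, manifest.

    Positives of distinct terms are disjoint protein sets.  Each positive
    sequence receives each of its term's motifs (independently, with
    probability ``planting_rate``) overwriting a random window, so the
    sequence length distribution is preserved.  Label noise then flips
    each protein's membership in each term with probability
    ``label_noise``; the manifest records both the true (planted) and the
    observed (post-noise) memberships.
    """
    cfg = config
    dag, by_level = _toy_dag(cfg.depth, cfg.branching)
    terms = _pick_annotated_terms(dag, by_level, len(cfg.term_positive_counts), cfg.depth)

    rng_seq = np.random.default_rng([cfg.seed, 0])
    rng_assign = np.random.default_rng([cfg.seed, 1])
    rng_plant = np.random.default_rng([cfg.seed, 2])
    rng_noise = np.random.default_rng([cfg.seed, 3])
    rng_motif = np.random.default_rng([cfg.seed, 4])

    ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    lo, hi = cfg.length_range
    sequences = []
    for _ in ids:
        length = int(rng_seq.integers(lo, hi + 1))
        sequences.append("".join(rng_seq.choice(alphabet, size=length)))

    # disjoint positive sets per term
    shuffled = rng_assign.permutation(cfg.n_proteins)
    true_pos: dict[str, list[int]] = {}
    cursor = 0
    for term, count in zip(terms, cfg.term_positive_counts):
        true_pos[term] = sorted(int(i) for i in shuffled[cursor:cursor + count])
        cursor += count

    # per-term signals (with optional complementary subgroups on term 0)
    signals = cfg.subgroup_signals
    if signals is None and cfg.subgroup_motifs is not None:
        signals = tuple(SubgroupSignal(motifs=tuple(g)) for g in cfg.subgroup_motifs)
    used: set[str] = set()
    term_motifs: dict[str, list[str]] = {}
    subgroups: dict[str, dict[str, list[int]]] = {}
    for t_i, term in enumerate(terms):
        if signals is not None and t_i == 0:
            term_motifs[term] = [m for sig in signals for m in sig.motifs]
            members = true_pos[term]
            assignment: dict[str, list[int]] = {}
            for g_i in range(len(signals)):
                assignment[f"subgroup_{g_i}"] = members[g_i::len(signals)]
            subgroups[term] = assignment
            used |= set(term_motifs[term])
        else:
            term_motifs[term] = _random_motifs(rng_motif, cfg.motifs_per_term, used)
            used |= set(term_motifs[term])

    # plant signals into positive sequences
    for term in terms:
        if term in subgroups:
            # complementary mode: each subgroup carries its own signal, so
            # no single detector (or feature family) covers the whole class
            group_map = subgroups[term]
            for g_i, gname in enumerate(sorted(group_map)):
                sig = signals[g_i]
                for idx in group_map[gname]:
                    if rng_plant.random() >= cfg.planting_rate:
                        continue
                    if sig.motifs:
                        # one pool motif per member: a sparse, split-friendly signal
                        motif = sig.motifs[int(rng_plant.integers(0, len(sig.motifs)))]
                        sequences[idx] = _plant(sequences[idx], motif, rng_plant)
                    else:
                        sequences[idx] = _tilted_sequence(
                            len(sequences[idx]),
                            sig.composition_letters,
                            sig.composition_strength,
                            rng_plant,
                        )
        else:
            for idx in true_pos[term]:
                for motif in term_motifs[term]:
                    if rng_plant.random() < cfg.planting_rate:
                        sequences[idx] = _plant(sequences[idx], motif, rng_plant)

    # label noise: flip membership per (protein, term)
    observed_pos: dict[str, list[int]] = {}
    for term in terms:
        members = set(true_pos[term])
        flips = rng_noise.random(cfg.n_proteins) < cfg.label_noise
        observed = {
            i for i in range(cfg.n_proteins)
            if (i in members) != bool(flips[i])
        }
        observed_pos[term] = sorted(observed)

    records = [ProteinRecord(id=pid, sequence=seq) for pid, seq in zip(ids, sequences)]
    annotations: list[AnnotationRecord] = []
    for term in terms:
        for j, idx in enumerate(observed_pos[term]):
            code = _EVIDENCE_CYCLE[j % len(_EVIDENCE_CYCLE)]
            annotations.append(AnnotationRecord(ids[idx], term, code))
    # optional electronic-annotation decoys that the evidence filter must drop
    for d in range(cfg.n_iea_decoys):
        idx = int(rng_noise.integers(0, cfg.n_proteins))
        annotations.append(AnnotationRecord(ids[idx], terms[d % len(terms)], "IEA"))

    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_proteins": cfg.n_proteins,
        "terms": {
            term: {
                "level": dag.term_level(term),
                "motifs": term_motifs[term],
                "n_true_positives": len(true_pos[term]),
                "true_positives": [ids[i] for i in true_pos[term]],
                "observed_positives": [ids[i] for i in observed_pos[term]],
                "subgroups": {
                    g: [ids[i] for i in members]
                    for g, members in subgroups.get(term, {}).items()
                },
                "subgroup_signals": (
                    [dataclasses.asdict(sig) for sig in signals]
                    if term in subgroups else []
                ),
            }
            for term in terms
        },
    }
    return Fixture(config=cfg, dag=dag, records=records, annotations=annotations, manifest=manifest)


def complementary_signal_fixture(config: FixtureConfig) -> Fixture:
    """A single-term fixture whose positives split into motif subgroups.

    The positives are the union of disjoint subgroups, each carrying a
    different planted signal (a motif pool or a composition tilt), so no
    single detector covers the whole positive class and aggregating
    detectors is provably helpful.  With one subgroup this reduces to
    :func:`generate_fixture`.
    """
    if config.subgroup_motifs is None and config.subgroup_signals is None:
        raise ValueError(
            "complementary_signal_fixture requires subgroup_motifs or subgroup_signals"
        )
    if len(config.term_positive_counts) != 1:
        raise ValueError("complementary_signal_fixture uses exactly one annotated term")
    return generate_fixture(config)


def default_complementary_config(seed: int = 0) -> FixtureConfig:
    """The standard complementary-signal study conditions.

    About 600 proteins with one annotated term of 250 positives split into
    two equal subgroups carrying signals of different *families*: one
    subgroup carries sparse motifs (one of a four-motif pool per member,
    planted at rate 0.9) that split-selecting tree learners detect but
    regularized linear models cannot recover among 8000 features, the
    other a strong residue-composition tilt (W/Y/H/C enriched 3x, applied
    at rate 0.9) that linear models detect as a dense direction but that
    offers no high-purity single split; 5% label noise.  Because neither
    feature family covers both subgroups, every individual base
    classifier is recall-limited to roughly half the positive class, and
    only aggregation across heterogeneous classifiers recovers the union.
    """
    return FixtureConfig(
        n_proteins=600,
        length_range=(80, 140),
        term_positive_counts=(250,),
        subgroup_signals=(
            SubgroupSignal(motifs=("ACD", "EFG", "HIK", "LMN")),
            SubgroupSignal(composition_letters="WYHC", composition_strength=3.0),
        ),
        planting_rate=0.9,
        label_noise=0.05,
        depth=2,
        branching=2,
        seed=seed,
    )
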