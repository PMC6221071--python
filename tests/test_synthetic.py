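import json

import numpy as np
import pytest

from goensembles.datasets import filter_annotations, label_term
from goensembles.evaluation import fmax
from goensembles.synthetic import (
    FixtureConfig,
    SubgroupSignal,
    complementary_signal_fixture,
    default_complementary_config,
    generate_fixture,
)


def small_config(**overrides):
    defaults = dict(
        n_proteins=120,
        length_range=(30, 60),
        depth=3,
        branching=2,
        term_positive_counts=(20, 15),
        planting_rate=1.0,
        label_noise=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return FixtureConfig(**defaults)


class TestGenerateFixture:
    def test_full_planting_makes_motifs_visible(self):
        fx = generate_fixture(small_config())
        seq_by_id = {r.id: r.sequence for r in fx.records}
        for term, info in fx.manifest["terms"].items():
            for pid in info["true_positives"]:
                assert all(m in seq_by_id[pid] for m in info["motifs"]), (term, pid)

    def test_zero_planting_leaves_no_enrichment(self):
        fx = generate_fixture(small_config(planting_rate=0.0, seed=3))
        seq_by_id = {r.id: r.sequence for r in fx.records}
        for term, info in fx.manifest["terms"].items():
            pos = set(info["true_positives"])
            carriers = lambda ids: np.mean(
                [any(m in seq_by_id[p] for m in info["motifs"]) for p in ids]
            )
            neg = [r.id for r in fx.records if r.id not in pos]
            assert abs(carriers(sorted(pos)) - carriers(neg)) < 0.25

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config()
        p1 = generate_fixture(cfg).write(tmp_path / "a")
        p2 = generate_fixture(cfg).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self):
        a = generate_fixture(small_config(seed=1))
        b = generate_fixture(small_config(seed=2))
        assert [r.sequence for r in a.records] != [r.sequence for r in b.records]

    def test_manifest_positives_match_label_term_without_noise(self):
        fx = generate_fixture(small_config())
        ann = filter_annotations(fx.annotations)
        universe = {r.id for r in fx.records}
        for term, info in fx.manifest["terms"].items():
            ds = label_term(term, ann, fx.dag, universe)
            assert ds.positives == set(info["true_positives"])
            assert ds.positives == set(info["observed_positives"])

    def test_label_noise_perturbs_observed_not_true(self):
        fx = generate_fixture(small_config(label_noise=0.3, seed=5))
        for info in fx.manifest["terms"].values():
            assert set(info["observed_positives"]) != set(info["true_positives"])
            assert info["n_true_positives"] == len(info["true_positives"])

    def test_annotated_term_levels_span_configured_depths(self):
        cfg = small_config(term_positive_counts=(15, 15, 15), depth=3)
        fx = generate_fixture(cfg)
        levels = sorted(info["level"] for info in fx.manifest["terms"].values())
        assert levels == [1, 2, 3]
        for term, info in fx.manifest["terms"].items():
            assert fx.dag.term_level(term) == info["level"]

    def test_annotations_survive_evidence_filter(self):
        fx = generate_fixture(small_config(n_iea_decoys=5))
        kept = filter_annotations(fx.annotations)
        assert all(r.evidence_code != "IEA" for r in kept)
        assert any(r.evidence_code == "IEA" for r in fx.annotations)

    def test_infeasible_positive_counts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            FixtureConfig(n_proteins=10, term_positive_counts=(8, 8))

    def test_written_files_are_readable_standard_formats(self, tmp_path):
        from goensembles.datasets import read_annotation_tsv
        from goensembles.features import read_fasta
        from goensembles.ontology import OntologyDag

        fx = generate_fixture(small_config())
        paths = fx.write(tmp_path)
        records = read_fasta(paths["fasta"])
        assert [r.id for r in records] == [r.id for r in fx.records]
        dag = OntologyDag.from_obo(paths["obo"])
        assert set(dag.terms) == set(fx.dag.terms)
        assert read_annotation_tsv(paths["annotations"]) == fx.annotations
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["n_proteins"] == fx.config.n_proteins


class TestComplementaryFixture:
    def test_single_motif_detectors_cover_half_each(self):
        cfg = small_config(
            n_proteins=200,
            term_positive_counts=(60,),
            subgroup_motifs=(("ACD",), ("WYW",)),
        )
        fx = complementary_signal_fixture(cfg)
        info = next(iter(fx.manifest["terms"].values()))
        seq_by_id = {r.id: r.sequence for r in fx.records}
        pos = info["true_positives"]
        for motif, group in [("ACD", "subgroup_0"), ("WYW", "subgroup_1")]:
            recall = np.mean([motif in seq_by_id[p] for p in pos])
            group_frac = len(info["subgroups"][group]) / len(pos)
            assert recall == pytest.approx(group_frac, abs=0.12)

    def test_mean_of_detectors_beats_either_alone(self):
        cfg = small_config(
            n_proteins=300,
            term_positive_counts=(100,),
            subgroup_motifs=(("ACD",), ("WYW",)),
        )
        fx = complementary_signal_fixture(cfg)
        info = next(iter(fx.manifest["terms"].values()))
        seq_by_id = {r.id: r.sequence for r in fx.records}
        ids = [r.id for r in fx.records]
        y = np.array([1 if p in set(info["true_positives"]) else 0 for p in ids])
        d1 = np.array([1.0 if "ACD" in seq_by_id[p] else 0.0 for p in ids])
        d2 = np.array([1.0 if "WYW" in seq_by_id[p] else 0.0 for p in ids])
        f1 = fmax(d1, y).fmax
        f2 = fmax(d2, y).fmax
        fm = fmax((d1 + d2) / 2, y).fmax
        assert fm > max(f1, f2)

    def test_requires_subgroup_definition(self):
        with pytest.raises(ValueError, match="subgroup"):
            complementary_signal_fixture(small_config(term_positive_counts=(20,)))

    def test_single_subgroup_reduces_to_plain_fixture(self):
        cfg = small_config(
            n_proteins=100,
            term_positive_counts=(20,),
            subgroup_motifs=(("ACD",),),
        )
        fx = complementary_signal_fixture(cfg)
        info = next(iter(fx.manifest["terms"].values()))
        seq_by_id = {r.id: r.sequence for r in fx.records}
        assert all("ACD" in seq_by_id[p] for p in info["true_positives"])

    def test_default_config_is_balanced_and_mixed_family(self):
        cfg = default_complementary_config(seed=0)
        assert cfg.n_proteins == 600
        assert cfg.planting_rate == 0.9
        assert cfg.label_noise == 0.05
        fx = complementary_signal_fixture(cfg)
        info = next(iter(fx.manifest["terms"].values()))
        sizes = [len(v) for v in info["subgroups"].values()]
        assert abs(sizes[0] - sizes[1]) <= 1
        kinds = [bool(sig["motifs"]) for sig in info["subgroup_signals"]]
        assert kinds == [True, False]

    def test_tilt_group_is_composition_enriched(self):
        cfg = default_complementary_config(seed=2)
        fx = complementary_signal_fixture(cfg)
        info = next(iter(fx.manifest["terms"].values()))
        seq_by_id = {r.id: r.sequence for r in fx.records}
        tilt = info["subgroups"]["subgroup_1"]
        others = [r.id for r in fx.records if r.id not in set(info["true_positives"])]

        def wyhc_frac(ids):
            seqs = "".join(seq_by_id[p] for p in ids)
            return sum(seqs.count(c) for c in "WYHC") / len(seqs)

        assert wyhc_frac(tilt) > wyhc_frac(others) + 0.1
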