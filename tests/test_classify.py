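"""Regime orchestration and rarity-based conflict resolution."""

import itertools

import pytest

from temporel.backend import (
    BackendError,
    CountingBackend,
    OracleBackend,
    ScriptedBackend,
)
from temporel.classify import (
    TIE_BREAK_ORDER,
    TrainingCounts,
    classify_binary_all,
    classify_instance,
    classify_multiclass,
    classify_zeroshot_all,
    resolve_conflict,
    run_extraction,
)
from temporel.context import enumerate_pairs
from temporel.evaluate import score_records
from temporel.schema import NONE_LABEL, RELATION_LABELS


@pytest.fixture(scope="module")
def instances(small_corpus):
    docs, _ = small_corpus
    return [inst for doc in docs[:5] for inst in enumerate_pairs(doc)]


class TestTrainingCounts:
    def test_from_table1(self):
        counts = TrainingCounts.from_table1()
        assert counts["BEGINS-AT"] == 202
        assert counts["SIMULTANEOUS"] == 14
        assert counts["BEFORE-OVERLAP"] == 357

    def test_from_bank(self, bank):
        counts = TrainingCounts.from_bank(bank)
        assert set(counts.counts) == set(RELATION_LABELS)
        assert all(v >= 3 for v in counts.counts.values())

    def test_missing_type_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            TrainingCounts(counts={"BEFORE": 1})

    def test_negative_rejected(self):
        counts = dict.fromkeys(RELATION_LABELS, 1)
        counts["OVERLAP"] = -2
        with pytest.raises(ValueError, match="non-negative"):
            TrainingCounts(counts=counts)


class TestResolveConflict:
    def test_rarest_wins_with_table1_counts(self):
        counts = TrainingCounts.from_table1()
        assert resolve_conflict({"BEGINS-AT", "SIMULTANEOUS"}, counts) == "SIMULTANEOUS"

    def test_empty_set_is_none(self):
        assert resolve_conflict(set(), TrainingCounts.from_table1()) == NONE_LABEL

    def test_singleton(self):
        assert resolve_conflict({"OVERLAP"}, TrainingCounts.from_table1()) == "OVERLAP"

    def test_tie_break_by_declaration_order(self):
        counts = TrainingCounts(counts=dict.fromkeys(RELATION_LABELS, 10))
        assert resolve_conflict({"BEFORE", "OVERLAP"}, counts) == "BEFORE"

    def test_tie_break_brute_force_over_permutations(self):
        counts = TrainingCounts(counts=dict.fromkeys(RELATION_LABELS, 5))
        for subset_size in (2, 3):
            for subset in itertools.combinations(RELATION_LABELS, subset_size):
                expected = min(subset, key=TIE_BREAK_ORDER.index)
                for ordering in itertools.permutations(subset):
                    assert resolve_conflict(list(ordering), counts) == expected

    def test_permutation_invariance_with_varied_counts(self):
        counts = TrainingCounts.from_table1()
        subset = ("ENDS-AT", "CONTAINS", "BEFORE", "SIMULTANEOUS")
        results = {
            resolve_conflict(list(p), counts) for p in itertools.permutations(subset)
        }
        assert results == {"ENDS-AT"}  # count 7 is the minimum of the subset

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            resolve_conflict({"AFTER"}, TrainingCounts.from_table1())


class TestMulticlass:
    def test_oracle_identity(self, instances, bank, oracle):
        for inst in instances[:20]:
            assert classify_multiclass(inst, bank, oracle) == inst.gold

    def test_unparseable_output_becomes_none(self, instances, bank):
        backend = ScriptedBackend(lambda req: "je ne sais pas du tout")
        assert classify_multiclass(instances[0], bank, backend) == NONE_LABEL

    def test_single_backend_call_per_instance(self, instances, bank, oracle):
        counting = CountingBackend(oracle)
        classify_multiclass(instances[0], bank, counting)
        assert counting.calls == 1


class TestBinary:
    def test_oracle_yields_singleton_or_empty(self, instances, bank, oracle):
        for inst in instances[:10]:
            positives = classify_binary_all(inst, bank, oracle)
            if inst.gold == NONE_LABEL:
                assert positives == set()
            else:
                assert positives == {inst.gold}

    def test_all_negative_backend_empty_set(self, instances, bank):
        backend = ScriptedBackend(lambda req: NONE_LABEL)
        assert classify_binary_all(instances[0], bank, backend) == set()

    def test_forced_positives(self, instances, bank):
        forced = {"BEFORE", "BEFORE-OVERLAP"}

        def respond(req):
            rel = req.metadata["relation"]
            return rel if rel in forced else NONE_LABEL

        positives = classify_binary_all(instances[0], bank, ScriptedBackend(respond))
        assert positives == forced

    def test_exactly_seven_backend_calls(self, instances, bank, oracle):
        counting = CountingBackend(oracle)
        classify_binary_all(instances[0], bank, counting)
        assert counting.calls == 7

    def test_failed_subcall_counts_negative(self, instances, bank):
        def respond(req):
            rel = req.metadata["relation"]
            if rel == "OVERLAP":
                raise BackendError("down")
            return rel if rel in ("OVERLAP", "BEFORE") else NONE_LABEL

        positives = classify_binary_all(instances[0], bank, ScriptedBackend(respond))
        assert positives == {"BEFORE"}


class TestZeroShot:
    def test_oracle_identity(self, instances, oracle):
        for inst in instances[:10]:
            positives = classify_zeroshot_all(inst, oracle)
            expected = set() if inst.gold == NONE_LABEL else {inst.gold}
            assert positives == expected

    def test_seven_calls(self, instances, oracle):
        counting = CountingBackend(oracle)
        classify_zeroshot_all(instances[0], counting)
        assert counting.calls == 7


class TestClassifyInstance:
    def test_regime_validation(self, instances, bank, oracle):
        with pytest.raises(ValueError, match="regime"):
            classify_instance(instances[0], "ensemble", oracle, bank=bank)

    def test_multiclass_requires_bank(self, instances, oracle):
        with pytest.raises(ValueError, match="bank"):
            classify_instance(instances[0], "multiclass", oracle)

    @pytest.mark.parametrize("regime", ["multiclass", "binary", "zeroshot"])
    def test_oracle_identity_all_regimes(self, instances, bank, oracle, regime):
        for inst in instances[:8]:
            got = classify_instance(inst, regime, oracle, bank=bank)
            assert got == inst.gold


def test_regimes_agree_under_oracle(instances, bank, oracle):
    for inst in instances[:10]:
        multi = classify_instance(inst, "multiclass", oracle, bank=bank)
        binary = classify_instance(inst, "binary", oracle, bank=bank)
        assert multi == binary == inst.gold


def test_corpus_level_identity_multiset(small_corpus, bank):
    docs, _ = small_corpus
    docs = docs[:8]
    oracle = OracleBackend.from_documents(docs)
    records = run_extraction(docs, "multiclass", oracle, bank=bank)
    assert sorted(r.predicted for r in records) == sorted(r.gold for r in records)
    report = score_records(records)
    assert report.micro_f1 == 1.0


def test_run_extraction_record_count(small_corpus, bank, oracle):
    docs, _ = small_corpus
    docs = docs[:3]
    n_pairs = sum(len(enumerate_pairs(d)) for d in docs)
    records = run_extraction(docs, "binary", oracle, bank=bank)
    assert len(records) == n_pairs
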