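"""Metric computation and inter-annotator agreement."""

import copy
import random

import pytest

from temporel.corpus_io import AnnotatedDocument, Entity, Relation
from temporel.evaluate import iaa, score, score_records
from temporel.schema import ALL_LABELS, NONE_LABEL, RELATION_LABELS
from temporel.synth import GenerationConfig, generate_corpus


def _keys(n):
    return [("d", f"S{i}", f"P{i}") for i in range(n)]


def test_perfect_predictions_score_one():
    keys = _keys(10)
    gold = {k: RELATION_LABELS[i % 7] for i, k in enumerate(keys)}
    report = score(gold, gold)
    for label in RELATION_LABELS:
        if report.per_label[label].support:
            assert report.per_label[label].f1 == 1.0
    assert report.micro_f1 == 1.0


def test_hand_contingency():
    """4 gold BEGINS-AT; 3 found plus 2 spurious → P=0.6, R=0.75, F1≈0.667."""
    keys = _keys(6)
    gold = {keys[i]: "BEGINS-AT" for i in range(4)}
    gold[keys[4]] = NONE_LABEL
    gold[keys[5]] = NONE_LABEL
    predictions = {keys[i]: "BEGINS-AT" for i in range(3)}
    predictions[keys[3]] = NONE_LABEL
    predictions[keys[4]] = "BEGINS-AT"
    predictions[keys[5]] = "BEGINS-AT"
    m = score(predictions, gold).per_label["BEGINS-AT"]
    assert m.precision == pytest.approx(0.6)
    assert m.recall == pytest.approx(0.75)
    assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / (0.6 + 0.75))
    assert m.support == 4


def test_zero_support_zero_predictions_flagged_undefined():
    keys = _keys(3)
    gold = {k: "BEFORE" for k in keys}
    report = score(gold, gold)
    m = report.per_label["SIMULTANEOUS"]
    assert m.undefined and m.f1 == 0.0 and m.support == 0
    assert not report.per_label["BEFORE"].undefined


def test_support_sums_to_gold_relation_count():
    rng = random.Random(0)
    keys = _keys(50)
    gold = {k: rng.choice(ALL_LABELS) for k in keys}
    report = score(gold, gold)
    expected = sum(1 for v in gold.values() if v != NONE_LABEL)
    assert sum(m.support for m in report.per_label.values()) == expected


def test_mismatched_instance_sets_rejected():
    gold = {k: "BEFORE" for k in _keys(3)}
    predictions = {k: "BEFORE" for k in _keys(2)}
    with pytest.raises(ValueError, match="differ"):
        score(predictions, gold)


def test_unknown_label_rejected():
    keys = _keys(1)
    with pytest.raises(ValueError, match="unknown"):
        score({keys[0]: "AFTER"}, {keys[0]: "BEFORE"})


def test_micro_f1_equals_accuracy():
    rng = random.Random(4)
    keys = _keys(200)
    gold = {k: rng.choice(RELATION_LABELS) for k in keys}
    predictions = {k: rng.choice(ALL_LABELS) for k in keys}
    report = score(predictions, gold)
    accuracy = sum(predictions[k] == gold[k] for k in keys) / len(keys)
    assert report.micro_f1 == pytest.approx(accuracy)


def test_macro_invariant_under_label_permutation():
    rng = random.Random(5)
    keys = _keys(300)
    gold = {k: rng.choice(RELATION_LABELS) for k in keys}
    predictions = {k: rng.choice(RELATION_LABELS) for k in keys}
    base = score(predictions, gold)
    permutation = dict(zip(RELATION_LABELS, RELATION_LABELS[1:] + RELATION_LABELS[:1]))
    permuted = score(
        {k: permutation[v] for k, v in predictions.items()},
        {k: permutation[v] for k, v in gold.items()},
    )
    assert permuted.macro_f1 == pytest.approx(base.macro_f1)


def test_order_independence():
    rng = random.Random(6)
    keys = _keys(100)
    gold = {k: rng.choice(ALL_LABELS) for k in keys}
    predictions = {k: rng.choice(ALL_LABELS) for k in keys}
    shuffled = list(keys)
    rng.shuffle(shuffled)
    a = score(predictions, gold)
    b = score({k: predictions[k] for k in shuffled}, {k: gold[k] for k in shuffled})
    assert a.to_dict() == b.to_dict()


def test_against_sklearn_reference():
    """Dual route: per-label P/R/F1 must match scikit-learn's computation."""
    from sklearn.metrics import precision_recall_fscore_support

    rng = random.Random(7)
    keys = _keys(400)
    gold = {k: rng.choice(ALL_LABELS) for k in keys}
    predictions = {k: rng.choice(ALL_LABELS) for k in keys}
    report = score(predictions, gold)
    y_true = [gold[k] for k in keys]
    y_pred = [predictions[k] for k in keys]
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=list(RELATION_LABELS), zero_division=0
    )
    for i, label in enumerate(RELATION_LABELS):
        m = report.per_label[label]
        assert m.precision == pytest.approx(p[i])
        assert m.recall == pytest.approx(r[i])
        assert m.f1 == pytest.approx(f[i])
        assert m.support == s[i]


def test_confusion_tally_includes_none():
    keys = _keys(2)
    gold = {keys[0]: "BEFORE", keys[1]: NONE_LABEL}
    predictions = {keys[0]: NONE_LABEL, keys[1]: NONE_LABEL}
    report = score(predictions, gold)
    assert report.confusion[("BEFORE", NONE_LABEL)] == 1
    assert report.confusion[(NONE_LABEL, NONE_LABEL)] == 1


def test_report_serialization_round_trip():
    import json

    keys = _keys(20)
    gold = {k: RELATION_LABELS[i % 7] for i, k in enumerate(keys)}
    report = score(gold, gold)
    payload = json.loads(report.to_json())
    assert payload["macro_f1"] == report.macro_f1
    table = report.to_table()
    for label in RELATION_LABELS:
        assert label in table


def test_score_records_requires_gold():
    from temporel.classify import PredictionRecord

    rec = PredictionRecord("d", "S", "P", predicted="BEFORE", gold=None)
    with pytest.raises(ValueError, match="gold"):
        score_records([rec])


# --- inter-annotator agreement ------------------------------------------------


def _single_type_doc(n_relations, rtype="BEFORE-OVERLAP"):
    words, entities = [], []
    for i in range(n_relations):
        words += [f"{i:02d}/01/2020", f"signe{i}"]
    text = " ".join(words)
    pos = 0
    relations = []
    for i in range(n_relations):
        date = f"{i:02d}/01/2020"
        sign = f"signe{i}"
        ds = text.index(date)
        ss = text.index(sign)
        entities.append(Entity(f"T{2*i+1}", "DOV", ds, ds + len(date), date))
        entities.append(Entity(f"T{2*i+2}", "Phenotype", ss, ss + len(sign), sign))
        relations.append(Relation(f"R{i+1}", rtype, f"T{2*i+1}", f"T{2*i+2}"))
    doc = AnnotatedDocument("d0", text, entities, relations)
    doc.validate()
    return doc


def test_identical_annotations_agree_perfectly():
    doc = _single_type_doc(5)
    assert iaa([doc], [copy.deepcopy(doc)]) == 1.0


def test_hand_computed_iaa():
    """A: 10 relations; B misses 2 and adds 1 spurious → F1 = 16/19."""
    doc_a = _single_type_doc(10)
    doc_b = copy.deepcopy(doc_a)
    doc_b.relations = doc_b.relations[:8]
    # spurious: relate DOV 0 to phenotype 1 (pair A never annotated)
    doc_b.relations.append(Relation("R99", "BEFORE-OVERLAP", "T1", "T4"))
    assert iaa([doc_a], [doc_b]) == pytest.approx(16 / 19)
    assert iaa([doc_b], [doc_a]) == pytest.approx(16 / 19)


def test_disjoint_document_sets_rejected():
    doc_a = _single_type_doc(2)
    doc_b = copy.deepcopy(doc_a)
    doc_b.doc_id = "other"
    with pytest.raises(ValueError, match="different documents"):
        iaa([doc_a], [doc_b])


def test_entity_ids_do_not_matter():
    doc_a = _single_type_doc(4)
    doc_b = copy.deepcopy(doc_a)
    # annotator B numbered entities differently
    mapping = {e.id: f"X{i}" for i, e in enumerate(doc_b.entities)}
    doc_b.entities = [
        Entity(mapping[e.id], e.etype, e.start, e.end, e.surface)
        for e in doc_b.entities
    ]
    doc_b.relations = [
        Relation(r.id, r.rtype, mapping[r.source], mapping[r.target])
        for r in doc_b.relations
    ]
    assert iaa([doc_a], [doc_b]) == 1.0


def _perturbed(docs, rng):
    """A second annotator: drops ~30% of relations and relabels ~20%."""
    out = []
    for doc in docs:
        clone = copy.deepcopy(doc)
        kept = []
        for rel in clone.relations:
            if rng.random() < 0.3:
                continue
            if rng.random() < 0.2:
                rel = Relation(
                    rel.id,
                    rng.choice([l for l in RELATION_LABELS if l != rel.rtype]),
                    rel.source,
                    rel.target,
                )
            kept.append(rel)
        clone.relations = kept
        out.append(clone)
    return out


def test_iaa_symmetry_100_seeded_trials():
    base = generate_corpus(GenerationConfig(n_docs=4, seed=13))
    rng = random.Random(99)
    for _ in range(100):
        other = _perturbed(base, rng)
        assert iaa(base, other) == pytest.approx(iaa(other, base))


def test_iaa_decreases_with_disagreement():
    base = generate_corpus(GenerationConfig(n_docs=6, seed=17))
    rng = random.Random(3)
    assert iaa(base, base) == 1.0
    assert iaa(base, _perturbed(base, rng)) < 1.0
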