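"""Metrics, AUC, balanced down-sampling, bias labelling, length stratification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from repliclass.evaluation import (
    ConfusionMatrix,
    auc,
    balanced_downsample,
    compute_metrics,
    label_contigs_by_kmer_bias,
    length_stratified_report,
)
from repliclass.kmer import build_database, shared_fraction


def oracle_metrics(tp, tn, fp, fn):
    """Independent re-statement of the ten printed formulas."""
    def d(a, b):
        return a / b if b else None
    sens, prec = d(tp, tp + fn), d(tp, tp + fp)
    return {
        "sensitivity": sens,
        "specificity": d(tn, tn + fp),
        "accuracy": d(tp + tn, tp + tn + fp + fn),
        "precision": prec,
        "fnr": d(fn, tp + fn),
        "fpr": d(fp, tn + fp),
        "for": d(fn, fn + tn),
        "fdr": d(fp, fp + tp),
        "npv": d(tn, fn + tn),
        "f1": (2 * sens * prec / (sens + prec)) if (sens and prec) else None,
    }


def test_compute_metrics_worked_example():
    m = compute_metrics(ConfusionMatrix(tp=9, fn=1, tn=8, fp=2))
    assert m.sensitivity == pytest.approx(0.9)
    assert m.specificity == pytest.approx(0.8)
    assert m.precision == pytest.approx(9 / 11)
    assert m.f1 == pytest.approx(2 * (0.9 * 9 / 11) / (0.9 + 9 / 11))
    assert m.prevalence == pytest.approx(0.5)


def test_perfect_prediction():
    m = compute_metrics(ConfusionMatrix(tp=5, tn=7, fp=0, fn=0))
    assert (m.sensitivity, m.specificity, m.accuracy, m.f1) == (1.0, 1.0, 1.0, 1.0)
    assert (m.fnr, m.fpr, m.for_, m.fdr) == (0.0, 0.0, 0.0, 0.0)


def test_label_inversion_swaps_sensitivity_and_specificity():
    m = compute_metrics(ConfusionMatrix(tp=9, fn=1, tn=6, fp=4))
    inv = compute_metrics(ConfusionMatrix(tp=6, fn=4, tn=9, fp=1))
    assert m.sensitivity == inv.specificity
    assert m.specificity == inv.sensitivity


def test_metrics_match_oracle_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(100):
        tp, tn, fp, fn = rng.integers(0, 50, size=4)
        got = compute_metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))).to_dict()
        expected = oracle_metrics(int(tp), int(tn), int(fp), int(fn))
        for key, val in expected.items():
            if val is None:
                assert got[key] is None
            else:
                assert got[key] == pytest.approx(val, abs=1e-12)


def test_complementary_pair_identities():
    rng = np.random.default_rng(1)
    for _ in range(50):
        tp, tn, fp, fn = (int(x) for x in rng.integers(1, 50, size=4))
        m = compute_metrics(ConfusionMatrix(tp, tn, fp, fn))
        assert m.sensitivity + m.fnr == pytest.approx(1.0, abs=1e-12)
        assert m.specificity + m.fpr == pytest.approx(1.0, abs=1e-12)
        assert m.precision + m.fdr == pytest.approx(1.0, abs=1e-12)
        assert m.npv + m.for_ == pytest.approx(1.0, abs=1e-12)


def test_zero_denominators_reported_missing():
    m = compute_metrics(ConfusionMatrix(0, 0, 0, 0))
    assert all(v is None for v in m.to_dict().values())
    no_pos = compute_metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=0))
    assert no_pos.sensitivity is None
    assert no_pos.precision is None
    assert no_pos.specificity == 1.0


def test_auc_examples():
    assert auc([0.9, 0.8, 0.2, 0.1], ["plasmid", "plasmid", "chromosome", "chromosome"]) == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], ["plasmid", "plasmid", "chromosome", "chromosome"]) == 0.5
    got = auc([0.9, 0.8, 0.85, 0.1], ["plasmid", "plasmid", "chromosome", "chromosome"])
    assert got == pytest.approx(0.75)


def test_auc_single_class_undefined():
    with pytest.raises(ValueError):
        auc([0.5, 0.6], ["plasmid", "plasmid"])


def test_auc_matches_brute_force_and_sklearn():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 1)  # coarse scores force ties
        truth = np.where(rng.random(n) < 0.5, "plasmid", "chromosome")
        if len(set(truth)) < 2:
            continue
        pos = scores[truth == "plasmid"]
        neg = scores[truth == "chromosome"]
        brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg])
        got = auc(scores, truth)
        assert got == pytest.approx(brute)
        assert got == pytest.approx(roc_auc_score(truth == "plasmid", scores))


def _records(n_chrom, n_plasmid, length=1000):
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n_chrom + n_plasmid)],
            "length": length,
            "truth": ["chromosome"] * n_chrom + ["plasmid"] * n_plasmid,
        }
    )


def test_balanced_downsample_equalizes_counts():
    table = _records(1000, 100)
    out = balanced_downsample(table, seed=0)
    counts = out["truth"].value_counts()
    assert counts["chromosome"] == 100
    assert counts["plasmid"] == 100


def test_balanced_downsample_noop_when_balanced():
    table = _records(50, 50)
    out = balanced_downsample(table, seed=0)
    pd.testing.assert_frame_equal(out, table)


def test_balanced_downsample_deterministic_and_stratified():
    table = pd.concat([_records(30, 10, length=500), _records(8, 20, length=2000)], ignore_index=True)
    a = balanced_downsample(table, seed=3)
    b = balanced_downsample(table, seed=3)
    pd.testing.assert_frame_equal(a, b)
    for length, group in a.groupby("length"):
        counts = group["truth"].value_counts()
        assert counts["chromosome"] == counts["plasmid"]


def test_balanced_downsample_requires_both_classes():
    with pytest.raises(ValueError):
        balanced_downsample(_records(10, 0), seed=0)


def test_bias_labeling_recovers_verbatim_fragments(small_genome):
    chrom = small_genome.chromosome
    plasmid = small_genome.plasmids[0]
    contigs = [
        ("c_frag", chrom[1][10_000:13_000]),
        ("p_frag", plasmid[1][500:2_500]),
    ]
    labels, discarded = label_contigs_by_kmer_bias(contigs, [chrom], small_genome.plasmids)
    assert dict(labels) == {"c_frag": "chromosome", "p_frag": "plasmid"}
    assert discarded == []


def test_bias_labeling_discards_low_sharing_contigs(small_genome):
    rng = np.random.default_rng(4)
    chrom = small_genome.chromosome
    alien = "".join(rng.choice(list("ACGT"), size=400))
    contig = chrom[1][:2_000] + alien
    union = build_database([chrom] + small_genome.plasmids, 21, 1.0)
    sf = shared_fraction("q", contig, union).shared_fraction
    assert 0.5 < sf < 0.95  # fixture construction places it below the discard threshold
    labels, discarded = label_contigs_by_kmer_bias([("chimera", contig)], [chrom], small_genome.plasmids)
    assert labels == []
    assert discarded == [("chimera", "misassembled")]


def test_bias_labeling_discards_exact_ties(small_genome):
    chrom = small_genome.chromosome
    plasmid = small_genome.plasmids[1]
    half = 1_000
    contig = chrom[1][5_000 : 5_000 + half] + plasmid[1][100 : 100 + half]
    labels, discarded = label_contigs_by_kmer_bias(
        [("chimera", contig)], [chrom], small_genome.plasmids, discard_threshold=0.9
    )
    assert labels == []
    assert discarded == [("chimera", "ambiguous")]


def test_length_stratified_report_counts():
    rng = np.random.default_rng(5)
    n = 200
    lengths = rng.integers(100, 5000, size=n)
    truth = np.where(rng.random(n) < 0.4, "plasmid", "chromosome")
    pred = np.where(rng.random(n) < 0.1, "chromosome", truth)  # mostly right
    table = pd.DataFrame({"length": lengths, "truth": truth, "predicted": pred})
    report = length_stratified_report(table, bins=[0, 500, 1000, 2000])
    assert report[0].n_records == n
    for threshold in (500, 1000, 2000):
        assert report[threshold].n_records == int((lengths >= threshold).sum())
    assert report[2000].n_records <= report[1000].n_records <= report[500].n_records
    # bin 0 equals the unstratified report
    unstrat = length_stratified_report(table, bins=[0])[0]
    assert unstrat.metrics.to_dict() == report[0].metrics.to_dict()


def test_length_stratified_report_excludes_filtered_calls():
    table = pd.DataFrame(
        {
            "length": [300, 1500, 1500],
            "truth": ["plasmid", "plasmid", "chromosome"],
            "predicted": ["filtered", "plasmid", "chromosome"],
        }
    )
    report = length_stratified_report(table, bins=[0])
    assert report[0].n_records == 2
    assert report[0].metrics.accuracy == 1.0
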