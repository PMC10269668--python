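"""ORF scanning, alignment scoring, marker hits and the derived features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repliclass.kmer import reverse_complement
from repliclass.markers import (
    MPS_EVALUE_MAX,
    CategoryFeatures,
    MarkerDatabase,
    MarkerHit,
    MarkerRecord,
    NaiveBackend,
    best_hit_per_gene,
    category_features,
    find_orfs,
    neg_log_evalue,
    nucleotide_alignment_score,
    protein_alignment_score,
    pseudo_evalue,
    rds_features,
    search_markers,
    ungapped_local_score,
)


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


def test_find_orfs_minimal_example():
    orfs = find_orfs("ATGAAATAA", min_aa=2)
    assert len(orfs) == 1
    assert orfs[0].protein == "MK"
    assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (0, 9, "+")


def test_find_orfs_no_start_codon():
    assert find_orfs("C" * 300, min_aa=2) == []


def test_find_orfs_requires_terminating_stop():
    assert find_orfs("ATGAAAAAA", min_aa=2) == []


def test_find_orfs_strand_symmetric():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=3_000))
    fwd = sorted(o.protein for o in find_orfs(seq, min_aa=10))
    rev = sorted(o.protein for o in find_orfs(reverse_complement(seq), min_aa=10))
    assert fwd == rev
    assert fwd  # fixture long enough to contain ORFs


def test_find_orfs_reports_forward_coordinates():
    # reverse-complement of ATG AAA TAA embedded in context
    core = "TTACATTTACATTTACATTTACATTTTTACATTTTTCAT"  # contains revcomp ORF
    orfs = find_orfs(core, min_aa=2)
    for orf in orfs:
        assert 0 <= orf.start < orf.end <= len(core)
        assert (orf.end - orf.start) % 3 == 0


# ---------------------------------------------------------------------------
# Scores and E-values
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("e,expected", [(1e-50, 50.0), (1.0, 0.0), (0.0, 300.0), (10.0, 0.0)])
def test_neg_log_evalue(e, expected):
    assert neg_log_evalue(e) == expected


def test_neg_log_evalue_rejects_negative():
    with pytest.raises(ValueError):
        neg_log_evalue(-1.0)


def test_ungapped_local_score_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(20):
        M = rng.normal(size=(8, 11))
        # brute force: every diagonal run
        best = 0.0
        m, n = M.shape
        for i in range(m):
            for j in range(n):
                total = 0.0
                for t in range(min(m - i, n - j)):
                    total += M[i + t, j + t]
                    best = max(best, total)
        assert ungapped_local_score(M) == pytest.approx(best)


def test_exact_protein_match_scores_diagonal_sum():
    protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    score = protein_alignment_score(protein, protein)
    assert score > 4 * len(protein)  # BLOSUM62 diagonal is >= 4 for every residue


def test_nucleotide_score_finds_reverse_strand_copy():
    rng = np.random.default_rng(2)
    motif = "".join(rng.choice(list("ACGT"), size=60))
    host = "".join(rng.choice(list("ACGT"), size=500))
    planted = host[:200] + reverse_complement(motif) + host[200:]
    assert nucleotide_alignment_score(planted, motif) == 5.0 * 60


def test_pseudo_evalue_formula():
    assert pseudo_evalue(10.0, 100, 60) == pytest.approx(100 * 60 * 2.0**-10)
    assert pseudo_evalue(5000.0, 100, 60) == 0.0  # underflow


# ---------------------------------------------------------------------------
# Category and RDS features
# ---------------------------------------------------------------------------


def _hit(category="conjugation", score=100.0, e=1e-60, rds=None, gene=None):
    return MarkerHit("q", category, "m", score, e, rds=rds, gene_id=gene)


def test_category_features_absence_default():
    assert category_features([], "conjugation") == CategoryFeatures(0.0, 0.0, 0)


def test_category_features_presence_rule():
    feats = category_features([_hit(score=120.0, e=1e-60)], "conjugation")
    assert feats == CategoryFeatures(120.0, 60.0, 1)
    below = category_features([_hit(e=1e-10), _hit(e=1e-40)], "conjugation")
    assert below.max_neg_log_e == 40.0
    assert below.present == 0


def test_category_features_threshold_is_inclusive():
    assert category_features([_hit(e=1e-50)], "conjugation").present == 1
    assert category_features([_hit(e=1e-49)], "conjugation").present == 0


@pytest.mark.parametrize(
    "values,expected_bias",
    [([5.0, 5.0], 1), ([-12.0, -10.0], -1), ([0.0], 0), ([4.9], 0), ([-9.9], 0)],
)
def test_rds_bias_thresholds(values, expected_bias):
    hits = [_hit("mps", rds=v, gene=f"g{i}") for i, v in enumerate(values)]
    feats = rds_features(hits)
    assert feats.avg_score == pytest.approx(np.mean(values))
    assert feats.max_score == max(values)
    assert feats.bias == expected_bias


def test_rds_features_empty_and_invalid():
    assert rds_features([]).avg_score == 0.0
    with pytest.raises(ValueError):
        rds_features([_hit("conjugation")])  # lacks rds


@given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=20))
@settings(max_examples=50, deadline=None)
def test_rds_features_permutation_invariant(values):
    hits = [_hit("mps", rds=v, gene=f"g{i}") for i, v in enumerate(values)]
    rng = np.random.default_rng(0)
    shuffled = [hits[i] for i in rng.permutation(len(hits))]
    a, b = rds_features(hits), rds_features(shuffled)
    assert a.avg_score == pytest.approx(b.avg_score)
    assert a.avg_score == pytest.approx(float(np.mean(values)))
    assert a.bias == b.bias


def test_best_hit_per_gene_keeps_lowest_evalue():
    hits = [
        _hit("mps", score=10.0, e=1e-20, rds=1.0, gene="g1"),
        _hit("mps", score=99.0, e=1e-10, rds=2.0, gene="g1"),
        _hit("mps", score=5.0, e=1e-5, rds=3.0, gene="g2"),
    ]
    best = best_hit_per_gene(hits)
    assert len(best) == 2
    assert {h.gene_id: h.rds for h in best} == {"g1": 1.0, "g2": 3.0}


# ---------------------------------------------------------------------------
# Backend
# ---------------------------------------------------------------------------


def test_backend_finds_planted_orit(small_genome, backend):
    pid, seq = small_genome.plasmids[0]
    hits = backend.search(pid, seq, small_genome.marker_db)
    orit = [h for h in hits if h.category == "orit"]
    assert orit and max(neg_log_evalue_of(h) for h in orit) >= 50

def neg_log_evalue_of(h):
    return neg_log_evalue(h.evalue)


def test_backend_empty_marker_db():
    empty = MarkerDatabase([])
    with pytest.warns(UserWarning, match="lacks categories"):
        hits = search_markers("q", "ACGT" * 300, NaiveBackend(), empty)
    assert hits == []


def test_backend_is_deterministic(small_genome, backend):
    pid, seq = small_genome.plasmids[1]
    first = backend.search(pid, seq, small_genome.marker_db)
    second = backend.search(pid, seq, small_genome.marker_db)
    assert first == second


def test_backend_mps_hits_carry_rds_and_are_deduplicated(small_genome, backend):
    pid, seq = small_genome.plasmids[0]
    hits = [h for h in backend.search(pid, seq, small_genome.marker_db) if h.category == "mps"]
    assert hits
    assert all(h.rds is not None and h.evalue <= MPS_EVALUE_MAX for h in hits)
    genes = [h.gene_id for h in hits]
    assert len(genes) == len(set(genes))  # one best hit per gene


def test_marker_db_tsv_round_trip(tmp_path, small_genome):
    path = tmp_path / "markers.tsv"
    small_genome.marker_db.save_tsv(path)
    loaded = MarkerDatabase.load_tsv(path)
    assert loaded.records == small_genome.marker_db.records
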