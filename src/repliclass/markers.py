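"""Genomic-marker search and the marker-derived features.

Beyond raw k-mer sharing, the classifier uses higher-level genomic markers:
conjugation, mobilization and replication genes, AMR genes, marker protein sequences
(MPS) carrying a replicon distribution score (RDS, positive for plasmid-enriched and
negative for chromosome-enriched proteins), the oriT transfer-origin motif, and rRNA
genes (chromosome-exclusive).  For every category the features are the maximum
alignment score and maximum -log10(E-value) over all hits on the sequence, plus a 0/1
presence flag that is set when the maximum -log10(E-value) reaches 50 (E <= 1e-50).

Search is abstracted behind :class:`SearchBackend`.  The built-in
:class:`NaiveBackend` extracts ORFs with a six-frame ATG->stop scan, scores candidate
genes by best ungapped local alignment (BLOSUM62 for proteins, +5/-4 for
nucleotides), and converts a raw score S into the pseudo E-value ``e = m * n *
2**(-S)`` (m, n the query/target lengths).  This statistic is intentionally simple —
deterministic and adequate for planted-marker fixtures — and is *not* equivalent to
HMMER/DIAMOND/BLAST statistics.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.Align import substitution_matrices

from .kmer import seq_codes

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

CATEGORIES = ("conjugation", "mobilization", "replication", "amr", "mps", "orit", "rrna")
PROTEIN_CATEGORIES = frozenset({"conjugation", "mobilization", "replication", "amr", "mps"})
NUCLEOTIDE_CATEGORIES = frozenset({"orit", "rrna"})

#: -log10(E) at or above which a marker category is marked present.
PRESENCE_NEG_LOG_E = 50.0
#: Cap for -log10(E) when the E-value underflows to 0.
NEG_LOG_E_CAP = 300.0
#: rdsBias is +1 when the average RDS is >= this value ...
RDS_BIAS_PLASMID = 5.0
#: ... and -1 when it is <= this value; otherwise 0.
RDS_BIAS_CHROMOSOME = -10.0
#: Default minimum ORF length (codons) for the built-in backend.
DEFAULT_MIN_ORF_AA = 30
#: Best-hit E-value an ORF must reach against the MPS database to enter RDS averaging.
MPS_EVALUE_MAX = 1e-10

# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerRecord:
    """One entry of a marker database (protein or nucleotide payload)."""

    marker_id: str
    category: str
    sequence: str
    rds: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown marker category {self.category!r}")
        if (self.rds is not None) != (self.category == "mps"):
            raise ValueError("rds must be present exactly for category 'mps'")

    @property
    def moltype(self) -> str:
        return "protein" if self.category in PROTEIN_CATEGORIES else "nucleotide"


class MarkerDatabase:
    """Marker records grouped by category; round-trips through a TSV file."""

    def __init__(self, records: Iterable[MarkerRecord]):
        self.records: list[MarkerRecord] = list(records)
        self.by_category: dict[str, list[MarkerRecord]] = {}
        for rec in self.records:
            self.by_category.setdefault(rec.category, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def categories(self) -> set[str]:
        return set(self.by_category)

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["marker_id", "category", "rds", "sequence"])
            for rec in self.records:
                rds = "NA" if rec.rds is None else repr(rec.rds)
                writer.writerow([rec.marker_id, rec.category, rds, rec.sequence])

    @classmethod
    def load_tsv(cls, path: str | Path) -> "MarkerDatabase":
        records = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:4] != ["marker_id", "category", "rds", "sequence"]:
                raise ValueError(f"{path}: not a marker database TSV")
            for row in reader:
                marker_id, category, rds, sequence = row[:4]
                records.append(
                    MarkerRecord(
                        marker_id=marker_id,
                        category=category,
                        sequence=sequence,
                        rds=None if rds == "NA" else float(rds),
                    )
                )
        return cls(records)


@dataclass(frozen=True)
class MarkerHit:
    """One search hit of a marker against a query sequence."""

    query_id: str
    category: str
    marker_id: str
    score: float
    evalue: float
    rds: Optional[float] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if (self.rds is not None) != (self.category == "mps"):
            raise ValueError("rds must be present exactly for category 'mps'")


@dataclass(frozen=True)
class CategoryFeatures:
    max_score: float
    max_neg_log_e: float
    present: int


@dataclass(frozen=True)
class RDSFeatures:
    avg_score: float
    max_score: float
    bias: int


@dataclass(frozen=True)
class Orf:
    """An open reading frame; coordinates are forward-strand, 0-based half-open,
    spanning start codon through stop codon."""

    protein: str
    start: int
    end: int
    strand: str


# ---------------------------------------------------------------------------
# ORF extraction (six-frame ATG->stop scan)
# ---------------------------------------------------------------------------

_B = "ACGT"
_AA = np.array(
    [str(Seq(a + b + c).translate()) for a in _B for b in _B for c in _B]
)
_STOP_VALS = np.nonzero(_AA == "*")[0].astype(np.int16)
_ATG_VAL = np.int16(0 * 16 + 3 * 4 + 2)


def find_orfs(seq: str, min_aa: int = DEFAULT_MIN_ORF_AA) -> list[Orf]:
    """All maximal ATG->stop ORFs of >= ``min_aa`` codons on both strands.

    Maximal means the earliest in-frame ATG after the previous stop (or sequence
    start) for each stop codon.  ORFs without a terminating stop codon, and ORFs
    interrupted by an ambiguous codon, are not reported.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    codes = seq_codes(seq)
    L = codes.size
    orfs: list[Orf] = []
    for strand in ("+", "-"):
        if strand == "+":
            cc = codes
        else:
            rev = codes[::-1]
            cc = np.where(rev > 3, np.uint8(255), np.uint8(3) - rev)
        for frame in range(3):
            ncod = (L - frame) // 3
            if ncod < min_aa + 1:
                continue
            cod = cc[frame : frame + 3 * ncod].reshape(ncod, 3).astype(np.int16)
            valid = (cod < 4).all(axis=1)
            val = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
            val[~valid] = -1
            start_idx = np.nonzero(val == _ATG_VAL)[0]
            is_stop = np.isin(val, _STOP_VALS)
            breaker_idx = np.nonzero(is_stop | ~valid)[0]
            prev = -1
            for b in breaker_idx:
                if val[b] == -1:  # ambiguous codon: breaks ORFs, terminates none
                    prev = b
                    continue
                pos = np.searchsorted(start_idx, prev + 1)
                if pos < start_idx.size and start_idx[pos] < b:
                    s = int(start_idx[pos])
                    if b - s >= min_aa:
                        protein = "".join(_AA[val[s:b]])
                        nt_start = int(frame + 3 * s)
                        nt_end = int(frame + 3 * (b + 1))
                        if strand == "+":
                            orfs.append(Orf(protein, nt_start, nt_end, "+"))
                        else:
                            orfs.append(Orf(protein, L - nt_end, L - nt_start, "-"))
                prev = b
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def neg_log_evalue(e: float) -> float:
    """-log10(E), floored at 0 (E >= 1) and capped at 300 (E underflowed to 0)."""
    if e < 0:
        raise ValueError("E-value must be >= 0")
    if e == 0:
        return NEG_LOG_E_CAP
    return float(min(max(0.0, -math.log10(e)), NEG_LOG_E_CAP))


def pseudo_evalue(score: float, m: int, n: int) -> float:
    """Pseudo E-value ``m * n * 2**(-score)`` of an ungapped local score."""
    if score <= 0:
        return float(m * n)
    try:
        return float(m) * float(n) * math.pow(2.0, -score)
    except OverflowError:
        return 0.0


def ungapped_local_score(score_matrix: np.ndarray) -> float:
    """Best ungapped local alignment score given a pairwise score matrix.

    Equivalent to the maximum, over all diagonals, of the maximum-sum contiguous run
    (Smith-Waterman with gaps forbidden); 0 when no positive-scoring run exists.
    """
    M = score_matrix
    if M.size == 0:
        return 0.0
    if M.shape[0] > M.shape[1]:
        M = M.T
    m, n = M.shape
    run = np.zeros(n)
    shifted = np.empty(n)
    best = 0.0
    for i in range(m):
        shifted[0] = 0.0
        shifted[1:] = run[:-1]
        np.maximum(shifted, 0.0, out=shifted)
        run = shifted + M[i]
        row_max = run.max()
        if row_max > best:
            best = float(row_max)
    return best


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ALPHABET = str(_BLOSUM62.alphabet)
_BLOSUM_ARRAY = np.array(_BLOSUM62)
_AA_INDEX = np.full(128, _BLOSUM_ALPHABET.index("X"), dtype=np.intp)
for _j, _c in enumerate(_BLOSUM_ALPHABET):
    _AA_INDEX[ord(_c)] = _j


def _protein_indices(protein: str) -> np.ndarray:
    return _AA_INDEX[np.frombuffer(protein.upper().encode("ascii"), dtype=np.uint8)]


def protein_alignment_score(a: str, b: str) -> float:
    """Best ungapped local BLOSUM62 score between two protein sequences."""
    ia, ib = _protein_indices(a), _protein_indices(b)
    return ungapped_local_score(_BLOSUM_ARRAY[np.ix_(ia, ib)])


NT_MATCH = 5.0
NT_MISMATCH = -4.0


def nucleotide_alignment_score(a: str, b: str, both_strands: bool = True) -> float:
    """Best ungapped local +5/-4 score between two DNA sequences.

    With ``both_strands`` the reverse complement of ``b`` is also scored and the
    maximum taken, making the score strand-symmetric.
    """
    ca, cb = seq_codes(a), seq_codes(b)
    score = _nt_score(ca, cb)
    if both_strands:
        rcb = np.where(cb[::-1] > 3, np.uint8(255), np.uint8(3) - cb[::-1])
        score = max(score, _nt_score(ca, rcb))
    return score


def _nt_score(ca: np.ndarray, cb: np.ndarray) -> float:
    if ca.size == 0 or cb.size == 0:
        return 0.0
    eq = (ca[:, None] == cb[None, :]) & (ca[:, None] < 4) & (cb[None, :] < 4)
    return ungapped_local_score(np.where(eq, NT_MATCH, NT_MISMATCH))


# ---------------------------------------------------------------------------
# Feature derivation
# ---------------------------------------------------------------------------


def category_features(hits: Sequence[MarkerHit], category: Optional[str] = None) -> CategoryFeatures:
    """Maximum score / maximum -log10(E) / presence flag over a category's hits.

    With no hits every field defaults to 0.  ``present`` is 1 exactly when the
    maximum -log10(E) is >= 50.
    """
    if category is not None:
        hits = [h for h in hits if h.category == category]
    if not hits:
        return CategoryFeatures(0.0, 0.0, 0)
    max_score = max(h.score for h in hits)
    max_nle = max(neg_log_evalue(h.evalue) for h in hits)
    return CategoryFeatures(max_score, max_nle, int(max_nle >= PRESENCE_NEG_LOG_E))


def best_hit_per_gene(hits: Sequence[MarkerHit]) -> list[MarkerHit]:
    """Keep the best hit (lowest E-value, ties by higher score then marker id) per gene."""
    best: dict[Optional[str], MarkerHit] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if cur is None or (h.evalue, -h.score, h.marker_id) < (cur.evalue, -cur.score, cur.marker_id):
            best[h.gene_id] = h
    return [best[g] for g in sorted(best, key=str)]


def rds_features(mps_hits: Sequence[MarkerHit]) -> RDSFeatures:
    """Average / maximum per-gene RDS and the rdsBias trichotomy.

    Expects one (best) hit per gene; bias is +1 when the average RDS is >= 5, -1 when
    it is <= -10, else 0.  No genes -> (0, 0, 0).
    """
    for h in mps_hits:
        if h.rds is None:
            raise ValueError(f"MPS hit {h.marker_id} lacks an RDS value")
    if not mps_hits:
        return RDSFeatures(0.0, 0.0, 0)
    values = [h.rds for h in mps_hits]
    avg = float(np.mean(values))
    if avg >= RDS_BIAS_PLASMID:
        bias = 1
    elif avg <= RDS_BIAS_CHROMOSOME:
        bias = -1
    else:
        bias = 0
    return RDSFeatures(avg, float(max(values)), bias)


# ---------------------------------------------------------------------------
# Search backends
# ---------------------------------------------------------------------------


class SearchBackend:
    """Contract for marker search: deterministic hit lists with a common schema."""

    name: str = "abstract"
    capabilities: frozenset = frozenset()

    def search(self, query_id: str, seq: str, marker_db: MarkerDatabase) -> list[MarkerHit]:
        raise NotImplementedError


class NaiveBackend(SearchBackend):
    """Built-in alignment backend: six-frame ORFs + ungapped local scoring.

    Protein categories are searched ORF-by-ORF with BLOSUM62; nucleotide categories
    (oriT, rRNA) are searched against the whole sequence on both strands with +5/-4
    scoring.  Raw scores become pseudo E-values via ``e = m * n * 2**(-S)``.  For the
    MPS category only ORFs whose best hit reaches ``mps_evalue_max`` contribute, one
    best hit per ORF, so that the RDS average reflects confidently matched genes.
    """

    name = "naive"
    capabilities = frozenset(CATEGORIES)

    def __init__(
        self,
        min_orf_aa: int = DEFAULT_MIN_ORF_AA,
        mps_evalue_max: float = MPS_EVALUE_MAX,
    ):
        self.min_orf_aa = min_orf_aa
        self.mps_evalue_max = mps_evalue_max

    def search(self, query_id: str, seq: str, marker_db: MarkerDatabase) -> list[MarkerHit]:
        hits: list[MarkerHit] = []
        protein_cats = [c for c in CATEGORIES if c in PROTEIN_CATEGORIES]
        need_orfs = any(marker_db.by_category.get(c) for c in protein_cats)
        orfs = find_orfs(seq, self.min_orf_aa) if need_orfs else []
        orf_idx = [_protein_indices(o.protein) for o in orfs]

        for category in CATEGORIES:
            records = marker_db.by_category.get(category)
            if not records:
                continue
            if category in NUCLEOTIDE_CATEGORIES:
                for rec in records:
                    score = nucleotide_alignment_score(seq, rec.sequence)
                    if score <= 0:
                        continue
                    e = pseudo_evalue(score, len(seq), len(rec.sequence))
                    hits.append(MarkerHit(query_id, category, rec.marker_id, score, e))
                continue
            rec_idx = [_protein_indices(rec.sequence) for rec in records]
            for gi, (orf, ia) in enumerate(zip(orfs, orf_idx)):
                gene_id = f"{orf.strand}{orf.start}-{orf.end}"
                candidates: list[MarkerHit] = []
                for rec, ib in zip(records, rec_idx):
                    score = ungapped_local_score(_BLOSUM_ARRAY[np.ix_(ia, ib)])
                    if score <= 0:
                        continue
                    e = pseudo_evalue(score, len(orf.protein), len(rec.sequence))
                    candidates.append(
                        MarkerHit(
                            query_id,
                            category,
                            rec.marker_id,
                            score,
                            e,
                            rds=rec.rds,
                            gene_id=gene_id,
                        )
                    )
                if category == "mps":
                    kept = best_hit_per_gene(candidates)
                    hits.extend(h for h in kept if h.evalue <= self.mps_evalue_max)
                else:
                    hits.extend(candidates)
        return hits


def search_markers(
    query_id: str,
    seq: str,
    backend: SearchBackend,
    marker_db: MarkerDatabase,
) -> list[MarkerHit]:
    """Run a backend over all categories it supports; missing categories warn."""
    missing = [c for c in CATEGORIES if c not in marker_db.categories()]
    if missing:
        warnings.warn(
            f"marker database lacks categories: {', '.join(missing)}; "
            "those categories will yield no hits",
            stacklevel=2,
        )
    return backend.search(query_id, seq, marker_db)


def write_hits_tsv(hits: Sequence[MarkerHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["query_id", "category", "marker_id", "score", "evalue"])
        for h in hits:
            writer.writerow([h.query_id, h.category, h.marker_id, repr(h.score), repr(h.evalue)])
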