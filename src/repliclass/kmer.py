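"""Canonical k-mer set databases with min-hash sketching and shared-fraction queries.

Plasmid and chromosome sequences differ in k-mer composition, so the fraction of a
query's k-mers found in a reference k-mer database is a strong signal of replicon
origin.  This module implements the four reference databases used by the classifier:

* ``r_k18``  — chromosome k-mers at k=18, min-hash sketched at f=0.1;
* ``p_k25``  — plasmid k-mers at k=25 (unsketched);
* ``rmp_k18`` — chromosome-minus-plasmid ("chromosome-unique") k-mers at k=18;
* ``pmr_k25`` — plasmid-minus-chromosome ("plasmid-unique") k-mers at k=25.

K-mers are stored canonically (the lexicographically smaller of a k-mer and its
reverse complement) so every query is strand-invariant.  Internally k-mers are packed
into 64-bit integers (2 bits per base, A<C<G<T, big-endian), which preserves
lexicographic order; the min-hash sketch keeps a k-mer iff a fixed-seed 64-bit hash of
its packed form falls below ``f * 2**64``.  Queries are filtered by the same criterion
before counting, so a query drawn verbatim from a database's source scores 1.0
regardless of sketching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Defaults (package-wide constants live here, at the head of the pipeline)
# ---------------------------------------------------------------------------

#: Default k for chromosome-side databases.
DEFAULT_CHROMOSOME_K = 18
#: Default k for plasmid-side databases.
DEFAULT_PLASMID_K = 25
#: Default min-hash sketch fraction f.
DEFAULT_SKETCH_FRACTION = 0.1
#: Fixed seed of the sketch hash; baked into the on-disk format for reproducibility.
HASH_SEED = 42
#: On-disk database format version understood by this build.
DB_FORMAT_VERSION = 1
#: Largest k representable in the 2-bit uint64 packing.
MAX_K = 31

_DB_MAGIC = b"RKDB"


class AmbiguousKmerError(ValueError):
    """Raised when a k-mer contains a non-ACGT symbol."""


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.array(list("ACGT"))
_RC_TABLE = str.maketrans("ACGTacgt", "TGCATGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case normalised to upper)."""
    return seq.upper().translate(_RC_TABLE)[::-1]


def seq_codes(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0,C=1,G=2,T=3; 255 for any other symbol)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")


def canonical_kmer(kmer: str) -> str:
    """Return the lexicographically smaller of a k-mer and its reverse complement.

    Idempotent; raises :class:`AmbiguousKmerError` on non-ACGT symbols (callers skip
    such k-mers).
    """
    if len(kmer) < 1:
        raise ValueError("k-mer must be non-empty")
    up = kmer.upper()
    if any(c not in "ACGT" for c in up):
        raise AmbiguousKmerError(f"ambiguous k-mer: {kmer!r}")
    rc = reverse_complement(up)
    return up if up <= rc else rc


def canonical_codes(seq: str, k: int) -> np.ndarray:
    """Packed canonical codes of every valid length-k window of ``seq`` (with repeats).

    Windows containing a non-ACGT symbol are skipped; lowercase input is uppercased by
    the encoding table.
    """
    _check_k(k)
    codes = seq_codes(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = codes > 3
    cum = np.concatenate(([0], np.cumsum(bad)))
    ok = (cum[k:] - cum[:-k]) == 0
    c = np.where(bad, 0, codes).astype(np.uint64)
    comp = np.uint64(3) - c
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | c[j : j + n]
        rev = (rev << two) | comp[k - 1 - j : k - 1 - j + n]
    return np.minimum(fwd, rev)[ok]


def distinct_canonical_codes(seq: str, k: int) -> np.ndarray:
    """Sorted distinct packed canonical k-mer codes of ``seq``."""
    return np.unique(canonical_codes(seq, k))


def decode_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Unpack uint64 codes back to k-mer strings."""
    _check_k(k)
    codes = np.asarray(codes, dtype=np.uint64)
    shifts = np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)
    idx = (codes[:, None] >> shifts[None, :]) & np.uint64(3)
    return ["".join(row) for row in _BASES[idx.astype(np.intp)]]


def extract_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical k-mers of all valid length-k windows of ``seq``."""
    return set(decode_kmers(distinct_canonical_codes(seq, k), k))


# ---------------------------------------------------------------------------
# Sketch hash: splitmix64 finalizer over the packed code, fixed seed
# ---------------------------------------------------------------------------

_MIX_ADD = np.uint64(0x9E3779B97F4A7C15)
_MIX_M1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX_M2 = np.uint64(0x94D049BB133111EB)


def _mix64(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        z = x + _MIX_ADD
        z = (z ^ (z >> np.uint64(30))) * _MIX_M1
        z = (z ^ (z >> np.uint64(27))) * _MIX_M2
        return z ^ (z >> np.uint64(31))


def kmer_hash(codes: np.ndarray, seed: int = HASH_SEED) -> np.ndarray:
    """Deterministic 64-bit hash of packed canonical k-mer codes."""
    codes = np.asarray(codes, dtype=np.uint64)
    seed_mix = _mix64(np.array([seed], dtype=np.uint64))[0]
    return _mix64(codes ^ seed_mix)


def sketch_mask(codes: np.ndarray, sketch_fraction: float, seed: int = HASH_SEED) -> np.ndarray:
    """Boolean mask of codes passing the min-hash criterion H(kmer) < f * 2**64."""
    if not 0.0 < sketch_fraction <= 1.0:
        raise ValueError("sketch_fraction must be in (0, 1]")
    codes = np.asarray(codes, dtype=np.uint64)
    if sketch_fraction >= 1.0:
        return np.ones(codes.size, dtype=bool)
    threshold = np.uint64(int(sketch_fraction * 2**64))
    return kmer_hash(codes, seed) < threshold


# ---------------------------------------------------------------------------
# Database
# ---------------------------------------------------------------------------


@dataclass
class KmerDatabase:
    """A set of canonical k-mers at fixed ``k`` with an optional min-hash sketch.

    ``kmers`` is a sorted, duplicate-free uint64 array of packed canonical codes; if
    ``sketch_fraction`` < 1 every stored k-mer passes the sketch criterion.
    """

    k: int
    kmers: np.ndarray
    sketch_fraction: float = 1.0
    label: str = ""
    source_count: int = 0
    hash_seed: int = HASH_SEED

    def __post_init__(self) -> None:
        _check_k(self.k)
        if not 0.0 < self.sketch_fraction <= 1.0:
            raise ValueError("sketch_fraction must be in (0, 1]")
        self.kmers = np.unique(np.asarray(self.kmers, dtype=np.uint64))

    def __len__(self) -> int:
        return int(self.kmers.size)

    def __contains__(self, kmer: str) -> bool:
        code = distinct_canonical_codes(canonical_kmer(kmer), self.k)
        if code.size != 1:
            return False
        i = int(np.searchsorted(self.kmers, code[0]))
        return i < self.kmers.size and self.kmers[i] == code[0]

    def kmer_strings(self) -> list[str]:
        """All stored k-mers as strings (intended for small databases and tests)."""
        return decode_kmers(self.kmers, self.k)

    @classmethod
    def from_kmers(
        cls,
        kmers: Iterable[str],
        k: int,
        sketch_fraction: float = 1.0,
        label: str = "",
        apply_sketch: bool = True,
    ) -> "KmerDatabase":
        """Build a database directly from k-mer strings (canonicalised on the way in)."""
        codes = []
        for km in kmers:
            if len(km) != k:
                raise ValueError(f"k-mer {km!r} does not have length {k}")
            codes.append(distinct_canonical_codes(km, k)[0])
        arr = np.array(codes, dtype=np.uint64)
        if apply_sketch and sketch_fraction < 1.0:
            arr = arr[sketch_mask(arr, sketch_fraction)]
        return cls(k=k, kmers=arr, sketch_fraction=sketch_fraction, label=label)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the database; byte-identical for identical databases."""
        header = {
            "format_version": DB_FORMAT_VERSION,
            "k": self.k,
            "sketch_fraction": self.sketch_fraction,
            "hash_seed": self.hash_seed,
            "label": self.label,
            "source_count": self.source_count,
            "n_kmers": len(self),
        }
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_DB_MAGIC)
            fh.write(len(blob).to_bytes(4, "little"))
            fh.write(blob)
            fh.write(self.kmers.astype("<u8").tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "KmerDatabase":
        with open(path, "rb") as fh:
            if fh.read(4) != _DB_MAGIC:
                raise ValueError(f"{path}: not a k-mer database file")
            hlen = int.from_bytes(fh.read(4), "little")
            header = json.loads(fh.read(hlen))
            if header.get("format_version") != DB_FORMAT_VERSION:
                raise ValueError(
                    f"{path}: unsupported database format version "
                    f"{header.get('format_version')!r}"
                )
            kmers = np.frombuffer(fh.read(), dtype="<u8").astype(np.uint64)
        db = cls(
            k=header["k"],
            kmers=kmers,
            sketch_fraction=header["sketch_fraction"],
            label=header["label"],
            source_count=header["source_count"],
            hash_seed=header["hash_seed"],
        )
        if len(db) != header["n_kmers"]:
            raise ValueError(f"{path}: truncated database")
        return db


@dataclass
class KmerQueryResult:
    """Shared-k-mer query outcome for one sequence against one database."""

    query_id: str
    n_query_kmers: int
    n_shared: int
    shared_fraction: float
    informative: bool = True


def build_database(
    sequences: Iterable[tuple[str, str]],
    k: int,
    sketch_fraction: float = DEFAULT_SKETCH_FRACTION,
    label: str = "",
) -> KmerDatabase:
    """Union of canonical k-mers over all sequences, filtered by the min-hash sketch.

    Deterministic across runs and platforms (fixed-seed hash, sorted storage).
    """
    _check_k(k)
    parts = []
    count = 0
    for _sid, seq in sequences:
        count += 1
        codes = distinct_canonical_codes(seq, k)
        if sketch_fraction < 1.0:
            codes = codes[sketch_mask(codes, sketch_fraction)]
        parts.append(codes)
    if count == 0:
        warnings.warn("building k-mer database from an empty sequence list", stacklevel=2)
    merged = (
        np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.uint64)
    )
    return KmerDatabase(
        k=k, kmers=merged, sketch_fraction=sketch_fraction, label=label, source_count=count
    )


def subtract(a: KmerDatabase, b: KmerDatabase) -> KmerDatabase:
    """Set difference a \\ b of two databases built at the same k.

    The result keeps ``a``'s sketch fraction: sketching is applied when each side is
    built, then the subtraction acts on the stored sets.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    diff = np.setdiff1d(a.kmers, b.kmers, assume_unique=True)
    label = f"{a.label}_minus_{b.label}" if a.label and b.label else a.label
    return KmerDatabase(
        k=a.k,
        kmers=diff,
        sketch_fraction=a.sketch_fraction,
        label=label,
        source_count=a.source_count,
    )


def shared_fraction(query_id: str, seq: str, db: KmerDatabase) -> KmerQueryResult:
    """Fraction of the query's sketch-surviving distinct canonical k-mers in ``db``.

    The query is filtered by the database's own sketch criterion before counting, so
    the denominator is the query's sketch-surviving k-mer count and a verbatim source
    sequence scores 1.0 regardless of sketching.  A query with no informative k-mers
    (too short, or all windows ambiguous) scores 0 with ``informative=False``.
    """
    codes = distinct_canonical_codes(seq, db.k)
    if db.sketch_fraction < 1.0:
        codes = codes[sketch_mask(codes, db.sketch_fraction, db.hash_seed)]
    n_query = int(codes.size)
    if n_query == 0:
        return KmerQueryResult(query_id, 0, 0, 0.0, informative=False)
    idx = np.searchsorted(db.kmers, codes)
    idx[idx == db.kmers.size] = max(db.kmers.size - 1, 0)
    if db.kmers.size:
        n_shared = int(np.count_nonzero(db.kmers[idx] == codes))
    else:
        n_shared = 0
    return KmerQueryResult(query_id, n_query, n_shared, n_shared / n_query)


def build_reference_databases(
    chromosomes: Sequence[tuple[str, str]],
    plasmids: Sequence[tuple[str, str]],
    k_chromosome: int = DEFAULT_CHROMOSOME_K,
    k_plasmid: int = DEFAULT_PLASMID_K,
    sketch_fraction: float = DEFAULT_SKETCH_FRACTION,
) -> dict[str, KmerDatabase]:
    """Build the four reference databases keyed ``r_k18/p_k25/rmp_k18/pmr_k25``.

    The chromosome database is min-hash sketched (``sketch_fraction``); the plasmid
    database is unsketched.  The "unique" databases are set differences computed at a
    common k on each side, with the subtrahend unsketched so that every shared k-mer
    is removed.
    """
    r = build_database(chromosomes, k_chromosome, sketch_fraction, label="chromosome")
    p = build_database(plasmids, k_plasmid, 1.0, label="plasmid")
    p_at_kr = build_database(plasmids, k_chromosome, 1.0, label="plasmid")
    r_at_kp = build_database(chromosomes, k_plasmid, 1.0, label="chromosome")
    rmp = subtract(r, p_at_kr)
    rmp.label = "chromosome_minus_plasmid"
    pmr = subtract(p, r_at_kp)
    pmr.label = "plasmid_minus_chromosome"
    return {"r_k18": r, "p_k25": p, "rmp_k18": rmp, "pmr_k25": pmr}
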