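"""Deterministic synthetic genomes for exercising the whole pipeline.

The generator emulates the two ingredients the classifier feeds on: (i) two
compositionally distinct sequence classes — chromosome and plasmid backbones are
drawn from different order-2 Markov chains (GC 0.42 vs 0.58 by default), standing in
for the taxonomic k-mer signal of real replicon collections — and (ii) planted marker
cassettes: plasmids receive exact copies of toy conjugation / mobilization /
replication / AMR genes, positive-RDS marker-protein genes and a 60-bp oriT motif,
while chromosomes receive rRNA motifs and negative-RDS marker-protein genes.  Every
cassette is an exact copy of a toy marker-database entry, so the built-in alignment
backend recovers it with a pseudo E-value far below the 1e-50 presence threshold.

Everything is a pure function of the seed.  A fragmenter cuts replicons into
log-normally sized contigs to emulate a fragmented short-read assembly (no read
errors or coverage model — see the methods note for what that implies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .fasta import write_fasta
from .markers import _AA, MarkerDatabase, MarkerRecord
from .training import LabeledSequence

# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

_DEFAULT_MARKER_PLAN = {
    "plasmid": {"conjugation": 1, "mobilization": 1, "replication": 1, "amr": 1, "orit": 1, "mps": 2},
    "chromosome": {"rrna": 2, "mps": 4},
}


@dataclass
class SynthGenomeSpec:
    """Study conditions for one synthetic genome set.

    The chromosome must exceed 500 kb so that it survives the chromosome length
    filter applied during training-set construction.
    """

    seed: int = 1
    chromosome_length: int = 600_000
    n_plasmids: int = 8
    plasmid_length_range: tuple[int, int] = (5_000, 60_000)
    chromosome_gc: float = 0.42
    plasmid_gc: float = 0.58
    markov_persistence: float = 0.3
    marker_plan: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MARKER_PLAN.items()})

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0 or self.n_plasmids < 0:
            raise ValueError("lengths and counts must be positive")
        lo, hi = self.plasmid_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid plasmid_length_range")
        for gc in (self.chromosome_gc, self.plasmid_gc):
            if not 0.0 < gc < 1.0:
                raise ValueError("GC targets must be in (0, 1)")


# ---------------------------------------------------------------------------
# Backbone composition: order-2 Markov chain
# ---------------------------------------------------------------------------

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _transition_tensor(gc: float, persistence: float) -> np.ndarray:
    """P(next | prev2, prev1): GC-target base frequencies modulated by a context
    preference for repeating the two preceding bases."""
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = np.empty((4, 4, 4))
    eye = np.eye(4)
    for b1 in range(4):
        for b2 in range(4):
            w = p_base * (1.0 + persistence * eye[b2] + 0.5 * persistence * eye[b1])
            T[b1, b2] = w / w.sum()
    return T


def markov_sequence(rng: np.random.Generator, length: int, gc: float, persistence: float) -> str:
    """Draw a DNA string of the given length from the order-2 chain."""
    if length <= 0:
        return ""
    T = _transition_tensor(gc, persistence)
    cum = T.cumsum(axis=2)
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]).cumsum()
    u = rng.random(length)
    out = np.empty(length, dtype=np.intp)
    out[0] = np.searchsorted(p_base, u[0])
    if length > 1:
        out[1] = np.searchsorted(p_base, u[1])
    cum_list = cum.tolist()
    o = out
    for i in range(2, length):
        row = cum_list[o[i - 2]][o[i - 1]]
        x = u[i]
        o[i] = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
    return _ASCII[out].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Toy marker database
# ---------------------------------------------------------------------------

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for _i, _aa in enumerate(_AA):
    _b = "ACGT"
    _codon = _b[_i // 16] + _b[(_i // 4) % 4] + _b[_i % 4]
    _CODONS_BY_AA.setdefault(str(_aa), []).append(_codon)

MARKER_PROTEIN_LENGTH = 90
ORIT_LENGTH = 60
RRNA_LENGTH = 120

#: RDS values of the toy marker-protein entries (plasmid- and chromosome-enriched).
PLASMID_MPS_RDS = (8.0, 10.0, 6.0)
CHROMOSOME_MPS_RDS = (-12.0, -15.0, -11.0)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_AMINO_ACIDS), size=length - 1))
    return "M" + body


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _ASCII[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Coding DNA for a protein (start-M codon through a TAA stop), synonymous codons
    chosen at random."""
    codons = [rng.choice(_CODONS_BY_AA[aa]) for aa in protein]
    return "".join(codons) + "TAA"


def make_toy_marker_db(rng: np.random.Generator) -> MarkerDatabase:
    """A small marker database covering every category, with RDS-carrying MPS entries."""
    records: list[MarkerRecord] = []
    for cat in ("conjugation", "mobilization", "replication", "amr"):
        for suffix in "ab":
            records.append(
                MarkerRecord(f"{cat[:4]}_{suffix}", cat, _random_protein(rng, MARKER_PROTEIN_LENGTH))
            )
    for i, rds in enumerate(PLASMID_MPS_RDS):
        records.append(
            MarkerRecord(f"mps_plasmid_{i}", "mps", _random_protein(rng, MARKER_PROTEIN_LENGTH), rds=rds)
        )
    for i, rds in enumerate(CHROMOSOME_MPS_RDS):
        records.append(
            MarkerRecord(
                f"mps_chromosome_{i}", "mps", _random_protein(rng, MARKER_PROTEIN_LENGTH), rds=rds
            )
        )
    records.append(MarkerRecord("orit_a", "orit", _random_dna(rng, ORIT_LENGTH)))
    for suffix in "ab":
        records.append(MarkerRecord(f"rrna_{suffix}", "rrna", _random_dna(rng, RRNA_LENGTH)))
    return MarkerDatabase(records)


# ---------------------------------------------------------------------------
# Genome assembly with planted cassettes
# ---------------------------------------------------------------------------


def _cassette_dna(rng: np.random.Generator, record: MarkerRecord) -> str:
    if record.moltype == "protein":
        return _reverse_translate(rng, record.sequence)
    return record.sequence


def _cassettes_for(
    rng: np.random.Generator,
    label: str,
    plan: dict[str, int],
    marker_db: MarkerDatabase,
) -> list[tuple[MarkerRecord, str]]:
    chosen: list[tuple[MarkerRecord, str]] = []
    for category, count in sorted(plan.items()):
        pool = marker_db.by_category.get(category, [])
        if category == "mps":
            prefix = "mps_plasmid" if label == "plasmid" else "mps_chromosome"
            pool = [r for r in pool if r.marker_id.startswith(prefix)]
        if not pool:
            raise ValueError(f"marker database has no usable {category!r} entries")
        for i in range(count):
            rec = pool[i % len(pool)]
            chosen.append((rec, _cassette_dna(rng, rec)))
    return chosen


def _plant(
    rng: np.random.Generator,
    backbone: str,
    cassettes: list[tuple[MarkerRecord, str]],
) -> tuple[str, list[dict]]:
    """Replace non-overlapping stretches of the backbone with the cassette sequences.

    Each cassette is placed at a random offset inside its own equal slice of the
    replicon, which guarantees non-overlap; raises if the replicon is too short for
    its cassette footprint.
    """
    if not cassettes:
        return backbone, []
    L = len(backbone)
    n = len(cassettes)
    slice_len = L // n
    rows = []
    seq = list(backbone)
    for i, (rec, dna) in enumerate(cassettes):
        lo = i * slice_len
        hi = min((i + 1) * slice_len, L)
        if hi - lo < len(dna) + 2:
            raise ValueError(
                f"replicon of {L} bp is below the cassette footprint "
                f"({n} cassettes, longest slice need {len(dna) + 2} bp)"
            )
        start = int(lo + 1 + rng.integers(0, hi - lo - len(dna) - 1))
        seq[start : start + len(dna)] = list(dna)
        rows.append(
            {
                "marker_id": rec.marker_id,
                "category": rec.category,
                "start": start,
                "end": start + len(dna),
                "strand": "+",
            }
        )
    return "".join(seq), rows


@dataclass
class SyntheticGenome:
    """A generated genome set: one chromosome, plasmids, toy markers, truth tables."""

    spec: SynthGenomeSpec
    chromosome: tuple[str, str]
    plasmids: list[tuple[str, str]]
    marker_db: MarkerDatabase
    replicons: pd.DataFrame
    cassettes: pd.DataFrame

    def labeled_replicons(self) -> list[LabeledSequence]:
        out = [LabeledSequence(self.chromosome[0], self.chromosome[1], "chromosome")]
        out.extend(LabeledSequence(pid, seq, "plasmid") for pid, seq in self.plasmids)
        return out

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.chromosome], out_dir / "chromosome.fa")
        write_fasta(self.plasmids, out_dir / "plasmids.fa")
        self.marker_db.save_tsv(out_dir / "markers.tsv")
        write_fasta(
            [(r.marker_id, r.sequence) for r in self.marker_db.records],
            out_dir / "markers.fa",
        )
        manifest = pd.concat(
            [
                self.replicons.assign(record_type="replicon"),
                self.cassettes.assign(record_type="cassette"),
            ],
            ignore_index=True,
        )
        cols = ["record_type"] + [c for c in manifest.columns if c != "record_type"]
        manifest[cols].to_csv(out_dir / "manifest.tsv", sep="\t", index=False)


def generate_genome(spec: SynthGenomeSpec) -> SyntheticGenome:
    """Generate the chromosome, plasmids, toy marker database and truth manifest.

    Fully reproducible from ``spec.seed``; the manifest records every replicon's
    label and every cassette's coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    marker_db = make_toy_marker_db(rng)

    replicon_rows = []
    cassette_rows = []

    backbone = markov_sequence(rng, spec.chromosome_length, spec.chromosome_gc, spec.markov_persistence)
    cassettes = _cassettes_for(rng, "chromosome", spec.marker_plan.get("chromosome", {}), marker_db)
    chrom_seq, rows = _plant(rng, backbone, cassettes)
    chrom_id = "chromosome_1"
    replicon_rows.append({"id": chrom_id, "label": "chromosome", "length": len(chrom_seq)})
    cassette_rows.extend({**r, "replicon_id": chrom_id} for r in rows)
    chromosome = (chrom_id, chrom_seq)

    plasmids = []
    lo, hi = spec.plasmid_length_range
    for i in range(spec.n_plasmids):
        length = int(rng.integers(lo, hi + 1))
        backbone = markov_sequence(rng, length, spec.plasmid_gc, spec.markov_persistence)
        cassettes = _cassettes_for(rng, "plasmid", spec.marker_plan.get("plasmid", {}), marker_db)
        seq, rows = _plant(rng, backbone, cassettes)
        pid = f"plasmid_{i + 1}"
        plasmids.append((pid, seq))
        replicon_rows.append({"id": pid, "label": "plasmid", "length": len(seq)})
        cassette_rows.extend({**r, "replicon_id": pid} for r in rows)

    return SyntheticGenome(
        spec=spec,
        chromosome=chromosome,
        plasmids=plasmids,
        marker_db=marker_db,
        replicons=pd.DataFrame(replicon_rows, columns=["id", "label", "length"]),
        cassettes=pd.DataFrame(
            cassette_rows,
            columns=["marker_id", "category", "start", "end", "strand", "replicon_id"],
        ),
    )


# ---------------------------------------------------------------------------
# Assembly fragmenter
# ---------------------------------------------------------------------------

#: Default contig-length model: log-normal with median 2 kb, floored at 200 bp.
DEFAULT_FRAGMENT_MEDIAN = 2_000
DEFAULT_FRAGMENT_SIGMA = 0.7
DEFAULT_FRAGMENT_MIN = 200


def fragment_assembly(
    replicons: Sequence[LabeledSequence],
    n_fragments: int,
    length_distribution: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Cut random subsequences from replicons, emulating a fragmented assembly.

    Source replicons are drawn proportionally to their length; fragment lengths come
    from ``length_distribution`` (default log-normal, median 2 kb, min 200 bp) and
    are clipped to the source length.  Returns the contigs and a truth table
    recording each contig's source replicon, label and coordinates.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    rng = np.random.default_rng(seed)
    if n_fragments == 0 or not replicons:
        return [], pd.DataFrame(columns=["id", "source_id", "label", "start", "end", "length"])
    if length_distribution is None:
        def length_distribution(r: np.random.Generator, n: int) -> np.ndarray:
            lengths = r.lognormal(mean=np.log(DEFAULT_FRAGMENT_MEDIAN), sigma=DEFAULT_FRAGMENT_SIGMA, size=n)
            return np.maximum(lengths.astype(int), DEFAULT_FRAGMENT_MIN)

    weights = np.array([len(r.sequence) for r in replicons], dtype=float)
    weights /= weights.sum()
    sources = rng.choice(len(replicons), size=n_fragments, p=weights)
    lengths = length_distribution(rng, n_fragments)

    contigs: list[tuple[str, str]] = []
    rows = []
    for i, (src_idx, length) in enumerate(zip(sources, lengths)):
        rep = replicons[src_idx]
        length = int(min(length, len(rep.sequence)))
        start = int(rng.integers(0, len(rep.sequence) - length + 1))
        cid = f"contig_{i + 1:05d}"
        contigs.append((cid, rep.sequence[start : start + length]))
        rows.append(
            {
                "id": cid,
                "source_id": rep.id,
                "label": rep.label,
                "start": start,
                "end": start + length,
                "length": length,
            }
        )
    return contigs, pd.DataFrame(rows, columns=["id", "source_id", "label", "start", "end", "length"])
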