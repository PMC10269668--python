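"""Assembly of the fixed-order 26-feature vector for one sequence.

Five shared-k-mer features (``r_k18``, ``rmp_k18``, ``p_k25``, ``pmr_k25`` and the
ratio ``rp = r_k18 / (r_k18 + p_k25)``) are combined with 21 genomic-marker features:
per-category maximum alignment score, maximum -log10(E-value) and presence flags for
conjugation / mobilization / AMR / replication genes, the RDS summary (average,
maximum, bias), oriT and rRNA motif features, and ``maxEvalue`` — the maximum of all
E-value-derived features except ``rRNAMaxEvalue`` (rRNA indicates chromosomes, the
others plasmids).  K-mer fractions are expressed on [0, 1]; ``rp`` is scale-invariant
so the choice is cosmetic but fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kmer import KmerDatabase, shared_fraction
from .markers import (
    MarkerDatabase,
    MarkerHit,
    SearchBackend,
    category_features,
    rds_features,
)

#: Canonical feature order; identical between training and prediction, and pinned by
#: a version string stored inside trained models.
FEATURE_NAMES: tuple[str, ...] = (
    "r_k18",
    "rmp_k18",
    "p_k25",
    "pmr_k25",
    "rp",
    "ConjMaxScore",
    "ConjMaxEvalue",
    "MobiMaxScore",
    "MobiMaxEvalue",
    "AMRMaxScore",
    "AMRMaxEvalue",
    "RepMaxScore",
    "RepMaxEvalue",
    "hasConjugation",
    "hasMobilization",
    "hasAMR",
    "hasReplication",
    "RDSAvgScore",
    "RDSMaxScore",
    "rdsBias",
    "OritMaxEvalue",
    "hasOriT",
    "rRNAMaxScore",
    "rRNAMaxEvalue",
    "hasrRNA",
    "maxEvalue",
)

FEATURE_ORDER_VERSION = "fv1"

#: Database keys expected by :func:`assemble_features`.
KMER_DB_KEYS = ("r_k18", "rmp_k18", "p_k25", "pmr_k25")


def rp_ratio(r: float, p: float) -> float:
    """Chromosome-vs-plasmid sharing ratio r / (r + p); 0.5 when both are zero.

    Values near 1 indicate chromosome-biased sharing, near 0 plasmid-biased.
    """
    if r < 0 or p < 0:
        raise ValueError("rp_ratio inputs must be non-negative")
    if r + p == 0:
        return 0.5
    return r / (r + p)


@dataclass(frozen=True)
class FeatureVector:
    r_k18: float
    rmp_k18: float
    p_k25: float
    pmr_k25: float
    rp: float
    ConjMaxScore: float
    ConjMaxEvalue: float
    MobiMaxScore: float
    MobiMaxEvalue: float
    AMRMaxScore: float
    AMRMaxEvalue: float
    RepMaxScore: float
    RepMaxEvalue: float
    hasConjugation: int
    hasMobilization: int
    hasAMR: int
    hasReplication: int
    RDSAvgScore: float
    RDSMaxScore: float
    rdsBias: int
    OritMaxEvalue: float
    hasOriT: int
    rRNAMaxScore: float
    rRNAMaxEvalue: float
    hasrRNA: int
    maxEvalue: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "FeatureVector":
        kwargs = {}
        for f in dataclass_fields(cls):
            v = values[f.name]
            kwargs[f.name] = int(v) if f.type == "int" else float(v)
        return cls(**kwargs)


assert tuple(f.name for f in dataclass_fields(FeatureVector)) == FEATURE_NAMES


def assemble_features(
    query_id: str,
    seq: str,
    kmer_dbs: Mapping[str, KmerDatabase],
    hits: Sequence[MarkerHit],
) -> FeatureVector:
    """Build the 26-feature vector from the four k-mer databases and marker hits."""
    for key in KMER_DB_KEYS:
        if key not in kmer_dbs:
            raise KeyError(f"missing k-mer database {key!r}")
    km = {key: shared_fraction(query_id, seq, kmer_dbs[key]).shared_fraction for key in KMER_DB_KEYS}

    conj = category_features(hits, "conjugation")
    mobi = category_features(hits, "mobilization")
    amr = category_features(hits, "amr")
    rep = category_features(hits, "replication")
    orit = category_features(hits, "orit")
    rrna = category_features(hits, "rrna")
    rds = rds_features([h for h in hits if h.category == "mps"])

    max_evalue = max(
        conj.max_neg_log_e,
        mobi.max_neg_log_e,
        amr.max_neg_log_e,
        rep.max_neg_log_e,
        orit.max_neg_log_e,
    )
    return FeatureVector(
        r_k18=km["r_k18"],
        rmp_k18=km["rmp_k18"],
        p_k25=km["p_k25"],
        pmr_k25=km["pmr_k25"],
        rp=rp_ratio(km["r_k18"], km["p_k25"]),
        ConjMaxScore=conj.max_score,
        ConjMaxEvalue=conj.max_neg_log_e,
        MobiMaxScore=mobi.max_score,
        MobiMaxEvalue=mobi.max_neg_log_e,
        AMRMaxScore=amr.max_score,
        AMRMaxEvalue=amr.max_neg_log_e,
        RepMaxScore=rep.max_score,
        RepMaxEvalue=rep.max_neg_log_e,
        hasConjugation=conj.present,
        hasMobilization=mobi.present,
        hasAMR=amr.present,
        hasReplication=rep.present,
        RDSAvgScore=rds.avg_score,
        RDSMaxScore=rds.max_score,
        rdsBias=rds.bias,
        OritMaxEvalue=orit.max_neg_log_e,
        hasOriT=orit.present,
        rRNAMaxScore=rrna.max_score,
        rRNAMaxEvalue=rrna.max_neg_log_e,
        hasrRNA=rrna.present,
        maxEvalue=max_evalue,
    )


def feature_vector_for_sequence(
    query_id: str,
    seq: str,
    kmer_dbs: Mapping[str, KmerDatabase],
    backend: SearchBackend,
    marker_db: MarkerDatabase,
) -> FeatureVector:
    """Convenience wrapper: run the marker search, then assemble the vector."""
    hits = backend.search(query_id, seq, marker_db)
    return assemble_features(query_id, seq, kmer_dbs, hits)


def feature_table(
    sequences: Sequence[tuple[str, str]],
    kmer_dbs: Mapping[str, KmerDatabase],
    backend: SearchBackend,
    marker_db: MarkerDatabase,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Feature table for many sequences: id, length, optional label, 26 columns."""
    rows = []
    for i, (sid, seq) in enumerate(sequences):
        fv = feature_vector_for_sequence(sid, seq, kmer_dbs, backend, marker_db)
        row: dict[str, object] = {"id": sid, "length": len(seq)}
        if labels is not None:
            row["label"] = labels[i]
        row.update(fv.to_dict())
        rows.append(row)
    cols = ["id", "length"] + (["label"] if labels is not None else []) + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    # shortest round-trippable float representation keeps the table bit-exact
    table.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return table
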