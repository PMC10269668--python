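"""End-to-end classification of assembled contigs.

Each input sequence is first routed by length: contigs longer than the cutoff
(500 kb by default) are labelled chromosome outright — molecules that long are
essentially never plasmids, and skipping feature extraction for them saves most of
the runtime on finished genomes.  Contigs shorter than the minimum length (500 bp by
default, configurable down to 1) are reported as ``filtered`` rather than silently
dropped, so downstream record counts reconcile.  Everything in between gets the full
26-feature extraction and a forest vote; the plasmid call is made at probability >=
``prob_threshold`` (default 0.5, i.e. majority vote).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .fasta import read_fasta
from .features import FEATURE_NAMES, feature_table
from .kmer import KmerDatabase
from .markers import MarkerDatabase, NaiveBackend, SearchBackend
from .training import NEGATIVE_LABEL, POSITIVE_LABEL, TrainedModel

DEFAULT_LENGTH_CUTOFF = 500_000
DEFAULT_MIN_LENGTH = 500
DEFAULT_PROB_THRESHOLD = 0.5

FILTERED_LABEL = "filtered"


@dataclass(frozen=True)
class PredictionRecord:
    id: str
    length: int
    label: str
    plasmid_probability: Optional[float] = None
    bypass: bool = False
    note: str = ""


def classify(
    contigs: Union[str, Path, Sequence[tuple[str, str]]],
    model: TrainedModel,
    kmer_dbs: Mapping[str, KmerDatabase],
    marker_db: MarkerDatabase,
    backend: Optional[SearchBackend] = None,
    length_cutoff: int = DEFAULT_LENGTH_CUTOFF,
    min_length: int = DEFAULT_MIN_LENGTH,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    strict_threshold: bool = False,
) -> list[PredictionRecord]:
    """Classify contigs as chromosome or plasmid.

    Length > ``length_cutoff``: chromosome with ``bypass=True`` and no feature
    extraction.  Length < ``min_length``: ``filtered``.  Otherwise the forest's
    plasmid probability decides: plasmid iff probability >= ``prob_threshold``
    (with ``strict_threshold`` a probability exactly at the threshold goes to
    chromosome).  Output preserves input order; re-running with identical inputs,
    model and databases is bit-identical.
    """
    if model.feature_order != FEATURE_NAMES:
        raise ValueError("model feature order does not match this build's feature order")
    if isinstance(contigs, (str, Path)):
        contigs = list(read_fasta(contigs))
    else:
        contigs = list(contigs)
    if not contigs:
        warnings.warn("no input sequences", stacklevel=2)
        return []
    if backend is None:
        backend = NaiveBackend()

    records: list[Optional[PredictionRecord]] = [None] * len(contigs)
    to_predict: list[int] = []
    for i, (cid, seq) in enumerate(contigs):
        L = len(seq)
        if L > length_cutoff:
            records[i] = PredictionRecord(cid, L, NEGATIVE_LABEL, None, bypass=True)
        elif L < min_length:
            records[i] = PredictionRecord(cid, L, FILTERED_LABEL, None)
        else:
            to_predict.append(i)

    if to_predict:
        batch = [contigs[i] for i in to_predict]
        table = feature_table(batch, kmer_dbs, backend, marker_db)
        probs = model.predict_proba(table)
        kmer_cols = table[["r_k18", "rmp_k18", "p_k25", "pmr_k25"]].to_numpy()
        for j, i in enumerate(to_predict):
            cid, seq = contigs[i]
            p = float(probs[j])
            if strict_threshold:
                label = POSITIVE_LABEL if p > prob_threshold else NEGATIVE_LABEL
            else:
                label = POSITIVE_LABEL if p >= prob_threshold else NEGATIVE_LABEL
            note = ""
            if not np.any(kmer_cols[j] > 0) and set(seq.upper()) - set("ACGT"):
                note = "no_informative_kmers"
            records[i] = PredictionRecord(cid, len(seq), label, p, note=note)
    return [r for r in records if r is not None]


PREDICTION_COLUMNS = ("id", "length", "label", "plasmid_probability", "bypass", "note")


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for r in records:
            prob = "" if r.plasmid_probability is None else repr(r.plasmid_probability)
            writer.writerow([r.id, r.length, r.label, prob, str(r.bypass).lower(), r.note])


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != PREDICTION_COLUMNS:
            raise ValueError(f"{path}: not a predictions TSV")
        for row in reader:
            cid, length, label, prob, bypass, note = row
            records.append(
                PredictionRecord(
                    id=cid,
                    length=int(length),
                    label=label,
                    plasmid_probability=None if prob == "" else float(prob),
                    bypass=bypass == "true",
                    note=note,
                )
            )
    return records
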