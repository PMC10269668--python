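"""Benchmark harness: confusion-matrix metrics, AUC, balanced down-sampling,
length-stratified reporting, and k-mer-bias truth labelling for assembled contigs.

Plasmids are the positive class.  Ten metrics are derived from the confusion matrix:
sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/total, precision
tp/(tp+fp), FNR fn/(tp+fn), FPR fp/(tn+fp), FOR fn/(fn+tn), FDR fp/(fp+tp), NPV
tn/(fn+tn) and F1 = 2*(sensitivity*precision)/(sensitivity+precision).  Metrics with
a zero denominator are reported as missing (``None``) rather than coerced, and
prevalence is always reported alongside, because precision/F1 are biased by class
imbalance.  AUC is the rank-sum (Mann-Whitney) estimator: the probability that a
random plasmid outranks a random chromosome, ties counted 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .kmer import KmerDatabase, build_database, shared_fraction

POSITIVE_LABEL = "plasmid"
NEGATIVE_LABEL = "chromosome"

#: Contigs sharing less than this fraction of k-mers with the reference union are
#: considered mis-assembled and discarded before truth labelling.
DEFAULT_DISCARD_THRESHOLD = 0.95
#: k used for the bias labelling of assembled contigs (midpoint of 18 and 25).
DEFAULT_LABELING_K = 21

DEFAULT_LENGTH_BINS = (0, 500, 1000, 2000)


@dataclass(frozen=True)
class ConfusionMatrix:
    """tp/tn/fp/fn counts with plasmid as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls,
        truth: Sequence[str],
        predicted: Sequence[str],
        positive: str = POSITIVE_LABEL,
        negative: str = NEGATIVE_LABEL,
    ) -> "ConfusionMatrix":
        if len(truth) != len(predicted):
            raise ValueError("truth and predicted must have equal length")
        tp = tn = fp = fn = 0
        for t, p in zip(truth, predicted):
            if t not in (positive, negative) or p not in (positive, negative):
                raise ValueError(f"non-binary label pair ({t!r}, {p!r})")
            if t == positive:
                if p == positive:
                    tp += 1
                else:
                    fn += 1
            else:
                if p == positive:
                    fp += 1
                else:
                    tn += 1
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class MetricsReport:
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    precision: Optional[float]
    fnr: Optional[float]
    fpr: Optional[float]
    for_: Optional[float]
    fdr: Optional[float]
    npv: Optional[float]
    f1: Optional[float]
    prevalence: Optional[float]
    auc: Optional[float] = None

    def to_dict(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "for": self.for_,
            "fdr": self.fdr,
            "npv": self.npv,
            "f1": self.f1,
            "prevalence": self.prevalence,
            "auc": self.auc,
        }


def _div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The ten confusion-matrix metrics; zero-denominator metrics are ``None``."""
    sens = _div(cm.tp, cm.tp + cm.fn)
    spec = _div(cm.tn, cm.tn + cm.fp)
    prec = _div(cm.tp, cm.tp + cm.fp)
    if sens is not None and prec is not None and sens + prec > 0:
        f1 = 2 * (sens * prec) / (sens + prec)
    else:
        f1 = None
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=_div(cm.tp + cm.tn, cm.total),
        precision=prec,
        fnr=_div(cm.fn, cm.tp + cm.fn),
        fpr=_div(cm.fp, cm.tn + cm.fp),
        for_=_div(cm.fn, cm.fn + cm.tn),
        fdr=_div(cm.fp, cm.fp + cm.tp),
        npv=_div(cm.tn, cm.fn + cm.tn),
        f1=f1,
        prevalence=_div(cm.tp + cm.fn, cm.total),
    )


def auc(probabilities: Sequence[float], truth: Sequence[str], positive: str = POSITIVE_LABEL) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 0.5."""
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray([t == positive for t in truth], dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined when only one class is present")
    ranks = rankdata(scores)
    rank_sum = ranks[y].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def balanced_downsample(
    records: pd.DataFrame,
    seed: int = 0,
    label_col: str = "truth",
    length_col: str = "length",
) -> pd.DataFrame:
    """Down-sample the majority class to the minority count within each length stratum.

    Uniform without replacement, seeded; an already balanced stratum is returned
    unchanged and a single-class stratum is dropped.  Raises if either class is
    absent from the whole table.
    """
    labels = records[label_col]
    for cls in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if not (labels == cls).any():
            raise ValueError(f"class {cls!r} is empty")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _length, group in records.groupby(length_col, sort=True):
        counts = group[label_col].value_counts()
        n_pos = int(counts.get(POSITIVE_LABEL, 0))
        n_neg = int(counts.get(NEGATIVE_LABEL, 0))
        target = min(n_pos, n_neg)
        if target == 0:
            continue
        idx_parts = []
        for cls, n_cls in ((POSITIVE_LABEL, n_pos), (NEGATIVE_LABEL, n_neg)):
            cls_idx = group.index[group[label_col] == cls].to_numpy()
            if n_cls > target:
                cls_idx = rng.choice(cls_idx, size=target, replace=False)
            idx_parts.append(cls_idx)
        keep.append(np.concatenate(idx_parts))
    if not keep:
        raise ValueError("no length stratum contains both classes")
    kept = set(np.concatenate(keep).tolist())
    return records.loc[[i in kept for i in records.index]]


def label_contigs_by_kmer_bias(
    contigs: Sequence[tuple[str, str]],
    ref_chromosomes: Sequence[tuple[str, str]],
    ref_plasmids: Sequence[tuple[str, str]],
    discard_threshold: float = DEFAULT_DISCARD_THRESHOLD,
    k: int = DEFAULT_LABELING_K,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Truth-label assembled contigs by their shared-k-mer bias against a reference.

    A contig sharing less than ``discard_threshold`` of its k-mers with the whole
    reference (chromosomes and plasmids jointly) is discarded as mis-assembled.  The
    rest are labelled by the larger of the shared fractions against the chromosome
    set versus the plasmid set; an exact tie is discarded as ambiguous.

    Returns ``(labels, discarded)`` where labels are ``(id, "chromosome"|"plasmid")``
    and discarded are ``(id, "misassembled"|"ambiguous")``.
    """
    if not ref_chromosomes or not ref_plasmids:
        raise ValueError("reference chromosome and plasmid sets must be non-empty")
    chrom_db = build_database(ref_chromosomes, k, 1.0, label="chromosome")
    plasmid_db = build_database(ref_plasmids, k, 1.0, label="plasmid")
    union_db = KmerDatabase(
        k=k,
        kmers=np.union1d(chrom_db.kmers, plasmid_db.kmers),
        sketch_fraction=1.0,
        label="reference_union",
        source_count=chrom_db.source_count + plasmid_db.source_count,
    )
    labels: list[tuple[str, str]] = []
    discarded: list[tuple[str, str]] = []
    for cid, seq in contigs:
        whole = shared_fraction(cid, seq, union_db)
        if whole.shared_fraction < discard_threshold:
            discarded.append((cid, "misassembled"))
            continue
        sc = shared_fraction(cid, seq, chrom_db).shared_fraction
        sp = shared_fraction(cid, seq, plasmid_db).shared_fraction
        if sc > sp:
            labels.append((cid, NEGATIVE_LABEL))
        elif sp > sc:
            labels.append((cid, POSITIVE_LABEL))
        else:
            discarded.append((cid, "ambiguous"))
    return labels, discarded


@dataclass(frozen=True)
class StratumReport:
    min_length: int
    n_records: int
    metrics: MetricsReport


def length_stratified_report(
    records: pd.DataFrame,
    bins: Sequence[int] = DEFAULT_LENGTH_BINS,
    truth_col: str = "truth",
    pred_col: str = "predicted",
    length_col: str = "length",
) -> dict[int, StratumReport]:
    """One metrics report per minimum-length filter, over records of length >= bin.

    Records whose prediction is not a binary chromosome/plasmid call (e.g. length-
    filtered contigs) are excluded from every bin.
    """
    binary = records[records[pred_col].isin([POSITIVE_LABEL, NEGATIVE_LABEL])]
    out: dict[int, StratumReport] = {}
    for threshold in bins:
        sub = binary[binary[length_col] >= threshold]
        if len(sub) == 0:
            metrics = compute_metrics(ConfusionMatrix(0, 0, 0, 0))
        else:
            cm = ConfusionMatrix.from_labels(sub[truth_col].tolist(), sub[pred_col].tolist())
            metrics = compute_metrics(cm)
        out[int(threshold)] = StratumReport(int(threshold), len(sub), metrics)
    return out
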