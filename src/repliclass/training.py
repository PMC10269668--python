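"""Sliding-window training-set construction and random-forest model fitting.

Complete replicons are cut into fixed-size overlapping windows (ten strata from
500 kb down to 500 bp) so the model learns from fragments of every length a draft
assembly may contain.  Chromosomal replicons shorter than 500 kb are excluded
entirely to avoid mislabelled plasmids contaminating the chromosome class.  Within
each window-size stratum 80% of windows are drawn without replacement, truncated to a
100,000-window ceiling.  A random forest (500 trees) is fitted on a random 2/3 of the
sampled windows and evaluated on the remaining 1/3; repeated refitting with fresh
splits measures the stability of the holdout metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .evaluation import ConfusionMatrix, MetricsReport, auc, compute_metrics
from .features import FEATURE_NAMES, FEATURE_ORDER_VERSION

#: Number of trees in the forest.
DEFAULT_NTREES = 500
#: Fraction of windows sampled per stratum.
DEFAULT_SAMPLE_FRAC = 0.8
#: Per-stratum ceiling on sampled windows.
DEFAULT_SAMPLE_CAP = 100_000
#: Chromosomal replicons shorter than this contribute no training windows (bp).
DEFAULT_CHROMOSOME_MIN_LEN = 500_000

MODEL_FORMAT_VERSION = 1

POSITIVE_LABEL = "plasmid"
NEGATIVE_LABEL = "chromosome"


@dataclass(frozen=True)
class WindowSpec:
    """A sliding-window stratum: window length and overlap between adjacent windows."""

    window: int
    overlap: int

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window:
            raise ValueError("require 0 <= overlap < window")

    @property
    def step(self) -> int:
        return self.window - self.overlap


#: The ten window strata: (window, overlap) = (500 kb, 50 kb) ... (500 bp, 50 bp).
DEFAULT_WINDOW_SPECS: tuple[WindowSpec, ...] = tuple(
    WindowSpec(w, o)
    for w, o in [
        (500_000, 50_000),
        (200_000, 20_000),
        (100_000, 10_000),
        (50_000, 5_000),
        (20_000, 2_000),
        (10_000, 1_000),
        (5_000, 500),
        (2_000, 200),
        (1_000, 100),
        (500, 50),
    ]
)


def specs_up_to(max_window: int, specs: Sequence[WindowSpec] = DEFAULT_WINDOW_SPECS) -> list[WindowSpec]:
    """The default strata restricted to window sizes <= ``max_window``."""
    return [s for s in specs if s.window <= max_window]


@dataclass(frozen=True)
class LabeledSequence:
    """A replicon with its class label; ``source_replicon_length`` defaults to the
    sequence's own length but may describe a longer parent molecule."""

    id: str
    sequence: str
    label: str
    source_replicon_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"label must be chromosome|plasmid, got {self.label!r}")
        if self.source_replicon_length is None:
            object.__setattr__(self, "source_replicon_length", len(self.sequence))


@dataclass(frozen=True)
class TrainingWindow:
    id: str
    sequence: str
    label: str
    window: int
    start: int
    source_id: str


def slide_windows(seq: str, spec: WindowSpec) -> list[tuple[int, int, str]]:
    """Windows (start, end, subsequence) at starts 0, step, 2*step, ...

    0-based half-open; a sequence shorter than the window yields no windows and a
    trailing fragment shorter than the window is dropped.
    """
    out = []
    for start in range(0, len(seq) - spec.window + 1, spec.step):
        out.append((start, start + spec.window, seq[start : start + spec.window]))
    return out


def build_training_set(
    replicons: Sequence[LabeledSequence],
    specs: Sequence[WindowSpec] = DEFAULT_WINDOW_SPECS,
    sample_frac: float = DEFAULT_SAMPLE_FRAC,
    cap: int = DEFAULT_SAMPLE_CAP,
    chrom_min_len: int = DEFAULT_CHROMOSOME_MIN_LEN,
    seed: int = 0,
) -> list[TrainingWindow]:
    """Window, filter and sample replicons into a labelled training set.

    Chromosomal replicons whose source molecule is shorter than ``chrom_min_len``
    contribute nothing.  Per window-size stratum, ``floor(sample_frac * N)`` windows
    are drawn uniformly without replacement, then the draw is truncated to ``cap``
    (sample-then-truncate).  Reproducible under ``seed``.
    """
    if not 0.0 < sample_frac <= 1.0:
        raise ValueError("sample_frac must be in (0, 1]")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    kept: list[TrainingWindow] = []
    eligible = [
        rep
        for rep in replicons
        if not (rep.label == NEGATIVE_LABEL and rep.source_replicon_length < chrom_min_len)
    ]
    for spec in specs:
        stratum: list[TrainingWindow] = []
        for rep in eligible:
            for start, end, sub in slide_windows(rep.sequence, spec):
                stratum.append(
                    TrainingWindow(
                        id=f"{rep.id}|w{spec.window}|{start}",
                        sequence=sub,
                        label=rep.label,
                        window=spec.window,
                        start=start,
                        source_id=rep.id,
                    )
                )
        if not stratum:
            warnings.warn(f"window stratum {spec.window} bp is empty; skipped", stacklevel=2)
            continue
        n_draw = int(sample_frac * len(stratum))
        if n_draw == 0:
            warnings.warn(
                f"window stratum {spec.window} bp: sample of {len(stratum)} windows "
                "is empty; skipped",
                stacklevel=2,
            )
            continue
        # sample first, then truncate the draw to the per-stratum ceiling
        idx = np.sort(rng.choice(len(stratum), size=n_draw, replace=False)[:cap])
        kept.extend(stratum[i] for i in idx)
    return kept


@dataclass
class TrainedModel:
    """A fitted random forest mapping feature vectors to plasmid probability."""

    forest: RandomForestClassifier
    ntrees: int
    seed: int
    feature_order: tuple[str, ...] = FEATURE_NAMES
    feature_order_version: str = FEATURE_ORDER_VERSION
    format_version: int = MODEL_FORMAT_VERSION
    training_summary: dict = field(default_factory=dict)
    holdout_metrics: Optional[MetricsReport] = None

    def predict_proba(self, features) -> np.ndarray:
        """Plasmid probability for each row of a feature table or (n, 26) array."""
        X = _as_matrix(features, self.feature_order)
        proba = self.forest.predict_proba(X)
        pos = list(self.forest.classes_).index(POSITIVE_LABEL)
        return proba[:, pos]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": self.format_version,
                "feature_order": list(self.feature_order),
                "feature_order_version": self.feature_order_version,
                "ntrees": self.ntrees,
                "seed": self.seed,
                "training_summary": self.training_summary,
                "holdout_metrics": self.holdout_metrics,
                "forest": self.forest,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {payload.get('format_version')!r}")
        return cls(
            forest=payload["forest"],
            ntrees=payload["ntrees"],
            seed=payload["seed"],
            feature_order=tuple(payload["feature_order"]),
            feature_order_version=payload["feature_order_version"],
            format_version=payload["format_version"],
            training_summary=payload["training_summary"],
            holdout_metrics=payload["holdout_metrics"],
        )


def _as_matrix(features, feature_order: Sequence[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in feature_order if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")
        return features.loc[:, list(feature_order)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_order):
        raise ValueError(f"expected an (n, {len(feature_order)}) feature matrix")
    return X


def train(
    features,
    labels: Sequence[str],
    ntrees: int = DEFAULT_NTREES,
    seed: int = 0,
) -> TrainedModel:
    """Fit a random forest on a seeded 2/3 split and evaluate on the 1/3 holdout.

    Classes are left unbalanced, exactly as sampled (the per-class counts are
    recorded in ``training_summary``).  Deterministic under a fixed seed.
    """
    X = _as_matrix(features, FEATURE_NAMES)
    y = np.asarray(labels, dtype=object)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    classes = set(y.tolist())
    if len(classes) < 2:
        raise ValueError("training requires both classes to be present")
    X_tr, X_ho, y_tr, y_ho = train_test_split(X, y, test_size=1 / 3, random_state=seed % 2**31)
    forest = RandomForestClassifier(n_estimators=ntrees, random_state=(seed + 1) % 2**31)
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_ho)
    cm = ConfusionMatrix.from_labels(y_ho, pred)
    metrics = compute_metrics(cm)
    if len(set(y_ho.tolist())) == 2:
        pos = list(forest.classes_).index(POSITIVE_LABEL)
        metrics.auc = auc(forest.predict_proba(X_ho)[:, pos], y_ho)
    summary = {
        "n_total": int(y.size),
        "n_plasmid": int(np.sum(y == POSITIVE_LABEL)),
        "n_chromosome": int(np.sum(y == NEGATIVE_LABEL)),
        "n_train": int(y_tr.size),
        "n_holdout": int(y_ho.size),
        "holdout_confusion": cm,
    }
    return TrainedModel(
        forest=forest,
        ntrees=ntrees,
        seed=seed,
        training_summary=summary,
        holdout_metrics=metrics,
    )


def repetition_seeds(seed: int, repetitions: int) -> list[int]:
    """Per-repetition seeds derived from one master seed (kept below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(repetitions)]


def repeated_training(
    features,
    labels: Sequence[str],
    repetitions: int = 100,
    ntrees: int = DEFAULT_NTREES,
    seed: int = 0,
) -> list[MetricsReport]:
    """Refit with independent 2/3-1/3 resampling per repetition; returns the
    per-repetition holdout metrics for dispersion reporting."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    return [
        train(features, labels, ntrees=ntrees, seed=s).holdout_metrics
        for s in repetition_seeds(seed, repetitions)
    ]


def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Impurity-decrease importances of the 26 features, sorted descending.

    Importances are non-negative and sum to 1.
    """
    imp = model.forest.feature_importances_
    pairs = sorted(zip(model.feature_order, imp), key=lambda t: (-t[1], t[0]))
    return [(name, float(v)) for name, v in pairs]
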