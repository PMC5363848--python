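"""Classification metrics, discrimination scenarios, PFM scoring, k-mer counts.

Metrics follow the confusion-matrix conventions used throughout the
analysis: success rate (accuracy), balanced success rate (mean of
sensitivity and specificity, robust to class imbalance), sensitivity, PPV,
and ROC AUC — all reported on a 0-100 percent scale.

The scenario machinery reassembles the three cluster categories (bound by
one protein only, by the other only, or by both) into positive/negative
contrasts and runs the full model-selection pipeline on each.  PFM scoring
implements the log-odds scan with the 0.6 x maximum-score classification
threshold used to benchmark position-frequency-matrix motifs against the
string-kernel models.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ScenarioSpec",
    "ScenarioResult",
    "SCENARIOS",
    "PFM",
    "compute_metrics",
    "confusion_counts",
    "run_scenario",
    "read_meme_minimal",
    "pfm_score",
    "pfm_max_score",
    "pfm_classify",
    "count_kmer_occurrences",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-derived metrics plus ROC AUC, all in percent.

    ``roc_auc`` is None when only one class is present (undefined).
    """

    success_rate: float
    balanced_success_rate: float
    sensitivity: float
    ppv: float
    roc_auc: float | None


@dataclass(frozen=True)
class ScenarioSpec:
    """A positive/negative contrast over the three cluster categories."""

    name: str
    positive: tuple
    negative: tuple

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative sources must be disjoint")


#: The four discrimination scenarios over {hur_only, ttp_only, common}.
SCENARIOS = {
    1: ScenarioSpec("scenario1", ("hur_only",), ("ttp_only", "common")),
    2: ScenarioSpec("scenario2", ("ttp_only",), ("hur_only", "common")),
    3: ScenarioSpec("scenario3", ("common",), ("hur_only", "ttp_only")),
    4: ScenarioSpec("scenario4", ("hur_only",), ("ttp_only",)),
}


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    report: MetricsReport
    top_features: list
    grid: object  # GridSearchResult


def confusion_counts(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == -1) & (p == 1)).sum()),
        tn=int(((y == -1) & (p == -1)).sum()),
        fn=int(((y == 1) & (p == -1)).sum()),
    )


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else 0.0


def compute_metrics(labels, predictions, scores=None) -> MetricsReport:
    """Success rate, balanced success rate, sensitivity, PPV and ROC AUC (%).

    ROC AUC is computed from ``scores`` (decision values) with midrank tie
    handling; with a single class present it is undefined and returned as
    None (the confusion-derived metrics are still reported).
    """
    cm = confusion_counts(labels, predictions)
    sens = _pct(cm.tp, cm.tp + cm.fn)
    spec = _pct(cm.tn, cm.tn + cm.fp)
    report_roc = None
    y = np.asarray(labels)
    if scores is not None:
        if len(set(y.tolist())) == 2:
            report_roc = 100.0 * float(roc_auc_score(y, np.asarray(scores)))
        else:
            warnings.warn("single-class input: ROC AUC undefined", stacklevel=2)
    return MetricsReport(
        success_rate=_pct(cm.tp + cm.tn, cm.total),
        balanced_success_rate=(sens + spec) / 2.0,
        sensitivity=sens,
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        roc_auc=report_roc,
    )


def run_scenario(spec: ScenarioSpec, sequences: dict, config) -> ScenarioResult:
    """Run the model-selection pipeline on one category contrast.

    ``sequences`` maps category name -> list of SequenceRecord; records are
    relabeled according to the scenario.  Reports holdout metrics (balanced
    success rate is the headline under class imbalance) and the top eight
    weighted features.
    """
    from dataclasses import replace

    from .model import feature_weights, grid_search

    for cat in spec.positive + spec.negative:
        if not sequences.get(cat):
            raise ValueError(f"scenario {spec.name}: category {cat!r} is empty")
    records = []
    for cat in spec.positive:
        records += [replace(r, label="positive") for r in sequences[cat]]
    for cat in spec.negative:
        records += [replace(r, label="negative") for r in sequences[cat]]
    result = grid_search(records, config)
    return ScenarioResult(
        spec=spec,
        report=result.holdout_report,
        top_features=feature_weights(result.model, 8),
        grid=result,
    )


@dataclass
class PFM:
    """Position frequency matrix: 4 rows (A, C, G, U) x L columns."""

    matrix: np.ndarray
    name: str = ""
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PFM matrix must be 4 x L")
        if self.matrix.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PFM columns must sum to 1 (got {sums})")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2 odds vs the uniform 0.25 background, with pseudocount."""
        with np.errstate(divide="ignore"):
            return np.log2((self.matrix + self.pseudocount) / 0.25)

    @property
    def consensus(self) -> str:
        return "".join("ACGU"[i] for i in self.matrix.argmax(axis=0))


def read_meme_minimal(path, pseudocount: float = 1e-3) -> list[PFM]:
    """Parse motifs from a MEME-minimal text file (ACGT or ACGU alphabet)."""
    motifs = []
    name = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1] if len(line.split()) > 1 else ""
            elif line.startswith("letter-probability matrix"):
                rows, expect = [], 0
                for field in line.split(":", 1)[1].split():
                    if field == "w=":
                        expect = -1
                    elif expect == -1:
                        expect = int(field)
                        break
            elif name is not None and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
                if expect and len(rows) == expect:
                    motifs.append(
                        PFM(np.array(rows).T, name=name, pseudocount=pseudocount)
                    )
                    name, rows = None, []
    if name is not None and rows:  # w= absent: matrix ran to end of block
        motifs.append(PFM(np.array(rows).T, name=name, pseudocount=pseudocount))
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def pfm_score(seq: str, pfm: PFM) -> float:
    """Best log-odds window score of the motif along the sequence.

    No reverse-strand scan (RNA).  Sequences shorter than the motif are an
    error.  Positions with a non-ACGU character contribute the background
    log-odds of 0.
    """
    w = pfm.width
    if len(seq) < w:
        raise ValueError(
            f"sequence length {len(seq)} shorter than motif width {w}"
        )
    lo = pfm.log_odds()
    best = -np.inf
    idx = [_BASE_INDEX.get(ch, -1) for ch in seq.replace("T", "U")]
    for start in range(len(seq) - w + 1):
        score = 0.0
        for j in range(w):
            b = idx[start + j]
            if b >= 0:
                score += lo[b, j]
        best = max(best, score)
    return float(best)


def pfm_max_score(pfm: PFM) -> float:
    """Score of the per-column argmax (consensus) string."""
    return float(pfm.log_odds().max(axis=0).sum())


def pfm_classify(records, pfm: PFM, fraction: float = 0.6) -> ConfusionCounts:
    """Threshold classification at fraction x maximum achievable score.

    A record scoring above the threshold is called positive; a score tying
    the threshold exactly (e.g. the consensus at fraction 1) also passes.
    Records shorter than the motif cannot score and are called negative.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    threshold = fraction * pfm_max_score(pfm)
    tp = fp = tn = fn = 0
    for rec in records:
        if len(rec.seq) < pfm.width:
            logger.warning("record %s shorter than motif; scored as negative", rec.id)
            called_positive = False
        else:
            score = pfm_score(rec.seq, pfm)
            called_positive = score > threshold or math.isclose(
                score, threshold, rel_tol=1e-9, abs_tol=1e-12
            )
        if rec.label == "positive":
            tp, fn = tp + called_positive, fn + (not called_positive)
        else:
            fp, tn = fp + called_positive, tn + (not called_positive)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _count_occurrences(kmer: str, seq: str) -> int:
    """Overlapping occurrence count of ``kmer`` in ``seq``."""
    count = start = 0
    while True:
        pos = seq.find(kmer, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def count_kmer_occurrences(kmers, categorized: dict) -> pd.DataFrame:
    """Overlapping occurrence counts of each k-mer per record category.

    Returns a DataFrame indexed by category with one column per k-mer.
    """
    rows = {}
    for category, records in categorized.items():
        rows[category] = {
            kmer: sum(_count_occurrences(kmer, r.seq) for r in records)
            for kmer in kmers
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(kmers))
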