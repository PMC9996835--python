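"""Imbalance-aware evaluation of eukaryote contig classifiers.

Real drinking-water metagenomes are heavily prokaryote-dominated, so a
classifier's headline accuracy on a balanced test set is misleading.
The protocol here therefore (i) randomly subsamples the test set to a
eukaryote:prokaryote base-pair ratio of 0.05, (ii) scores the subsample
with the Matthews correlation coefficient (MCC), precision and recall
with *eukaryote* as the positive class, and (iii) repeats the
subsampling 100 times, reporting the mean and standard deviation of
each metric.

Predictions of ``unclassified`` can either be counted as negative calls
(``as_negative``, the end-to-end view: an unrecovered eukaryotic contig
is a miss) or dropped before scoring (``exclude``, the view under which
reference tools that answer rarely but correctly score near-perfectly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "Confusion",
    "confusion",
    "mcc",
    "precision",
    "recall",
    "compute_metrics",
    "subsample_to_ratio",
    "evaluate",
    "MetricsResult",
]

UnclassifiedMode = Literal["as_negative", "exclude"]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __iter__(self):
        return iter((self.tp, self.fp, self.tn, self.fn))


def _align(predicted: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    if set(predicted["contig_id"]) != set(truth["contig_id"]):
        raise ValueError("predicted and truth must cover the same contig ids")
    if (truth["true_label"] == "unknown").any():
        raise ValueError("truth contains contigs with unknown labels")
    pred = predicted.set_index("contig_id")["final_label"]
    merged = truth[["contig_id", "true_label", "length_bp"]].copy()
    merged["final_label"] = pred.reindex(merged["contig_id"]).to_numpy()
    return merged


def confusion(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    unclassified_mode: UnclassifiedMode = "as_negative",
) -> Confusion:
    """Confusion counts with eukaryote as the positive class.

    ``as_negative`` treats ``unclassified`` predictions as negative
    (noneukaryote) calls; ``exclude`` drops those contigs before
    counting.
    """
    merged = _align(predicted, truth)
    return _confusion_from_arrays(
        (merged["true_label"] == "eukaryote").to_numpy(),
        merged["final_label"].to_numpy(),
        unclassified_mode,
    )


def _confusion_from_arrays(
    truth_pos: np.ndarray, pred: np.ndarray, mode: UnclassifiedMode
) -> Confusion:
    if mode == "exclude":
        keep = pred != "unclassified"
        truth_pos, pred = truth_pos[keep], pred[keep]
    elif mode != "as_negative":
        raise ValueError(f"unknown unclassified_mode {mode!r}")
    pred_pos = pred == "eukaryote"
    tp = int(np.sum(truth_pos & pred_pos))
    fp = int(np.sum(~truth_pos & pred_pos))
    fn = int(np.sum(truth_pos & ~pred_pos))
    tn = int(np.sum(~truth_pos & ~pred_pos))
    return Confusion(tp, fp, tn, fn)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0.0 when a marginal is empty.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision(tp: int, fp: int, tn: int, fn: int) -> float:
    return tp / (tp + fp) if (tp + fp) > 0 else 0.0


def recall(tp: int, fp: int, tn: int, fn: int) -> float:
    return tp / (tp + fn) if (tp + fn) > 0 else 0.0


def compute_metrics(conf: Confusion) -> dict:
    """All three metrics plus per-metric degenerate-denominator flags.

    A degenerate flag marks a metric whose defining denominator was
    zero, in which case the value is reported as 0.0 by convention.
    """
    tp, fp, tn, fn = conf
    return {
        "mcc": mcc(tp, fp, tn, fn),
        "mcc_degenerate": (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) == 0,
        "precision": precision(tp, fp, tn, fn),
        "precision_degenerate": (tp + fp) == 0,
        "recall": recall(tp, fp, tn, fn),
        "recall_degenerate": (tp + fn) == 0,
    }


def _subsample_indices(
    is_euk: np.ndarray,
    length_bp: np.ndarray,
    target_ratio: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices retained after bp-ratio subsampling (order unspecified)."""
    euk_idx = np.flatnonzero(is_euk)
    prok_idx = np.flatnonzero(~is_euk)
    if euk_idx.size == 0 or prok_idx.size == 0:
        raise ValueError("both classes must be present for ratio subsampling")
    euk_bp = float(length_bp[euk_idx].sum())
    prok_bp = float(length_bp[prok_idx].sum())
    ratio = euk_bp / prok_bp
    if ratio > target_ratio:
        # eukaryotes over-represented: drop random eukaryotic contigs
        # until the bp ratio first reaches <= target
        drop_order = rng.permutation(euk_idx)
        removed = np.cumsum(length_bp[drop_order])
        k = int(np.searchsorted((euk_bp - removed) / prok_bp <= target_ratio, True)) + 1
        keep_euk = drop_order[k:]
        return np.concatenate([keep_euk, prok_idx])
    if ratio < target_ratio:
        # prokaryotes over-represented: drop random prokaryotic contigs
        drop_order = rng.permutation(prok_idx)
        removed = np.cumsum(length_bp[drop_order])
        remaining = prok_bp - removed
        with np.errstate(divide="ignore"):
            reached = euk_bp / remaining >= target_ratio
        k = int(np.searchsorted(reached, True)) + 1
        keep_prok = drop_order[k:]
        return np.concatenate([euk_idx, keep_prok])
    return np.concatenate([euk_idx, prok_idx])


def subsample_to_ratio(
    truth: pd.DataFrame,
    target_ratio: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.Index:
    """Subsample contigs to a target eukaryote:prokaryote bp ratio.

    The class that is over-represented relative to ``target_ratio`` (in
    bp) is down-sampled contig-by-contig, in random order, until the
    realized ratio first crosses the target (<= when eukaryotes were
    over-represented, >= when prokaryotes were); the other class is kept
    in full. The realized ratio is therefore within one contig's bp of
    the target. An input already at the target is returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_euk = (truth["true_label"] == "eukaryote").to_numpy()
    idx = _subsample_indices(
        is_euk, truth["length_bp"].to_numpy(dtype=float), target_ratio, rng
    )
    return pd.Index(truth["contig_id"].to_numpy()[np.sort(idx)])


@dataclass(frozen=True)
class MetricsResult:
    """Per-repeat confusion counts and metrics, plus their mean and sd."""

    per_repeat: pd.DataFrame  # tp, fp, tn, fn, mcc, precision, recall, degenerate
    mean: dict[str, float]
    sd: dict[str, float]
    n_repeats: int
    unclassified_mode: str

    def summary(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "unclassified_mode": self.unclassified_mode,
            "mean": dict(self.mean),
            "sd": dict(self.sd),
        }


def evaluate(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    target_ratio: float = 0.05,
    n_repeats: int = 100,
    seed: int = 0,
    unclassified_mode: UnclassifiedMode = "as_negative",
) -> MetricsResult:
    """Repeated ratio-subsampled evaluation.

    Each repeat independently subsamples the contig set to
    ``target_ratio`` (eukaryote:prokaryote, in bp), computes the
    confusion counts under ``unclassified_mode``, and scores MCC,
    precision and recall; the result carries per-repeat values and the
    across-repeat mean and standard deviation (ddof=1 when
    ``n_repeats > 1``).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    merged = _align(predicted, truth)
    truth_pos = (merged["true_label"] == "eukaryote").to_numpy()
    pred = merged["final_label"].to_numpy()
    length_bp = merged["length_bp"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    for _ in range(n_repeats):
        idx = _subsample_indices(truth_pos, length_bp, target_ratio, rng)
        conf = _confusion_from_arrays(truth_pos[idx], pred[idx], unclassified_mode)
        m = compute_metrics(conf)
        rows.append(
            {
                "tp": conf.tp,
                "fp": conf.fp,
                "tn": conf.tn,
                "fn": conf.fn,
                "mcc": m["mcc"],
                "precision": m["precision"],
                "recall": m["recall"],
                "degenerate": m["mcc_degenerate"]
                or m["precision_degenerate"]
                or m["recall_degenerate"],
            }
        )
    per_repeat = pd.DataFrame(rows)
    metrics = ["mcc", "precision", "recall"]
    mean = {k: float(per_repeat[k].mean()) for k in metrics}
    sd = {
        k: float(per_repeat[k].std(ddof=1)) if n_repeats > 1 else 0.0
        for k in metrics
    }
    return MetricsResult(per_repeat, mean, sd, n_repeats, unclassified_mode)
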