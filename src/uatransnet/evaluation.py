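"""Segmentation metrics, confusion-matrix utilities and cohort splitting.

Metrics follow the usual pixel-count definitions:

    ACC = (TP+TN)/(TP+TN+FP+FN)     PRE = TP/(TP+FP)    REC = TP/(TP+FN)
    IOU = TP/(TP+FP+FN)             DSC = 2|A∩B|/(|A|+|B|)
    F1  = 2·PRE·REC/(PRE+REC)

Zero-denominator metrics are reported as ``None`` (undefined), never as 0,
so aggregates are not silently dragged down.  Reports round to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricSet", "SplitPlan", "confusion_from_masks",
           "compute_metrics", "dsc_from_masks", "percent_change",
           "stratified_split", "evaluate_masks", "aggregate_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Six metrics in [0,1]; ``None`` marks an undefined (0/0) value."""

    acc: float | None
    pre: float | None
    rec: float | None
    iou: float | None
    dsc: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return mask.astype(bool)


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two same-shape binary masks."""
    pred, truth = _binary(pred, "pred"), _binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return ConfusionCounts(tp=int((pred & truth).sum()),
                           fp=int((pred & ~truth).sum()),
                           fn=int((~pred & truth).sum()),
                           tn=int((~pred & ~truth).sum()))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    pre = _ratio(c.tp, c.tp + c.fp)
    rec = _ratio(c.tp, c.tp + c.fn)
    f1 = None
    if pre is not None and rec is not None and pre + rec > 0:
        f1 = 2 * pre * rec / (pre + rec)
    elif pre == 0 or rec == 0:
        f1 = 0.0
    return MetricSet(acc=_ratio(c.tp + c.tn, c.total),
                     pre=pre, rec=rec,
                     iou=_ratio(c.tp, c.tp + c.fp + c.fn),
                     dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
                     f1=f1)


def dsc_from_masks(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dice overlap 2|A∩B|/(|A|+|B|); undefined (None) when both are empty."""
    a, b = _binary(a, "a"), _binary(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2 * int((a & b).sum()) / denom


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for before == 0")
    return 100.0 * (after - before) / before


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple
    test_ids: tuple
    strata: dict
    seed: int

    @property
    def train_fraction(self) -> float:
        n = len(self.train_ids) + len(self.test_ids)
        return len(self.train_ids) / n


def stratified_split(strata: dict, train_fraction: float, seed: int) -> SplitPlan:
    """Random split stratified on a label, hitting the exact global count.

    `strata` maps record id -> stratum label (e.g. an age group).  Each
    stratum contributes floor/ceil of its proportional share; leftover
    slots go to strata with the largest fractional remainders, so the
    global train count is exactly ``round(train_fraction * n)`` and every
    stratum's train share is within one case of the global fraction.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    ids = list(strata)
    n = len(ids)
    if n == 0:
        raise ValueError("no records to split")
    target = round(train_fraction * n)
    groups: dict = {}
    for rid, s in strata.items():
        groups.setdefault(s, []).append(rid)
    labels = sorted(groups, key=str)
    ideal = {s: train_fraction * len(groups[s]) for s in labels}
    take = {s: int(np.floor(ideal[s])) for s in labels}
    leftover = target - sum(take.values())
    # largest-remainder apportionment of the remaining slots
    by_rem = sorted(labels, key=lambda s: (-(ideal[s] - take[s]), str(s)))
    for s in by_rem[:max(leftover, 0)]:
        take[s] += 1
    rng = np.random.default_rng(seed)
    train, test = [], []
    for s in labels:
        members = sorted(groups[s], key=str)
        rng.shuffle(members)
        k = min(take[s], len(members))
        train.extend(members[:k])
        test.extend(members[k:])
    return SplitPlan(tuple(train), tuple(test), dict(strata), seed)


def evaluate_masks(preds, truths) -> pd.DataFrame:
    """Per-image metric table (one row per pair) plus macro/micro summaries.

    Macro: metrics per image then mean ± sd over images (undefined values
    excluded).  Micro: metrics of the pooled pixel counts.
    """
    rows, pooled = [], np.zeros(4, dtype=np.int64)
    for i, (p, t) in enumerate(zip(preds, truths)):
        c = confusion_from_masks(p, t)
        pooled += (c.tp, c.fp, c.fn, c.tn)
        rows.append({"image": i, **compute_metrics(c).as_dict()})
    df = pd.DataFrame(rows)
    cols = ["acc", "pre", "rec", "iou", "dsc", "f1"]
    mean = {k: df[k].dropna().mean() for k in cols}
    sd = {k: df[k].dropna().std(ddof=0) for k in cols}
    micro = compute_metrics(ConfusionCounts(*[int(v) for v in pooled])).as_dict()
    df = pd.concat([df, pd.DataFrame([
        {"image": "macro_mean", **mean},
        {"image": "macro_sd", **sd},
        {"image": "micro", **micro}])], ignore_index=True)
    for k in cols:
        df[k] = df[k].astype(float).round(3)
    return df


def aggregate_metrics(preds, truths) -> dict:
    """Mean ± sd of per-image metrics (macro) and pooled (micro) metrics."""
    df = evaluate_masks(preds, truths)
    out = {}
    for name in ("macro_mean", "macro_sd", "micro"):
        row = df[df["image"] == name].iloc[0]
        out[name] = {k: float(row[k]) for k in ("acc", "pre", "rec", "iou", "dsc", "f1")}
    return out
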