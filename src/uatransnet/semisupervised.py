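"""Mean-teacher dataset optimization.

A classifier is trained to split a dataset into an *effective* part (clear,
well-delineated lesions) and a *difficult* part (small or blurred lesions)
so that training can be staged on the cleaner cases first.  Labels exist
for only part of the data; the rest is exploited through a consistency
loss between a *student* network, updated by gradient descent, and a
*teacher* whose parameters are an exponential moving average (EMA) of the
student's:

    theta'_t = alpha * theta'_{t-1} + (1 - alpha) * theta_t

The training objective is

    Loss = Loss_1 + w * Loss_2

with ``Loss_1`` the mean binary cross-entropy on the labeled batch and
``Loss_2`` the Jensen-Shannon divergence between student and teacher
predictive distributions on the unlabeled batch (the symmetric counterpart
of KL divergence, bounded by ln 2).  Binary predictions p are treated as
two-point distributions (p, 1-p).  All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Tensor
from .nn import EPS, Adam, bce_loss
from .network import Classifier, NetworkConfig, build_classifier

__all__ = ["TeacherStudentState", "PartitionResult", "MeanTeacherConfig",
           "supervised_loss", "kl_divergence", "js_consistency_loss",
           "total_loss", "ema_update", "mean_teacher_step",
           "train_mean_teacher", "partition_dataset"]


def supervised_loss(labels, preds) -> float:
    """Mean binary cross-entropy (natural log, eps-clipped probabilities)."""
    labels = np.asarray(labels, dtype=np.float64)
    preds = np.asarray(preds, dtype=np.float64)
    if labels.shape != preds.shape:
        raise ValueError("labels and predictions differ in length")
    if labels.size == 0:
        raise ValueError("need at least one sample")
    p = np.clip(preds, EPS, 1.0 - EPS)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def _check_dist(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size < 2:
        raise ValueError(f"{name} must be a 1-D distribution over >= 2 outcomes")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} is not a probability distribution (sum={p.sum()})")
    return np.clip(p, EPS, None)


def kl_divergence(p, q) -> float:
    """KL(P || Q) = sum p ln(p/q), in nats; nonnegative (Gibbs)."""
    p, q = _check_dist(p, "P"), _check_dist(q, "Q")
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    return float(np.sum(p * np.log(p / q)))


def js_consistency_loss(p_student, p_teacher) -> float:
    """Jensen-Shannon divergence: symmetric, bounded by ln 2, 0 iff P = Q.

    JS(P,Q) = KL(P||M)/2 + KL(Q||M)/2 with M the equal mixture of P and Q.
    """
    p = _check_dist(p_student, "P_student")
    q = _check_dist(p_teacher, "P_teacher")
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def total_loss(sup: float, cons: float, weight: float = 1.0) -> float:
    """Combined objective: supervised + weight * consistency."""
    return float(sup + weight * cons)


@dataclass
class TeacherStudentState:
    """Paired parameter collections plus the EMA decay alpha."""

    student: Classifier
    teacher: Classifier
    ema_decay: float = 0.99
    step: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ValueError("ema_decay must lie in [0, 1]")
        s, t = self.student.state_dict(), self.teacher.state_dict()
        if set(s) != set(t) or any(s[k].shape != t[k].shape for k in s):
            raise ValueError("student and teacher parameters are not congruent")


def ema_update(state: TeacherStudentState, decay: float | None = None) -> TeacherStudentState:
    """theta'_t = alpha*theta'_{t-1} + (1-alpha)*theta_t, elementwise;
    the student is untouched.  Every teacher parameter stays a convex
    combination of its old value and the student's.  `decay` overrides the
    state's alpha for this update (used by the warm-up schedule)."""
    a = state.ema_decay if decay is None else decay
    if not 0.0 <= a <= 1.0:
        raise ValueError("decay must lie in [0, 1]")
    s_params = dict(state.student.named_parameters())
    for name, tp in state.teacher.named_parameters():
        tp.data = a * tp.data + (1.0 - a) * s_params[name].data.astype(tp.data.dtype)
    return state


@dataclass
class MeanTeacherConfig:
    ema_decay: float = 0.99
    consistency_weight: float = 1.0
    ramp_epochs: int = 0          # >0: weight ramps linearly over these epochs
    lr: float = 1e-3
    batch_size: int = 16
    noise_sd: float = 0.05        # independent input perturbation per branch
    epochs: int = 5


def _js_tensor(p_student: Tensor, p_teacher: np.ndarray) -> Tensor:
    """Differentiable mean JS over a batch of two-point distributions.

    The teacher side is a constant (no gradient flows into the teacher).
    """
    ps = p_student.clip(EPS, 1.0 - EPS)
    pt = np.clip(np.asarray(p_teacher, dtype=ps.data.dtype), EPS, 1.0 - EPS)
    m1 = (ps + pt) * 0.5
    m0 = 1.0 - m1
    kl_s = ps * (ps.log() - m1.log()) + (1.0 - ps) * ((1.0 - ps).log() - m0.log())
    kl_t = Tensor(pt * np.log(pt)) - pt * m1.log() \
        + Tensor((1.0 - pt) * np.log(1.0 - pt)) - (1.0 - pt) * m0.log()
    return (kl_s * 0.5 + kl_t * 0.5).mean()


def mean_teacher_step(batch_labeled, batch_unlabeled, state: TeacherStudentState,
                      optimizer: Adam, cfg: MeanTeacherConfig,
                      rng: np.random.Generator) -> dict:
    """One optimization step.

    Student sees the labeled batch and a noisy view of the unlabeled batch;
    the teacher sees an independently-noised view of the unlabeled batch.
    Loss = BCE(labels, student) + w * JS(student, teacher); the student
    takes a gradient step, then the teacher EMA-tracks it.
    """
    images, labels = batch_labeled
    if len(images) == 0:
        raise ValueError("labeled batch must be nonempty")
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.float32)
    if images.ndim == 3:
        images = images[:, None]
    optimizer.zero_grad()
    p_lab = state.student(Tensor(images))[:, 0]
    loss_sup = bce_loss(p_lab, labels)
    losses = {"supervised": float(loss_sup.data)}
    loss = loss_sup
    if batch_unlabeled is not None and len(batch_unlabeled) and cfg.consistency_weight > 0:
        unl = np.asarray(batch_unlabeled, dtype=np.float32)
        if unl.ndim == 3:
            unl = unl[:, None]
        noisy_s = unl + rng.normal(0, cfg.noise_sd, unl.shape).astype(np.float32)
        noisy_t = unl + rng.normal(0, cfg.noise_sd, unl.shape).astype(np.float32)
        p_s = state.student(Tensor(noisy_s))[:, 0]
        p_t = state.teacher.predict(noisy_t)
        loss_cons = _js_tensor(p_s, p_t)
        losses["consistency"] = float(loss_cons.data)
        loss = loss + cfg.consistency_weight * loss_cons
    losses["total"] = float(loss.data)
    loss.backward()
    optimizer.step()
    # warm-up: early teachers track the student closely, then settle to alpha
    ema_update(state, decay=min(state.ema_decay, 1.0 - 1.0 / (state.step + 1)))
    state.step += 1
    return losses


def train_mean_teacher(labeled, unlabeled, cfg: MeanTeacherConfig,
                       net_cfg: NetworkConfig, seed: int = 0) -> TeacherStudentState:
    """Full mean-teacher loop over epochs of shuffled mini-batches.

    `labeled` is (images, labels); `unlabeled` an image stack (may be empty,
    which reduces to plain supervised training).  Fixed seeds give
    bit-reproducible trajectories.
    """
    images, labels = labeled
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.float32)
    unlabeled = np.asarray(unlabeled, dtype=np.float32)
    state = TeacherStudentState(build_classifier(net_cfg, seed),
                                build_classifier(net_cfg, seed),
                                ema_decay=cfg.ema_decay)
    optimizer = Adam(state.student.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(seed)
    n, b = len(images), cfg.batch_size
    for epoch in range(cfg.epochs):
        w = cfg.consistency_weight
        if cfg.ramp_epochs > 0:
            w *= min(1.0, (epoch + 1) / cfg.ramp_epochs)
        step_cfg = MeanTeacherConfig(**{**vars(cfg), "consistency_weight": w})
        order = rng.permutation(n)
        u_order = rng.permutation(len(unlabeled)) if len(unlabeled) else []
        for i in range(0, n, b):
            idx = order[i:i + b]
            if len(unlabeled):
                uidx = u_order[(i // b * b) % len(unlabeled):][:b]
                ub = unlabeled[uidx] if len(uidx) else None
            else:
                ub = None
            mean_teacher_step((images[idx], labels[idx]), ub, state,
                              optimizer, step_cfg, rng)
    return state


@dataclass(frozen=True)
class PartitionResult:
    """Disjoint, exhaustive effective/difficult split with per-id scores."""

    effective: tuple
    difficult: tuple
    scores: dict = field(default_factory=dict)

    @property
    def proportions(self) -> tuple[float, float]:
        n = len(self.effective) + len(self.difficult)
        return len(self.effective) / n, len(self.difficult) / n


def partition_dataset(classifier: Classifier, images, ids=None,
                      confidence_threshold: float = 0.5) -> PartitionResult:
    """Split by classifier confidence: score >= threshold -> effective."""
    images = np.asarray(images, dtype=np.float32)
    scores = classifier.predict(images)
    if ids is None:
        ids = list(range(len(images)))
    eff = tuple(i for i, s in zip(ids, scores) if s >= confidence_threshold)
    dif = tuple(i for i, s in zip(ids, scores) if s < confidence_threshold)
    return PartitionResult(eff, dif, {i: float(s) for i, s in zip(ids, scores)})
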