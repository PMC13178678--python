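"""Contrastive pre-training objectives and their input transforms.

Encoder-agnostic building blocks: an ECG is split into two consecutive
segments, a random subset of leads is masked, and two InfoNCE-style losses
operate on whatever embeddings an encoder produces — a *token* loss aligning
each masked position's contextual embedding with its quantized target
against negatives drawn from the same segment, and a *segment* loss drawing
together global averages of segments from the same recording or patient
while pushing apart all others.  Both use cosine similarity at temperature
tau (default 0.1).  Quantization/codebook learning and encoders are out of
scope; embeddings are accepted as given numeric batches, so the losses are
testable on desk-scale arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ParameterError, ValidationError
from .io import ECGRecord

_LOG_STREAM_MASK = 53
_LOG_STREAM_NEG = 59
_LOG_STREAM_DESCENT = 61


@dataclass
class MaskSpec:
    """Random lead masking: replace n whole leads with a constant value."""

    n_leads_masked: int = 3
    mask_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_leads_masked <= 12:
            raise ParameterError("n_leads_masked must lie in [0, 12]")


@dataclass
class LossConfig:
    temperature: float = 0.1
    n_negatives: int = 4

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.n_negatives < 1:
            raise ParameterError("n_negatives must be >= 1")


@dataclass
class EmbeddingBatch:
    """Embeddings (items x dim) with per-item record and patient identity."""

    embeddings: np.ndarray
    record_ids: Sequence[str]
    patient_ids: Sequence[str]
    role: str = "segment_global"

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if self.embeddings.ndim != 2:
            raise ValidationError("embeddings must be 2-D (items x dim)")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValidationError("embeddings contain non-finite values")
        n = self.embeddings.shape[0]
        if len(self.record_ids) != n or len(self.patient_ids) != n:
            raise ValidationError("identity lists must align with embedding rows")
        self.record_ids = list(map(str, self.record_ids))
        self.patient_ids = list(map(str, self.patient_ids))

    @property
    def n_items(self) -> int:
        return self.embeddings.shape[0]


def split_segments(record: ECGRecord) -> tuple[ECGRecord, ECGRecord]:
    """Split a record into two consecutive non-overlapping halves.

    An odd trailing sample is dropped from the end.  Both segments inherit
    the metadata, with the segment index appended to record_id.
    """
    n = record.n_samples
    if n < 2:
        raise ParameterError("record must have at least 2 samples")
    half = n // 2
    seg1 = record.copy_with(
        signal=record.signal[:, :half].copy(),
        record_id=f"{record.record_id}_seg1",
    )
    seg2 = record.copy_with(
        signal=record.signal[:, half : 2 * half].copy(),
        record_id=f"{record.record_id}_seg2",
    )
    return seg1, seg2


def mask_leads(record: ECGRecord, spec: MaskSpec) -> tuple[ECGRecord, np.ndarray]:
    """Replace exactly ``n_leads_masked`` random leads with ``mask_value``.

    Returns (masked record, boolean mask indicator per lead); deterministic
    under ``spec.seed``.
    """
    n_leads = record.signal.shape[0]
    if spec.n_leads_masked > n_leads:
        raise ParameterError("n_leads_masked exceeds available leads")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), _LOG_STREAM_MASK]))
    chosen = rng.choice(n_leads, size=spec.n_leads_masked, replace=False)
    indicator = np.zeros(n_leads, dtype=bool)
    indicator[chosen] = True
    signal = record.signal.copy()
    signal[indicator] = spec.mask_value
    return record.copy_with(signal=signal), indicator


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    return (a / na) @ (b / nb).T


def token_contrastive_loss(
    context: EmbeddingBatch,
    quantized: EmbeddingBatch,
    masked_positions: Sequence[int],
    config: LossConfig | None = None,
    seed: int = 0,
) -> float:
    """InfoNCE loss aligning each masked token's context with its quantized target.

    For each masked position t the positive is the quantized vector at t and
    K negatives are drawn uniformly without replacement from the other
    positions of the same segment:

        -log  exp(cos(c_t, q_t)/tau) / sum_{k in {t} U negatives} exp(cos(c_t, q_k)/tau)

    averaged over masked positions.  Deterministic under ``seed``.
    """
    config = config or LossConfig()
    masked_positions = list(masked_positions)
    if not masked_positions:
        raise ParameterError("masked_positions must be nonempty")
    if context.embeddings.shape != quantized.embeddings.shape:
        raise ParameterError("context and quantized batches must align by position")
    n = quantized.n_items
    if n - 1 < config.n_negatives:
        raise ParameterError(
            f"need >= {config.n_negatives + 1} candidate quantized vectors, got {n}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _LOG_STREAM_NEG]))
    sims = _cosine_matrix(context.embeddings, quantized.embeddings) / config.temperature
    losses = []
    for t in masked_positions:
        others = np.delete(np.arange(n), t)
        negatives = rng.choice(others, size=config.n_negatives, replace=False)
        logits = sims[t, np.concatenate(([t], negatives))]
        # -log softmax at the positive (index 0), computed stably
        m = logits.max()
        losses.append(-(logits[0] - m) + np.log(np.exp(logits - m).sum()))
    return float(np.mean(losses))


def segment_contrastive_loss(
    batch: EmbeddingBatch,
    config: LossConfig | None = None,
    positive_rule: str = "same_record",
) -> float:
    """Multi-segment contrastive loss over global segment embeddings.

    For each anchor i with positive set P(i) (other items sharing the record
    or the patient, per ``positive_rule``):

        -log  sum_{p in P(i)} exp(cos_ip/tau) / sum_{j != i} exp(cos_ij/tau)

    averaged over anchors; anchors with no positive are excluded (error if
    none remain).
    """
    config = config or LossConfig()
    if positive_rule not in ("same_record", "same_patient"):
        raise ParameterError("positive_rule must be 'same_record' or 'same_patient'")
    n = batch.n_items
    if n < 2:
        raise ParameterError("need at least 2 items")
    # segments produced by split_segments carry '<record>_segK' ids; strip the
    # suffix so two halves of one recording count as the same record
    if positive_rule == "same_record":
        keys = [rid.rsplit("_seg", 1)[0] for rid in batch.record_ids]
    else:
        keys = list(batch.patient_ids)
    keys = np.asarray(keys)
    sims = _cosine_matrix(batch.embeddings, batch.embeddings) / config.temperature
    losses = []
    for i in range(n):
        positives = np.flatnonzero((keys == keys[i]) & (np.arange(n) != i))
        if positives.size == 0:
            continue
        others = np.delete(np.arange(n), i)
        m = sims[i, others].max()
        num = np.exp(sims[i, positives] - m).sum()
        den = np.exp(sims[i, others] - m).sum()
        losses.append(-np.log(num / den))
    if not losses:
        raise ParameterError("no anchor has a positive under the rule")
    return float(np.mean(losses))


def descend_segment_loss(
    batch: EmbeddingBatch,
    config: LossConfig | None = None,
    positive_rule: str = "same_patient",
    steps: int = 500,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> tuple[EmbeddingBatch, list[float]]:
    """Toy gradient-descent harness on raw embedding coordinates.

    Minimizes :func:`segment_contrastive_loss` by central finite differences
    — no encoder, no autodiff — to demonstrate the objective's geometry:
    embeddings sharing a patient collapse onto a common direction while
    distinct patients repel.  Returns the optimized batch and the loss
    trajectory.
    """
    config = config or LossConfig()
    emb = batch.embeddings.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _LOG_STREAM_DESCENT]))
    emb += 1e-6 * rng.standard_normal(emb.shape)  # break exact ties

    def loss_of(e: np.ndarray) -> float:
        return segment_contrastive_loss(
            EmbeddingBatch(e, batch.record_ids, batch.patient_ids, batch.role),
            config,
            positive_rule,
        )

    eps = 1e-5
    history = [loss_of(emb)]
    for _ in range(steps):
        grad = np.zeros_like(emb)
        for i in range(emb.shape[0]):
            for j in range(emb.shape[1]):
                emb[i, j] += eps
                up = loss_of(emb)
                emb[i, j] -= 2 * eps
                down = loss_of(emb)
                emb[i, j] += eps
                grad[i, j] = (up - down) / (2 * eps)
        norm = np.linalg.norm(grad)
        if norm == 0:
            break
        emb -= learning_rate * grad / norm
        # keep coordinates bounded: cosine loss is scale-free per row
        emb /= np.maximum(np.linalg.norm(emb, axis=1, keepdims=True), 1e-12)
        history.append(loss_of(emb))
    out = EmbeddingBatch(emb, batch.record_ids, batch.patient_ids, batch.role)
    return out, history
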