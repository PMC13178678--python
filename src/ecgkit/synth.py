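"""Synthetic 12-lead ECGs, injectable artefacts, and multilabel audit cohorts.

The waveform generator is deliberately spectral/amplitude-controlled rather
than physiologically detailed: beats are sums of Gaussian bumps (P, Q, R, S,
T) convolved over an R-peak train, projected onto the 12 leads by a fixed
coefficient vector (aVR negative).  That is all the harmonization pipeline's
mathematics needs — controllable band energies, peak amplitudes and artefact
content — while keeping every property of the output derivable in closed
form.

Generated records are mean-subtracted per lead (AC coupling), so a clean
record carries essentially no energy below 1 Hz and never trips the
high-pass gate.  No broadband noise is added by default; white noise is an
injectable artefact class like wander and mains interference, so cohort
spectra vary boundedly (a prerequisite for a per-bin exceedance rule with
zero false positives on in-distribution records).

Randomness: every operation derives its generator from a single integer seed
via a named :class:`numpy.random.SeedSequence` stream, so outputs are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ParameterError, ValidationError
from .io import CANONICAL_LEADS, ECGRecord, PredictionSet

# Fixed per-lead projection multipliers for the single source beat train.
# Signs/magnitudes loosely follow typical limb/precordial polarity (aVR and
# V1 predominantly negative); the constant vector guarantees inter-lead
# consistency without a torso model.
LEAD_PROJECTION = np.array(
    [1.00, 1.10, 0.25, -0.90, 0.45, 0.70, -0.35, 0.60, 0.95, 1.20, 1.10, 0.95]
)

_STREAMS = {"clean_ecg": 11, "artefact": 23, "cohort": 37}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class BeatTemplate:
    """PQRST morphology as Gaussian bumps: (center offset s, width s, amplitude mV)."""

    waves: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "P": (-0.200, 0.025, 0.12),
            "Q": (-0.035, 0.012, -0.10),
            "R": (0.000, 0.016, 1.00),
            "S": (0.035, 0.014, -0.20),
            "T": (0.220, 0.060, 0.30),
        }
    )
    heart_rate_bpm: float = 60.0
    rr_jitter_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.heart_rate_bpm <= 220.0:
            raise ValidationError("heart_rate_bpm must lie in [30, 220]")
        if not 0.0 <= self.rr_jitter_fraction < 0.5:
            raise ValidationError("rr_jitter_fraction must lie in [0, 0.5)")
        for name, (_, width, amp) in self.waves.items():
            if width <= 0:
                raise ValidationError(f"wave {name}: width must be positive")
        if self.waves.get("R", (0, 1, 0))[2] <= 0:
            raise ValidationError("R amplitude must be positive")

    def scaled(self, factor: float) -> "BeatTemplate":
        """Return a copy with every wave amplitude multiplied by ``factor``."""
        waves = {k: (c, w, a * factor) for k, (c, w, a) in self.waves.items()}
        return replace(self, waves=waves)


def simulate_clean_ecg(
    template: BeatTemplate | None = None,
    sampling_rate_hz: float = 250.0,
    duration_s: float = 10.0,
    seed: int = 0,
    record_id: str = "sim",
    patient_id: str = "",
    age_years: float | None = None,
    sex: str | None = None,
) -> ECGRecord:
    """Simulate a clean 12-lead record (mV) from a beat template.

    Deterministic under ``seed`` (the seed only matters when
    ``rr_jitter_fraction > 0``).
    """
    template = template or BeatTemplate()
    rr = 60.0 / template.heart_rate_bpm
    if duration_s < 2 * rr:
        raise ParameterError("duration must cover at least 2 beats")
    rng = _rng(seed, "clean_ecg")
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    n_beats = int(np.floor(duration_s / rr))
    centers = rr * (np.arange(n_beats) + 0.5)
    if template.rr_jitter_fraction > 0:
        centers = centers + rr * template.rr_jitter_fraction * rng.uniform(
            -1.0, 1.0, size=n_beats
        )
    source = np.zeros(n)
    for _, (offset, width, amp) in template.waves.items():
        # (beats x samples) Gaussian bumps summed over beats
        d = t[None, :] - (centers[:, None] + offset)
        source += amp * np.exp(-0.5 * (d / width) ** 2).sum(axis=0)
    source -= source.mean()  # AC coupling: no DC component
    signal = LEAD_PROJECTION[:, None] * source[None, :]
    return ECGRecord(
        record_id=record_id,
        patient_id=patient_id or record_id,
        signal=signal,
        sampling_rate_hz=sampling_rate_hz,
        lead_names=CANONICAL_LEADS,
        units="mV",
        age_years=age_years,
        sex=sex,
    )


@dataclass
class ArtefactSpec:
    """One injectable artefact.

    kinds: ``baseline_wander`` (< 1 Hz sinusoid, random phase), ``powerline``
    (fixed-frequency sinusoid, >= 30 Hz), ``scale_drift`` (multiplicative),
    ``white_noise`` (additive zero-mean Gaussian, SD = amplitude_mv).
    """

    kind: str
    frequency_hz: float | None = None
    amplitude_mv: float | None = None
    scale_factor: float | None = None
    leads: Sequence[int] | str = "all"

    def __post_init__(self) -> None:
        if self.kind not in ("baseline_wander", "powerline", "scale_drift", "white_noise"):
            raise ParameterError(f"unknown artefact kind {self.kind!r}")
        if self.kind == "baseline_wander":
            if self.frequency_hz is None or not 0 < self.frequency_hz < 1:
                raise ValidationError("wander frequency must lie in (0, 1) Hz")
            if not self.amplitude_mv or self.amplitude_mv <= 0:
                raise ValidationError("wander amplitude_mv must be positive")
        elif self.kind == "powerline":
            if self.frequency_hz is None or self.frequency_hz < 30:
                raise ValidationError("powerline frequency must be >= 30 Hz")
            if not self.amplitude_mv or self.amplitude_mv <= 0:
                raise ValidationError("powerline amplitude_mv must be positive")
        elif self.kind == "scale_drift":
            if self.scale_factor is None or self.scale_factor <= 0:
                raise ValidationError("scale_factor must be positive")
        elif self.kind == "white_noise":
            if not self.amplitude_mv or self.amplitude_mv <= 0:
                raise ValidationError("white_noise amplitude_mv must be positive")

    def lead_indices(self, n_leads: int) -> np.ndarray:
        if isinstance(self.leads, str):
            if self.leads != "all":
                raise ParameterError("leads must be 'all' or a sequence of indices")
            return np.arange(n_leads)
        idx = np.asarray(self.leads, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n_leads):
            raise ParameterError("lead index out of range")
        return idx


def inject_artefact(record: ECGRecord, spec: ArtefactSpec, seed: int = 0) -> ECGRecord:
    """Return a new record with ``spec`` applied to the specified leads only.

    Unspecified leads are bitwise unchanged.  Deterministic under ``seed``.
    """
    rng = _rng(seed, "artefact")
    signal = record.signal.copy()
    idx = spec.lead_indices(signal.shape[0])
    t = np.arange(signal.shape[1]) / record.sampling_rate_hz
    if spec.kind in ("baseline_wander", "powerline"):
        phase = rng.uniform(0, 2 * np.pi)
        tone = spec.amplitude_mv * np.sin(2 * np.pi * spec.frequency_hz * t + phase)
        signal[idx] += tone[None, :]
    elif spec.kind == "scale_drift":
        signal[idx] *= spec.scale_factor
    elif spec.kind == "white_noise":
        signal[idx] += rng.normal(0.0, spec.amplitude_mv, size=(idx.size, signal.shape[1]))
    return record.copy_with(signal=signal)


# ---------------------------------------------------------------------------
# multilabel audit cohorts
# ---------------------------------------------------------------------------

AGE_GROUP_RANGES = {"<55": (30.0, 54.0), "55–75": (55.0, 75.0), ">75": (76.0, 95.0)}


@dataclass
class AuditCohortSpec:
    """Statistical recipe for a synthetic multilabel prediction cohort.

    Scores are generated on a latent Gaussian scale (positives at
    ``pos_loc``, negatives at ``neg_loc``) and mapped through a logistic
    sigmoid into (0, 1); AUROC is rank-based, so the analytic value
    Phi(delta_mu / sqrt(pos_scale^2 + neg_scale^2)) is preserved exactly.
    Group shifts and the membership shift act additively on the latent scale.
    """

    n_records: int = 1000
    label_prevalences: Sequence[float] = (0.3,)
    pos_loc: float = 1.0
    neg_loc: float = -1.0
    pos_scale: float = 1.0
    neg_scale: float = 1.0
    #: additive latent shift per (partition, group), e.g. {("sex", "F"): 0.5}
    group_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    membership_shift: float = 0.0
    member_fraction: float = 0.5
    sex_proportion_f: float = 0.5
    age_group_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < p < 1 for p in self.label_prevalences):
            raise ValidationError("prevalences must lie in (0, 1)")
        for (_, _), delta in self.group_shift.items():
            if delta < 0:
                raise ValidationError("group shifts must be nonnegative")

    def analytic_auroc(self) -> float:
        """Closed-form AUROC of the two latent Gaussians (no shifts)."""
        from scipy.stats import norm

        return float(
            norm.cdf(
                (self.pos_loc - self.neg_loc)
                / np.hypot(self.pos_scale, self.neg_scale)
            )
        )


def simulate_audit_cohort(
    spec: AuditCohortSpec,
) -> tuple[PredictionSet, pd.DataFrame, np.ndarray]:
    """Simulate (PredictionSet, group table, membership flags).

    Truths are per-label Bernoulli(prevalence); latent scores are Gaussian
    per class, shifted by the record's group deltas and (for members) the
    membership shift, then squashed into (0, 1).  Deterministic under
    ``spec.seed``.
    """
    rng = _rng(spec.seed, "cohort")
    n = spec.n_records
    labels = [f"label_{i}" for i in range(len(spec.label_prevalences))]

    age_names = list(AGE_GROUP_RANGES)
    age_group = rng.choice(len(age_names), size=n, p=np.asarray(spec.age_group_probs))
    ages = np.empty(n)
    for g, (lo, hi) in enumerate(AGE_GROUP_RANGES.values()):
        mask = age_group == g
        ages[mask] = rng.uniform(lo, hi, size=mask.sum())
    sex = np.where(rng.random(n) < spec.sex_proportion_f, "F", "M")
    for g in range(3):
        if (age_group == g).sum() < 2:
            raise ParameterError(f"age group {age_names[g]} has < 2 records")
    for s in ("F", "M"):
        if (sex == s).sum() < 2:
            raise ParameterError(f"sex group {s} has < 2 records")

    members = rng.random(n) < spec.member_fraction
    shift = np.zeros(n)
    for (partition, group), delta in spec.group_shift.items():
        if partition == "sex":
            shift += delta * (sex == group)
        elif partition == "age":
            shift += delta * (np.asarray(age_names)[age_group] == group)
        else:
            raise ParameterError(f"unknown partition {partition!r}")
    shift += spec.membership_shift * members

    prev = np.asarray(spec.label_prevalences)
    truths = (rng.random((n, len(labels))) < prev[None, :]).astype(np.int8)
    latent = np.where(
        truths == 1,
        rng.normal(spec.pos_loc, spec.pos_scale, size=truths.shape),
        rng.normal(spec.neg_loc, spec.neg_scale, size=truths.shape),
    )
    latent = latent + shift[:, None]
    scores = expit(latent)

    record_ids = [f"rec_{i:06d}" for i in range(n)]
    preds = PredictionSet(record_ids, labels, scores, truths)
    groups = pd.DataFrame(
        {"record_id": record_ids, "age": ages, "sex": sex, "age_group_drawn": np.asarray(age_names)[age_group]}
    )
    return preds, groups, members
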