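"""Three-stage 12-lead ECG harmonization.

Stage 1 — *gated zero-phase high-pass*: each record's FFT band energies are
compared; when the energy below 1 Hz exceeds the 1–30 Hz diagnostic band by
more than an order of magnitude on any lead, a 1 Hz order-4 Butterworth
high-pass is applied forward–backward (zero net phase) to all leads.

Stage 2 — *cohort-referenced narrowband suppression*: a reference cohort
provides the per-lead, per-bin mean and SD of post-high-pass amplitude
spectra.  Maximal contiguous runs of bins whose amplitude exceeds
``mean + k_sd * SD`` (default k = 2) and whose width is at most 2 Hz — the
signature of mains interference at 50/60 Hz, not broadband exceedance — are
flattened onto a LOESS fit of the log-amplitude spectrum, phases untouched.

Stage 3 — *amplitude scaling*: signals are rescaled so the cohort's robust
peak-to-peak millivolt statistic (99th − 1st percentile, median over leads,
median over records) matches the reference target; per-dataset scaling (one
factor per cohort) is the default so between-record voltage differences are
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import (
    DegenerateFitError,
    DegenerateRecordError,
    InsufficientCohortError,
    ParameterError,
    ReferenceMismatchError,
    TooShortError,
    UnsupportedRateError,
)
from .io import ECGRecord

LOW_BAND_EDGE_HZ = 1.0   # low band is [0, 1) Hz, DC bin included
DIAG_BAND_HZ = (1.0, 30.0)  # diagnostic band, inclusive


# ---------------------------------------------------------------------------
# spectra and band energies
# ---------------------------------------------------------------------------

def _amplitude_spectrum(signal: np.ndarray, fs: float):
    """One-sided amplitude spectrum and Parseval-consistent per-bin energy.

    Amplitude is normalized so a pure sinusoid of amplitude ``a`` at a
    bin-aligned frequency reads ``a`` at its bin.  Per-bin energies sum to
    the time-domain energy ``sum(x**2)`` exactly (rFFT Parseval identity).
    """
    n = signal.shape[-1]
    X = np.fft.rfft(signal, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.abs(X)
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    amplitude = mag * scale / n
    energy = mag**2 * scale / n
    return freqs, amplitude, energy, X


@dataclass
class SpectralProfile:
    """Per-lead one-sided amplitude spectrum with low/diagnostic band energies."""

    freqs: np.ndarray            # (n_bins,)
    amplitude: np.ndarray        # (n_leads, n_bins)
    energy: np.ndarray           # (n_leads, n_bins), sums to time-domain energy
    e_low: np.ndarray            # (n_leads,)
    e_diag: np.ndarray           # (n_leads,)
    ratio: np.ndarray            # (n_leads,) E_low / E_diag, inf where E_diag == 0
    sampling_rate_hz: float
    n_samples: int

    @property
    def max_ratio(self) -> float:
        return float(np.max(self.ratio))


def band_energies(record: ECGRecord) -> SpectralProfile:
    """Compute the spectral profile the high-pass gate decides on.

    Requires sampling rate >= 60 Hz so the 30 Hz diagnostic-band edge exists.
    """
    fs = record.sampling_rate_hz
    if fs < 2 * DIAG_BAND_HZ[1]:
        raise UnsupportedRateError(
            f"sampling rate {fs} Hz < {2 * DIAG_BAND_HZ[1]} Hz; the "
            f"{DIAG_BAND_HZ[1]} Hz band edge does not exist"
        )
    freqs, amplitude, energy, _ = _amplitude_spectrum(record.signal, fs)
    low = freqs < LOW_BAND_EDGE_HZ
    diag = (freqs >= DIAG_BAND_HZ[0]) & (freqs <= DIAG_BAND_HZ[1])
    e_low = energy[:, low].sum(axis=1)
    e_diag = energy[:, diag].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            e_diag > 0, e_low / np.where(e_diag > 0, e_diag, 1.0),
            np.where(e_low > 0, np.inf, 0.0),
        )
    return SpectralProfile(
        freqs=freqs,
        amplitude=amplitude,
        energy=energy,
        e_low=e_low,
        e_diag=e_diag,
        ratio=ratio,
        sampling_rate_hz=fs,
        n_samples=record.n_samples,
    )


# ---------------------------------------------------------------------------
# gated zero-phase high-pass
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """High-pass gate and filter parameters.

    ``gate_ratio`` is the strict low/diagnostic energy-ratio threshold (an
    order of magnitude by default); the filter is an order-4 Butterworth
    magnitude design applied forward-backward.
    """

    cutoff_hz: float = 1.0
    order: int = 4
    gate_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff_hz must be positive")
        if self.gate_ratio <= 1:
            raise ParameterError("gate_ratio must exceed 1")


def needs_highpass(profile: SpectralProfile, config: FilterConfig | None = None) -> bool:
    """True iff any lead's low/diagnostic energy ratio strictly exceeds the gate."""
    config = config or FilterConfig()
    return bool(np.any(profile.ratio > config.gate_ratio))


def _min_samples(fs: float, config: FilterConfig) -> int:
    # the filter needs ~3 cutoff periods of context to resolve the stopband
    return int(round(3 * fs / config.cutoff_hz))


def apply_zero_phase_highpass(
    record: ECGRecord, config: FilterConfig | None = None
) -> ECGRecord:
    """Zero-phase Butterworth-magnitude high-pass on all leads.

    Realized in the DFT domain: each lead's spectrum is multiplied by the
    squared order-``n`` Butterworth magnitude response (the response of one
    forward plus one backward pass), which has zero phase by construction.
    Compared to a time-domain forward-backward pass with edge padding, this
    realization has no edge transients — a large low-frequency component is
    removed without splashing broadband residue — and it composes exactly
    with the spectral detection stage, which uses the same DFT.

    Output length equals input length; DC is removed.  Raises
    :class:`TooShortError` for records shorter than ~3 cutoff periods.
    """
    config = config or FilterConfig()
    fs = record.sampling_rate_hz
    min_samples = _min_samples(fs, config)
    if record.n_samples < min_samples:
        raise TooShortError(
            f"record of {record.n_samples} samples is shorter than the "
            f"{min_samples}-sample minimum (~3 cutoff periods)"
        )
    n = record.n_samples
    X = np.fft.rfft(record.signal, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    x = (freqs / config.cutoff_hz) ** (2 * config.order)
    gain = x / (1.0 + x)  # |H|^2: forward + backward pass
    filtered = np.fft.irfft(X * gain[None, :], n=n, axis=-1)
    return record.copy_with(signal=filtered)


def highpass_gain(freq_hz: float, config: FilterConfig | None = None) -> float:
    """Analytic amplitude gain of the forward-backward filter at ``freq_hz``.

    The squared Butterworth magnitude response:
    ``(f/fc)^(2n) / (1 + (f/fc)^(2n))`` for a high-pass of order ``n``.
    """
    config = config or FilterConfig()
    x = (freq_hz / config.cutoff_hz) ** (2 * config.order)
    return x / (1.0 + x)


# ---------------------------------------------------------------------------
# cohort spectral reference and narrowband suppression
# ---------------------------------------------------------------------------

@dataclass
class SpectralReference:
    """Per-lead, per-bin amplitude mean/SD over a (post-high-pass) cohort."""

    freqs: np.ndarray
    mean: np.ndarray  # (n_leads, n_bins)
    sd: np.ndarray    # (n_leads, n_bins)
    k_sd: float
    n_records: int
    sampling_rate_hz: float
    n_samples: int

    def threshold(self) -> np.ndarray:
        """Detection threshold mean + k_sd * SD plus a tiny absolute floor.

        The floor (1e-7 x each lead's maximum mean amplitude) keeps bins
        whose cohort amplitude is numerically zero — e.g. between exact
        harmonics of a noiseless comb spectrum — from being flagged on
        machine-epsilon fluctuations.  It is orders of magnitude below any
        physically meaningful spectral amplitude.
        """
        floor = 1e-7 * self.mean.max(axis=1, keepdims=True)
        return np.maximum(self.mean + self.k_sd * self.sd, floor)


def resample_record(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Polyphase-resample a record to ``target_fs``."""
    if record.sampling_rate_hz == target_fs:
        return record
    frac = Fraction(target_fs / record.sampling_rate_hz).limit_denominator(1000)
    resampled = sps.resample_poly(record.signal, frac.numerator, frac.denominator, axis=-1)
    return record.copy_with(signal=resampled, sampling_rate_hz=target_fs)


def _gated_highpass(record: ECGRecord, config: FilterConfig) -> tuple[ECGRecord, SpectralProfile, bool]:
    profile = band_energies(record)
    if needs_highpass(profile, config):
        return apply_zero_phase_highpass(record, config), profile, True
    return record, profile, False


def build_spectral_reference(
    cohort: Sequence[ECGRecord],
    k_sd: float = 2.0,
    config: FilterConfig | None = None,
) -> SpectralReference:
    """Mean/SD amplitude spectra of a reference cohort, post high-pass stage.

    Requires >= 10 records; records at other sampling rates are polyphase-
    resampled to the first record's rate before spectral comparison.
    """
    if len(cohort) < 10:
        raise InsufficientCohortError(
            f"need >= 10 records to build a spectral reference, got {len(cohort)}"
        )
    config = config or FilterConfig()
    fs = cohort[0].sampling_rate_hz
    n = cohort[0].n_samples
    spectra = []
    freqs = None
    for record in cohort:
        record = resample_record(record, fs)
        if record.n_samples != n:
            raise ReferenceMismatchError(
                "cohort records have different lengths after resampling"
            )
        record, _, _ = _gated_highpass(record, config)
        f, amplitude, _, _ = _amplitude_spectrum(record.signal, fs)
        freqs = f
        spectra.append(amplitude)
    stack = np.stack(spectra)  # (n_records, n_leads, n_bins)
    return SpectralReference(
        freqs=freqs,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        k_sd=k_sd,
        n_records=len(cohort),
        sampling_rate_hz=fs,
        n_samples=n,
    )


class Band(NamedTuple):
    """A flagged narrowband exceedance on one lead."""

    lead: int
    f_lo: float
    f_hi: float


def detect_narrowband(
    record: ECGRecord,
    reference: SpectralReference,
    max_bandwidth_hz: float = 2.0,
) -> list[Band]:
    """Flag maximal runs of bins exceeding the cohort mean + k_sd * SD.

    Runs wider than ``max_bandwidth_hz`` are discarded: broadband exceedance
    (e.g. a record in the wrong units) is not mains interference.  Returned
    sorted by lead, then frequency.
    """
    if record.sampling_rate_hz != reference.sampling_rate_hz:
        record = resample_record(record, reference.sampling_rate_hz)
    if record.n_samples != reference.n_samples:
        raise ReferenceMismatchError(
            f"record length {record.n_samples} does not match reference "
            f"length {reference.n_samples} after resampling"
        )
    freqs, amplitude, _, _ = _amplitude_spectrum(record.signal, record.sampling_rate_hz)
    if not np.allclose(freqs, reference.freqs):
        raise ReferenceMismatchError("frequency grids do not align")
    df = freqs[1] - freqs[0]
    exceed = amplitude > reference.threshold()
    bands: list[Band] = []
    for lead in range(amplitude.shape[0]):
        mask = exceed[lead]
        if not mask.any():
            continue
        # maximal contiguous runs of True
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            width = (stop - start) * df
            if width <= max_bandwidth_hz:
                bands.append(Band(lead, float(freqs[start]), float(freqs[stop - 1])))
    bands.sort(key=lambda band: (band.lead, band.f_lo))
    return bands


def suppress_narrowband(
    record: ECGRecord,
    bands: Iterable[Band],
    loess_span: float = 0.1,
) -> ECGRecord:
    """Flatten flagged bins onto a LOESS baseline of the log-amplitude spectrum.

    Per lead, a degree-1 LOESS curve (span = ``loess_span`` of the frequency
    axis) is fitted to the log amplitude spectrum *excluding* flagged bins;
    flagged-bin amplitudes are replaced by the LOESS prediction with phases
    preserved.  Unflagged bins are untouched, so diagnostic-band energy
    outside the flagged bands is conserved exactly.
    """
    bands = list(bands)
    if not bands:
        return record.copy_with()
    fs = record.sampling_rate_hz
    n = record.n_samples
    freqs, amplitude, _, X = _amplitude_spectrum(record.signal, fs)
    n_bins = freqs.size
    flagged = {lead: np.zeros(n_bins, dtype=bool) for lead in set(b.lead for b in bands)}
    for band in bands:
        lo = np.searchsorted(freqs, band.f_lo - 1e-12)
        hi = np.searchsorted(freqs, band.f_hi + 1e-12)
        flagged[band.lead][lo:hi] = True
    X = X.copy()
    tiny = np.finfo(float).tiny
    for lead, mask in flagged.items():
        if mask.mean() > 0.5:
            raise DegenerateFitError(
                f"lead {lead}: flagged bins cover more than half of the spectrum"
            )
        log_amp = np.log(amplitude[lead] + tiny)
        span = freqs[-1] - freqs[0]
        fitted = lowess(
            log_amp[~mask],
            freqs[~mask],
            frac=loess_span,
            it=0,
            delta=0.002 * span,
            is_sorted=True,
        )
        # evaluate the baseline at the flagged bins by interpolating the fit
        pred = np.interp(freqs[mask], fitted[:, 0], fitted[:, 1])
        new_amp = np.exp(pred)
        old_amp = amplitude[lead][mask]
        gain = np.where(old_amp > 0, new_amp / np.where(old_amp > 0, old_amp, 1.0), 0.0)
        X[lead, mask] *= gain
        # a zero-amplitude flagged bin gets the baseline with zero phase
        zero_bins = np.flatnonzero(mask)[old_amp == 0]
        if zero_bins.size:
            scale = n / np.where(zero_bins == 0, 1.0, 2.0)
            X[lead, zero_bins] = new_amp[old_amp == 0] * scale
    cleaned = np.fft.irfft(X, n=n, axis=-1)
    return record.copy_with(signal=cleaned)


# ---------------------------------------------------------------------------
# amplitude scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaleReference:
    """Target robust millivolt amplitude statistic of the reference cohort."""

    target_mv: float
    mode: str = "per_dataset"

    def __post_init__(self) -> None:
        if self.target_mv <= 0:
            raise ParameterError("target_mv must be positive")
        if self.mode not in ("per_dataset", "per_record"):
            raise ParameterError("mode must be 'per_dataset' or 'per_record'")


def robust_peak_to_peak(record: ECGRecord) -> np.ndarray:
    """Per-lead robust peak-to-peak: 99th minus 1st percentile of samples."""
    q01, q99 = np.percentile(record.signal, [1, 99], axis=1)
    return q99 - q01


def record_amplitude_stat(record: ECGRecord) -> float:
    """Median over leads of the robust peak-to-peak amplitude (mV)."""
    return float(np.median(robust_peak_to_peak(record)))


def build_scale_reference(
    cohort: Sequence[ECGRecord], mode: str = "per_dataset"
) -> ScaleReference:
    """Target statistic T: cohort median of per-record robust amplitudes."""
    if not cohort:
        raise InsufficientCohortError("empty cohort")
    stats = [record_amplitude_stat(r) for r in cohort]
    return ScaleReference(target_mv=float(np.median(stats)), mode=mode)


def estimate_scale_factor(
    cohort: Sequence[ECGRecord],
    reference: ScaleReference,
    mode: str | None = None,
) -> float | np.ndarray:
    """Scale factor(s) mapping the cohort onto the reference amplitude target.

    ``per_dataset``: one factor ``T / median(record stats)`` for the whole
    cohort (preserves between-record voltage ratios exactly).
    ``per_record``: one factor per record, same formula without the outer
    median.
    """
    if not cohort:
        raise InsufficientCohortError("empty cohort")
    mode = mode or reference.mode
    stats = np.array([record_amplitude_stat(r) for r in cohort])
    if np.any(stats <= 0):
        flat = [cohort[i].record_id for i in np.flatnonzero(stats <= 0)]
        raise DegenerateRecordError(f"flat record(s) with zero robust amplitude: {flat}")
    if mode == "per_dataset":
        return float(reference.target_mv / np.median(stats))
    if mode == "per_record":
        return reference.target_mv / stats
    raise ParameterError("mode must be 'per_dataset' or 'per_record'")


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RecordReport:
    """Per-record log of every pipeline decision and factor."""

    record_id: str
    max_ratio: float
    highpass_applied: bool
    bands: list[Band] = field(default_factory=list)
    scale_factor: float = 1.0
    e_low_before: float = 0.0
    e_diag_before: float = 0.0
    e_low_after: float = 0.0
    e_diag_after: float = 0.0


@dataclass
class HarmonizeReport:
    """One row per input record."""

    rows: list[RecordReport]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.rows],
                "max_ratio": [r.max_ratio for r in self.rows],
                "highpass_applied": [r.highpass_applied for r in self.rows],
                "n_bands": [len(r.bands) for r in self.rows],
                "bands": [
                    ";".join(f"{b.lead}:{b.f_lo:g}-{b.f_hi:g}" for b in r.bands)
                    for r in self.rows
                ],
                "scale_factor": [r.scale_factor for r in self.rows],
                "e_low_before": [r.e_low_before for r in self.rows],
                "e_diag_before": [r.e_diag_before for r in self.rows],
                "e_low_after": [r.e_low_after for r in self.rows],
                "e_diag_after": [r.e_diag_after for r in self.rows],
            }
        )


def harmonize_record(
    record: ECGRecord,
    spectral_reference: SpectralReference,
    scale_reference: ScaleReference,
    filter_config: FilterConfig | None = None,
    max_bandwidth_hz: float = 2.0,
    loess_span: float = 0.1,
    scale_factor: float | None = None,
) -> tuple[ECGRecord, RecordReport]:
    """Run the three-stage pipeline on one record.

    Stages run in order: (1) gate + zero-phase high-pass, (2) narrowband
    detection + LOESS suppression, (3) amplitude scaling.  When
    ``scale_factor`` is None it is computed per record; cohort-level
    (per-dataset) scaling should pass the shared factor from
    :func:`estimate_scale_factor` (see :func:`harmonize_cohort`).
    """
    filter_config = filter_config or FilterConfig()
    record = resample_record(record, spectral_reference.sampling_rate_hz)
    cleaned, profile, applied = _gated_highpass(record, filter_config)
    bands = detect_narrowband(cleaned, spectral_reference, max_bandwidth_hz)
    if bands:
        cleaned = suppress_narrowband(cleaned, bands, loess_span)
    if scale_factor is None:
        scale_factor = float(
            estimate_scale_factor([cleaned], scale_reference, mode="per_record")[0]
        ) if scale_reference.mode == "per_record" else float(
            estimate_scale_factor([cleaned], scale_reference, mode="per_dataset")
        )
    cleaned = cleaned.copy_with(signal=cleaned.signal * scale_factor, units="mV")
    after = band_energies(cleaned)
    report = RecordReport(
        record_id=record.record_id,
        max_ratio=profile.max_ratio,
        highpass_applied=applied,
        bands=bands,
        scale_factor=scale_factor,
        e_low_before=float(profile.e_low.sum()),
        e_diag_before=float(profile.e_diag.sum()),
        e_low_after=float(after.e_low.sum()),
        e_diag_after=float(after.e_diag.sum()),
    )
    return cleaned, report


def harmonize_cohort(
    records: Sequence[ECGRecord],
    spectral_reference: SpectralReference,
    scale_reference: ScaleReference,
    filter_config: FilterConfig | None = None,
    max_bandwidth_hz: float = 2.0,
    loess_span: float = 0.1,
) -> tuple[list[ECGRecord], HarmonizeReport]:
    """Harmonize a cohort; per-dataset scaling computes one shared factor
    from the records *after* filtering and suppression, then applies it."""
    filter_config = filter_config or FilterConfig()
    if scale_reference.mode == "per_record":
        out = [
            harmonize_record(
                r, spectral_reference, scale_reference, filter_config,
                max_bandwidth_hz, loess_span,
            )
            for r in records
        ]
        return [r for r, _ in out], HarmonizeReport([rep for _, rep in out])

    staged: list[tuple[ECGRecord, RecordReport]] = []
    for record in records:
        record = resample_record(record, spectral_reference.sampling_rate_hz)
        cleaned, profile, applied = _gated_highpass(record, filter_config)
        bands = detect_narrowband(cleaned, spectral_reference, max_bandwidth_hz)
        if bands:
            cleaned = suppress_narrowband(cleaned, bands, loess_span)
        staged.append(
            (
                cleaned,
                RecordReport(
                    record_id=record.record_id,
                    max_ratio=profile.max_ratio,
                    highpass_applied=applied,
                    bands=bands,
                    e_low_before=float(profile.e_low.sum()),
                    e_diag_before=float(profile.e_diag.sum()),
                ),
            )
        )
    factor = estimate_scale_factor(
        [c for c, _ in staged], scale_reference, mode="per_dataset"
    )
    out_records: list[ECGRecord] = []
    rows: list[RecordReport] = []
    for cleaned, report in staged:
        scaled = cleaned.copy_with(signal=cleaned.signal * factor, units="mV")
        after = band_energies(scaled)
        report.scale_factor = float(factor)
        report.e_low_after = float(after.e_low.sum())
        report.e_diag_after = float(after.e_diag.sum())
        out_records.append(scaled)
        rows.append(report)
    return out_records, HarmonizeReport(rows)
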