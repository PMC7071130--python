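"""Signal conditioning and beat segmentation for 12-lead ECG records.

Pipeline order: per-lead min-max standardization to [-1, 1], Daubechies-6
wavelet denoising with baseline-drift removal (coarsest approximation band
zeroed, detail bands soft-thresholded), Pan-Tompkins QRS detection on a
single detection lead, and extraction of 651-sample beat windows
(250 samples before each R peak, 400 after) with the first and last beats
of every record discarded.  The whole module is deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pywt
from scipy import signal as sps

from .io import BEAT_LENGTH, BeatDataset, BeatSample, EcgRecord



@dataclasses.dataclass
class PreprocessConfig:
    wavelet_name: str = "db6"
    decomposition_level: int = 9
    pre_samples: int = 250
    post_samples: int = 400
    detection_lead: str = "II"
    threshold_rule: str = "soft"

    def __post_init__(self):
        if self.pre_samples + self.post_samples + 1 != BEAT_LENGTH:
            raise ValueError(
                f"pre+post+1 must equal the beat length {BEAT_LENGTH}")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError("threshold_rule must be 'soft' or 'hard'")


@dataclasses.dataclass
class QrsAnnotations:
    peak_indices: np.ndarray
    detection_lead: str = "II"

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.peak_indices.size > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")


def _replace(record: EcgRecord, signals: np.ndarray) -> EcgRecord:
    return EcgRecord(signals, fs=record.fs, lead_names=record.lead_names,
                     patient_id=record.patient_id, record_id=record.record_id,
                     label=record.label)


def standardize(record: EcgRecord) -> EcgRecord:
    """Per-lead affine min-max map onto [-1, 1]; constant leads map to zero."""
    out = np.empty_like(record.signals)
    for i in range(record.signals.shape[0]):
        lead = record.signals[i]
        lo, hi = lead.min(), lead.max()
        if hi == lo:
            warnings.warn(
                f"lead {record.lead_names[i]} is constant; standardized to 0",
                stacklevel=2)
            out[i] = 0.0
        else:
            out[i] = 2.0 * (lead - lo) / (hi - lo) - 1.0
    return _replace(record, out)


def denoise_and_detrend(record: EcgRecord, cfg: PreprocessConfig | None = None,
                        clip: bool = True) -> EcgRecord:
    """DB6 multilevel wavelet denoising plus baseline-drift removal.

    The approximation coefficients at the coarsest level are zeroed (this
    removes sub-hertz baseline wander at the default level 9 / 1000 Hz) and
    the detail coefficients are thresholded with the universal rule
    sigma * sqrt(2 ln N), sigma estimated from the finest detail band via
    MAD / 0.6745.  With ``clip`` the output is re-clipped to [-1, 1] so the
    standardized range survives reconstruction overshoot.
    """
    cfg = cfg or PreprocessConfig()
    n = record.n_samples
    if n < 2 ** cfg.decomposition_level:
        raise ValueError(
            f"record length {n} < 2^{cfg.decomposition_level}; "
            "use a lower decomposition_level")
    # clamp to the deepest level that is free of boundary artifacts
    level = min(cfg.decomposition_level,
                pywt.dwt_max_level(n, pywt.Wavelet(cfg.wavelet_name).dec_len))
    level = max(level, 1)
    out = np.empty_like(record.signals)
    for i in range(record.signals.shape[0]):
        x = record.signals[i]
        coeffs = pywt.wavedec(x, cfg.wavelet_name, level=level)
        coeffs[0] = np.zeros_like(coeffs[0])  # baseline band
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
        if thr > 0:
            coeffs[1:] = [pywt.threshold(c, thr, mode=cfg.threshold_rule)
                          for c in coeffs[1:]]
        rec = pywt.waverec(coeffs, cfg.wavelet_name)[:n]
        out[i] = np.clip(rec, -1.0, 1.0) if clip else rec
    return _replace(record, out)


# -- Pan-Tompkins QRS detection ----------------------------------------------

def _moving_window_integration(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_qrs(record: EcgRecord, cfg: PreprocessConfig | None = None) -> QrsAnnotations:
    """Pan-Tompkins R-peak detection on the configured detection lead.

    Stages: 5-15 Hz band-pass (zero-phase), derivative, squaring, 150 ms
    moving-window integration, adaptive dual thresholds with search-back and
    a 200 ms refractory period.  Detected fiducials are refined to the local
    extremum of the raw detection lead within +/-40 ms.
    """
    cfg = cfg or PreprocessConfig()
    fs = record.fs
    x = record.lead(cfg.detection_lead)
    if not np.any(x):
        return QrsAnnotations(np.array([], dtype=int), cfg.detection_lead)

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    deriv = np.gradient(filtered)
    squared = deriv ** 2
    mwi = _moving_window_integration(squared, max(int(round(0.150 * fs)), 1))

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    if cand.size == 0:
        return QrsAnnotations(np.array([], dtype=int), cfg.detection_lead)

    spki = float(np.max(mwi[:int(2 * fs)])) * 0.5 if mwi.size else 0.0
    npki = float(np.mean(mwi[:int(2 * fs)])) * 0.5
    peaks: list[int] = []
    rr_hist: list[float] = []
    last_accept = -10 * refractory
    i = 0
    while i < cand.size:
        p = int(cand[i])
        level = mwi[p]
        thr1 = npki + 0.25 * (spki - npki)
        if level > thr1 and p - last_accept > refractory:
            peaks.append(p)
            spki = 0.125 * level + 0.875 * spki
            if len(peaks) > 1:
                rr_hist.append(peaks[-1] - peaks[-2])
        else:
            npki = 0.125 * level + 0.875 * npki
            # search-back: if expected beat was missed, accept the best
            # candidate above the lower threshold
            if rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                if peaks and p - peaks[-1] > 1.66 * rr_avg and level > 0.5 * thr1 \
                        and p - last_accept > refractory:
                    peaks.append(p)
                    spki = 0.25 * level + 0.75 * spki
                    rr_hist.append(peaks[-1] - peaks[-2])
        if peaks:
            last_accept = peaks[-1]
        i += 1

    # refine to the raw-lead local extremum within +/-40 ms; clipped signals
    # can plateau at the extremum, so take the plateau's center sample
    half = int(round(0.040 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        mag = np.abs(x[lo:hi])
        top = np.flatnonzero(mag >= mag.max() - 1e-9)
        refined.append(lo + int(top[(len(top) - 1) // 2]))
    refined = sorted(set(refined))
    # enforce refractory after refinement
    final: list[int] = []
    for p in refined:
        if not final or p - final[-1] > refractory:
            final.append(p)
    return QrsAnnotations(np.array(final, dtype=int), cfg.detection_lead)


def segment_beats(record: EcgRecord, ann: QrsAnnotations,
                  cfg: PreprocessConfig | None = None) -> list[BeatSample]:
    """Cut 12 x 651 windows [p-250, p+400] around each R peak.

    Peaks whose window exits the record are skipped; afterwards the first
    and last surviving beats are dropped.  Fewer than three eligible peaks
    yield an empty list.
    """
    cfg = cfg or PreprocessConfig()
    n = record.n_samples
    eligible = [int(p) for p in ann.peak_indices
                if p - cfg.pre_samples >= 0 and p + cfg.post_samples < n]
    if len(eligible) < 3:
        return []
    beats = []
    for p in eligible[1:-1]:
        window = record.signals[:, p - cfg.pre_samples:p + cfg.post_samples + 1]
        beats.append(BeatSample(window.copy(), record.label, record.patient_id))
    return beats


def preprocess_record(record: EcgRecord,
                      cfg: PreprocessConfig | None = None) -> list[BeatSample]:
    """standardize -> denoise/detrend -> detect QRS -> segment, one record."""
    cfg = cfg or PreprocessConfig()
    rec = standardize(record)
    rec = denoise_and_detrend(rec, cfg)
    ann = detect_qrs(rec, cfg)
    return segment_beats(rec, ann, cfg)


def preprocess_records(records, cfg: PreprocessConfig | None = None,
                       class_names=None) -> BeatDataset:
    """Run the full pipeline over records and pool the beats."""
    cfg = cfg or PreprocessConfig()
    beats = []
    for rec in records:
        beats.extend(preprocess_record(rec, cfg))
    if class_names is None:
        class_names = tuple(sorted({b.label for b in beats}))
    return BeatDataset(beats, class_names)
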