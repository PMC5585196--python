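"""Nuisance regression, band-pass filtering, and the denoising QC statistic.

Stage order is fixed: confound regression first, then band-pass filtering of
the residuals.  The filter is a linear detrend followed by a brick-wall
discrete-Fourier filter — deterministic and exactly testable against an FFT
oracle; a Butterworth variant is available behind ``method="butterworth"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import CollinearityError, InvalidBandError, InvalidInputError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("regress_confounds", "bandpass")


@dataclass(frozen=True)
class FilterBand:
    """Pass band in Hz; defaults span the conventional resting-state band."""

    low_hz: float = 0.001
    high_hz: float = 0.1

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 <= self.low_hz < self.high_hz):
            raise InvalidBandError(
                f"need 0 <= low < high, got [{self.low_hz}, {self.high_hz}]"
            )
        if self.high_hz > nyquist + 1e-12:
            raise InvalidBandError(
                f"high_hz={self.high_hz} exceeds Nyquist {nyquist:.4g} Hz at "
                f"TR={tr_seconds}s"
            )


@dataclass
class QcSummary:
    """Cohort-average mean/SD of off-diagonal ROI-pair correlations."""

    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float

    def as_dict(self) -> dict:
        return {
            "mean_before": self.mean_before,
            "sd_before": self.sd_before,
            "mean_after": self.mean_after,
            "sd_after": self.sd_after,
        }


def _as_array(table) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    return np.asarray(table, dtype=float), None


def regress_confounds(roi_series, confound_table):
    """OLS-residualize every ROI series against [intercept | confounds].

    Residuals have zero mean and zero sample covariance with every confound
    column (to numerical precision).  Raises :class:`CollinearityError` when
    the design (including the implicit intercept) is rank deficient.
    """
    y, roi_cols = _as_array(roi_series)
    c, conf_cols = _as_array(confound_table)
    if y.ndim == 1:
        y = y[:, None]
    if c.ndim == 1:
        c = c[:, None]
    if y.shape[0] != c.shape[0]:
        raise InvalidInputError(
            f"time-point mismatch: series has {y.shape[0]}, confounds {c.shape[0]}"
        )
    n_t = y.shape[0]
    zero_cols = np.flatnonzero(~np.any(c != 0, axis=0))
    if zero_cols.size:
        # identically-zero channels carry no signal; regression degrades
        # gracefully to the remaining columns (intercept-only at the limit)
        logger.info("dropping %d identically-zero confound column(s)", zero_cols.size)
        keep_cols = np.setdiff1d(np.arange(c.shape[1]), zero_cols)
        c = c[:, keep_cols]
        if conf_cols is not None:
            conf_cols = [conf_cols[k] for k in keep_cols]
    design = np.column_stack([np.ones(n_t), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via incremental rank growth
        bad = []
        kept = design[:, :1]
        names = conf_cols or [f"confound_{k}" for k in range(c.shape[1])]
        for k in range(c.shape[1]):
            trial = np.column_stack([kept, c[:, k]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(names[k])
            else:
                kept = trial
        raise CollinearityError(bad)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if roi_cols is not None:
        return pd.DataFrame(resid, columns=roi_cols)
    return resid


def bandpass(roi_series, tr_seconds: float, band: FilterBand | None = None,
             method: str = "brickwall", order: int = 4, detrend: bool = True):
    """Linear detrend, then retain Fourier bins with low_hz <= f <= high_hz.

    Bin frequencies are k/(N*TR).  When ``low_hz`` falls below the first
    nonzero bin (the usual case for short runs), the low cut removes only
    the DC bin; this is logged, not an error.  ``detrend=False`` skips the
    linear detrend, leaving the pure spectral projection (a slow linear
    drift is not in the span of any retained bin, so the detrend and the
    brick-wall mask interact; the pure projection is the exactly
    idempotent core).
    """
    band = band or FilterBand()
    band.validate(tr_seconds)
    y, roi_cols = _as_array(roi_series)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n_t = y.shape[0]
    if n_t < 8:
        raise InvalidInputError("need at least 8 time points to filter")
    detrended = sp_signal.detrend(y, axis=0, type="linear") if detrend else y
    if method == "butterworth":
        nyq = 1.0 / (2.0 * tr_seconds)
        low = max(band.low_hz, 1e-12) / nyq
        high = min(band.high_hz / nyq, 1 - 1e-9)
        sos = sp_signal.butter(order, [low, high], btype="bandpass", output="sos")
        out = sp_signal.sosfiltfilt(sos, detrended, axis=0)
    elif method == "brickwall":
        freqs = np.fft.rfftfreq(n_t, d=tr_seconds)
        first_nonzero = freqs[1] if len(freqs) > 1 else np.inf
        if band.low_hz < first_nonzero:
            logger.info(
                "low cut %.4g Hz below first nonzero bin %.4g Hz: only the DC "
                "bin is removed",
                band.low_hz,
                first_nonzero,
            )
        keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
        keep[0] = False  # DC never survives (low_hz may be 0)
        spec = np.fft.rfft(detrended, axis=0)
        spec[~keep] = 0.0
        out = np.fft.irfft(spec, n=n_t, axis=0)
    else:
        raise InvalidInputError(f"unknown filter method {method!r}")
    if squeeze:
        out = out[:, 0]
    if roi_cols is not None:
        return pd.DataFrame(out, columns=roi_cols)
    return out


def denoise_subject(roi_series, confound_table, tr_seconds: float,
                    band: FilterBand | None = None, method: str = "brickwall"):
    """Full per-subject denoising: regression, then band-pass.

    Returns (clean_series, provenance) where provenance records the stage
    order actually applied.
    """
    resid = regress_confounds(roi_series, confound_table)
    clean = bandpass(resid, tr_seconds, band, method=method)
    band = band or FilterBand()
    provenance = {
        "stage_order": list(STAGE_ORDER),
        "band_hz": [band.low_hz, band.high_hz],
        "filter_method": method,
        "detrend": "linear",
    }
    return clean, provenance


def _offdiag_correlations(series) -> np.ndarray:
    y, _ = _as_array(series)
    if y.shape[0] < 3:
        raise InvalidInputError("need at least 3 time points for correlations")
    r = np.corrcoef(y.T)
    iu = np.triu_indices(r.shape[0], k=1)
    return r[iu]


def qc_correlation_shift(cohort_before, cohort_after) -> QcSummary:
    """Shift of the off-diagonal correlation distribution across denoising.

    Per subject: mean and SD of all off-diagonal pairwise Pearson
    correlations; the four summary numbers are the cohort averages before
    and after.  ``cohort_before``/``cohort_after`` are equal-length
    sequences of (time x ROI) tables for the same subjects.
    """
    before = list(cohort_before)
    after = list(cohort_after)
    if len(before) != len(after) or not before:
        raise InvalidInputError("cohorts must be nonempty and the same length")
    means_b, sds_b, means_a, sds_a = [], [], [], []
    for ts_b, ts_a in zip(before, after):
        rb = _offdiag_correlations(ts_b)
        ra = _offdiag_correlations(ts_a)
        means_b.append(rb.mean())
        sds_b.append(rb.std(ddof=0))
        means_a.append(ra.mean())
        sds_a.append(ra.std(ddof=0))
    return QcSummary(
        mean_before=float(np.mean(means_b)),
        sd_before=float(np.mean(sds_b)),
        mean_after=float(np.mean(means_a)),
        sd_after=float(np.mean(sds_a)),
    )
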