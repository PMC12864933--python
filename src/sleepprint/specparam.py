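"""Periodic / aperiodic decomposition of averaged sleep-EEG periodograms.

The model of a log10 power spectrum is an aperiodic backbone plus Gaussian
oscillatory peaks:

    log10 P(f) = b - log10(k + f**chi) + sum_i  h_i * exp(-(f - c_i)^2 / (2 s_i^2))

with offset ``b`` (log10 power), knee ``k`` (>= 0; ``k = 0`` is the pure
power-law "fixed" mode) and exponent ``chi`` (> 0).  Fitting proceeds as:

1. interpolate out mains line noise (log-linear across the notch band);
2. robust aperiodic fit: an initial nonlinear least squares, then a refit
   restricted to points not sitting above the first fit (peak regions are
   masked by a low residual-percentile threshold);
3. iterative peak extraction on the flattened spectrum: take the global
   maximum, stop when it falls below the absolute height floor or a
   relative threshold in residual-SD units, fit-and-subtract a Gaussian,
   repeat up to the peak cap;
4. joint multi-Gaussian refit of all collected peaks;
5. subtract the peak model from the original spectrum and refit the
   aperiodic component, yielding the final parameters;
6. goodness of fit R^2 between the original spectrum and the full model;
   fits under the quality gate are flagged excluded, not discarded.

``fit_joint_model`` is an independent cross-check: it fits backbone and all
peaks *simultaneously* by bounded least squares with BIC-based selection of
the peak count, sharing no code path with the iterative pipeline above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .preprocess import ArtifactMask
from .recording import EpochedRecording
from .spectra import welch_psd


# ----------------------------------------------------------------------
# types
# ----------------------------------------------------------------------
@dataclass
class Periodogram:
    """A log10 power spectrum on a strictly increasing frequency grid."""

    freqs: np.ndarray
    log_power: np.ndarray
    subject: str = ""
    night: int = 0
    stage: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.log_power = np.asarray(self.log_power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.log_power)):
            raise ValueError("log power must be finite")


@dataclass
class AperiodicParams:
    offset: float
    knee: float
    exponent: float
    mode: str = "knee"  # "knee" or "fixed" (knee pinned at 0)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - np.log10(self.knee + np.asarray(freqs) ** self.exponent)


@dataclass
class PeakParams:
    """One oscillatory peak; ``bandwidth`` is 2 x the Gaussian SD, in Hz."""

    center: float
    height: float  # log10 power above the aperiodic backbone
    bandwidth: float

    @property
    def sd(self) -> float:
        return self.bandwidth / 2.0

    def model(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs)
        return self.height * np.exp(-((f - self.center) ** 2) / (2 * self.sd**2))


@dataclass
class SpectralFit:
    aperiodic: AperiodicParams
    peaks: list[PeakParams]
    r_squared: float
    excluded: bool
    freqs: np.ndarray
    flattened: np.ndarray  # original - final aperiodic model
    residual: np.ndarray  # original - full model

    def full_model(self) -> np.ndarray:
        out = self.aperiodic.model(self.freqs)
        for p in self.peaks:
            out = out + p.model(self.freqs)
        return out


@dataclass(frozen=True)
class SpecparamSettings:
    """Tunable decomposition settings.

    ``peak_width_bounds`` bound the peak ``bandwidth`` (2 x Gaussian SD) in
    Hz; ``rel_threshold_sd`` is the detection threshold in units of the SD
    of the current flattened residual; ``r2_min`` is the exclusion gate.
    """

    mode: str = "knee"
    fit_range: tuple[float, float] = (0.5, 100.0)
    report_range: tuple[float, float] = (0.5, 45.0)
    max_peaks: int = 6
    peak_height_min: float = 0.10
    peak_width_bounds: tuple[float, float] = (0.5, 15.0)
    rel_threshold_sd: float = 2.0
    r2_min: float = 0.99
    line_noise_hz: float = 50.0
    line_half_width: float = 2.0
    ap_percentile: float = 2.5  # robust-refit residual percentile


class FitError(RuntimeError):
    """Nonlinear aperiodic fit failed to converge."""


# ----------------------------------------------------------------------
# line-noise interpolation
# ----------------------------------------------------------------------
def interpolate_line_noise(periodogram: Periodogram, center: float = 50.0,
                           half_width: float = 2.0) -> Periodogram:
    """Replace the mains band by log-linear interpolation between its edges."""
    f, p = periodogram.freqs, periodogram.log_power.copy()
    if not (f[0] <= center <= f[-1]):
        raise ValueError("line-noise center outside the frequency grid")
    inside = (f >= center - half_width) & (f <= center + half_width)
    lo_edge = np.flatnonzero(f < center - half_width)
    hi_edge = np.flatnonzero(f > center + half_width)
    if len(lo_edge) == 0 or len(hi_edge) == 0:
        raise ValueError(
            "interpolation band touches the grid boundary; cannot take a "
            "one-sided extension"
        )
    i0, i1 = lo_edge[-1], hi_edge[0]
    p[inside] = np.interp(f[inside], [f[i0], f[i1]], [p[i0], p[i1]])
    return Periodogram(f, p, periodogram.subject, periodogram.night,
                       periodogram.stage)


# ----------------------------------------------------------------------
# aperiodic fit
# ----------------------------------------------------------------------
def _ap_model_knee(f, b, k, chi):
    return b - np.log10(k + f**chi)


def _ap_model_fixed(f, b, chi):
    return b - chi * np.log10(f)


def _initial_guess(f: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    chi0 = (p[0] - p[-1]) / (np.log10(f[-1]) - np.log10(f[0]))
    chi0 = float(np.clip(chi0, 0.05, 8.0))
    b0 = float(p[0] + chi0 * np.log10(f[0]))
    return b0, 1.0, chi0


def _fit_once(f: np.ndarray, p: np.ndarray, mode: str,
              p0: tuple | None = None) -> AperiodicParams:
    if mode == "knee":
        if p0 is None:
            p0 = _initial_guess(f, p)
        bounds = ([-np.inf, 0.0, 1e-3], [np.inf, np.inf, 10.0])
        try:
            popt, _ = optimize.curve_fit(
                _ap_model_knee, f, p, p0=p0, bounds=bounds, maxfev=10000
            )
        except RuntimeError as err:
            resid = np.linalg.norm(p - _ap_model_knee(f, *p0))
            raise FitError(
                f"aperiodic fit did not converge (residual norm {resid:.3g})"
            ) from err
        return AperiodicParams(popt[0], popt[1], popt[2], "knee")
    b0, _, chi0 = _initial_guess(f, p) if p0 is None else p0
    bounds = ([-np.inf, 1e-3], [np.inf, 10.0])
    try:
        popt, _ = optimize.curve_fit(
            _ap_model_fixed, f, p, p0=(b0, chi0), bounds=bounds, maxfev=10000
        )
    except RuntimeError as err:
        raise FitError("aperiodic fit did not converge") from err
    return AperiodicParams(popt[0], 0.0, popt[1], "fixed")


def fit_aperiodic(periodogram: Periodogram, mode: str = "knee",
                  fit_range: tuple[float, float] = (0.5, 100.0),
                  robust: bool = True, ap_percentile: float = 2.5
                  ) -> AperiodicParams:
    """Nonlinear least-squares fit of the aperiodic backbone.

    With ``robust=True`` a second pass excludes points rising above the
    initial fit (flattened values above a low percentile threshold, i.e.
    peak regions) and refits on the remainder.
    """
    f, p = periodogram.freqs, periodogram.log_power
    sel = (f >= fit_range[0]) & (f <= fit_range[1])
    if sel.sum() < 10:
        raise ValueError("need at least 10 grid points in the fit range")
    f, p = f[sel], p[sel]
    params = _fit_once(f, p, mode)
    if not robust:
        return params
    flat = p - params.model(f)
    flat[flat < 0] = 0.0
    thresh = np.percentile(flat, ap_percentile)
    mask = flat <= thresh
    if mask.sum() >= 10:
        p0 = ((params.offset, params.knee, params.exponent)
              if mode == "knee" else (params.offset, 0.0, params.exponent))
        params = _fit_once(f[mask], p[mask], mode, p0=p0)
    return params


# ----------------------------------------------------------------------
# peak extraction
# ----------------------------------------------------------------------
def _gaussian_sum(f: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        c, h, s = params[i : i + 3]
        out = out + h * np.exp(-((f - c) ** 2) / (2 * s**2))
    return out


def _guess_sd(f: np.ndarray, resid: np.ndarray, imax: int,
              sd_bounds: tuple[float, float]) -> float:
    """Half-height width of the residual around its maximum, as a Gaussian SD."""
    h = resid[imax]
    half = h / 2.0
    left = imax
    while left > 0 and resid[left] > half:
        left -= 1
    right = imax
    while right < len(resid) - 1 and resid[right] > half:
        right += 1
    fwhm = f[right] - f[left]
    sd = fwhm / 2.355 if fwhm > 0 else sd_bounds[0]
    return float(np.clip(sd, sd_bounds[0], sd_bounds[1]))


def extract_peaks(
    freqs: np.ndarray, flattened: np.ndarray, max_peaks: int = 6,
    height_min: float = 0.10, width_bounds: tuple[float, float] = (0.5, 15.0),
    rel_threshold_sd: float = 2.0,
) -> list[PeakParams]:
    """Iterative fit-and-subtract Gaussian extraction, then a joint refit.

    Detection stops at ``max_peaks`` or when the tallest residual point
    drops below ``max(height_min, rel_threshold_sd * SD(residual))``.  After
    iteration all Gaussians are refit jointly (centers bounded to the grid,
    heights non-negative, SDs free); peaks whose fitted bandwidth leaves
    ``width_bounds``, whose fitted height falls below ``height_min``, or
    whose center sits within one SD of a grid edge (where backbone misfit
    masquerades as a peak) are dropped.  An empty list is a valid outcome.
    """
    f = np.asarray(freqs, dtype=float)
    resid = np.asarray(flattened, dtype=float).copy()
    sd_bounds = (width_bounds[0] / 2.0, width_bounds[1] / 2.0)
    guesses: list[tuple[float, float, float]] = []
    while len(guesses) < max_peaks:
        imax = int(np.argmax(resid))
        h = resid[imax]
        if h < max(height_min, rel_threshold_sd * resid.std()):
            break
        sd = _guess_sd(f, resid, imax, sd_bounds)
        cf = float(f[imax])
        resid = resid - h * np.exp(-((f - cf) ** 2) / (2 * sd**2))
        guesses.append((cf, h, sd))
    if not guesses:
        return []
    # joint multi-Gaussian refit on the original flattened spectrum
    p0, lo, hi = [], [], []
    for cf, h, sd in guesses:
        p0 += [cf, h, sd]
        lo += [max(f[0], cf - 2 * sd), 0.0, 1e-3]
        hi += [min(f[-1], cf + 2 * sd), np.inf, 2 * sd_bounds[1]]
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_sum, f, np.asarray(flattened, dtype=float), p0=p0,
            bounds=(lo, hi), maxfev=10000,
        )
    except RuntimeError:
        popt = np.asarray(p0)
    peaks = []
    for i in range(0, len(popt), 3):
        c, h, s = popt[i : i + 3]
        bw = 2.0 * s
        if not (width_bounds[0] <= bw <= width_bounds[1]):
            continue
        if h < height_min:
            continue
        if c - s < f[0] or c + s > f[-1]:  # edge-riding pseudo-peak
            continue
        peaks.append(PeakParams(float(c), float(h), float(bw)))
    peaks.sort(key=lambda pk: pk.center)
    return peaks


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------
def full_fit(periodogram: Periodogram,
             settings: SpecparamSettings | None = None) -> SpectralFit:
    """Line-noise interpolation -> aperiodic -> peaks -> final refit -> R^2."""
    s = settings if settings is not None else SpecparamSettings()
    pg = periodogram
    if (pg.freqs[0] < s.line_noise_hz - s.line_half_width
            and pg.freqs[-1] > s.line_noise_hz + s.line_half_width):
        pg = interpolate_line_noise(pg, s.line_noise_hz, s.line_half_width)
    sel = (pg.freqs >= s.fit_range[0]) & (pg.freqs <= s.fit_range[1])
    f, p = pg.freqs[sel], pg.log_power[sel]
    sub = Periodogram(f, p, pg.subject, pg.night, pg.stage)

    backbone = fit_aperiodic(sub, s.mode, s.fit_range, robust=True,
                             ap_percentile=s.ap_percentile)
    # repeated extraction cycles: the aperiodic refit after removing the
    # current peak set gives a cleaner backbone, against which peaks are
    # re-fit; stops when the exponent settles
    peaks: list[PeakParams] = []
    final = backbone
    prev_chi = np.inf
    for _ in range(4):
        if abs(backbone.exponent - prev_chi) < 1e-3:
            break
        prev_chi = backbone.exponent
        flat = p - backbone.model(f)
        peaks = extract_peaks(
            f, flat, max_peaks=s.max_peaks, height_min=s.peak_height_min,
            width_bounds=s.peak_width_bounds,
            rel_threshold_sd=s.rel_threshold_sd,
        )
        peak_model = np.zeros_like(f)
        for pk in peaks:
            peak_model += pk.model(f)
        # refit the backbone on the de-peaked spectrum, additionally masking
        # each peak's core so residual tail misfit cannot tilt the fit
        keep = np.ones_like(f, dtype=bool)
        for pk in peaks:
            keep &= np.abs(f - pk.center) > 2.0 * pk.sd
        if keep.sum() < max(10, len(f) // 4):
            keep = np.ones_like(f, dtype=bool)
        depeaked = Periodogram(f[keep], (p - peak_model)[keep], pg.subject,
                               pg.night, pg.stage)
        final = fit_aperiodic(depeaked, s.mode, s.fit_range, robust=False)
        backbone = final
    model = final.model(f) + peak_model
    r2 = float(np.corrcoef(p, model)[0, 1] ** 2) if np.std(model) > 0 else 0.0
    return SpectralFit(
        aperiodic=final, peaks=peaks, r_squared=r2,
        excluded=r2 < s.r2_min, freqs=f, flattened=p - final.model(f),
        residual=p - model,
    )


# ----------------------------------------------------------------------
# independent joint-fit oracle
# ----------------------------------------------------------------------
def fit_joint_model(periodogram: Periodogram, mode: str = "knee",
                    fit_range: tuple[float, float] = (0.5, 100.0),
                    max_peaks: int = 6, height_min: float = 0.10
                    ) -> SpectralFit:
    """Simultaneous fit of backbone + all peaks, selecting the peak count by BIC.

    A deliberately different route from :func:`full_fit` (no iterative
    subtraction, no robust masking): candidate peak seeds are local maxima
    of the smoothed residual, and for each candidate count all parameters
    are optimized jointly; the Bayesian information criterion picks the
    model order.  Used as a cross-check of the iterative pipeline.
    """
    f_all, p_all = periodogram.freqs, periodogram.log_power
    sel = (f_all >= fit_range[0]) & (f_all <= fit_range[1])
    f, p = f_all[sel], p_all[sel]
    n = len(f)

    def pack_residual(theta: np.ndarray, n_peaks: int) -> np.ndarray:
        if mode == "knee":
            b, k, chi = theta[0], theta[1], theta[2]
            base = b - np.log10(k + f**chi)
            rest = theta[3:]
        else:
            b, chi = theta[0], theta[1]
            base = b - chi * np.log10(f)
            rest = theta[2:]
        return base + _gaussian_sum(f, *rest) - p

    b0, k0, chi0 = _initial_guess(f, p)
    # smooth residual of a peak-insensitive backbone for candidate seeding
    # (the model-order search below is what distinguishes this route)
    crude = fit_aperiodic(Periodogram(f, p), mode, fit_range, robust=True)
    resid = p - crude.model(f)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(resid, kernel, mode="same")
    order = np.argsort(smooth)[::-1]
    seeds: list[int] = []
    for i in order:
        if smooth[i] < height_min / 2:
            break
        if f[i] - f[0] < 1.0 or f[-1] - f[i] < 1.0:
            continue  # edge curvature, not an oscillation
        if all(abs(f[i] - f[j]) > 2.0 for j in seeds):
            seeds.append(int(i))
        if len(seeds) >= max_peaks:
            break

    best = None
    best_bic = np.inf
    delta_bic = 2.0  # a richer model must earn its extra parameters
    for n_peaks in range(0, len(seeds) + 1):
        theta0 = [b0, k0, chi0] if mode == "knee" else [b0, chi0]
        lo = [-np.inf, 0.0, 1e-3] if mode == "knee" else [-np.inf, 1e-3]
        hi = [np.inf, np.inf, 10.0] if mode == "knee" else [np.inf, 10.0]
        for i in seeds[:n_peaks]:
            theta0 += [float(f[i]), max(float(smooth[i]), height_min), 1.5]
            lo += [f[0], 0.0, 0.1]
            hi += [f[-1], np.inf, 10.0]
        res = optimize.least_squares(
            pack_residual, theta0, args=(n_peaks,), bounds=(lo, hi),
            max_nfev=20000,
        )
        rss = float(np.sum(res.fun**2))
        n_par = len(theta0)
        bic = n * np.log(max(rss / n, 1e-300)) + n_par * np.log(n)
        if bic < best_bic - (delta_bic if best is not None else 0.0):
            best_bic = bic
            best = (res.x, n_peaks)
    theta, n_peaks = best
    if mode == "knee":
        ap = AperiodicParams(theta[0], theta[1], theta[2], "knee")
        rest = theta[3:]
    else:
        ap = AperiodicParams(theta[0], 0.0, theta[1], "fixed")
        rest = theta[2:]
    peaks = [
        PeakParams(float(rest[i]), float(rest[i + 1]), 2 * float(rest[i + 2]))
        for i in range(0, len(rest), 3)
        if rest[i + 1] >= height_min / 2
    ]
    peaks.sort(key=lambda pk: pk.center)
    model = ap.model(f) + sum(pk.model(f) for pk in peaks)
    r2 = float(np.corrcoef(p, model)[0, 1] ** 2)
    return SpectralFit(ap, peaks, r2, r2 < 0.99, f, p - ap.model(f), p - model)


# ----------------------------------------------------------------------
# cohort-level periodograms and batch fitting
# ----------------------------------------------------------------------
def average_periodograms(
    recordings: list[EpochedRecording],
    masks: dict | None = None,
    window_s: float = 4.0,
) -> list[Periodogram]:
    """Per subject-night-stage (NREM / REM) channel-averaged periodograms.

    PSDs are averaged in linear power over retained epochs and all
    channels, then log10-transformed.
    """
    out = []
    for rec in recordings:
        mask = masks.get((rec.subject_id, rec.night)) if masks else None
        retained = (
            mask.retained if isinstance(mask, ArtifactMask)
            else np.ones(rec.n_epochs, dtype=bool)
        )
        hyp = np.asarray(rec.hypnogram)
        for stage_name, members in (("NREM", ("N2", "N3")), ("REM", ("R",))):
            keep = retained & np.isin(hyp, members)
            if not keep.any():
                continue
            epochs = rec.epochs()[keep]
            freqs, psd = welch_psd(epochs, rec.sfreq, window_s=window_s)
            mean_psd = psd.mean(axis=(0, 1))
            out.append(
                Periodogram(freqs[freqs > 0],
                            np.log10(np.maximum(mean_psd[freqs > 0], 1e-15)),
                            rec.subject_id, rec.night, stage_name)
            )
    return out


def fit_cohort(periodograms: list[Periodogram],
               settings: SpecparamSettings | None = None) -> pd.DataFrame:
    """Batch :func:`full_fit`; one row per periodogram with fit parameters."""
    rows = []
    for pg in periodograms:
        fit = full_fit(pg, settings)
        rows.append(
            dict(subject=pg.subject, night=pg.night, stage=pg.stage,
                 offset=fit.aperiodic.offset, knee=fit.aperiodic.knee,
                 exponent=fit.aperiodic.exponent, n_peaks=len(fit.peaks),
                 r_squared=fit.r_squared, excluded=fit.excluded)
        )
    return pd.DataFrame(rows)
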