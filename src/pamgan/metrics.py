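"""Image-quality metrics for AR / generated / OR comparison.

The comparison protocol is: sensitivity via SNR and CNR over caller-chosen
rectangular ROIs, structural agreement via SSIM against a reference image,
and resolution via Gaussian fits to lateral/axial line profiles, reported
as FWHM = 2*sqrt(2*ln 2)*sigma.  Definitions:

* ``SNR(dB) = 10*log10(P_signal / P_noise)`` with P the mean squared
  amplitude over the ROI;
* ``CNR(dB) = 10*log10((mu_signal - mu_background) / sigma_background)``;
* ``SSIM`` is the standard luminance*contrast*structure index computed
  over sliding windows (uniform 7x7 window, K1=0.01, K2=0.03, unbiased
  covariance) — an independent reference implementation is used as a
  cross-check in the test suite, never as the implementation.

ROIs are always explicit caller input and are echoed into the report.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class UndefinedMetricError(ValueError):
    """The ROI choice makes the metric undefined (zero power/contrast)."""


class FitError(RuntimeError):
    """Gaussian profile fit failed to converge or input was degenerate."""


@dataclass(frozen=True)
class Roi:
    """Rectangular region with 0-based half-open bounds on a 2D image."""

    row0: int
    row1: int
    col0: int
    col1: int
    role: str = "signal"  # {"signal", "background"}

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"empty ROI {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"ROI bounds must be non-negative: {self}")

    def extract(self, img: np.ndarray) -> np.ndarray:
        if self.row1 > img.shape[0] or self.col1 > img.shape[1]:
            raise ValueError(f"ROI {self} exceeds image shape {img.shape}")
        return np.asarray(img, dtype=np.float64)[self.row0:self.row1, self.col0:self.col1]


def snr_db(img: np.ndarray, signal: Roi, noise: Roi) -> float:
    """Signal-to-noise ratio: 10*log10 of mean-squared-amplitude ratio."""
    p_signal = float(np.mean(signal.extract(img) ** 2))
    p_noise = float(np.mean(noise.extract(img) ** 2))
    if p_noise <= 0:
        raise UndefinedMetricError("noise ROI has zero power")
    return 10.0 * np.log10(p_signal / p_noise)


def cnr_db(img: np.ndarray, signal: Roi, background: Roi) -> float:
    """Contrast-to-noise ratio: 10*log10((mu_s - mu_b) / sigma_b)."""
    mu_s = float(np.mean(signal.extract(img)))
    bg = background.extract(img)
    mu_b = float(np.mean(bg))
    sigma_b = float(np.std(bg))
    if sigma_b <= 0:
        raise UndefinedMetricError("background ROI has zero standard deviation")
    ratio = (mu_s - mu_b) / sigma_b
    if ratio <= 0:
        raise UndefinedMetricError(
            f"signal mean {mu_s:.4g} does not exceed background mean {mu_b:.4g}"
        )
    return 10.0 * np.log10(ratio)


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
) -> float:
    """Mean structural similarity over sliding uniform windows.

    Local means/variances/covariance are computed with a ``window`` x
    ``window`` uniform filter (unbiased covariance normalization); the SSIM
    map is cropped by the filter half-width before averaging.  Symmetric in
    its arguments; ssim(x, x) == 1 exactly.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if window % 2 == 0 or window > min(a.shape):
        raise ValueError(f"window {window} must be odd and fit inside {a.shape}")
    np_win = window ** 2
    cov_norm = np_win / (np_win - 1)  # unbiased sample covariance
    f = lambda x: ndimage.uniform_filter(x, size=window)
    ua, ub = f(a), f(b)
    uaa, ubb, uab = f(a * a), f(b * b), f(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
    pad = (window - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def cw_ssim(
    a: np.ndarray,
    b: np.ndarray,
    n_orientations: int = 4,
    bandwidth: float = 0.15,
    center_freq: float = 0.25,
    k: float = 1e-4,
    window: int = 7,
) -> float:
    """Complex-wavelet SSIM via an FFT Gabor filter bank (optional metric).

    Compares complex band-pass coefficients, so it is insensitive to small
    translations and consistent luminance shifts.  Single scale with
    ``n_orientations`` log-Gabor-like orientations; the index follows the
    standard form (2|sum c_a conj(c_b)| + K) / (sum |c_a|^2 + |c_b|^2 + K)
    averaged over sliding windows and orientations.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    h, w = a.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    fa, fb = np.fft.fft2(a), np.fft.fft2(b)
    with np.errstate(divide="ignore"):
        radial = np.exp(-((np.log((rho + 1e-12) / center_freq)) ** 2) / (2 * bandwidth))
    radial[rho == 0] = 0.0
    scores = []
    uf = lambda x: ndimage.uniform_filter(x, size=window)
    for j in range(n_orientations):
        ang = np.pi * j / n_orientations
        dtheta = np.angle(np.exp(1j * (theta - ang)))
        angular = np.exp(-(dtheta**2) / (2 * (np.pi / n_orientations) ** 2))
        filt = radial * angular
        ca = np.fft.ifft2(fa * filt)
        cb = np.fft.ifft2(fb * filt)
        cross = uf((ca * np.conj(cb)).real) ** 2 + uf((ca * np.conj(cb)).imag) ** 2
        num = 2.0 * np.sqrt(np.maximum(cross, 0.0)) + k
        den = uf(np.abs(ca) ** 2) + uf(np.abs(cb) ** 2) + k
        scores.append((num / den).mean())
    return float(np.mean(scores))


@dataclass
class Profile:
    """Amplitude samples along an axis-aligned line with physical positions."""

    positions: np.ndarray  # strictly increasing, micrometres
    values: np.ndarray
    axis: str = "lateral"  # {"lateral", "axial"}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def extract_profile(
    img: np.ndarray,
    axis: str,
    index: int,
    pitch_um: float,
) -> Profile:
    """Sample an axis-aligned line through a b-scan or MAP image.

    For a b-scan stored ``(x, z)``: ``axis="lateral"`` samples across rows
    at depth column ``index`` (positions step by the lateral pitch);
    ``axis="axial"`` samples along row ``index`` (depth pitch).
    """
    img = np.asarray(img, dtype=np.float64)
    if axis == "lateral":
        if not (0 <= index < img.shape[1]):
            raise ValueError(f"column {index} outside image {img.shape}")
        values = img[:, index]
    elif axis == "axial":
        if not (0 <= index < img.shape[0]):
            raise ValueError(f"row {index} outside image {img.shape}")
        values = img[index, :]
    else:
        raise ValueError(f"axis must be 'lateral' or 'axial', got {axis!r}")
    positions = np.arange(values.size) * float(pitch_um)
    return Profile(positions=positions, values=values, axis=axis)


@dataclass
class GaussianFit:
    """Least-squares Gaussian fit of a line profile."""

    amplitude: float
    center_um: float
    sigma_um: float
    offset: float
    rmse: float

    @property
    def fwhm_um(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_um


def _gauss(x: np.ndarray, amp: float, center: float, sigma: float, offset: float) -> np.ndarray:
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + offset


def fit_gaussian(profile: Profile) -> GaussianFit:
    """Fit ``amp*exp(-(x-c)^2/(2 sigma^2)) + offset`` by least squares.

    Initialization from moments of the offset-subtracted profile.  The
    reported FWHM is ``2*sqrt(2*ln 2)*sigma``.
    """
    x, y = profile.positions, profile.values
    if x.size < 5:
        raise FitError(f"need >= 5 samples, got {x.size}")
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitError("constant profile: no peak to fit")
    offset0 = float(y.min())
    amp0 = span
    w = np.clip(y - offset0, 0.0, None)
    center0 = float(np.sum(x * w) / np.sum(w))
    var0 = float(np.sum(w * (x - center0) ** 2) / np.sum(w))
    sigma0 = max(np.sqrt(var0), float(np.diff(x).mean()) / 2.0)
    p0 = (amp0, center0, sigma0, offset0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=p0, maxfev=10000,
            bounds=([0.0, x[0] - (x[-1] - x[0]), 1e-9, -np.inf],
                    [np.inf, x[-1] + (x[-1] - x[0]), 10 * (x[-1] - x[0]), np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Gaussian fit failed (init {p0}): {exc}") from exc
    amp, center, sigma, offset = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_gauss(x, *popt) - y) ** 2)))
    return GaussianFit(amplitude=amp, center_um=center, sigma_um=sigma,
                       offset=offset, rmse=rmse)


@dataclass
class MetricsRow:
    label: str
    snr_db: float | None = None
    cnr_db: float | None = None
    ssim: float | None = None
    fwhm_um: float | None = None


@dataclass
class MetricsReport:
    """One metrics row per compared image plus ROI/profile provenance."""

    rows: list[MetricsRow]
    reference: str
    rois: dict = field(default_factory=dict)
    profile_lines: dict = field(default_factory=dict)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["label", "snr_db", "cnr_db", "ssim", "fwhm_um"])
        for r in self.rows:
            writer.writerow([
                r.label,
                *("" if v is None else repr(float(v))
                  for v in (r.snr_db, r.cnr_db, r.ssim, r.fwhm_um)),
            ])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, reference: str = "") -> "MetricsReport":
        rows = []
        for rec in csv.DictReader(io.StringIO(text)):
            rows.append(MetricsRow(
                label=rec["label"],
                **{k: (float(rec[k]) if rec[k] else None)
                   for k in ("snr_db", "cnr_db", "ssim", "fwhm_um")},
            ))
        return cls(rows=rows, reference=reference)


def compare_images(
    images: dict[str, np.ndarray],
    signal_roi: Roi | None = None,
    noise_roi: Roi | None = None,
    profile: tuple[str, int, float] | None = None,
    reference: str | None = None,
    ssim_window: int = 7,
) -> MetricsReport:
    """Build the AR / generated / OR comparison table.

    ``profile`` is ``(axis, index, pitch_um)`` for the FWHM measurement;
    SSIM is computed against the ``reference`` label (default ``"OR"`` when
    present, else the first label).  Deterministic; failures of individual
    metrics (undefined CNR, failed fit) are recorded as missing values
    rather than aborting the whole table.
    """
    shapes = {img.shape for img in images.values()}
    if len(shapes) != 1:
        raise ValueError(f"images must share a shape, got {shapes}")
    if reference is None:
        reference = "OR" if "OR" in images else next(iter(images))
    ref_img = images[reference]
    rows = []
    for label, img in images.items():
        row = MetricsRow(label=label)
        if signal_roi is not None and noise_roi is not None:
            try:
                row.snr_db = snr_db(img, signal_roi, noise_roi)
            except UndefinedMetricError:
                pass
            try:
                row.cnr_db = cnr_db(img, signal_roi, noise_roi)
            except UndefinedMetricError:
                pass
        row.ssim = ssim(img, ref_img, window=ssim_window)
        if profile is not None:
            axis, index, pitch = profile
            try:
                row.fwhm_um = fit_gaussian(extract_profile(img, axis, index, pitch)).fwhm_um
            except FitError:
                pass
        rows.append(row)
    return MetricsReport(
        rows=rows, reference=reference,
        rois={"signal": signal_roi, "noise": noise_roi},
        profile_lines={"profile": profile},
    )
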