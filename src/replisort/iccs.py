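"""Image cross-correlation spectroscopy (ICCS) on arbitrarily shaped nuclei.

For each nucleus the spatial auto-correlation function (ACF) of each channel
and the cross-correlation function (CCF) of the two channels are computed
over pixel lags inside the nucleus mask:

    G_ab(xi, eta) = < dI_a(x, y) dI_b(x + xi, y + eta) > / (mu_a * mu_b)

with fluctuations ``dI = I - mu`` taken about the in-mask means and the
lag average running over pixel pairs that both fall inside the mask.  The
masked normalization divides each lag by the number of such pairs (the
autocorrelation of the mask indicator), which keeps G unbiased for
irregular nuclear shapes.  All lag sums are FFT-accelerated.

A Gaussian ``G(r) = B * exp(-r^2 / w^2) + G_inf`` is fitted to the radial
profile of each correlation function (zero lag excluded — uncorrelated shot
noise only inflates the ACF there), and the colocalization fractions are
amplitude ratios:

    f1 = B_cc / B_22      (fraction of channel-1 signal correlated with 2)
    f2 = B_cc / B_11      (fraction of channel-2 signal correlated with 1)

ranging from 1 (maximum cross-correlation) through 0 (independence) to
negative values (anti-correlation).  A symmetric Pearson-style convention
``f = B_cc / sqrt(B_11 * B_22)`` is available as an option; evaluated on raw
zero-lag values it reduces exactly to the Pearson correlation coefficient of
the two channels over the mask pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .io import ChannelImage, CountMask
from .sorting import NucleusRecord, S_PHASES

DEFAULT_MAX_LAG_PX = 32
DEFAULT_MIN_OVERLAP = 200
DEFAULT_PAD_PX = 8
DEFAULT_MIN_FOCI_PX = 10


@dataclass
class IccsSettings:
    """Knobs of the per-nucleus ICCS computation."""

    max_lag_px: int = DEFAULT_MAX_LAG_PX
    min_overlap: int = DEFAULT_MIN_OVERLAP
    convention: str = "asymmetric"  # or "pearson"
    pad_px: int = DEFAULT_PAD_PX
    min_foci_px: int = DEFAULT_MIN_FOCI_PX

    def __post_init__(self) -> None:
        if self.convention not in ("asymmetric", "pearson"):
            raise ValueError("convention must be 'asymmetric' or 'pearson'")
        if self.max_lag_px < 1 or self.min_overlap < 1 or self.pad_px < 0:
            raise ValueError("invalid ICCS settings")


@dataclass
class CorrelationFunction:
    """G(xi, eta) on the square lag window [-L, L]^2 plus overlap counts."""

    values: np.ndarray
    overlap_counts: np.ndarray
    channel_pair: str  # "11", "22" or "12"
    max_lag_px: int

    @property
    def zero_lag(self) -> float:
        L = self.max_lag_px
        return float(self.values[L, L])


@dataclass
class GaussianFit:
    """Result of the radial Gaussian fit G(r) = B exp(-r^2/w^2) + G_inf."""

    amplitude_b: float
    width_w: float
    offset_ginf: float
    residual_rms: float
    converged: bool


@dataclass
class ColocResult:
    f1: float
    f2: float
    b11: float
    b22: float
    bcc: float
    convention: str
    qc_flags: set[str] = field(default_factory=set)


def _lag_sums(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """S(xi, eta) = sum_x a(x) b(x + lag) for lags in [-L, L]^2, via FFT."""
    full = signal.fftconvolve(a[::-1, ::-1], b, mode="full")
    cy, cx = a.shape[0] - 1, a.shape[1] - 1
    L = max_lag
    if L > min(cy, cx):
        raise ValueError("max_lag exceeds image extent")
    return full[cy - L : cy + L + 1, cx - L : cx + L + 1]


def masked_correlation(
    ch_a: np.ndarray | ChannelImage,
    ch_b: np.ndarray | ChannelImage,
    nucleus_mask: np.ndarray,
    max_lag_px: int = DEFAULT_MAX_LAG_PX,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    channel_pair: str = "12",
) -> CorrelationFunction:
    """Masked fluctuation correlation of two channel crops.

    Means are taken inside the mask; fluctuation products are summed per lag
    (FFT) and divided by the per-lag count of in-mask pixel pairs and by
    ``mu_a * mu_b``.  Lags with fewer than ``min_overlap`` pairs are NaN.
    """
    a = ch_a.pixels if isinstance(ch_a, ChannelImage) else np.asarray(ch_a, dtype=float)
    b = ch_b.pixels if isinstance(ch_b, ChannelImage) else np.asarray(ch_b, dtype=float)
    m = np.asarray(nucleus_mask, dtype=bool)
    if not (a.shape == b.shape == m.shape):
        raise ValueError("channel crops and mask must share shape")
    n_px = int(m.sum())
    if n_px < 100:
        raise ValueError("mask too small: need at least 100 pixels")

    mu_a = float(a[m].mean())
    mu_b = float(b[m].mean())
    if mu_a <= 0 or mu_b <= 0:
        raise ValueError("zero mean: channel has no signal within the mask")
    if np.ptp(a[m]) == 0 or np.ptp(b[m]) == 0:
        raise ValueError("degenerate channel: zero variance within the mask")

    mf = m.astype(float)
    da = (a - mu_a) * mf
    db = (b - mu_b) * mf

    s = _lag_sums(da, db, max_lag_px)
    w = _lag_sums(mf, mf, max_lag_px)
    w = np.rint(w)

    with np.errstate(invalid="ignore", divide="ignore"):
        g = s / (w * mu_a * mu_b)
    g[w < min_overlap] = np.nan
    return CorrelationFunction(g, w.astype(np.int64), channel_pair, max_lag_px)


def radial_profile(cf: CorrelationFunction) -> pd.DataFrame:
    """Average G over integer radial bins r = 1..max_lag.

    The zero lag is excluded from the bins (it is reported separately via
    ``cf.zero_lag``); bins without any finite lag have ``n_points`` 0 and a
    missing mean.
    """
    L = cf.max_lag_px
    yy, xx = np.mgrid[-L : L + 1, -L : L + 1]
    r = np.rint(np.hypot(yy, xx)).astype(int)
    g = cf.values
    rows = []
    for rb in range(1, L + 1):
        sel = (r == rb) & np.isfinite(g)
        n = int(sel.sum())
        rows.append((rb, float(g[sel].mean()) if n else float("nan"), n))
    return pd.DataFrame(rows, columns=["r", "g_mean", "n_points"])


def fit_gaussian(profile: pd.DataFrame, max_lag_px: int | None = None) -> GaussianFit:
    """Weighted least-squares fit of G(r) = B exp(-r^2/w^2) + G_inf.

    Bins are weighted by their lag counts; the width is bounded to
    [0.5, max_lag] px and the amplitude is free in sign.
    """
    usable = profile[np.isfinite(profile["g_mean"]) & (profile["n_points"] > 0)]
    if len(usable) < 5:
        raise ValueError("need at least 5 usable radial bins to fit")
    r = usable["r"].to_numpy(dtype=float)
    g = usable["g_mean"].to_numpy(dtype=float)
    n = usable["n_points"].to_numpy(dtype=float)
    if max_lag_px is None:
        max_lag_px = int(profile["r"].max())

    tail = float(g[-3:].mean())
    p0 = (float(g[0]) - tail, 2.0, tail)
    lo = (-np.inf, 0.5, -np.inf)
    hi = (np.inf, float(max_lag_px), np.inf)
    p0 = (p0[0], min(max(p0[1], 0.5), max_lag_px), p0[2])

    def model(rr, b, w, ginf):
        return b * np.exp(-(rr**2) / w**2) + ginf

    try:
        popt, _ = optimize.curve_fit(
            model, r, g, p0=p0, sigma=1.0 / np.sqrt(n), bounds=(lo, hi), maxfev=10000
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return GaussianFit(float("nan"), float("nan"), float("nan"), float("nan"), False)
    resid = g - model(r, *popt)
    rms = float(np.sqrt(np.average(resid**2, weights=n)))
    return GaussianFit(float(popt[0]), float(popt[1]), float(popt[2]), rms, True)


def coloc_fractions(
    fit11: GaussianFit,
    fit22: GaussianFit,
    fit_cc: GaussianFit,
    convention: str = "asymmetric",
) -> ColocResult:
    """Colocalization fractions from the three fitted amplitudes.

    Asymmetric (default): ``f1 = Bcc/B22``, ``f2 = Bcc/B11`` — the classical
    fraction-colocalized convention, which distinguishes the two channels.
    Pearson: ``f1 = f2 = Bcc/sqrt(B11*B22)``.  A negative Bcc propagates into
    negative fractions (anti-correlation); values are never clamped, and
    fractions outside [-1, 1] are flagged rather than altered.
    """
    if convention not in ("asymmetric", "pearson"):
        raise ValueError("convention must be 'asymmetric' or 'pearson'")
    flags: set[str] = set()
    b11, b22, bcc = fit11.amplitude_b, fit22.amplitude_b, fit_cc.amplitude_b
    if not (fit11.converged and fit22.converged and fit_cc.converged):
        flags.add("fit-failed")
        return ColocResult(float("nan"), float("nan"), b11, b22, bcc, convention, flags)
    if b11 <= 0 or b22 <= 0:
        flags.add("bad-acf")
        return ColocResult(float("nan"), float("nan"), b11, b22, bcc, convention, flags)
    if convention == "asymmetric":
        f1 = bcc / b22
        f2 = bcc / b11
    else:
        f1 = f2 = bcc / np.sqrt(b11 * b22)
    if abs(f1) > 1 or abs(f2) > 1:
        flags.add("out-of-range")
    return ColocResult(float(f1), float(f2), b11, b22, bcc, convention, flags)


def iccs_single(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    nucleus_mask: np.ndarray,
    settings: IccsSettings | None = None,
) -> ColocResult:
    """Full ICCS (two ACFs, CCF, fits, fractions) for one masked region."""
    settings = settings or IccsSettings()
    fits = {}
    for pair, (x, y) in {"11": (ch_a, ch_a), "22": (ch_b, ch_b), "12": (ch_a, ch_b)}.items():
        cf = masked_correlation(
            x, y, nucleus_mask, settings.max_lag_px, settings.min_overlap, pair
        )
        fits[pair] = fit_gaussian(radial_profile(cf), settings.max_lag_px)
    return coloc_fractions(fits["11"], fits["22"], fits["12"], settings.convention)


def _crop_bbox(labels: np.ndarray, label: int, pad: int, shape) -> tuple[slice, slice, bool]:
    ys, xs = np.nonzero(labels == label)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    at_border = y0 == 0 or x0 == 0 or y1 == shape[0] or x1 == shape[1]
    y0 = max(0, y0 - pad)
    x0 = max(0, x0 - pad)
    y1 = min(shape[0], y1 + pad)
    x1 = min(shape[1], x1 + pad)
    return slice(y0, y1), slice(x0, x1), at_border


def iccs_per_nucleus(
    rf: ChannelImage,
    tf: ChannelImage,
    mask: CountMask,
    records: list[NucleusRecord],
    settings: IccsSettings | None = None,
) -> list[NucleusRecord]:
    """Run ICCS for every S-phase nucleus; fills f1/f2 on the records.

    Channels must be background-subtracted.  G1/G2 (and excluded) nuclei are
    skipped — they carry no replication-foci signal.  Per-nucleus failures
    become qc flags and never abort the batch; nuclei touching the image
    border are processed with their available pixels and flagged "border".
    """
    settings = settings or IccsSettings()
    if not (rf.shape == tf.shape == mask.shape):
        raise ValueError("channels and mask must share shape")
    out = []
    for rec in records:
        rec = replace(rec, qc_flags=set(rec.qc_flags))
        if rec.phase not in S_PHASES:
            out.append(rec)
            continue
        if rec.n_rf < settings.min_foci_px:
            rec.qc_flags.add("insufficient-foci")
            out.append(rec)
            continue
        sy, sx, at_border = _crop_bbox(mask.labels, rec.label, settings.pad_px, mask.shape)
        if at_border:
            rec.qc_flags.add("border")
        nmask = mask.labels[sy, sx] == rec.label
        max_lag = min(settings.max_lag_px,
                      nmask.shape[0] - 1, nmask.shape[1] - 1)
        try:
            local = IccsSettings(max_lag, settings.min_overlap,
                                 settings.convention, settings.pad_px,
                                 settings.min_foci_px)
            res = iccs_single(rf.pixels[sy, sx], tf.pixels[sy, sx], nmask, local)
        except ValueError as err:
            rec.qc_flags.add(f"iccs-error:{err}")
            out.append(rec)
            continue
        rec.f1, rec.f2 = res.f1, res.f2
        rec.qc_flags |= res.qc_flags
        out.append(rec)
    return out
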