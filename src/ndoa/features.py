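"""The five per-window features feeding the depth-of-anaesthesia model.

Each 10 s EEG window is summarised by:

* **SE** — sample entropy, ``-ln(A_m/B_m)`` with Chebyshev distance,
  ``m = 2``, tolerance ``r = 0.2*std``; self-matches excluded.
* **FE** — fuzzy entropy, ``ln(phi_m) - ln(phi_{m+1})`` with exponential
  membership ``exp(-(d/r)^n)`` on de-meaned templates, ``m = 2``, ``n = 2``,
  ``r = 0.15*std``.
* **PE** — permutation entropy of ordinal patterns, ``m = 4``, delay 1,
  normalised by ``ln(m!)`` so it lies in [0, 1].
* **Hurst range response** — the minimum over dyadic scales of the mean
  per-segment range of cumulative mean-adjusted deviations (the range half
  of classical rescaled-range analysis; the full R/S curve is also exposed).
* **PSD feature** — an eigenvector (MUSIC-family) pseudospectrum statistic
  of the 6-level db16 wavelet coefficients, combined across levels as
  ``(k1*M + k2*S)/k3`` with ``k1, k2, k3 = 28, 90, 3``.

Low-frequency, high-amplitude EEG (deep anaesthesia) is more regular, so the
entropies fall as anaesthesia deepens; the awake state's low-voltage
broadband activity drives them up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
import scipy.linalg

from .errors import DegenerateSignalError, NdoaError
from .preprocess import DEFAULT_LEVELS, DEFAULT_WAVELET

FEATURE_NAMES = ("se", "fe", "pe", "hurst_rr", "psd_fea")


@dataclass
class EntropyParams:
    """Embedding/tolerance parameters shared by the entropy features."""

    m: int = 2
    r_se: float = 0.2    # sample-entropy tolerance, x std
    r_fe: float = 0.15   # fuzzy-entropy tolerance, x std
    n_fuzzy: int = 2
    tau: int = 1


@dataclass
class PSDFeatureParams:
    """Eigenvector pseudospectrum feature parameters.

    ``order`` is the autocorrelation-matrix order and ``n_noise`` the number
    of noise-subspace eigenvectors (the principal-eigenvector count); the
    pseudospectrum is evaluated on ``n_grid`` normalised frequencies over
    [0, pi) rad/sample, i.e. [0, 64] Hz at the 128 Hz recording rate.
    """

    k1: float = 28.0
    k2: float = 90.0
    k3: float = 3.0
    levels: int = DEFAULT_LEVELS
    wavelet: str = DEFAULT_WAVELET
    order: int = 12
    n_noise: int = 6
    n_grid: int = 128

    def __post_init__(self) -> None:
        if self.k3 == 0:
            raise NdoaError("k3 must be nonzero")
        if self.levels < 1:
            raise NdoaError("levels must be >= 1")


@dataclass
class FeatureVector:
    """The five per-window features plus a degeneracy flag.

    When ``degenerate`` is True (constant window, zero-entropy condition, or
    a non-finite sub-result) the feature values are placeholders (0.0) and
    must not be fed to the model; the flag, never NaN, carries the signal.
    """

    se: float = 0.0
    fe: float = 0.0
    pe: float = 0.0
    hurst_rr: float = 0.0
    psd_fea: float = 0.0
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.se, self.fe, self.pe, self.hurst_rr,
                         self.psd_fea], dtype=float)


def _chebyshev_pair_distances(templates: np.ndarray) -> np.ndarray:
    """(n, n) matrix of Chebyshev distances between template rows."""
    n, m = templates.shape
    d = np.abs(templates[:, None, 0] - templates[None, :, 0])
    for k in range(1, m):
        np.maximum(d, np.abs(templates[:, None, k] - templates[None, :, k]),
                   out=d)
    return d


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 1:
        raise NdoaError(f"sequence of {x.size} samples too short for "
                        f"m={m}, tau={tau}")
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2,
                   r: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` in nats.

    ``B`` counts template pairs of length ``m`` and ``A`` pairs of length
    ``m+1`` with Chebyshev distance strictly below ``r`` (default
    ``0.2*std(x)``); both counts run over the same ``N-m`` templates and
    exclude self-matches. Because ``r`` scales with the standard deviation,
    SE is invariant under positive affine maps of the signal. A perfectly
    ordered signal (``A = 0``) returns ``inf`` — the signalled
    infinite-entropy condition.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise NdoaError(f"need at least m+2={m + 2} samples, got {x.size}")
    if r is None:
        sd = x.std()
        if sd == 0.0:
            raise DegenerateSignalError("constant signal: sample entropy "
                                        "undefined (std = 0)")
        r = r_factor * sd
    n_templ = x.size - m  # common template count for both lengths
    templ_m1 = _embed(x, m + 1)
    d_m = _chebyshev_pair_distances(templ_m1[:, :m])
    # counts over unordered pairs i<j; the diagonal (distance 0) is removed
    b = (int(np.count_nonzero(d_m < r)) - n_templ) // 2
    np.maximum(d_m, np.abs(templ_m1[:, None, m] - templ_m1[None, :, m]),
               out=d_m)
    a = (int(np.count_nonzero(d_m < r)) - n_templ) // 2
    if b == 0:
        raise DegenerateSignalError("no matching templates at length m; "
                                    "sample entropy undefined")
    if a == 0:
        return math.inf
    return -math.log(a / b)


def fuzzy_entropy(x: np.ndarray, m: int = 2, n_fuzzy: int = 2,
                  r_factor: float = 0.15, r: float | None = None) -> float:
    """Fuzzy entropy ``ln(phi_m) - ln(phi_{m+1})`` in nats.

    Templates are de-meaned (each minus its own mean) before the Chebyshev
    distance, and matches are weighted by ``exp(-(d/r)^n)`` instead of a hard
    cut, which makes the statistic continuous in the data. Defaults
    ``m = 2``, ``n = 2``, ``r = 0.15*std(x)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise NdoaError(f"need at least m+2={m + 2} samples, got {x.size}")
    if r is None:
        sd = x.std()
        if sd == 0.0:
            raise DegenerateSignalError("constant signal: fuzzy entropy "
                                        "undefined (std = 0)")
        r = r_factor * sd
    if r <= 0:
        raise NdoaError(f"tolerance must be positive, got {r}")

    def phi(dim: int) -> float:
        templ = _embed(x, dim)[: x.size - m]  # common count N-m
        templ = templ - templ.mean(axis=1, keepdims=True)
        d = _chebyshev_pair_distances(templ)
        n_t = templ.shape[0]
        w = np.exp(-((d / r) ** n_fuzzy))
        # mean over unordered pairs; diagonal weights are exactly 1
        return float((w.sum() - n_t) / (n_t * (n_t - 1)))

    phi_m, phi_m1 = phi(m), phi(m + 1)
    if phi_m <= 0 or phi_m1 <= 0:
        raise DegenerateSignalError("vanishing membership sums: fuzzy "
                                    "entropy undefined")
    return math.log(phi_m) - math.log(phi_m1)


def permutation_entropy_norm(x: np.ndarray, m: int = 4, tau: int = 1) -> float:
    """Normalised permutation entropy ``-sum p ln p / ln(m!)`` in [0, 1].

    Only observed ordinal patterns contribute; ties are broken by order of
    occurrence (stable argsort). 0 iff a single pattern occurs; 1 when all
    ``m!`` patterns are equally frequent.
    """
    x = np.asarray(x, dtype=float)
    if x.size < (m - 1) * tau + 1:
        raise NdoaError(f"sequence of {x.size} samples too short for "
                        f"m={m}, tau={tau}")
    patterns = np.argsort(_embed(x, m, tau), axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(m))


def rescaled_range_curve(x: np.ndarray, scales=None):
    """Per-scale range statistics of cumulative mean-adjusted deviations.

    For each scale the signal is cut into non-overlapping segments; per
    segment the range R of the cumulative de-meaned sums and the population
    standard deviation S are computed. Returns ``(scales, mean_R, mean_RS)``
    where the means run over the segments of each scale, with S = 0
    (constant) segments excluded.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise NdoaError(f"need at least 8 samples, got {n}")
    if scales is None:
        scales, s = [], n
        while s >= 8:
            scales.append(s)
            s //= 2
    out_scales, mean_r, mean_rs = [], [], []
    for s in scales:
        n_seg = n // s
        if n_seg < 1:
            continue
        segs = x[: n_seg * s].reshape(n_seg, s)
        dev = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1)  # population (1/m) convention
        keep = sd > 0
        if not np.any(keep):
            continue
        out_scales.append(s)
        mean_r.append(float(r[keep].mean()))
        mean_rs.append(float((r[keep] / sd[keep]).mean()))
    if not out_scales:
        raise DegenerateSignalError("constant signal: rescaled-range "
                                    "analysis undefined")
    return (np.array(out_scales), np.array(mean_r), np.array(mean_rs))


def hurst_range_response(x: np.ndarray, scales=None,
                         classic: bool = False) -> float:
    """Hurst range-response feature.

    Default: the minimum over dyadic scales of the mean per-segment range R
    (taken literally as the feature definition; it is homogeneous of degree
    one in the signal amplitude, so it tracks the high-voltage swing of deep
    anaesthesia). With ``classic=True`` it instead returns the slope of
    ``log(mean R/S)`` against ``log(scale)`` — the standard Hurst exponent
    estimate from rescaled-range analysis.
    """
    sc, mean_r, mean_rs = rescaled_range_curve(x, scales)
    if classic:
        if sc.size < 2:
            raise NdoaError("need >= 2 scales for the classic R/S exponent")
        slope = np.polyfit(np.log(sc), np.log(mean_rs), 1)[0]
        return float(slope)
    return float(mean_r.min())


def ev_pseudospectrum(c: np.ndarray, order: int = 12, n_noise: int = 6,
                      n_grid: int = 128) -> np.ndarray:
    """Eigenvector-method (EV) pseudospectrum of a coefficient series.

    Builds the (order+1)-dimensional Toeplitz autocorrelation matrix of the
    de-meaned series, takes the ``n_noise`` eigenvectors with the smallest
    eigenvalues as the noise subspace, and evaluates

        P(w) = 1 / sum_k (1/lambda_k) |e(w)^H v_k|^2

    on ``n_grid`` frequencies over [0, pi) rad/sample. Inverse-eigenvalue
    weighting distinguishes EV from plain MUSIC and damps spurious peaks.
    """
    c = np.asarray(c, dtype=float)
    if c.size < order + 2:
        raise NdoaError(f"series of {c.size} values too short for "
                        f"order {order}")
    if n_noise < 1 or n_noise > order:
        raise NdoaError(f"n_noise must be in [1, order], got {n_noise}")
    c = c - c.mean()
    acf = np.correlate(c, c, mode="full")[c.size - 1: c.size + order] / c.size
    rmat = scipy.linalg.toeplitz(acf)
    lam, vec = np.linalg.eigh(rmat)  # ascending eigenvalues
    lam_noise = np.maximum(lam[:n_noise], 1e-300)
    v_noise = vec[:, :n_noise]
    w = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    steer = np.exp(-1j * np.outer(np.arange(order + 1), w))
    a = np.abs(v_noise.conj().T @ steer) ** 2  # (n_noise, n_grid)
    denom = (a / lam_noise[:, None]).sum(axis=0)
    return 1.0 / np.maximum(denom, 1e-300)


def psd_eigenvector_feature(x: np.ndarray,
                            params: PSDFeatureParams | None = None) -> float:
    """Wavelet-domain eigenvector pseudospectrum feature.

    The window is decomposed level by level (db16); at every level j both the
    approximation A_j and detail D_j series are given to the EV
    pseudospectrum estimator. Per level the pseudospectrum's mean and
    standard deviation are taken over the frequency grid; across levels

        M = 0.5*[ln(mean_j mean(E_Dj)) + ln(mean_j mean(E_Aj))]
        S = 0.5*[ln(mean_j  std(E_Dj)) + ln(mean_j  std(E_Aj))]

    and the feature is ``(k1*M + k2*S)/k3``.
    """
    if params is None:
        params = PSDFeatureParams()
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(params.wavelet)
    approx = x
    d_means, d_stds, a_means, a_stds = [], [], [], []
    for _ in range(params.levels):
        approx, detail = pywt.dwt(approx, wav)
        e_d = ev_pseudospectrum(detail, params.order, params.n_noise,
                                params.n_grid)
        e_a = ev_pseudospectrum(approx, params.order, params.n_noise,
                                params.n_grid)
        d_means.append(e_d.mean())
        d_stds.append(e_d.std())
        a_means.append(e_a.mean())
        a_stds.append(e_a.std())
    md, ma = float(np.mean(d_means)), float(np.mean(a_means))
    sd_, sa = float(np.mean(d_stds)), float(np.mean(a_stds))
    if min(md, ma, sd_, sa) <= 0:
        raise DegenerateSignalError("non-positive pseudospectrum statistics; "
                                    "feature undefined before log")
    m_term = 0.5 * (math.log(md) + math.log(ma))
    s_term = 0.5 * (math.log(sd_) + math.log(sa))
    return (params.k1 * m_term + params.k2 * s_term) / params.k3


def extract_features(x: np.ndarray,
                     entropy_params: EntropyParams | None = None,
                     psd_params: PSDFeatureParams | None = None,
                     pe_dim: int = 4) -> FeatureVector:
    """All five features of one (denoised) window.

    Degenerate windows never crash or emit NaN: the returned vector carries
    ``degenerate=True`` with placeholder values, and the caller flags the
    second.
    """
    ep = entropy_params or EntropyParams()
    x = np.asarray(x, dtype=float)
    try:
        fv = FeatureVector(
            se=sample_entropy(x, m=ep.m, r_factor=ep.r_se),
            fe=fuzzy_entropy(x, m=ep.m, n_fuzzy=ep.n_fuzzy,
                             r_factor=ep.r_fe),
            pe=permutation_entropy_norm(x, m=pe_dim, tau=ep.tau),
            hurst_rr=hurst_range_response(x),
            psd_fea=psd_eigenvector_feature(x, psd_params),
        )
    except (DegenerateSignalError, NdoaError):
        return FeatureVector(degenerate=True)
    if not np.all(np.isfinite(fv.as_array())):
        return FeatureVector(degenerate=True)
    return fv
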