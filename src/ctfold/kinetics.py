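"""Two-state dwell-time kinetics and score autocorrelation.

Compact/exposed label traces are segmented into contiguous dwells; dwell
durations are fitted with single- or double-exponential laws by maximum
likelihood (the mixture via expectation-maximization), transition rates are
estimated from event counts, and the relaxation of any per-frame observable
is summarized by its normalized autocorrelation and half-decay time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DwellRecord",
    "ExpFit",
    "AcfResult",
    "dwell_segments",
    "fit_exponential",
    "rates_from_counts",
    "autocorrelation",
    "mean_autocorrelation",
]


@dataclass(frozen=True)
class DwellRecord:
    """One contiguous run of a state label.

    ``truncated`` marks runs touching either trajectory end: their true
    duration is censored and they are excluded from histograms by default.
    """

    state: str
    duration: float  # ns
    replicate_id: str = "0"
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("dwell duration must be > 0")


@dataclass
class ExpFit:
    """Maximum-likelihood exponential (mixture) fit of dwell durations.

    Components are reported slow-first (largest time constant first).
    """

    n_components: int
    time_constants: np.ndarray  # ns
    weights: np.ndarray
    log_likelihood: float
    converged: bool = True


@dataclass
class AcfResult:
    lags: np.ndarray  # ns
    acf: np.ndarray
    half_decay: float  # ns; nan if the ACF never drops below 0.5


def dwell_segments(labels, dt: float, include_truncated: bool = False):
    """Segment a label trace from one contiguous replicate into dwells.

    Runs of equal labels become records of duration ``run_length * dt``;
    runs touching either end of the trace are flagged truncated and dropped
    unless ``include_truncated``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    arr = np.asarray(getattr(labels, "labels", labels))
    if arr.size == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    records = []
    for s, e in zip(starts, ends):
        truncated = s == 0 or e == arr.size
        if truncated and not include_truncated:
            continue
        records.append(
            DwellRecord(
                state=str(arr[s]), duration=float((e - s) * dt), truncated=truncated
            )
        )
    return records


def _exp_mixture_loglik(x, taus, weights):
    dens = np.zeros_like(x)
    for tau, w in zip(taus, weights):
        dens += w / tau * np.exp(-x / tau)
    return float(np.sum(np.log(dens)))


def fit_exponential(
    dwells,
    n_components: int = 1,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> ExpFit:
    """Fit an exponential (or two-component exponential mixture) to dwell
    durations by maximum likelihood.

    The single-exponential MLE is the sample mean in closed form. The
    mixture is fitted by EM from ``n_restarts`` random initializations
    (seeded, reproducible); the best log-likelihood wins.
    """
    x = np.asarray(
        [d.duration if isinstance(d, DwellRecord) else d for d in dwells], dtype=float
    )
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    minimum = 5 if n_components == 1 else 20
    if x.size < minimum:
        raise ValueError(
            f"{n_components}-component fit needs >= {minimum} dwells, got {x.size}"
        )
    if np.any(x <= 0):
        raise ValueError("dwell durations must be positive")

    if n_components == 1:
        tau = float(x.mean())
        return ExpFit(
            n_components=1,
            time_constants=np.array([tau]),
            weights=np.array([1.0]),
            log_likelihood=_exp_mixture_loglik(x, [tau], [1.0]),
        )

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(n_restarts):
        q = rng.uniform(0.05, 0.95, size=2)
        taus = np.maximum(np.quantile(x, np.sort(q)), x.mean() * 1e-3)
        if taus[0] == taus[1]:
            taus[1] *= 2.0
        weights = np.array([0.5, 0.5])
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            # E step: responsibilities under the current mixture
            log_d = np.stack(
                [np.log(w / t) - x / t for t, w in zip(taus, weights)], axis=1
            )
            log_norm = np.logaddexp(log_d[:, 0], log_d[:, 1])
            resp = np.exp(log_d - log_norm[:, None])
            ll = float(log_norm.sum())
            # M step: weighted means
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            taus = resp.T @ x / nk
            weights = nk / x.size
            if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_prev = ll
        any_converged |= converged
        if best is None or ll > best[0]:
            best = (ll, taus.copy(), weights.copy(), converged)

    ll, taus, weights, converged = best
    if not converged:
        warnings.warn(
            "EM for the exponential mixture did not converge; returning the "
            "best parameters found",
            stacklevel=2,
        )
    order = np.argsort(taus)[::-1]  # slow component first
    return ExpFit(
        n_components=2,
        time_constants=taus[order],
        weights=weights[order],
        log_likelihood=ll,
        converged=converged,
    )


def rates_from_counts(dwells, total_time: float) -> dict:
    """Event rates from completed-segment counts.

    ``decompaction`` is the rate of leaving the compact state (completed
    compact dwells per unit time); ``compaction`` the converse. Truncated
    segments do not count as events.
    """
    if total_time <= 0:
        raise ValueError("total_time must be > 0")
    n_compact = sum(1 for d in dwells if d.state == "compact" and not d.truncated)
    n_exposed = sum(1 for d in dwells if d.state == "exposed" and not d.truncated)
    return {
        "decompaction": n_compact / total_time,
        "compaction": n_exposed / total_time,
    }


def autocorrelation(series, dt: float, max_lag: float) -> AcfResult:
    """Normalized autocorrelation of a per-frame observable.

    acf(k) = sum (x_t - xbar)(x_{t+k} - xbar) / sum (x_t - xbar)^2, computed
    by FFT. The half-decay time is the first lag at which the ACF drops
    below 0.5, linearly interpolated between the bracketing lags.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("autocorrelation needs at least 10 frames")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("degenerate series: zero variance")
    n = x.size
    max_steps = min(int(round(max_lag / dt)), n - 1)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    corr = np.fft.irfft(f * np.conj(f), nfft)[: max_steps + 1]
    acf = corr / denom
    lags = np.arange(max_steps + 1) * dt
    half_decay = _half_decay(lags, acf)
    return AcfResult(lags=lags, acf=acf, half_decay=half_decay)


def _half_decay(lags, acf) -> float:
    below = np.flatnonzero(acf < 0.5)
    if below.size == 0:
        return float("nan")
    k = below[0]
    if k == 0:
        return 0.0
    a0, a1 = acf[k - 1], acf[k]
    frac = (a0 - 0.5) / (a0 - a1)
    return float(lags[k - 1] + frac * (lags[k] - lags[k - 1]))


def mean_autocorrelation(series_by_replicate, dt: float, max_lag: float) -> AcfResult:
    """ACF of a multi-replicate observable: per-replicate ACFs averaged at
    each lag, never crossing replicate boundaries."""
    results = [autocorrelation(s, dt, max_lag) for s in series_by_replicate]
    n_lags = min(r.acf.size for r in results)
    acf = np.mean([r.acf[:n_lags] for r in results], axis=0)
    lags = results[0].lags[:n_lags]
    return AcfResult(lags=lags, acf=acf, half_decay=_half_decay(lags, acf))
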