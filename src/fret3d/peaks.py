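"""Gaussian-mixture fitting of event-FRET histograms and peak degeneracy.

The pooled per-event apparent efficiencies form a histogram with one peak per
resolvable distance plus a dominant peak at E = 0 from donor-only binding
events.  The histogram is fitted as a Gaussian mixture by EM, with an
optional zero-anchored component (mean fixed at 0) for the donor-only
population; the number of free components is chosen by BIC.

When a molecule carries n sites, n(n-1)/2 distances are expected.  If fewer
peaks are detected than that triangular number, some peaks must be degenerate
(several equal distances under one peak); ``degenerate_expansions``
enumerates every way of assigning integer multiplicities to the detected
peaks so that they total n(n-1)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

_MIN_SD = 1e-3


@dataclass(frozen=True)
class GaussianPeak:
    mean: float
    sd: float
    weight: float
    sem: float
    n_events: float


@dataclass(frozen=True)
class ZeroPeak:
    """Donor-only population: mixture component with mean fixed at E = 0."""

    weight: float
    sd: float


@dataclass(frozen=True)
class PeakSet:
    """Fitted mixture, non-zero peaks sorted by mean E."""

    peaks: tuple
    zero_peak: ZeroPeak | None
    loglik: float
    bic: float
    n_total: int
    background_weight: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mean)))
        total = (
            sum(p.weight for p in self.peaks)
            + (self.zero_peak.weight if self.zero_peak else 0.0)
            + self.background_weight
        )
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        for p in self.peaks:
            if not 0.0 < p.mean < 1.0:
                raise ValueError("non-zero peak means must lie in (0, 1)")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.peaks])

    def to_dict(self) -> dict:
        d = {
            "peaks": [
                {"mean": p.mean, "sd": p.sd, "weight": p.weight, "sem": p.sem, "n": p.n_events}
                for p in self.peaks
            ],
            "loglik": self.loglik,
            "bic": self.bic,
            "n_total": self.n_total,
            "background_weight": self.background_weight,
        }
        d["zero_peak"] = (
            {"weight": self.zero_peak.weight, "sd": self.zero_peak.sd} if self.zero_peak else None
        )
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PeakSet":
        peaks = tuple(
            GaussianPeak(p["mean"], p["sd"], p["weight"], p["sem"], p["n"]) for p in d["peaks"]
        )
        zp = d.get("zero_peak")
        zero = ZeroPeak(zp["weight"], zp["sd"]) if zp else None
        return cls(peaks, zero, d.get("loglik", np.nan), d.get("bic", np.nan), d.get("n_total", 0),
                   background_weight=d.get("background_weight", 0.0))


@dataclass
class _Fit:
    means: np.ndarray      # free-component means
    sds: np.ndarray        # free-component SDs
    weights: np.ndarray    # free-component weights (of all events)
    resp_mass: np.ndarray  # free-component effective event counts
    zero_weight: float
    zero_sd: float
    with_zero: bool
    uniform_weight: float
    loglik: float
    bic: float


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _em_fit(xp: np.ndarray, n_zero: int, k_free: int, with_zero: bool,
            with_uniform: bool, rng: np.random.Generator,
            max_iter: int = 300, tol: float = 1e-7, init: str = "quantile"):
    """EM for a mixture of k Gaussians, an optional zero-censored component,
    and an optional uniform background on [0, 1].

    Efficiencies are clipped to [0, 1], so donor-only events whose averaged
    ratio falls below zero collapse onto an atom at exactly 0.  The zero
    component is therefore a normal censored at 0: probability mass 1/2 on
    the atom, density phi(x; 0, sigma0) for x > 0.  ``xp`` holds the strictly
    positive values; ``n_zero`` the atom count.
    """
    npos = len(xp)
    n = npos + n_zero
    if npos <= k_free:
        return None
    spread = max(xp.std(), 0.02)
    if init == "quantile":
        q = (np.arange(k_free) + 0.5) / k_free
        means = np.quantile(xp, q) + rng.normal(0.0, 0.01, k_free)
    elif init == "upper":
        # seed components above the donor-only spill region
        xs = xp[xp > 0.15]
        if len(xs) <= 2 * k_free:
            xs = xp
        q = (np.arange(k_free) + 0.5) / k_free
        means = np.quantile(xs, q) + rng.normal(0.0, 0.01, k_free)
    else:  # random data points, k-means-style restart
        means = np.sort(rng.choice(xp, size=k_free, replace=False))
    sds = np.full(k_free, max(spread / max(k_free, 1), 0.02))
    zero_sd = 0.03
    k_tot = k_free + int(with_zero) + int(with_uniform)
    w = np.full(k_tot, 1.0 / k_tot)
    # column layout: [zero?] + free comps + [uniform?]
    z_col = 0 if with_zero else None
    f0 = int(with_zero)
    u_col = k_tot - 1 if with_uniform else None
    ll_prev = -np.inf
    for _ in range(max_iter):
        logp = np.empty((npos, k_tot))
        zf = (xp[:, None] - means[None, :]) / sds[None, :]
        logp[:, f0:f0 + k_free] = (
            -0.5 * zf**2 - np.log(sds)[None, :] - _LOG_SQRT_2PI + np.log(w[f0:f0 + k_free])[None, :]
        )
        if with_zero:
            logp[:, z_col] = (
                -0.5 * (xp / zero_sd) ** 2 - np.log(zero_sd) - _LOG_SQRT_2PI + np.log(w[z_col])
            )
        if with_uniform:
            logp[:, u_col] = np.log(w[u_col])  # unit density on [0, 1]
        mx = logp.max(axis=1)
        log_norm = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
        ll = float(log_norm.sum())
        if n_zero:
            if not with_zero:
                return None  # atoms at 0 require the censored zero component
            ll += n_zero * (np.log(w[z_col]) + np.log(0.5))
        resp = np.exp(logp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if with_zero:
            nk[z_col] += n_zero
        if np.any(nk < 1e-8):
            for j in np.flatnonzero(nk < 1e-8):
                if j in (z_col, u_col):
                    continue
                means[j - f0] = xp[rng.integers(npos)]
                sds[j - f0] = spread
            w = np.full(k_tot, 1.0 / k_tot)
            ll_prev = -np.inf
            continue
        w = nk / n
        rf = resp[:, f0:f0 + k_free]
        means = (rf * xp[:, None]).sum(axis=0) / rf.sum(axis=0)
        var = (rf * (xp[:, None] - means[None, :]) ** 2).sum(axis=0) / rf.sum(axis=0)
        sds = np.sqrt(np.maximum(var, _MIN_SD**2))
        if with_zero:
            r0 = resp[:, z_col]
            # censored observations contribute E[v^2 | v <= 0] = sigma^2
            num = (r0 * xp**2).sum() + n_zero * zero_sd**2
            zero_sd = float(np.sqrt(max(num / nk[z_col], _MIN_SD**2)))
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    ll = ll_prev
    # weights (k_tot - 1) + free means + free SDs + zero SD
    p = (k_tot - 1) + 2 * k_free + int(with_zero)
    if p >= n:
        return None
    bic = -2.0 * ll + p * np.log(n)
    return _Fit(
        means.copy(), sds.copy(), w[f0:f0 + k_free].copy(), nk[f0:f0 + k_free].copy(),
        float(w[z_col]) if with_zero else 0.0, zero_sd, with_zero,
        float(w[u_col]) if with_uniform else 0.0, ll, bic,
    )


def _merge_unresolved(peaks, sd_factor: float):
    """Merge fitted components whose means are closer than sd_factor times
    the narrower SD: such pairs model one unresolvable peak, not two
    distances."""
    peaks = sorted(peaks, key=lambda p: p.mean)
    merged = True
    while merged and len(peaks) > 1:
        merged = False
        for i in range(len(peaks) - 1):
            a, b = peaks[i], peaks[i + 1]
            if b.mean - a.mean < sd_factor * min(a.sd, b.sd):
                w = a.weight + b.weight
                mean = (a.weight * a.mean + b.weight * b.mean) / w
                second = (
                    a.weight * (a.sd**2 + a.mean**2) + b.weight * (b.sd**2 + b.mean**2)
                ) / w
                sd = float(np.sqrt(max(second - mean**2, _MIN_SD**2)))
                n = a.n_events + b.n_events
                peaks[i] = GaussianPeak(mean, sd, w, sd / np.sqrt(max(n, 1.0)), n)
                del peaks[i + 1]
                merged = True
                break
    return peaks


def fit_peaks(events, k_max: int = 6, seed: int = 0, allow_zero_peak: bool = True,
              allow_background: bool = True, n_init: int = 4, min_events: int = 20,
              min_peak_weight: float = 0.10, merge_sd_factor: float = 1.0) -> PeakSet:
    """Fit the event-FRET distribution as a Gaussian mixture; pick k by BIC.

    The model is k free Gaussian peaks, optionally a zero-censored component
    for the donor-only population (required whenever events sit exactly at
    E = 0), and optionally a uniform background on [0, 1] that absorbs
    events blurred across binding-state changes.  All model sizes
    k = 1..k_max and both options are scored by BIC on the event values.

    Parameters
    ----------
    events : EventTable or array-like of E values
    k_max : maximum number of free (non-zero) components considered
    allow_zero_peak : consider models with the donor-only zero component
    allow_background : consider models with a uniform blur background
    min_peak_weight : components carrying less than this fraction of the
        total non-zero peak mass are reported as background, not as peaks
        (minor populations such as multi-acceptor binding states)
    """
    x = np.asarray(events.e_values() if hasattr(events, "e_values") else events, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array of efficiencies")
    if len(x) < min_events:
        raise ValueError(f"need at least {min_events} events, got {len(x)}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("efficiencies must lie in [0, 1]")
    n_zero = int((x == 0.0).sum())
    xp = x[x > 0.0]
    rng = np.random.default_rng(seed)
    best = None
    zero_options = (False, True) if allow_zero_peak else (False,)
    if n_zero and allow_zero_peak:
        zero_options = (True,)
    elif n_zero == 0 and float((x < 0.05).mean()) < 0.01:
        zero_options = (False,)  # no donor-only mass to model
    uniform_options = (False, True) if allow_background else (False,)
    inits = ["quantile", "upper"] + ["random"] * max(n_init - 2, 0)
    if len(xp) and float((xp <= 0.15).mean()) < 0.02:
        inits.remove("upper")  # redundant with the plain quantile init
    for with_zero in zero_options:
        for with_uniform in uniform_options:
            rising = 0
            prev_bic = np.inf
            for k_free in range(1, k_max + 1):
                candidate = None
                for init in inits:
                    fit = _em_fit(xp, n_zero, k_free, with_zero, with_uniform, rng, init=init)
                    if fit is None:
                        continue
                    if not np.all((fit.means > 0) & (fit.means < 1)):
                        continue
                    if candidate is None or fit.loglik > candidate.loglik:
                        candidate = fit
                if candidate is None:
                    continue
                if candidate.bic < prev_bic - 1e-9:
                    rising = 0
                else:
                    rising += 1
                prev_bic = candidate.bic
                if best is None or candidate.bic < best.bic - 1e-9:
                    best = candidate
                if rising >= 2:
                    break  # BIC worsening with k; larger models will not win
    if best is None:
        raise RuntimeError("mixture fitting failed for every model size")
    peaks = tuple(
        GaussianPeak(
            mean=float(best.means[j]),
            sd=float(best.sds[j]),
            weight=float(best.weights[j]),
            sem=float(best.sds[j] / np.sqrt(max(best.resp_mass[j], 1.0))),
            n_events=float(best.resp_mass[j]),
        )
        for j in range(len(best.means))
    )
    if merge_sd_factor > 0:
        peaks = tuple(_merge_unresolved(peaks, merge_sd_factor))
    background = best.uniform_weight
    if min_peak_weight > 0 and len(peaks) > 1:
        total_w = sum(p.weight for p in peaks)
        major = tuple(p for p in peaks if p.weight >= min_peak_weight * total_w)
        if not major:
            major = (max(peaks, key=lambda p: p.weight),)
        background += total_w - sum(p.weight for p in major)
        peaks = major
    zero = ZeroPeak(best.zero_weight, best.zero_sd) if best.with_zero else None
    return PeakSet(peaks, zero, best.loglik, best.bic, len(x),
                   background_weight=background)


def triangular_edge_count(n_sites: int) -> int:
    """Expected number of pairwise distances, m = n(n-1)/2."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return n_sites * (n_sites - 1) // 2


@dataclass(frozen=True)
class MultiplicityAssignment:
    """Integer multiplicity per detected peak, totalling n(n-1)/2."""

    multiplicities: tuple
    n_sites: int

    def __post_init__(self):
        object.__setattr__(self, "multiplicities", tuple(int(m) for m in self.multiplicities))
        if any(m < 1 for m in self.multiplicities):
            raise ValueError("multiplicities must be >= 1")
        if sum(self.multiplicities) != triangular_edge_count(self.n_sites):
            raise ValueError("multiplicities must sum to n(n-1)/2")

    @property
    def total(self) -> int:
        return sum(self.multiplicities)


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def degenerate_expansions(p_peaks: int, n_sites: int) -> list:
    """All ways of promoting p detected peaks to m = n(n-1)/2 distances.

    Returns every composition (mu_1, ..., mu_p) with mu_i >= 1 and
    sum mu_i = m, in lexicographic order.  A single assignment with all
    mu_i = 1 means no degeneracy is required.
    """
    if n_sites > 4:
        raise ValueError("multiplicity enumeration supports at most 4 sites")
    m = triangular_edge_count(n_sites)
    if not 1 <= p_peaks <= m:
        raise ValueError(f"p_peaks must be in [1, {m}] for n_sites={n_sites}")
    return [MultiplicityAssignment(c, n_sites) for c in _compositions(m, p_peaks)]


def histogram_tsv(values, path, bin_width: float = 0.02) -> None:
    """Export an efficiency histogram as TSV (bin_left, count)."""
    values = np.asarray(values, dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    pd.DataFrame({"bin_left": edges[:-1], "count": counts}).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )
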