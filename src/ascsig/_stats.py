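"""Vectorized survival statistics used throughout the pipeline.

The per-protein best-fit scan, the split-half simulation and the null
calibrations all need the two-group logrank statistic for thousands of
candidate group labelings over the *same* survival data.  ``SurvivalScan``
precomputes the risk-set structure (sorted times, distinct event times,
at-risk counts) once and then evaluates whole matrices of group indicators
with a handful of BLAS calls.  A one-dimensional Newton solver fits the Cox
partial likelihood for a single binary covariate (Breslow tie handling),
which is the only Cox model the analysis requires.

These routines are validated against lifelines in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = [
    "SurvivalScan",
    "logrank_p_value",
    "cox_binary_hr",
    "km_median",
    "CoxResult",
]

_MAX_BETA = 15.0  # |log HR| beyond this is treated as complete separation


class SurvivalScan:
    """Risk-set structure of one survival sample, reusable across group scans.

    Parameters
    ----------
    times : array of event/censoring times (months).
    events : boolean array, True where the event (relapse) was observed.
    """

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        if times.ndim != 1 or times.shape != events.shape:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if len(times) == 0:
            raise ValueError("empty survival sample")
        if np.any(times < 0) or not np.all(np.isfinite(times)):
            raise ValueError("times must be finite and non-negative")
        self.n = len(times)
        self._order = np.argsort(times, kind="stable")
        t = times[self._order]
        e = events[self._order].astype(float)
        starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
        d = np.add.reduceat(e, starts)
        keep = d > 0  # only distinct times with >=1 event contribute
        self._starts = starts[keep]
        self._d = d[keep]
        self._n_at = (self.n - self._starts).astype(float)
        self._e_sorted = e
        self.times = times
        self.events = events
        self.n_events = int(events.sum())

    # -- logrank ---------------------------------------------------------

    def logrank(self, groups):
        """Two-group logrank test for each column of ``groups``.

        Parameters
        ----------
        groups : (n,) or (n, m) boolean array; True marks the "high" group.

        Returns
        -------
        p : (m,) array of chi-square p-values (1.0 where the statistic is
            undefined, e.g. one group empty or no events).
        o_minus_e : (m,) observed-minus-expected events in the high group;
            positive values mean the high group relapses faster (HR > 1).
        var : (m,) hypergeometric variance of the statistic.
        """
        G = np.asarray(groups)
        squeeze = G.ndim == 1
        if squeeze:
            G = G[:, None]
        if G.shape[0] != self.n:
            raise ValueError("group indicator length does not match sample size")
        Gs = G[self._order].astype(float)
        if len(self._starts) == 0:
            shape = G.shape[1]
            out = (np.ones(shape), np.zeros(shape), np.zeros(shape))
            return tuple(x[0] for x in out) if squeeze else out
        # at-risk count of the high group at each distinct event time
        suff = np.cumsum(Gs[::-1], axis=0)[::-1]
        n1 = suff[self._starts]
        d1 = np.add.reduceat(Gs * self._e_sorted[:, None], self._starts, axis=0)
        d = self._d[:, None]
        n_at = self._n_at[:, None]
        frac = n1 / n_at
        o_minus_e = (d1 - d * frac).sum(axis=0)
        denom = np.where(n_at > 1, n_at - 1, 1.0)
        var = (d * frac * (1.0 - frac) * (n_at - d) / denom).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(var > 0, o_minus_e**2 / np.where(var > 0, var, 1.0), 0.0)
        p = np.where(var > 0, chi2.sf(stat, df=1), 1.0)
        if squeeze:
            return p[0], o_minus_e[0], var[0]
        return p, o_minus_e, var

    # -- Cox, single binary covariate ------------------------------------

    def _risk_counts(self, groups):
        G = np.asarray(groups)
        squeeze = G.ndim == 1
        if squeeze:
            G = G[:, None]
        Gs = G[self._order].astype(float)
        suff = np.cumsum(Gs[::-1], axis=0)[::-1]
        n1 = suff[self._starts]
        d1 = np.add.reduceat(Gs * self._e_sorted[:, None], self._starts, axis=0)
        return n1, d1, squeeze

    def cox_binary(self, groups, tol=1e-9, max_iter=60):
        """Breslow partial-likelihood HR of high (True) vs low, per column.

        Returns (hr, converged) arrays.  Complete separation is reported as
        ``inf`` (all events stacked on the high group) or ``0.0`` with
        ``converged=False``.
        """
        n1, d1, squeeze = self._risk_counts(groups)
        d = self._d[:, None]
        n_at = self._n_at[:, None]
        m = n1.shape[1]
        beta = np.zeros(m)
        active = np.ones(m, dtype=bool)
        if len(self._starts) == 0:
            hr = np.ones(m)
            conv = np.zeros(m, dtype=bool)
            return (hr[0], conv[0]) if squeeze else (hr, conv)
        for _ in range(max_iter):
            eb = np.exp(beta)
            s1 = n1 * eb  # risk-set weight of high group
            s0 = (n_at - n1) + s1
            r = np.where(s0 > 0, s1 / s0, 0.0)
            grad = (d1 - d * r).sum(axis=0)
            hess = (d * r * (1.0 - r)).sum(axis=0)
            step = np.where(hess > 1e-12, grad / np.where(hess > 1e-12, hess, 1.0), 0.0)
            step = np.clip(step, -2.0, 2.0)
            beta = np.where(active, beta + step, beta)
            done = np.abs(step) < tol
            active = active & ~done
            beta = np.clip(beta, -_MAX_BETA, _MAX_BETA)
            if not active.any():
                break
        converged = ~active & (np.abs(beta) < _MAX_BETA)
        hr = np.exp(beta)
        hr = np.where(beta >= _MAX_BETA, np.inf, hr)
        hr = np.where(beta <= -_MAX_BETA, 0.0, hr)
        if squeeze:
            return hr[0], bool(converged[0])
        return hr, converged


def logrank_p_value(times_a, events_a, times_b, events_b):
    """Standard two-group logrank chi-square p-value (nominal, unadjusted).

    If the statistic is undefined (no events, or a degenerate risk set) the
    p-value is reported as 1.0 with a warning.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate(
        [np.asarray(events_a, dtype=bool), np.asarray(events_b, dtype=bool)]
    )
    group = np.zeros(len(times), dtype=bool)
    group[: len(ta)] = True
    scan = SurvivalScan(times, events)
    p, _, var = scan.logrank(group)
    if var <= 0:
        warnings.warn("logrank statistic undefined (zero variance); p set to 1.0")
        return 1.0
    return float(p)


@dataclass
class CoxResult:
    hr: float
    converged: bool


def cox_binary_hr(times, events, group):
    """Univariate proportional-hazards HR for group=True vs group=False."""
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("both indicator levels must be present")
    scan = SurvivalScan(times, events)
    hr, converged = scan.cox_binary(group)
    return CoxResult(hr=float(hr), converged=bool(converged))


def km_median(times, events):
    """Kaplan-Meier median survival time; ``inf`` if the curve never
    reaches 0.5 (median not reached)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        return np.inf
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)
    n_at = len(times) - starts
    keep = d > 0
    if not keep.any():
        return np.inf
    surv = np.cumprod(1.0 - d[keep] / n_at[keep])
    hit = surv <= 0.5 + 1e-12
    if not hit.any():
        return np.inf
    return float(t[starts[keep][np.argmax(hit)]])
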