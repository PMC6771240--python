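"""Split-half robustness simulation for already-selected markers.

The cohort is randomly bisected into two equal halves (``n_reps`` times,
default 25, i.e. 50 simulated cohorts).  In each half every marker is
dichotomized at its *full-cohort* best-fit threshold (thresholds are not
refit — the simulation probes the stability of the selected marker
definition, not of the selection; ``refit_per_half=True`` refits for
comparison) and the logrank p and HR direction are recorded.

A marker is classified robust (adverse or favorable) when at least half of
the repetitions yield a significant p in *both* halves with a concordant
HR direction in both; the alternative median-p (< alpha) criterion is
reported as a separate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import SurvivalScan
from .core_data import CohortDataset
from .survival_assoc import DEFAULT_QUANTILE_GRID, _select_best

__all__ = [
    "SplitSimulationResult",
    "split_half_simulation",
    "classify_robustness",
]

ROBUST_ADVERSE = "robust_adverse"
ROBUST_FAVORABLE = "robust_favorable"
NOT_ROBUST = "not_robust"


@dataclass
class SplitSimulationResult:
    """Per-marker outcome of the split-half simulation: one (p, HR-sign)
    pair per simulated half-cohort (2 x n_reps in total)."""

    protein_id: str
    p_values: np.ndarray  # length 2*n_reps, halves interleaved per rep
    hr_signs: np.ndarray  # +1 / -1 (0 where undefined)
    median_p: float
    robust_class: str
    median_p_flag: bool = False
    qualifying_fraction: float = 0.0
    flagged_reps: list = field(default_factory=list)  # reps with a degenerate half


def split_half_simulation(
    cohort: CohortDataset,
    markers,
    n_reps: int = 25,
    seed: int = 0,
    alpha: float = 0.05,
    refit_per_half: bool = False,
    grid=DEFAULT_QUANTILE_GRID,
):
    """Run the bisection simulation; deterministic under ``seed``.

    ``markers`` maps protein id -> full-cohort threshold (e.g. the
    ``threshold`` column of the association table).  Returns a list of
    :class:`SplitSimulationResult`, one per marker, each carrying exactly
    ``2 * n_reps`` p-values.  Halves where a marker's dichotomization
    leaves a single group get p recorded as 1.0 and the rep flagged.
    """
    markers = dict(markers)
    pv = cohort.patient_values()
    times, events = cohort.survival_arrays(pv.index)
    n = len(pv)
    if n < 4:
        raise ValueError("cohort too small to bisect")
    ids = list(markers)
    X = pv[ids].to_numpy(dtype=float)
    thr = np.array([markers[p] for p in ids], dtype=float)

    rng = np.random.default_rng(seed)
    m = len(ids)
    p_store = np.ones((m, 2 * n_reps))
    sign_store = np.zeros((m, 2 * n_reps), dtype=int)
    flagged = [[] for _ in range(m)]

    for rep in range(n_reps):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2 :])  # odd n: sizes differ by 1
        for h, idx in enumerate(halves):
            scan = SurvivalScan(times[idx], events[idx])
            if refit_per_half:
                thr_h = np.array(
                    [
                        np.quantile(X[idx, j], grid)[
                            _select_best(
                                scan.logrank(
                                    X[idx, j][:, None] > np.quantile(X[idx, j], grid)[None, :]
                                )[0],
                                grid,
                            )
                        ]
                        for j in range(m)
                    ]
                )
            else:
                thr_h = thr
            G = X[idx][:, :] > thr_h[None, :]
            p, ome, var = scan.logrank(G)
            col = 2 * rep + h
            p_store[:, col] = np.where(var > 0, p, 1.0)
            sign_store[:, col] = np.sign(ome).astype(int)
            for j in np.flatnonzero(var <= 0):
                flagged[j].append(rep)

    results = []
    for j, pid in enumerate(ids):
        res = SplitSimulationResult(
            protein_id=pid,
            p_values=p_store[j].copy(),
            hr_signs=sign_store[j].copy(),
            median_p=float(np.median(p_store[j])),
            robust_class=NOT_ROBUST,
            flagged_reps=sorted(set(flagged[j])),
        )
        results.append(classify_robustness(res, alpha=alpha))
    return results


def classify_robustness(
    result: SplitSimulationResult, alpha: float = 0.05
) -> SplitSimulationResult:
    """Apply the >=50%-of-reps rule (class label) and the median-p flag.

    A rep qualifies as adverse when both of its halves have p < alpha and
    HR > 1 in both; favorable analogously with HR < 1.
    """
    p = np.asarray(result.p_values, dtype=float).reshape(-1, 2)
    s = np.asarray(result.hr_signs, dtype=int).reshape(-1, 2)
    sig_both = (p < alpha).all(axis=1)
    adverse = sig_both & (s > 0).all(axis=1)
    favorable = sig_both & (s < 0).all(axis=1)
    frac_adv = adverse.mean() if len(adverse) else 0.0
    frac_fav = favorable.mean() if len(favorable) else 0.0
    if frac_adv >= 0.5:
        robust_class, frac = ROBUST_ADVERSE, frac_adv
    elif frac_fav >= 0.5:
        robust_class, frac = ROBUST_FAVORABLE, frac_fav
    else:
        robust_class, frac = NOT_ROBUST, max(frac_adv, frac_fav)
    result.robust_class = robust_class
    result.qualifying_fraction = float(frac)
    result.median_p = float(np.median(result.p_values))
    result.median_p_flag = result.median_p < alpha
    return result
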