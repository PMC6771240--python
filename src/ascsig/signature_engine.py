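"""Threshold-indicator prognostic signatures: scoring, discovery, pairing.

A *signature* is an ordered set of proteins, each carrying a best-fit
abundance threshold and a risk direction (+1: high level is the
poor-prognosis side, from HR > 1; -1: low level is, from HR < 1).  A
patient's signature score is the fraction of the signature's proteins lying
on their risk side of their thresholds; a score above 0.5 predicts a short
relapse-free survival.

Two complementary signature types are searched for: type 1 signatures aim
to identify all long-term survivors, type 2 all short-term survivors.  The
search is an exhaustive scan for a 3-marker core (maximizing balanced
accuracy over the two survivor classes) followed by greedy forward
extension (singly or in pairs) under a lexicographic objective —
target-class accuracy first, other-class accuracy second, ties broken by
the smaller summed logrank p of the members.

A type-1/type-2 pair is combined per patient: if the two signatures
disagree on the short/long call the prediction is "not possible"
(abstention); otherwise the summed risk counts against the summed lengths
decide, with an exact tie also abstaining.  Pair performance is validated
by bootstrap resampling of patients without re-training.

On the scoring direction: the source analysis's verbatim scoring rule
("1 below the threshold") is inconsistent with its decision rule ("high
score predicts short RFS") for adverse markers; this module scores the
risk side (preserving the decision rule).  ``literal_below=True`` applies
the verbatim below-threshold rule for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import CohortDataset, SHORT, LONG

__all__ = [
    "SignatureDefinition",
    "SignatureScore",
    "SignaturePerformance",
    "CombinedPrediction",
    "score_signature",
    "evaluate_signature",
    "discover_core",
    "extend_signature",
    "combine_signatures",
    "search_signature_pairs",
    "bootstrap_performance",
    "build_signature_pool",
    "signatures_from_association",
]


@dataclass
class SignatureDefinition:
    """Ordered protein list with per-protein threshold and risk direction."""

    sig_type: int  # 1: identify all long-term survivors; 2: all short-term
    proteins: list
    thresholds: dict  # protein id -> abundance threshold
    risk_direction: dict  # protein id -> +1 (high = risk) or -1 (low = risk)

    def __post_init__(self):
        if self.sig_type not in (1, 2):
            raise ValueError("sig_type must be 1 or 2")
        if len(self.proteins) < 1:
            raise ValueError("signature must contain at least one protein")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("signature proteins must be unique")
        for p in self.proteins:
            if p not in self.thresholds or p not in self.risk_direction:
                raise ValueError(f"missing threshold/direction for {p!r}")
            if self.risk_direction[p] not in (+1, -1):
                raise ValueError(f"risk_direction for {p!r} must be +1 or -1")

    def __len__(self):
        return len(self.proteins)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sig_type": self.sig_type,
                "proteins": [
                    {
                        "id": p,
                        "threshold": self.thresholds[p],
                        "direction": self.risk_direction[p],
                    }
                    for p in self.proteins
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureDefinition":
        obj = json.loads(text)
        return cls(
            sig_type=obj["sig_type"],
            proteins=[e["id"] for e in obj["proteins"]],
            thresholds={e["id"]: e["threshold"] for e in obj["proteins"]},
            risk_direction={e["id"]: e["direction"] for e in obj["proteins"]},
        )


@dataclass
class SignatureScore:
    patient_id: str
    risk_count: int
    fraction: float
    predicts_short: bool


@dataclass
class SignaturePerformance:
    """Per-class correct-identification rates (percent).

    ``sensitivity_target_class``: % of the target class correctly called
    (long-term for type 1, short-term for type 2);
    ``rate_other_class``: % of the other class correctly called.
    """

    sig_type: int
    sensitivity_target_class: float
    rate_other_class: float
    n_short: int
    n_long: int
    defined: bool = True


@dataclass
class CombinedPrediction:
    patient_id: str
    consistent: bool
    combined_score: int
    max_score: int
    prediction: str  # "short" | "long" | "not_possible"


# ---------------------------------------------------------------------------
# scoring


def _indicator_matrix(values: pd.DataFrame, sig: SignatureDefinition, literal_below=False):
    """Boolean (patients x signature proteins) risk-indicator matrix."""
    missing = [p for p in sig.proteins if p not in values.columns]
    if missing:
        raise KeyError(f"missing protein value(s): {missing}")
    X = values[sig.proteins].to_numpy(dtype=float)
    thr = np.array([sig.thresholds[p] for p in sig.proteins], dtype=float)
    if literal_below:
        return X < thr[None, :]
    direction = np.array([sig.risk_direction[p] for p in sig.proteins])
    above = X > thr[None, :]
    return np.where(direction[None, :] == 1, above, ~above)


def score_signature(
    sig: SignatureDefinition, patient_values, patient_id=None, literal_below=False
) -> SignatureScore:
    """Score one patient: risk indicators summed over the signature.

    ``patient_values`` maps protein id -> abundance (Series or dict).  An
    indicator is set when the value lies on the protein's risk side of its
    threshold (strictly above for direction +1, at-or-below for -1).
    """
    if isinstance(patient_values, pd.Series):
        if patient_id is None:
            patient_id = patient_values.name
        row = patient_values.to_frame().T
    else:
        row = pd.DataFrame([patient_values])
    ind = _indicator_matrix(row, sig, literal_below=literal_below)[0]
    count = int(ind.sum())
    frac = count / len(sig)
    return SignatureScore(
        patient_id=patient_id,
        risk_count=count,
        fraction=frac,
        predicts_short=frac > 0.5,
    )


def _class_arrays(cohort: CohortDataset):
    """(values, y_short, y_long, classifiable_index) over classifiable
    patients with ascites measurements."""
    pv = cohort.patient_values()
    classes = cohort.clinical.survivor_class.reindex(pv.index)
    keep = classes.isin([SHORT, LONG]).to_numpy()
    pv = pv.loc[keep]
    classes = classes.loc[keep]
    return pv, (classes == SHORT).to_numpy(), (classes == LONG).to_numpy()


def evaluate_signature(
    sig: SignatureDefinition, cohort: CohortDataset, literal_below=False
) -> SignaturePerformance:
    """Per-class accuracy over classifiable (short/long) patients."""
    pv, y_short, y_long = _class_arrays(cohort)
    ind = _indicator_matrix(pv, sig, literal_below=literal_below)
    predicts_short = 2 * ind.sum(axis=1) > len(sig)
    n_short = int(y_short.sum())
    n_long = int(y_long.sum())
    short_rate = 100.0 * (predicts_short & y_short).sum() / n_short if n_short else np.nan
    long_rate = 100.0 * (~predicts_short & y_long).sum() / n_long if n_long else np.nan
    if sig.sig_type == 1:
        target, other = long_rate, short_rate
    else:
        target, other = short_rate, long_rate
    return SignaturePerformance(
        sig_type=sig.sig_type,
        sensitivity_target_class=target,
        rate_other_class=other,
        n_short=n_short,
        n_long=n_long,
        defined=bool(n_short and n_long),
    )


# ---------------------------------------------------------------------------
# discovery


def signatures_from_association(association: pd.DataFrame):
    """Thresholds and risk directions for every protein in an association
    table (``threshold`` and ``hr`` columns)."""
    thresholds = association["threshold"].to_dict()
    directions = {p: (1 if hr > 1.0 else -1) for p, hr in association["hr"].items()}
    return thresholds, directions


def _candidate_pool(association: pd.DataFrame, candidates=None):
    if candidates is None:
        if "significant" in association.columns:
            pool = list(association.index[association["significant"]])
        else:
            pool = list(association.index)
    else:
        pool = [p for p in candidates if p in association.index]
    return pool


def _objective_tuple(n_target_ok, n_other_ok, sum_p):
    # lexicographic: target-class correct count, other-class correct count,
    # then the smaller summed logrank p of the members
    return (n_target_ok, n_other_ok, -sum_p)


def _combo_chunks(n: int, k: int, chunk: int = 200_000):
    from itertools import islice

    it = combinations(range(n), k)
    while True:
        flat = np.fromiter(
            (i for combo in islice(it, chunk) for i in combo), dtype=np.int64
        )
        if flat.size == 0:
            return
        yield flat.reshape(-1, k)
        if flat.size < chunk * k:
            return


def discover_core(
    association: pd.DataFrame,
    cohort: CohortDataset,
    sig_type: int,
    core_size: int = 3,
    candidates=None,
    literal_below=False,
) -> SignatureDefinition:
    """Exhaustive search over all size-``core_size`` candidate subsets.

    The candidate pool defaults to the nominally significant proteins of
    the association table.  Objective: the core maximizes the *sum* of the
    two class rates (balanced accuracy), with ties broken toward the higher
    target-class rate and then the smaller summed logrank p of the members.
    A target-first lexicographic core objective is degenerate — it is
    maximized by conservative marker triples that never call the other
    class — so the balanced core is searched first and the target-first
    lexicographic refinement is left to the greedy extension.
    """
    pool = _candidate_pool(association, candidates)
    if len(pool) < core_size:
        raise ValueError(
            f"candidate pool of {len(pool)} is smaller than core_size={core_size}"
        )
    thresholds, directions = signatures_from_association(association)
    pv, y_short, y_long = _class_arrays(cohort)
    sig_all = SignatureDefinition(
        sig_type=sig_type,
        proteins=pool,
        thresholds={p: thresholds[p] for p in pool},
        risk_direction={p: directions[p] for p in pool},
    )
    I = _indicator_matrix(pv, sig_all, literal_below=literal_below).astype(np.int16)
    p_members = association.loc[pool, "p"].to_numpy(dtype=float)
    y_t = (y_long if sig_type == 1 else y_short).astype(np.float64)
    y_o = (y_short if sig_type == 1 else y_long).astype(np.float64)

    best = None
    best_combo = None
    for combos in _combo_chunks(len(pool), core_size):
        risk = I[:, combos].sum(axis=2)  # (n_pat, n_combos)
        predicts_short = 2 * risk > core_size
        correct_t = (~predicts_short if sig_type == 1 else predicts_short)
        correct_o = (predicts_short if sig_type == 1 else ~predicts_short)
        n_t = y_t @ correct_t
        n_o = y_o @ correct_o
        sum_p = p_members[combos].sum(axis=1)
        # balanced-accuracy argmax within the chunk (rates, not counts)
        r_t = n_t / max(y_t.sum(), 1.0)
        r_o = n_o / max(y_o.sum(), 1.0)
        order = np.lexsort((sum_p, -r_t, -(r_t + r_o)))
        i = order[0]
        cand = (r_t[i] + r_o[i], r_t[i], -sum_p[i])
        if best is None or cand > best:
            best = cand
            best_combo = combos[i]
    members = [pool[j] for j in best_combo]
    return SignatureDefinition(
        sig_type=sig_type,
        proteins=members,
        thresholds={p: thresholds[p] for p in members},
        risk_direction={p: directions[p] for p in members},
    )


def extend_signature(
    core: SignatureDefinition,
    association: pd.DataFrame,
    cohort: CohortDataset,
    max_len: int = 9,
    step: int = 2,
    candidates=None,
    literal_below=False,
) -> SignatureDefinition:
    """Greedy forward extension of a core signature.

    At each step the single candidate (``step=1``) or candidate pair
    (``step=2``) that maximizes the lexicographic objective is added;
    extension stops at ``max_len`` or when no addition strictly improves
    the objective.  Members are never removed.
    """
    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    if max_len < len(core):
        raise ValueError("max_len smaller than the core")
    pool = _candidate_pool(association, candidates)
    pool = [p for p in pool if p not in core.proteins]
    thresholds, directions = signatures_from_association(association)
    pv, y_short, y_long = _class_arrays(cohort)
    sig_type = core.sig_type
    y_t = (y_long if sig_type == 1 else y_short).astype(np.float64)
    y_o = (y_short if sig_type == 1 else y_long).astype(np.float64)
    p_assoc = association["p"]

    def objective(risk_counts, length, sum_p):
        predicts_short = 2 * risk_counts > length
        correct_t = ~predicts_short if sig_type == 1 else predicts_short
        correct_o = predicts_short if sig_type == 1 else ~predicts_short
        return _objective_tuple(float(y_t @ correct_t), float(y_o @ correct_o), sum_p)

    members = list(core.proteins)
    thr = {p: core.thresholds[p] for p in members}
    dirs = {p: core.risk_direction[p] for p in members}
    current_sig = SignatureDefinition(sig_type, members, thr, dirs)
    risk = _indicator_matrix(pv, current_sig, literal_below=literal_below).sum(axis=1)
    sum_p_members = float(p_assoc.reindex(members).fillna(1.0).sum())
    current_obj = objective(risk, len(members), sum_p_members)

    pool_sig = (
        SignatureDefinition(
            sig_type,
            pool,
            {p: thresholds[p] for p in pool},
            {p: directions[p] for p in pool},
        )
        if pool
        else None
    )
    I_pool = (
        _indicator_matrix(pv, pool_sig, literal_below=literal_below).astype(np.int16)
        if pool
        else None
    )
    p_pool = p_assoc.reindex(pool).fillna(1.0).to_numpy() if pool else None
    in_sig = np.zeros(len(pool), dtype=bool)

    while len(members) < max_len and pool:
        remaining = np.flatnonzero(~in_sig)
        if remaining.size == 0:
            break
        s = step if (step == 1 or max_len - len(members) >= 2) else 1
        if s == 2 and remaining.size >= 2:
            pairs = np.array(list(combinations(remaining, 2)), dtype=np.int64)
            add_risk = I_pool[:, pairs[:, 0]] + I_pool[:, pairs[:, 1]]
            add_p = p_pool[pairs].sum(axis=1)
            idx_sets = pairs
        else:
            add_risk = I_pool[:, remaining]
            add_p = p_pool[remaining]
            idx_sets = remaining[:, None]
        length = len(members) + idx_sets.shape[1]
        new_risk = risk[:, None] + add_risk
        predicts_short = 2 * new_risk > length
        correct_t = ~predicts_short if sig_type == 1 else predicts_short
        correct_o = predicts_short if sig_type == 1 else ~predicts_short
        n_t = y_t @ correct_t
        n_o = y_o @ correct_o
        total_p = sum_p_members + add_p
        order = np.lexsort((total_p, -n_o, -n_t))
        i = order[0]
        cand_obj = _objective_tuple(n_t[i], n_o[i], total_p[i])
        if cand_obj[:2] <= current_obj[:2]:
            break  # no strict improvement on the class rates
        chosen = idx_sets[i]
        for j in chosen:
            members.append(pool[j])
            in_sig[j] = True
        risk = risk + add_risk[:, i]
        sum_p_members = float(total_p[i])
        current_obj = cand_obj
    return SignatureDefinition(
        sig_type,
        members,
        {p: (core.thresholds.get(p, thresholds.get(p))) for p in members},
        {p: (core.risk_direction.get(p, directions.get(p))) for p in members},
    )


# ---------------------------------------------------------------------------
# combination & validation


def combine_signatures(
    sig1: SignatureDefinition,
    sig2: SignatureDefinition,
    cohort: CohortDataset,
    literal_below=False,
):
    """Combined prediction of a type-1/type-2 signature pair.

    Per patient: if the two signatures disagree on the short/long call the
    outcome is ``not_possible``; otherwise the summed risk counts decide —
    strictly above half the summed signature lengths predicts short,
    strictly below predicts long, an exact tie abstains.

    Returns ``(predictions, summary)`` where ``summary`` counts correct,
    false and abstained calls over classifiable patients.
    """
    if sig1.sig_type != 1 or sig2.sig_type != 2:
        raise ValueError("expects a (type 1, type 2) signature pair")
    pv = cohort.patient_values()
    classes = cohort.clinical.survivor_class.reindex(pv.index)
    i1 = _indicator_matrix(pv, sig1, literal_below=literal_below)
    i2 = _indicator_matrix(pv, sig2, literal_below=literal_below)
    c1 = i1.sum(axis=1)
    c2 = i2.sum(axis=1)
    s1 = 2 * c1 > len(sig1)
    s2 = 2 * c2 > len(sig2)
    consistent = s1 == s2
    combined = c1 + c2
    max_score = len(sig1) + len(sig2)
    prediction = np.where(
        ~consistent,
        "not_possible",
        np.where(
            2 * combined > max_score,
            SHORT,
            np.where(2 * combined < max_score, LONG, "not_possible"),
        ),
    )
    predictions = [
        CombinedPrediction(
            patient_id=pid,
            consistent=bool(consistent[i]),
            combined_score=int(combined[i]),
            max_score=max_score,
            prediction=str(prediction[i]),
        )
        for i, pid in enumerate(pv.index)
    ]
    classifiable = classes.isin([SHORT, LONG]).to_numpy()
    actual = classes.to_numpy()
    made = (prediction != "not_possible") & classifiable
    n_correct = int((made & (prediction == actual)).sum())
    n_false = int((made & (prediction != actual)).sum())
    n_abstain = int((classifiable & (prediction == "not_possible")).sum())
    n_classifiable = int(classifiable.sum())
    summary = {
        "n_classifiable": n_classifiable,
        "n_correct": n_correct,
        "n_false": n_false,
        "n_abstain": n_abstain,
        "correct_fraction": n_correct / n_classifiable if n_classifiable else np.nan,
        "n_predicted_short": int((made & (prediction == SHORT)).sum()),
        "n_predicted_long": int((made & (prediction == LONG)).sum()),
    }
    return predictions, summary


def search_signature_pairs(
    type1_pool: Sequence[SignatureDefinition],
    type2_pool: Sequence[SignatureDefinition],
    cohort: CohortDataset,
    literal_below=False,
):
    """Evaluate every type-1 x type-2 pair; keep pairs with zero false
    predictions, ranked by the fraction of classifiable patients correctly
    predicted.  Returns a list of dicts (sig1, sig2, summary)."""
    results = []
    for s1 in type1_pool:
        for s2 in type2_pool:
            _, summary = combine_signatures(s1, s2, cohort, literal_below=literal_below)
            if summary["n_false"] == 0:
                results.append({"sig1": s1, "sig2": s2, "summary": summary})
    # rank by correct fraction; on ties prefer the shorter (more
    # parsimonious, less overfit) pair
    results.sort(
        key=lambda r: (
            -r["summary"]["correct_fraction"],
            len(r["sig1"]) + len(r["sig2"]),
        )
    )
    return results


@dataclass
class BootstrapResult:
    median_correct_fraction: float
    ci_low: float
    ci_high: float
    values: np.ndarray
    n_missing: int = 0


def bootstrap_performance(
    sig1: SignatureDefinition,
    sig2: SignatureDefinition,
    cohort: CohortDataset,
    n_boot: int = 500,
    seed: int = 0,
    literal_below=False,
) -> BootstrapResult:
    """Bootstrap the combined predictor over resampled patient sets.

    Patients are resampled with replacement (same n); the signatures are
    *not* re-trained per resample.  Returns the median correct fraction and
    the percentile 95% interval over ``n_boot`` replicates; resamples with
    zero classifiable patients are recorded as missing and excluded.
    """
    pv = cohort.patient_values()
    classes = cohort.clinical.survivor_class.reindex(pv.index)
    i1 = _indicator_matrix(pv, sig1, literal_below=literal_below)
    i2 = _indicator_matrix(pv, sig2, literal_below=literal_below)
    c1 = i1.sum(axis=1)
    c2 = i2.sum(axis=1)
    s1 = 2 * c1 > len(sig1)
    s2 = 2 * c2 > len(sig2)
    max_score = len(sig1) + len(sig2)
    combined = c1 + c2
    prediction = np.where(
        s1 != s2,
        "not_possible",
        np.where(
            2 * combined > max_score,
            SHORT,
            np.where(2 * combined < max_score, LONG, "not_possible"),
        ),
    )
    actual = classes.to_numpy()
    classifiable = classes.isin([SHORT, LONG]).to_numpy()
    correct = (prediction == actual) & classifiable

    rng = np.random.default_rng(seed)
    n = len(pv)
    values = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        n_cls = classifiable[idx].sum()
        if n_cls == 0:
            continue
        values[b] = correct[idx].sum() / n_cls
    ok = ~np.isnan(values)
    n_missing = int((~ok).sum())
    if n_missing:
        import warnings

        warnings.warn(f"{n_missing} bootstrap resample(s) had no classifiable patients")
    kept = values[ok]
    return BootstrapResult(
        median_correct_fraction=float(np.median(kept)),
        ci_low=float(np.percentile(kept, 2.5)),
        ci_high=float(np.percentile(kept, 97.5)),
        values=values,
        n_missing=n_missing,
    )


def build_signature_pool(
    association: pd.DataFrame,
    cohort: CohortDataset,
    sig_type: int,
    lengths=(3, 5, 7, 9),
    steps=(1, 2),
    core_size: int = 3,
    candidates=None,
    n_random_cores: int = 0,
    subsample: float = 0.6,
    seed: int = 0,
    literal_below=False,
):
    """A pool of signatures of one type for pair search.

    The deterministic part is the exhaustive core plus its greedy
    extensions at each requested length and step size.  Optionally,
    ``n_random_cores`` additional cores are discovered on random
    ``subsample`` fractions of the candidate pool and extended likewise —
    a randomized exploration of marker combinations that diversifies the
    pool beyond one greedy chain.
    """
    base_pool = _candidate_pool(association, candidates)
    rng = np.random.default_rng(seed)
    candidate_sets = [base_pool]
    for _ in range(n_random_cores):
        k = max(core_size, int(round(subsample * len(base_pool))))
        if k >= len(base_pool):
            candidate_sets.append(base_pool)
        else:
            idx = rng.choice(len(base_pool), size=k, replace=False)
            candidate_sets.append([base_pool[i] for i in sorted(idx)])
    pool = []
    seen = set()
    for cand in candidate_sets:
        if len(cand) < core_size:
            continue
        core = discover_core(
            association,
            cohort,
            sig_type,
            core_size=core_size,
            candidates=cand,
            literal_below=literal_below,
        )
        for step in steps:
            for L in sorted(set(lengths)):
                if L < core_size:
                    continue
                sig = (
                    core
                    if L == core_size
                    else extend_signature(
                        core,
                        association,
                        cohort,
                        max_len=L,
                        step=step,
                        candidates=cand,
                        literal_below=literal_below,
                    )
                )
                key = tuple(sig.proteins)
                if key not in seen:
                    seen.add(key)
                    pool.append(sig)
    return pool
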