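"""Twelve procedures for converting occurrence probabilities to presence/absence.

A prediction is called "present" when probability ≥ t.  Four procedures set
the threshold directly (observed prevalence, mean predicted probability, the
presence/absence mean-probability midpoint, and fixed 0.5); the other eight
optimize an objective over a candidate set consisting of the sorted unique
probabilities, the midpoints between consecutive values, and {0, 1} — which
contains a global optimum of every objective because confusion counts are
step functions changing only at observed probabilities.  Ties in
optimization resolve to the smallest optimal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROCEDURES = (
    "ObsPrev",
    "AvgProb",
    "PRplot",
    "ROC",
    "SeSpeql",
    "TSS",
    "Fmeasure",
    "Kappa",
    "MidptProb",
    "OPS",
    "PredPrevObs",
    "Fixed",
)

# Procedures whose rule needs both observed classes.
_NEEDS_BOTH_CLASSES = frozenset(
    {"PRplot", "ROC", "SeSpeql", "TSS", "Fmeasure", "Kappa", "OPS", "PredPrevObs", "MidptProb"}
)
# Procedures defined by optimizing an objective over candidate thresholds.
OPTIMIZED = frozenset(
    {"PRplot", "ROC", "SeSpeql", "TSS", "Fmeasure", "Kappa", "OPS", "PredPrevObs"}
)
# Of those, these minimize a discrepancy (stored objective is the natural,
# minimized value; the maximizers store the maximized value).
MINIMIZED = frozenset({"PRplot", "ROC", "SeSpeql", "PredPrevObs"})


@dataclass(frozen=True)
class ThresholdSpec:
    procedure: str
    value: float
    objective: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.value}")


@dataclass(frozen=True)
class ConfusionCounts:
    """a: hits, b: false presences, c: misses, d: correct absences."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _validate(probabilities, observations) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    o = np.asarray(observations)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != o.shape:
        raise ValueError("probabilities and observations must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(o, (0, 1))):
        raise ValueError("observations must be binary")
    return p, o.astype(int)


def confusion(probabilities, observations, t: float) -> ConfusionCounts:
    """Confusion counts at threshold ``t`` (present iff probability ≥ t)."""
    p, o = _validate(probabilities, observations)
    pred = p >= t
    return ConfusionCounts(
        a=int(np.sum(pred & (o == 1))),
        b=int(np.sum(pred & (o == 0))),
        c=int(np.sum(~pred & (o == 1))),
        d=int(np.sum(~pred & (o == 0))),
    )


def candidate_thresholds(probabilities: np.ndarray) -> np.ndarray:
    """Sorted unique probabilities, their midpoints, and {0, 1}."""
    u = np.unique(np.asarray(probabilities, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate([[0.0, 1.0], u, mids]))


def _confusion_grid(p: np.ndarray, o: np.ndarray, ts: np.ndarray):
    """Vectorized confusion counts at every threshold in ``ts``."""
    order = np.argsort(p, kind="mergesort")
    sp, so = p[order], o[order]
    cum_pos = np.concatenate([[0], np.cumsum(so)])
    total_pos = cum_pos[-1]
    n = len(p)
    idx = np.searchsorted(sp, ts, side="left")  # count of entries < t
    pos_below = cum_pos[idx]
    a = total_pos - pos_below
    c = pos_below
    b = (n - idx) - a
    d = idx - pos_below
    return a.astype(float), b.astype(float), c.astype(float), d.astype(float)


def _kappa_vec(a, b, c, d):
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    with np.errstate(invalid="ignore", divide="ignore"):
        k = (po - pe) / (1.0 - pe)
    return np.where(np.isclose(pe, 1.0), 0.0, k)


def _objectives(a, b, c, d, prevalence):
    """objective arrays keyed by procedure; larger-is-better convention."""
    n = a + b + c + d
    pos, neg = a + c, b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(pos > 0, a / pos, np.nan)
        spec = np.where(neg > 0, d / neg, np.nan)
        precision = np.where(a + b > 0, a / (a + b), np.nan)
        f1 = np.where(2 * a + b + c > 0, 2 * a / (2 * a + b + c), 0.0)
    pred_prev = (a + b) / n
    pr_gap = np.abs(precision - sens)
    pr_gap = np.where(np.isnan(pr_gap), np.inf, pr_gap)
    return {
        "TSS": sens + spec - 1.0,
        "Kappa": _kappa_vec(a, b, c, d),
        "Fmeasure": f1,
        "OPS": (a + d) / n,
        "ROC": -np.sqrt((1.0 - spec) ** 2 + (1.0 - sens) ** 2),
        "SeSpeql": -np.abs(sens - spec),
        "PRplot": -pr_gap,
        "PredPrevObs": -np.abs(pred_prev - prevalence),
    }


def select_threshold(probabilities, observations, procedure: str) -> ThresholdSpec:
    """Threshold under one procedure; see module docstring for the rules."""
    return select_all_thresholds(probabilities, observations, (procedure,))[procedure]


def select_all_thresholds(
    probabilities, observations, procedures=PROCEDURES
) -> dict[str, ThresholdSpec]:
    """All requested procedures at once (shares the candidate-grid scan)."""
    p, o = _validate(probabilities, observations)
    prevalence = float(o.mean())
    one_class = prevalence in (0.0, 1.0)
    out: dict[str, ThresholdSpec] = {}

    needed = [proc for proc in procedures if proc in OPTIMIZED]
    if needed:
        if one_class:
            raise ValueError(
                f"procedure {needed[0]} requires both observed classes "
                f"(observed prevalence {prevalence})"
            )
        ts = candidate_thresholds(p)
        a, b, c, d = _confusion_grid(p, o, ts)
        objs = _objectives(a, b, c, d, prevalence)

    for proc in procedures:
        if proc == "Fixed":
            out[proc] = ThresholdSpec(proc, 0.5)
        elif proc == "ObsPrev":
            out[proc] = ThresholdSpec(proc, prevalence)
        elif proc == "AvgProb":
            out[proc] = ThresholdSpec(proc, float(p.mean()))
        elif proc == "MidptProb":
            if one_class:
                raise ValueError("procedure MidptProb requires both observed classes")
            mid = 0.5 * (p[o == 1].mean() + p[o == 0].mean())
            out[proc] = ThresholdSpec(proc, float(np.clip(mid, 0.0, 1.0)))
        elif proc in OPTIMIZED:
            vals = objs[proc]
            best = np.nanmax(vals)
            # candidates are sorted ascending; first optimum = smallest threshold
            i = int(np.flatnonzero(vals >= best - 0.0)[0])
            obj = -float(vals[i]) if proc in MINIMIZED else float(vals[i])
            out[proc] = ThresholdSpec(proc, float(ts[i]), objective=obj)
        else:
            raise ValueError(f"unknown thresholding procedure {proc!r}; known: {PROCEDURES}")
    return out


def binary_map(probabilities, spec: ThresholdSpec) -> np.ndarray:
    """Apply a threshold spec: 1 where probability ≥ value, else 0."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    return (p >= spec.value).astype(int)
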