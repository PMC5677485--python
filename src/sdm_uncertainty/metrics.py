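"""Binary-prediction skill metrics: kappa, TSS, rank AUC, prevalence match.

All four are computed per (species, covariate set, threshold, split) cell;
for mixed-effects modeling each is mapped to the unit interval where
necessary (kappa and TSS via (x + 1)/2), clamped away from {0, 1}, and
logit transformed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .thresholding import ConfusionCounts

#: metrics whose natural range is [-1, 1] and need (x+1)/2 before logit
SIGNED_METRICS = frozenset({"kappa", "tss"})
METRICS = ("kappa", "tss", "auc", "prevalence_match")


def kappa(cc: ConfusionCounts) -> float:
    """Cohen's kappa: chance-corrected agreement from the confusion table."""
    n = cc.n
    if n == 0:
        raise ValueError("empty confusion table")
    po = (cc.a + cc.d) / n
    pe = ((cc.a + cc.b) * (cc.a + cc.c) + (cc.c + cc.d) * (cc.b + cc.d)) / n**2
    if np.isclose(pe, 1.0):
        warnings.warn("degenerate margins (chance agreement = 1); kappa set to 0")
        return 0.0
    return float((po - pe) / (1.0 - pe))


def tss(cc: ConfusionCounts) -> float:
    """True Skill Statistic: sensitivity + specificity − 1."""
    pos, neg = cc.a + cc.c, cc.b + cc.d
    if pos == 0 or neg == 0:
        raise ValueError("TSS requires both observed classes")
    return float(cc.a / pos + cc.d / neg - 1.0)


def auc(probabilities, observations) -> float:
    """Rank-based (Mann–Whitney) AUC with half credit for ties."""
    p = np.asarray(probabilities, dtype=float)
    o = np.asarray(observations).astype(int)
    n1 = int(o.sum())
    n0 = len(o) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both observed classes")
    ranks = rankdata(p)  # average ranks handle ties with 0.5 credit
    u = ranks[o == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def prevalence_match(predicted_binary, observations, method: str = "difference") -> float:
    """Agreement between predicted and observed prevalence.

    ``difference``: 1 − |p̂ − p| (default).  ``ratio``: min(p̂, p)/max(p̂, p)
    (1 when both are zero).
    """
    yhat = np.asarray(predicted_binary).astype(float)
    y = np.asarray(observations).astype(float)
    if yhat.size == 0:
        raise ValueError("empty input")
    phat, p = yhat.mean(), y.mean()
    if method == "difference":
        return float(1.0 - abs(phat - p))
    if method == "ratio":
        hi = max(phat, p)
        return 1.0 if hi == 0 else float(min(phat, p) / hi)
    raise ValueError(f"unknown prevalence_match method {method!r}")


def logit_metric(x: float, metric: str | None = None, eps: float = 1e-6) -> float:
    """Logit transform after mapping to (0, 1).

    Metrics ranging over [-1, 1] (kappa, TSS) are first mapped via
    (x + 1)/2; the value is then clamped into [eps, 1 − eps].
    """
    v = (x + 1.0) / 2.0 if metric in SIGNED_METRICS else float(x)
    v = min(max(v, eps), 1.0 - eps)
    return float(np.log(v / (1.0 - v)))


def metric_bundle(test_probs, test_obs, predicted_binary, eps: float = 1e-6,
                  prevalence_method: str = "difference") -> dict[str, float]:
    """kappa/TSS/AUC/prevalence-match (and logit twins) for one cell.

    AUC is computed on the continuous probabilities (pre-threshold); the
    other three use the supplied binary map.
    """
    yhat = np.asarray(predicted_binary).astype(int)
    y = np.asarray(test_obs).astype(int)
    cc = ConfusionCounts(
        a=int(np.sum((yhat == 1) & (y == 1))),
        b=int(np.sum((yhat == 1) & (y == 0))),
        c=int(np.sum((yhat == 0) & (y == 1))),
        d=int(np.sum((yhat == 0) & (y == 0))),
    )
    vals = {
        "kappa": kappa(cc),
        "tss": tss(cc),
        "auc": auc(test_probs, y),
        "prevalence_match": prevalence_match(yhat, y, method=prevalence_method),
    }
    for name in METRICS:
        vals[f"{name}_logit"] = logit_metric(vals[name], metric=name, eps=eps)
    return vals
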