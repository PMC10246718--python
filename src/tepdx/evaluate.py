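"""Diagnostic-statistics battery for the TEP classifier and CA125.

AUCs use the Mann-Whitney estimator with DeLong structural-component
variance; paired marker comparisons use the two-sided DeLong test.
Confusion-matrix metrics carry exact Clopper-Pearson CIs; the battery also
covers permutation-null p-values, fixed-specificity operating points,
calibration curves, decision-curve analysis (net benefit) and the clinical
subgroup harness (endometriosis / borderline / early-stage / non-epithelial /
high-grade-serous contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "DecisionCurve",
    "auc_with_ci",
    "delong_components",
    "delong_test",
    "binary_metrics",
    "metrics_from_rates",
    "permutation_test",
    "sens_at_spec",
    "calibration_curve",
    "decision_curve",
    "subgroup_report",
]

CA125_CUTOFF = 35.0  # mU/L


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticMetrics:
    acc: float
    sn: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    kappa: float
    f1: float | None
    acc_ci: tuple = (None, None)
    sn_ci: tuple = (None, None)
    sp_ci: tuple = (None, None)
    ppv_ci: tuple = (None, None)
    npv_ci: tuple = (None, None)
    auc: float | None = None
    auc_ci: tuple = (None, None)
    auc_pvalue: float | None = None

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "acc": self.acc,
            "acc_ci": list(self.acc_ci),
            "sn": self.sn,
            "sn_ci": list(self.sn_ci),
            "sp": self.sp,
            "sp_ci": list(self.sp_ci),
            "ppv": self.ppv,
            "ppv_ci": list(self.ppv_ci),
            "npv": self.npv,
            "npv_ci": list(self.npv_ci),
            "kappa": self.kappa,
            "f1": self.f1,
            "auc_pvalue": self.auc_pvalue,
        }


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.treat_none is None:
            self.treat_none = np.zeros_like(np.asarray(self.thresholds, dtype=float))


# ---------------------------------------------------------------------------
# AUC with DeLong inference
# ---------------------------------------------------------------------------


def _positive_mask(labels) -> np.ndarray:
    """Boolean mask of the positive class (OC when present, else 1, else the
    lexicographically larger label)."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if "OC" in classes:
        return labels == "OC"
    if set(classes) == {0, 1}:
        return labels == 1
    return labels == classes[-1]


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    return scores[pos], scores[~pos]


def delong_components(scores, labels):
    """Structural components (V10 per positive, V01 per negative) and the AUC."""
    x, y = _split_scores(scores, labels)
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def auc_with_ci(scores, labels, level: float = 0.95):
    """Mann-Whitney AUC (ties count 1/2) with DeLong variance and normal CI."""
    v10, v01, auc = delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return auc, var, (lo, hi)


def delong_test(scores_a, scores_b, labels):
    """Two-sided DeLong comparison of two correlated AUCs on the same samples.

    Returns ``(z, p)``; a zero-variance difference (e.g. a marker against a
    monotone transform of itself) yields p = 1 with a warning.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must have identical shape")
    va10, va01, auc_a = delong_components(scores_a, labels)
    vb10, vb01, auc_b = delong_components(scores_b, labels)
    m, n = len(va10), len(va01)

    def _var(u):
        return np.var(u, ddof=1) if len(u) > 1 else 0.0

    def _cov(u, v):
        return np.cov(u, v, ddof=1)[0, 1] if len(u) > 1 else 0.0

    var = (
        _var(va10) / m
        + _var(vb10) / m
        - 2 * _cov(va10, vb10) / m
        + _var(va01) / n
        + _var(vb01) / n
        - 2 * _cov(va01, vb01) / n
    )
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) > 0:
            warnings.warn("zero DeLong variance with nonzero AUC difference")
        else:
            warnings.warn("zero variance of the AUC difference; p set to 1")
        return 0.0, 1.0
    z = delta / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------


def _rate_ci(k: int, n: int, level: float = 0.95):
    if n == 0:
        return (None, None)
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return (float(lo), float(hi))


def binary_metrics(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticMetrics:
    """ACC/SN/SP/PPV/NPV with exact Clopper-Pearson CIs, plus kappa and F1.

    Rates with a zero denominator are reported as missing (None), never as 0.
    """
    N = cm.total
    acc = (cm.tp + cm.tn) / N
    npos, nneg = cm.tp + cm.fn, cm.tn + cm.fp
    ppos, pneg = cm.tp + cm.fp, cm.tn + cm.fn
    sn = cm.tp / npos if npos else None
    sp = cm.tn / nneg if nneg else None
    ppv = cm.tp / ppos if ppos else None
    npv = cm.tn / pneg if pneg else None
    pe = (ppos * npos + pneg * nneg) / N**2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0
    f1 = (2 * ppv * sn / (ppv + sn)) if (ppv and sn and (ppv + sn) > 0) else None
    return DiagnosticMetrics(
        acc=acc,
        sn=sn,
        sp=sp,
        ppv=ppv,
        npv=npv,
        kappa=kappa,
        f1=f1,
        acc_ci=_rate_ci(cm.tp + cm.tn, N, level),
        sn_ci=_rate_ci(cm.tp, npos, level) if npos else (None, None),
        sp_ci=_rate_ci(cm.tn, nneg, level) if nneg else (None, None),
        ppv_ci=_rate_ci(cm.tp, ppos, level) if ppos else (None, None),
        npv_ci=_rate_ci(cm.tn, pneg, level) if pneg else (None, None),
    )


def metrics_from_rates(sn: float, sp: float, n_pos: int, n_neg: int):
    """Rebuild a confusion matrix (and metrics) from printed SN/SP percentages.

    ``sn`` and ``sp`` are percentages in [0, 100]. Cell counts are rounded to
    the nearest integer; if the reconstructed rate then differs from the input
    by more than 0.05 percentage points a warning carries both values.
    """
    if not (0 <= sn <= 100 and 0 <= sp <= 100):
        raise ValueError("sn and sp must be percentages in [0, 100]")
    tp = int(round(sn * n_pos / 100))
    tn = int(round(sp * n_neg / 100))
    cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    for name, stated, rebuilt in (("sn", sn, 100 * tp / n_pos if n_pos else None),
                                  ("sp", sp, 100 * tn / n_neg if n_neg else None)):
        if rebuilt is not None and abs(rebuilt - stated) > 0.05:
            warnings.warn(f"{name} inconsistent after rounding: stated {stated}, rebuilt {rebuilt:.2f}")
    return cm, binary_metrics(cm)


# ---------------------------------------------------------------------------
# permutation null, operating points, calibration, decision curves
# ---------------------------------------------------------------------------


def permutation_test(scores, labels, B: int = 999, seed: int = 0) -> float:
    """Add-one permutation p-value for the observed AUC against label shuffles."""
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _, _, auc_obs = delong_components(scores, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(labels)
        _, _, auc_p = delong_components(scores, perm)
        if auc_p >= auc_obs:
            hits += 1
    return (1 + hits) / (B + 1)


def sens_at_spec(scores, labels, spec: float = 0.90):
    """Sensitivity at the smallest threshold reaching the target specificity.

    Candidate thresholds are midpoints between adjacent distinct scores plus
    +/- infinity sentinels; positivity is score >= threshold. Returns
    ``(sensitivity, attained_specificity, threshold)``.
    """
    x, y = _split_scores(scores, labels)
    s = np.unique(np.concatenate([x, y]))
    mids = (s[:-1] + s[1:]) / 2 if len(s) > 1 else np.array([])
    cand = np.concatenate(([-np.inf], s[:1], mids, [np.inf]))
    cand = np.unique(cand)
    for t in cand:  # ascending: the first qualifying threshold is the smallest
        spec_t = np.mean(y < t)
        if spec_t >= spec:
            return float(np.mean(x >= t)), float(spec_t), float(t)
    t = np.inf
    return float(np.mean(x >= t)), float(np.mean(y < t)), float(t)


def calibration_curve(probs, labels, bins: int = 10) -> pd.DataFrame:
    """Reliability table over equal-width probability bins (empty bins omitted)."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    yb = _positive_mask(labels)
    edges = np.linspace(0, 1, bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        m = which == b
        if m.any():
            rows.append(
                {
                    "bin": b,
                    "mean_predicted": float(probs[m].mean()),
                    "observed_rate": float(yb[m].mean()),
                    "n": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


def decision_curve(probs, labels, thresholds) -> DecisionCurve:
    """Net benefit NB(p_t) = TP/N - FP/N * p_t/(1-p_t) across thresholds.

    Positivity is prob >= p_t; treat-all and treat-none reference strategies
    are included. Thresholds must lie strictly inside (0, 1).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    yb = _positive_mask(labels)
    N = len(yb)
    prev = yb.mean()
    nb, ta = [], []
    for t in thresholds:
        called = probs >= t
        tp = np.sum(called & yb) / N
        fp = np.sum(called & ~yb) / N
        w = t / (1 - t)
        nb.append(tp - fp * w)
        ta.append(prev - (1 - prev) * w)
    return DecisionCurve(
        thresholds=thresholds, net_benefit=np.array(nb), treat_all=np.array(ta)
    )


# ---------------------------------------------------------------------------
# subgroup harness
# ---------------------------------------------------------------------------

EARLY_STAGES = {"I", "IA", "IB", "IC", "II", "IIA"}


def is_early_stage(figo) -> pd.Series:
    """FIGO I-IIA count as early stage; IIB-IV as late."""
    s = pd.Series(figo, dtype="object")
    return s.isin(EARLY_STAGES)


def default_subgroups(meta: pd.DataFrame) -> dict:
    """Boolean (positives, controls) masks for the standard clinical contrasts."""
    cls = meta["class"]
    oc = cls == "OC"
    bam = cls == "BAM"
    early = is_early_stage(meta["figo_stage"])
    return {
        "endometriosis_vs_oc": (oc, meta["histology"] == "endometriosis"),
        "borderline_vs_bam": (oc & (meta["histology"] == "borderline"), bam),
        "early_stage_vs_bam": (oc & early, bam),
        "non_epithelial_vs_bam": (oc & (meta["histology"] == "non_epithelial"), bam),
        "hgsoc_vs_bam": (oc & (meta["histology"] == "serous") & (meta["grade"] == "poor"), bam),
    }


def _marker_metrics(scores: np.ndarray, calls: np.ndarray, y: np.ndarray) -> DiagnosticMetrics:
    auc, _, ci = auc_with_ci(scores, y)
    cm = ConfusionMatrix(
        tp=int(np.sum(calls & (y == 1))),
        fp=int(np.sum(calls & (y == 0))),
        tn=int(np.sum(~calls & (y == 0))),
        fn=int(np.sum(~calls & (y == 1))),
    )
    m = binary_metrics(cm)
    m.auc, m.auc_ci = auc, ci
    return m


def subgroup_report(
    meta: pd.DataFrame,
    tep_probs: pd.Series,
    ca125: pd.Series,
    combined_probs: pd.Series | None = None,
    groups: dict | None = None,
    threshold: float = 0.5,
) -> dict:
    """Full metric panels per clinical subgroup and marker.

    For each subgroup the three markers (TEP panel, CA125, combination) are
    evaluated with full metrics and a DeLong comparison against CA125 on the
    CA125-complete subset. Empty subgroups are skipped with a warning.
    """
    groups = groups if groups is not None else default_subgroups(meta)
    report = {}
    for name, (pos_mask, neg_mask) in groups.items():
        pos_mask = np.asarray(pos_mask, dtype=bool)
        neg_mask = np.asarray(neg_mask, dtype=bool)
        if not pos_mask.any() or not neg_mask.any():
            warnings.warn(f"subgroup {name!r} empty on one side; skipped")
            continue
        sel = pos_mask | neg_mask
        y = pos_mask[sel].astype(int)
        idx = meta.index[sel]
        entry = {"n_pos": int(pos_mask.sum()), "n_neg": int(neg_mask.sum()), "markers": {}}

        tep = tep_probs.loc[idx].to_numpy(dtype=float)
        ca = ca125.loc[idx].to_numpy(dtype=float)
        markers = {"tep": (tep, tep >= threshold)}
        ca_ok = ~np.isnan(ca)
        if ca_ok.any() and len(np.unique(y[ca_ok])) == 2:
            markers["ca125"] = (ca, ca >= CA125_CUTOFF)
        if combined_probs is not None:
            comb = combined_probs.loc[idx].to_numpy(dtype=float)
            markers["combined"] = (comb, comb >= threshold)

        for mname, (scores, calls) in markers.items():
            if mname == "ca125":
                m = _marker_metrics(scores[ca_ok], calls[ca_ok], y[ca_ok])
            else:
                m = _marker_metrics(scores, calls, y)
            if "ca125" in markers and ca_ok.sum() >= 4:
                # comparison vs CA125 on the complete-case subset
                _, p = delong_test(scores[ca_ok], markers["ca125"][0][ca_ok] if mname != "ca125" else scores[ca_ok], y[ca_ok])
                m.auc_pvalue = p
            entry["markers"][mname] = m
        report[name] = entry
    return report
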