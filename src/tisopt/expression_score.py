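"""Expression scoring: ROC/AUC, likelihood ratios, 4PL fit, posterior score.

Lower opening energy predicts expression success ("less than type"): at a
threshold t, records with opening energy <= t are called positive.  From the
cumulative TP/FP/TN/FN counts a positive likelihood ratio
``PLR(t) = sensitivity / (1 - specificity)`` is computed per threshold, a
four-parameter logistic ``y = d + (a - d) / (1 + (x/c)^b)`` is fitted to
PLR against the opening-energy threshold, and Bayes' rule turns a prior
probability of success (0.49 by default, the historical proportion of
expressed over cloned constructs) into a posterior:

    posterior odds = prior odds * fitted PLR(opening energy)
    Expression Score = 100 * posterior odds / (1 + posterior odds)
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score

from .core_seq import LabeledDataset

__all__ = [
    "DEFAULT_PRIOR",
    "PlrCurve",
    "FourPL",
    "ScoreModel",
    "roc_auc",
    "plr",
    "plr_curve",
    "bootstrap_plr_ci",
    "fit_4pl",
    "fit_score_model",
    "expression_score",
    "ks_distance",
]

#: proportion of 'Expressed' (21,046) over 'Cloned' (42,774) targets
DEFAULT_PRIOR = round(21_046 / 42_774, 2)


def roc_auc(dataset: LabeledDataset, orientation: str = "lower_is_positive") -> float:
    """AUC of opening energy as a predictor of success (midrank tie handling).

    Equals the normalized Mann-Whitney pair statistic.  With the default
    orientation, lower opening energy scores toward the positive (success)
    class.
    """
    dataset.require_both_classes()
    x = dataset.opening_energy
    if orientation == "lower_is_positive":
        x = -x
    elif orientation != "higher_is_positive":
        raise ValueError(f"unknown orientation {orientation!r}")
    return float(roc_auc_score(dataset.outcome, x))


def plr(tp: int, fn: int, fp: int, tn: int) -> float:
    """Positive likelihood ratio (tp/(tp+fn)) / (fp/(fp+tn)).

    ``fp = 0`` with ``tp > 0`` returns +inf (flagged sentinel); counts must
    be non-negative with both classes represented.
    """
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("need at least one record in each outcome class")
    sens = tp / (tp + fn)
    fpr = fp / (fp + tn)
    if fpr == 0.0:
        return math.inf if sens > 0 else math.nan
    return sens / fpr


@dataclass
class PlrCurve:
    """Threshold-wise cumulative counts and positive likelihood ratios."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    plr: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = self.tp + self.fn
        neg = self.fp + self.tn
        if len(set(pos.tolist())) != 1 or len(set(neg.tolist())) != 1:
            raise ValueError("TP+FN and FP+TN must be constant across thresholds")

    def to_frame(self):
        import pandas as pd

        data = {
            "threshold": self.thresholds, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn, "plr": self.plr,
        }
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)


def plr_curve(dataset: LabeledDataset, thresholds=None) -> PlrCurve:
    """Cumulative "less than type" likelihood-ratio curve.

    Positives at threshold t are records with opening energy <= t; by
    construction the curve at the maximum observed threshold has FN = 0.
    Default thresholds are every distinct observed energy.
    """
    dataset.require_both_classes()
    if thresholds is None:
        thresholds = np.unique(dataset.opening_energy)
    else:
        thresholds = np.asarray(sorted(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold list")
    x = dataset.opening_energy
    y = dataset.outcome
    tps, fps, tns, fns, ratios = [], [], [], [], []
    for t in thresholds:
        called = x <= t
        tp = int(np.sum(called & (y == 1)))
        fp = int(np.sum(called & (y == 0)))
        fn = int(np.sum(~called & (y == 1)))
        tn = int(np.sum(~called & (y == 0)))
        tps.append(tp)
        fps.append(fp)
        tns.append(tn)
        fns.append(fn)
        ratios.append(plr(tp, fn, fp, tn))
    return PlrCurve(
        thresholds=thresholds,
        tp=np.array(tps), fp=np.array(fps), tn=np.array(tns), fn=np.array(fns),
        plr=np.array(ratios, dtype=float),
    )


def bootstrap_plr_ci(dataset: LabeledDataset, threshold: float,
                     b: int = 10_000, seed: int | None = None,
                     max_redraws: int = 10) -> tuple[float, float]:
    """Percentile 95% CI of the PLR at one threshold, B resamples of records.

    Resamples with a class absent are redrawn up to ``max_redraws`` times and
    then dropped with a warning.  Deterministic per seed.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    dataset.require_both_classes()
    rng = np.random.default_rng(seed)
    x = dataset.opening_energy
    y = dataset.outcome
    n = len(dataset)
    values = np.empty(b)
    dropped = 0
    for rep in range(b):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            ys = y[idx]
            if 0 < ys.sum() < n:
                break
        else:
            values[rep] = np.nan
            dropped += 1
            continue
        xs = x[idx]
        called = xs <= threshold
        tp = int(np.sum(called & (ys == 1)))
        fp = int(np.sum(called & (ys == 0)))
        values[rep] = plr(tp, int((ys == 1).sum()) - tp, fp,
                          int((ys == 0).sum()) - fp)
    if dropped:
        warnings.warn(f"dropped {dropped} degenerate bootstrap replicates")
    finite = values[np.isfinite(values)]
    if finite.size < b // 2:
        warnings.warn("more than half of bootstrap replicates were non-finite")
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass(frozen=True)
class FourPL:
    """Four-parameter logistic y = d + (a - d) / (1 + (x/c)^b), c > 0."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("4PL midpoint c must be > 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)
        return float(out) if out.ndim == 0 else out

    @property
    def decreasing(self) -> bool:
        """True when the curve is monotone decreasing for x > 0."""
        return self.b * (self.a - self.d) > 0


def _4pl_residuals(params, x, y, w):
    a, b, logc, d = params
    with np.errstate(over="ignore"):
        pred = d + (a - d) / (1.0 + (x / math.exp(logc)) ** b)
    return (pred - y) * w


def fit_4pl(x, y, weights=None) -> tuple[FourPL, dict]:
    """Least-squares 4PL fit with multi-start initialization.

    Non-finite points are excluded (counted in the diagnostics); at least 4
    finite points are required.  Returns (FourPL, diagnostics) where the
    diagnostics carry the residual norm, convergence flag and exclusions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0)
    n_excluded = int((~keep).sum())
    x, y, w = x[keep], y[keep], w[keep]
    if x.size < 4:
        raise ValueError(f"need >= 4 finite points to fit a 4PL, got {x.size}")

    if np.ptp(y) == 0.0:
        const = float(y[0])
        model = FourPL(a=const, b=1.0, c=float(np.median(x)), d=const)
        return model, {"residual_norm": 0.0, "converged": True,
                       "n_excluded": n_excluded, "degenerate": True}

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    spread = y_hi - y_lo
    starts = []
    for b0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        for cq in (0.25, 0.5, 0.75):
            c0 = float(np.quantile(x, cq))
            starts.append((y_hi + 0.05 * spread, b0, math.log(max(c0, 1e-6)),
                           y_lo - 0.05 * spread))
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                _4pl_residuals, p0, args=(x, y, w), method="lm",
                max_nfev=20_000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("4PL fit failed to converge from every start")
    a, b, logc, d = best.x
    model = FourPL(a=float(a), b=float(b), c=float(math.exp(logc)), d=float(d))
    diagnostics = {
        "residual_norm": float(np.linalg.norm(best.fun)),
        "converged": bool(best.success),
        "n_excluded": n_excluded,
        "degenerate": False,
    }
    if not best.success:
        diagnostics["message"] = best.message
    return model, diagnostics


@dataclass
class ScoreModel:
    """Fitted 4PL likelihood-ratio curve plus a prior success probability."""

    fourpl: FourPL
    prior: float = DEFAULT_PRIOR
    provenance: str = ""
    diagnostics: dict = field(default_factory=dict)
    lr_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError(f"prior must be in (0, 1), got {self.prior}")

    def score(self, oe: float) -> float:
        """Expression Score in [0, 100] for an opening energy (kcal/mol)."""
        lr = self.fourpl(oe)
        if lr <= 0:
            warnings.warn(f"fitted likelihood ratio {lr:.3g} <= 0 at "
                          f"{oe} kcal/mol; clamped")
            lr = self.lr_floor
        prior_odds = self.prior / (1.0 - self.prior)
        odds = prior_odds * lr
        return 100.0 * odds / (1.0 + odds)

    def score_rounded(self, oe: float) -> int:
        return round(self.score(oe))

    def to_json(self, path=None) -> str:
        payload = {
            "fourpl": {"a": self.fourpl.a, "b": self.fourpl.b,
                       "c": self.fourpl.c, "d": self.fourpl.d},
            "prior": self.prior,
            "provenance": self.provenance,
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ScoreModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as handle:
                    payload = json.load(handle)
        return cls(
            fourpl=FourPL(**payload["fourpl"]),
            prior=payload.get("prior", DEFAULT_PRIOR),
            provenance=payload.get("provenance", ""),
            diagnostics=payload.get("diagnostics", {}),
        )


def expression_score(oe: float, model: ScoreModel) -> float:
    """Expression Score (percent) for one opening energy under a fitted model."""
    return model.score(oe)


def fit_score_model(dataset: LabeledDataset, thresholds=None,
                    prior: float | str = DEFAULT_PRIOR,
                    min_count: int = 5, n_thresholds: int = 60,
                    bootstrap_b: int = 0, seed: int | None = None,
                    provenance: str = "") -> ScoreModel:
    """Fit the full PLR -> 4PL -> posterior pipeline on a labeled dataset.

    Thresholds default to ``n_thresholds`` energy quantiles; thresholds with
    fewer than ``min_count`` cumulative TP or FP are excluded from the fit
    (the ratio is unstable there), as are infinite ratios (their count is
    logged in the diagnostics).  ``prior`` may be the string "empirical" to
    use the dataset prevalence.  When ``bootstrap_b`` > 0, percentile CIs
    are attached to the curve.
    """
    dataset.require_both_classes()
    if thresholds is None:
        qs = np.linspace(0.02, 0.98, n_thresholds)
        thresholds = np.unique(np.quantile(dataset.opening_energy, qs))
    curve = plr_curve(dataset, thresholds)
    if bootstrap_b:
        los, his = [], []
        rng = np.random.default_rng(seed)
        for t in curve.thresholds:
            lo, hi = bootstrap_plr_ci(dataset, float(t), b=bootstrap_b,
                                      seed=int(rng.integers(2**31)))
            los.append(lo)
            his.append(hi)
        curve.ci_low = np.array(los)
        curve.ci_high = np.array(his)
    stable = (curve.tp >= min_count) & (curve.fp >= min_count) & np.isfinite(curve.plr)
    n_infinite = int(np.sum(~np.isfinite(curve.plr)))
    model4, diag = fit_4pl(curve.thresholds[stable], curve.plr[stable])
    diag["n_infinite_plr"] = n_infinite
    diag["n_thresholds_fit"] = int(stable.sum())
    prior_value = dataset.n_success / len(dataset) if prior == "empirical" else float(prior)
    return ScoreModel(
        fourpl=model4,
        prior=prior_value,
        provenance=provenance or f"fitted on {len(dataset)} records "
                                 f"({dataset.n_success} successes); prior={prior}",
        diagnostics=diag,
    )


def ks_distance(sample_a, sample_b) -> float:
    """Kolmogorov-Smirnov statistic: sup-norm distance between empirical CDFs."""
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("KS distance needs non-empty samples")
    return float(stats.ks_2samp(sample_a, sample_b).statistic)
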