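"""Clinical calibration of functional scores.

Benchmarks a score map against pathogenic / proxy-benign reference variant
sets (balanced precision-recall curves, AUBPRC, R90BP) and transforms
scores into natural-log likelihood ratios of pathogenicity (LLRp) via
kernel density estimates of the two reference score distributions, with
bootstrap confidence intervals and ACMG/AMP-style categorical evidence
strengths on the Tavtigian odds-of-pathogenicity scale.

Balanced precision re-weights the reference sets 50/50:

    balanced precision = recall / (recall + FPR)

which equals the precision that would be observed with equally sized
positive and negative sets.  Densities use the Epanechnikov kernel with a
Sheather–Jones bandwidth (computed for the Gaussian kernel and converted
through the canonical-kernel ratio).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import ReferenceSets

#: canonical-bandwidth conversion Gaussian -> Epanechnikov:
#: (R(K)/sigma_K^4)^(1/5) ratio = 15^(1/5) / (1/(2 sqrt(pi)))^(1/5)
EPANECHNIKOV_FACTOR = (15.0 ** 0.2) / ((0.5 / np.sqrt(np.pi)) ** 0.2)

DENSITY_FLOOR_FRACTION = 1e-6

#: odds of pathogenicity for "very strong" evidence (Tavtigian et al. framework)
DEFAULT_OP_VST = 350.0

PATHOGENIC_LEVELS = ("supporting", "moderate", "strong", "very_strong")


def _phi4(t: np.ndarray) -> np.ndarray:
    return (t**4 - 6 * t**2 + 3) * stats.norm.pdf(t)


def _phi6(t: np.ndarray) -> np.ndarray:
    return (t**6 - 15 * t**4 + 45 * t**2 - 15) * stats.norm.pdf(t)


def sheather_jones_bandwidth(x: np.ndarray) -> float:
    """Sheather–Jones solve-the-equation bandwidth (Gaussian kernel).

    Follows the original two-stage plug-in construction: pilot bandwidths
    from the scale estimate lambda = min(sd, IQR/1.349), pilot functionals
    from the 4th/6th Gaussian-density derivatives, and the fixed point of

        h = ( R(phi) / (n * S(alpha2(h))) )^(1/5)

    found by root bracketing.  Raises for degenerate (constant) samples.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations for a bandwidth")
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    lam = min(sd, iqr / 1.349) if iqr > 0 else sd
    if lam <= 0:
        raise ValueError("zero bandwidth: sample is constant")

    # pilot bandwidths; 1.24 = 0.920 * 1.349 etc. for the combined scale estimate
    a = 1.24 * lam * n ** (-1 / 7)
    b = 1.23 * lam * n ** (-1 / 9)
    diffs = x[:, None] - x[None, :]
    s_a = _phi4(diffs / a).sum() / (n * n * a**5)
    t_b = -_phi6(diffs / b).sum() / (n * n * b**7)
    if s_a <= 0 or t_b <= 0:
        raise ValueError("Sheather–Jones pilot functionals degenerate")

    c1 = 1.0 / (2.0 * np.sqrt(np.pi) * n)
    ratio = 1.357 * (s_a / t_b) ** (1 / 7)

    def objective(h: float) -> float:
        alpha2 = ratio * h ** (5 / 7)
        s = _phi4(diffs / alpha2).sum() / (n * n * alpha2**5)
        if s <= 0:
            return np.inf
        return (c1 / s) ** 0.2 - h

    h0 = 1.06 * lam * n ** (-1 / 5)
    lo, hi = h0 / 20.0, h0 * 5.0
    flo, fhi = objective(lo), objective(hi)
    tries = 0
    while flo * fhi > 0 and tries < 10:
        lo /= 2.0
        hi *= 2.0
        flo, fhi = objective(lo), objective(hi)
        tries += 1
    if flo * fhi > 0:
        return h0  # fall back to the normal-reference rule
    return float(optimize.brentq(objective, lo, hi, xtol=1e-6 * h0))


class EpanechnikovKDE:
    """Univariate KDE with the Epanechnikov kernel K(u) = 3/4 (1 - u^2).

    Bandwidth defaults to Sheather–Jones (converted from the Gaussian
    kernel through the canonical-kernel ratio).
    """

    def __init__(self, data: np.ndarray, bandwidth: float | None = None):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 1 or len(self.data) == 0:
            raise ValueError("data must be a non-empty 1-d array")
        if bandwidth is None:
            bandwidth = EPANECHNIKOV_FACTOR * sheather_jones_bandwidth(self.data)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.bandwidth = float(bandwidth)

    @property
    def support(self) -> tuple[float, float]:
        return (
            float(self.data.min() - self.bandwidth),
            float(self.data.max() + self.bandwidth),
        )

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        u = (x[:, None] - self.data[None, :]) / self.bandwidth
        k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
        return k.mean(axis=1) / self.bandwidth


@dataclass
class CalibrationReport:
    """Benchmark and calibration results for one map and reference pair."""

    curve: pd.DataFrame
    aubprc: float
    r90bp: float
    per_variant: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _resolve_scores(
    scores: pd.DataFrame, variants: list[str], set_name: str, min_n: int = 5
) -> np.ndarray:
    lookup = scores.set_index("hgvs_p")["score"]
    vals, unscored = [], []
    for v in variants:
        s = lookup.get(v, np.nan)
        if np.isfinite(s):
            vals.append(float(s))
        else:
            unscored.append(v)
    if len(vals) < min_n:
        raise ValueError(
            f"{set_name} reference set has only {len(vals)} scored variants "
            f"(need >= {min_n}); unscored: {unscored[:10]}"
        )
    return np.array(vals)


def confusion_summary(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Precision / recall / FPR / balanced precision from confusion counts."""
    pos, neg = tp + fn, fp + tn
    called = tp + fp
    recall = tp / pos if pos else np.nan
    fpr = fp / neg if neg else np.nan
    precision = tp / called if called else np.nan
    bp = recall / (recall + fpr) if (recall + fpr) > 0 else np.nan
    return {
        "precision": precision,
        "recall": recall,
        "fpr": fpr,
        "balanced_precision": bp,
    }


def balanced_prc_curve(
    scores: pd.DataFrame, refsets: ReferenceSets, min_n: int = 5
) -> CalibrationReport:
    """Balanced precision vs recall curve with AUBPRC and R90BP.

    Orientation is lower-score-more-pathogenic: at each threshold t a
    variant is called pathogenic when score <= t (ties go to the
    pathogenic side).  AUBPRC integrates the curve over recall by
    trapezoid after keeping the maximum balanced precision at each
    distinct recall; R90BP is the maximum recall at balanced precision
    >= 0.90 (0 when never reached).
    """
    pos = _resolve_scores(scores, refsets.positives, "positive", min_n)
    neg = _resolve_scores(scores, refsets.negatives, "negative", min_n)
    thresholds = np.unique(np.concatenate([pos, neg]))

    rows = []
    for t in thresholds:
        tp = int((pos <= t).sum())
        fp = int((neg <= t).sum())
        m = confusion_summary(tp, fp, len(neg) - fp, len(pos) - tp)
        if m["recall"] == 0 and m["fpr"] == 0:
            continue
        rows.append(dict(threshold=float(t), recall=m["recall"], fpr=m["fpr"],
                         balanced_precision=m["balanced_precision"]))
    curve = pd.DataFrame(rows)

    best = curve.groupby("recall")["balanced_precision"].max().sort_index()
    recalls = best.index.to_numpy()
    bps = best.to_numpy()
    # extend to recall 0 with the leftmost observed balanced precision
    recalls = np.concatenate([[0.0], recalls])
    bps = np.concatenate([[bps[0]], bps])
    aubprc = float(np.trapezoid(bps, recalls))

    ok = best[best >= 0.90]
    r90bp = float(ok.index.max()) if len(ok) else 0.0
    return CalibrationReport(
        curve=curve, aubprc=aubprc, r90bp=r90bp,
        meta={"n_pos": len(pos), "n_neg": len(neg)},
    )


def _floored_density(kde: EpanechnikovKDE, x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    floor = DENSITY_FLOOR_FRACTION * kde.pdf(grid).max()
    return np.maximum(kde.pdf(x), floor)


def kde_llr(
    scores: pd.DataFrame | np.ndarray,
    refsets: ReferenceSets | None = None,
    *,
    pos_scores: np.ndarray | None = None,
    neg_scores: np.ndarray | None = None,
    query: np.ndarray | None = None,
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-variant natural-log likelihood ratio of pathogenicity.

    Separate Epanechnikov/Sheather–Jones densities f_P and f_B are fit to
    the positive and negative reference score sets; LLRp(s) =
    ln(f_P(s) / f_B(s)).  Query scores outside the joint support are
    clamped to its nearest edge and both densities are floored at 1e-6 of
    their maximum before the ratio, so LLRp is finite everywhere.

    Either pass a score table plus ``refsets`` (queries default to every
    scored variant), or raw ``pos_scores`` / ``neg_scores`` / ``query``
    arrays.
    """
    if pos_scores is None or neg_scores is None:
        if refsets is None:
            raise ValueError("need refsets or explicit pos_scores/neg_scores")
        pos_scores = _resolve_scores(scores, refsets.positives, "positive", min_n)
        neg_scores = _resolve_scores(scores, refsets.negatives, "negative", min_n)
    if query is None:
        if isinstance(scores, pd.DataFrame):
            q_df = scores[scores["score"].notna()]
            query = q_df["score"].to_numpy(dtype=float)
            labels = q_df["hgvs_p"].to_numpy()
        else:
            query = np.asarray(scores, dtype=float)
            labels = None
    else:
        query = np.asarray(query, dtype=float)
        labels = None

    f_p = EpanechnikovKDE(np.asarray(pos_scores, dtype=float))
    f_b = EpanechnikovKDE(np.asarray(neg_scores, dtype=float))
    lo = min(f_p.support[0], f_b.support[0])
    hi = max(f_p.support[1], f_b.support[1])
    grid = np.linspace(lo, hi, 512)
    clamped = np.clip(query, lo, hi)
    # difference of logs (not log of ratio) so set-swap antisymmetry is exact
    llr = np.log(_floored_density(f_p, clamped, grid)) - np.log(
        _floored_density(f_b, clamped, grid)
    )
    out = pd.DataFrame({"score": query, "llr": llr})
    if labels is not None:
        out.insert(0, "hgvs_p", labels)
    out.attrs["bandwidths"] = {"positive": f_p.bandwidth, "negative": f_b.bandwidth}
    out.attrs["support"] = (lo, hi)
    return out


def llr_confidence_intervals(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    query: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for LLRp.

    Each resample draws both reference sets with replacement
    (independently), refits both densities (bandwidth included), and
    re-evaluates LLRp at every query score.  Resamples with a degenerate
    (constant) set are dropped and counted.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile CIs")
    rng = np.random.default_rng(seed)
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    query = np.asarray(query, dtype=float)
    draws = np.empty((n_boot, len(query)))
    dropped = 0
    kept = 0
    for _ in range(n_boot):
        p = pos[rng.integers(0, len(pos), len(pos))]
        b = neg[rng.integers(0, len(neg), len(neg))]
        try:
            res = kde_llr(None, pos_scores=p, neg_scores=b, query=query, min_n=2)
        except ValueError:
            dropped += 1
            continue
        draws[kept] = res["llr"].to_numpy()
        kept += 1
    if kept == 0:
        raise ValueError("all bootstrap resamples degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(draws[:kept], [100 * alpha, 100 * (1 - alpha)], axis=0)
    out = pd.DataFrame({"ci_lo": lo, "ci_hi": hi})
    out.attrs["n_dropped"] = dropped
    return out


def evidence_thresholds(op_vst: float = DEFAULT_OP_VST) -> dict[str, float]:
    """LLRp thresholds for supporting/moderate/strong/very-strong evidence.

    Evidence strengths halve the exponent of the very-strong odds of
    pathogenicity: supporting = op^(1/8), moderate = op^(1/4), strong =
    op^(1/2), very strong = op; benign-side thresholds are the negations.
    """
    if op_vst <= 1:
        raise ValueError("op_vst must exceed 1")
    return {
        "supporting": np.log(op_vst) / 8.0,
        "moderate": np.log(op_vst) / 4.0,
        "strong": np.log(op_vst) / 2.0,
        "very_strong": np.log(op_vst),
    }


def evidence_strength(
    llr: float,
    ci: tuple[float, float] | None = None,
    op_vst: float = DEFAULT_OP_VST,
    ci_gated: bool = True,
) -> str:
    """Categorical ACMG/AMP-style evidence from an LLRp value.

    Pathogenic-side categories require LLRp to reach the corresponding
    threshold; the benign side is mirrored.  With ``ci_gated`` (default) a
    non-indeterminate category is assigned only when the CI excludes 0 on
    the opposite side, which guards against over-calling from sparse
    reference sets.
    """
    th = evidence_thresholds(op_vst)
    if ci_gated and ci is not None:
        ci_lo, ci_hi = ci
        if llr > 0 and ci_lo <= 0:
            return "indeterminate"
        if llr < 0 and ci_hi >= 0:
            return "indeterminate"
    for level in reversed(PATHOGENIC_LEVELS):
        if llr >= th[level]:
            return f"{level}_pathogenic"
    for level in reversed(PATHOGENIC_LEVELS):
        if llr <= -th[level]:
            return f"{level}_benign"
    return "indeterminate"


def calibrate(
    scores: pd.DataFrame,
    refsets: ReferenceSets,
    n_boot: int = 500,
    seed: int = 0,
    op_vst: float = DEFAULT_OP_VST,
    ci_gated: bool = True,
) -> CalibrationReport:
    """Full calibration: curve, AUBPRC/R90BP, LLRp with CI and evidence."""
    report = balanced_prc_curve(scores, refsets)
    pos = _resolve_scores(scores, refsets.positives, "positive", 20)
    neg = _resolve_scores(scores, refsets.negatives, "negative", 20)
    llr = kde_llr(scores, refsets)
    ci = llr_confidence_intervals(
        pos, neg, llr["score"].to_numpy(), n_boot=n_boot, seed=seed
    )
    per_variant = pd.concat([llr.reset_index(drop=True), ci], axis=1)
    per_variant["evidence"] = [
        evidence_strength(r.llr, (r.ci_lo, r.ci_hi), op_vst=op_vst, ci_gated=ci_gated)
        for r in per_variant.itertuples()
    ]
    report.per_variant = per_variant
    report.meta.update(
        {"n_boot": n_boot, "seed": seed, "op_vst": op_vst,
         "n_dropped_resamples": ci.attrs.get("n_dropped", 0)}
    )
    return report


def write_calibration(report: CalibrationReport, out_dir: str | Path) -> None:
    """Persist curve TSV, per-variant TSV, and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.curve.to_csv(out / "balanced_prc_curve.tsv", sep="\t", index=False)
    if report.per_variant is not None:
        report.per_variant.to_csv(out / "llr_per_variant.tsv", sep="\t", index=False)
    summary = {"aubprc": report.aubprc, "r90bp": report.r90bp, **report.meta}
    (out / "calibration.json").write_text(json.dumps(summary, indent=2))
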