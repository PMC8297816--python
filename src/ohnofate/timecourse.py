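"""Per-gene time-course statistics and the nutritional-responsiveness call.

The decision tree mirrors common practice for fasting-refeeding qPCR
series: Shapiro-Wilk on model residuals gates between a parametric branch
(one-way ANOVA + Tukey HSD) and a non-parametric branch (Kruskal-Wallis +
Dunn); non-normal data get one Box-Cox rescue attempt before falling back
to ranks. A gene is called nutritionally responsive when the omnibus test
is significant and at least one post-hoc contrast between the end of
fasting (0 h) and a refed timepoint is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ADJUSTMENTS = ("none", "bonferroni", "holm")


@dataclass
class GateResult:
    is_normal: bool
    p: float
    degenerate: bool = False


@dataclass
class TimecourseResult:
    gene: str
    normality_p: float
    transform: str  # "none" or "boxcox(lambda=...)"
    boxcox_lambda: float | None
    test_used: str  # "anova_tukey" or "kruskal_dunn"
    omnibus_p: float
    pairwise_p: pd.DataFrame  # timepoint x timepoint, symmetric, unit diagonal
    letters: dict = field(default_factory=dict)
    responsive: bool | None = None

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.pairwise_p < alpha


def _residuals(values_by_group: dict) -> np.ndarray:
    res = []
    for vals in values_by_group.values():
        v = np.asarray(vals, dtype=float)
        res.append(v - v.mean())
    return np.concatenate(res)


def normality_gate(values_by_group: dict, alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk on residuals (observations minus their group mean)."""
    res = _residuals(values_by_group)
    if len(res) < 3:
        raise ValueError("normality gate needs at least 3 observations")
    if np.allclose(res, res[0]):
        return GateResult(is_normal=False, p=float("nan"), degenerate=True)
    p = float(stats.shapiro(res).pvalue)
    return GateResult(is_normal=p >= alpha, p=p)


def boxcox(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen by profile-likelihood grid search.

    The grid spans [-5, 5] in steps of 0.01; likelihood ties (within 1e-12)
    are broken toward lambda = 1 (no transformation). The transform is
    (y^lambda - 1)/lambda, or ln(y) at lambda = 0, and is monotone in y.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    grid = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 2)
    llf = _boxcox_llf_grid(grid, y)
    best = llf.max()
    candidates = grid[llf >= best - 1e-12]
    lam = float(candidates[np.argmin(np.abs(candidates - 1.0))])
    transformed = np.log(y) if lam == 0 else (y**lam - 1.0) / lam
    return transformed, lam


def _boxcox_llf_grid(grid: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Box-Cox profile log-likelihood at each lambda (vectorized).

    llf(lam) = (lam - 1) sum(ln y) - n/2 ln(var of transformed values).
    """
    n = len(y)
    log_y = np.log(y)
    sum_log = log_y.sum()
    lam = grid[:, None]
    with np.errstate(over="ignore"):
        trans = np.where(lam == 0, log_y[None, :], (y[None, :] ** lam - 1.0) / np.where(lam == 0, 1.0, lam))
    var = trans.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        llf = (grid - 1.0) * sum_log - n / 2.0 * np.log(var)
    return np.where(np.isfinite(llf), llf, -np.inf)


def _tukey_pairwise(groups: list[np.ndarray]) -> np.ndarray:
    """Tukey HSD p-values from the studentized-range distribution.

    Uses the statsmodels studentized-range approximation (psturng),
    which reports p in [0.001, 0.9]; values beyond are clipped — far
    from any decision threshold used here.
    """
    from statsmodels.stats.libqsturng import psturng

    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(ns.sum() - k)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    s2 = ss_within / df
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 * 0.5 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(np.atleast_1d(psturng(q, k, df))[0])
            out[i, j] = out[j, i] = p
    return out


def _dunn_pairwise(groups: list[np.ndarray], adjust: str) -> np.ndarray:
    """Dunn's test: pairwise z statistics on mean ranks, tie-corrected."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(groups)
    raw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            raw[i, j] = raw[j, i] = p
    return _adjust_pairwise(raw, adjust)


def _adjust_pairwise(raw: np.ndarray, adjust: str) -> np.ndarray:
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"adjust must be one of {ADJUSTMENTS}")
    k = raw.shape[0]
    iu = np.triu_indices(k, 1)
    p = raw[iu]
    if adjust == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    elif adjust == "holm":
        order = np.argsort(p)
        m = len(p)
        stepped = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            stepped[idx] = min(running, 1.0)
        p_adj = stepped
    else:
        p_adj = p
    out = np.ones((k, k))
    out[iu] = p_adj
    out[(iu[1], iu[0])] = p_adj
    return out


def compact_letters(pairwise_sig: pd.DataFrame) -> dict:
    """Compact letter display via the insert-and-absorb algorithm.

    Two groups share at least one letter iff their pairwise difference is
    NOT significant. Letter sets are assigned deterministically (columns
    ordered by their first member's position).
    """
    sig = pairwise_sig.astype(bool)
    if not sig.equals(sig.T):
        raise ValueError("pairwise significance matrix must be symmetric")
    labels = list(sig.index)
    columns: list[set] = [set(labels)]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if not sig.loc[a, b]:
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
            # absorb: drop columns contained in another
            columns = [
                c
                for c in columns
                if c and not any(c < other for other in columns)
            ]
            # deduplicate while preserving insertion order
            seen: list[set] = []
            for c in columns:
                if c not in seen:
                    seen.append(c)
            columns = seen
    order = {lab: i for i, lab in enumerate(labels)}
    columns.sort(key=lambda c: min(order[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        for lab in sorted(col, key=order.get):
            letters[lab] += alphabet[i % len(alphabet)]
    return letters


def omnibus_and_posthoc(
    values_by_timepoint: dict,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    gene: str = "",
    posthoc: bool = True,
) -> TimecourseResult:
    """Run the full gate -> transform -> re-gate -> test decision tree.

    Parametric branch: one-way ANOVA with Tukey HSD pairwise p-values
    (on the transformed scale when Box-Cox was applied). Non-parametric
    branch: Kruskal-Wallis with Dunn pairwise tests (``adjust`` applied).
    ``posthoc=False`` skips the pairwise stage (omnibus only; the
    pairwise matrix is filled with ones).
    """
    tps = sorted(values_by_timepoint)
    groups = []
    for tp in tps:
        v = np.asarray(values_by_timepoint[tp], dtype=float)
        if len(v) < 2:
            raise ValueError(f"timepoint {tp} has fewer than 2 observations")
        groups.append(v)
    if len(groups) < 2:
        raise ValueError("need at least 2 timepoint groups")

    gate = normality_gate(dict(zip(tps, groups)), alpha)
    transform = "none"
    lam = None
    test_groups = groups
    is_normal = gate.is_normal
    if not is_normal and not gate.degenerate and all((g > 0).all() for g in groups):
        transformed, lam = boxcox(np.concatenate(groups))
        tg, start = [], 0
        for g in groups:
            tg.append(transformed[start : start + len(g)])
            start += len(g)
        regate = normality_gate(dict(zip(tps, tg)), alpha)
        if regate.is_normal:
            transform = f"boxcox(lambda={lam})"
            test_groups = tg
            is_normal = True
        else:
            lam = None

    k = len(tps)
    if is_normal:
        test_used = "anova_tukey"
        omnibus_p = float(stats.f_oneway(*test_groups).pvalue)
        pairwise = _tukey_pairwise(test_groups) if posthoc else np.ones((k, k))
    else:
        test_used = "kruskal_dunn"
        if np.ptp(np.concatenate(test_groups)) == 0:
            # degenerate: identical observations carry no evidence
            omnibus_p, pairwise = 1.0, np.ones((k, k))
        else:
            omnibus_p = float(stats.kruskal(*test_groups).pvalue)
            pairwise = (
                _dunn_pairwise(test_groups, adjust)
                if posthoc
                else np.ones((k, k))
            )
    pairwise_p = pd.DataFrame(pairwise, index=tps, columns=tps)
    letters = compact_letters(pairwise_p < alpha)
    return TimecourseResult(
        gene=gene,
        normality_p=gate.p,
        transform=transform,
        boxcox_lambda=lam,
        test_used=test_used,
        omnibus_p=omnibus_p,
        pairwise_p=pairwise_p,
        letters=letters,
    )


def responsiveness(
    result: TimecourseResult,
    fasted_ref: float = 0,
    refed_set: list | None = None,
    alpha: float = 0.05,
) -> bool:
    """Nutritional responsiveness: 0 h differs from at least one refed point.

    True iff the omnibus test is significant AND any pairwise contrast
    between ``fasted_ref`` and a member of ``refed_set`` (default: every
    timepoint after 0 h present in the result) is significant at alpha.
    """
    tps = list(result.pairwise_p.index)
    if fasted_ref not in tps:
        raise ValueError(f"fasted_ref timepoint {fasted_ref} not in result")
    if refed_set is None:
        refed_set = [t for t in tps if t > fasted_ref]
    missing = [t for t in refed_set if t not in tps]
    if missing:
        raise ValueError(f"refed timepoints not in result: {missing}")
    if result.omnibus_p >= alpha:
        return False
    row = result.pairwise_p.loc[fasted_ref, refed_set]
    return bool((row < alpha).any())


def timecourse_table(results: list[TimecourseResult]) -> pd.DataFrame:
    """Flatten a list of results into one row per gene (TSV-friendly)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "normality_p": r.normality_p,
                "transform": r.transform,
                "test_used": r.test_used,
                "omnibus_p": r.omnibus_p,
                "responsive": r.responsive,
                "letters": ";".join(
                    f"{tp}:{r.letters[tp]}" for tp in r.pairwise_p.index
                ),
            }
        )
    return pd.DataFrame(rows)
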