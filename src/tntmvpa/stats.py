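"""Group-level statistics for the suppression analysis.

Covers the study's inferential toolkit: suppression-induced reduction
scores (pre-post change for suppress items corrected by the baseline
change), balanced within-subject factorial ANOVAs with two-level factors
(Type-3-equivalent in this balanced, all-within setting) reporting
generalized eta squared, paired/one-sample t-tests with Cohen's d,
per-subject trialwise correlation tests on Fisher-z coefficients, and
robust skipped Spearman correlations with a minimum-covariance-
determinant outlier rule and percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.covariance import MinCovDet

from .rsa import fisher_z

logger = logging.getLogger(__name__)

#: consistency factor making the MAD estimate the sd under normality
MAD_SCALE = 1.4826


@dataclass
class GroupStatResult:
    """One inferential result (F or t test, or a robust correlation)."""

    effect: str
    stat_name: str  # "F", "t" or "r_skipped"
    stat: float
    df: tuple
    p: float | None = None
    d: float | None = None
    eta2g: float | None = None
    ci: tuple | None = None
    outliers: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "effect": self.effect,
            "stat": self.stat_name,
            "value": self.stat,
            "df": "x".join(str(d) for d in self.df),
            "p": self.p,
            "d": self.d,
            "eta2g": self.eta2g,
        }
        if self.ci is not None:
            out["ci_low"], out["ci_high"] = self.ci
        return out


# ---------------------------------------------------------------------------
# reduction scores
# ---------------------------------------------------------------------------


def reduction_scores(cells: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Per-subject suppression-induced reduction.

    reduction = (pre_suppress - post_suppress) - (pre_baseline - post_baseline)

    Parameters
    ----------
    cells : DataFrame
        Long format with columns subject, phase (pretest/posttest),
        condition (baseline/suppress at least) and the value column.
        Subjects missing any of the four cells are rejected with a
        report.
    """
    need = {("pretest", "suppress"), ("posttest", "suppress"),
            ("pretest", "baseline"), ("posttest", "baseline")}
    wide = cells.pivot_table(
        index="subject", columns=["phase", "condition"], values=value, aggfunc="mean"
    )
    missing = [c for c in need if c not in wide.columns]
    if missing:
        raise ValueError(f"missing design cells: {sorted(missing)}")
    incomplete = wide.loc[:, sorted(need)].isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"subjects with missing cells: {wide.index[incomplete].tolist()}"
        )
    out = pd.DataFrame(index=wide.index)
    out["reduction"] = (
        wide[("pretest", "suppress")] - wide[("posttest", "suppress")]
    ) - (wide[("pretest", "baseline")] - wide[("posttest", "baseline")])
    return out.reset_index()


# ---------------------------------------------------------------------------
# within-subject factorial ANOVA
# ---------------------------------------------------------------------------


def _subsets(s):
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))


def rm_anova(data: np.ndarray, factor_names: list[str] | None = None) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA with two-level factors.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, 2, ..., 2)
        One cell mean per subject and factor-level combination (balanced
        by construction; unbalanced input is rejected).
    factor_names : list of str
        One name per within factor.

    Returns
    -------
    DataFrame with columns effect, F, df1, df2, p, eta2g. Each effect's
    F equals the squared one-sample t of its orthogonal subject-level
    contrast (exact for two-level within factors), and generalized eta
    squared is SS_effect / (SS_effect + SS_subjects + sum of all error
    strata).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 2:
        raise ValueError("data must be subjects x factor cells")
    k = data.ndim - 1
    if any(s != 2 for s in data.shape[1:]):
        raise ValueError("every within factor must have exactly 2 levels")
    if not np.all(np.isfinite(data)):
        raise ValueError("unbalanced data (missing cells) rejected")
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if factor_names is None:
        factor_names = [f"F{i + 1}" for i in range(k)]
    if len(factor_names) != k:
        raise ValueError("one name per factor required")

    axes = tuple(range(data.ndim))  # 0 = subject
    # balanced decomposition: effect tensor for subset A of axes is the
    # Moebius alternating sum of marginal means over subsets of A
    marg = {}
    for B in _subsets(axes):
        keep = tuple(sorted(B))
        other = tuple(a for a in axes if a not in keep)
        m = data.mean(axis=other, keepdims=True) if other else data
        marg[keep] = m
    ss = {}
    for A in _subsets(axes):
        A = tuple(sorted(A))
        eff = np.zeros_like(data)
        for B in _subsets(A):
            sign = (-1) ** (len(A) - len(B))
            eff = eff + sign * marg[tuple(sorted(B))]
        ss[A] = float(np.sum(eff**2))

    ss_subj = ss[(0,)]
    error_total = sum(ss[tuple(sorted((0,) + S))] for S in _subsets(range(1, k + 1)) if S)
    rows = []
    for S in _subsets(range(1, k + 1)):
        if not S:
            continue
        S = tuple(sorted(S))
        name = ":".join(factor_names[a - 1] for a in S)
        ss_eff = ss[S]
        ss_err = ss[tuple(sorted((0,) + S))]
        df1, df2 = 1, n - 1
        scale = max(ss[()] if () in ss else 0.0, ss_subj, 1.0)
        if ss_eff <= 1e-14 * scale:  # exactly-null effect (e.g. additive data)
            F, p = 0.0, 1.0
        elif ss_err == 0:
            F, p = np.inf, 0.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
        eta2g = ss_eff / (ss_eff + ss_subj + error_total)
        rows.append(
            {"effect": name, "F": float(F), "df1": df1, "df2": df2, "p": p, "eta2g": eta2g}
        )
    return pd.DataFrame(rows)


def cells_to_array(
    cells: pd.DataFrame, factors: list[str], value: str = "value"
) -> tuple[np.ndarray, list[list]]:
    """Pivot a long cell table to the (subjects x 2 x ... x 2) array."""
    levels = [sorted(cells[f].unique()) for f in factors]
    wide = cells.pivot_table(index="subject", columns=factors, values=value, aggfunc="mean")
    shape = (len(wide),) + tuple(len(l) for l in levels)
    full_cols = pd.MultiIndex.from_product(levels) if len(factors) > 1 else pd.Index(levels[0])
    wide = wide.reindex(columns=full_cols)
    return wide.to_numpy().reshape(shape), levels


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


def one_sample_t(x: np.ndarray, mu0: float = 0.0, effect: str = "one-sample") -> GroupStatResult:
    """Two-sided one-sample t-test with Cohen's d = mean(x - mu0) / sd(x)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 finite observations")
    diff = x - mu0
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd <= 1e-12 * max(abs(mean), 1e-300):  # numerically zero variance
        if mean == 0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            logger.warning(
                "one_sample_t[%s]: zero variance with nonzero mean; t degenerate", effect
            )
            t, p, d = np.inf * np.sign(mean), 0.0, np.inf * np.sign(mean)
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), n - 1)
        d = mean / sd
    return GroupStatResult(effect=effect, stat_name="t", stat=float(t), df=(n - 1,), p=p, d=d)


def paired_t(x: np.ndarray, y: np.ndarray, effect: str = "paired") -> GroupStatResult:
    """Two-sided paired t-test; d = mean(x - y) / sd(x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0, effect=effect)


def summary_t_vs_chance(
    mean_acc: float, sd_acc: float, n: int, chance: float = 50.0, effect: str = "accuracy-vs-chance"
) -> GroupStatResult:
    """One-sample t against chance from a published accuracy summary
    (mean, SD, n) rather than raw per-subject values."""
    if n < 2 or sd_acc <= 0:
        raise ValueError("need n >= 2 and a positive SD")
    t = (mean_acc - chance) / (sd_acc / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    d = (mean_acc - chance) / sd_acc
    return GroupStatResult(effect=effect, stat_name="t", stat=float(t), df=(n - 1,), p=p, d=d)


# ---------------------------------------------------------------------------
# trialwise evidence-vividness correlation test
# ---------------------------------------------------------------------------


def trialwise_corr_test(
    trials: pd.DataFrame,
    x: str = "evidence",
    y: str = "vividness",
    effect: str = "trialwise-corr",
) -> GroupStatResult:
    """Per-subject Pearson correlation over trials, Fisher-z transformed,
    tested against zero with a group one-sample t.

    Subjects with zero-variance ratings (or evidence) have an undefined
    correlation and are excluded with a report. The group mean z and its
    95% t-interval are returned in ``extra``.
    """
    zs, excluded = [], []
    for subj, df in trials.groupby("subject"):
        xv = df[x].to_numpy(dtype=float)
        yv = df[y].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
        if xv.size < 3 or xv.std() == 0 or yv.std() == 0:
            excluded.append(subj)
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        zs.append(fisher_z(r))
    if excluded:
        logger.warning("trialwise_corr_test: excluded subjects with undefined r: %s", excluded)
    zs = np.asarray(zs)
    res = one_sample_t(zs, 0.0, effect=effect)
    mean_z = zs.mean()
    se = zs.std(ddof=1) / np.sqrt(zs.size) if zs.size > 1 else np.nan
    half = sps.t.ppf(0.975, zs.size - 1) * se if zs.size > 1 else np.nan
    res.extra = {"mean_z": float(mean_z), "n_excluded": len(excluded)}
    res.ci = (float(mean_z - half), float(mean_z + half))
    return res


# ---------------------------------------------------------------------------
# robust skipped Spearman correlation
# ---------------------------------------------------------------------------


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    if abs(r) > 1 - 1e-12:  # exact monotone relations hit +/-1 exactly
        r = round(r)
    return r


def mcd_center(xy: np.ndarray, seed: int | None = None) -> np.ndarray:
    """Robust bivariate center via the fast minimum-covariance-determinant
    estimator with h = floor((n + 3) / 2) support points."""
    n = xy.shape[0]
    h = int(np.floor((n + 3) / 2))
    mcd = MinCovDet(
        support_fraction=h / n, random_state=None if seed is None else int(seed) % (2**31)
    )
    mcd.fit(xy)
    return mcd.location_


def skipped_outliers(xy: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Boolean outlier flags from the projection rule.

    Each observation defines a projection direction from the robust
    center; a point is flagged if, on any projection, its distance from
    the median exceeds sqrt(chi2_{0.975, 2}) robust standard deviations
    (MAD x 1.4826).
    """
    n = xy.shape[0]
    cutoff = np.sqrt(sps.chi2.ppf(0.975, df=2))
    centered = xy - center
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        d = centered[i]
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        proj = centered @ (d / norm)
        med = np.median(proj)
        mad = np.median(np.abs(proj - med))
        if mad == 0:
            continue
        flagged |= np.abs(proj - med) / (MAD_SCALE * mad) > cutoff
    return flagged


def skipped_spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    effect: str = "skipped-spearman",
) -> GroupStatResult:
    """Robust skipped Spearman correlation with percentile-bootstrap CI.

    Procedure: (1) robust bivariate center by minimum covariance
    determinant; (2) projection-based outlier flagging (see
    :func:`skipped_outliers`); (3) Spearman rank correlation on the
    non-flagged points; (4) 95% percentile bootstrap over ``n_boot``
    seeded resamples of the kept points (outlier detection is not re-run
    inside the bootstrap).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 10:
        raise ValueError("skipped correlation requires at least 10 paired observations")
    xy = np.column_stack([x, y])
    center = mcd_center(xy, seed=seed)
    flagged = skipped_outliers(xy, center)
    kept = ~flagged
    if kept.sum() < 4:
        raise ValueError(
            f"too few survivors after outlier removal ({int(kept.sum())} of {n}); "
            "the bivariate distribution may be degenerate"
        )
    xk, yk = x[kept], y[kept]
    r = _spearman(xk, yk)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 83]))
    m = xk.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        boots[b] = _spearman(xk[idx], yk[idx])
    boots = boots[np.isfinite(boots)]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return GroupStatResult(
        effect=effect,
        stat_name="r_skipped",
        stat=r,
        df=(int(kept.sum()) - 2,),
        ci=ci,
        outliers=np.flatnonzero(flagged),
        extra={"n_kept": int(kept.sum()), "n_boot": int(n_boot)},
    )
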