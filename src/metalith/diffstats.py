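"""Per-metabolite univariate statistics and fold-change tables.

The study contrasts two groups at a time within a stratum (one tissue, and
for treatment contrasts one genotype): classical fixed-effects one-way ANOVA
on the normalized intensities, the ratio of group means as the fold change,
an additive linear-model covariate screen, and a per-sample metabolite-ratio
statistic used for pathway throughput (e.g. hypoxanthine/inosine for purine
salvage).

Ratios reported in the contrast tables are ratios of group means, not means
of per-sample ratios; this is the convention under which reference-scaled
group means reproduce the published contrast ratios exactly. The per-sample
convention is used only by :func:`ratio_statistic`, whose mean±SD requires
per-sample values.

Missing values are handled available-case: each metabolite's statistics use
the samples where it was measured. No imputation, and by default no
multiplicity correction (Benjamini-Hochberg q-values are reported alongside
for reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .study_io import IntensityMatrix

__all__ = [
    "DiffStatsError",
    "DifferentialResult",
    "RatioStatistic",
    "anova_oneway",
    "anova_from_summary",
    "fold_change",
    "percent_change",
    "differential_table",
    "covariate_screen",
    "ratio_statistic",
]

# upper-tail p reported when the F statistic is infinite (zero within-group
# variance with nonzero between-group variance); keeps p in (0, 1]
P_FLOOR = 1e-300


class DiffStatsError(Exception):
    pass


def _selection_label(sel: Mapping[str, str]) -> str:
    return ", ".join(f"{k}={v}" for k, v in sel.items())


@dataclass
class DifferentialResult:
    """One metabolite's two-group contrast within one stratum."""

    metabolite_id: str
    name: str
    stratum: dict
    contrast: tuple  # (numerator selection, denominator selection)
    n_num: int
    n_den: int
    mean_num: float
    sd_num: float
    mean_den: float
    sd_den: float
    ratio: float  # mean_num / mean_den
    F: float
    p: float
    q: float = math.nan  # Benjamini-Hochberg, filled by differential_table
    significant: bool = False

    @property
    def stratum_label(self) -> str:
        return _selection_label(self.stratum) if self.stratum else "all"


@dataclass
class RatioStatistic:
    """Per-sample ratio of two metabolites, summarized per group."""

    numerator_id: str
    denominator_id: str
    group_a: dict
    group_b: dict
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    percent_change: int  # round(100 * (mean_b / mean_a - 1))
    n_excluded: int  # samples dropped for a missing or zero denominator


# ---------------------------------------------------------------------------
# ANOVA


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    Returns (F, p) with F on (k-1, N-k) degrees of freedom. Degenerate
    inputs follow fixed conventions: zero between- and within-group variance
    gives (0, 1); zero within-group variance with a real group difference
    gives (inf, P_FLOOR).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DiffStatsError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise DiffStatsError(f"group {i} has fewer than 2 values")
        if np.isnan(a).any():
            raise DiffStatsError("NaN in ANOVA input; drop missing values first")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays)))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise DiffStatsError("no residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, P_FLOOR
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return f, max(p, P_FLOOR)


def anova_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-group one-way ANOVA from summary statistics.

    Algebraically identical to :func:`anova_oneway` on any raw data having
    these means, SDs (sample SD, ddof=1) and sizes; lets published Avg±SD
    tables be re-tested without the raw values.
    """
    if n1 < 2 or n2 < 2:
        raise DiffStatsError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise DiffStatsError("SDs must be nonnegative")
    n = n1 + n2
    grand = (n1 * mean1 + n2 * mean2) / n
    ss_between = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ss_within = (n1 - 1) * sd1**2 + (n2 - 1) * sd2**2
    df_w = n - 2
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, P_FLOOR
    f = ss_between / (ss_within / df_w)
    p = float(stats.f.sf(f, 1, df_w))
    return f, max(p, P_FLOOR)


def anova_welch(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (optional alternative)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = stats.f_oneway(*arrays) if len(arrays) > 2 else stats.ttest_ind(
        arrays[0], arrays[1], equal_var=False
    )
    if len(arrays) == 2:
        return float(res.statistic**2), float(res.pvalue)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# fold change


def fold_change(values_num: Sequence[float], values_den: Sequence[float]) -> float:
    """Ratio of group means, excluding MISSING values."""
    a = np.asarray(values_num, dtype=float)
    b = np.asarray(values_den, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise DiffStatsError("empty group in fold_change")
    den = b.mean()
    if den <= 0:
        raise DiffStatsError("denominator group mean must be positive")
    return float(a.mean() / den)


# ---------------------------------------------------------------------------
# differential table


def differential_table(
    m: IntensityMatrix,
    stratum: Mapping[str, str],
    contrast: tuple[Mapping[str, str], Mapping[str, str]],
    alpha: float = 0.05,
    log2_transform: bool = False,
) -> list[DifferentialResult]:
    """One DifferentialResult per metabolite for a two-group contrast.

    ``contrast`` is a (numerator, denominator) pair of factor selections
    applied within ``stratum``. Significance is flagged at raw p < alpha
    (default 0.05, no multiplicity correction); BH q-values are filled in
    alongside. With ``log2_transform`` the ANOVA runs on log2 intensities
    (zeros excluded); ratios always stay on the natural scale.
    """
    strat_ids = m.select_samples(stratum) if stratum else m.sample_ids
    if not strat_ids:
        raise DiffStatsError(f"stratum {dict(stratum)} selects no samples")
    sub = m.subset(sample_ids=strat_ids)
    num_sel, den_sel = contrast
    num_ids = sub.select_samples(num_sel)
    den_ids = sub.select_samples(den_sel)
    if not num_ids or not den_ids:
        raise DiffStatsError("a contrast group selects no samples in the stratum")

    results: list[DifferentialResult] = []
    for mid in sub.metabolite_ids:
        col = sub.values[mid]
        a = col.loc[num_ids].dropna().to_numpy()
        b = col.loc[den_ids].dropna().to_numpy()
        name = str(sub.annotations.loc[mid, "name"])
        mean_a = float(a.mean()) if a.size else math.nan
        mean_b = float(b.mean()) if b.size else math.nan
        sd_a = float(a.std(ddof=1)) if a.size > 1 else math.nan
        sd_b = float(b.std(ddof=1)) if b.size > 1 else math.nan
        ratio = mean_a / mean_b if (a.size and b.size and mean_b > 0) else math.nan
        if a.size >= 2 and b.size >= 2:
            if log2_transform:
                aa, bb = a[a > 0], b[b > 0]
                if aa.size >= 2 and bb.size >= 2:
                    F, p = anova_oneway([np.log2(aa), np.log2(bb)])
                else:
                    F, p = math.nan, math.nan
            else:
                F, p = anova_oneway([a, b])
        else:
            F, p = math.nan, math.nan
        results.append(
            DifferentialResult(
                metabolite_id=mid,
                name=name,
                stratum=dict(stratum),
                contrast=(dict(num_sel), dict(den_sel)),
                n_num=int(a.size),
                n_den=int(b.size),
                mean_num=mean_a,
                sd_num=sd_a,
                mean_den=mean_b,
                sd_den=sd_b,
                ratio=ratio,
                F=F,
                p=p,
                significant=bool(not math.isnan(p) and p < alpha),
            )
        )
    ps = np.array([r.p for r in results])
    ok = ~np.isnan(ps)
    if ok.any():
        qs = np.full_like(ps, math.nan)
        qs[ok] = multipletests(ps[ok], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# covariate screen


def covariate_screen(
    m: IntensityMatrix,
    covariates: Sequence[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Additive linear model per metabolite, partial F-test per covariate.

    Each metabolite's normalized intensity is regressed on all covariates at
    once (categorical factors dummy-coded, numeric covariates linear); the
    reported p-value per covariate is the partial F-test comparing the full
    model against the model without that covariate. Returns a long-format
    frame (metabolite_id, covariate, F, p) and the count of metabolites
    significant for at least one covariate at raw p < alpha.

    This is a per-metabolite approximation of a joint multivariate screen;
    it asks the same question (which study parameters explain metabolite
    variation) one response at a time.
    """
    import statsmodels.api as sm

    for cov in covariates:
        if cov not in m.samples.columns:
            raise DiffStatsError(f"unknown covariate {cov!r}")
        col = m.samples[cov].dropna()
        if col.nunique() < 2:
            raise DiffStatsError(f"covariate {cov!r} has no variation")

    # build the full design matrix once; track the columns of each covariate
    pieces: list[pd.DataFrame] = []
    owner: dict[str, str] = {}
    for cov in covariates:
        col = m.samples[cov]
        if col.dtype == object or col.dtype.name == "category":
            d = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
        else:
            d = col.astype(float).to_frame(cov)
        for c in d.columns:
            owner[c] = cov
        pieces.append(d)
    X_full = pd.concat(pieces, axis=1)
    X_full.insert(0, "Intercept", 1.0)

    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        # identify aliased covariates by dropping columns greedily
        aliased = []
        keep = ["Intercept"]
        for c in X_full.columns[1:]:
            trial = X_full[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(c)
            else:
                aliased.append(owner[c])
        raise DiffStatsError(f"rank-deficient design; aliased covariates: {sorted(set(aliased))}")

    rows = []
    flagged: set[str] = set()
    for mid in m.metabolite_ids:
        y = m.values[mid]
        use = y.notna() & X_full.notna().all(axis=1)
        if use.sum() <= X_full.shape[1]:
            continue
        yv = y[use].to_numpy(dtype=float)
        Xv = X_full.loc[use]
        full = sm.OLS(yv, Xv.to_numpy()).fit()
        for cov in covariates:
            drop = [c for c in Xv.columns if owner.get(c) == cov]
            Xr = Xv.drop(columns=drop)
            red = sm.OLS(yv, Xr.to_numpy()).fit()
            df_num = len(drop)
            df_den = full.df_resid
            if full.ssr == 0 or df_den < 1:
                F, p = math.nan, math.nan
            else:
                F = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
                p = float(stats.f.sf(F, df_num, df_den))
            rows.append({"metabolite_id": mid, "covariate": cov, "F": F, "p": p})
            if not math.isnan(p) and p < alpha:
                flagged.add(mid)
    return pd.DataFrame(rows), len(flagged)


def percent_change(mean_a: float, mean_b: float) -> int:
    """Integer percent change of mean_b relative to mean_a."""
    if mean_a == 0:
        raise DiffStatsError("reference mean must be nonzero")
    return int(round(100.0 * (mean_b / mean_a - 1.0)))


# ---------------------------------------------------------------------------
# per-sample metabolite ratio


def ratio_statistic(
    m: IntensityMatrix,
    numerator_id: str,
    denominator_id: str,
    group_a: Mapping[str, str],
    group_b: Mapping[str, str],
) -> RatioStatistic:
    """Mean±SD of the per-sample ratio numerator/denominator in two groups,
    and the integer percent change of the group-b mean relative to group-a.

    Samples where either metabolite is MISSING or the denominator is zero
    are excluded (counted in ``n_excluded``).
    """
    for mid in (numerator_id, denominator_id):
        if mid not in m.values.columns:
            raise DiffStatsError(f"unknown metabolite {mid!r}")

    def group_ratios(sel: Mapping[str, str]) -> tuple[np.ndarray, int]:
        sids = m.select_samples(sel)
        if not sids:
            raise DiffStatsError(f"group {dict(sel)} selects no samples")
        num = m.values.loc[sids, numerator_id].to_numpy(dtype=float)
        den = m.values.loc[sids, denominator_id].to_numpy(dtype=float)
        ok = ~np.isnan(num) & ~np.isnan(den) & (den > 0)
        return num[ok] / den[ok], int((~ok).sum())

    ra, ex_a = group_ratios(group_a)
    rb, ex_b = group_ratios(group_b)
    if ra.size == 0 or rb.size == 0:
        raise DiffStatsError("no usable per-sample ratios in a group")
    mean_a, mean_b = float(ra.mean()), float(rb.mean())
    percent = int(round(100.0 * (mean_b / mean_a - 1.0)))
    return RatioStatistic(
        numerator_id=numerator_id,
        denominator_id=denominator_id,
        group_a=dict(group_a),
        group_b=dict(group_b),
        mean_a=mean_a,
        sd_a=float(ra.std(ddof=1)) if ra.size > 1 else math.nan,
        n_a=int(ra.size),
        mean_b=mean_b,
        sd_b=float(rb.std(ddof=1)) if rb.size > 1 else math.nan,
        n_b=int(rb.size),
        percent_change=percent,
        n_excluded=ex_a + ex_b,
    )
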