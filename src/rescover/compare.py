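"""Method-comparison framework.

Benchmarks each alternative cover measurement against the line transect:
distribution summaries, the pairwise Spearman matrix, binary adoption
agreement at the 30 % threshold, graded-category (AQUASTAT-style)
false reporting, and linear probability models of measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Conventional conservation-agriculture adoption threshold, percent cover.
ADOPTION_THRESHOLD = 30.0

#: Graded adoption categories (FAO AQUASTAT convention).
CATEGORY_LABELS = ("<30", "30-60", "60-90", ">90")

#: Dummy-coding reference levels for the measurement-error regressions.
LPM_REFERENCES = {"head_sex": "male", "residue_type": "teff",
                  "soil": "leptosol", "slope": "flat"}

#: Methods whose errors may plausibly depend on who answers the survey:
#: the interviewee methods get the household covariates in their models.
INTERVIEWEE_METHODS = ("m1", "m3")


@dataclass
class ThresholdConfusion:
    """Binary adoption agreement of one method against the benchmark."""

    method: str
    correct_adopter: int
    correct_nonadopter: int
    false_positive: int
    false_negative: int

    @property
    def n(self) -> int:
        return (self.correct_adopter + self.correct_nonadopter
                + self.false_positive + self.false_negative)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.correct_adopter + self.correct_nonadopter) / self.n

    @property
    def error_rate(self) -> float:
        return 100.0 * (self.false_positive + self.false_negative) / self.n


@dataclass
class LpmFit:
    """A fitted linear probability model of measurement error."""

    method: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    n: int
    references: dict = field(default_factory=dict)

    def stars(self) -> pd.Series:
        """Significance stars at the 0.1 / 0.05 / 0.01 levels."""
        def star(p):
            return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""
        return self.pvalues.map(star)


def spearman_matrix(records: pd.DataFrame, methods: list[str]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman matrix with per-pair n and p-values.

    Average ranks handle ties; a pair with an all-tied vector gets NaN
    (correlation undefined) rather than a number.
    """
    k = len(methods)
    rho = pd.DataFrame(np.eye(k), index=methods, columns=methods)
    npair = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    pval = pd.DataFrame(np.zeros((k, k)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        npair.loc[a, a] = records[a].notna().sum()
        for b in methods[i + 1:]:
            sub = records[[a, b]].dropna()
            n = len(sub)
            if n < 3:
                raise ValueError(f"fewer than 3 complete pairs for {a}-{b}")
            npair.loc[a, b] = npair.loc[b, a] = n
            if sub[a].nunique() == 1 or sub[b].nunique() == 1:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, npair, pval


def summarize_distributions(records: pd.DataFrame, methods: list[str],
                            benchmark: str = "lt") -> pd.DataFrame:
    """Five-number summary per method plus the median gap to the benchmark."""
    rows = {}
    bench_median = records[benchmark].median()
    for m in methods:
        col = records[m].dropna()
        if col.empty:
            raise ValueError(f"method {m} has no observations")
        q = col.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        rows[m] = {"min": q[0.0], "q1": q[0.25], "median": q[0.5],
                   "q3": q[0.75], "max": q[1.0], "n": len(col),
                   "median_minus_lt": q[0.5] - bench_median}
    return pd.DataFrame(rows).T


def classify_adoption(cover, threshold: float = ADOPTION_THRESHOLD):
    """Adopter iff cover meets the threshold ("at least 30 %" — inclusive)."""
    return np.asarray(cover, dtype=float) >= threshold


def confusion_30(records: pd.DataFrame, method: str, benchmark: str = "lt",
                 threshold: float = ADOPTION_THRESHOLD) -> ThresholdConfusion:
    """Cross-classify a method against the benchmark at the adoption threshold."""
    sub = records[[benchmark, method]].dropna()
    if sub.empty:
        raise ValueError(f"no overlapping observations for {method}")
    truth = classify_adoption(sub[benchmark], threshold)
    pred = classify_adoption(sub[method], threshold)
    return ThresholdConfusion(
        method=method,
        correct_adopter=int((truth & pred).sum()),
        correct_nonadopter=int((~truth & ~pred).sum()),
        false_positive=int((~truth & pred).sum()),
        false_negative=int((truth & ~pred).sum()),
    )


def aquastat_category(cover) -> np.ndarray:
    """Graded adoption category: <30, 30-60, 60-90, >90 (lower-inclusive bins)."""
    c = np.asarray(cover, dtype=float)
    idx = np.digitize(c, [30.0, 60.0, 90.0])   # right-open bins
    return np.asarray(CATEGORY_LABELS, dtype=object)[idx]


def category_false_reporting(records: pd.DataFrame, method: str,
                             benchmark: str = "lt") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate benchmark vs method categories; rate over/under reporting.

    Returns the full 4x4 contingency table (benchmark rows) and, per
    benchmark category, the fraction of plots the method places below,
    within, and above that category.
    """
    sub = records[[benchmark, method]].dropna()
    bcat = pd.Categorical(aquastat_category(sub[benchmark]),
                          categories=CATEGORY_LABELS, ordered=True)
    mcat = pd.Categorical(aquastat_category(sub[method]),
                          categories=CATEGORY_LABELS, ordered=True)
    table = pd.crosstab(bcat, mcat, rownames=[benchmark], colnames=[method],
                        dropna=False)
    table = table.reindex(index=CATEGORY_LABELS, columns=CATEGORY_LABELS,
                          fill_value=0)
    rates = {}
    bcodes, mcodes = bcat.codes, mcat.codes
    for i, lab in enumerate(CATEGORY_LABELS):
        in_cat = bcodes == i
        n = int(in_cat.sum())
        if n == 0:
            rates[lab] = {"under": np.nan, "correct": np.nan, "over": np.nan, "n": 0}
            continue
        rates[lab] = {
            "under": float((mcodes[in_cat] < i).mean()),
            "correct": float((mcodes[in_cat] == i).mean()),
            "over": float((mcodes[in_cat] > i).mean()),
            "n": n,
        }
    return table, pd.DataFrame(rates).T


def measurement_error_outcome(records: pd.DataFrame, method: str,
                              benchmark: str = "lt",
                              threshold: float = ADOPTION_THRESHOLD) -> pd.Series:
    """1 iff the 30 %-threshold classifications disagree; rows with a missing
    method value are excluded (which drives the per-model n)."""
    sub = records[[benchmark, method]].dropna()
    truth = classify_adoption(sub[benchmark], threshold)
    pred = classify_adoption(sub[method], threshold)
    return pd.Series((truth != pred).astype(int), index=sub.index, name="error")


def _lpm_design(records: pd.DataFrame, method: str) -> pd.DataFrame:
    """Dummy-coded design matrix for one method's error regression.

    Household covariates (and distance) enter only for the interviewee
    methods; field characteristics enter for all methods.  Reference
    levels: male head, teff residue, leptosol soil, flat slope.
    """
    cols = {}
    if method in INTERVIEWEE_METHODS:
        cols["female_head"] = (records["head_sex"] != LPM_REFERENCES["head_sex"]).astype(float)
        cols["head_age"] = records["head_age"].astype(float)
        cols["head_education"] = records["head_education"].astype(float)
        cols["training"] = records["training"].astype(float)
        cols["farm_size"] = records["farm_size"].astype(float)
        cols["herd_tlu"] = records["herd_tlu"].astype(float)
        cols["phones"] = records["phones"].astype(float)
        cols["distance"] = records["distance"].astype(float)
    cols["field_size"] = records["field_size"].astype(float)
    for lev in ("barley", "maize", "wheat"):
        cols[f"{lev}_residue"] = (records["residue_type"] == lev).astype(float)
    for lev in ("cambisol", "luvisol", "vertisol"):
        cols[f"{lev}_soil"] = (records["soil"] == lev).astype(float)
    cols["rocks_gt20"] = records["rocks_gt20"].astype(float)
    for lev in ("slight", "steep"):
        cols[f"{lev}_slope"] = (records["slope"] == lev).astype(float)
    return pd.DataFrame(cols, index=records.index)


def fit_lpm(outcome: pd.Series, covariates: pd.DataFrame,
            method: str = "", robust: bool = False) -> LpmFit:
    """OLS linear probability model of a binary error outcome.

    Plain (non-robust) standard errors by default.  Raises on a
    rank-deficient design; perfect separation is not an error for OLS.
    """
    y = np.asarray(outcome, dtype=float)
    x = sm.add_constant(covariates.astype(float), has_constant="add")
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    if len(y) <= x.shape[1]:
        raise ValueError("need more observations than parameters")
    res = sm.OLS(y, x).fit(cov_type="HC1" if robust else "nonrobust")
    return LpmFit(method=method, params=res.params, bse=res.bse,
                  tvalues=res.tvalues, pvalues=res.pvalues,
                  r2=float(res.rsquared), r2_adj=float(res.rsquared_adj),
                  n=int(res.nobs), references=dict(LPM_REFERENCES))


def fit_lpm_for_method(records: pd.DataFrame, method: str,
                       robust: bool = False) -> LpmFit:
    """Build the error outcome and covariate design for a method and fit."""
    outcome = measurement_error_outcome(records, method)
    design = _lpm_design(records.loc[outcome.index], method)
    fit = fit_lpm(outcome, design, method=method, robust=robust)
    return fit


def run_comparison(records: pd.DataFrame,
                   methods: list[str] | None = None) -> dict:
    """Run the full comparison suite against the LT benchmark.

    Returns a dict with the correlation matrix, distribution summaries,
    per-method threshold confusions, category tables and LPM fits.
    """
    methods = methods or ["m1", "m2", "m3", "m4", "m5", "m6"]
    all_methods = ["lt"] + methods
    rho, npair, pval = spearman_matrix(records, all_methods)
    lpm = {}
    for m in methods:
        try:
            lpm[m] = fit_lpm_for_method(records, m)
        except ValueError:
            lpm[m] = None   # too few rows / rank-deficient design (tiny runs)
    return {
        "spearman": rho,
        "spearman_n": npair,
        "spearman_p": pval,
        "summary": summarize_distributions(records, all_methods),
        "confusion": {m: confusion_30(records, m) for m in methods},
        "categories": {m: category_false_reporting(records, m) for m in methods},
        "lpm": lpm,
    }
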