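"""Two-sample screening of handwriting features and cohort-balance tables.

Every feature is compared between the AD and HC groups, per task, with a
normality-gated choice of test: the pooled-variance Student t-test when both
groups pass Shapiro-Wilk and a Levene variance-homogeneity check, otherwise
the Mann-Whitney U test (midranks, tie and continuity corrections, exact
enumeration for small samples).  Each feature is additionally rank-correlated
(Spearman) against the MoCA-BC reference score.  Missing feature values are
mean-imputed before testing.

Strokes are pooled as independent observations by default — the convention
of the source analysis — even though strokes within a participant are
correlated; ``aggregate="participant"`` averages strokes per participant
first, which is the honest-inference option.  No multiple-testing correction
is applied by default; Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .kinematic_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: Total sample size at or below which the Mann-Whitney p-value is computed
#: by exact enumeration of group assignments.
EXACT_ENUMERATION_MAX_N = 10


class DegenerateDataError(ValueError):
    """The requested test is undefined for this input."""


# ---------------------------------------------------------------------------
# elementary tests


def students_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided pooled-variance independent-samples t-test.

    Returns (t, p) with df = n_a + n_b - 2.  Degenerate pooled variance is
    an error: use the Mann-Whitney test instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("t-test needs >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateDataError(
            "zero pooled variance; the Mann-Whitney test handles degenerate spread"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _rank_sums_u(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_a = ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0
    return float(u_a), ranks


def _mw_sigma(n_a: int, n_b: int, ranks: np.ndarray) -> float:
    n = n_a + n_b
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    if n <= 1:
        return 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return float(np.sqrt(max(var, 0.0)))


def _mw_z(u: float, n_a: int, n_b: int, sigma: float) -> float:
    mu = n_a * n_b / 2.0
    if sigma == 0.0:
        return 0.0
    d = u - mu
    if d > 0:
        d -= 0.5
    elif d < 0:
        d += 0.5
    return d / sigma


def _mw_exact_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group assignments of the ranks.

    p = P(|U - n_a n_b / 2| >= |observed deviation|) under random assignment
    of the pooled (mid)ranks; valid with ties because the midranks are held
    fixed.
    """
    n = len(ranks)
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    base = n_a * (n_a + 1) / 2.0
    count = total = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - base
        total += 1
        if abs(u - mu) >= dev:
            count += 1
    return count / total


def mann_whitney_u(group_a, group_b, method: str = "auto") -> tuple[float, float, float]:
    """Mann-Whitney U test with midranks, tie and continuity corrections.

    Returns (U, z, p) where U counts pairs in which group A exceeds group B
    (ties half-weighted).  ``method`` selects the p-value: "exact"
    enumerates all group assignments (feasible for small samples; used
    automatically when n_a + n_b <= 10), "asymptotic" uses the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("Mann-Whitney needs non-empty groups")
    u, ranks = _rank_sums_u(a, b)
    sigma = _mw_sigma(len(a), len(b), ranks)
    z = _mw_z(u, len(a), len(b), sigma)
    if method == "auto":
        method = "exact" if len(a) + len(b) <= EXACT_ENUMERATION_MAX_N else "asymptotic"
    if method == "exact":
        p = _mw_exact_p(ranks, len(a), u)
    elif method == "asymptotic":
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z)))) if sigma > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return u, z, float(p)


def choose_test(group_a, group_b, alpha_gate: float = DEFAULT_ALPHA) -> str:
    """Select "t" or "mann_whitney" via a normality + variance gate.

    The t-test is used only when both groups pass Shapiro-Wilk at
    ``alpha_gate`` and a Levene variance-homogeneity check passes; groups
    too small for the gate (n < 3) or with degenerate spread fall back to
    the Mann-Whitney test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        return "mann_whitney"
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return "mann_whitney"
    for g in (a, b):
        if stats.shapiro(g).pvalue <= alpha_gate:
            return "mann_whitney"
    if stats.levene(a, b).pvalue <= alpha_gate:
        return "mann_whitney"
    return "t"


def spearman_vs_moca(values, moca) -> tuple[float, float]:
    """Spearman rank correlation (midranks) of a feature against MoCA-BC."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(moca, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("Spearman needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("Spearman undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# screening


def impute_column_mean(col: pd.Series) -> pd.Series:
    """Replace missing values with the mean of the observed ones.

    The observed-value mean of the column is preserved exactly.
    """
    if col.isna().all():
        return col
    return col.fillna(col.mean())


def _screen_one(
    a: np.ndarray, b: np.ndarray, alpha: float, alpha_gate: float
) -> dict:
    test = choose_test(a, b, alpha_gate)
    if test == "t":
        try:
            statistic, p = students_t(a, b)
        except DegenerateDataError:
            test = "mann_whitney"
    if test == "mann_whitney":
        _, statistic, p = mann_whitney_u(a, b)
    if test == "t":
        summary = {
            "summary_type": "mean_sd",
            "ad_center": float(np.mean(a)), "ad_spread": float(np.std(a, ddof=1)),
            "hc_center": float(np.mean(b)), "hc_spread": float(np.std(b, ddof=1)),
        }
    else:
        qa = np.percentile(a, [25, 50, 75])
        qb = np.percentile(b, [25, 50, 75])
        summary = {
            "summary_type": "median_iqr",
            "ad_center": float(qa[1]), "ad_spread": float(qa[2] - qa[0]),
            "hc_center": float(qb[1]), "hc_spread": float(qb[2] - qb[0]),
        }
    return {
        "test_used": test, "statistic": float(statistic), "p_value": float(p),
        "significant": bool(p < alpha), **summary,
    }


def screen_features(
    features: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    alpha_gate: float = DEFAULT_ALPHA,
    aggregate: str | None = None,
    bh_correction: bool = False,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Screen every feature per task: group test + Spearman vs MoCA-BC.

    Parameters
    ----------
    features :
        Per-stroke feature table with ``group``, ``task_id`` (and
        ``participant_id``, ``moca_bc``) key columns.
    aggregate :
        ``None`` pools strokes as independent observations;
        ``"participant"`` averages strokes per participant first.
    bh_correction :
        Apply Benjamini-Hochberg across features within each task; the
        ``significant`` flag then uses the adjusted p-values.

    Returns one row per (feature, task) with the test label, statistic,
    two-sided p, group summaries (mean±SD for t-tested features, median+IQR
    otherwise), Spearman rho/p, and the significance flag.
    """
    if "group" not in features.columns or "task_id" not in features.columns:
        raise ValueError("feature table must carry 'group' and 'task_id' columns")
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_NAMES if c in features.columns]
    if not feature_columns:
        raise ValueError("no feature columns found in table")

    table = features
    if aggregate == "participant":
        keys = ["participant_id", "group", "task_id"]
        table = (
            features.groupby(keys, as_index=False)[
                feature_columns + (["moca_bc"] if "moca_bc" in features else [])
            ].mean()
        )
    elif aggregate is not None:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    rows = []
    for task_id, sub in table.groupby("task_id", sort=True):
        groups = set(sub["group"])
        if not {"AD", "HC"} <= groups:
            raise ValueError(f"task {task_id}: both AD and HC groups are required")
        for name in feature_columns:
            raw = sub[name].astype(float)
            col = impute_column_mean(raw)
            a = col[sub["group"] == "AD"].to_numpy()
            b = col[sub["group"] == "HC"].to_numpy()
            base = {"feature_name": name, "task_id": task_id}
            # a group with no observed value at all cannot be rescued by
            # imputation from the other group
            all_missing = (
                raw[sub["group"] == "AD"].isna().all()
                or raw[sub["group"] == "HC"].isna().all()
            )
            if all_missing or len(a) == 0 or len(b) == 0:
                logger.warning("task %s feature %s untestable (missing group)", task_id, name)
                rows.append({**base, "test_used": "untestable", "statistic": np.nan,
                             "p_value": np.nan, "significant": False,
                             "summary_type": "none", "ad_center": np.nan,
                             "ad_spread": np.nan, "hc_center": np.nan,
                             "hc_spread": np.nan, "spearman_rho": np.nan,
                             "spearman_p": np.nan})
                continue
            result = _screen_one(a, b, alpha, alpha_gate)
            rho = rho_p = np.nan
            if "moca_bc" in sub.columns:
                pairs = pd.DataFrame({"x": col, "m": sub["moca_bc"]}).dropna()
                if len(pairs) >= 3:
                    try:
                        rho, rho_p = spearman_vs_moca(pairs["x"], pairs["m"])
                    except DegenerateDataError:
                        pass
            rows.append({**base, **result, "spearman_rho": rho, "spearman_p": rho_p})
    out = pd.DataFrame(rows)

    if bh_correction:
        adj = np.full(len(out), np.nan)
        for task_id in out["task_id"].unique():
            mask = (out["task_id"] == task_id) & out["p_value"].notna()
            p = out.loc[mask, "p_value"].to_numpy()
            adj[mask.to_numpy()] = _benjamini_hochberg(p)
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# cohort balance


_CATEGORICAL = ["gender", "work_nature", "residence_status", "residence_area"]
_CONTINUOUS = ["age", "education_years"]


def cohort_balance(records) -> pd.DataFrame:
    """Demographic comparability table between the AD and HC groups.

    Categorical variables use the chi-square test of independence (no
    continuity correction); continuous/ordinal variables use the
    Mann-Whitney test (z reported); the ordinal income band uses
    Kruskal-Wallis.  MoCA-BC and MMSE are compared the same way as
    continuous variables.  A variable with a single observed category is
    skipped with a note.
    """
    rows = []
    participants: dict[str, dict] = {}
    for r in records:
        participants.setdefault(r.participant_id, {
            "group": r.group, "moca_bc": r.moca_bc, "mmse": r.mmse, **r.demographics,
        })
    frame = pd.DataFrame(participants.values())
    if frame.empty or frame["group"].nunique() < 2:
        raise DegenerateDataError("cohort balance needs both groups")

    def add(variable, test, statistic, p, note=""):
        rows.append({"variable": variable, "test": test,
                     "statistic": statistic, "p_value": p, "note": note})

    for var in _CATEGORICAL:
        if var not in frame.columns:
            continue
        contingency = pd.crosstab(frame[var], frame["group"])
        if contingency.shape[0] < 2:
            add(var, "chi_square", np.nan, np.nan, "single category; test skipped")
            continue
        chi2, p, _, _ = stats.chi2_contingency(contingency.to_numpy(), correction=False)
        add(var, "chi_square", float(chi2), float(p))

    for var in _CONTINUOUS + ["moca_bc", "mmse"]:
        if var not in frame.columns or frame[var].isna().all():
            continue
        a = frame.loc[frame["group"] == "AD", var].dropna().to_numpy(dtype=float)
        b = frame.loc[frame["group"] == "HC", var].dropna().to_numpy(dtype=float)
        _, z, p = mann_whitney_u(a, b, method="asymptotic")
        add(var, "mann_whitney", float(z), float(p))

    if "income_band" in frame.columns:
        groups = [g["income_band"].to_numpy(dtype=float)
                  for _, g in frame.groupby("group")]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups if len(g)}) == 1:
            add("income_band", "kruskal_wallis", np.nan, np.nan, "single category; test skipped")
        else:
            h, p = stats.kruskal(*groups)
            add("income_band", "kruskal_wallis", float(h), float(p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sklearn-style screener


class FeatureScreener(BaseEstimator, TransformerMixin):
    """Selector over feature columns by two-sample significance.

    ``fit(X, y)`` runs the normality-gated test per column of ``X`` (a
    numeric DataFrame) against the group labels ``y``; ``transform``
    restricts to the significant columns.  Fitted attributes:
    ``comparisons_`` (one row per feature), ``support_`` (boolean mask),
    ``significant_features_``.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, alpha_gate: float = DEFAULT_ALPHA,
                 pos_label: str = "AD"):
        self.alpha = alpha
        self.alpha_gate = alpha_gate
        self.pos_label = pos_label

    def fit(self, X: pd.DataFrame, y, moca=None):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        mask = y == self.pos_label
        if mask.all() or not mask.any():
            raise ValueError("both classes must be present")
        rows = []
        for name in X.columns:
            col = impute_column_mean(X[name].astype(float))
            a = col[mask].to_numpy()
            b = col[~mask].to_numpy()
            result = _screen_one(a, b, self.alpha, self.alpha_gate)
            rho = rho_p = np.nan
            if moca is not None:
                pairs = pd.DataFrame({"x": col.to_numpy(), "m": np.asarray(moca, dtype=float)}).dropna()
                if len(pairs) >= 3:
                    try:
                        rho, rho_p = spearman_vs_moca(pairs["x"], pairs["m"])
                    except DegenerateDataError:
                        pass
            rows.append({"feature_name": name, **result,
                         "spearman_rho": rho, "spearman_p": rho_p})
        self.comparisons_ = pd.DataFrame(rows)
        self.support_ = self.comparisons_["significant"].to_numpy(dtype=bool)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.significant_features_ = list(self.feature_names_in_[self.support_])
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return X.loc[:, self.significant_features_]
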