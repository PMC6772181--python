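"""Inferential layer: TF cluster permutation tests, mixed-effects trend
models and Bonferroni correction.

The exploratory contrast runs an unpaired two-sample t test between
conditions in every time–frequency bin of the log power, forms
4-connected clusters of suprathreshold bins (two-sided bin-level p <
.05 by default), scores each cluster by the sum of |t| and compares it
with the permutation null of the maximum cluster mass under random
reassignment of the trial labels (1000 draws by default) — a max-
statistic correction over the whole TF plane.

Band-level hypotheses use linear mixed-effects models on single-trial
values (restricted maximum likelihood via statsmodels MixedLM):

    power ~ 1 + CS * Time * Region,  random = ~ 1 + Region | participant
    PLI   ~ 1 + CS * Time,           random = ~ 1 | participant

with Time the raw block number.  Marginal (Wald) F tests are reported
per fixed-effect term with numerator df 1 (all factors are two-level or
linear) and a residual-scale denominator df; band-level p values are
Bonferroni corrected over the three bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats


@dataclass
class Cluster:
    bins: np.ndarray          # (n, 2) freq/time indices
    mass: float               # sum of |t|
    sign: int
    p: float = np.nan


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    threshold: float
    clusters: list
    null_max_mass: np.ndarray
    n_perm: int
    seed: int

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p < 0.05]


@dataclass
class LMEResult:
    terms: pd.DataFrame       # term, estimate, F, df1, df2, p
    random_variances: dict
    converged: bool
    formula: str
    n_obs: int

    def p(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def estimate(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])

    def F(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "F"])


# ---------------------------------------------------------------------------
# cluster permutation


def _t_maps(X: np.ndarray, labels: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Two-sample t statistics for many label permutations at once.

    X: (trials, bins); perms: (n_perm, trials) boolean group-1 indicator.
    Returns (n_perm, bins).  Zero-variance bins give t = 0.
    """
    n = X.shape[0]
    n1 = perms.sum(axis=1).astype(float)
    n2 = n - n1
    P = perms.astype(float)
    s1 = P @ X
    q1 = P @ (X ** 2)
    st = X.sum(axis=0)
    qt = (X ** 2).sum(axis=0)
    m1 = s1 / n1[:, None]
    m2 = (st[None, :] - s1) / n2[:, None]
    ss1 = q1 - n1[:, None] * m1 ** 2
    ss2 = (qt[None, :] - q1) - n2[:, None] * m2 ** 2
    dof = n - 2
    sp2 = (ss1 + ss2) / dof
    denom = np.sqrt(sp2 * (1.0 / n1[:, None] + 1.0 / n2[:, None]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[~np.isfinite(t)] = 0.0
    return t


_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity


def _clusters_of(t: np.ndarray, thr: float):
    """4-connected suprathreshold clusters, positive and negative
    separately; mass = sum of |t|."""
    out = []
    for sign in (+1, -1):
        mask = (sign * t) > thr
        lab, n = ndimage.label(mask, structure=_STRUCTURE)
        for k in range(1, n + 1):
            idx = np.argwhere(lab == k)
            mass = float(np.abs(t[lab == k]).sum())
            out.append(Cluster(idx, mass, sign))
    return out


def tf_cluster_permutation(log_power: np.ndarray, labels: np.ndarray,
                           n_perm: int = 1000, bin_alpha: float = 0.05,
                           seed: int = 0) -> ClusterTestResult:
    """Cluster-level permutation test of a two-condition TF contrast.

    ``log_power``: (trials, n_freqs, n_times) log power; ``labels``:
    condition per trial (exactly two levels).  Cluster p values are
    (1 + #{null >= observed}) / (1 + n_perm).
    """
    log_power = np.asarray(log_power, float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    g1 = labels == levels[0]
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("need at least two trials per condition")
    n_trials, nf, nt = log_power.shape
    X = log_power.reshape(n_trials, -1)
    if np.any(X.std(axis=0) == 0):
        warnings.warn("zero-variance bins: their t set to 0")

    t_obs = _t_maps(X, g1, g1[None, :])[0].reshape(nf, nt)
    thr = sstats.t.ppf(1.0 - bin_alpha / 2.0, n_trials - 2)
    clusters = _clusters_of(t_obs, thr)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(X.shape[1], 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = np.zeros((k, n_trials), bool)
        for j in range(k):
            perms[j, rng.permutation(n_trials)[:g1.sum()]] = True
        T = _t_maps(X, g1, perms)
        for j in range(k):
            cs = _clusters_of(T[j].reshape(nf, nt), thr)
            null[done + j] = max((c.mass for c in cs), default=0.0)
        done += k

    for c in clusters:
        c.p = float((1 + np.sum(null >= c.mass)) / (1 + n_perm))
    return ClusterTestResult(t_obs, float(thr), clusters, null, n_perm, seed)


def cluster_overlap(cluster: Cluster, bins: np.ndarray) -> float:
    """Fraction of target bins (n, 2 array) covered by the cluster."""
    have = {tuple(b) for b in cluster.bins}
    want = [tuple(b) for b in bins]
    return sum(1 for b in want if b in have) / len(want)


# ---------------------------------------------------------------------------
# mixed-effects models


def _wald_terms(res, design_info, n_obs: int) -> pd.DataFrame:
    """Marginal Wald F test per fixed-effect term (numerator df from the
    term's columns; denominator df = n_obs - fixed-effect rank)."""
    k_fe = res.k_fe
    df2 = max(n_obs - k_fe, 1)
    rows = []
    fe_params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    for term, sl in design_info.term_name_slices.items():
        idx = np.arange(sl.start, sl.stop)
        b = fe_params[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            chi2 = np.nan
        df1 = len(idx)
        Fv = chi2 / df1
        p = float(sstats.f.sf(Fv, df1, df2)) if np.isfinite(Fv) else np.nan
        rows.append({"term": term, "estimate": float(b[0]) if df1 == 1 else np.nan,
                     "F": Fv, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows)


def fit_lme(table: pd.DataFrame, formula: str, groups: str = "participant",
            re_formula: str | None = None) -> LMEResult:
    """REML mixed model via statsmodels MixedLM with marginal Wald F
    tests per fixed term.

    ``re_formula=None`` fits a random intercept; pass e.g. ``"~Region"``
    for a random region slope; pass ``"ols"`` to drop random effects
    entirely (plain least squares, used for degeneracy checks).
    """
    import statsmodels.formula.api as smf

    table = table.copy()
    required = _formula_columns(formula)
    if re_formula != "ols":
        required = required + [groups]
    missing = sorted(set(required) - set(table.columns))
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    if re_formula == "ols":
        ols = smf.ols(formula, table).fit()
        di = ols.model.data.design_info
        res = _OLSShim(ols, len(ols.params))
        terms = _wald_terms(res, di, len(table))
        return LMEResult(terms, {}, True, formula + " [OLS]", len(table))

    if table[groups].nunique() < 2:
        raise ValueError("need at least two participants for random effects")
    md = smf.mixedlm(formula, table, groups=table[groups],
                     re_formula=re_formula)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = md.fit(reml=True, method="lbfgs", maxiter=200)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = md.fit(reml=True, method="powell", maxiter=500)
            converged = bool(getattr(res, "converged", True))
    di = md.data.design_info
    terms = _wald_terms(res, di, len(table))
    rv = {}
    try:
        cr = np.asarray(res.cov_re)
        for i, name in enumerate(md.data.exog_re_names or ["Intercept"]):
            rv[name] = float(cr[i, i])
    except Exception:
        pass
    return LMEResult(terms, rv, converged, formula, len(table))


class _OLSShim:
    """Adapter so OLS results expose the MixedLM attributes _wald_terms
    reads."""

    def __init__(self, res, k_fe):
        self._res = res
        self.k_fe = k_fe
        self.fe_params = np.asarray(res.params)

    def cov_params(self):
        return np.asarray(self._res.cov_params())


_FORMULA_BUILTINS = {"C", "Q", "I", "np", "log", "center", "standardize"}


def _formula_columns(formula: str) -> list:
    import re

    names = re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula)
    return [n for n in dict.fromkeys(names) if n not in _FORMULA_BUILTINS]


def bonferroni(p, m: int = 3):
    """Bonferroni adjustment: min(1, p*m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must be in (0, 1]")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


def power_lme(table: pd.DataFrame, band: str) -> LMEResult:
    """Band-power model: power ~ CS x Time x Region with random intercept
    and region slope by participant (amygdala as reference level)."""
    sub = table[table["band"] == band].copy()
    sub["CS"] = pd.Categorical(sub["condition"], categories=["CS-", "CS+"])
    sub["Region"] = pd.Categorical(
        sub["region"], categories=["amygdala", "hippocampus"])
    sub["Time"] = sub["block"].astype(float)
    return fit_lme(sub, "power ~ 1 + CS * Time * Region",
                   re_formula="~Region")


def pli_lme(table: pd.DataFrame) -> LMEResult:
    """PLI model: pli ~ CS x Time with random intercept by participant."""
    sub = table.copy()
    sub["CS"] = pd.Categorical(sub["condition"], categories=["CS-", "CS+"])
    sub["Time"] = sub["block"].astype(float)
    return fit_lme(sub, "pli ~ 1 + CS * Time", re_formula=None)


def posthoc_time_trend(table: pd.DataFrame, condition: str,
                       value: str = "pli") -> LMEResult:
    """Within-condition block trend: value ~ Time, random intercept."""
    sub = table[table["condition"] == condition].copy()
    if sub.empty:
        raise ValueError(f"no rows for condition {condition}")
    sub["Time"] = sub["block"].astype(float)
    return fit_lme(sub, f"{value} ~ 1 + Time", re_formula=None)
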