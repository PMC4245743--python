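"""Statistical ranking of the measure catalog.

Two post-hoc routes assess which measures discriminate experimental groups
or conditions:

1. ANOVA screening (repeated-measures one-way, or mixed two-way for
   multi-group studies) with Bonferroni correction, followed by a
   multinomial logistic regression on the few most significant z-scored
   measures; measures are ordered by the Euclidean norm of their logistic
   coefficients across all pairwise category contrasts.
2. A partial least squares (PLS2) regression of a centered indicator
   response on all z-scored measures; ordering again by the per-measure
   coefficient norm across category columns.

Both routes report the in-sample correct rate: the fraction of
observations whose most probable predicted category matches the truth.
The samples these designs produce are too small for a train/test split, so
all rates are in-sample by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core_io import StudyDesign, get_logger

log = get_logger("gaitshotgun.ranking")

__all__ = [
    "AnovaResult",
    "LogisticModel",
    "PlsModel",
    "RankingReport",
    "rm_anova_oneway",
    "mixed_anova_twoway",
    "oneway_anova_between",
    "bonferroni_threshold",
    "relative_difference",
    "select_by_pvalue",
    "zscore",
    "euclidean_beta_norm",
    "fit_multinomial_logistic",
    "correct_rate",
    "fit_pls_indicator",
    "rank_measures",
]

ALPHA = 0.05
DEFAULT_TOP_K = 7
DEFAULT_PLS_COMPONENTS = 7
RIDGE = 1e-8
#: escalated penalty used only when the unpenalized-like fit fails to
#: converge (perfect or quasi-separation)
RIDGE_FALLBACK = (1e-4, 1e-2)
#: on z-scored predictors, coefficients beyond this magnitude indicate
#: (quasi-)separation even when Newton technically converged
COEF_SEPARATION_BOUND = 30.0
MAX_NEWTON_ITER = 100


# ---------------------------------------------------------------------------
# ANOVA screening
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-measure F/p/partial-eta2 table with its Bonferroni threshold."""

    table: pd.DataFrame  # columns: measure, effect, F, p, eta_p2
    family_size: int

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.family_size)


def bonferroni_threshold(n: int) -> float:
    """Family-wise 5% significance threshold: 0.05 divided by the family size."""
    if n < 1:
        raise ValueError("family size must be >= 1")
    return ALPHA / n


def _f_pvalue(f: float, df1: float, df2: float) -> float:
    if not math.isfinite(f):
        return 0.0
    return float(spstats.f.sf(f, df1, df2))


def _pivot(table: pd.DataFrame, design: StudyDesign, measure: str) -> pd.DataFrame | None:
    """Subject x condition matrix of one measure; None when incomplete."""
    df = table[[measure]].reset_index()
    wide = df.pivot(index="subject", columns="condition", values=measure)
    wide = wide.reindex(index=design.subjects, columns=design.conditions)
    if wide.isna().any().any():
        return None
    return wide


def rm_anova_oneway(table: pd.DataFrame, design: StudyDesign) -> AnovaResult:
    """Repeated-measures one-way ANOVA (condition as within factor) per measure.

    The error term is the subject-by-condition interaction; partial eta
    squared is SS_effect / (SS_effect + SS_error).  Measures with missing
    cells (incomplete within-design) are skipped with a log line.
    """
    conditions = design.conditions
    if len(conditions) < 2:
        raise ValueError("within factor has one level")
    rows = []
    for measure in table.columns:
        wide = _pivot(table, design, measure)
        if wide is None:
            log.info("skipping measure %r: incomplete within-design", measure)
            continue
        x = wide.to_numpy(dtype=float)
        s, c = x.shape
        grand = x.mean()
        ss_cond = s * np.sum((x.mean(axis=0) - grand) ** 2)
        ss_subj = c * np.sum((x.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((x - grand) ** 2)
        ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
        df1, df2 = c - 1, (c - 1) * (s - 1)
        ms_err = ss_err / df2
        f = math.inf if ms_err == 0 and ss_cond > 0 else (
            0.0 if ms_err == 0 else (ss_cond / df1) / ms_err)
        eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
        rows.append({"measure": measure, "effect": "condition",
                     "F": f, "p": _f_pvalue(f, df1, df2), "eta_p2": eta})
    return AnovaResult(table=pd.DataFrame(rows), family_size=max(len(rows), 1))


def mixed_anova_twoway(table: pd.DataFrame, design: StudyDesign) -> AnovaResult:
    """Mixed two-way ANOVA: condition (within) x group (between), per measure.

    The group effect is tested against subjects-within-groups; condition and
    the interaction against the condition-by-subject-within-groups residual.
    A zero error variance with a non-zero effect is reported as F = inf,
    p = 0.
    """
    groups = design.groups
    conditions = design.conditions
    if len(groups) < 2 or len(conditions) < 2:
        raise ValueError("mixed ANOVA needs >= 2 groups and >= 2 conditions")
    group_of = {s: design.group_of(s) for s in design.subjects}
    for g in groups:
        if sum(1 for s in design.subjects if group_of[s] == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    c = len(conditions)
    rows = []
    for measure in table.columns:
        wide = _pivot(table, design, measure)
        if wide is None:
            log.info("skipping measure %r: incomplete within-design", measure)
            continue
        x = wide.to_numpy(dtype=float)
        subj_groups = np.array([groups.index(group_of[s]) for s in wide.index])
        grand = x.mean()
        subj_means = x.mean(axis=1)
        cond_means = x.mean(axis=0)
        n_subj = x.shape[0]

        # between-subject stratum
        ss_between = c * np.sum((subj_means - grand) ** 2)
        ss_group = 0.0
        group_means = {}
        for gi in range(len(groups)):
            sel = subj_groups == gi
            group_means[gi] = x[sel].mean()
            ss_group += c * sel.sum() * (group_means[gi] - grand) ** 2
        ss_subj_within = max(ss_between - ss_group, 0.0)
        df_group, df_sw = len(groups) - 1, n_subj - len(groups)

        # within-subject stratum
        ss_within = np.sum((x - subj_means[:, None]) ** 2)
        ss_cond = n_subj * np.sum((cond_means - grand) ** 2)
        ss_inter = 0.0
        for gi in range(len(groups)):
            sel = subj_groups == gi
            cell = x[sel].mean(axis=0)
            ss_inter += sel.sum() * np.sum(
                (cell - group_means[gi] - cond_means + grand) ** 2)
        ss_err = max(ss_within - ss_cond - ss_inter, 0.0)
        df_cond = c - 1
        df_inter = (len(groups) - 1) * (c - 1)
        df_err = (n_subj - len(groups)) * (c - 1)

        for effect, ss, df1, ss_e, df2 in (
                ("group", ss_group, df_group, ss_subj_within, df_sw),
                ("condition", ss_cond, df_cond, ss_err, df_err),
                ("interaction", ss_inter, df_inter, ss_err, df_err)):
            ms_e = ss_e / df2
            f = math.inf if ms_e == 0 and ss > 0 else (
                0.0 if ms_e == 0 else (ss / df1) / ms_e)
            eta = ss / (ss + ss_e) if (ss + ss_e) > 0 else 0.0
            rows.append({"measure": measure, "effect": effect,
                         "F": f, "p": _f_pvalue(f, df1, df2), "eta_p2": eta})
    n_measures = len({r["measure"] for r in rows})
    return AnovaResult(table=pd.DataFrame(rows), family_size=max(n_measures, 1))


def oneway_anova_between(values: pd.DataFrame, groups: pd.Series) -> AnovaResult:
    """Ordinary one-way between-subjects ANOVA per measure column.

    Used on per-subject relative-difference scores in multi-group studies.
    """
    labels = np.asarray(groups.astype(str))
    level_names = list(dict.fromkeys(labels))
    if len(level_names) < 2:
        raise ValueError("between factor has one level")
    rows = []
    for measure in values.columns:
        x = values[measure].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xv, lv = x[ok], labels[ok]
        grand = xv.mean()
        ss_group = sum((lv == g).sum() * ((xv[lv == g]).mean() - grand) ** 2
                       for g in level_names)
        ss_err = sum(np.sum((xv[lv == g] - xv[lv == g].mean()) ** 2)
                     for g in level_names)
        df1, df2 = len(level_names) - 1, xv.size - len(level_names)
        ms_err = ss_err / df2
        f = math.inf if ms_err == 0 and ss_group > 0 else (
            0.0 if ms_err == 0 else (ss_group / df1) / ms_err)
        eta = ss_group / (ss_group + ss_err) if (ss_group + ss_err) > 0 else 0.0
        rows.append({"measure": measure, "effect": "group",
                     "F": f, "p": _f_pvalue(f, df1, df2), "eta_p2": eta})
    return AnovaResult(table=pd.DataFrame(rows), family_size=max(len(rows), 1))


def relative_difference(x1, x2):
    """Paired relative difference: (x1 - x2) / pair mean, per subject.

    Antisymmetric in its arguments; a zero pair mean yields NaN for that
    subject (logged).
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal shape")
    mean = (a + b) / 2.0
    out = np.full(a.shape, math.nan)
    ok = mean != 0
    if not np.all(ok):
        log.warning("relative difference undefined for %d zero-mean pair(s)",
                    int(np.sum(~ok)))
    out[ok] = (a[ok] - b[ok]) / mean[ok]
    return out


def select_by_pvalue(anova: AnovaResult, k: int = DEFAULT_TOP_K,
                     mode: str = "top_k", effect: str | None = None) -> list[str]:
    """Measure subset for the regression stage.

    ``top_k`` returns the k most significant measures (smallest p);
    ``threshold`` returns those below the Bonferroni level.  Ties are
    broken by larger partial eta squared, then by name.
    """
    df = anova.table
    if effect is not None:
        df = df[df["effect"] == effect]
    df = df.sort_values(["p", "eta_p2", "measure"],
                        ascending=[True, False, True], kind="mergesort")
    if mode == "threshold":
        return df.loc[df["p"] < anova.threshold, "measure"].tolist()
    if mode != "top_k":
        raise ValueError(f"unknown selection mode {mode!r}")
    if k > len(df):
        log.warning("requested top %d of only %d measures", k, len(df))
    return df["measure"].head(k).tolist()


# ---------------------------------------------------------------------------
# multinomial logistic regression
# ---------------------------------------------------------------------------

def euclidean_beta_norm(coefficients) -> float:
    """A measure's ranking statistic: the Euclidean norm of its regression
    coefficients across category contrasts (logistic pairwise contrasts, or
    PLS category columns)."""
    return float(np.linalg.norm(np.asarray(coefficients, dtype=float)))


def zscore(X: np.ndarray) -> np.ndarray:
    """Column z-scores (population SD).  Raises on constant columns."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"cannot z-score constant column(s) at positions {bad}")
    return (X - X.mean(axis=0)) / sd


@dataclass
class LogisticModel:
    """Fitted multinomial logit with pairwise-contrast coefficient norms."""

    categories: list[str]
    reference: str
    measure_names: list[str]
    coef: np.ndarray            # (K-1) x (p+1), intercept first, vs reference
    beta_pairs: dict[tuple[str, str], np.ndarray]  # contrast -> p-vector
    beta_norm: pd.Series        # per measure, over all pairwise contrasts
    pvalues: np.ndarray         # Wald p per fitted coefficient, like coef
    probabilities: np.ndarray   # n x K
    correct_rate: float
    converged: bool

    def ordering(self) -> list[str]:
        return list(self.beta_norm.sort_values(ascending=False).index)


def _softmax_probs(Z: np.ndarray) -> np.ndarray:
    # Z: n x (K-1) linear predictors vs reference (reference column = 0)
    full = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def fit_multinomial_logistic(X: np.ndarray, y, measure_names: list[str] | None = None,
                             reference: str | None = None,
                             z_score: bool = True) -> LogisticModel:
    """Maximum-likelihood multinomial logistic regression.

    Fits log(pi_j / pi_ref) = b0_j + sum_i beta_ij x_i by Newton-Raphson
    with a tiny ridge (1e-8) for numerical safety under (near-)separation;
    a fit stopped at the iteration cap is flagged.  Measures are z-scored
    before entering the regression.  The per-measure norm is the Euclidean
    norm over the coefficients of *all* pairwise category contrasts (for
    three categories: the two reference contrasts plus their difference).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = pd.Series(list(y)).astype(str)
    categories = sorted(y.unique())
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    if n <= p:
        raise ValueError("observations must exceed the number of measures included")
    if measure_names is None:
        measure_names = [f"x{i + 1}" for i in range(p)]
    if reference is None:
        reference = categories[-1]
    if reference not in categories:
        raise ValueError(f"reference {reference!r} not among categories {categories}")
    non_ref = [c for c in categories if c != reference]
    K = len(categories)

    if z_score:
        X = zscore(X)
    # rank check on the design
    design = np.concatenate([np.ones((n, 1)), X], axis=1)
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("rank-deficient design matrix: collinear measure columns")

    Y = np.zeros((n, K - 1))
    for j, cat in enumerate(non_ref):
        Y[:, j] = (y == cat).to_numpy(dtype=float)

    d = p + 1

    def _newton(ridge: float) -> tuple[np.ndarray, bool]:
        w = np.zeros((K - 1) * d)
        for _ in range(MAX_NEWTON_ITER):
            W = w.reshape(K - 1, d)
            P = _softmax_probs(design @ W.T)[:, : K - 1]
            grad = (design.T @ (Y - P)).T.reshape(-1) - ridge * w
            H = np.zeros(((K - 1) * d, (K - 1) * d))
            for j in range(K - 1):
                for k_ in range(K - 1):
                    wgt = P[:, j] * ((j == k_) - P[:, k_])
                    H[j * d:(j + 1) * d, k_ * d:(k_ + 1) * d] = \
                        design.T @ (design * wgt[:, None])
            H += ridge * np.eye(H.shape[0])
            step = np.linalg.solve(H, grad)
            w = w + step
            if np.max(np.abs(step)) < 1e-10:
                return w, True
        return w, False

    w, converged = _newton(RIDGE)
    if converged and np.max(np.abs(w)) > COEF_SEPARATION_BOUND:
        converged = False
    if not converged:
        # (quasi-)separation: the ML optimum is at infinity; refit with an
        # escalating ridge so the coefficients are genuinely bounded
        for ridge in RIDGE_FALLBACK:
            w, converged = _newton(ridge)
            if converged and np.max(np.abs(w)) <= COEF_SEPARATION_BOUND:
                break
        log.warning("logistic fit did not converge at the base ridge "
                    "(possible separation); coefficients bounded by the "
                    "ridge fallback")
        converged = False

    W = w.reshape(K - 1, d)
    # Wald p-values from the inverse Hessian at the optimum
    Z = design @ W.T
    P = _softmax_probs(Z)[:, : K - 1]
    H = np.zeros(((K - 1) * d, (K - 1) * d))
    for j in range(K - 1):
        for k_ in range(K - 1):
            wgt = P[:, j] * ((j == k_) - P[:, k_])
            H[j * d:(j + 1) * d, k_ * d:(k_ + 1) * d] = design.T @ (design * wgt[:, None])
    H += RIDGE * np.eye(H.shape[0])
    se = np.sqrt(np.diag(np.linalg.inv(H))).reshape(K - 1, d)
    zstat = W / se
    pvals = 2 * spstats.norm.sf(np.abs(zstat))

    # pairwise contrasts: beta_cat - beta_ref (= coef rows) and differences
    beta_by_cat = {cat: W[j, 1:] for j, cat in enumerate(non_ref)}
    beta_by_cat[reference] = np.zeros(p)
    beta_pairs: dict[tuple[str, str], np.ndarray] = {}
    for a_i in range(K):
        for b_i in range(a_i + 1, K):
            ca, cb = categories[a_i], categories[b_i]
            beta_pairs[(ca, cb)] = beta_by_cat[ca] - beta_by_cat[cb]
    stacked = np.stack(list(beta_pairs.values()))  # n_pairs x p
    norms = pd.Series([euclidean_beta_norm(stacked[:, i]) for i in range(p)],
                      index=measure_names, name="beta_norm")

    probs = _softmax_probs(design @ W.T)
    model = LogisticModel(
        categories=categories, reference=reference, measure_names=measure_names,
        coef=W, beta_pairs=beta_pairs, beta_norm=norms, pvalues=pvals,
        probabilities=probs, correct_rate=0.0, converged=converged)
    model.correct_rate = correct_rate(model, None, y)
    return model


def correct_rate(model: LogisticModel, X=None, y=None) -> float:
    """In-sample fraction of observations assigned to their true category.

    Classification is by the highest predicted probability; exact ties are
    broken toward the reference category.
    """
    probs = model.probabilities
    y = pd.Series(list(y)).astype(str).to_numpy()
    cats = model.categories
    ref_idx = cats.index(model.reference)
    pred = []
    for row in probs:
        best = np.flatnonzero(row == row.max())
        idx = ref_idx if ref_idx in best else best[0]
        pred.append(cats[idx])
    return float(np.mean(np.asarray(pred) == y))


# ---------------------------------------------------------------------------
# partial least squares regression on an indicator response
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """PLS2 decomposition X = T P' + delta, Y = U Q' + eps, with Y ~ X beta."""

    categories: list[str]
    measure_names: list[str]
    n_components: int
    T: np.ndarray
    U: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    W: np.ndarray
    coef: np.ndarray            # p x K, on the z-scored X scale
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    beta_norm: pd.Series
    probabilities: np.ndarray   # predicted indicator scores, n x K
    correct_rate: float
    x_residual: np.ndarray | None = None
    y_residual: np.ndarray | None = None

    def ordering(self) -> list[str]:
        return list(self.beta_norm.sort_values(ascending=False).index)

    def predict_scores(self, X_raw: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X_raw, dtype=float) - self.x_mean) / self.x_std
        return Xc @ self.coef + self.y_mean


def fit_pls_indicator(X: np.ndarray, y, n_components: int = DEFAULT_PLS_COMPONENTS,
                      measure_names: list[str] | None = None) -> PlsModel:
    """PLS2 regression of a centered one-hot response on z-scored measures.

    NIPALS deflation: each component's X-weight vector maximizes covariance
    with the current Y residual; scores are mutually orthogonal and X is
    exactly reconstructed as T P' plus the residual.  Classification is by
    the arg-max of the predicted indicator scores; the per-measure norm is
    Euclidean across the category columns of the coefficient matrix.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = pd.Series(list(y)).astype(str)
    categories = sorted(y.unique())
    if n_components > min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} exceeds min(measures, observations-1)"
            f"={min(p, n - 1)}")
    if measure_names is None:
        measure_names = [f"x{i + 1}" for i in range(p)]

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    if np.any(x_std == 0):
        raise ValueError("cannot scale constant measure column(s)")
    Xc = (X - x_mean) / x_std
    Yind = np.stack([(y == c).to_numpy(dtype=float) for c in categories], axis=1)
    y_mean = Yind.mean(axis=0)
    Yc = Yind - y_mean

    Xd, Yd = Xc.copy(), Yc.copy()
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((len(categories), n_components))
    Wmat = np.zeros((p, n_components))
    for a in range(n_components):
        u = Yd[:, int(np.argmax((Yd ** 2).sum(axis=0)))].copy()
        for _ in range(500):
            wv = Xd.T @ u
            nw = np.linalg.norm(wv)
            if nw == 0:
                break
            wv /= nw
            t_vec = Xd @ wv
            qv = Yd.T @ t_vec / (t_vec @ t_vec)
            u_new = Yd @ qv / (qv @ qv)
            if np.linalg.norm(u_new - u) < 1e-12 * max(1.0, np.linalg.norm(u)):
                u = u_new
                break
            u = u_new
        t_vec = Xd @ wv
        tt = t_vec @ t_vec
        if tt == 0:
            log.warning("PLS stopped early at component %d (no X variance left)", a + 1)
            T, U, P, Q, Wmat = (M[:, :a] for M in (T, U, P, Q, Wmat))
            n_components = a
            break
        pv = Xd.T @ t_vec / tt
        qv = Yd.T @ t_vec / tt
        T[:, a], U[:, a], P[:, a], Q[:, a], Wmat[:, a] = t_vec, u, pv, qv, wv
        Xd = Xd - np.outer(t_vec, pv)
        Yd = Yd - np.outer(t_vec, qv)

    # beta on the scaled X: W (P'W)^-1 Q'
    PtW = P.T @ Wmat
    coef = Wmat @ np.linalg.solve(PtW, Q.T)
    scores = Xc @ coef + y_mean
    norms = pd.Series([euclidean_beta_norm(coef[i]) for i in range(p)],
                      index=measure_names, name="beta_norm")
    pred = np.asarray(categories)[np.argmax(scores, axis=1)]
    rate = float(np.mean(pred == y.to_numpy()))
    return PlsModel(categories=categories, measure_names=measure_names,
                    n_components=n_components, T=T, U=U, P=P, Q=Q, W=Wmat,
                    coef=coef, x_mean=x_mean, x_std=x_std, y_mean=y_mean,
                    beta_norm=norms, probabilities=scores, correct_rate=rate,
                    x_residual=Xd, y_residual=Yd)


# ---------------------------------------------------------------------------
# the two ranking routes
# ---------------------------------------------------------------------------

@dataclass
class RankingReport:
    """Outputs of both post-hoc routes over one measure table."""

    anova: AnovaResult
    selected: list[str]
    logistic: LogisticModel
    pls: PlsModel
    orderings: dict[str, list[str]] = field(default_factory=dict)
    mode: str = "studyA"
    #: raw-table mixed two-way ANOVA (studyB mode only)
    anova_mixed: AnovaResult | None = None

    def summary(self) -> str:
        lines = [f"ranking report (mode={self.mode})",
                 f"ANOVA family size N={self.anova.family_size}, "
                 f"Bonferroni threshold={self.anova.threshold:.6f}",
                 f"selected measures: {', '.join(self.selected)}",
                 f"logistic correct rate: {self.logistic.correct_rate:.3f}",
                 f"PLS correct rate: {self.pls.correct_rate:.3f}",
                 "", "logistic ordering (by beta-norm):"]
        for name in self.orderings["logistic"]:
            lines.append(f"  {name}: {self.logistic.beta_norm[name]:.3f}")
        lines.append("PLS top measures (by beta-norm):")
        for name in self.orderings["pls"][:10]:
            lines.append(f"  {name}: {self.pls.beta_norm[name]:.3f}")
        return "\n".join(lines)


def _drop_unusable(table: pd.DataFrame) -> pd.DataFrame:
    """Remove measure columns with missing values or no variance."""
    usable = []
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            log.info("dropping measure %r: missing values", col)
        elif np.std(vals) == 0:
            log.info("dropping measure %r: zero variance", col)
        else:
            usable.append(col)
    return table[usable]


def rank_measures(table: pd.DataFrame, design: StudyDesign,
                  mode: str = "studyA", top_k: int = DEFAULT_TOP_K,
                  pls_components: int = DEFAULT_PLS_COMPONENTS,
                  selection: str = "top_k") -> RankingReport:
    """Run both post-hoc routes over a measure table.

    ``studyA`` mode treats every subject x condition row as an observation
    and predicts the condition (screening by repeated-measures one-way
    ANOVA).  ``studyB`` mode requires exactly two conditions: for each
    measure the per-subject relative difference between the conditions
    forms one observation, and the predicted category is the group
    (screening by one-way between-subjects ANOVA on the differences; a
    mixed two-way ANOVA on the raw table is also included in the report's
    ANOVA table).
    """
    if len(design.conditions) < 2:
        raise ValueError("within factor has one level")
    table = _drop_unusable(table)
    if table.shape[1] == 0:
        raise ValueError("no usable measure columns")

    mixed: AnovaResult | None = None
    if mode == "studyA":
        anova = rm_anova_oneway(table, design)
        effect = "condition"
        X_full = table.to_numpy(dtype=float)
        obs_index = table.index
        labels = pd.Series([cond for _, cond in obs_index], index=obs_index)
        measure_names = list(table.columns)
    elif mode == "studyB":
        if len(design.conditions) != 2:
            raise ValueError("studyB mode requires exactly two conditions")
        c1, c2 = design.conditions
        wide1 = table.xs(c1, level="condition").reindex(design.subjects)
        wide2 = table.xs(c2, level="condition").reindex(design.subjects)
        rel = pd.DataFrame(
            relative_difference(wide1.to_numpy(dtype=float),
                                wide2.to_numpy(dtype=float)),
            index=design.subjects, columns=table.columns)
        rel = _drop_unusable(rel)
        groups = pd.Series([design.group_of(s) for s in rel.index], index=rel.index)
        anova = oneway_anova_between(rel, groups)
        # the raw-table mixed ANOVA complements the screening table
        mixed = mixed_anova_twoway(table, design)
        effect = "group"
        X_full = rel.to_numpy(dtype=float)
        labels = groups
        measure_names = list(rel.columns)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    selected = select_by_pvalue(anova, k=top_k, mode=selection, effect=effect)
    sel_idx = [measure_names.index(m) for m in selected]
    logistic = fit_multinomial_logistic(X_full[:, sel_idx], labels,
                                        measure_names=selected)
    l = min(pls_components, min(len(measure_names), X_full.shape[0] - 1))
    if l < pls_components:
        log.warning("reducing PLS components to %d (rank bound)", l)
    pls = fit_pls_indicator(X_full, labels, n_components=l,
                            measure_names=measure_names)
    return RankingReport(
        anova=anova, selected=selected, logistic=logistic, pls=pls,
        orderings={"logistic": logistic.ordering(), "pls": pls.ordering()},
        mode=mode, anova_mixed=mixed)
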