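"""Group-level inference for repeated-measures ERG designs.

Each crab is measured in every treatment, so observations cluster within
animals.  The workhorse is a random-intercept linear model (one variance
component for crab identity) combined with permutation tests of fixed
effects:

* the model is estimated by REML through a one-dimensional profile over the
  variance ratio lambda = tau^2/sigma^2, solving generalised least squares
  at each candidate - a formulation that stays well behaved on the tiny
  designs permutation enumeration needs;
* the test statistic for a term is the reduction in residual sum of squares
  between the null and full models on the GLS-whitened scale, with the
  variance components plugged in from the full-model fit and held fixed
  across permutations (the standard permutation-of-residuals compromise);
* permutations shuffle the tested term's labels *within* subject, the
  exchangeable unit under a random intercept; p = (r + 1)/(N + 1).

The within-subject whitening transform subtracts a fixed multiple of the
subject-block column sum, which is invariant under within-subject row
permutation - so designs are whitened once and only the tested term's
columns are re-permuted, keeping 10,000 permutations cheap.

Welch's t-test covers the unpaired unequal-variance comparisons, and the
six pairwise treatment contrasts are within-subject sign-flip permutation
tests with Holm adjustment (a conservative, permutation-native replacement
for parametric multivariate-t contrasts).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, ModelError

__all__ = [
    "ModelFit",
    "PermutationResult",
    "fit_random_intercept",
    "permutation_fixed_effect_test",
    "welch_t_test",
    "pairwise_contrasts",
]

DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class ModelFit:
    """Random-intercept linear model summary."""

    coefficients: dict[str, float]
    residual_variance: float
    subject_variance: float
    n_obs: int
    n_subjects: int
    formula: str


@dataclass(frozen=True)
class PermutationResult:
    """One permutation test: observed statistic, count and p-value."""

    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    term: str
    exact: bool = False


def _group_slices(groups: np.ndarray) -> dict:
    return {g: np.nonzero(groups == g)[0] for g in np.unique(groups)}


def _gls_profile(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """REML estimation of (beta, sigma2, tau2) via a 1-d profile over lambda.

    For lambda = tau2/sigma2 the marginal covariance is
    sigma2 * (I + lambda * Z Z'); each subject block of the inverse is
    I - lambda/(1 + n lambda) * J.  The profiled -2 REML log-likelihood is
    minimised over log-lambda by bounded scalar search.
    """
    n, p = X.shape
    slices = _group_slices(groups)
    sizes = {g: len(ix) for g, ix in slices.items()}

    def gls(lam: float):
        # accumulate X'V⁻¹X, X'V⁻¹y, y'V⁻¹y block-wise
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        logdet_v = 0.0
        for g, ix in slices.items():
            ng = sizes[g]
            c = lam / (1.0 + ng * lam)
            Xg, yg = X[ix], y[ix]
            sx, sy = Xg.sum(axis=0), yg.sum()
            XtX += Xg.T @ Xg - c * np.outer(sx, sx)
            Xty += Xg.T @ yg - c * sx * sy
            yty += yg @ yg - c * sy * sy
            logdet_v += math.log1p(ng * lam)
        beta = np.linalg.solve(XtX, Xty)
        rss = float(yty - beta @ Xty)
        return beta, rss, XtX, logdet_v

    def neg2_reml(log_lam: float) -> float:
        lam = math.exp(log_lam)
        try:
            _, rss, XtX, logdet_v = gls(lam)
        except np.linalg.LinAlgError:
            return math.inf
        sigma2 = rss / (n - p)
        sign, logdet_x = np.linalg.slogdet(XtX)
        if sign <= 0 or sigma2 <= 0:
            return math.inf
        return (n - p) * math.log(sigma2) + logdet_v + logdet_x

    res = sp_optimize.minimize_scalar(
        neg2_reml, bounds=(math.log(1e-8), math.log(1e8)), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = math.exp(res.x)
    # accept a boundary solution at ~zero subject variance
    if neg2_reml(math.log(1e-10)) <= res.fun:
        lam = 0.0
    beta, rss, _, _ = gls(lam)
    sigma2 = rss / (n - p)
    return beta, sigma2, lam * sigma2, lam


def fit_random_intercept(data: pd.DataFrame, formula: str, subject: str) -> ModelFit:
    """Fit ``response ~ fixed effects`` with a random intercept per subject.

    REML via the variance-ratio profile.  Raises `ModelError` on singular
    fixed-effect designs (naming the columns) or with fewer than two
    subjects.
    """
    if subject not in data.columns:
        raise ModelError(f"subject column {subject!r} missing")
    groups = data[subject].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ModelError("need >= 2 subjects for a random-intercept model")
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ModelError(
            f"singular fixed-effect design; collinear terms among {list(X.columns)}"
        )
    if len(data) <= Xm.shape[1]:
        raise ModelError("fewer observations than fixed-effect parameters")
    beta, sigma2, tau2, _ = _gls_profile(np.asarray(y).ravel(), Xm, groups)
    return ModelFit(
        coefficients=dict(zip(X.columns, map(float, beta))),
        residual_variance=float(sigma2),
        subject_variance=float(tau2),
        n_obs=int(len(data)),
        n_subjects=int(len(np.unique(groups))),
        formula=formula,
    )


def _whiten(M: np.ndarray, groups: np.ndarray, sigma2: float, tau2: float) -> np.ndarray:
    """Apply V^{-1/2} for V = sigma2*I + tau2*J per subject block.

    Within a block of size n, V^{-1/2} = (1/sigma)(I - c/n * J) with
    c = 1 - sigma/sqrt(sigma2 + n*tau2).
    """
    sigma = math.sqrt(sigma2)
    W = np.array(M, dtype=float, copy=True)
    if W.ndim == 1:
        W = W[:, None]
        squeeze = True
    else:
        squeeze = False
    for g, ix in _group_slices(groups).items():
        n = len(ix)
        c = 1.0 - sigma / math.sqrt(sigma2 + n * tau2)
        block = W[ix]
        W[ix] = (block - (c / n) * block.sum(axis=0, keepdims=True)) / sigma
    return W.ravel() if squeeze else W


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _term_column_indexes(design_info, term: str) -> list[int]:
    """Column indexes of every design term whose factors involve `term`."""
    out: list[int] = []
    for t, sl in design_info.term_name_slices.items():
        if t == "Intercept":
            continue
        factors = t.split(":")
        if any(term == f or f.startswith(f"C({term}") or f == f"C({term})"
               for f in factors):
            out.extend(range(sl.start, sl.stop))
    return out


def permutation_fixed_effect_test(
    data: pd.DataFrame,
    formula: str,
    term: str,
    subject: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    *,
    exact: bool = False,
    within_subject: bool = True,
) -> PermutationResult:
    """Permutation test of one fixed-effect term in the random-intercept model.

    The observed statistic is RSS(null) - RSS(full) on the whitened scale
    (variance components from the full-model REML fit, held fixed).
    Permutations shuffle `term`'s labels within each subject;
    ``within_subject=False`` shuffles whole rows freely instead (a
    sensitivity check that ignores the clustering).  ``exact=True``
    enumerates every within-subject relabelling (feasible only for tiny
    designs) and returns the exhaustive p-value, counting the identity.

    Raises
    ------
    DesignError
        If the term is constant within every subject while within-subject
        shuffling was requested, or the term does not appear in the model.
    """
    if term not in data.columns:
        raise DesignError(f"term {term!r} is not a column of the data")
    if not exact and n_perm < 99:
        raise DesignError("n_perm must be >= 99")
    groups = data[subject].to_numpy()
    slices = _group_slices(groups)
    if within_subject:
        tvals = data[term].to_numpy()
        if all(len(set(tvals[ix])) <= 1 for ix in slices.values()):
            raise DesignError(
                f"term {term!r} is constant within every subject; "
                "within-subject shuffling cannot permute it"
            )

    mf = fit_random_intercept(data, formula, subject)
    sigma2 = max(mf.residual_variance, 1e-12)
    tau2 = max(mf.subject_variance, 0.0)

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    term_cols = _term_column_indexes(X.design_info, term)
    if not term_cols:
        raise DesignError(f"term {term!r} does not appear in {formula!r}")
    other_cols = [i for i in range(X.shape[1]) if i not in term_cols]

    yw = _whiten(np.asarray(y).ravel(), groups, sigma2, tau2)
    Xw = _whiten(X.to_numpy(), groups, sigma2, tau2)
    rss_null = _rss(Xw[:, other_cols], yw)

    def stat(term_block: np.ndarray) -> float:
        Xf = np.column_stack([Xw[:, other_cols], term_block])
        return rss_null - _rss(Xf, yw)

    base_block = Xw[:, term_cols]
    obs = stat(base_block)

    def permute_block(perm_by_group: dict) -> np.ndarray:
        # whitening commutes with within-subject row permutation, so the
        # whitened term columns can be permuted directly
        block = base_block.copy()
        for g, perm in perm_by_group.items():
            ix = slices[g]
            block[ix] = block[ix][perm]
        return block

    if exact:
        per_group = {
            g: list(itertools.permutations(range(len(ix))))
            for g, ix in slices.items()
        }
        total = 1
        for v in per_group.values():
            total *= len(v)
        if total > 500_000:
            raise DesignError(f"exhaustive enumeration infeasible ({total} relabellings)")
        keys = list(per_group)
        count = 0
        for combo in itertools.product(*(per_group[k] for k in keys)):
            s = stat(permute_block({k: np.array(p) for k, p in zip(keys, combo)}))
            if s >= obs - 1e-12:
                count += 1
        return PermutationResult(
            observed=obs, n_permutations=total, p_value=count / total,
            seed=None, term=term, exact=True,
        )

    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        if within_subject:
            block = permute_block(
                {g: rng.permutation(len(ix)) for g, ix in slices.items()}
            )
        else:
            block = base_block[rng.permutation(base_block.shape[0])]
        if stat(block) >= obs - 1e-12:
            r += 1
    return PermutationResult(
        observed=obs, n_permutations=n_perm, p_value=(r + 1) / (n_perm + 1),
        seed=seed, term=term,
    )


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    Degrees of freedom by Welch-Satterthwaite.  Two samples with zero
    variance and equal means return (0, n1+n2-2, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DesignError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return (
            math.copysign(math.inf, x.mean() - y.mean()),
            float(x.size + y.size - 2),
            0.0,
        )
    res = sp_stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_contrasts(
    data: pd.DataFrame,
    response: str,
    group: str,
    subject: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> pd.DataFrame:
    """All six pairwise within-subject contrasts between four conditions.

    For each pair of levels the statistic is the mean of per-subject mean
    differences; the null distribution flips the sign of each subject's
    difference (exhaustively when at most 16 subjects have data, otherwise
    by sampling `n_perm` flips).  Holm-adjusted p-values are reported
    alongside the raw ones (adjusted >= raw always).
    """
    levels = sorted(data[group].unique())
    if len(levels) != 4:
        raise DesignError(f"expected 4 levels of {group!r}, found {len(levels)}")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        da = data[data[group] == a].groupby(subject)[response].mean()
        db = data[data[group] == b].groupby(subject)[response].mean()
        common = da.index.intersection(db.index)
        if len(common) < 2:
            raise DesignError(f"fewer than 2 subjects share conditions {a} and {b}")
        d = (da[common] - db[common]).to_numpy()
        obs = abs(d.mean())
        n = d.size
        if n <= 16:
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
            stats = np.abs(signs @ d) / n
            p_raw = float(np.mean(stats >= obs - 1e-12))
        else:
            flips = rng.choice([1.0, -1.0], size=(n_perm, n))
            stats = np.abs(flips @ d) / n
            p_raw = (int(np.sum(stats >= obs - 1e-12)) + 1) / (n_perm + 1)
        rows.append({"a": a, "b": b, "estimate": float(d.mean()),
                     "n_subjects": n, "p_raw": p_raw})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out
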