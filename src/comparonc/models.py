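"""Comparative analyses of species-level cancer mortality risk.

The central model is a zero-inflated two-part regression on the species
trait table:

* a *detection* part — phylogenetic logistic regression (penalized
  quasi-likelihood with a tree-structured random effect of scale s2) for
  whether any cancer death was observed in a species, with the log count
  of necropsied individuals as a detectability covariate;
* a *magnitude* part — weighted PGLS of logit(risk) on log body mass and
  log adult life expectancy among species with non-zero risk, weighted by
  log necropsy count, with Pagel's lambda profiled by maximum likelihood.

Splitting at zero avoids logit(0) without any ad hoc continuity
correction.  Supporting analyses: phylogenetic signal, phylogenetic
paired t-tests for sex bias, per-food-item diet models, and order-level
linear models with pairwise contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sstats

from .phylo import (
    ModelFit,
    Phylogeny,
    gls_fit,
    lambda_ml,
    lambda_transform,
)

logger = logging.getLogger(__name__)

# species excluded from the magnitude part by default when requested:
# very short-lived outliers whose leverage dominates the life-expectancy axis
HIGH_LEVERAGE_SPECIES = ("Lagurus lagurus", "Cricetus cricetus", "Dasyuroides byrnei")


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


# ---------------------------------------------------------------------------
# phylogenetic signal


@dataclass
class SignalResult:
    lam: float
    pvalue: float
    loglik_lam: float
    loglik_zero: float
    degenerate: bool = False


def phylo_signal(
    trait: np.ndarray,
    tree: Phylogeny | np.ndarray,
    species=None,
    boundary_correction: bool = False,
) -> SignalResult:
    """ML Pagel's lambda for a trait with a likelihood-ratio test vs 0.

    The null distribution is chi-square with 1 df; since lambda = 0 lies on
    the boundary of the parameter space, ``boundary_correction=True`` halves
    the P value (50:50 mixture convention).
    """
    y = np.asarray(trait, dtype=float)
    if y.size < 4:
        raise ValueError("phylogenetic signal needs at least 4 species")
    if np.allclose(y, y[0]):
        return SignalResult(0.0, 1.0, np.nan, np.nan, degenerate=True)
    X = np.ones((y.size, 1))
    lam, fit = lambda_ml(y, X, tree, species=species, names=["intercept"])
    if isinstance(tree, Phylogeny):
        _, C1 = tree.covariance(1.0, species=species)
    else:
        C1 = np.asarray(tree, dtype=float)
    fit0 = gls_fit(y, X, lambda_transform(C1, 0.0), names=["intercept"], lam=0.0)
    lr = max(0.0, 2.0 * (fit.loglik - fit0.loglik))
    p = float(sstats.chi2.sf(lr, df=1))
    if boundary_correction:
        p = p / 2.0 if lr > 0 else 1.0
    return SignalResult(lam=lam, pvalue=p, loglik_lam=fit.loglik, loglik_zero=fit0.loglik)


# ---------------------------------------------------------------------------
# phylogenetic logistic regression (PQL)


def binary_pglmm(
    y01: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    names=None,
    s2: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    s2_max: float = 10.0,
) -> ModelFit:
    """Logistic regression with a phylogenetically structured random effect.

    Model: logit P(y_i = 1) = x_i'beta + b_i, b ~ N(0, s2 * C).  Fitted by
    penalized quasi-likelihood: the working response is iterated jointly
    with (beta, b), and s2 is refreshed each sweep by maximizing the
    restricted likelihood of the working linear mixed model.  With ``s2``
    fixed at 0 the iteration is exactly IRLS for plain logistic regression.

    Separation (diverging coefficients) is reported via ``converged=False``
    rather than raised.
    """
    y = np.asarray(y01, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)

    estimate_s2 = s2 is None
    s2_cur = 0.01 if estimate_s2 else float(s2)
    ybar = np.clip(y.mean(), 0.01, 0.99)
    beta = np.zeros(p)
    beta[0] = np.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0
    b = np.zeros(n)

    separated = False
    converged = False
    V = None
    for _ in range(max_iter):
        eta = X @ beta + b
        mu = inv_logit(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w

        def working_fit(s2_val):
            Vw = np.diag(1.0 / w) + s2_val * C
            Lw = linalg.cholesky(Vw, lower=True)
            Xw = linalg.solve_triangular(Lw, X, lower=True)
            zw = linalg.solve_triangular(Lw, z, lower=True)
            XtX = Xw.T @ Xw
            bta = linalg.solve(XtX, Xw.T @ zw, assume_a="pos")
            r = zw - Xw @ bta
            logdetV = 2.0 * np.sum(np.log(np.diag(Lw)))
            sign, logdetXtX = np.linalg.slogdet(XtX)
            reml = -0.5 * (logdetV + logdetXtX + float(r @ r))
            return bta, reml, Vw, XtX

        if estimate_s2:
            res = optimize.minimize_scalar(
                lambda s: -working_fit(s)[1],
                bounds=(0.0, s2_max),
                method="bounded",
                options={"xatol": 1e-5},
            )
            s2_cur = float(res.x)
            if -res.fun < -working_fit(0.0)[1]:
                s2_cur = 0.0
        beta_new, _, V, XtX = working_fit(s2_cur)

        # random-effect BLUP: b = s2 C V^{-1} (z - X beta)
        rz = z - X @ beta_new
        b_new = s2_cur * (C @ linalg.solve(V, rz, assume_a="pos"))

        delta = max(
            np.max(np.abs(beta_new - beta)), np.max(np.abs(b_new - b)) if n else 0.0
        )
        beta, b = beta_new, b_new
        if np.max(np.abs(beta)) > 15.0:
            separated = True
            break
        if delta < tol:
            converged = True
            break

    cov_beta = linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    zstat = beta / se
    pval = 2.0 * sstats.norm.sf(np.abs(zstat))
    fit = ModelFit(
        names=names,
        coef=beta,
        se=se,
        tstat=zstat,
        pvalue=pval,
        lam=None,
        s2=s2_cur,
        loglik=np.nan,
        n=n,
        df_resid=n - p,
        weights_desc="binomial working weights",
        converged=converged and not separated,
        y=y,
        X=X,
        V=V,
    )
    if separated:
        logger.warning("binary_pglmm: separation detected (|coef| diverging)")
    return fit


# ---------------------------------------------------------------------------
# zero-inflated two-part model


@dataclass
class ZeroInflatedFit:
    detection: ModelFit | None
    magnitude: ModelFit
    zero_species: list[str]
    nonzero_species: list[str]
    response: str
    notes: list[str]


def _require_positive(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        if (df[c] <= 0).any():
            bad = df.loc[df[c] <= 0, "species"].tolist()
            raise ValueError(f"non-positive {c} for {bad}")
    return df


def fit_zero_inflated(
    traits: pd.DataFrame,
    tree: Phylogeny,
    response: str = "cmr",
    exclude_species=None,
    interaction: bool = False,
    min_nonzero: int = 10,
) -> ZeroInflatedFit:
    """Two-part zero-inflated phylogenetic model of cancer mortality risk.

    ``traits`` needs columns: species, <response>, n_necropsied, body_mass,
    life_expectancy (plus icm_eligible when response='icm').
    """
    notes: list[str] = []
    df = traits.copy()
    if response == "icm" and "icm_eligible" in df.columns:
        df = df[df["icm_eligible"].astype(bool)]
    df = df.dropna(subset=[response, "body_mass", "life_expectancy", "n_necropsied"])
    _require_positive(df, ["body_mass", "life_expectancy", "n_necropsied"])
    df = df[df["species"].isin(set(tree.tip_labels))]
    df = df.reset_index(drop=True)

    risk = df[response].to_numpy(dtype=float)
    detected = (risk > 0).astype(float)
    log_mass = np.log(df["body_mass"].to_numpy(dtype=float))
    log_le = np.log(df["life_expectancy"].to_numpy(dtype=float))
    log_n = np.log(df["n_necropsied"].to_numpy(dtype=float))
    species = df["species"].tolist()

    # part 1: detection
    detection = None
    if detected.min() == detected.max():
        notes.append("detection part skipped: response has no zero/non-zero split")
    else:
        sub = tree.prune_to(species)
        _, C1 = sub.covariance(1.0, species=species)
        Xd = np.column_stack([np.ones(len(df)), log_n, log_mass, log_le])
        detection = binary_pglmm(
            detected,
            Xd,
            C1,
            names=["intercept", "log_n_necropsied", "log_body_mass", "log_life_expectancy"],
        )

    # part 2: magnitude on risks strictly inside (0, 1); a risk of exactly 1
    # (every necropsied death attributed to cancer, only seen in tiny
    # samples) has no logit and is set aside like the zeros
    saturated = df.loc[risk >= 1, "species"].tolist()
    if saturated:
        notes.append(f"species with risk = 1 excluded from magnitude part: {saturated}")
    nz = df[(risk > 0) & (risk < 1)].reset_index(drop=True)
    if exclude_species:
        dropped = nz[nz["species"].isin(set(exclude_species))]["species"].tolist()
        if dropped:
            notes.append(f"high-leverage exclusions: {dropped}")
        nz = nz[~nz["species"].isin(set(exclude_species))].reset_index(drop=True)
    if len(nz) < min_nonzero:
        raise ValueError(
            f"only {len(nz)} species with non-zero {response}; "
            f"need at least {min_nonzero} for the magnitude part"
        )
    y = logit(nz[response].to_numpy(dtype=float))
    lm = np.log(nz["body_mass"].to_numpy(dtype=float))
    le = np.log(nz["life_expectancy"].to_numpy(dtype=float))
    w = np.log(nz["n_necropsied"].to_numpy(dtype=float))
    cols = [np.ones(len(nz)), lm, le]
    names = ["intercept", "log_body_mass", "log_life_expectancy"]
    if interaction:
        cols.append(lm * le)
        names.append("log_body_mass:log_life_expectancy")
    X = np.column_stack(cols)
    sub = tree.prune_to(nz["species"].tolist())
    _, magnitude = lambda_ml(
        y,
        X,
        sub,
        case_weights=w,
        species=nz["species"].tolist(),
        names=names,
        weights_desc="ln(n_necropsied) precision weights",
    )
    return ZeroInflatedFit(
        detection=detection,
        magnitude=magnitude,
        zero_species=df.loc[risk == 0, "species"].tolist(),
        nonzero_species=nz["species"].tolist(),
        response=response,
        notes=notes,
    )


def predict_risk(fit: ModelFit, body_mass: float, life_expectancy: float) -> float:
    """Predicted risk (percent) from a magnitude-part fit at given covariates."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if body_mass <= 0 or life_expectancy <= 0:
        raise ValueError("body mass and life expectancy must be positive")
    lp = (
        fit.coef_named("intercept")
        + fit.coef_named("log_body_mass") * np.log(body_mass)
        + fit.coef_named("log_life_expectancy") * np.log(life_expectancy)
    )
    if "log_body_mass:log_life_expectancy" in fit.names:
        lp += fit.coef_named("log_body_mass:log_life_expectancy") * np.log(
            body_mass
        ) * np.log(life_expectancy)
    return float(inv_logit(lp) * 100.0)


def anchored_doubling_prediction(
    p1_pct: float, p2_pct: float, n_doublings: float
) -> float:
    """Extrapolate a logit-linear doubling model through two predictions.

    Given predicted risks (percent) at a covariate value and at its double,
    the per-doubling logit slope is fixed and the model extends to any
    number of doublings from the first anchor; e.g. anchors at 1 kg and
    2 kg extrapolate to 1,024 kg with ``n_doublings=10``.
    """
    l1 = float(logit(p1_pct / 100.0))
    l2 = float(logit(p2_pct / 100.0))
    return float(inv_logit(l1 + n_doublings * (l2 - l1)) * 100.0)


# ---------------------------------------------------------------------------
# prediction-based partial R^2


def _phylo_predictions(fit: ModelFit) -> np.ndarray:
    """Leave-one-out conditional (kriging) predictions under the fitted
    error covariance: each species is predicted from the model mean plus
    the covariance-weighted residuals of all other species."""
    y, X, V = fit.y, fit.X, fit.V
    mu = X @ fit.coef
    r = y - mu
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Vii = V[np.ix_(mask, mask)]
        vi = V[i, mask]
        preds[i] = mu[i] + vi @ linalg.solve(Vii, r[mask], assume_a="pos")
    return preds


def partial_r2(full: ModelFit, reduced: ModelFit) -> float:
    """Prediction-based partial R^2 of the terms dropped from ``full``.

    1 - SSE_pred(full) / SSE_pred(reduced), clipped at 0, using each
    model's phylogeny-informed conditional predictions.
    """
    if reduced.n != full.n or not set(reduced.names) <= set(full.names):
        raise ValueError("reduced model must nest in full (same species)")
    if not np.allclose(reduced.y, full.y):
        raise ValueError("models were fitted to different responses")
    sse_full = float(np.sum((full.y - _phylo_predictions(full)) ** 2))
    sse_red = float(np.sum((reduced.y - _phylo_predictions(reduced)) ** 2))
    if sse_red <= 0:
        return 0.0
    return max(0.0, 1.0 - sse_full / sse_red)


# ---------------------------------------------------------------------------
# sex bias: phylogenetic paired t-test


@dataclass
class PairedTestResult:
    tstat: float
    df: int
    pvalue: float
    lam: float
    mean_difference: float
    degenerate: bool = False


def phylo_paired_ttest(
    values_a,
    values_b,
    tree: Phylogeny | np.ndarray,
    species=None,
    df_convention: str = "n-2",
) -> PairedTestResult:
    """Test whether paired species values differ, under phylogenetic
    covariance: a GLS intercept-only fit to the within-species differences
    with ML lambda.  ``df_convention`` in {"n-1", "n-2", "n-3"}.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired species")
    d = a - b
    if np.allclose(d, d[0]) and np.allclose(d.std(), 0.0):
        return PairedTestResult(np.nan, 0, np.nan, 0.0, float(d.mean()), degenerate=True)
    lam, fit = lambda_ml(d, np.ones((d.size, 1)), tree, species=species, names=["mean_diff"])
    t = float(fit.tstat[0])
    n = d.size
    df = {"n-1": n - 1, "n-2": n - 2, "n-3": n - 3}[df_convention]
    p = float(2.0 * sstats.t.sf(abs(t), df))
    return PairedTestResult(
        tstat=t, df=df, pvalue=p, lam=lam, mean_difference=float(fit.coef[0])
    )


# ---------------------------------------------------------------------------
# diet models


DIET_ITEMS = ("animal", "invertebrate", "vertebrate", "fish", "reptile", "bird", "mammal")

_DIET_BINARY = {"never": 0, "occasional": 0, "secondary": 1, "primary": 1}


def recode_diet(level: str) -> int:
    """Four-level diet coding collapsed to binary: never/occasional -> 0,
    secondary/primary -> 1."""
    try:
        return _DIET_BINARY[level]
    except KeyError:
        raise ValueError(f"unknown diet level {level!r}")


def diet_model(
    traits: pd.DataFrame,
    tree: Phylogeny,
    diet_item: str,
    response: str = "cmr",
) -> tuple[ModelFit, bool]:
    """PGLS of logit risk on a binary diet flag plus the base covariates
    (log mass, log life expectancy), on non-zero-risk species only.

    Returns (fit, sparse_flag); sparse_flag marks a diet level with fewer
    than 3 species.
    """
    col = f"diet_{diet_item}"
    if col not in traits.columns:
        raise KeyError(f"traits table has no column {col}")
    df = traits.dropna(subset=[response, "body_mass", "life_expectancy", col])
    df = df[(df[response] > 0) & (df[response] < 1)].reset_index(drop=True)
    df = df[df["species"].isin(set(tree.tip_labels))].reset_index(drop=True)
    flag = df[col].astype(int).to_numpy()
    counts = np.bincount(flag, minlength=2)
    sparse = bool(counts.min() < 3)
    if sparse:
        logger.warning("diet item %s: a level has < 3 species", diet_item)
    y = logit(df[response].to_numpy(dtype=float))
    X = np.column_stack(
        [
            np.ones(len(df)),
            flag.astype(float),
            np.log(df["body_mass"].to_numpy(dtype=float)),
            np.log(df["life_expectancy"].to_numpy(dtype=float)),
        ]
    )
    names = ["intercept", col, "log_body_mass", "log_life_expectancy"]
    w = np.log(df["n_necropsied"].to_numpy(dtype=float)) if "n_necropsied" in df else None
    sub = tree.prune_to(df["species"].tolist())
    _, fit = lambda_ml(
        y, X, sub, case_weights=w, species=df["species"].tolist(), names=names,
        weights_desc="ln(n_necropsied) precision weights" if w is not None else "unit",
    )
    return fit, sparse


# ---------------------------------------------------------------------------
# order differences


@dataclass
class OrderContrasts:
    means: pd.DataFrame  # order, n_species, mean_risk_pct
    contrasts: pd.DataFrame  # order_a, order_b, estimate, p_adjusted


def order_contrasts(
    traits: pd.DataFrame,
    response: str = "cmr",
    min_species: int = 2,
    adjust: str = "tukey",
) -> OrderContrasts:
    """One-way linear model of percentage risk on taxonomic order, with all
    pairwise order differences (Tukey-adjusted by default; 'none' and
    'bonferroni' also supported).  Orders with fewer than ``min_species``
    species are dropped.
    """
    df = traits.dropna(subset=[response, "order"]).copy()
    counts = df.groupby("order")["species"].count()
    orders = counts[counts >= min_species].index.tolist()
    if len(orders) < 2:
        raise ValueError("need at least two orders with enough species")
    df = df[df["order"].isin(orders)]
    risk_pct = df[response].to_numpy(dtype=float) * 100.0
    groups = df["order"].to_numpy()

    means = (
        pd.DataFrame({"order": groups, "risk_pct": risk_pct})
        .groupby("order")
        .agg(n_species=("risk_pct", "size"), mean_risk_pct=("risk_pct", "mean"))
        .reset_index()
    )

    if adjust == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(risk_pct, groups)
        tbl = pd.DataFrame(
            res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
        )
        contrasts = pd.DataFrame(
            {
                "order_a": tbl["group1"],
                "order_b": tbl["group2"],
                "estimate": -tbl["meandiff"].astype(float),
                "p_adjusted": tbl["p-adj"].astype(float),
            }
        )
    else:
        rows = []
        k = len(orders)
        m = k * (k - 1) // 2
        gm = {o: risk_pct[groups == o] for o in orders}
        # pooled residual variance from the one-way model
        resid = np.concatenate([gm[o] - gm[o].mean() for o in orders])
        dfree = len(risk_pct) - k
        s2 = float(resid @ resid) / dfree
        for i in range(k):
            for j in range(i + 1, k):
                a, b = orders[i], orders[j]
                est = gm[a].mean() - gm[b].mean()
                se = np.sqrt(s2 * (1 / len(gm[a]) + 1 / len(gm[b])))
                p = 2 * sstats.t.sf(abs(est / se), dfree)
                if adjust == "bonferroni":
                    p = min(1.0, p * m)
                rows.append(
                    {"order_a": a, "order_b": b, "estimate": est, "p_adjusted": p}
                )
        contrasts = pd.DataFrame(rows)
    return OrderContrasts(means=means, contrasts=contrasts)
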