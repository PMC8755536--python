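"""Phylogeny handling and the generalized least-squares engine.

The comparative analyses model species-level residuals as correlated
according to shared evolutionary history: under Brownian motion the
covariance of two species equals the depth of their most recent common
ancestor.  Pagel's lambda rescales the off-diagonal covariances,
interpolating between a star phylogeny (lambda = 0, independent species)
and the full Brownian expectation (lambda = 1).

``gls_fit`` solves the weighted phylogenetic regression by Cholesky
whitening; ``lambda_ml`` profiles the maximum-likelihood lambda on [0, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize
from scipy import stats as sstats


class Phylogeny:
    """Rooted tree with branch lengths; tip labels are canonical binomials."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        if isinstance(source, Path):
            tree = dendropy.Tree.get(path=str(source), schema="newick")
        elif "(" in source:  # newick data, not a path
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        return cls(tree)

    def write_newick(self, path: str | Path) -> None:
        self._tree.write(path=str(path), schema="newick", suppress_rooting=True)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True)

    # -- basic queries ------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            lf.taxon.label: lf.root_distance for lf in self._tree.leaf_node_iter()
        }

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        span = depths.max() - depths.min()
        return bool(span <= rel_tol * max(depths.max(), 1e-300))

    # -- manipulation -------------------------------------------------------

    def prune_to(self, species: Sequence[str]) -> "Phylogeny":
        keep = set(species)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree)

    def graft_sister(self, existing_tip: str, new_tip: str) -> "Phylogeny":
        """Attach ``new_tip`` as sister of ``existing_tip``.

        The existing terminal edge is split at its midpoint and both tips
        hang from the new node with equal lengths, so tip depths (and
        ultrametricity) are preserved.
        """
        if new_tip in self.tip_labels:
            raise ValueError(f"tip {new_tip!r} already in tree")
        tree = self._tree.clone(depth=1)
        leaf = None
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == existing_tip:
                leaf = lf
                break
        if leaf is None:
            raise KeyError(f"tip {existing_tip!r} not in tree")
        length = leaf.edge.length if leaf.edge.length is not None else 0.0
        parent = leaf.parent_node
        if parent is None:
            raise ValueError("cannot graft onto a single-tip tree root")
        parent.remove_child(leaf)
        mid = parent.new_child(edge_length=length / 2.0)
        mid.add_child(leaf)
        leaf.edge.length = length / 2.0
        taxon = tree.taxon_namespace.new_taxon(label=new_tip)
        mid.new_child(taxon=taxon, edge_length=length / 2.0)
        return Phylogeny(tree)

    # -- covariance ---------------------------------------------------------

    def covariance(self, lam: float = 1.0, species: Sequence[str] | None = None):
        """(species order, C(lambda)) shared-path-length covariance matrix."""
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        order = list(species) if species is not None else self.tip_labels
        tree = self._tree
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        missing = set(order) - set(leaves)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        pdm = tree.phylogenetic_distance_matrix()
        n = len(order)
        depths = np.array([leaves[sp].root_distance for sp in order])
        C = np.empty((n, n))
        for i, a in enumerate(order):
            C[i, i] = depths[i]
            for j in range(i + 1, n):
                d = pdm.patristic_distance(leaves[a].taxon, leaves[order[j]].taxon)
                shared = 0.5 * (depths[i] + depths[j] - d)
                C[i, j] = C[j, i] = shared
        return order, lambda_transform(C, lam)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda, keeping the diagonal."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def read_newick(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(path)


# ---------------------------------------------------------------------------
# GLS


class SingularDesignError(ValueError):
    pass


@dataclass
class ModelFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    lam: float | None
    s2: float | None
    loglik: float
    n: int
    df_resid: int
    weights_desc: str
    converged: bool = True
    # retained inputs for prediction-based diagnostics
    y: np.ndarray | None = field(default=None, repr=False)
    X: np.ndarray | None = field(default=None, repr=False)
    V: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"n = {self.n}, logLik = {self.loglik:.4f}, "
            f"lambda = {self.lam if self.lam is not None else 'NA'}, "
            f"s2 = {self.s2 if self.s2 is not None else 'NA'}, "
            f"weights: {self.weights_desc}"
        ]
        lines.append(f"{'term':<24}{'coef':>12}{'se':>12}{'stat':>10}{'P':>12}")
        for nm, b, s, t, p in zip(
            self.names, self.coef, self.se, self.tstat, self.pvalue
        ):
            lines.append(f"{nm:<24}{b:>12.5f}{s:>12.5f}{t:>10.3f}{p:>12.4g}")
        return "\n".join(lines)

    def coef_named(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coef,
                "se": self.se,
                "stat": self.tstat,
                "p": self.pvalue,
            }
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting
        _, R, piv = linalg.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad = bad or [names[p] for p in piv[rank:]]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    covariance: np.ndarray,
    case_weights: np.ndarray | None = None,
    names: Sequence[str] | None = None,
    lam: float | None = None,
    weights_desc: str = "unit",
) -> ModelFit:
    """Weighted phylogenetic GLS.

    The error covariance is ``sigma^2 * D C D`` with ``D = diag(1/sqrt(w))``:
    case weights act as precision multipliers, shrinking the residual
    variance of well-sampled species without altering correlations.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n or covariance.shape != (n, n):
        raise ValueError("y, X and covariance must be row-aligned")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    _check_rank(X, names)

    if case_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(case_weights, dtype=float).ravel()
        if np.any(w <= 0):
            raise ValueError("case weights must be positive")
    d = 1.0 / np.sqrt(w)
    V = covariance * np.outer(d, d)

    # near-zero terminal branches (e.g. fresh sister grafts) can leave V
    # semi-definite to machine precision; a vanishing diagonal jitter fixes
    # that without masking genuinely singular inputs
    scale = float(np.mean(np.diag(V)))
    L = None
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            L = linalg.cholesky(V + jitter * scale * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            continue
    if L is None:
        raise SingularDesignError("covariance matrix is not positive definite")
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)

    XtX = Xw.T @ Xw
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdetV + n)

    df_resid = n - p
    sigma2_unb = rss / df_resid if df_resid > 0 else np.nan
    cov_beta = sigma2_unb * linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tstat = beta / se
    pvalue = 2.0 * sstats.t.sf(np.abs(tstat), df_resid) if df_resid > 0 else np.full(p, np.nan)

    return ModelFit(
        names=names,
        coef=beta,
        se=se,
        tstat=tstat,
        pvalue=np.asarray(pvalue),
        lam=lam,
        s2=None,
        loglik=loglik,
        n=n,
        df_resid=df_resid,
        weights_desc=weights_desc,
        y=y,
        X=X,
        V=V,
    )


def lambda_ml(
    y: np.ndarray,
    X: np.ndarray,
    tree: Phylogeny | np.ndarray,
    case_weights: np.ndarray | None = None,
    species: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
    tol: float = 1e-6,
    weights_desc: str = "unit",
) -> tuple[float, ModelFit]:
    """Profile maximum-likelihood Pagel's lambda on [0, 1].

    ``tree`` may be a :class:`Phylogeny` (covariance built for ``species``)
    or a precomputed lambda=1 covariance matrix.  A profile whose optimum
    sits at the lower bound is reported as a lambda = 0 fit (the refit rule
    for estimates that would otherwise go negative).
    """
    if isinstance(tree, Phylogeny):
        _, C1 = tree.covariance(1.0, species=species)
    else:
        C1 = np.asarray(tree, dtype=float)

    def nll(lam: float) -> float:
        fit = gls_fit(
            y, X, lambda_transform(C1, lam), case_weights, names=names,
            lam=lam, weights_desc=weights_desc,
        )
        return -fit.loglik

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol}
    )
    candidates = {0.0: nll(0.0), 1.0: nll(1.0)}
    if res.success:
        candidates[float(res.x)] = float(res.fun)
    lam_hat = min(candidates, key=candidates.get)
    fit = gls_fit(
        y, X, lambda_transform(C1, lam_hat), case_weights, names=names,
        lam=lam_hat, weights_desc=weights_desc,
    )
    fit.converged = bool(res.success)
    return lam_hat, fit
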