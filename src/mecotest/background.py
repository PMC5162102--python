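"""Background alteration-probability estimation.

The null model for every test in this package is a matrix of per-gene,
per-tumor alteration probabilities ``p_ij``.  Two estimators are provided:

* **binomial** — the homogeneous model: ``p_ij = x_i. / m`` for every tumor
  ``j``.  Expected per-gene alteration counts match the observed counts,
  but per-tumor counts do not.  This is the naive comparator whose
  anti-conservative behaviour the heterogeneous model corrects.

* **entropy** — the heterogeneous model: maximize the information entropy
  ``H(p) = -sum p log p + (1-p) log(1-p)`` subject to *both* marginal
  constraints, ``sum_j p_ij = x_i.`` and ``sum_i p_ij = x_.j``.  The
  maximum-entropy solution has the logistic form

      p_ij = 1 / (1 + exp(mu_i + lam_j))

  with one gene parameter ``mu_i`` and one tumor parameter ``lam_j``, so
  only ``n + m`` numbers are fitted rather than ``n * m`` probabilities.
  Genes with equal alteration counts provably share the same ``mu``
  (likewise tumors and ``lam``), which reduces the dimensionality further.

The entropy program is solved in its convex dual

    F(mu, lam) = sum_ij log(1 + exp(-(mu_i + lam_j)))
                 + sum_i mu_i x_i. + sum_j lam_j x_.j

whose partial derivatives are exactly the marginal residuals
``x_i. - sum_j p_ij`` and ``x_.j - sum_i p_ij``; convergence is declared
when the largest absolute residual falls below ``tol``.  The minimization
uses L-BFGS.  All-zero / all-one rows and columns make the dual parameters
diverge; they are peeled off beforehand and assigned exact 0/1
probabilities.

A stratified variant fits each tumor subgroup (e.g. cancer type)
separately and concatenates the per-stratum probability matrices, so that
margins are matched within every subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .alteration_data import AlterationMatrix

__all__ = [
    "BackgroundMatrix",
    "DualParameters",
    "ConvergenceError",
    "estimate_binomial_background",
    "estimate_background",
    "estimate_stratified_background",
    "write_background",
    "read_background",
]

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 5000


class ConvergenceError(RuntimeError):
    """Entropy fit failed to reach the residual tolerance.

    Carries the best residual achieved in ``residual`` so callers can
    decide to relax ``tol``.
    """

    def __init__(self, residual: float, tol: float, n_iter: int) -> None:
        super().__init__(
            f"background fit did not converge: max marginal residual "
            f"{residual:.3e} > tol {tol:.1e} after {n_iter} iterations"
        )
        self.residual = residual
        self.tol = tol
        self.n_iter = n_iter


@dataclass
class DualParameters:
    """Shared dual parameters of the entropy fit for one stratum.

    ``mu`` holds one value per distinct gene alteration count and ``lam``
    one per distinct tumor alteration count; ``row_map`` / ``col_map``
    send each gene / tumor to its parameter index (-1 marks a degenerate
    row / column whose probabilities are exactly 0 or 1 and which has no
    finite parameter).
    """

    mu: np.ndarray
    lam: np.ndarray
    row_map: np.ndarray
    col_map: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Rebuild ``p_ij = 1/(1 + exp(mu_i + lam_j))`` for non-degenerate
        entries; degenerate entries are returned as NaN."""
        n, m = self.row_map.size, self.col_map.size
        p = np.full((n, m), np.nan)
        r_ok = self.row_map >= 0
        c_ok = self.col_map >= 0
        if r_ok.any() and c_ok.any():
            s = (
                self.mu[self.row_map[r_ok]][:, None]
                + self.lam[self.col_map[c_ok]][None, :]
            )
            p[np.ix_(r_ok, c_ok)] = expit(-s)
        return p


@dataclass
class BackgroundMatrix:
    """Per-gene, per-tumor alteration probabilities aligned with a matrix.

    ``method`` is ``"binomial"`` or ``"entropy"``; ``fit_report`` maps each
    stratum id (or ``"__all__"``) to its maximum marginal residual and
    iteration count; ``dual`` holds the per-stratum logistic parameters of
    entropy fits.
    """

    probs: np.ndarray
    gene_labels: list[str]
    tumor_labels: list[str]
    method: str
    strata: dict[str, str] | None = None
    fit_report: dict[str, dict] = field(default_factory=dict)
    dual: dict[str, DualParameters] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.gene_labels), len(self.tumor_labels)):
            raise ValueError("probs shape does not match labels")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        self.probs = np.clip(p, 0.0, 1.0)

    @property
    def n_genes(self) -> int:
        return self.probs.shape[0]

    @property
    def n_tumors(self) -> int:
        return self.probs.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_labels.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene label: {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.probs[self.gene_index(gene)]

    def aligned_with(self, X: AlterationMatrix) -> bool:
        return (
            self.gene_labels == X.gene_labels
            and self.tumor_labels == X.tumor_labels
        )


# -- binomial (homogeneous) estimator -------------------------------------


def estimate_binomial_background(X: AlterationMatrix) -> BackgroundMatrix:
    """Homogeneous background: ``p_ij = x_i. / m`` for every tumor.

    When the matrix carries strata the fraction is computed within each
    stratum, so per-gene expected counts match observed counts per group.
    """
    if X.n_tumors < 1:
        raise ValueError("matrix has no tumors")
    probs = np.empty(X.values.shape, dtype=float)
    if X.strata is None:
        probs[:] = (X.gene_sums / X.n_tumors)[:, None]
    else:
        for s in X.stratum_ids():
            cols = X.stratum_columns(s)
            sub = X.values[:, cols]
            probs[:, cols] = (sub.sum(axis=1) / cols.size)[:, None]
    return BackgroundMatrix(
        probs,
        list(X.gene_labels),
        list(X.tumor_labels),
        method="binomial",
        strata=dict(X.strata) if X.strata else None,
    )


# -- entropy (heterogeneous) estimator -------------------------------------


def _peel_degenerate(row_sums: np.ndarray, col_sums: np.ndarray):
    """Iteratively resolve all-zero / all-one rows and columns.

    Returns (p_fixed, row_active, col_active, eff_row, eff_col) where
    ``p_fixed`` holds 0/1 for resolved entries and NaN elsewhere, and
    ``eff_row`` / ``eff_col`` are the margins of the remaining core
    problem.  Resolving an all-one row decrements the remaining column
    margins (those entries are forced to 1), and symmetrically.
    """
    n, m = row_sums.size, col_sums.size
    p = np.full((n, m), np.nan)
    r = row_sums.astype(float).copy()
    c = col_sums.astype(float).copy()
    row_act = np.ones(n, dtype=bool)
    col_act = np.ones(m, dtype=bool)
    changed = True
    while changed:
        changed = False
        n_cols = int(col_act.sum())
        for i in np.where(row_act)[0]:
            if r[i] <= 0:
                p[i, col_act] = 0.0
                row_act[i] = False
                changed = True
            elif r[i] >= n_cols:
                p[i, col_act] = 1.0
                c[col_act] -= 1.0
                row_act[i] = False
                changed = True
        n_rows = int(row_act.sum())
        for j in np.where(col_act)[0]:
            if not col_act[j]:
                continue
            if c[j] <= 0:
                p[row_act, j] = 0.0
                col_act[j] = False
                changed = True
            elif c[j] >= n_rows:
                p[row_act, j] = 1.0
                r[row_act] -= 1.0
                col_act[j] = False
                changed = True
    return p, row_act, col_act, r, c


def _fit_entropy_core(
    row_sums: np.ndarray,
    col_sums: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, DualParameters, float, int]:
    """Fit the logistic dual on one stratum; returns (probs, dual, residual, n_iter)."""
    n, m = row_sums.size, col_sums.size
    p_fixed, row_act, col_act, eff_r, eff_c = _peel_degenerate(row_sums, col_sums)

    row_map = np.full(n, -1, dtype=int)
    col_map = np.full(m, -1, dtype=int)
    if not row_act.any() or not col_act.any():
        probs = np.nan_to_num(p_fixed, nan=0.0)
        dual = DualParameters(np.empty(0), np.empty(0), row_map, col_map)
        return probs, dual, 0.0, 0

    ar = np.where(row_act)[0]
    ac = np.where(col_act)[0]
    # parameter sharing: one mu per distinct effective row sum
    r_vals, r_inv = np.unique(eff_r[ar], return_inverse=True)
    c_vals, c_inv = np.unique(eff_c[ac], return_inverse=True)
    row_map[ar] = r_inv
    col_map[ac] = c_inv
    r_cnt = np.bincount(r_inv).astype(float)
    c_cnt = np.bincount(c_inv).astype(float)
    kr, kc = r_vals.size, c_vals.size
    m_act, n_act = ac.size, ar.size

    def unpack(theta):
        return theta[:kr], theta[kr:]

    def objective(theta):
        mu, lam = unpack(theta)
        s = mu[:, None] + lam[None, :]
        # log(1 + e^{-s}) via logaddexp for stability
        log_terms = np.logaddexp(0.0, -s)
        f = (r_cnt[:, None] * c_cnt[None, :] * log_terms).sum()
        f += (r_cnt * mu * r_vals).sum() + (c_cnt * lam * c_vals).sum()
        p = expit(-s)
        # gradient components = weighted marginal residuals
        g_mu = r_cnt * (r_vals - (p * c_cnt[None, :]).sum(axis=1))
        g_lam = c_cnt * (c_vals - (p * r_cnt[:, None]).sum(axis=0))
        return f, np.concatenate([g_mu, g_lam])

    # initialization: row parameter at the binomial logit, columns neutral
    mu0 = -logit(np.clip(r_vals / m_act, 1e-9, 1 - 1e-9))
    theta0 = np.concatenate([mu0, np.zeros(kc)])

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": tol * 1e-4},
    )
    mu, lam = unpack(res.x)

    def residuals(mu, lam):
        p = expit(-(mu[:, None] + lam[None, :]))
        res_r = np.abs(r_vals - (p * c_cnt[None, :]).sum(axis=1)).max()
        res_c = np.abs(c_vals - (p * r_cnt[:, None]).sum(axis=0)).max()
        return float(max(res_r, res_c))

    residual = residuals(mu, lam)
    n_iter = int(res.nit)
    # alternating Newton polish: with one side fixed, each shared parameter
    # solves an independent monotone 1-D margin equation, so a few damped
    # Newton sweeps drive the residuals below any realistic tolerance even
    # when L-BFGS stalls on the flat gauge direction
    while residual > tol * 0.5 and n_iter < max_iter:
        p = expit(-(mu[:, None] + lam[None, :]))
        f = (p * c_cnt[None, :]).sum(axis=1) - r_vals
        fp = (p * (1 - p) * c_cnt[None, :]).sum(axis=1)
        mu += np.clip(f / np.maximum(fp, 1e-12), -2.0, 2.0)
        p = expit(-(mu[:, None] + lam[None, :]))
        f = (p * r_cnt[:, None]).sum(axis=0) - c_vals
        fp = (p * (1 - p) * r_cnt[:, None]).sum(axis=0)
        lam += np.clip(f / np.maximum(fp, 1e-12), -2.0, 2.0)
        n_iter += 1
        residual = residuals(mu, lam)
    if residual > tol:
        raise ConvergenceError(residual, tol, n_iter)
    p_core = expit(-(mu[:, None] + lam[None, :]))

    probs = p_fixed.copy()
    probs[np.ix_(row_act, col_act)] = p_core[np.ix_(row_map[ar], col_map[ac])]
    probs = np.nan_to_num(probs, nan=0.0)
    dual = DualParameters(mu.copy(), lam.copy(), row_map, col_map)
    return probs, dual, residual, n_iter


def estimate_background(
    X: AlterationMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> BackgroundMatrix:
    """Maximum-entropy background matching gene and tumor margins.

    ``tol`` is the largest allowed absolute marginal residual in units of
    expected alteration counts (default 1e-4).  Raises
    :class:`ConvergenceError` when the fit cannot reach it within
    ``max_iter`` L-BFGS iterations.
    """
    if X.n_genes < 1 or X.n_tumors < 1:
        raise ValueError("matrix must have at least one gene and one tumor")
    probs, dual, resid, n_iter = _fit_entropy_core(
        X.gene_sums.astype(float), X.tumor_sums.astype(float), tol, max_iter
    )
    return BackgroundMatrix(
        probs,
        list(X.gene_labels),
        list(X.tumor_labels),
        method="entropy",
        strata=None,
        fit_report={"__all__": {"max_residual": resid, "n_iter": n_iter, "tol": tol}},
        dual={"__all__": dual},
    )


def estimate_stratified_background(
    X: AlterationMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> BackgroundMatrix:
    """Entropy background fitted separately per stratum and concatenated.

    Each tumor subgroup gets its own fit, so expected gene and tumor
    alteration counts match the observed counts *within* every subgroup,
    not merely globally.
    """
    if X.strata is None:
        raise ValueError("matrix has no strata; use estimate_background")
    probs = np.empty(X.values.shape, dtype=float)
    report: dict[str, dict] = {}
    duals: dict[str, DualParameters] = {}
    for s in X.stratum_ids():
        cols = X.stratum_columns(s)
        sub = X.values[:, cols]
        p, dual, resid, n_iter = _fit_entropy_core(
            sub.sum(axis=1).astype(float),
            sub.sum(axis=0).astype(float),
            tol,
            max_iter,
        )
        probs[:, cols] = p
        report[s] = {"max_residual": resid, "n_iter": n_iter, "tol": tol}
        duals[s] = dual
    return BackgroundMatrix(
        probs,
        list(X.gene_labels),
        list(X.tumor_labels),
        method="entropy",
        strata=dict(X.strata),
        fit_report=report,
        dual=duals,
    )


# -- persistence -----------------------------------------------------------


def write_background(P: BackgroundMatrix, path: str | Path) -> None:
    """Write probabilities as TSV plus a ``.meta.yaml`` sidecar."""
    import pandas as pd
    import yaml

    path = Path(path)
    pd.DataFrame(P.probs, index=P.gene_labels, columns=P.tumor_labels).to_csv(
        path, sep="\t"
    )
    meta = {
        "method": P.method,
        "strata": P.strata,
        "fit_report": {
            k: {kk: (float(vv) if isinstance(vv, (int, float)) else vv) for kk, vv in v.items()}
            for k, v in P.fit_report.items()
        },
    }
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_background(path: str | Path) -> BackgroundMatrix:
    import pandas as pd
    import yaml

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta: Mapping = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return BackgroundMatrix(
        df.to_numpy(dtype=float),
        [str(g) for g in df.index],
        [str(t) for t in df.columns],
        method=str(meta.get("method", "entropy")),
        strata=meta.get("strata"),
        fit_report=meta.get("fit_report", {}),
    )
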