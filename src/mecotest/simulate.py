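"""Synthetic alteration data with realistic marginal heterogeneity.

Real tumor cohorts show two kinds of marginal structure that break
i.i.d. independence tests: gene alteration frequencies are heavy-tailed
(few frequently altered genes, many rare ones) and per-tumor alteration
loads are strongly over-dispersed (some tumors carry many times more
alterations than others).  This module generates *null* matrices that
reproduce both margins without any dependence between genes, and plants
positive cases — co-occurring pairs, mutually exclusive pairs, and
mutually exclusive gene sets — on top of them.

The null generator realizes prescribed gene/tumor degree sequences as a
random bipartite graph (configuration model) whose adjacency matrix is
the alteration matrix: margins are matched *exactly*, and beyond the
margins alterations are independent.  Because no external cohort ships
with the package, the marginal model is synthetic: a truncated discrete
power law for gene frequencies and log-normal per-tumor loads, with
explicit degree sequences accepted for users who have real margins.

Planted pairs are calibrated against the null background by quantile
regression of a pair statistic (impurity or overlap) on pair coverage:
mutually exclusive pairs fall below the 1st percentile of impurity,
co-occurring pairs above the 99th percentile of overlap, mirroring how
extreme the real positive cases are relative to independent pairs of the
same coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from scipy.optimize import brentq
from scipy.special import expit

from .alteration_data import AlterationMatrix, filter_genes
from .background import BackgroundMatrix, estimate_background, estimate_binomial_background
from .independence import test_group

__all__ = [
    "SimulationConfig",
    "QuantileModel",
    "GroupSpec",
    "sample_marginals",
    "generate_null_matrix",
    "simulate_null_matrix",
    "fit_impurity_quantile",
    "inject_pair",
    "generate_me_group",
    "sample_group_spec",
    "run_benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate a mid-size pan-cancer-style cohort: 600 genes by
    800 tumors (roughly 120 of the genes pass the 50-alteration testing
    filter), gene alteration frequencies following a truncated power
    law on [1%, 50%] with tail exponent 1.8, and log-normal per-tumor
    loads with coefficient of variation ``tumor_dispersion`` (0.8 by
    default, comfortably over-dispersed).  ``min_alterations_tested``
    reflects the convention of testing only genes altered in at least 50
    tumors; rarer genes still inform the background fit.
    """

    n_genes: int = 600
    n_tumors: int = 800
    gene_tail_exponent: float = 1.8
    gene_freq_min: float = 0.01
    gene_freq_max: float = 0.5
    tumor_dispersion: float = 0.8
    min_alterations_tested: int = 50
    seed: int = 0
    gene_degrees: tuple[int, ...] | None = None  # explicit override
    tumor_degrees: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tumors < 1:
            raise ValueError("n_genes and n_tumors must be positive")
        if self.tumor_dispersion < 0:
            raise ValueError("tumor_dispersion must be nonnegative")
        if not 0 < self.gene_freq_min <= self.gene_freq_max <= 1:
            raise ValueError("need 0 < gene_freq_min <= gene_freq_max <= 1")
        if (self.gene_degrees is None) != (self.tumor_degrees is None):
            raise ValueError("give both explicit degree sequences or neither")
        if self.gene_degrees is not None:
            g = np.asarray(self.gene_degrees)
            t = np.asarray(self.tumor_degrees)
            if g.sum() != t.sum():
                raise ValueError("explicit degree sequences must have equal sums")
            if np.any(g < 0) or np.any(t < 0):
                raise ValueError("degrees must be nonnegative")
            if np.any(g > t.size) or np.any(t > g.size):
                raise ValueError("a degree exceeds the opposite dimension")


@dataclass(frozen=True)
class QuantileModel:
    """Linear quantile fit of a pair statistic on pair coverage.

    ``predict`` evaluates ``max(0, intercept + slope * coverage)``; the
    clip keeps predictions valid for count/proportion statistics.
    """

    tau: float
    mode: str  # 'impurity' or 'overlap'
    intercept: float
    slope: float

    def predict(self, coverage: float | np.ndarray) -> np.ndarray:
        return np.maximum(self.intercept + self.slope * np.asarray(coverage, float), 0.0)


@dataclass(frozen=True)
class GroupSpec:
    """Recipe for one planted mutually exclusive gene set."""

    coverage_fraction: float
    impurity: float
    min_genes: int = 3
    max_genes: int = 6

    def __post_init__(self) -> None:
        if not 0.2 <= self.coverage_fraction <= 0.8:
            raise ValueError("coverage_fraction must lie in [0.2, 0.8]")
        if self.impurity not in (0.02, 0.05, 0.08):
            raise ValueError("impurity must be one of {0.02, 0.05, 0.08}")
        if not 1 <= self.min_genes <= self.max_genes:
            raise ValueError("invalid gene-count bounds")


def sample_group_spec(rng: np.random.Generator) -> GroupSpec:
    """Draw a group recipe: coverage from a truncated normal with mean 0.4
    and sd 0.2 on [0.2, 0.8]; impurity uniformly from {0.02, 0.05, 0.08}."""
    a, b = (0.2 - 0.4) / 0.2, (0.8 - 0.4) / 0.2
    cov = float(stats.truncnorm.rvs(a, b, loc=0.4, scale=0.2, random_state=rng))
    imp = float(rng.choice([0.02, 0.05, 0.08]))
    return GroupSpec(coverage_fraction=cov, impurity=imp)


# -- marginal model --------------------------------------------------------


def sample_marginals(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw gene and tumor degree sequences with equal sums.

    Gene degrees: frequencies from a truncated power law with density
    proportional to ``f^-alpha`` on ``[freq_min, freq_max]``, times the
    tumor count.  Tumor degrees: log-normal loads with the requested
    coefficient of variation, rescaled (largest-remainder rounding) so the
    two sequences sum to the same total.  Deterministic given ``cfg.seed``.
    """
    if cfg.gene_degrees is not None:
        return (
            np.asarray(cfg.gene_degrees, dtype=int),
            np.asarray(cfg.tumor_degrees, dtype=int),
        )
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.n_tumors

    # inverse-CDF sampling of the truncated power law
    alpha = cfg.gene_tail_exponent
    lo, hi = cfg.gene_freq_min, cfg.gene_freq_max
    u = rng.uniform(size=n)
    if abs(alpha - 1.0) < 1e-9:
        freqs = lo * (hi / lo) ** u
    else:
        a1 = 1.0 - alpha
        freqs = (lo**a1 + u * (hi**a1 - lo**a1)) ** (1.0 / a1)
    gene_deg = np.maximum(np.rint(freqs * m).astype(int), 1)
    gene_deg = np.minimum(gene_deg, m)
    total = int(gene_deg.sum())

    # log-normal tumor loads with CV = tumor_dispersion
    cv = cfg.tumor_dispersion
    if cv == 0:
        loads = np.ones(m)
    else:
        sigma2 = np.log(1.0 + cv**2)
        loads = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=m)
    loads = loads / loads.sum() * total
    tumor_deg = np.floor(loads).astype(int)
    # largest-remainder rounding to hit the total exactly
    short = total - int(tumor_deg.sum())
    order = np.argsort(-(loads - np.floor(loads)))
    tumor_deg[order[:short]] += 1
    if np.any(tumor_deg > n):
        # shave overfull tumors and redistribute to the least-loaded ones
        excess = int((tumor_deg - np.minimum(tumor_deg, n)).sum())
        tumor_deg = np.minimum(tumor_deg, n)
        room = np.argsort(tumor_deg)
        k = 0
        while excess > 0:
            j = room[k % m]
            if tumor_deg[j] < n:
                tumor_deg[j] += 1
                excess -= 1
            k += 1
    if int(tumor_deg.sum()) != total:
        raise ValueError("infeasible marginal configuration: cannot match totals")
    return gene_deg, tumor_deg


# -- configuration-model null ----------------------------------------------


def generate_null_matrix(
    gene_degrees: Sequence[int],
    tumor_degrees: Sequence[int],
    seed: int,
    gene_labels: Sequence[str] | None = None,
    tumor_labels: Sequence[str] | None = None,
) -> AlterationMatrix:
    """Bipartite configuration-model matrix with the exact given margins.

    Gene and tumor stubs are paired uniformly at random; duplicate edges
    are then repaired by degree-preserving checkerboard swaps (pick a
    multi-edge (i, j) and a random edge (k, l) with cells (i, l) and
    (k, j) empty; rewire to break the duplicate).  Margins are preserved
    exactly throughout.  Raises if the sequence cannot be made simple
    within a bounded number of swap attempts.
    """
    g = np.asarray(gene_degrees, dtype=int)
    t = np.asarray(tumor_degrees, dtype=int)
    if g.sum() != t.sum():
        raise ValueError("degree sequences must have equal sums")
    if np.any(g < 0) or np.any(t < 0):
        raise ValueError("degrees must be nonnegative")
    if np.any(g > t.size) or np.any(t > g.size):
        raise ValueError("a degree exceeds the opposite dimension")
    rng = np.random.default_rng(seed)
    n, m = g.size, t.size

    gene_stubs = np.repeat(np.arange(n), g)
    tumor_stubs = np.repeat(np.arange(m), t)
    rng.shuffle(tumor_stubs)
    mat = np.zeros((n, m), dtype=np.int32)
    np.add.at(mat, (gene_stubs, tumor_stubs), 1)

    # repair multi-edges by checkerboard swaps in stub space: exchange the
    # tumor endpoints of a duplicate edge instance and a random edge
    # instance; margins are untouched and target cells must be empty, so
    # every accepted swap strictly reduces the duplicate count
    n_edges = int(g.sum())
    max_attempts = 10_000 * max(n_edges, 1)
    attempts = 0
    while True:
        cells = mat[gene_stubs, tumor_stubs]
        dup_idx = np.where(cells > 1)[0]
        if dup_idx.size == 0:
            break
        for r2 in dup_idx:
            i, j = gene_stubs[r2], tumor_stubs[r2]
            if mat[i, j] <= 1:  # already repaired via an earlier swap
                continue
            while True:
                attempts += 1
                if attempts > max_attempts:
                    raise ValueError(
                        "degree sequence could not be realized as a simple "
                        "bipartite graph within the swap budget"
                    )
                r = int(rng.integers(n_edges))
                k, l = gene_stubs[r], tumor_stubs[r]
                if k == i or l == j or mat[i, l] != 0 or mat[k, j] != 0:
                    continue
                mat[i, j] -= 1
                mat[k, l] -= 1
                mat[i, l] += 1
                mat[k, j] += 1
                tumor_stubs[r2], tumor_stubs[r] = l, j
                break

    genes = list(gene_labels) if gene_labels is not None else [f"G{i:04d}" for i in range(n)]
    tumors = list(tumor_labels) if tumor_labels is not None else [f"T{j:04d}" for j in range(m)]
    return AlterationMatrix(mat.astype(np.int8), genes, tumors)


def simulate_null_matrix(cfg: SimulationConfig) -> AlterationMatrix:
    """Convenience: sample marginals and realize the configuration model."""
    gene_deg, tumor_deg = sample_marginals(cfg)
    return generate_null_matrix(gene_deg, tumor_deg, seed=cfg.seed + 1)


# -- pair statistics and quantile calibration ------------------------------


def _pair_stats(rows: np.ndarray, a: int, b: int) -> tuple[int, int, float]:
    """(coverage, overlap, impurity) of one gene pair; impurity is the
    proportion of covered tumors altered in both genes."""
    ra, rb = rows[a], rows[b]
    overlap = int((ra & rb).sum())
    coverage = int((ra | rb).sum())
    impurity = overlap / coverage if coverage else 0.0
    return coverage, overlap, impurity


def fit_impurity_quantile(
    X_null: AlterationMatrix,
    tau: float,
    mode: str = "impurity",
    min_alterations: int = 50,
    max_pairs: int = 20_000,
    seed: int = 0,
) -> QuantileModel:
    """Quantile-regression calibration of pair statistics on the null.

    Fits the ``tau``-quantile of the chosen statistic (impurity proportion
    or overlap count) as a linear function of pair coverage, by pinball
    loss, over independent gene pairs of the null matrix that pass the
    alteration-count filter.  Falls back to binned empirical quantiles
    when the linear fit is degenerate.
    """
    if mode not in ("impurity", "overlap"):
        raise ValueError(f"mode must be 'impurity' or 'overlap', got {mode!r}")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    Xf = filter_genes(X_null, min_alterations)
    k = Xf.n_genes
    if k * (k - 1) // 2 < 100:
        raise ValueError("need at least 100 independent gene pairs after filtering")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    rows = Xf.values.astype(bool)
    cov = np.empty(len(pairs))
    y = np.empty(len(pairs))
    for q, (i, j) in enumerate(pairs):
        c, o, imp = _pair_stats(rows, i, j)
        cov[q] = c
        y[q] = imp if mode == "impurity" else o
    if cov.max() == cov.min():
        raise ValueError("degenerate coverage range; cannot fit a quantile model")

    import statsmodels.api as sm

    exog = sm.add_constant(cov)
    try:
        fit = sm.QuantReg(y, exog).fit(q=tau)
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        if not (np.isfinite(intercept) and np.isfinite(slope)):
            raise ValueError
    except Exception:
        # binned-empirical fallback: straight line through the quantiles of
        # the lower and upper coverage halves
        med = np.median(cov)
        lo_mask, hi_mask = cov <= med, cov > med
        x1, x2 = cov[lo_mask].mean(), cov[hi_mask].mean()
        y1 = np.quantile(y[lo_mask], tau)
        y2 = np.quantile(y[hi_mask], tau)
        slope = (y2 - y1) / (x2 - x1)
        intercept = y1 - slope * x1
    return QuantileModel(tau=tau, mode=mode, intercept=intercept, slope=slope)


# -- planted positives -----------------------------------------------------


def null_gene_profile(P: BackgroundMatrix, count: int) -> np.ndarray:
    """Per-tumor alteration probabilities of a hypothetical independent
    gene with ``count`` alterations, under the fitted logistic model.

    Uses the tumor parameters ``lam_j`` of the entropy fit and solves the
    one-dimensional margin equation ``sum_j 1/(1 + exp(mu + lam_j)) =
    count`` for the gene parameter.  Planting alterations with these
    inclusion probabilities makes a planted gene marginally
    indistinguishable from a null gene of equal frequency, which is what
    keeps planted genes from showing phantom associations with null genes.
    """
    dual = P.dual.get("__all__")
    if dual is None:
        raise ValueError("background carries no dual parameters; use an entropy fit")
    m = dual.col_map.size
    lam_full = np.full(m, np.inf)  # all-zero columns: probability 0
    ok = dual.col_map >= 0
    lam_full[ok] = dual.lam[dual.col_map[ok]]
    finite = np.isfinite(lam_full)
    if count <= 0 or not finite.any():
        return np.zeros(m)

    def margin(mu: float) -> float:
        return float(expit(-(mu + lam_full[finite])).sum()) - count

    if margin(-60.0) < 0:  # count exceeds what the profile can carry
        mu = -60.0
    elif margin(60.0) > 0:
        mu = 60.0
    else:
        mu = brentq(margin, -60.0, 60.0, xtol=1e-10)
    w = np.zeros(m)
    w[finite] = expit(-(mu + lam_full[finite]))
    return w


def _sample_tumors(rng, weights, size, exclude=None):
    """Fixed-size sample with inclusion probabilities proportional to
    ``weights`` (capped at 1), via systematic PPS sampling.

    Plain sequential weighted sampling without replacement flattens the
    weight bias for large samples; systematic probability-proportional-
    to-size sampling keeps each tumor's inclusion probability exactly
    ``min(1, c * w_j)``, which is what a margin-matched background model
    predicts for load-biased alterations."""
    if size == 0:
        return np.empty(0, dtype=int)
    w = weights.astype(float).copy()
    if exclude is not None:
        w[exclude] = 0.0
    w = np.maximum(w, 1e-9)
    if size > (w > 1e-9).size:
        raise ValueError("sample size exceeds available tumors")

    # scale so capped inclusion probabilities sum to the sample size
    lo, hi = 0.0, size / w.sum()
    while np.minimum(hi * w, 1.0).sum() < size - 1e-9:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * w, 1.0).sum() < size:
            lo = mid
        else:
            hi = mid
    pi = np.minimum(hi * w, 1.0)

    order = rng.permutation(w.size)
    cum = np.cumsum(pi[order])
    start = rng.uniform(0, 1)
    picks = np.searchsorted(cum, start + np.arange(size), side="left")
    picks = np.unique(np.clip(picks, 0, w.size - 1))
    chosen = order[picks]
    # duplicates from rounding are rare; top up with the heaviest leftovers
    if chosen.size < size:
        mask = np.ones(w.size, dtype=bool)
        mask[chosen] = False
        extra = np.argsort(-w * mask)[: size - chosen.size]
        chosen = np.concatenate([chosen, extra])
    return rng.permutation(chosen)


def inject_pair(
    X: AlterationMatrix,
    kind: str,
    coverage: int,
    qmodel: QuantileModel,
    seed: int,
    labels: tuple[str, str] | None = None,
) -> tuple[AlterationMatrix, tuple[str, str]]:
    """Append one planted gene pair calibrated against the null quantiles.

    ``kind='me'`` plants a mutually exclusive pair whose impurity lies
    below the model's (1st-percentile) prediction at its coverage;
    ``kind='co'`` plants a co-occurring pair whose overlap count exceeds
    the (99th-percentile) prediction.  The two per-gene alteration counts
    are drawn to sum to ``coverage``; covered tumors are sampled with
    probability proportional to their overall alteration load.
    """
    if kind not in ("me", "co"):
        raise ValueError(f"kind must be 'me' or 'co', got {kind!r}")
    if kind == "me" and qmodel.mode != "impurity":
        raise ValueError("me injection needs an impurity-mode quantile model")
    if kind == "co" and qmodel.mode != "overlap":
        raise ValueError("co injection needs an overlap-mode quantile model")
    m = X.n_tumors
    if not 2 <= coverage <= m:
        raise ValueError(f"coverage must lie in [2, {m}]")
    rng = np.random.default_rng(seed)
    f1 = int(rng.integers(max(1, int(0.3 * coverage)), int(0.7 * coverage) + 1))
    f2 = coverage - f1
    if min(f1, f2) < 1:
        f1, f2 = coverage // 2, coverage - coverage // 2

    bound = float(qmodel.predict(coverage))
    if kind == "me":
        # largest overlap o with impurity o / (f1 + f2 - o) below the bound
        o_max = 0
        for o in range(min(f1, f2) + 1):
            if bound > 0 and o / (f1 + f2 - o) < bound:
                o_max = o
            else:
                break
        overlap = int(rng.integers(0, o_max + 1))
    else:
        o_lo = int(np.floor(bound)) + 1
        if o_lo > min(f1, f2):
            raise ValueError(
                f"overlap bound {bound:.1f} unsatisfiable at coverage {coverage}; "
                "try a larger coverage"
            )
        overlap = int(rng.integers(o_lo, min(f1, f2) + 1))

    loads = X.tumor_sums
    both = _sample_tumors(rng, loads, overlap)
    used = np.zeros(m, dtype=bool)
    used[both] = True
    only1 = _sample_tumors(rng, loads, f1 - overlap, exclude=used)
    used[only1] = True
    only2 = _sample_tumors(rng, loads, f2 - overlap, exclude=used)

    row1 = np.zeros(m, dtype=np.int8)
    row2 = np.zeros(m, dtype=np.int8)
    row1[both] = row1[only1] = 1
    row2[both] = row2[only2] = 1
    if labels is None:
        tag = f"{kind.upper()}{rng.integers(10**8):08d}"
        labels = (f"{tag}_a", f"{tag}_b")
    newX = AlterationMatrix(
        np.vstack([X.values, row1, row2]),
        [*X.gene_labels, labels[0], labels[1]],
        list(X.tumor_labels),
        dict(X.strata) if X.strata else None,
    )
    return newX, labels


def generate_me_group(
    X: AlterationMatrix,
    spec: GroupSpec,
    seed: int,
    label_prefix: str | None = None,
    min_gene_count: int = 50,
    background: BackgroundMatrix | None = None,
) -> tuple[AlterationMatrix, list[str]]:
    """Append one planted mutually exclusive gene set.

    A purely exclusive pattern is built first: per-gene alteration counts
    are sampled from the empirical frequency distribution of the null
    matrix until their sum reaches the requested coverage (resampling
    until the gene count lands in [min_genes, max_genes]), and each gene
    is assigned a disjoint block of covered tumors drawn with inclusion
    probabilities equal to the logistic tumor profile of a null gene of
    the same frequency (see :func:`null_gene_profile`; ``background`` may
    supply a pre-fitted entropy background, otherwise one is fitted).
    Impure alterations — extra alterations in an already covered tumor —
    are then added one at a time, targeting tumors proportionally to
    their load, until ``round(impurity * coverage)`` tumors are impure.
    """
    rng = np.random.default_rng(seed)
    m = X.n_tumors
    coverage = int(round(spec.coverage_fraction * m))
    # draw per-gene counts from the empirical distribution of genes that
    # themselves pass the testing filter, so planted genes stay testable
    freqs = X.gene_sums
    freqs = freqs[freqs >= min_gene_count]
    if freqs.size == 0:
        freqs = X.gene_sums[X.gene_sums > 0]
    if freqs.size == 0:
        raise ValueError("null matrix has no altered genes to draw frequencies from")

    counts: list[int] | None = None
    for _ in range(5000):
        trial: list[int] = []
        total = 0
        while total < coverage and len(trial) <= spec.max_genes:
            f = int(rng.choice(freqs))
            f = min(f, coverage - total)
            trial.append(f)
            total += f
        if (
            spec.min_genes <= len(trial) <= spec.max_genes
            and total == coverage
            and min(trial) >= min(min_gene_count, coverage // spec.max_genes)
        ):
            counts = trial
            break
    if counts is None:
        raise ValueError(
            f"could not partition coverage {coverage} into "
            f"[{spec.min_genes}, {spec.max_genes}] testable gene counts"
        )

    loads = X.tumor_sums
    if background is None:
        background = estimate_background(X)
    rows = np.zeros((len(counts), m), dtype=np.int8)
    used = np.zeros(m, dtype=bool)
    # place larger genes first while tumor choice is least constrained
    order = np.argsort(-np.asarray(counts))
    for gi in order:
        profile = null_gene_profile(background, counts[gi])
        block = _sample_tumors(rng, profile, counts[gi], exclude=used)
        rows[gi, block] = 1
        used[block] = True

    n_impure = int(round(spec.impurity * coverage))
    covered_mask = used
    if n_impure > 0:
        w = loads.astype(float).copy()
        w[~covered_mask] = 0.0
        if w.sum() <= 0:
            w = covered_mask.astype(float)
        impure_tumors = rng.choice(m, size=n_impure, replace=False, p=w / w.sum())
        for j in impure_tumors:
            current = rows[:, j]
            zeros = np.where(current == 0)[0]
            if zeros.size == 0:
                continue
            rows[rng.choice(zeros), j] = 1

    prefix = label_prefix or f"MEG{rng.integers(10**8):08d}"
    labels = [f"{prefix}_{chr(ord('a') + i)}" for i in range(len(counts))]
    newX = AlterationMatrix(
        np.vstack([X.values, rows]),
        [*X.gene_labels, *labels],
        list(X.tumor_labels),
        dict(X.strata) if X.strata else None,
    )
    return newX, labels


# -- benchmark -------------------------------------------------------------

DEFAULT_ALPHAS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def _matched_negative(
    rng: np.random.Generator,
    Xf: AlterationMatrix,
    size: int,
    target_freqs: np.ndarray,
    tol: float = 0.10,
) -> list[str]:
    """Pick ``size`` independent genes whose frequencies match the planted
    group's gene frequencies within a +-``tol`` relative band (band doubled
    on failure)."""
    sums = Xf.gene_sums
    chosen: list[int] = []
    for f in target_freqs:
        band = tol
        for _ in range(20):
            cand = np.where(
                (np.abs(sums - f) <= band * max(f, 1))
                & ~np.isin(np.arange(Xf.n_genes), chosen)
            )[0]
            if cand.size:
                chosen.append(int(rng.choice(cand)))
                break
            band *= 2
        else:
            raise ValueError("could not frequency-match a negative group")
    return [Xf.gene_labels[i] for i in chosen]


def run_benchmark(
    cfg: SimulationConfig,
    n_datasets: int = 3,
    n_pos: int = 30,
    n_neg: int = 30,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    statistic: str = "impurity",
) -> pd.DataFrame:
    """Calibration and sensitivity of the group test on planted data.

    For each of ``n_datasets`` seeded replicates: generate a null matrix,
    plant ``n_pos`` mutually exclusive gene sets, pick ``n_neg``
    frequency-matched independent gene sets as negatives, estimate the
    heterogeneous background on the *complete* matrix (planted genes
    included), and apply both the heterogeneous-background group test and
    the homogeneous (binomial) comparator.  Returns a tidy table of
    false/true positive rates per significance level, averaged across
    replicates.
    """
    rows = []
    for ds in range(n_datasets):
        seed = cfg.seed + 1000 * (ds + 1)
        rng = np.random.default_rng(seed)
        X = simulate_null_matrix(replace(cfg, seed=seed))
        P_null = estimate_background(X)
        pos_groups: list[list[str]] = []
        for g in range(n_pos):
            spec = sample_group_spec(rng)
            X, labels = generate_me_group(X, spec, seed=seed + 17 * g + 7,
                                          label_prefix=f"MEG{g:03d}",
                                          background=P_null)
            pos_groups.append(labels)
        Xf_names = filter_genes(X, cfg.min_alterations_tested)
        neg_pool = AlterationMatrix(
            Xf_names.values[
                [not any(l in g for g in pos_groups) for l in Xf_names.gene_labels]
            ],
            [l for l in Xf_names.gene_labels if not any(l in g for g in pos_groups)],
            list(Xf_names.tumor_labels),
        )
        neg_groups: list[list[str]] = []
        for g in range(n_neg):
            ref = pos_groups[g % len(pos_groups)]
            target = np.array([int(X.row(l).sum()) for l in ref])
            neg_groups.append(_matched_negative(rng, neg_pool, len(ref), target))

        for method, P in (
            ("poisson_binomial", estimate_background(X)),
            ("binomial", estimate_binomial_background(X)),
        ):
            p_pos = [test_group(X, P, g, statistic).p_value for g in pos_groups]
            p_neg = [test_group(X, P, g, statistic).p_value for g in neg_groups]
            for a in alphas:
                rows.append(
                    {
                        "dataset": ds,
                        "method": method,
                        "alpha": a,
                        "tpr": float(np.mean([p <= a for p in p_pos])),
                        "fpr": float(np.mean([p <= a for p in p_neg])),
                    }
                )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["method", "alpha"], as_index=False)[["tpr", "fpr"]]
        .mean()
        .sort_values(["method", "alpha"])
        .reset_index(drop=True)
    )
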