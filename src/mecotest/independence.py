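"""Pairwise and group-based co-occurrence / mutual exclusivity tests.

Given a background matrix of per-gene, per-tumor alteration probabilities
``p_ij``, the number of tumors altered in both genes of an independent
pair is a sum of independent Bernoulli trials with per-tumor success
probabilities ``p_aj * p_bj`` — a Poisson-binomial variable.  The pairwise
test compares the observed overlap against this null: the upper tail
supports co-occurrence, the lower tail mutual exclusivity.

The group tests generalize this to gene sets through three per-tumor
event statistics:

* **coverage** — the tumor is altered in at least one gene of the set;
* **exclusivity** — altered in exactly one gene;
* **impurity** — altered in more than one gene.

Each statistic again counts tumors with independent, tumor-specific event
probabilities, hence is Poisson-binomial under the null.  Coverage and
exclusivity are tested in the upper tail; impurity (the default mutual
exclusivity statistic) in the lower tail.  For a two-gene set the impurity
parameterization reduces exactly to the pairwise joint probability
``p_1j * p_2j``.

Stratification needs no extra logic here: a stratified background matrix
already carries subgroup-matched probabilities and the tests consume it
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .alteration_data import AlterationMatrix, GeneSet
from .background import BackgroundMatrix
from .poibin import PoissonBinomial, tail

__all__ = [
    "PairResult",
    "GroupResult",
    "pair_overlap",
    "expected_overlap",
    "test_pair",
    "test_all_pairs",
    "group_event_probabilities",
    "test_group",
    "results_to_frame",
]

GROUP_STATISTICS = ("coverage", "exclusivity", "impurity")
# tail direction implied by each group statistic
_GROUP_TAIL = {"coverage": "upper", "exclusivity": "upper", "impurity": "lower"}



@dataclass
class PairResult:
    """Outcome of one pairwise independence test."""

    gene_a: str
    gene_b: str
    direction: str  # 'cooccurrence' or 'exclusivity'
    observed_overlap: int
    expected_overlap: float
    p_value: float
    support_size: int  # attainable outcomes, for discrete FDR
    joint_probs: np.ndarray | None = None  # per-tumor p_aj * p_bj
    q_value: float | None = None


@dataclass
class GroupResult:
    """Outcome of one groupwise mutual exclusivity test."""

    genes: GeneSet
    statistic: str
    observed: int
    expected: float
    p_value: float
    support_size: int
    event_probs: np.ndarray | None = None
    q_value: float | None = None

    @property
    def direction(self) -> str:
        return _GROUP_TAIL[self.statistic]


def _check_aligned(X: AlterationMatrix, P: BackgroundMatrix) -> None:
    if not P.aligned_with(X):
        raise ValueError("alteration matrix and background matrix are not aligned")


def pair_overlap(X: AlterationMatrix, a: str, b: str) -> int:
    """Number of tumors altered in both ``a`` and ``b``."""
    return int((X.row(a) & X.row(b)).sum())


def expected_overlap(P: BackgroundMatrix, a: str, b: str) -> float:
    """Expected overlap under independence: ``sum_j p_aj * p_bj``."""
    return float((P.row(a) * P.row(b)).sum())


def test_pair(
    X: AlterationMatrix,
    P: BackgroundMatrix,
    a: str,
    b: str,
    direction: str = "exclusivity",
) -> PairResult:
    """Poisson-binomial test of one gene pair against the background.

    ``direction='cooccurrence'`` computes the upper tail
    ``P(overlap >= observed)``; ``direction='exclusivity'`` the lower tail
    ``P(overlap <= observed)``.  The observed point is included in either
    tail.
    """
    _check_aligned(X, P)
    if direction not in ("cooccurrence", "exclusivity"):
        raise ValueError(f"unknown direction {direction!r}")
    joint = P.row(a) * P.row(b)
    obs = pair_overlap(X, a, b)
    d = PoissonBinomial(joint)
    p = tail(d, obs, "upper" if direction == "cooccurrence" else "lower")
    # the observed point is attainable, so its tail is mathematically > 0;
    # guard against numerical underflow only
    p = max(p, float(np.finfo(float).tiny))
    return PairResult(
        gene_a=a,
        gene_b=b,
        direction=direction,
        observed_overlap=obs,
        expected_overlap=float(joint.sum()),
        p_value=min(p, 1.0),
        support_size=d.n + 1,
        joint_probs=joint,
    )


def test_all_pairs(
    X: AlterationMatrix,
    P: BackgroundMatrix,
    direction: str = "exclusivity",
    pair_filter: Callable[[str, str], bool] | None = None,
    genes: Sequence[str] | None = None,
) -> list[PairResult]:
    """Test every unordered gene pair, in lexicographic label order.

    ``pair_filter(a, b)`` may veto pairs (e.g. genes on the same
    chromosome, via a user-supplied map).  ``genes`` restricts testing to
    a subset of the matrix's genes.
    """
    _check_aligned(X, P)
    labels = sorted(genes if genes is not None else X.gene_labels)
    if len(labels) < 2:
        raise ValueError("need at least two genes to form pairs")
    out = []
    for a, b in combinations(labels, 2):
        if pair_filter is not None and not pair_filter(a, b):
            continue
        out.append(test_pair(X, P, a, b, direction))
    return out


def group_event_probabilities(
    P: BackgroundMatrix, genes: Sequence[str] | GeneSet, statistic: str
) -> np.ndarray:
    """Per-tumor event probability vector for a group statistic.

    With per-gene probabilities ``p_ij`` for the genes ``i`` in the set:

    * coverage:    ``1 - prod_i (1 - p_ij)``
    * exclusivity: ``sum_i p_ij * prod_{k != i} (1 - p_kj)``
    * impurity:    coverage minus exclusivity

    so ``coverage = exclusivity + impurity`` holds for every tumor.
    """
    if statistic not in GROUP_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; use one of {GROUP_STATISTICS}")
    labels = genes.genes if isinstance(genes, GeneSet) else list(genes)
    if not labels:
        raise ValueError("empty gene set")
    rows = np.vstack([P.row(g) for g in labels])  # (k, m)
    none_alt = np.prod(1.0 - rows, axis=0)
    coverage = 1.0 - none_alt
    if statistic == "coverage":
        return coverage
    # exclusivity: sum_i p_i * prod_{k != i} (1 - p_k), computed per gene to
    # stay exact when some 1 - p_k is zero
    k = rows.shape[0]
    excl = np.zeros(rows.shape[1])
    for i in range(k):
        others = np.prod(np.delete(1.0 - rows, i, axis=0), axis=0) if k > 1 else 1.0
        excl += rows[i] * others
    if statistic == "exclusivity":
        return excl
    if k == 1:
        return np.zeros(rows.shape[1])
    return np.clip(coverage - excl, 0.0, 1.0)


def _observed_group_count(X: AlterationMatrix, labels: Sequence[str], statistic: str) -> int:
    rows = np.vstack([X.row(g) for g in labels])
    per_tumor = rows.sum(axis=0)
    if statistic == "coverage":
        return int((per_tumor >= 1).sum())
    if statistic == "exclusivity":
        return int((per_tumor == 1).sum())
    return int((per_tumor > 1).sum())


def test_group(
    X: AlterationMatrix,
    P: BackgroundMatrix,
    genes: Sequence[str] | GeneSet,
    statistic: str = "impurity",
) -> GroupResult:
    """Groupwise mutual exclusivity test for one gene set.

    The default statistic is impurity (tumors altered in more than one
    gene), tested in the lower tail: mutually exclusive sets show *less*
    impurity than independent genes would.
    """
    _check_aligned(X, P)
    gs = genes if isinstance(genes, GeneSet) else GeneSet("+".join(genes), "", list(genes))
    probs = group_event_probabilities(P, gs, statistic)
    obs = _observed_group_count(X, gs.genes, statistic)
    d = PoissonBinomial(probs)
    p = tail(d, obs, _GROUP_TAIL[statistic])
    pmin = float(np.finfo(float).tiny)
    return GroupResult(
        genes=gs,
        statistic=statistic,
        observed=obs,
        expected=float(probs.sum()),
        p_value=min(max(p, pmin), 1.0),
        support_size=d.n + 1,
        event_probs=probs,
    )


def results_to_frame(results: Iterable[PairResult | GroupResult]) -> pd.DataFrame:
    """Serialize results to a tidy table (TSV-ready)."""
    rows = []
    for r in results:
        if isinstance(r, PairResult):
            rows.append(
                {
                    "gene_a": r.gene_a,
                    "gene_b": r.gene_b,
                    "direction": r.direction,
                    "observed": r.observed_overlap,
                    "expected": r.expected_overlap,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
            )
        else:
            rows.append(
                {
                    "gene_set": r.genes.name,
                    "statistic": r.statistic,
                    "n_genes": len(r.genes),
                    "observed": r.observed,
                    "expected": r.expected,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
            )
    return pd.DataFrame(rows)
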