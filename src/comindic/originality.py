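"""Per-species originality scores from trees.

Two metrics quantify how isolated a species is on a dendrogram or
phylogeny:

* ``equal_splits`` — each branch's length is apportioned to the tips below
  it, divided equally at every subsequent split on the way down.  The
  scores sum to the total branch length; long pendant branches (unique
  trait states) dominate.
* ``qe`` — the species weights that maximize Rao's quadratic entropy
  p'Dp over the probability simplex for a distance matrix D.  The
  maximizing weights concentrate on species whose removal would lose the
  most pairwise dissimilarity; rare-but-shared states matter more here.

Scores can be reported raw or as proportions (summing to one), and a
resampling analysis measures how stable the scores of a core species set
are when extra species are added to the trait table.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traits import DistanceMatrix, TraitTable, gower_distance
from .trees import RootedTree, TreeError, cophenetic, upgma

logger = logging.getLogger(__name__)

METRICS = ("equal_splits", "qe")


@dataclass
class SpeciesScoreVector:
    """Per-species scores (originality or specialization)."""

    species_ids: list
    values: np.ndarray
    metric: str = "equal_splits"
    trait_set: str = "custom"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.species_ids) != self.values.size:
            raise ValueError("ids and values length mismatch")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if (self.values < 0).any():
            raise ValueError("scores must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized scores must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.species_ids, name=self.metric)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metric={self.metric}\n")
            fh.write(f"# trait_set={self.trait_set}\n")
            fh.write(f"# normalized={self.normalized}\n")
            fh.write("species,value\n")
            for sp, v in zip(self.species_ids, self.values):
                fh.write(f"{sp},{v:.12g}\n")

    @classmethod
    def from_csv(cls, path) -> "SpeciesScoreVector":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                elif line and line != "species,value":
                    sp, _, v = line.partition(",")
                    rows.append((sp, float(v)))
        ids = [r[0] for r in rows]
        vals = np.array([r[1] for r in rows])
        return cls(
            ids,
            vals,
            metric=meta.get("metric", "custom"),
            trait_set=meta.get("trait_set", "custom"),
            normalized=meta.get("normalized", "False") == "True",
        )


def equal_splits(tree: RootedTree, trait_set: str = "custom") -> SpeciesScoreVector:
    """Equal-splits originality: branch lengths split equally at each node.

    ES_i sums, over the edges on the root-to-tip path, the edge length
    divided by the product of child counts of every internal node passed
    below that edge.  Summed over tips this recovers the total branch
    length exactly.
    """
    root = tree.root
    if len(root.children) == 1:
        warnings.warn(
            "root has a single child; its edge is passed down without a split"
        )
    scores: dict = {}

    def descend(node, acc: float) -> None:
        if node.is_tip:
            scores[node.label] = acc
            return
        k = len(node.children)
        for child in node.children:
            if child.length is None:
                raise TreeError(
                    f"missing branch length above {child.label or 'internal node'}"
                )
            descend(child, acc / k + child.length)

    if root.is_tip:
        raise TreeError("tree has a single tip; originality undefined")
    for child in root.children:
        if child.length is None:
            raise TreeError(
                f"missing branch length above {child.label or 'internal node'}"
            )
        descend(child, child.length)
    tips = tree.tip_labels
    return SpeciesScoreVector(
        tips,
        np.array([scores[t] for t in tips]),
        metric="equal_splits",
        trait_set=trait_set,
        normalized=False,
    )


def _solve_support(d: np.ndarray, support: np.ndarray):
    """Stationary point of p'Dp on the simplex restricted to ``support``.

    Solves 2 D_SS p = lam * 1, 1'p = 1 for (p, lam); returns None when the
    bordered system is singular.
    """
    s = np.flatnonzero(support)
    k = s.size
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = 2.0 * d[np.ix_(s, s)]
    A[:k, k] = -1.0
    A[k, :k] = 1.0
    b = np.zeros(k + 1)
    b[k] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    p = np.zeros(d.shape[0])
    p[s] = sol[:k]
    return p, sol[k]


def qe_originality(
    dm: DistanceMatrix, trait_set: str = "custom", tol: float = 1e-10
) -> SpeciesScoreVector:
    """Weights maximizing Rao's quadratic entropy p'Dp on the simplex.

    Solved by an iterative active-set method: start from full support,
    solve the equality-constrained stationarity system, drop the most
    negative coordinate while any is negative, then verify the
    Karush-Kuhn-Tucker condition 2(Dp)_j <= lam for excluded species and
    re-admit the worst violator.  For ultrametric D the objective is
    concave on the simplex, so the procedure terminates at the unique
    global maximizer.
    """
    d = dm.d
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 species")
    if not np.any(d > 0):
        raise ValueError("no originality signal: all distances are zero")

    support = np.ones(n, dtype=bool)
    for _ in range(4 * n * n):
        sol = _solve_support(d, support)
        if sol is None:
            # singular restricted system: fall back to uniform on support
            p = support / support.sum()
            lam = 2.0 * float(p @ d @ p)
        else:
            p, lam = sol
        neg = (p < -tol) & support
        if neg.any():
            worst = np.argmin(np.where(support, p, np.inf))
            support[worst] = False
            if support.sum() == 1:
                # a single species can never be a maximizer of p'Dp (value 0)
                support[:] = True
                support[worst] = False
            continue
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        grad = 2.0 * d @ p
        outside = ~support
        if outside.any():
            viol = grad - lam
            viol[support] = -np.inf
            j = int(np.argmax(viol))
            if viol[j] > max(tol, 1e-9 * abs(lam)):
                support[j] = True
                continue
        return SpeciesScoreVector(
            list(dm.labels), p, metric="qe", trait_set=trait_set, normalized=True
        )
    raise RuntimeError("active-set iteration did not converge")


def qe_brute_force(d: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Exhaustive support enumeration for small n (independent oracle)."""
    n = d.shape[0]
    best_val, best_p = -np.inf, None
    for r in range(2, n + 1):
        for subset in itertools.combinations(range(n), r):
            support = np.zeros(n, dtype=bool)
            support[list(subset)] = True
            sol = _solve_support(d, support)
            if sol is None:
                continue
            p, _ = sol
            if (p < -tol).any():
                continue
            p = np.clip(p, 0.0, None)
            p /= p.sum()
            val = float(p @ d @ p)
            if val > best_val + tol:
                best_val, best_p = val, p
    return best_p


def as_proportions(scores: SpeciesScoreVector) -> SpeciesScoreVector:
    """Rescale scores to proportions summing to one."""
    total = scores.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero score vector")
    return replace(scores, values=scores.values / total, normalized=True)


def scores_from_traits(
    table: TraitTable,
    metric: str = "equal_splits",
    trait_set: str = "custom",
    proportions: bool = False,
) -> SpeciesScoreVector:
    """Full trait-to-score chain: Gower -> UPGMA -> originality metric."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    dm = gower_distance(table)
    if metric == "equal_splits":
        out = equal_splits(upgma(dm), trait_set=trait_set)
    else:
        out = qe_originality(cophenetic(upgma(dm)), trait_set=trait_set)
    return as_proportions(out) if proportions else out


@dataclass
class AdditionSensitivityReport:
    """Stability of core-species scores under random species additions."""

    r2_per_rep: np.ndarray
    added_counts: np.ndarray
    metric: str
    seed: int
    mean_r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_r2 = float(np.mean(self.r2_per_rep))


def species_addition_sensitivity(
    base: TraitTable,
    extended: TraitTable,
    metric: str = "equal_splits",
    n_reps: int = 50,
    seed: int = 0,
) -> AdditionSensitivityReport:
    """Regress scores recomputed with extra species on the base scores.

    Each replicate adds a random non-empty subset of the extra species,
    recomputes proportion-normalized scores, and records the coefficient
    of determination (0-100 scale) of extended-on-base scores over the
    shared species.  High R-squared means the ranking is robust to the
    species pool.
    """
    if base.kinds != extended.kinds:
        raise ValueError("base and extended tables have different trait schemas")
    base_ids = set(base.species_ids)
    ext_ids = set(extended.species_ids)
    if not base_ids <= ext_ids:
        raise ValueError("extended table must contain every base species")
    extras = sorted(ext_ids - base_ids)
    if not extras:
        raise ValueError("extended table adds no species")

    base_scores = scores_from_traits(base, metric=metric, proportions=True)
    # align to table order: score vectors come back in tree tip order
    base_series = base_scores.as_series().loc[base.species_ids]
    rng = np.random.default_rng(seed)
    r2s, counts = [], []
    for _ in range(n_reps):
        k = int(rng.integers(1, len(extras) + 1))
        chosen = list(rng.choice(extras, size=k, replace=False))
        sub = extended.subset(base.species_ids + sorted(chosen))
        ext_scores = scores_from_traits(sub, metric=metric, proportions=True)
        ext_series = ext_scores.as_series().loc[base.species_ids]
        x = base_series.to_numpy()
        y = ext_series.to_numpy()
        xc = x - x.mean()
        yc = y - y.mean()
        denom = float((xc @ xc) * (yc @ yc))
        r2 = float((xc @ yc) ** 2 / denom) if denom > 0 else 1.0
        r2s.append(100.0 * r2)
        counts.append(k)
    return AdditionSensitivityReport(
        np.array(r2s), np.array(counts), metric=metric, seed=seed
    )
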