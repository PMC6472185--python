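"""Directed gene-regulatory-network inference from expression matrices.

Both inference schemes decompose the network problem into one regression
per target gene: the target's expression profile (standardized to unit
variance) is regressed on the profiles of all candidate regulators across
samples, and the importance a tree ensemble assigns to regulator *j* when
predicting target *i* becomes the weight of the directed edge *j → i*.
Importance is the total impurity (variance) decrease attributed to the
predictor, summed over all split nodes and averaged over trees — the raw,
unnormalized quantity, so weights are comparable across targets whose
ensembles differ in depth.

Two ensembles are offered:

* ``genie3`` — Random-Forest or Extra-Trees regression with ``sqrt(p)``
  candidate features per split (classic steady-state inference).
* ``grnboost2`` — stochastic gradient boosting of shallow trees with a
  small learning rate, subsampling, and early stopping when the moving
  average of out-of-bag improvements over a configurable window turns
  negative.

Samples are treated as exchangeable observations; with fewer than ten
samples a warning is emitted because per-target regressions are then
heavily under-determined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .matrix import ExpressionMatrix

MIN_SAMPLES_WARN = 10


class GRNEdge(NamedTuple):
    regulator: str
    target: str
    weight: float


@dataclass(frozen=True)
class GRNResult:
    edges: tuple[GRNEdge, ...]
    algorithm: str  # genie3_rf | genie3_et | grnboost2
    seed: int
    params: dict = field(default_factory=dict)

    def sorted_edges(self) -> list[GRNEdge]:
        """Weight-descending, ties broken by (regulator, target) name."""
        return sorted(self.edges, key=lambda e: (-e.weight, e.regulator, e.target))

    def to_frame(self) -> pd.DataFrame:
        rows = self.sorted_edges()
        return pd.DataFrame(
            {
                "regulator": [e.regulator for e in rows],
                "target": [e.target for e in rows],
                "weight": [e.weight for e in rows],
                "rank": range(1, len(rows) + 1),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.regulator, e.target, weight=float(e.weight))
        nx.write_graphml(g, str(path))


def _as_samples_by_genes(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    return values.T  # samples x genes


def _check_input(data: pd.DataFrame) -> None:
    n_samples, n_genes = data.shape
    if n_genes < 3 or n_samples < 3:
        raise DomainError(
            f"network inference needs >= 3 genes and >= 3 samples, "
            f"got {n_genes} genes x {n_samples} samples"
        )
    if n_samples < MIN_SAMPLES_WARN:
        warnings.warn(
            f"only {n_samples} samples; tree-ensemble regressions are "
            "under-determined below ~10 observations",
            stacklevel=3,
        )


def _tree_importance(tree) -> np.ndarray:
    # unnormalized: sum over nodes of weighted impurity decrease / n_samples
    return tree.tree_.compute_feature_importances(normalize=False)


def _target_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _regressor_indices(
    genes: list[str], regulators: Sequence[str] | None
) -> list[int]:
    if regulators is None:
        return list(range(len(genes)))
    missing = sorted(set(regulators) - set(genes))
    if missing:
        raise ValidationError(f"regulators absent from the matrix: {missing}")
    reg_set = set(regulators)
    return [i for i, g in enumerate(genes) if g in reg_set]


def _infer(
    matrix: ExpressionMatrix | pd.DataFrame,
    fit_one,
    algorithm: str,
    seed: int,
    params: dict,
    regulators: Sequence[str] | None,
) -> GRNResult:
    """Shared per-target loop: standardize, fit, collect importances."""
    data = _as_samples_by_genes(matrix)
    _check_input(data)
    genes = list(data.columns)
    x_all = data.to_numpy(dtype=float)
    reg_idx = _regressor_indices(genes, regulators)
    seeds = _target_seeds(seed, len(genes))

    edges: list[GRNEdge] = []
    for t, target in enumerate(genes):
        y = x_all[:, t]
        sd = y.std()
        predictors = [i for i in reg_idx if i != t]
        if not predictors:
            continue
        if sd == 0:
            warnings.warn(f"target '{target}' is constant; incoming weights set to 0",
                          stacklevel=3)
            importances = np.zeros(len(predictors))
        else:
            importances = fit_one(x_all[:, predictors], y / sd, int(seeds[t]))
        for i, w in zip(predictors, importances):
            edges.append(GRNEdge(genes[i], target, float(max(w, 0.0))))
    return GRNResult(edges=tuple(edges), algorithm=algorithm, seed=seed, params=params)


def infer_genie3(
    matrix: ExpressionMatrix | pd.DataFrame,
    n_trees: int = 1000,
    variant: str = "ET",
    max_features: float | str = "sqrt",
    seed: int = 0,
    regulators: Sequence[str] | None = None,
) -> GRNResult:
    """Random-Forest / Extra-Trees network inference.

    ``variant`` selects the base ensemble: ``"RF"`` (bootstrapped Random
    Forest) or ``"ET"`` (Extra-Trees on the full sample).  Edge weight
    j → i is the mean over trees of the total variance reduction predictor
    j contributes in target i's ensemble.  Fully deterministic given
    ``seed``.
    """
    from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor

    if variant not in ("RF", "ET"):
        raise ValidationError(f"variant must be 'RF' or 'ET', got {variant!r}")
    cls = RandomForestRegressor if variant == "RF" else ExtraTreesRegressor

    def fit_one(x: np.ndarray, y: np.ndarray, target_seed: int) -> np.ndarray:
        est = cls(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=target_seed,
            bootstrap=(variant == "RF"),
            n_jobs=1,
        )
        est.fit(x, y)
        per_tree = np.array([_tree_importance(t) for t in est.estimators_])
        return per_tree.mean(axis=0)

    return _infer(
        matrix,
        fit_one,
        algorithm=f"genie3_{variant.lower()}",
        seed=seed,
        params={"n_trees": n_trees, "max_features": max_features, "variant": variant},
        regulators=regulators,
    )


class _EarlyStopMonitor:
    """Stop boosting once the moving average of OOB improvements goes negative."""

    def __init__(self, window: int):
        self.window = window

    def __call__(self, i: int, model, locals_) -> bool:
        if i < self.window:
            return False
        recent = model.oob_improvement_[i - self.window + 1 : i + 1]
        return float(np.mean(recent)) < 0.0


def infer_grnboost2(
    matrix: ExpressionMatrix | pd.DataFrame,
    max_rounds: int = 500,
    learning_rate: float = 0.01,
    early_stop_window: int = 25,
    subsample: float = 0.9,
    max_depth: int = 3,
    seed: int = 0,
    regulators: Sequence[str] | None = None,
) -> GRNResult:
    """Stochastic gradient-boosting network inference with early stopping.

    Each boosting round fits a shallow tree to a random ``subsample``
    fraction of the samples; the held-out remainder yields an out-of-bag
    improvement per round.  Boosting stops early when the mean improvement
    over the last ``early_stop_window`` rounds is negative (a window larger
    than ``max_rounds`` disables early stopping, i.e. fixed-round
    boosting).  Edge weights are summed tree importances as in GENIE3.
    """
    from sklearn.ensemble import GradientBoostingRegressor

    monitor = _EarlyStopMonitor(early_stop_window)

    def fit_one(x: np.ndarray, y: np.ndarray, target_seed: int) -> np.ndarray:
        est = GradientBoostingRegressor(
            n_estimators=max_rounds,
            learning_rate=learning_rate,
            subsample=subsample,
            max_depth=max_depth,
            random_state=target_seed,
        )
        est.fit(x, y, monitor=monitor if subsample < 1.0 else None)
        per_tree = np.array([_tree_importance(stage[0]) for stage in est.estimators_])
        return per_tree.sum(axis=0)

    return _infer(
        matrix,
        fit_one,
        algorithm="grnboost2",
        seed=seed,
        params={
            "max_rounds": max_rounds,
            "learning_rate": learning_rate,
            "early_stop_window": early_stop_window,
            "subsample": subsample,
            "max_depth": max_depth,
        },
        regulators=regulators,
    )


def top_n_links(result: GRNResult, n: int) -> GRNResult:
    """The n highest-weight links (weight > 0), a prefix of the full sort.

    The kept node set is exactly the endpoints of the kept edges; the
    top-n edge set is monotone in n by construction.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    positive = [e for e in result.sorted_edges() if e.weight > 0]
    return GRNResult(
        edges=tuple(positive[:n]),
        algorithm=result.algorithm,
        seed=result.seed,
        params=dict(result.params, top_n=n),
    )
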