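"""k-modes clustering of category patterns with elbow-based selection of k.

k-modes is the categorical analogue of k-means: the dissimilarity between two
patterns is the number of attribute positions where their categories differ
(simple matching), and a cluster's representative is its *mode*, the
attribute-wise most frequent category among members.  The absent-data code 0
participates as an ordinary category by default, since patterns legitimately
contain structural zeros (drug not given, parameter not monitored).

Fitting alternates batch assignment (nearest mode, ties to the lowest cluster
index) and mode updates (ties to the lowest category code) until labels stop
changing; the best of ``n_init`` restarts by total cost is kept.  The first
restart uses Cao's deterministic density initialization, the rest draw k
distinct patterns under the seed.  Empty clusters keep their stale mode, which
keeps the per-iteration cost provably non-increasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .patterns import UniquePatternTable

__all__ = [
    "matching_distance",
    "kmodes_fit",
    "elbow_select",
    "assign_full",
    "KModesModel",
    "ElbowCurve",
]


def matching_distance(a, b) -> int:
    """Number of attribute positions where two category vectors differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.sum(a != b))


def _distances(X: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """(n, k) matching distances between every pattern and every mode."""
    return (X[:, None, :] != modes[None, :, :]).sum(axis=2)


def _update_modes(X: np.ndarray, labels: np.ndarray, modes: np.ndarray, n_cat: int) -> np.ndarray:
    new = modes.copy()
    for c in range(modes.shape[0]):
        members = X[labels == c]
        if members.shape[0] == 0:
            continue  # empty cluster: keep stale mode
        counts = (members[:, :, None] == np.arange(n_cat)[None, None, :]).sum(axis=0)
        new[c] = counts.argmax(axis=1)  # argmax ties -> lowest category code
    return new


def _cao_init(X: np.ndarray, k: int, n_cat: int) -> np.ndarray:
    """Cao's deterministic density-based initialization.

    The first mode is the densest pattern (average attribute-category
    frequency); each further mode maximizes density x distance to the nearest
    already-chosen mode.  All ties break to the lowest row index.
    """
    n, L = X.shape
    freq = np.stack([np.bincount(X[:, j], minlength=n_cat) for j in range(L)]) / n  # (L, n_cat)
    dens = freq[np.arange(L)[None, :], X].mean(axis=1)  # (n,)
    chosen = [int(dens.argmax())]
    while len(chosen) < k:
        d = _distances(X, X[chosen]).min(axis=1)
        score = dens * d
        idx = int(score.argmax())
        if d[idx] == 0:  # all remaining duplicate a chosen mode: pick any distinct pattern
            cand = np.nonzero(d > 0)[0]
            if cand.size == 0:
                raise ValueError("fewer distinct patterns than k")
            idx = int(cand[0])
        chosen.append(idx)
    return X[chosen].copy()


@dataclass
class KModesModel:
    """A fitted k-modes model: modes, per-pattern labels and total cost."""

    k: int
    modes: np.ndarray
    labels: np.ndarray
    cost: int
    seed: int
    n_init: int
    n_iter_run: int
    cost_history: list[int] = field(default_factory=list)

    def predict(self, patterns) -> np.ndarray:
        X = np.asarray(patterns, dtype=np.int64)
        return _distances(X, self.modes).argmin(axis=1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "modes": self.modes.tolist(),
            "labels": self.labels.tolist(),
            "cost": int(self.cost),
            "seed": int(self.seed),
            "n_init": int(self.n_init),
            "n_iter_run": int(self.n_iter_run),
            "cost_history": [int(c) for c in self.cost_history],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d) -> "KModesModel":
        return cls(
            k=int(d["k"]),
            modes=np.asarray(d["modes"], dtype=np.int64),
            labels=np.asarray(d["labels"], dtype=np.int64),
            cost=int(d["cost"]),
            seed=int(d["seed"]),
            n_init=int(d["n_init"]),
            n_iter_run=int(d["n_iter_run"]),
            cost_history=[int(c) for c in d.get("cost_history", [])],
        )

    @classmethod
    def load(cls, path: str | Path) -> "KModesModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _run_single(X: np.ndarray, modes: np.ndarray, max_iter: int, n_cat: int):
    n = X.shape[0]
    labels = None
    history: list[int] = []
    it = 0
    for it in range(1, max_iter + 1):
        D = _distances(X, modes)
        new_labels = D.argmin(axis=1)  # ties -> lowest cluster index
        cost = int(D[np.arange(n), new_labels].sum())
        history.append(cost)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        modes = _update_modes(X, labels, modes, n_cat)
    return labels, modes, history[-1], history, it


def kmodes_fit(
    patterns,
    k: int,
    seed: int = 0,
    n_init: int = 20,
    max_iter: int = 100,
) -> KModesModel:
    """Fit k-modes on category patterns; best of ``n_init`` restarts by cost.

    Fully reproducible from ``seed``.  ``k`` must not exceed the number of
    distinct patterns.
    """
    X = np.asarray(patterns, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty input: need a nonempty 2-D pattern array")
    if n_init < 1 or max_iter < 1:
        raise ValueError("n_init and max_iter must be >= 1")
    uniq = np.unique(X, axis=0)
    if not 1 <= k <= uniq.shape[0]:
        raise ValueError(f"k={k} must be in [1, number of unique patterns = {uniq.shape[0]}]")
    n_cat = max(int(X.max()) + 1, 6)

    rng = np.random.default_rng(seed)
    best: KModesModel | None = None
    for r in range(n_init):
        if r == 0:
            init = _cao_init(X, k, n_cat)
        elif r % 2 == 1:
            idx = rng.choice(uniq.shape[0], size=k, replace=False)
            init = uniq[np.sort(idx)].copy()
        else:
            # free random modes: reaches optima whose modes are not data points
            init = rng.integers(0, n_cat, size=(k, X.shape[1]))
        labels, modes, cost, history, n_iter = _run_single(X, init, max_iter, n_cat)
        if best is None or cost < best.cost:
            best = KModesModel(
                k=k,
                modes=modes,
                labels=labels,
                cost=cost,
                seed=seed,
                n_init=n_init,
                n_iter_run=n_iter,
                cost_history=history,
            )
    return best


@dataclass
class ElbowCurve:
    """Cost-vs-k curve with the knee chosen by maximum second difference."""

    ks: list[int]
    costs: list[int]
    chosen_k: int
    method: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.ks, "cost": self.costs})


def elbow_select(
    patterns,
    k_max: int = 25,
    seed: int = 0,
    n_init: int = 20,
    max_iter: int = 100,
    chosen_k: int | None = None,
) -> ElbowCurve:
    """Fit k = 1..k_max and pick the knee of the cost curve.

    The knee is the k maximizing the second difference
    cost(k-1) - 2 cost(k) + cost(k+1); a config-supplied ``chosen_k`` overrides
    the automatic choice (tag ``preset``).  k_max is capped at the number of
    distinct patterns.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = np.asarray(patterns, dtype=np.int64)
    n_distinct = np.unique(X, axis=0).shape[0]
    kk = min(k_max, n_distinct)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=kk)
    ks = list(range(1, kk + 1))
    costs = [kmodes_fit(X, k, seed=int(seeds[k - 1]), n_init=n_init, max_iter=max_iter).cost for k in ks]

    if chosen_k is not None:
        if not 1 <= chosen_k <= kk:
            raise ValueError(f"chosen_k={chosen_k} outside [1, {kk}]")
        return ElbowCurve(ks=ks, costs=costs, chosen_k=int(chosen_k), method="preset")
    c = np.asarray(costs, dtype=float)
    if kk < k_max:
        # the curve terminated at the number of distinct patterns; beyond it the
        # cost is exactly flat, so extend it for the boundary second difference
        c = np.append(c, c[-1])
    if c.size >= 3:
        d2 = c[:-2] - 2.0 * c[1:-1] + c[2:]
        pick = ks[0] + 1 + int(d2.argmax())
    else:
        pick = ks[-1]
    return ElbowCurve(ks=ks, costs=costs, chosen_k=pick, method="max_second_difference")


def assign_full(model: KModesModel, unique_table: UniquePatternTable) -> np.ndarray:
    """Propagate cluster labels from unique patterns to every source record."""
    if model.labels.shape[0] != unique_table.n_unique:
        raise ValueError(
            f"model fitted on {model.labels.shape[0]} patterns but table has "
            f"{unique_table.n_unique} uniques"
        )
    return model.labels[unique_table.record_ids]
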