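"""Fast correlation-based filter: SU relevance ranking + redundancy pruning.

Continuous feature columns are discretized with Fayyad-Irani supervised
entropy minimization (MDL stopping rule) before any entropy is computed.
Symmetrical uncertainty SU(a, b) = 2 [H(a) - H(a|b)] / [H(a) + H(b)].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def _entropy(codes: np.ndarray) -> float:
    return _entropy_from_counts(np.unique(codes, return_counts=True)[1])


def _joint_entropy(a: np.ndarray, b: np.ndarray) -> float:
    pairs = a.astype(np.int64) * (b.max() + 1) + b.astype(np.int64)
    return _entropy(pairs)


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU between two discrete columns, in [0, 1]; 0 when both are constant."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be 1-D and of equal length")
    _, a = np.unique(a, return_inverse=True)
    _, b = np.unique(b, return_inverse=True)
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0:
        return 0.0
    mi = ha + hb - _joint_entropy(a, b)
    return float(2.0 * mi / (ha + hb))


# --------------------------------------------------------------------------
# Fayyad-Irani MDL discretization
# --------------------------------------------------------------------------

def _class_entropy(y: np.ndarray) -> float:
    return _entropy_from_counts(np.unique(y, return_counts=True)[1])


def _mdl_cuts(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Recursive entropy-minimization cut points with the MDL stopping rule."""
    order = np.argsort(x, kind="mergesort")
    x, y = x[order], y[order]

    def recurse(lo: int, hi: int, cuts: list[float]) -> None:
        xs, ys = x[lo:hi], y[lo:hi]
        n = hi - lo
        if n < 2:
            return
        # candidate boundaries: midpoints between adjacent distinct values
        distinct = np.nonzero(np.diff(xs))[0]
        if distinct.size == 0:
            return
        ent_s = _class_entropy(ys)
        best = None
        for idx in distinct:
            left, right = ys[: idx + 1], ys[idx + 1:]
            e = (left.size * _class_entropy(left)
                 + right.size * _class_entropy(right)) / n
            if best is None or e < best[0]:
                best = (e, idx)
        e_split, idx = best
        gain = ent_s - e_split
        left, right = ys[: idx + 1], ys[idx + 1:]
        k = np.unique(ys).size
        k1, k2 = np.unique(left).size, np.unique(right).size
        delta = (np.log2(3.0 ** k - 2.0)
                 - (k * ent_s - k1 * _class_entropy(left)
                    - k2 * _class_entropy(right)))
        if gain <= (np.log2(n - 1) + delta) / n:
            return
        cuts.append(float((xs[idx] + xs[idx + 1]) / 2.0))
        recurse(lo, lo + idx + 1, cuts)
        recurse(lo + idx + 1, hi, cuts)

    cuts: list[float] = []
    recurse(0, len(x), cuts)
    return sorted(cuts)


def discretize(column: np.ndarray, labels: np.ndarray,
               edges: list[float] | None = None) -> tuple[np.ndarray, list[float]]:
    """Supervised MDL discretization; returns (codes, bin edges).

    Pass previously computed edges to reuse a training-set discretization.
    A column yielding no accepted cut collapses to a single bin (SU = 0).
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    if column.size < 2:
        raise ValueError("need at least 2 rows")
    if edges is None:
        edges = _mdl_cuts(column, labels)
    return np.searchsorted(edges, column, side="right"), list(edges)


@dataclass
class SelectionResult:
    """Outcome of FCBF: ranking, survivors, and discard provenance."""

    ranked: list[tuple[str, float]]
    selected: list[str]
    discarded: list[tuple[str, str]]          # (feature, dominating feature)
    irrelevant: list[str] = field(default_factory=list)  # SU(X, Y) == 0
    bin_edges: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ranked": [[n, su] for n, su in self.ranked],
            "selected": list(self.selected),
            "discarded": [[n, d] for n, d in self.discarded],
            "irrelevant": list(self.irrelevant),
            "bin_edges": {k: list(v) for k, v in self.bin_edges.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(ranked=[tuple(x) for x in d["ranked"]],
                   selected=list(d["selected"]),
                   discarded=[tuple(x) for x in d["discarded"]],
                   irrelevant=list(d.get("irrelevant", [])),
                   bin_edges={k: list(v) for k, v in
                              d.get("bin_edges", {}).items()})


def fcbf(table: pd.DataFrame, feature_names: list[str] | None = None,
         label_col: str = "group") -> SelectionResult:
    """Run FCBF on (training) rows of a feature table.

    Step 1 ranks features by SU with the labels (descending, ties broken by
    feature name).  Step 2 walks the ranking and discards every lower-ranked
    feature that shares at least as much information with a surviving
    higher-ranked feature as with the labels.
    """
    if table.empty:
        raise ValueError("empty training table")
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in (label_col, "subject_id", "split")]
    y = table[label_col].to_numpy()

    codes: dict[str, np.ndarray] = {}
    result_edges: dict[str, list[float]] = {}
    su_y: dict[str, float] = {}
    for name in feature_names:
        c, edges = discretize(table[name].to_numpy(), y)
        codes[name] = c
        result_edges[name] = edges
        su_y[name] = symmetrical_uncertainty(c, y)

    ranked = sorted(su_y.items(), key=lambda kv: (-kv[1], kv[0]))
    irrelevant = [n for n, su in ranked if su == 0.0]
    active = [n for n, su in ranked if su > 0.0]

    discarded: list[tuple[str, str]] = []
    dropped: set[str] = set()
    for i, fi in enumerate(active):
        if fi in dropped:
            continue
        for fj in active[i + 1:]:
            if fj in dropped:
                continue
            if symmetrical_uncertainty(codes[fi], codes[fj]) >= su_y[fj]:
                dropped.add(fj)
                discarded.append((fj, fi))
    selected = [n for n in active if n not in dropped]
    return SelectionResult(ranked=ranked, selected=selected,
                           discarded=discarded, irrelevant=irrelevant,
                           bin_edges=result_edges)
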