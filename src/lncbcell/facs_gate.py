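"""Recursive partitioning of flow-cytometry events with two-marker gates.

Each internal node splits events with a quadrant rule on a pair of surface
markers — two thresholds combined by AND or OR, each inequality flippable
(8 rule forms) — chosen by exhaustive search over marker pairs and an
empirical-quantile threshold grid to maximize the decrease in Gini
impurity.  Trees are depth-limited (default 3), leaves carry the majority
subset label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

#: rule forms: (flip_x, flip_y, combine). flip False means ">= threshold".
RULE_FORMS: tuple[tuple[bool, bool, str], ...] = tuple(
    (fx, fy, op) for op in ("and", "or") for fx in (False, True) for fy in (False, True)
)


def gini(class_counts) -> float:
    """Gini impurity 1 - sum_k (n_k / n)^2."""
    c = np.asarray(class_counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative class counts")
    n = c.sum()
    if n == 0:
        raise ValueError("all class counts are zero")
    p = c / n
    return float(1.0 - (p * p).sum())


@dataclass
class GateRule:
    marker_x: str
    marker_y: str
    t_x: float
    t_y: float
    flip_x: bool  # False: x >= t_x ; True: x < t_x
    flip_y: bool
    combine: str  # "and" | "or"

    def evaluate(self, events: pd.DataFrame) -> np.ndarray:
        for m in (self.marker_x, self.marker_y):
            if m not in events.columns:
                raise ValueError(f"missing marker column {m!r}")
        cx = events[self.marker_x].to_numpy() >= self.t_x
        cy = events[self.marker_y].to_numpy() >= self.t_y
        if self.flip_x:
            cx = ~cx
        if self.flip_y:
            cy = ~cy
        return (cx & cy) if self.combine == "and" else (cx | cy)

    def describe(self) -> str:
        ox = "<" if self.flip_x else ">="
        oy = "<" if self.flip_y else ">="
        return (
            f"({self.marker_x} {ox} {self.t_x:.4g}) {self.combine.upper()} "
            f"({self.marker_y} {oy} {self.t_y:.4g})"
        )


@dataclass
class GateNode:
    rule: GateRule | None = None
    true_child: "GateNode | None" = None
    false_child: "GateNode | None" = None
    label: str | None = None
    proportions: dict[str, float] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclass
class GateTree:
    root: GateNode
    markers: list[str]
    max_depth: int

    def depth(self) -> int:
        def rec(node: GateNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(rec(node.true_child), rec(node.false_child))

        return rec(self.root)

    def to_dict(self) -> dict:
        def rec(node: GateNode) -> dict:
            if node.is_leaf:
                return {"label": node.label, "proportions": node.proportions}
            r = node.rule
            return {
                "rule": {
                    "marker_x": r.marker_x, "marker_y": r.marker_y,
                    "t_x": r.t_x, "t_y": r.t_y,
                    "flip_x": r.flip_x, "flip_y": r.flip_y, "combine": r.combine,
                },
                "true": rec(node.true_child),
                "false": rec(node.false_child),
            }

        return {"max_depth": self.max_depth, "markers": self.markers, "tree": rec(self.root)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GateTree":
        def rec(nd: dict) -> GateNode:
            if "rule" in nd:
                return GateNode(
                    rule=GateRule(**nd["rule"]),
                    true_child=rec(nd["true"]),
                    false_child=rec(nd["false"]),
                )
            return GateNode(label=nd["label"], proportions=nd.get("proportions", {}))

        return cls(root=rec(d["tree"]), markers=d["markers"], max_depth=d["max_depth"])


def _grid(values: np.ndarray, quantiles: np.ndarray) -> np.ndarray:
    return np.unique(np.quantile(values, quantiles))


def best_gate(
    events: pd.DataFrame,
    labels: pd.Series,
    markers: list[str] | None = None,
    quantiles: np.ndarray | None = None,
) -> tuple[GateRule | None, float]:
    """Exhaustive search for the impurity-minimizing two-marker quadrant rule.

    Searches all unordered marker pairs x threshold grid (empirical
    quantiles, default 5%..95% in steps of 5%) x the 8 rule forms; returns
    the rule maximizing the Gini decrease, or (None, 0.0) when no split
    improves.  Ties break deterministically by (marker pair, t_x, t_y,
    rule-form index).
    """
    if markers is None:
        markers = [m for m in events.columns if np.issubdtype(events[m].dtype, np.number)]
    else:
        markers = list(markers)
    if quantiles is None:
        # 5%..95% in 5% steps plus the data extremes, so a rule can collapse
        # to a single effective threshold (second condition vacuously true)
        quantiles = np.concatenate(([0.0], np.arange(0.05, 0.951, 0.05), [1.0]))
    classes, y_codes = np.unique(labels.to_numpy(), return_inverse=True)
    if len(classes) < 2:
        return None, 0.0
    n = len(y_codes)
    n_classes = len(classes)
    total_counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    g_parent = gini(total_counts)

    usable = [m for m in markers if np.std(events[m].to_numpy(dtype=float)) > 0]
    best: tuple[float, tuple, GateRule] | None = None
    for mx, my in combinations(sorted(usable), 2):
        x = events[mx].to_numpy(dtype=float)
        yv = events[my].to_numpy(dtype=float)
        tx_grid = _grid(x, quantiles)
        ty_grid = _grid(yv, quantiles)
        ntx, nty = len(tx_grid), len(ty_grid)
        # per-class 2-D histogram with the thresholds as inner bin edges;
        # suffix sums give count(x >= tx_i AND y >= ty_j) for every i, j
        xe = np.concatenate(([-np.inf], tx_grid, [np.inf]))
        ye = np.concatenate(([-np.inf], ty_grid, [np.inf]))
        A = np.empty((n_classes, ntx, nty))
        B = np.empty((n_classes, ntx))   # count(x >= tx_i)
        C = np.empty((n_classes, nty))   # count(y >= ty_j)
        for c in range(n_classes):
            sel = y_codes == c
            h, _, _ = np.histogram2d(x[sel], yv[sel], bins=[xe, ye])
            suf = np.flip(np.flip(h, 0).cumsum(0), 0)
            suf = np.flip(np.flip(suf, 1).cumsum(1), 1)
            A[c] = suf[1:, 1:]
            B[c] = suf[1:, 0]
            C[c] = suf[0, 1:]
        Nc = total_counts[:, None, None]
        Bc, Cc = B[:, :, None], C[:, None, :]
        # class counts landing on the rule's TRUE side, per rule form,
        # by inclusion-exclusion from the >=/>= quadrant counts
        form_counts = {
            (False, False, "and"): A,
            (False, True, "and"): Bc - A,
            (True, False, "and"): Cc - A,
            (True, True, "and"): Nc - Bc - Cc + A,
            (False, False, "or"): Bc + Cc - A,
            (False, True, "or"): Nc - Cc + A,
            (True, False, "or"): Nc - Bc + A,
            (True, True, "or"): Nc - A,
        }
        for form_idx, form in enumerate(RULE_FORMS):
            counts_true = form_counts[form]
            n_true = counts_true.sum(axis=0)
            counts_false = total_counts[:, None, None] - counts_true
            n_false = n - n_true
            with np.errstate(divide="ignore", invalid="ignore"):
                g_true = 1.0 - ((counts_true / n_true) ** 2).sum(axis=0)
                g_false = 1.0 - ((counts_false / n_false) ** 2).sum(axis=0)
            g_true = np.where(n_true > 0, g_true, 0.0)
            g_false = np.where(n_false > 0, g_false, 0.0)
            delta = g_parent - (n_true / n) * g_true - (n_false / n) * g_false
            delta = np.where((n_true == 0) | (n_false == 0), -np.inf, delta)
            # mathematically tied candidates must fall to the deterministic
            # tie-break, not to floating-point noise in the gini arithmetic
            delta = np.round(delta, 12)
            flat_idx = int(np.argmax(delta))
            d = float(delta.ravel()[flat_idx])
            if d <= 0:
                continue
            ti, tj = np.unravel_index(flat_idx, (ntx, nty))
            fx, fy, op = form
            key = (-d, (mx, my), float(tx_grid[ti]), float(ty_grid[tj]), form_idx)
            if best is None or key < best[1]:
                rule = GateRule(mx, my, float(tx_grid[ti]), float(ty_grid[tj]), fx, fy, op)
                best = (d, key, rule)
    if best is None:
        return None, 0.0
    return best[2], best[0]


def build_tree(
    events: pd.DataFrame,
    labels: pd.Series,
    max_depth: int = 3,
    markers: list[str] | None = None,
    quantiles: np.ndarray | None = None,
) -> GateTree:
    """Recursively fit Gini-optimal gates; stop at purity, depth, or no gain."""
    if len(events) == 0:
        raise ValueError("no events to fit")
    if markers is None:
        markers = [m for m in events.columns if np.issubdtype(events[m].dtype, np.number)]
    else:
        markers = list(markers)
    y = labels.reset_index(drop=True)
    ev = events.reset_index(drop=True)

    def majority(lbls: pd.Series) -> tuple[str, dict[str, float]]:
        counts = lbls.value_counts()
        props = (counts / counts.sum()).to_dict()
        top = counts.max()
        label = sorted(counts.index[counts == top])[0]
        return label, props

    def rec(mask: np.ndarray, depth: int) -> GateNode:
        lbls = y[mask]
        label, props = majority(lbls)
        if depth >= max_depth or lbls.nunique() == 1:
            return GateNode(label=label, proportions=props)
        rule, delta = best_gate(ev[mask], lbls, markers=markers, quantiles=quantiles)
        if rule is None or delta <= 0:
            return GateNode(label=label, proportions=props)
        side = rule.evaluate(ev[mask])
        full_true = mask.copy()
        full_true[mask] = side
        full_false = mask.copy()
        full_false[mask] = ~side
        return GateNode(
            rule=rule,
            true_child=rec(full_true, depth + 1),
            false_child=rec(full_false, depth + 1),
            label=label,
            proportions=props,
        )

    root = rec(np.ones(len(ev), dtype=bool), 0)
    return GateTree(root=root, markers=markers, max_depth=max_depth)


def apply_tree(tree: GateTree, events: pd.DataFrame) -> pd.DataFrame:
    """Route events through the tree; returns per-event label and path."""
    missing = [m for m in tree.markers if m not in events.columns]
    if missing:
        raise ValueError(f"events missing marker columns: {missing}")
    n = len(events)
    labels = np.empty(n, dtype=object)
    paths = np.empty(n, dtype=object)
    if n == 0:
        return pd.DataFrame({"label": labels, "path": paths})

    def rec(node: GateNode, mask: np.ndarray, path: str) -> None:
        if not mask.any():
            return
        if node.is_leaf:
            labels[mask] = node.label
            paths[mask] = path or "root"
            return
        side = node.rule.evaluate(events[mask])
        t = mask.copy()
        t[mask] = side
        f = mask.copy()
        f[mask] = ~side
        rec(node.true_child, t, path + "T")
        rec(node.false_child, f, path + "F")

    rec(tree.root, np.ones(n, dtype=bool), "")
    return pd.DataFrame({"label": labels, "path": paths}, index=events.index)
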