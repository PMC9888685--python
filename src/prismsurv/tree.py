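"""The PRISM/HPRISM recursive-partitioning engine.

The engine approximates a surface-varying-coefficient survival model: a
binary tree over the individual-level covariates z partitions the cohort into
cells A_l, and within each cell a Stute-weighted regression of log survival
time on the focus variable x (optionally plus an x*w interaction with a
tract-level contextual variable w — the hierarchical, HPRISM, mode) is fit.

Splits are scored by the reduction in the sum of squared *imputed* residuals,

    dRSS(s) = sum_{i in parent} rhat_i^2
              - (sum_{i in left} rhat_i^2 + sum_{i in right} rhat_i^2),

where each daughter term comes from a model refit (weights recomputed,
censored residuals re-imputed) within that daughter. A log-rank alternative
scores a split by |LR(left) - LR(right)|, the absolute difference of the
two-sample log-rank statistics comparing focus groups inside each daughter.
Growth stops rpart-style: a split is accepted only if its dRSS is at least
cp times the root's imputed-residual RSS.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import _fastscan
from .data_model import Dataset, validate_dataset
from .stute import (FitError, NodeModel, StuteWeights, _impute,
                    _stute_d_sorted, _wls_core, fit_node_model)

log = logging.getLogger(__name__)

__all__ = [
    "SplitRule",
    "TreeNode",
    "TreeConfig",
    "PrismTree",
    "grow",
    "predict",
    "best_split",
    "evaluate_split",
    "logrank_split_statistic",
]


@dataclass
class SplitRule:
    """A binary split: ``z < s`` for numeric/ordinal, or ``z in s`` (a level
    set) for nominal covariates. Records satisfying the rule go left."""

    variable: str
    kind: str  # "threshold" | "subset"
    s: object  # float threshold or frozenset of level labels
    delta_rss: float = float("nan")

    def to_dict(self):
        s = sorted(self.s) if self.kind == "subset" else self.s
        return {"variable": self.variable, "kind": self.kind, "s": s,
                "delta_rss": self.delta_rss}

    @classmethod
    def from_dict(cls, d):
        s = frozenset(d["s"]) if d["kind"] == "subset" else d["s"]
        return cls(d["variable"], d["kind"], s, d.get("delta_rss", float("nan")))


@dataclass
class TreeConfig:
    mode: str = "HPRISM"  # "PRISM" | "HPRISM"
    contextual_variable: str | None = None
    criterion: str = "delta_rss"  # "delta_rss" | "logrank"
    cp: float = 0.01
    min_node: int = 20
    min_events_per_group: int = 1
    max_depth: int | None = None
    daughter_residuals: str = "refit"  # "refit" | "parent"
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("PRISM", "HPRISM"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "HPRISM" and not self.contextual_variable:
            raise ValueError("HPRISM requires a contextual_variable")
        if self.cp < 0:
            raise ValueError("cp must be >= 0")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")

    @property
    def hprism(self):
        return self.mode == "HPRISM"


@dataclass
class TreeNode:
    id: int
    depth: int
    members: np.ndarray  # record row indices, sorted by (y, events-first)
    model: NodeModel
    sse: float  # sum of squared imputed residuals under this node's model
    parent: int | None = None
    rule: SplitRule | None = None
    left: int | None = None
    right: int | None = None

    @property
    def is_terminal(self):
        return self.rule is None


class PrismTree:
    """A fitted PRISM/HPRISM tree."""

    def __init__(self, nodes: dict, config: TreeConfig, ds: Dataset):
        self.nodes = nodes
        self.config = config
        self._ds = ds

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def root_sse(self) -> float:
        return self.root.sse

    @property
    def terminal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.is_terminal]

    def node(self, node_id) -> TreeNode:
        return self.nodes[node_id]

    def route(self, ds: Dataset) -> np.ndarray:
        """Terminal-node id for each record of ``ds``."""
        out = np.zeros(len(ds), dtype=int)
        idx = np.arange(len(ds))
        self._route(self.root, ds, idx, out)
        return out

    def _route(self, node, ds, idx, out):
        if node.is_terminal:
            out[idx] = node.id
            return
        rule = node.rule
        if rule.kind == "threshold":
            left = ds.encode(rule.variable)[idx] < rule.s
        else:
            col = ds.df[rule.variable].iloc[idx].astype(str)
            observed = set(self._ds.df[rule.variable]
                           .iloc[node.members].astype(str))
            known = col.isin(observed).to_numpy()
            left = col.isin({str(lv) for lv in rule.s}).to_numpy()
            if not known.all():
                ln, rn = self.nodes[node.left], self.nodes[node.right]
                bigger_left = len(ln.members) >= len(rn.members)
                warnings.warn(
                    f"level(s) of {rule.variable!r} unseen at node {node.id}; "
                    f"routing to the larger daughter", stacklevel=2)
                left[~known] = bigger_left
        self._route(self.nodes[node.left], ds, idx[left], out)
        self._route(self.nodes[node.right], ds, idx[~left], out)

    def predict(self, ds: Dataset) -> np.ndarray:
        """Predicted log survival time: route each record by its z values,
        then yhat = theta0_l + theta1_l*x (+ theta2_l*x*w)."""
        leaf = self.route(ds)
        x = ds.x
        w = ds.w(self.config.contextual_variable) if self.config.hprism else None
        yhat = np.empty(len(ds))
        for nid in np.unique(leaf):
            m = leaf == nid
            model = self.nodes[nid].model
            yhat[m] = model.predict(x[m], None if w is None else w[m])
        return yhat

    # -- serialization ------------------------------------------------------
    def to_dict(self, include_members=False):
        nodes = []
        for n in sorted(self.nodes.values(), key=lambda v: v.id):
            d = {
                "id": n.id, "parent": n.parent, "depth": n.depth,
                "left": n.left, "right": n.right,
                "rule": None if n.rule is None else n.rule.to_dict(),
                "model": {
                    "theta0": n.model.theta0, "theta1": n.model.theta1,
                    "theta2": n.model.theta2, "rss": n.model.rss,
                    "n": n.model.n, "n_events": n.model.n_events,
                    "mean_log_surv": n.model.mean_log_surv,
                },
                "sse": n.sse,
            }
            if include_members:
                d["members"] = n.members.tolist()
            nodes.append(d)
        return {"config": {k: v for k, v in vars(self.config).items()},
                "nodes": nodes}

    def to_json(self, path=None, include_members=False):
        obj = self.to_dict(include_members)
        if path is None:
            return json.dumps(obj, indent=1)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


# ---------------------------------------------------------------------------
# grow context: flat arrays + candidate enumeration + node fitting
# ---------------------------------------------------------------------------

class _Context:
    def __init__(self, ds: Dataset, cfg: TreeConfig):
        self.ds = ds
        self.cfg = cfg
        self.y = ds.y
        self.delta = ds.delta
        self.x = ds.x
        self.w = ds.w(cfg.contextual_variable) if cfg.hprism else None
        self.tract = np.unique(ds.tract, return_inverse=True)[1]
        self.zcols = {}
        for s in ds.z_specs:
            vals = ds.encode(s.name)
            self.zcols[s.name] = (s, vals)
        self.znames = ds.z_names

    def sorted_members(self, idx):
        idx = np.asarray(idx)
        o = np.lexsort((-self.delta[idx], self.y[idx]))
        return idx[o]

    def _sse(self, sidx):
        """Sum of squared imputed residuals of the refit on presorted member
        indices (fast path for split scoring)."""
        delta = self.delta[sidx]
        d = _stute_d_sorted(delta)
        *_, resid, _ = _wls_core(self.y[sidx], d, self.x[sidx],
                                 None if self.w is None else self.w[sidx])
        r_hat = _impute(resid, delta)
        return float(r_hat @ r_hat)

    def fit(self, sidx):
        """Fit the node model on presorted member indices; returns
        (NodeModel, imputed residuals rhat, sse)."""
        y = self.y[sidx]
        delta = self.delta[sidx]
        x = self.x[sidx]
        w = None if self.w is None else self.w[sidx]
        d = _stute_d_sorted(delta)
        weights = StuteWeights(order=np.arange(sidx.size), d=d)
        model = fit_node_model(y, delta, x, weights, w)
        r = y - model.predict(x, w)
        r_hat = _impute(r, delta)
        return model, r_hat, float(r_hat @ r_hat)

    # -- feasibility --------------------------------------------------------
    def feasible(self, sidx, left_mask):
        cfg = self.cfg
        nl = int(left_mask.sum())
        nr = left_mask.size - nl
        if nl < cfg.min_node or nr < cfg.min_node:
            return False
        ev = self.delta[sidx] > 0
        x1 = self.x[sidx] == 1
        for side in (left_mask, ~left_mask):
            for grp in (x1, ~x1):
                sel = side & ev & grp
                cnt = int(sel.sum())
                if cnt < max(1, cfg.min_events_per_group):
                    return False
                if cfg.hprism:
                    t = self.tract[sidx[sel]]
                    if t.size < 2 or not (t != t[0]).any():
                        return False
        return True

    # -- candidate enumeration ----------------------------------------------
    def candidates(self, sidx):
        """Yield (var_index, SplitRule, left_mask) in deterministic tie-break
        order: variable index first, then threshold / lexicographic subset."""
        for vi in range(len(self.znames)):
            yield from self.var_candidates(sidx, vi)

    def thresholds(self, sidx, vi):
        """Candidate cutpoints for a numeric/ordinal covariate: midpoints
        between consecutive distinct observed values within the node."""
        _, vals = self.zcols[self.znames[vi]]
        uniq = np.unique(vals[sidx])
        return (uniq[:-1] + uniq[1:]) / 2.0

    def var_candidates(self, sidx, vi):
        name = self.znames[vi]
        spec, vals = self.zcols[name]
        v = vals[sidx]
        if spec.scale in ("continuous", "ordinal"):
            for s in self.thresholds(sidx, vi):
                yield vi, SplitRule(name, "threshold", float(s)), v < s
            return
        levels = list(spec.levels)
        observed = [lv for lv in levels if (v == levels.index(lv)).any()]
        k = len(observed)
        if k < 2:
            return
        codes = {lv: levels.index(lv) for lv in observed}
        if k <= 6:
            # all 2^(k-1)-1 partitions: the last observed level stays right
            pool = observed[:-1]
            subsets = []
            for r in range(1, len(pool) + 1):
                subsets.extend(frozenset(c) for c in combinations(pool, r))
            subsets.sort(key=lambda fs: tuple(sorted(fs)))
        else:
            # order levels by Stute-weighted mean y among uncensored,
            # then scan prefixes as if ordinal (rpart-style)
            d = _stute_d_sorted(self.delta[sidx])
            yv = self.y[sidx]
            means = []
            for lv in observed:
                m = v == codes[lv]
                dm = d[m].sum()
                means.append((d[m] @ yv[m] / dm) if dm > 0 else np.inf)
            order = [observed[i] for i in np.argsort(means, kind="stable")]
            subsets = [frozenset(order[: j + 1]) for j in range(k - 1)]
        for fs in subsets:
            cset = np.array([codes[lv] for lv in fs])
            yield vi, SplitRule(name, "subset", fs), np.isin(v, cset)

    # -- criteria -----------------------------------------------------------
    def score_delta_rss(self, parent_sse, sidx, left_mask):
        try:
            if self.cfg.daughter_residuals == "refit":
                sl = self._sse(sidx[left_mask])
                sr = self._sse(sidx[~left_mask])
            else:
                # keep the parent's coefficients; re-impute the censored
                # residuals within each daughter
                model, _, _ = self.fit(sidx)
                y = self.y[sidx]
                x = self.x[sidx]
                w = None if self.w is None else self.w[sidx]
                r = y - model.predict(x, w)
                delta = self.delta[sidx]
                sl = sr = 0.0
                for mask, acc in ((left_mask, "l"), (~left_mask, "r")):
                    rh = _impute(r[mask], delta[mask])
                    val = float(rh @ rh)
                    if acc == "l":
                        sl = val
                    else:
                        sr = val
        except (FitError, np.linalg.LinAlgError):
            return None
        return parent_sse - (sl + sr)

    def score_logrank(self, sidx, left_mask):
        from lifelines.statistics import logrank_test

        t = np.exp(self.y[sidx])
        ev = self.delta[sidx]
        x1 = self.x[sidx] == 1
        stats = []
        for side in (left_mask, ~left_mask):
            a, b = side & x1, side & ~x1
            if ev[a].sum() < 1 or ev[b].sum() < 1:
                return None
            res = logrank_test(t[a], t[b], event_observed_A=ev[a],
                               event_observed_B=ev[b])
            stats.append(float(res.test_statistic))
        return abs(stats[0] - stats[1])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _rule_left_mask(ctx, sidx, rule):
    spec, vals = ctx.zcols[rule.variable]
    v = vals[sidx]
    if rule.kind == "threshold":
        return v < rule.s
    codes = [list(spec.levels).index(lv) for lv in rule.s]
    return np.isin(v, np.array(codes))


def evaluate_split(ds: Dataset, cfg: TreeConfig, members, rule: SplitRule):
    """dRSS for one candidate split of the member set, or None if the
    candidate is infeasible (exclusion criteria or daughter fit failure)."""
    ctx = _Context(ds, cfg)
    sidx = ctx.sorted_members(members)
    left = _rule_left_mask(ctx, sidx, rule)
    if not ctx.feasible(sidx, left):
        return None
    _, _, parent_sse = ctx.fit(sidx)
    return ctx.score_delta_rss(parent_sse, sidx, left)


def logrank_split_statistic(ds: Dataset, cfg: TreeConfig, members, rule: SplitRule):
    """|LR(left) - LR(right)| where LR is the two-sample log-rank statistic
    comparing focus groups within a daughter (computed on the time scale;
    the log-rank test is rank-invariant so log vs raw time is immaterial)."""
    ctx = _Context(ds, cfg)
    sidx = ctx.sorted_members(members)
    left = _rule_left_mask(ctx, sidx, rule)
    if not ctx.feasible(sidx, left):
        return None
    return ctx.score_logrank(sidx, left)


def best_split(ds: Dataset, cfg: TreeConfig, members) -> SplitRule | None:
    """Exhaustive search over all covariates and candidate cutpoints;
    returns the feasible candidate maximising the criterion (ties broken by
    variable index, then smaller threshold / lexicographically smaller level
    set), or None when no candidate is feasible."""
    ctx = _Context(ds, cfg)
    sidx = ctx.sorted_members(members)
    return _best_split(ctx, sidx)


def _best_split(ctx, sidx, parent_sse=None):
    if parent_sse is None:
        try:
            _, _, parent_sse = ctx.fit(sidx)
        except (FitError, np.linalg.LinAlgError):
            return None
    cfg = ctx.cfg
    use_kernel = (_fastscan.HAVE_NUMBA and cfg.criterion == "delta_rss"
                  and cfg.daughter_residuals == "refit")
    best = None
    best_score = -np.inf
    if use_kernel:
        yk = ctx.y[sidx]
        dk = ctx.delta[sidx].astype(np.int64)
        xk = ctx.x[sidx]
        wk = ctx.w[sidx] if ctx.w is not None else np.zeros(sidx.size)
        tk = ctx.tract[sidx].astype(np.int64)
    for vi, name in enumerate(ctx.znames):
        spec, vals = ctx.zcols[name]
        if use_kernel and spec.scale in ("continuous", "ordinal"):
            thr = ctx.thresholds(sidx, vi)
            if thr.size == 0:
                continue
            sides = _fastscan.scan_thresholds(
                yk, dk, xk, wk, tk, vals[sidx], thr, cfg.min_node,
                max(1, cfg.min_events_per_group), cfg.hprism,
                ctx.w is not None)
            scores = parent_sse - sides
            k = int(np.argmax(scores))  # first max -> smallest threshold
            if np.isfinite(scores[k]) and scores[k] > best_score:
                best_score = float(scores[k])
                best = SplitRule(name, "threshold", float(thr[k]),
                                 delta_rss=float(scores[k]))
            continue
        for _, rule, left in ctx.var_candidates(sidx, vi):
            if not ctx.feasible(sidx, left):
                continue
            if cfg.criterion == "logrank":
                score = ctx.score_logrank(sidx, left)
                drss = (ctx.score_delta_rss(parent_sse, sidx, left)
                        if score is not None else None)
            else:
                score = ctx.score_delta_rss(parent_sse, sidx, left)
                drss = score
            if score is None or drss is None:
                continue
            if score > best_score:
                best_score = score
                rule.delta_rss = drss
                best = rule
    return best


def grow(ds: Dataset, cfg: TreeConfig) -> PrismTree:
    """Grow a PRISM/HPRISM tree by depth-first recursive partitioning.

    A split is accepted only when its dRSS is at least ``cp`` times the root's
    imputed-residual RSS and all exclusion criteria hold (each daughter has at
    least ``min_node`` records and ``min_events_per_group`` uncensored records
    of each focus group; in HPRISM mode those events must additionally span at
    least two tracts per group). Deterministic given (Dataset, TreeConfig).
    """
    rep = validate_dataset(ds)
    if not rep.ok:
        raise FitError("; ".join(rep.fatal))
    ctx = _Context(ds, cfg)
    sidx = ctx.sorted_members(np.arange(len(ds)))
    model, _, sse = ctx.fit(sidx)
    nodes = {}
    root = TreeNode(id=0, depth=0, members=sidx, model=model, sse=sse)
    nodes[0] = root
    counter = [0]
    threshold = cfg.cp * sse

    def recurse(node):
        if cfg.max_depth is not None and node.depth >= cfg.max_depth:
            return
        if node.members.size < 2 * cfg.min_node:
            return
        rule = _best_split(ctx, node.members, node.sse)
        if rule is None or rule.delta_rss < threshold:
            return
        left_mask = _rule_left_mask(ctx, node.members, rule)
        lidx, ridx = node.members[left_mask], node.members[~left_mask]
        lmodel, _, lsse = ctx.fit(lidx)
        rmodel, _, rsse = ctx.fit(ridx)
        node.rule = rule

        def add_child(cidx, mdl, s):
            counter[0] += 1
            child = TreeNode(id=counter[0], depth=node.depth + 1, members=cidx,
                             model=mdl, sse=s, parent=node.id)
            nodes[child.id] = child
            return child.id

        node.left = add_child(lidx, lmodel, lsse)
        node.right = add_child(ridx, rmodel, rsse)
        recurse(nodes[node.left])
        recurse(nodes[node.right])

    recurse(root)
    log.info("grew %s tree: %d nodes, %d terminal", cfg.mode, len(nodes),
             sum(n.is_terminal for n in nodes.values()))
    return PrismTree(nodes, cfg, ds)


def predict(tree: PrismTree, ds: Dataset) -> np.ndarray:
    return tree.predict(ds)
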