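import json

import numpy as np
import pandas as pd
import pytest

import prismsurv as ps
from prismsurv.stute import _impute
from prismsurv.tree import (SplitRule, _Context, evaluate_split,
                            logrank_split_statistic)


def _plain_dataset(y, delta, x, z1, tract=None, w=None):
    n = len(y)
    df = pd.DataFrame({
        "time_days": np.exp(np.asarray(y, float)),
        "event": delta, "race": x, "z1": z1,
        "tract_id": tract if tract is not None else np.arange(n) % 3,
        "w": w if w is not None else np.zeros(n),
    })
    df["y"] = np.asarray(y, float)
    specs = [
        ps.VariableSpec("time_days", "time"),
        ps.VariableSpec("event", "event"),
        ps.VariableSpec("race", "focus"),
        ps.VariableSpec("z1", "individual", "continuous"),
        ps.VariableSpec("tract_id", "tract"),
        ps.VariableSpec("w", "contextual"),
    ]
    return ps.Dataset(df, specs)


# ---------------------------------------------------------------------------
# dRSS evaluation
# ---------------------------------------------------------------------------

def test_delta_rss_matches_plain_decomposition_without_censoring():
    """With no censoring the imputed residuals are the raw residuals, so dRSS
    must equal the ordinary least-squares RSS decomposition computed
    independently."""
    rng = np.random.default_rng(8)
    n = 12
    z1 = np.sort(rng.uniform(0, 1, n))
    x = np.tile([0.0, 1.0], n // 2)
    y = 1.0 + 0.5 * x + (z1 > 0.5) * 1.5 + rng.normal(0, 0.3, n)
    ds = _plain_dataset(y, np.ones(n, int), x, z1)
    cfg = ps.TreeConfig(mode="PRISM", min_node=2)

    def ols_rss(idx):
        X = np.column_stack([np.ones(idx.size), x[idx]])
        resid = y[idx] - X @ np.linalg.lstsq(X, y[idx], rcond=None)[0]
        return float(resid @ resid)

    all_idx = np.arange(n)
    parent = ols_rss(all_idx)
    for s in [np.quantile(z1, 0.4), np.quantile(z1, 0.6)]:
        rule = SplitRule("z1", "threshold", float(s))
        got = evaluate_split(ds, cfg, all_idx, rule)
        want = parent - (ols_rss(all_idx[z1 < s]) + ols_rss(all_idx[z1 >= s]))
        assert got == pytest.approx(want, abs=1e-9)


def test_delta_rss_zero_for_identical_decomposition():
    # y exactly linear in x: every fit is exact, so splitting gains nothing
    n = 16
    x = np.tile([0.0, 1.0], n // 2)
    y = 2.0 + 3.0 * x
    z1 = np.linspace(0, 1, n)
    ds = _plain_dataset(y, np.ones(n, int), x, z1)
    cfg = ps.TreeConfig(mode="PRISM", min_node=2)
    got = evaluate_split(ds, cfg, np.arange(n), SplitRule("z1", "threshold", 0.5))
    assert got == pytest.approx(0.0, abs=1e-18)


def test_infeasible_candidate_returns_none():
    n = 12
    x = np.array([1.0] * 6 + [0.0] * 6)  # race separates perfectly with z1
    z1 = np.array([0.1] * 6 + [0.9] * 6)
    y = np.arange(n, dtype=float)
    ds = _plain_dataset(y, np.ones(n, int), x, z1)
    cfg = ps.TreeConfig(mode="PRISM", min_node=2)
    assert evaluate_split(ds, cfg, np.arange(n),
                          SplitRule("z1", "threshold", 0.5)) is None


def test_parent_residual_mode_gains_nothing_without_censoring():
    """Keeping the parent's coefficients (no daughter refit), an uncensored
    sample has nothing to re-impute, so every split's dRSS is exactly 0."""
    rng = np.random.default_rng(14)
    n = 24
    z1 = rng.uniform(0, 1, n)
    x = np.tile([0.0, 1.0], n // 2)
    y = 1.0 + 0.5 * x + (z1 > 0.5) * 1.5 + rng.normal(0, 0.3, n)
    ds = _plain_dataset(y, np.ones(n, int), x, z1)
    cfg = ps.TreeConfig(mode="PRISM", min_node=4, daughter_residuals="parent")
    for q in (0.3, 0.5, 0.7):
        got = evaluate_split(ds, cfg, np.arange(n),
                             SplitRule("z1", "threshold", float(np.quantile(z1, q))))
        assert got == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# brute-force oracle for the full search
# ---------------------------------------------------------------------------

def _brute_force_best(ds, cfg, members):
    """Independent exhaustive argmax: enumerate midpoint thresholds directly
    from the data and score each via evaluate_split."""
    best, best_val = None, -np.inf
    for name in ds.z_names:
        v = ds.encode(name)[members]
        uniq = np.unique(v)
        for s in (uniq[:-1] + uniq[1:]) / 2.0:
            rule = SplitRule(name, "threshold", float(s))
            val = evaluate_split(ds, cfg, members, rule)
            if val is not None and val > best_val:
                best, best_val = rule, val
    return best, best_val


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("mode", ["PRISM", "HPRISM"])
def test_best_split_equals_brute_force(seed, mode):
    truth = ps.two_leaf_truth(n=50, M=6, censor_rate_target=0.3)
    ds = ps.simulate(truth, seed=seed)
    cfg = ps.TreeConfig(mode=mode,
                        contextual_variable="w" if mode == "HPRISM" else None,
                        min_node=5)
    members = np.arange(len(ds))
    want, want_val = _brute_force_best(ds, cfg, members)
    got = ps.best_split(ds, cfg, members)
    if want is None:
        assert got is None
        return
    assert got.variable == want.variable
    assert got.s == pytest.approx(want.s, abs=1e-12)
    assert got.delta_rss == pytest.approx(want_val, rel=1e-9)


def test_best_split_tie_break_prefers_lower_variable_index():
    # z2 duplicates z1, so the best thresholds tie exactly; the winner must
    # be the lower-indexed variable with the smaller cutpoint
    rng = np.random.default_rng(1)
    n = 40
    z1 = rng.uniform(0, 1, n)
    x = np.tile([0.0, 1.0], n // 2)
    y = (z1 > 0.5) * 2.0 + 0.3 * x + rng.normal(0, 0.1, n)
    df = pd.DataFrame({"time_days": np.exp(y), "event": 1, "race": x,
                       "z1": z1, "z2": z1, "tract_id": np.arange(n) % 4,
                       "w": 0.0})
    df["y"] = y
    specs = [ps.VariableSpec("time_days", "time"), ps.VariableSpec("event", "event"),
             ps.VariableSpec("race", "focus"),
             ps.VariableSpec("z1", "individual", "continuous"),
             ps.VariableSpec("z2", "individual", "continuous"),
             ps.VariableSpec("tract_id", "tract"), ps.VariableSpec("w", "contextual")]
    ds = ps.Dataset(df, specs)
    cfg = ps.TreeConfig(mode="PRISM", min_node=5)
    got = ps.best_split(ds, cfg, np.arange(n))
    assert got.variable == "z1"


def test_exclusion_rule_returns_none_when_no_candidate_feasible():
    n = 20
    x = np.array([1.0] * 10 + [0.0] * 10)
    z1 = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1.0, 10)])
    y = np.arange(n, dtype=float)
    ds = _plain_dataset(y, np.ones(n, int), x, z1)
    cfg = ps.TreeConfig(mode="PRISM", min_node=2)
    assert ps.best_split(ds, cfg, np.arange(n)) is None


# ---------------------------------------------------------------------------
# log-rank splitting criterion
# ---------------------------------------------------------------------------

def test_logrank_statistic_matches_textbook_arithmetic():
    """One daughter has a hand-computable 2-sample log-rank table; the other
    has identical survival by race (statistic 0), so the absolute difference
    equals the first daughter's chi-squared statistic."""
    y = np.log([1, 2, 3, 4, 5.0, 5.0, 6.0, 6.0])
    delta = np.ones(8, int)
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    z1 = np.array([0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9])
    ds = _plain_dataset(y, delta, x, z1)
    cfg = ps.TreeConfig(mode="PRISM", criterion="logrank", min_node=2)
    rule = SplitRule("z1", "threshold", 0.5)

    # left daughter: times (1,3) group1 vs (2,4) group0, all events
    t = np.array([1, 2, 3, 4.0])
    grp = np.array([1, 0, 1, 0])
    O = E = V = 0.0
    at_risk = np.ones(4, bool)
    for tt in np.unique(t):
        d_tot = (t == tt).sum()
        n_tot = at_risk.sum()
        n1 = at_risk[grp == 1].sum()
        d1 = ((t == tt) & (grp == 1)).sum()
        O += d1
        E += d_tot * n1 / n_tot
        if n_tot > 1:
            V += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        at_risk &= t != tt
    expected = (O - E) ** 2 / V
    got = logrank_split_statistic(ds, cfg, np.arange(8), rule)
    assert got == pytest.approx(expected, rel=1e-9)


def test_logrank_zero_for_identical_daughter_experiences():
    y = np.log([1, 2, 3, 4, 1, 2, 3, 4.0])
    delta = np.ones(8, int)
    x = np.array([1, 0, 1, 0, 1, 0, 1, 0.0])
    z1 = np.array([0.1] * 4 + [0.9] * 4)
    ds = _plain_dataset(y, delta, x, z1)
    cfg = ps.TreeConfig(mode="PRISM", criterion="logrank", min_node=2)
    got = logrank_split_statistic(ds, cfg, np.arange(8),
                                  SplitRule("z1", "threshold", 0.5))
    assert got == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# growth, stopping, prediction
# ---------------------------------------------------------------------------

def test_huge_cp_gives_root_only_tree(two_leaf_ds):
    cfg = ps.TreeConfig(mode="HPRISM", contextual_variable="w", cp=1e9)
    tree = ps.grow(two_leaf_ds, cfg)
    assert len(tree.nodes) == 1
    pred = tree.predict(two_leaf_ds)
    m = tree.root.model
    want = m.predict(two_leaf_ds.x, two_leaf_ds.w("w"))
    np.testing.assert_allclose(pred, want)


def test_terminal_nodes_partition_and_satisfy_exclusion(hprism_tree, two_leaf_ds,
                                                        hprism_cfg):
    terms = hprism_tree.terminal_nodes
    all_members = np.sort(np.concatenate([t.members for t in terms]))
    np.testing.assert_array_equal(all_members, np.arange(len(two_leaf_ds)))
    internal = [n for n in hprism_tree.nodes.values() if not n.is_terminal]
    assert len(terms) == len(internal) + 1
    delta, x = two_leaf_ds.delta, two_leaf_ds.x
    tract = two_leaf_ds.tract
    for t in terms:
        assert t.members.size >= hprism_cfg.min_node
        for g in (0, 1):
            ev = t.members[(delta[t.members] == 1) & (x[t.members] == g)]
            assert ev.size >= 1
            assert len(set(tract[ev])) >= 2
    # depth-first id assignment: children created after their parent
    for n in hprism_tree.nodes.values():
        if n.parent is not None:
            assert n.id > n.parent


def test_hprism_node_rss_never_exceeds_prism(two_leaf_ds):
    # nested least squares on the identical member set
    y, delta, x = two_leaf_ds.y, two_leaf_ds.delta, two_leaf_ds.x
    w = two_leaf_ds.w("w")
    wts = ps.stute_weights(y, delta)
    m_h = ps.fit_node_model(y, delta, x, wts, w=w)
    m_p = ps.fit_node_model(y, delta, x, wts)
    assert m_h.rss <= m_p.rss + 1e-10


def test_grow_is_deterministic(two_leaf_ds, hprism_cfg):
    t1 = ps.grow(two_leaf_ds, hprism_cfg)
    t2 = ps.grow(two_leaf_ds, hprism_cfg)
    assert t1.to_json() == t2.to_json()


def test_predict_routes_training_records_to_their_nodes(hprism_tree, two_leaf_ds):
    leaf = hprism_tree.route(two_leaf_ds)
    for t in hprism_tree.terminal_nodes:
        np.testing.assert_array_equal(np.sort(np.flatnonzero(leaf == t.id)),
                                      np.sort(t.members))


def test_predict_arithmetic_in_a_node():
    m = ps.NodeModel(theta0=1.0, theta1=0.2, theta2=0.01, rss=0, n=1,
                     n_events=1, mean_log_surv=0.0)
    assert m.predict(np.array([1.0]), np.array([50.0]))[0] == pytest.approx(1.7)


def test_unseen_nominal_level_routes_to_larger_daughter():
    rng = np.random.default_rng(4)
    n = 80
    lev = np.array(["a", "b", "c"])[rng.integers(0, 3, n)]
    x = np.tile([0.0, 1.0], n // 2)
    y = (lev == "a") * 2.0 + 0.5 * x + rng.normal(0, 0.1, n)
    df = pd.DataFrame({"time_days": np.exp(y), "event": 1, "race": x,
                       "hist": lev, "tract_id": np.arange(n) % 5, "w": 0.0})
    df["y"] = y
    specs = [ps.VariableSpec("time_days", "time"), ps.VariableSpec("event", "event"),
             ps.VariableSpec("race", "focus"),
             ps.VariableSpec("hist", "individual", "nominal", levels=("a", "b", "c", "d")),
             ps.VariableSpec("tract_id", "tract"), ps.VariableSpec("w", "contextual")]
    ds = ps.Dataset(df, specs)
    tree = ps.grow(ds, ps.TreeConfig(mode="PRISM", min_node=5, cp=0.01))
    assert tree.root.rule is not None and tree.root.rule.kind == "subset"
    df2 = df.iloc[:4].copy()
    df2["hist"] = "d"  # level never observed in training
    ds2 = ps.Dataset(df2, specs)
    with pytest.warns(UserWarning, match="unseen"):
        leaf = tree.route(ds2)
    bigger = max((tree.nodes[tree.root.left], tree.nodes[tree.root.right]),
                 key=lambda nd: nd.members.size)
    # records fall into the larger daughter's subtree
    sub = {bigger.id}
    frontier = [bigger]
    while frontier:
        nd = frontier.pop()
        for c in (nd.left, nd.right):
            if c is not None:
                sub.add(c)
                frontier.append(tree.nodes[c])
    assert set(leaf) <= sub


def test_tree_json_round_trip(hprism_tree):
    obj = json.loads(hprism_tree.to_json())
    assert obj["config"]["mode"] == "HPRISM"
    ids = {nd["id"] for nd in obj["nodes"]}
    assert ids == set(hprism_tree.nodes)
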