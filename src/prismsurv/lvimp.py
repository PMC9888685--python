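"""Local variable importance (Lvimp) by permutation with full tree rebuild,
and Andrews-curve embeddings of per-node importance vectors.

The Lvimp of covariate k at terminal node l answers: if k were pure noise,
how much worse would this subgroup's predictions be? Each replicate permutes
k's column across the whole dataset, rebuilds the entire tree under the same
configuration, routes the original node's members down the rebuilt tree, and
compares their Stute-weighted squared prediction error with the original.
Values at or below zero mark variables that are not important for that node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset
from .stute import FitError, stute_weights
from .tree import PrismTree, grow

__all__ = ["LvimpTable", "AndrewsCurve", "lvimp_value", "lvimp_table",
           "andrews_curve", "node_andrews_curves"]


@dataclass
class LvimpTable:
    """Terminal-node x variable matrix of importance values and within-node
    ranks (1 = most important; ties share the minimum rank)."""

    values: pd.DataFrame  # index: terminal node id, columns: variable names
    ranks: pd.DataFrame
    seed: int | None

    def formatted(self) -> pd.DataFrame:
        """Value with rank in parentheses, one row per variable."""
        out = self.values.T.copy().astype(object)
        for node in self.values.index:
            for var in self.values.columns:
                out.loc[var, node] = (
                    f"{self.values.loc[node, var]:.4f}"
                    f"({int(self.ranks.loc[node, var])})")
        return out


def _node_weighted_error(ds, members, predicted):
    """Stute-weighted mean squared prediction error over a node's members,
    weighted by the node's own Kaplan-Meier weights."""
    y = ds.y[members]
    delta = ds.delta[members]
    wts = stute_weights(y, delta)
    dsum = wts.d.sum()
    if dsum <= 0:
        return np.nan
    err = y - predicted
    return float(wts.d @ (err * err) / dsum)


def _permuted_dataset(ds, variable, rng):
    df = ds.df.copy()
    df[variable] = df[variable].to_numpy()[rng.permutation(len(df))]
    return Dataset(df, ds.specs)


def _replicate_errors(tree, ds, variable, rng, terminal_ids):
    """One noising replicate: permute, rebuild, and return the weighted error
    of each requested original terminal node under the rebuilt tree."""
    noised = _permuted_dataset(ds, variable, rng)
    try:
        rebuilt = grow(noised, tree.config)
    except FitError:
        return {nid: np.nan for nid in terminal_ids}
    pred = rebuilt.predict(noised)
    return {nid: _node_weighted_error(ds, tree.node(nid).members,
                                      pred[tree.node(nid).members])
            for nid in terminal_ids}


def _var_rng(seed, var_index):
    # independent, order-free stream per variable
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(var_index,)))


def _original_errors(tree, ds, terminal_ids):
    pred = tree.predict(ds)
    return {nid: _node_weighted_error(ds, tree.node(nid).members,
                                      pred[tree.node(nid).members])
            for nid in terminal_ids}


def lvimp_value(tree: PrismTree, ds: Dataset, node_id: int, variable: str,
                n_perm: int = 10, seed: int | None = None) -> float:
    """Lvimp of one covariate at one terminal node: mean over ``n_perm``
    permutation replicates of (noised error - original error)."""
    node = tree.node(node_id)
    if not node.is_terminal:
        raise ValueError(f"node {node_id} is not terminal")
    if variable not in ds.z_names:
        raise ValueError(f"{variable!r} is not an individual-level covariate")
    orig = _original_errors(tree, ds, [node_id])[node_id]
    rng = _var_rng(seed, ds.z_names.index(variable))
    noised = [_replicate_errors(tree, ds, variable, rng, [node_id])[node_id]
              for _ in range(n_perm)]
    return float(np.nanmean(noised) - orig)


def lvimp_table(tree: PrismTree, ds: Dataset, n_perm: int = 10,
                seed: int | None = None, rank_abs: bool = False) -> LvimpTable:
    """Full terminal-node x covariate importance table.

    One rebuild per (variable, replicate) serves every terminal node, so the
    cost is K * n_perm tree fits. Ranks are within-node, descending by signed
    value by default (``rank_abs`` ranks by magnitude instead); ties share the
    minimum rank.
    """
    terminal_ids = sorted(n.id for n in tree.terminal_nodes)
    orig = _original_errors(tree, ds, terminal_ids)
    values = pd.DataFrame(index=terminal_ids, columns=ds.z_names, dtype=float)
    for vi, var in enumerate(ds.z_names):
        rng = _var_rng(seed, vi)
        errs = {nid: [] for nid in terminal_ids}
        for _ in range(n_perm):
            rep = _replicate_errors(tree, ds, var, rng, terminal_ids)
            for nid in terminal_ids:
                errs[nid].append(rep[nid])
        for nid in terminal_ids:
            values.loc[nid, var] = np.nanmean(errs[nid]) - orig[nid]
    key = values.abs() if rank_abs else values
    ranks = key.rank(axis=1, method="min", ascending=False).astype(int)
    return LvimpTable(values=values, ranks=ranks, seed=seed)


@dataclass
class AndrewsCurve:
    c: np.ndarray
    grid: np.ndarray
    f: np.ndarray


def andrews_curve(c, n_grid: int = 512) -> AndrewsCurve:
    """Finite Fourier-series embedding of a vector on t in [-pi, pi]:

        f_c(t) = c1/sqrt(2) + c2 sin(t) + c3 cos(t) + c4 sin(2t) + c5 cos(2t) + ...

    (the standard Andrews construction with increasing frequencies). The map
    is linear in c and 2*pi-periodic."""
    c = np.asarray(c, float)
    if c.size == 0:
        raise ValueError("andrews_curve: empty coefficient vector")
    t = np.linspace(-np.pi, np.pi, n_grid)
    f = np.full_like(t, c[0] / np.sqrt(2.0))
    for j in range(1, c.size):
        freq = (j + 1) // 2
        f = f + c[j] * (np.sin(freq * t) if j % 2 == 1 else np.cos(freq * t))
    return AndrewsCurve(c=c, grid=t, f=f)


def node_andrews_curves(table: LvimpTable, n_grid: int = 512) -> dict:
    """One Andrews curve per terminal node, built from that node's
    rank-ordered Lvimp values (most important first)."""
    curves = {}
    for nid in table.values.index:
        order = table.ranks.loc[nid].sort_values(kind="stable").index
        curves[nid] = andrews_curve(table.values.loc[nid, order].to_numpy(), n_grid)
    return curves
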