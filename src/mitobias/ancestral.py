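"""Ancestral state reconstruction and per-site Total Substitution Scores.

Two reconstruction methods are provided for a site column on a rooted tree:

* :func:`fitch_parsimony` — minimum-change ancestral states via a unit-cost
  Sankoff dynamic program (exact on multifurcating trees), deterministic
  alphabetical tie-breaking.  This is the default for TSS because it is
  fully reproducible and oracle-verifiable; parsimony gives a lower bound
  on the true number of substitutions, so TSS values are conservative.
* :func:`marginal_ml_states` — per-node marginal posteriors under a
  single-rate HKY model by Felsenstein pruning (up-pass) and an outside
  recursion (down-pass), with per-node rescaling against underflow.

The Total Substitution Score (TSS) of a site is the number of branches on
which the assigned parent and child states differ; nothing is counted above
the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import code
from .stats import bonferroni, ks_two_sample, significance_band
from .trees import RootedTree
from .variants import FREQUENCY_CLASSES, MergedVariantTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_INF = np.iinfo(np.int32).max // 2


@dataclass
class AncestralAssignment:
    """One base per node for one site column, plus the method that produced it."""

    states: list[str]  # indexed by node id
    method: str
    min_changes: int | None = None
    posteriors: np.ndarray | None = None  # (n_nodes, 4) for marginal_ml


def _leaf_state_indices(
    column: Mapping[str, str | None], tree: RootedTree
) -> dict[int, int | None]:
    out: dict[int, int | None] = {}
    for v in tree.leaves:
        name = tree.name[v]
        if name not in column:
            raise ValueError(f"leaf {name!r} missing from site column")
        state = column[name]
        if state is None:
            out[v] = None
        else:
            s = state.upper()
            if s in ("-", "N") or s not in _BASE_INDEX:
                out[v] = None  # gap/ambiguity: treat as missing (full state set)
            else:
                out[v] = _BASE_INDEX[s]
    return out


def fitch_parsimony(
    column: Mapping[str, str | None], tree: RootedTree
) -> tuple[int, AncestralAssignment]:
    """Minimum substitutions for one site and one optimal assignment.

    ``column`` maps leaf name to a base, or ``None``/gap/``N`` for missing
    data (which contributes the full state set).  Ties at ambiguous nodes
    are broken in fixed alphabetical order A<C<G<T, making the returned
    assignment (and hence TSS) bit-reproducible.
    """
    leaf_states = _leaf_state_indices(column, tree)
    cost = np.zeros((tree.n_nodes, 4), dtype=np.int64)
    for v in tree.postorder:
        if tree.is_leaf(v):
            s = leaf_states[v]
            if s is not None:
                cost[v] = _INF
                cost[v][s] = 0
        else:
            for c in tree.children[v]:
                # min over child state of (child cost + 1{change}), per parent state
                child_min = cost[c].min()
                cost[v] += np.minimum(cost[c], child_min + 1)
    min_changes = int(cost[tree.root].min())

    states = [""] * tree.n_nodes
    chosen = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.preorder:
        if v == tree.root:
            chosen[v] = int(np.argmin(cost[v]))  # argmin takes first = alphabetical
        else:
            p = chosen[tree.parent[v]]
            penal = cost[v] + (np.arange(4) != p)
            chosen[v] = int(np.argmin(penal))
        states[v] = BASES[chosen[v]]
    return min_changes, AncestralAssignment(
        states=states, method="fitch", min_changes=min_changes
    )


def hky_rate_matrix(kappa: float, base_frequencies) -> np.ndarray:
    """HKY85 rate matrix (A,C,G,T order), scaled to one expected substitution
    per unit branch length at stationarity."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    pi = np.asarray(base_frequencies, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("base_frequencies must be 4 non-negative values summing to 1")
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if code.is_transition(BASES[i], BASES[j]):
                rate *= kappa
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def marginal_ml_states(
    column: Mapping[str, str | None],
    tree: RootedTree,
    kappa: float = 2.0,
    base_frequencies=(0.25, 0.25, 0.25, 0.25),
) -> AncestralAssignment:
    """Marginal ML ancestral states under single-rate HKY.

    Posteriors are exact marginals given the fixed branch lengths and model;
    the assignment is the per-node argmax with alphabetical tie-breaking.
    Observed leaves keep their observed state; missing leaves get a uniform
    partial likelihood and are assigned by posterior.
    """
    q = hky_rate_matrix(kappa, base_frequencies)
    pi = np.asarray(base_frequencies, dtype=float)
    pmats = {}
    for v in range(tree.n_nodes):
        t = tree.edge_length[v]
        if v != tree.root and t not in pmats:
            pmats[t] = expm(q * t)

    leaf_states = _leaf_state_indices(column, tree)
    partial = np.ones((tree.n_nodes, 4))
    for v in tree.postorder:
        if tree.is_leaf(v):
            s = leaf_states[v]
            if s is not None:
                partial[v] = 0.0
                partial[v][s] = 1.0
        else:
            for c in tree.children[v]:
                partial[v] *= pmats[tree.edge_length[c]] @ partial[c]
        norm = partial[v].sum()
        if norm == 0.0:
            raise FloatingPointError("zero partial likelihood; invalid model?")
        partial[v] /= norm  # rescale; posteriors are normalization-free

    outside = np.ones((tree.n_nodes, 4))
    outside[tree.root] = pi
    for v in tree.preorder:
        if tree.is_leaf(v):
            continue
        # message from v to each child: outside[v] times siblings' contributions
        msgs = [pmats[tree.edge_length[c]] @ partial[c] for c in tree.children[v]]
        for k, c in enumerate(tree.children[v]):
            above = outside[v].copy()
            for j, m in enumerate(msgs):
                if j != k:
                    above *= m
            outside[c] = pmats[tree.edge_length[c]].T @ above
            outside[c] /= outside[c].sum()

    post = partial * outside
    post /= post.sum(axis=1, keepdims=True)
    states = []
    for v in range(tree.n_nodes):
        if tree.is_leaf(v) and leaf_states[v] is not None:
            states.append(BASES[leaf_states[v]])
        else:
            states.append(BASES[int(np.argmax(post[v]))])
    return AncestralAssignment(states=states, method="marginal_ml", posteriors=post)


def site_log_likelihood(
    column: Mapping[str, str | None],
    tree: RootedTree,
    kappa: float = 2.0,
    base_frequencies=(0.25, 0.25, 0.25, 0.25),
) -> float:
    """Total log-likelihood of one site under the HKY model (pruning)."""
    q = hky_rate_matrix(kappa, base_frequencies)
    pi = np.asarray(base_frequencies, dtype=float)
    leaf_states = _leaf_state_indices(column, tree)
    partial = np.ones((tree.n_nodes, 4))
    log_scale = 0.0
    for v in tree.postorder:
        if tree.is_leaf(v):
            s = leaf_states[v]
            if s is not None:
                partial[v] = 0.0
                partial[v][s] = 1.0
        else:
            for c in tree.children[v]:
                partial[v] *= expm(q * tree.edge_length[c]) @ partial[c]
            norm = partial[v].sum()
            log_scale += np.log(norm)
            partial[v] /= norm
    return float(np.log(pi @ partial[tree.root]) + log_scale)


def total_substitution_score(
    assignment: AncestralAssignment, tree: RootedTree
) -> int:
    """Number of branches whose parent and child states differ."""
    s = assignment.states
    return sum(
        1
        for v in range(tree.n_nodes)
        if v != tree.root and s[v] != s[tree.parent[v]]
    )


def tss_table(
    alignment_columns: pd.DataFrame,
    tree: RootedTree,
    method: str = "fitch",
    kappa: float = 2.0,
    base_frequencies=(0.25, 0.25, 0.25, 0.25),
) -> pd.DataFrame:
    """Compute a TSS per row of a site table.

    ``alignment_columns`` must carry one row per site with a ``column``
    field mapping leaf name -> base; all other columns are passed through.
    """
    scores = []
    for col in alignment_columns["column"]:
        if method == "fitch":
            score, assign = fitch_parsimony(col, tree)
        elif method == "ml":
            assign = marginal_ml_states(col, tree, kappa, base_frequencies)
            score = total_substitution_score(assign, tree)
        else:
            raise ValueError(f"unknown method {method!r}")
        scores.append(score)
    out = alignment_columns.drop(columns=["column"]).copy()
    out["tss"] = scores
    out["method"] = method
    return out


def _pairwise_ks(groups: dict, min_n: int = 2) -> list[dict]:
    rows = []
    for (a, b) in combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        if len(xa) < min_n or len(xb) < min_n:
            rows.append(
                {"group_a": a, "group_b": b, "n1": len(xa), "n2": len(xb),
                 "d": np.nan, "p_raw": np.nan, "skipped": True}
            )
            continue
        r = ks_two_sample(xa, xb)
        rows.append(
            {"group_a": a, "group_b": b, "n1": r.n1, "n2": r.n2,
             "d": r.d_statistic, "p_raw": r.p_value, "skipped": False}
        )
    return rows


def _finish_matrix(rows: list[dict], extra: dict) -> list[dict]:
    for r in rows:
        r.update(extra)
    return rows


def tss_frequency_association(
    tss: pd.DataFrame, merged: MergedVariantTable
) -> pd.DataFrame:
    """KS comparisons of TSS between population-frequency classes.

    Each synonymous P3 variant at a scored site contributes its site's TSS
    to its frequency class; classes are compared pairwise within each
    degeneracy class.  The sparse ``common`` class is excluded from testing.
    Bonferroni correction multiplies each raw p by the number of performed
    tests across the whole matrix.
    """
    t = merged.table
    syn3 = t[(t["codon_position"] == 3) & t["is_synonymous"]]
    joined = syn3.merge(tss, on=["gene", "codon_index"], how="inner")
    rows: list[dict] = []
    for cls, grp in joined.groupby("degeneracy_class", observed=True):
        groups = {
            fc: sub["tss"].to_numpy()
            for fc, sub in grp.groupby("frequency_class", observed=True)
            if fc != "common" and len(sub)
        }
        rows += _finish_matrix(_pairwise_ks(groups), {"degeneracy_class": cls})
    return _correct(rows)


def tss_amino_acid_comparison(tss: pd.DataFrame) -> pd.DataFrame:
    """KS comparisons of site TSS between amino acids within a degeneracy class."""
    rows: list[dict] = []
    for cls, grp in tss.groupby("degeneracy_class", observed=True):
        groups = {
            aa: sub["tss"].to_numpy()
            for aa, sub in grp.groupby("amino_acid", observed=True)
        }
        rows += _finish_matrix(_pairwise_ks(groups), {"degeneracy_class": cls})
    return _correct(rows)


def _correct(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["degeneracy_class", "group_a", "group_b", "n1", "n2", "d",
                 "p_raw", "skipped"],
    )
    if df.empty:
        df["p_corrected"] = pd.Series(dtype=float)
        df["band"] = pd.Series(dtype=str)
        return df.astype({"skipped": bool, "d": float, "p_raw": float})
    tested = ~df["skipped"]
    corrected = np.full(len(df), np.nan)
    if tested.any():
        corrected[tested.to_numpy()] = bonferroni(df.loc[tested, "p_raw"])
    df["p_corrected"] = corrected
    df["band"] = [
        significance_band(p) if np.isfinite(p) else "n/a" for p in corrected
    ]
    return df


def frequency_class_order() -> list[str]:
    return list(FREQUENCY_CLASSES)
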