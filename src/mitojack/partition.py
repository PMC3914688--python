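"""Greedy BIC search for the best partitioning scheme over data blocks.

Each candidate group of blocks is fitted on a fixed guide tree under GTR+G
(nucleotides) or BIN+G (RY data) with one free rate multiplier on the shared
branch lengths ("proportional" branch-length linking).  Schemes are scored by
BIC with n = total sites; the greedy pass starts from all blocks separate
and keeps applying the pairwise merge with the largest BIC reduction.

Free-parameter accounting per group: GTR+G counts 5 relative
exchangeabilities + 3 free frequencies + gamma shape + rate multiplier = 10;
BIN+G counts 1 frequency + shape + multiplier = 3.  Shared branch lengths
are counted once per scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import DataBlock, SiteMatrix
from .ml import (PartitionedLikelihood, SubstitutionModel, encode_matrix,
                 starting_tree)
from .trees import Tree

_K_PER_GROUP = {"GTR4": 10, "BIN2": 3}


@dataclass(frozen=True)
class ModelFit:
    lnl: float
    k: int          # free parameters of the group model
    n: int          # sites in the group
    model: SubstitutionModel
    rate_multiplier: float
    boundary_alpha: bool = False   # degenerate (near-constant) group flag

    @property
    def bic(self) -> float:
        return -2.0 * self.lnl + self.k * np.log(max(self.n, 1))


@dataclass
class PartitionScheme:
    groups: list[frozenset]           # disjoint sets of block names
    fits: dict[frozenset, ModelFit]
    n_branch_parameters: int

    @property
    def lnl(self) -> float:
        return sum(f.lnl for f in self.fits.values())

    @property
    def k(self) -> int:
        return (sum(f.k for f in self.fits.values())
                + self.n_branch_parameters)

    @property
    def n(self) -> int:
        return sum(f.n for f in self.fits.values())

    @property
    def bic(self) -> float:
        return -2.0 * self.lnl + self.k * np.log(max(self.n, 1))

    def as_blocks(self, blocks: list[DataBlock]) -> list[DataBlock]:
        """Merge the column sets of each group into one DataBlock per group."""
        by_name = {b.name: b for b in blocks}
        out = []
        for group in self.groups:
            cols: list[int] = []
            for name in sorted(group):
                cols.extend(by_name[name].columns)
            out.append(DataBlock("+".join(sorted(group)), tuple(sorted(cols))))
        return out

    def report(self) -> pd.DataFrame:
        rows = []
        for group in self.groups:
            f = self.fits[group]
            rows.append({
                "group": "+".join(sorted(group)),
                "lnl": f.lnl,
                "k": f.k,
                "n": f.n,
                "bic": f.bic,
                "rate_multiplier": f.rate_multiplier,
                "alpha": f.model.alpha,
            })
        return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def _merge_columns(blocks: list[DataBlock], names: frozenset) -> DataBlock:
    cols: list[int] = []
    by_name = {b.name: b for b in blocks}
    for name in sorted(names):
        cols.extend(by_name[name].columns)
    return DataBlock("+".join(sorted(names)), tuple(sorted(cols)))


def fit_group(matrix: SiteMatrix, blocks: list[DataBlock],
              group: frozenset, tree: Tree,
              model_kind: str | None = None) -> ModelFit:
    """Fit one block group on the fixed guide tree.

    Optimizes substitution parameters, gamma shape and the group rate
    multiplier; branch lengths stay at their guide-tree values.  A group of
    (near-)constant columns hits the upper alpha boundary and is flagged.
    """
    block = _merge_columns(blocks, group)
    groups = encode_matrix(matrix, [block])
    g = groups[0]
    if model_kind is None:
        model_kind = "GTR4" if g.n_states == 4 else "BIN2"
    if model_kind == "GTR4":
        model = SubstitutionModel.gtr(frequencies=g.empirical_frequencies())
    else:
        model = SubstitutionModel.binary(frequencies=g.empirical_frequencies())
    engine = PartitionedLikelihood(groups, [model], tree.copy().unroot(),
                                   matrix.taxa)
    engine.optimize_parameters(optimize_multipliers=True,
                               fix_first_multiplier=False)
    lnl = engine.lnl()
    constant = all(
        len(set(col[col < g.n_states])) <= 1
        for col in (g.patterns[:, j] for j in range(g.patterns.shape[1]))
    )
    boundary = constant or model.alpha >= 99.0 or model.alpha <= 0.021
    return ModelFit(lnl, _K_PER_GROUP[model_kind], g.n_sites, model,
                    float(engine.rate_multipliers[0]), boundary)


def guide_tree(matrix: SiteMatrix, blocks: list[DataBlock] | None = None,
               user_tree: Tree | None = None) -> Tree:
    """Guide tree for scheme search: user tree, else NJ with branch lengths
    optimized once under a single joint model."""
    groups = encode_matrix(matrix, blocks)
    if user_tree is not None:
        tree = user_tree.copy().unroot()
    else:
        tree = starting_tree(matrix, groups)
    try:
        merged = encode_matrix(matrix, None) if len(groups) > 1 else groups
    except ValueError:  # mixed alphabets: keep the per-block grouping
        merged = groups
    from .ml import default_models

    engine = PartitionedLikelihood(merged, default_models(merged), tree,
                                   matrix.taxa)
    engine.optimize_branch_lengths(max_sweeps=2)
    return engine.tree


def greedy_scheme_search(matrix: SiteMatrix, blocks: list[DataBlock],
                         tree: Tree | None = None,
                         model_kind: str | None = None,
                         verbose: bool = False) -> PartitionScheme:
    """PartitionFinder-style greedy merge search under BIC.

    Starts from the all-separate scheme; each round fits every pairwise
    merge (cached) and applies the one with the largest BIC reduction; stops
    when no merge reduces the scheme BIC.  Ties break lexicographically on
    the merged group name, so the result does not depend on block order.
    """
    if not blocks:
        raise ValueError("need at least one data block")
    if tree is None:
        tree = guide_tree(matrix, blocks)
    n_branches = sum(1 for n in tree.postorder() if n.parent is not None)

    cache: dict[frozenset, ModelFit] = {}

    def fit(group: frozenset) -> ModelFit:
        if group not in cache:
            cache[group] = fit_group(matrix, blocks, group, tree, model_kind)
        return cache[group]

    groups = sorted((frozenset([b.name]) for b in blocks),
                    key=lambda g: sorted(g))
    for g in groups:
        fit(g)

    def scheme_bic(gs: list[frozenset]) -> float:
        lnl = sum(fit(g).lnl for g in gs)
        k = sum(fit(g).k for g in gs) + n_branches
        n = sum(fit(g).n for g in gs)
        return -2.0 * lnl + k * np.log(max(n, 1))

    current = scheme_bic(groups)
    while len(groups) > 1:
        best = None  # (new_bic, merged_name, i, j)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                merged = groups[i] | groups[j]
                candidate = [g for k_, g in enumerate(groups)
                             if k_ not in (i, j)] + [merged]
                bic = scheme_bic(candidate)
                name = "+".join(sorted(merged))
                key = (bic, name)
                if best is None or key < best[0]:
                    best = (key, i, j, merged)
        (bic, _), i, j, merged = best
        if bic >= current - 1e-9:
            break
        groups = [g for k_, g in enumerate(groups) if k_ not in (i, j)]
        groups.append(merged)
        groups.sort(key=lambda g: sorted(g))
        current = bic
        if verbose:  # pragma: no cover - logging aid
            print(f"merged -> {'+'.join(sorted(merged))}  BIC {bic:.2f}")
    return PartitionScheme(groups, {g: fit(g) for g in groups}, n_branches)


def write_scheme(scheme: PartitionScheme, blocks: list[DataBlock],
                 matrix: SiteMatrix, path) -> None:
    from .alignment import write_raxml_partitions

    write_raxml_partitions(scheme.as_blocks(blocks), matrix, path)
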