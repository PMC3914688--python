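"""Taxon-jackknife experiment: rerun inference under nested taxon subsets
and recoding schemes, and tabulate clade support.

Each case drops a set of taxa, optionally RY-recodes third (nt3) or first
and third (nt13) codon positions, infers a tree with bootstrap support, and
queries the clades of interest.  Support above 60% counts as significant,
and a clade absent from the best tree is reported as not recovered with its
(residual) bootstrap frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import DataBlock, SiteMatrix, ry_recode, split_codon_blocks
from .ml import bootstrap, ml_search, monophyly
from .simulate import JackknifeCase

#: bootstrap percentage treated as significant support
SIGNIFICANT_SUPPORT = 60.0

_RECODINGS = {"none": frozenset(), "nt3_RY": frozenset({3}),
              "nt13_RY": frozenset({1, 3})}


@dataclass(frozen=True)
class CladeResult:
    clade: str
    n_taxa: int
    monophyletic: bool
    support: float | None
    significant: bool


def _variant_blocks(matrix: SiteMatrix, blocks: list[DataBlock],
                    partitioned: bool) -> list[DataBlock]:
    """Alphabet-homogeneous blocks for one analysis variant.

    Codon positions are always split so that RY-recoded positions never mix
    with nucleotide positions; the unpartitioned variant then pools columns
    by alphabet only (one DNA partition + one RY partition).
    """
    split = split_codon_blocks(matrix, blocks, positions=(1, 2, 3))
    if partitioned:
        return split
    pooled: dict[str, list[int]] = {}
    for b in split:
        alpha = matrix.alphabets[b.columns[0]]
        pooled.setdefault(alpha, []).extend(b.columns)
    return [DataBlock(name, tuple(sorted(cols)))
            for name, cols in sorted(pooled.items())]


def prepare_case(matrix: SiteMatrix, blocks: list[DataBlock],
                 case: JackknifeCase) -> tuple[SiteMatrix, list[DataBlock]]:
    """Taxon-dropped, recoded matrix and matching blocks for one case."""
    kept = case.kept(matrix.taxa)
    if len(kept) < 4:
        raise ValueError(f"case {case.label}: fewer than 4 taxa remain")
    sub = matrix.select_taxa(kept)
    positions = _RECODINGS[case.recoding]
    if positions:
        sub = ry_recode(sub, positions)
    return sub, _variant_blocks(sub, blocks, case.partitioned)


def run_case(matrix: SiteMatrix, blocks: list[DataBlock], case: JackknifeCase,
             clades: dict[str, frozenset], bootstrap_replicates: int = 100,
             seed: int = 0) -> dict[str, CladeResult]:
    """Drop, recode, infer, bootstrap, and query each clade of interest.

    Clades are restricted to the taxa that survive the exclusion; a clade
    reduced below two taxa is reported as not applicable (None).
    """
    sub, vblocks = prepare_case(matrix, blocks, case)
    result = ml_search(sub, vblocks)
    _, freqs = bootstrap(sub, result, replicates=bootstrap_replicates,
                         seed=seed, blocks=vblocks)
    out: dict[str, CladeResult] = {}
    for name, taxa in clades.items():
        remaining = frozenset(taxa) & frozenset(sub.taxa)
        if len(remaining) < 2 or len(remaining) >= len(sub.taxa) - 1:
            out[name] = CladeResult(name, len(remaining), False, None, False)
            continue
        q = monophyly(result.tree, set(remaining), freqs)
        support = q.support if q.support is not None else 0.0
        out[name] = CladeResult(name, len(remaining), q.monophyletic, support,
                                q.monophyletic and support > SIGNIFICANT_SUPPORT)
    return out


def run_grid(matrix: SiteMatrix, blocks: list[DataBlock],
             cases: list[JackknifeCase], clades: dict[str, frozenset],
             bootstrap_replicates: int = 100, seed: int = 0) -> pd.DataFrame:
    """Long-form support table over all cases (one bootstrap seed per case,
    derived deterministically from ``seed``)."""
    import time

    rows = []
    for i, case in enumerate(cases):
        started = time.perf_counter()
        results = run_case(matrix, blocks, case, clades,
                           bootstrap_replicates, seed=seed + 1000 * i)
        elapsed = round(time.perf_counter() - started, 2)
        for name, r in results.items():
            rows.append({
                "case": case.label,
                "recoding": case.recoding,
                "partitioned": case.partitioned,
                "clade": name,
                "n_taxa": r.n_taxa,
                "monophyletic": r.monophyletic,
                "support": r.support,
                "significant": r.significant,
                "seed": seed + 1000 * i,
                "seconds": elapsed,
            })
    return pd.DataFrame(rows)


def pivot_support(table: pd.DataFrame) -> pd.DataFrame:
    """Case x clade pivot with '-' for clades absent from the best tree."""

    def cell(row):
        if row["support"] is None or pd.isna(row["support"]):
            return "na"
        if not row["monophyletic"]:
            return "-"
        return f"{row['support']:.0f}"

    t = table.copy()
    t["cell"] = t.apply(cell, axis=1)
    return t.pivot(index="case", columns="clade", values="cell")
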