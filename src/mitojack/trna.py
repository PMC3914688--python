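"""Mitochondrial tRNA cloverleaf analysis.

``fold_cloverleaf`` performs a bounded exhaustive search over cloverleaf
decompositions of a tRNA gene (acceptor stem fixed at 7 pairs, anticodon
loop fixed at 7 nt) allowing the D arm and the T arm to be declared absent,
which is how the dipluran truncations (trnR, trnC, trnS1, trnS2) manifest.
``fitch_map`` places arm-loss events on a tree by Fitch parsimony.

This is a purpose-built structural classifier, not a general tRNA finder:
the gene boundaries are taken as given and only the arm decomposition is
searched.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trees import Tree

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

MIN_LEN, MAX_LEN = 50, 80


class FoldError(ValueError):
    """No decomposition satisfies the cloverleaf constraints."""


@dataclass(frozen=True)
class Arm:
    stem: int
    loop: int

    @property
    def span(self) -> int:
        return 2 * self.stem + self.loop


@dataclass(frozen=True)
class CloverleafStructure:
    """Arm-by-arm decomposition of a tRNA gene.

    Spans in gene order: acceptor 5' strand (7) | linker1 | D arm or remnant
    | linker2 | anticodon 5' stem | anticodon loop (7) | anticodon 3' stem |
    variable loop | T arm or remnant | acceptor 3' strand (7).
    """

    length: int
    acceptor_pairs: int           # valid pairs out of 7
    linker1: int
    d_arm: Arm | None             # None = absent
    d_remnant: int                # unpaired remnant loop when absent
    linker2: int
    anticodon_stem: int
    anticodon_pairs: int
    variable_loop: int
    t_arm: Arm | None
    t_remnant: int
    anticodon: str | None
    score: float

    @property
    def d_arm_present(self) -> bool:
        return self.d_arm is not None

    @property
    def spans(self) -> tuple:
        d = self.d_arm.span if self.d_arm else self.d_remnant
        t = self.t_arm.span if self.t_arm else self.t_remnant
        return (7, self.linker1, d, self.linker2, self.anticodon_stem, 7,
                self.anticodon_stem, self.variable_loop, t, 7)

    def dot_bracket(self) -> str:
        out = []
        out.append("(" * 7)
        out.append("." * self.linker1)
        if self.d_arm:
            out.append("(" * self.d_arm.stem + "." * self.d_arm.loop
                       + ")" * self.d_arm.stem)
        else:
            out.append("." * self.d_remnant)
        out.append("." * self.linker2)
        out.append("(" * self.anticodon_stem + "." * 7
                   + ")" * self.anticodon_stem)
        out.append("." * self.variable_loop)
        if self.t_arm:
            out.append("(" * self.t_arm.stem + "." * self.t_arm.loop
                       + ")" * self.t_arm.stem)
        else:
            out.append("." * self.t_remnant)
        out.append(")" * 7)
        return "".join(out)


@dataclass(frozen=True)
class FoldConstraints:
    """Search bounds; mitochondrial tRNAs are degenerate, so mismatch
    tolerances and the D-stem presence threshold are configurable."""

    acceptor_min_pairs: int = 5      # out of 7
    d_stem_range: tuple = (2, 4)     # a shorter stem counts as arm loss
    d_loop_range: tuple = (3, 10)
    d_remnant_range: tuple = (0, 16)
    ac_stem_range: tuple = (4, 5)
    ac_min_pairs_deficit: int = 1    # allow one mismatch in anticodon stem
    t_stem_range: tuple = (2, 5)
    t_loop_range: tuple = (3, 9)
    t_remnant_range: tuple = (0, 16)
    variable_loop_range: tuple = (3, 24)
    linker1_options: tuple = (2, 1)  # canonical first: deterministic ties
    linker2_options: tuple = (1, 0, 2)


def _stem_pairs(seq: str, x: int, y: int, n: int) -> int:
    """Count valid pairs between seq[x:x+n] and seq[y:y+n] (antiparallel)."""
    return sum(
        (seq[x + k], seq[y + n - 1 - k]) in _PAIRS for k in range(n)
    )


def fold_cloverleaf(seq: str, anticodon: str | None = None,
                    constraints: FoldConstraints = FoldConstraints()
                    ) -> CloverleafStructure:
    """Best-scoring cloverleaf decomposition of a tRNA gene sequence.

    Score = total canonical+wobble (G-U) pairs minus stem mismatches; ties
    prefer more pairs, then a present D arm, then a smaller variable loop.
    Raises :class:`FoldError` when even the acceptor stem cannot form.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    c = constraints
    if not MIN_LEN <= L <= MAX_LEN:
        raise FoldError(f"length {L} outside [{MIN_LEN}, {MAX_LEN}]")
    acc_pairs = _stem_pairs(seq, 0, L - 7, 7)
    if acc_pairs < c.acceptor_min_pairs:
        raise FoldError(
            f"acceptor stem has only {acc_pairs} valid pairs "
            f"(needs {c.acceptor_min_pairs})"
        )
    inner = L - 14  # between the acceptor strands
    anticodon = anticodon.upper().replace("U", "T") if anticodon else None

    best = None
    best_key = None

    d_options = [Arm(d, dl)
                 for d in range(c.d_stem_range[0], c.d_stem_range[1] + 1)
                 for dl in range(c.d_loop_range[0], c.d_loop_range[1] + 1)]
    t_options = [Arm(t, tl)
                 for t in range(c.t_stem_range[0], c.t_stem_range[1] + 1)
                 for tl in range(c.t_loop_range[0], c.t_loop_range[1] + 1)]

    for l1 in c.linker1_options:
        d_start = 7 + l1
        for l2 in c.linker2_options:
            d_candidates = [(d, d.span) for d in d_options]
            d_candidates += [(None, r) for r in range(c.d_remnant_range[0],
                                                     c.d_remnant_range[1] + 1)]
            for d_obj, d_span in d_candidates:
                if d_obj is not None:
                    if _stem_pairs(seq, d_start,
                                   d_start + d_obj.stem + d_obj.loop,
                                   d_obj.stem) < d_obj.stem:
                        continue  # D stems must pair perfectly
                    d_pairs = d_obj.stem
                else:
                    d_pairs = 0
                ac_start = d_start + d_span + l2
                for a in range(c.ac_stem_range[0], c.ac_stem_range[1] + 1):
                    ac_pairs = _stem_pairs(seq, ac_start, ac_start + a + 7, a)
                    if ac_pairs < a - c.ac_min_pairs_deficit:
                        continue
                    if anticodon is not None:
                        mid = ac_start + a + 2
                        if seq[mid : mid + 3] != anticodon:
                            continue
                    used = l1 + d_span + l2 + 2 * a + 7
                    for t_arm in [*t_options, None]:
                        if t_arm is not None:
                            v = inner - used - t_arm.span
                            if not (c.variable_loop_range[0] <= v
                                    <= c.variable_loop_range[1]):
                                continue
                            t_start = 7 + used + v
                            if _stem_pairs(seq, t_start,
                                           t_start + t_arm.stem + t_arm.loop,
                                           t_arm.stem) < t_arm.stem:
                                continue
                            t_pairs, t_rem = t_arm.stem, 0
                        else:
                            # remnant + variable loop split the leftover
                            leftover = inner - used
                            t_rem = max(c.t_remnant_range[0],
                                        leftover - c.variable_loop_range[1])
                            v = leftover - t_rem
                            if (v < c.variable_loop_range[0]
                                    or t_rem > c.t_remnant_range[1]):
                                continue
                            t_pairs = 0
                        total_pairs = acc_pairs + d_pairs + ac_pairs + t_pairs
                        mismatches = (7 - acc_pairs) + (a - ac_pairs)
                        score = total_pairs - mismatches
                        key = (score, total_pairs, d_obj is not None, -v)
                        if best_key is None or key > best_key:
                            best_key = key
                            best = CloverleafStructure(
                                L, acc_pairs, l1, d_obj,
                                0 if d_obj else d_span, l2, a, ac_pairs,
                                v, t_arm, t_rem, anticodon, score,
                            )
    if best is None:
        raise FoldError("no decomposition satisfies the cloverleaf constraints")
    return best


def call_d_arm(structure: CloverleafStructure) -> tuple[str, int]:
    """("present"|"absent", remnant loop length).

    The remnant loop is the unpaired span replacing a lost D arm (0 when the
    arm is present).
    """
    if structure.d_arm_present:
        return "present", 0
    return "absent", structure.d_remnant


# --- truncation character matrices and parsimony mapping ---------------------


def truncation_matrix(folds: dict[str, dict[str, CloverleafStructure]]) -> pd.DataFrame:
    """taxa x tRNA binary matrix (1 = D-arm absent) from per-taxon folds."""
    rows = {
        taxon: {gene: int(not s.d_arm_present) for gene, s in genes.items()}
        for taxon, genes in folds.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def read_truncation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df


@dataclass(frozen=True)
class FitchEvent:
    clade: frozenset      # tips below the branch where the change maps
    parent_state: int
    child_state: int


def fitch_map(tree: Tree, chars: pd.DataFrame,
              root_preference: int = 0) -> dict[str, tuple[int, list[FitchEvent]]]:
    """Fitch parsimony mapping of binary characters onto a rooted tree.

    Returns per character ``(parsimony length, events)`` for one minimal
    reconstruction; ambiguous down-pass states resolve toward the parent,
    and the root toward ``root_preference`` (0 = arm present, the ancestral
    full cloverleaf).  '?' tips are compatible with both states.
    """
    tips = set(tree.tip_names())
    missing = tips - set(chars.index)
    if missing:
        raise KeyError(f"tree taxa absent from the character matrix: "
                       f"{sorted(missing)}")
    results = {}
    post = tree.postorder()
    for char in chars.columns:
        states: dict[int, frozenset] = {}
        below: dict[int, frozenset] = {}
        length = 0
        for node in post:
            if node.is_tip:
                raw = str(chars.loc[node.name, char])
                states[id(node)] = (frozenset({0, 1}) if raw in ("?", "nan")
                                    else frozenset({int(raw)}))
                below[id(node)] = frozenset([node.name])
            else:
                inter = None
                union = frozenset()
                for ch in node.children:
                    s = states[id(ch)]
                    inter = s if inter is None else inter & s
                    union |= s
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
                if inter:
                    states[id(node)] = inter
                else:
                    states[id(node)] = union
                    length += 1
        # top-down resolution
        assigned: dict[int, int] = {}
        events: list[FitchEvent] = []
        for node in tree.preorder():
            sset = states[id(node)]
            if node is tree.root:
                assigned[id(node)] = (root_preference if root_preference in sset
                                      else min(sset))
                continue
            p = assigned[id(node.parent)]
            mine = p if p in sset else min(sset)
            assigned[id(node)] = mine
            if mine != p:
                clade = (below[id(node)] if not node.is_tip
                         else frozenset([node.name]))
                events.append(FitchEvent(clade, p, mine))
        results[char] = (length, events)
    return results
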