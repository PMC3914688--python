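"""Synthetic data with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_genome` emits an annotated circular mitogenome following
  the pancrustacean 37-gene template: controllable AT content and strand
  skews, valid (possibly incomplete) stop codons, tRNA genes built from
  cloverleaf templates with per-gene D-arm loss, an A+T-rich region, and the
  conserved nad4/nad4L (-7) and nad6/cob (-1) overlaps.
* :func:`simulate_alignment` evolves a partitioned nucleotide matrix along a
  tree under GTR+G with per-lineage rate multipliers and composition targets
  (the ingredients of a long-branch-attraction artifact).
* :func:`lba_preset` packages the taxon-jackknife study scenario: a
  16-taxon tree whose fast, AT-rich "camp" clade is attracted to fast
  outgroups unless the intermediate "proj" lineage is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import pancrustacea
from .alignment import ColumnLabel, SiteMatrix
from .genome import CircularGenome, GeneAnnotation, reverse_complement
from .ml import SubstitutionModel, discrete_gamma_rates
from .trees import Node, Tree

# --- base sampling -----------------------------------------------------------


def base_probabilities(at_content: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """P(A, C, G, T) matching an AT content and strand skews."""
    if not 0 < at_content < 1:
        raise ValueError("AT content must be a fraction in (0, 1)")
    at, gc = at_content, 1.0 - at_content
    p = np.array([
        at * (1 + at_skew) / 2,
        gc * (1 - gc_skew) / 2,
        gc * (1 + gc_skew) / 2,
        at * (1 - at_skew) / 2,
    ])
    if (p < 0).any():
        raise ValueError("skew targets are inconsistent with the AT content")
    return p / p.sum()


_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(_BASES, size=n, p=probs))


# --- tRNA synthesis ----------------------------------------------------------

# loop alphabets without internal canonical/wobble pairs (no A-T, G-C, G-T),
# drawn per loop so loop composition is skew-balanced in expectation
_LOOP_ALPHABETS = (np.array(list("AC")), np.array(list("CT")))


def _rand_loop(rng: np.random.Generator, n: int) -> str:
    letters = _LOOP_ALPHABETS[int(rng.integers(2))]
    return "".join(rng.choice(letters, size=n))


def _rand_stem(rng: np.random.Generator, n: int) -> tuple[str, str]:
    """A perfectly Watson-Crick paired stem (5' strand, 3' strand)."""
    five = "".join(rng.choice(_BASES, size=n))
    return five, reverse_complement(five)


@dataclass(frozen=True)
class TrnaTruth:
    d_arm_present: bool
    spans: tuple          # gene-order spans as in CloverleafStructure.spans
    anticodon: str


def synthesize_trna(rng: np.random.Generator, anticodon: str,
                    d_arm: bool = True) -> tuple[str, TrnaTruth]:
    """A synthetic tRNA gene that folds into the intended cloverleaf.

    Stems are perfect Watson-Crick pairs; loops use an A/C alphabet so no
    spurious stem can form inside them, which keeps the intended
    decomposition the unique best fold.
    """
    acc5, acc3 = _rand_stem(rng, 7)
    linker1 = _rand_loop(rng, 2)
    if d_arm:
        d_stem = int(rng.integers(3, 5))
        d_loop = int(rng.integers(5, 9))
        d5, d3 = _rand_stem(rng, d_stem)
        d_section = d5 + _rand_loop(rng, d_loop) + d3
        d_span = 2 * d_stem + d_loop
    else:
        d_span = int(rng.integers(4, 13))
        d_section = _rand_loop(rng, d_span)
    # junction characters are chosen so that sliding the arm boundaries
    # cannot fabricate extra stem pairs: 'C' pairs only with G, and no loop
    # alphabet contains G
    linker2 = "C"
    ac5 = "C" + "".join(rng.choice(_BASES, size=4))
    ac3 = reverse_complement(ac5)
    ac_loop = _rand_loop(rng, 2) + anticodon.upper().replace("U", "T") + _rand_loop(rng, 2)
    t_stem = int(rng.integers(3, 6))
    t_loop_len = int(rng.integers(5, 8))
    t5, t3 = _rand_stem(rng, t_stem)
    t_section = t5 + _rand_loop(rng, t_loop_len) + t3
    var_loop = _rand_loop(rng, int(rng.integers(3, 6)))
    # the base flanking the T stem must not extend it by pairing with the
    # stem's outermost 3' base
    partners = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}
    t3_outer = t3[-1]
    allowed = sorted({"A", "C", "T"} - partners[t3_outer])
    var_loop = var_loop[:-1] + str(rng.choice(allowed))
    seq = (acc5 + linker1 + d_section + linker2 + ac5 + ac_loop + ac3
           + var_loop + t_section + acc3)
    spans = (7, 2, d_span, 1, 5, 7, 5, len(var_loop),
             2 * t_stem + t_loop_len, 7)
    return seq, TrnaTruth(d_arm, spans, anticodon.upper().replace("U", "T"))


def trna_anticodon(gene: str) -> str:
    """Anticodon (DNA alphabet) from a trnX-anticodon gene symbol."""
    return gene.split("-")[1].upper().replace("U", "T")


# --- genome simulation -------------------------------------------------------


@dataclass
class GenomeRecipe:
    """Target composition and structure of a simulated dipluran-like genome.

    Defaults follow the seven-genome comparison table: per-gene lengths and
    spacers from the Octostigma column (which carries the conserved -7 and
    -1 overlaps), AT content / skews in the dipluran range, incomplete stops
    on roughly a third of the PCGs.
    """

    gene_order: tuple = pancrustacea.GENE_ORDER
    at_content: float = 0.68
    at_skew: float = 0.04
    gc_skew: float = -0.35
    at_rich_at_content: float = 0.85
    incomplete_stop_prob: float = 0.3
    noncanonical_start_prob: float = 0.1
    gene_lengths: dict = field(default_factory=dict)   # overrides
    spacers: dict = field(default_factory=dict)        # overrides, by upstream gene
    d_arm_absent: frozenset = frozenset({"trnS-gcu"})  # lost in all diplurans
    reference_species: str = "os"

    def length_of(self, gene: str) -> int:
        if gene in self.gene_lengths:
            return self.gene_lengths[gene]
        row = next(r for r in pancrustacea.TABLE if r.gene == gene)
        si = pancrustacea.SPECIES.index(self.reference_species)
        return row.sizes[si]

    def spacer_after(self, gene: str) -> int:
        if gene in self.spacers:
            return self.spacers[gene]
        row = next(r for r in pancrustacea.TABLE if r.gene == gene)
        si = pancrustacea.SPECIES.index(self.reference_species)
        return row.spacers[si]


def _pcg_sequence(rng: np.random.Generator, length: int, probs: np.ndarray,
                  recipe: GenomeRecipe, force_start: str | None = None,
                  force_stop: str | None = None) -> tuple[str, str, str]:
    """(cds, start codon, stop codon); length is adjusted to the stop class."""
    if force_start is not None:
        start = force_start
    elif rng.random() < recipe.noncanonical_start_prob:
        start = str(rng.choice(["TTG", "GTG", "TTA"]))
    else:
        start = "AT" + str(rng.choice(_BASES))
    if force_stop is not None:
        stop = force_stop
    elif rng.random() < recipe.incomplete_stop_prob:
        stop = str(rng.choice(["T", "TA"]))
    else:
        stop = str(rng.choice(["TAA", "TAG"]))
    n_body = max((length - len(stop)) // 3 - 1, 1)
    body = []
    for _ in range(n_body):
        codon = _random_bases(rng, 3, probs)
        while codon in ("TAA", "TAG"):
            codon = _random_bases(rng, 3, probs)
        body.append(codon)
    return start + "".join(body) + stop, start, stop


def simulate_genome(recipe: GenomeRecipe | None = None, seed: int = 0
                    ) -> tuple[CircularGenome, dict]:
    """Simulate an annotated genome plus a per-gene truth table.

    Truth entries: PCGs carry ``start``/``stop`` codons as placed in the
    final assembly; tRNAs carry a :class:`TrnaTruth`.  Negative spacers are
    honored by letting the downstream gene keep the already-written overlap
    except for its own terminal codons, which take priority (this is how the
    real nad4/nad4L and nad6/cob overlaps are laid out).
    """
    recipe = recipe or GenomeRecipe()
    rng = np.random.default_rng(seed)
    # skew targets are defined on the deposited (J) strand, so coding-sense
    # sequences of N genes are sampled with negated skews
    probs_j = base_probabilities(recipe.at_content, recipe.at_skew, recipe.gc_skew)
    probs_n = base_probabilities(recipe.at_content, -recipe.at_skew, -recipe.gc_skew)

    order = list(recipe.gene_order)
    is_pcg = {g: not (g.startswith("trn") or g.startswith("rrn"))
              for g, _ in order}
    # overlaps are kept only between protein-coding neighbors (the conserved
    # nad4/nad4L, nad6/cob, atp8/atp6 pattern); an overlap onto a tRNA would
    # corrupt its cloverleaf, so those spacers are clipped to zero
    eff_spacer: dict[str, int] = {}
    force_start: dict[str, str] = {}
    force_stop: dict[str, str] = {}
    for (g1, s1), (g2, s2) in zip(order, order[1:]):
        sp = recipe.spacer_after(g1)
        if sp < 0 and not (is_pcg[g1] and is_pcg[g2]):
            sp = 0
        if sp < 0 and is_pcg[g1] and is_pcg[g2] and s1 == s2 == "J" and sp >= -2:
            # abutting codons share bases: TAA stop + ATN start at a 1-nt
            # overlap (the nad6/cob arrangement)
            force_stop[g1] = "TAA"
            force_start[g2] = "AT" + str(rng.choice(_BASES))
        eff_spacer[g1] = sp
    eff_spacer[order[-1][0]] = recipe.spacer_after(order[-1][0])

    # pass 1: per-gene coding-sense sequences and truths
    seqs: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for gene, strand in order:
        length = recipe.length_of(gene)
        probs = probs_j if strand == "J" else probs_n
        if gene.startswith("trn"):
            trna, t_truth = synthesize_trna(
                rng, trna_anticodon(gene), d_arm=gene not in recipe.d_arm_absent
            )
            seqs[gene] = trna
            truth[gene] = {"class": "tRNA", "trna": t_truth}
        elif gene.startswith("rrn"):
            seqs[gene] = _random_bases(rng, length, probs)
            truth[gene] = {"class": "rRNA"}
        else:
            cds, start, stop = _pcg_sequence(rng, length, probs, recipe,
                                             force_start.get(gene),
                                             force_stop.get(gene))
            seqs[gene] = cds
            truth[gene] = {"class": "PCG", "start": start, "stop": stop}

    # pass 2: layout
    spans: list[tuple[str, str, int, int]] = []  # gene, strand, start, end
    cursor = 0
    for gene, strand in order:
        L = len(seqs[gene])
        spans.append((gene, strand, cursor, cursor + L))
        cursor += L + eff_spacer[gene]
    total = cursor  # the final spacer is the A+T-rich region
    if total <= 0:
        raise ValueError("recipe lengths and spacers give a non-positive genome")

    genome_chars: list[str | None] = [None] * total
    for gene, strand, start, end in spans:
        coding = seqs[gene]
        placed = coding if strand == "J" else reverse_complement(coding)
        # genome positions of this gene's own terminal codons
        protected: set[int] = set()
        if truth[gene]["class"] == "PCG":
            ns, np_ = 3, len(truth[gene]["stop"])
            if strand == "J":
                protected |= set(range(start, start + ns))
                protected |= set(range(end - np_, end))
            else:
                protected |= set(range(end - ns, end))
                protected |= set(range(start, start + np_))
        for off, ch in enumerate(placed):
            pos = start + off
            if genome_chars[pos] is None or pos in protected:
                genome_chars[pos] = ch
    # the A+T-rich region shares the strand-wide skew targets
    at_rich_probs = base_probabilities(recipe.at_rich_at_content,
                                       recipe.at_skew, recipe.gc_skew)
    for pos, ch in enumerate(genome_chars):
        if ch is None:
            genome_chars[pos] = str(rng.choice(_BASES, p=at_rich_probs))

    annotations = [
        GeneAnnotation(gene, strand, start, end,
                       truth[gene]["class"])
        for gene, strand, start, end in spans
    ]
    genome = CircularGenome(f"sim{seed}", "".join(genome_chars), True, annotations)

    # record the codons as actually assembled (overlaps may have rewritten
    # interior bases, never the protected terminal codons)
    from .genome import classify_codons, gene_sequence

    for gene, strand, *_ in spans:
        if truth[gene]["class"] == "PCG":
            start_call, stop_call = classify_codons(gene_sequence(genome, gene))
            truth[gene]["start_call"] = start_call
            truth[gene]["stop_call"] = stop_call
    return genome, truth


# --- sequence evolution on trees --------------------------------------------


@dataclass(frozen=True)
class LineageOverride:
    """Rate/composition override for a named clade.

    ``scope`` "stem" touches only the branch subtending the clade (a long
    naked branch, the classic LBA geometry); "clade" also rescales every
    branch inside it.
    """

    rate: float = 1.0
    at_content: float | None = None   # composition drift target
    scope: str = "clade"              # "clade" | "stem"


@dataclass(frozen=True)
class PartitionSpec:
    name: str
    n_sites: int
    kind: str = "PCG"                  # "PCG" (codon labels) or "rRNA"
    frequencies: tuple = (0.3125, 0.17, 0.1275, 0.39)
    exchangeabilities: tuple = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)
    alpha: float = 0.5


@dataclass
class EvolutionScenario:
    tree: Tree
    partitions: list[PartitionSpec]
    overrides: dict = field(default_factory=dict)  # frozenset(tips)|tip -> LineageOverride

    def total_sites(self) -> int:
        return sum(p.n_sites for p in self.partitions)


def _override_freqs(base: np.ndarray, at_target: float) -> np.ndarray:
    at = base[0] + base[3]
    gc = base[1] + base[2]
    out = np.array([
        base[0] / at * at_target,
        base[1] / gc * (1 - at_target),
        base[2] / gc * (1 - at_target),
        base[3] / at * at_target,
    ])
    return out / out.sum()


def _edge_override(node: Node, tipsets: dict, overrides: dict) -> LineageOverride | None:
    """Innermost override that applies to this edge."""
    best = None
    best_size = None
    mine = tipsets[id(node)]
    for key, ov in overrides.items():
        clade = frozenset([key]) if isinstance(key, str) else frozenset(key)
        applies = (mine == clade if ov.scope == "stem" else mine <= clade)
        if applies and (best is None or len(clade) < best_size):
            best, best_size = ov, len(clade)
    return best


def simulate_alignment(scenario: EvolutionScenario, seed: int = 0
                       ) -> tuple[SiteMatrix, Tree]:
    """Markov evolution of a partitioned nucleotide matrix along a tree.

    The root sequence is drawn from each partition's stationary frequencies;
    per-site gamma rate categories are fixed across the tree; lineage
    overrides rescale branch lengths and/or redirect the composition via a
    nonstationary rate matrix on the affected branches.
    """
    rng = np.random.default_rng(seed)
    tree = scenario.tree.copy()
    tips = tree.tips()
    tipsets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipsets[id(node)] = frozenset([node.name])
        else:
            tipsets[id(node)] = frozenset().union(
                *(tipsets[id(c)] for c in node.children))

    columns = []
    labels: list[ColumnLabel] = []
    tip_rows: dict[str, list[np.ndarray]] = {t.name: [] for t in tips}
    for part in scenario.partitions:
        base_freqs = np.asarray(part.frequencies, float)
        base_model = SubstitutionModel.gtr(part.exchangeabilities, base_freqs,
                                           alpha=part.alpha)
        cats = rng.integers(0, base_model.ncat, size=part.n_sites)
        rates = discrete_gamma_rates(part.alpha, base_model.ncat)
        states: dict[int, np.ndarray] = {
            id(tree.root): rng.choice(4, size=part.n_sites, p=base_freqs)
        }
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent_states = states[id(node.parent)]
            ov = _edge_override(node, tipsets, scenario.overrides)
            model = base_model
            rate = 1.0
            if ov is not None:
                rate = ov.rate
                if ov.at_content is not None:
                    model = SubstitutionModel.gtr(
                        part.exchangeabilities,
                        _override_freqs(base_freqs, ov.at_content),
                        alpha=part.alpha,
                    )
            t = (node.length or 0.0) * rate
            child = np.empty(part.n_sites, dtype=np.int64)
            P = model.transition_matrices(t)  # (ncat, 4, 4)
            for c in range(base_model.ncat):
                Pc = P[c] / P[c].sum(axis=1, keepdims=True)
                for s in range(4):
                    idx = np.nonzero((cats == c) & (parent_states == s))[0]
                    if idx.size:
                        child[idx] = rng.choice(4, size=idx.size, p=Pc[s])
            states[id(node)] = child
        for tip in tips:
            tip_rows[tip.name].append(states[id(tip)])
        for i in range(part.n_sites):
            pos = "rRNA" if part.kind == "rRNA" else str(i % 3 + 1)
            labels.append(ColumnLabel(part.name, pos, i))

    taxa = [t.name for t in tips]
    data = np.array([
        _BASES[np.concatenate(tip_rows[t])] for t in taxa
    ], dtype="<U1")
    matrix = SiteMatrix(taxa, data, labels, ["nt"] * len(labels))
    return matrix, tree


# --- the taxon-jackknife (LBA) preset ---------------------------------------


CAMP = ("camp1", "camp2", "camp3")
JAPY = ("japy1", "japy2", "japy3")
PROJ = "proj"
INGROUP = CAMP + (PROJ,) + JAPY

#: rate and composition overrides that make the "camp" clade and the far
#: fast outgroups converge (rate x8, AT 0.80)
LBA_RATE = 8.0
LBA_AT = 0.80


def _lba_tree() -> Tree:
    # geometry calibrated so that the artifact robustly wins exactly when
    # the intermediate proj lineage is missing: a short ingroup stem (0.06)
    # carries the true signal, proj sits close to camp (the anchor), and the
    # camp/fast stems take the x8 rate + AT-0.80 overrides
    fast = "(fast1:0.25,(fast2:0.20,fast3:0.20):0.10)"
    camp = "((camp1:0.06,camp2:0.06):0.05,camp3:0.08)"
    rabdura = f"({camp}:0.07,proj:0.06)"
    japy = "((japy1:0.07,japy2:0.07):0.05,japy3:0.10)"
    diplura = f"({rabdura}:0.14,{japy}:0.08)"
    n5 = f"(out1:0.18,{diplura}:0.06)"
    n4 = f"(out2:0.18,{n5}:0.08)"
    n3 = f"({fast}:0.10,{n4}:0.10)"
    n2 = f"(out3:0.20,{n3}:0.06)"
    n1 = f"(out4:0.20,{n2}:0.08)"
    newick = f"(out6:0.25,out5:0.22,{n1}:0.08);"
    from .trees import parse_newick

    return parse_newick(newick)


def lba_default_partitions() -> list[PartitionSpec]:
    return [
        PartitionSpec("pcgA", 1200, "PCG", alpha=0.4),
        PartitionSpec("pcgB", 900, "PCG", alpha=0.6,
                      frequencies=(0.35, 0.15, 0.12, 0.38)),
        PartitionSpec("pcgC", 600, "PCG", alpha=0.8),
        PartitionSpec("rrn", 300, "rRNA", alpha=0.5,
                      frequencies=(0.34, 0.14, 0.14, 0.38)),
    ]


@dataclass(frozen=True)
class JackknifeCase:
    label: str
    excluded_taxa: frozenset
    recoding: str = "none"          # none | nt3_RY | nt13_RY
    partitioned: bool = True

    def kept(self, taxa: list[str]) -> list[str]:
        return [t for t in taxa if t not in self.excluded_taxa]


def lba_cases(recoding: str = "none",
              partitioned: bool = False) -> list[JackknifeCase]:
    """The six nested taxon samplings of the jackknife experiment.

    The default variant is the single-partition nucleotide GTR+G analysis
    (the cheapest column of the support table, which already shows the
    recovery pattern); recoded/partitioned variants are available through
    the arguments.
    """
    defs = [
        ("A", frozenset()),
        ("B", frozenset({PROJ})),
        ("C", frozenset({"camp3", PROJ, "japy1", "japy2"})),
        ("D", frozenset({"camp3", "japy1", "japy2"})),
        ("E", frozenset(CAMP)),
        ("F", frozenset(JAPY)),
    ]
    return [JackknifeCase(label, excl, recoding, partitioned)
            for label, excl in defs]


def lba_clades() -> dict[str, frozenset]:
    return {
        "diplura": frozenset(INGROUP),
        "rabdura": frozenset(CAMP + (PROJ,)),
    }


def lba_preset(seed: int = 0, n_sites: int | None = None
               ) -> tuple[SiteMatrix, list[JackknifeCase], dict, Tree]:
    """Matrix + cases + clade definitions for the taxon-sampling experiment.

    The generating tree holds a true 7-tip ingroup ("diplura": camp + proj +
    japy); the camp subclade and a distant fast clade share rate x8 and
    AT-content 0.80 overrides, which pulls camp toward the outgroup when the
    intermediate proj lineage is excluded.
    """
    parts = lba_default_partitions()
    if n_sites is not None:
        scale = n_sites / sum(p.n_sites for p in parts)
        parts = [replace(p, n_sites=max(int(round(p.n_sites * scale)), 30))
                 for p in parts]
    tree = _lba_tree()
    overrides = {
        frozenset(CAMP): LineageOverride(rate=LBA_RATE, at_content=LBA_AT,
                                         scope="stem"),
        frozenset({"fast1", "fast2", "fast3"}):
            LineageOverride(rate=LBA_RATE, at_content=LBA_AT, scope="stem"),
    }
    scenario = EvolutionScenario(tree, parts, overrides)
    matrix, true_tree = simulate_alignment(scenario, seed)
    return matrix, lba_cases(), lba_clades(), true_tree
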