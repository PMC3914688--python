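"""Nucleotide composition, strand-skew and codon-usage statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
J strand for the whole genome and on the coding sense of J- and N-oriented
protein-coding genes, overall and per codon position.  Non-ACGT symbols are
excluded from every numerator and denominator.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import CircularGenome, gene_sequence


@dataclass(frozen=True)
class BaseCounts:
    A: int = 0
    C: int = 0
    G: int = 0
    T: int = 0
    other: int = 0

    @classmethod
    def from_seq(cls, seq: str) -> "BaseCounts":
        c = Counter(seq.upper())
        acgt = {b: c.get(b, 0) for b in "ACGT"}
        other = sum(c.values()) - sum(acgt.values())
        return cls(acgt["A"], acgt["C"], acgt["G"], acgt["T"], other)

    def __add__(self, o: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.A + o.A, self.C + o.C, self.G + o.G,
                          self.T + o.T, self.other + o.other)

    @property
    def total(self) -> int:
        return self.A + self.C + self.G + self.T + self.other


def at_skew(counts: BaseCounts) -> float | None:
    """(A - T)/(A + T); None when A + T = 0."""
    denom = counts.A + counts.T
    return None if denom == 0 else (counts.A - counts.T) / denom


def gc_skew(counts: BaseCounts) -> float | None:
    """(G - C)/(G + C); None when G + C = 0."""
    denom = counts.G + counts.C
    return None if denom == 0 else (counts.G - counts.C) / denom


def at_content(counts: BaseCounts) -> float | None:
    """100 * (A + T)/(A + C + G + T); None for an all-ambiguous sequence."""
    denom = counts.A + counts.C + counts.G + counts.T
    return None if denom == 0 else 100.0 * (counts.A + counts.T) / denom


@dataclass(frozen=True)
class SkewReport:
    category: str             # J_all | J_PCG | N_PCG
    codon_position: str       # all | 1 | 2 | 3
    at_content: float | None
    at_skew: float | None
    gc_skew: float | None


def _position_counts(seqs: list[str], position: int) -> BaseCounts:
    """Pooled counts at one codon position (1-based) over coding-sense CDSs."""
    counts = BaseCounts()
    for s in seqs:
        counts = counts + BaseCounts.from_seq(s[position - 1 :: 3])
    return counts


def skew_profile(genome: CircularGenome) -> list[SkewReport]:
    """Skew/content reports for the J strand and for J-/N-oriented PCGs.

    N-oriented PCG statistics are computed on the coding sense (the reverse
    complement of the deposited strand), with codon positions defined on that
    sense.
    """
    reports = []

    def emit(category, seqs):
        pooled = BaseCounts()
        for s in seqs:
            pooled = pooled + BaseCounts.from_seq(s)
        reports.append(SkewReport(category, "all", at_content(pooled),
                                  at_skew(pooled), gc_skew(pooled)))
        if category != "J_all":
            for pos in (1, 2, 3):
                c = _position_counts(seqs, pos)
                reports.append(SkewReport(category, str(pos), at_content(c),
                                          at_skew(c), gc_skew(c)))

    emit("J_all", [genome.seq])
    j_pcgs = [gene_sequence(genome, a.name) for a in genome.annotations
              if a.feature_class == "PCG" and a.strand == "J"]
    n_pcgs = [gene_sequence(genome, a.name) for a in genome.annotations
              if a.feature_class == "PCG" and a.strand == "N"]
    if j_pcgs:
        emit("J_PCG", j_pcgs)
    if n_pcgs:
        emit("N_PCG", n_pcgs)
    return reports


ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def codon_usage(cds_set: list[str]) -> pd.DataFrame:
    """Codon counts and frequencies over all complete codons of a CDS set.

    Trailing incomplete codons are ignored; codons containing ambiguity codes
    are excluded from the 64-codon table and tallied in ``n_ambiguous``
    (stored in ``DataFrame.attrs``).
    """
    counts = Counter()
    ambiguous = 0
    for cds in cds_set:
        cds = cds.upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                ambiguous += 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "codon": ALL_CODONS,
            "count": [counts.get(c, 0) for c in ALL_CODONS],
        }
    )
    df["frequency"] = df["count"] / total if total else 0.0
    df.attrs["n_ambiguous"] = ambiguous
    return df


def genome_summary(genome: CircularGenome) -> dict:
    """One summary row per genome: length, AT%, AT skew, GC skew (J strand)."""
    counts = BaseCounts.from_seq(genome.seq)
    return {
        "id": genome.id,
        "length": len(genome),
        "at_percent": round(at_content(counts), 2),
        "at_skew": round(at_skew(counts), 2),
        "gc_skew": round(gc_skew(counts), 2),
    }


def summary_table(genomes: list[CircularGenome]) -> pd.DataFrame:
    return pd.DataFrame([genome_summary(g) for g in genomes])


def skew_table(genome: CircularGenome) -> pd.DataFrame:
    """Per-category skew matrix (the supplementary-table style report)."""
    rows = [
        {
            "id": genome.id,
            "category": r.category,
            "codon_position": r.codon_position,
            "at_percent": None if r.at_content is None else round(r.at_content, 2),
            "at_skew": None if r.at_skew is None else round(r.at_skew, 2),
            "gc_skew": None if r.gc_skew is None else round(r.gc_skew, 2),
        }
        for r in skew_profile(genome)
    ]
    return pd.DataFrame(rows)
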