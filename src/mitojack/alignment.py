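"""Supermatrix assembly: codon retro-alignment, conserved-block trimming,
concatenation with data-block bookkeeping, codon-position splitting and RY
recoding.

A :class:`SiteMatrix` is a rectangular character matrix with one label per
column: (source gene, codon position "1"/"2"/"3" or "rRNA", original
coordinate) plus a per-column alphabet tag ("nt", "aa" or "ry").  ``'-'`` is
an alignment gap, ``'?'`` missing data; both are treated as missing by the
likelihood machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from Bio.Seq import Seq

INVERTEBRATE_MITO_TABLE = 5

GAP_CHARS = ("-", "?")

#: IUPAC ambiguity resolution under RY recoding: codes resolving within one
#: class keep the class, cross-class codes become missing.
_RY_MAP = {
    "A": "R", "G": "R", "C": "Y", "T": "Y",
    "R": "R", "Y": "Y",
    "W": "?", "S": "?", "K": "?", "M": "?", "B": "?", "D": "?", "H": "?",
    "V": "?", "N": "?",
    "-": "-", "?": "?",
}


@dataclass(frozen=True)
class ColumnLabel:
    gene: str
    codon_position: str  # "1" | "2" | "3" | "rRNA"
    coordinate: int      # position in the source alignment


@dataclass(frozen=True)
class DataBlock:
    name: str
    columns: tuple

    def __len__(self):
        return len(self.columns)


@dataclass
class SiteMatrix:
    taxa: list[str]
    data: np.ndarray                 # (ntaxa, ncols), dtype '<U1'
    labels: list[ColumnLabel]
    alphabets: list[str] = field(default_factory=list)  # per column

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, n_columns)")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per column required")
        if not self.alphabets:
            self.alphabets = ["nt"] * self.data.shape[1]
        if len(self.alphabets) != self.data.shape[1]:
            raise ValueError("one alphabet per column required")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def select_columns(self, idx) -> "SiteMatrix":
        idx = list(idx)
        return SiteMatrix(
            list(self.taxa),
            self.data[:, idx],
            [self.labels[i] for i in idx],
            [self.alphabets[i] for i in idx],
        )

    def select_taxa(self, taxa: list[str]) -> "SiteMatrix":
        rows = [self.taxa.index(t) for t in taxa]
        return SiteMatrix(list(taxa), self.data[rows], list(self.labels),
                          list(self.alphabets))

    def drop_constant_gap_columns(self) -> "SiteMatrix":
        keep = [
            i for i in range(self.n_columns)
            if not all(c in GAP_CHARS for c in self.data[:, i])
        ]
        return self.select_columns(keep)

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_sequences(cls, taxa: list[str], rows: list[str], gene: str,
                       codon_position: str | None = None,
                       alphabet: str = "nt") -> "SiteMatrix":
        """Build from equal-length aligned rows; codon positions cycle 1,2,3
        unless a fixed ``codon_position`` (e.g. "rRNA") is given."""
        ncol = len(rows[0])
        if any(len(r) != ncol for r in rows):
            raise ValueError("aligned rows must have equal length")
        labels = [
            ColumnLabel(gene,
                        codon_position if codon_position else str(i % 3 + 1), i)
            for i in range(ncol)
        ]
        data = np.array([list(r.upper()) for r in rows], dtype="<U1")
        return cls(list(taxa), data, labels, [alphabet] * ncol)

    @classmethod
    def read_fasta(cls, path: str | Path, gene: str | None = None,
                   codon_position: str | None = None,
                   alphabet: str = "nt") -> "SiteMatrix":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records],
            gene or Path(path).stem, codon_position, alphabet,
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, taxon in enumerate(self.taxa):
                fh.write(f">{taxon}\n{''.join(self.data[i])}\n")

    def write_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP: name, whitespace, full row."""
        width = max(len(t) for t in self.taxa) + 2
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_columns}\n")
            for i, taxon in enumerate(self.taxa):
                fh.write(f"{taxon:<{width}}{''.join(self.data[i])}\n")

    @classmethod
    def read_phylip(cls, path: str | Path, gene: str = "matrix") -> "SiteMatrix":
        lines = Path(path).read_text().strip().split("\n")
        n, ncol = map(int, lines[0].split())
        taxa, rows = [], []
        for line in lines[1 : n + 1]:
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.replace(" ", ""))
        if any(len(r) != ncol for r in rows):
            raise ValueError("row length disagrees with header")
        return cls.from_sequences(taxa, rows, gene)


# --- retro-alignment ---------------------------------------------------------


def _strip_terminal_stop(cds: str) -> str:
    cds = cds.upper()
    rem = len(cds) % 3
    if rem == 0 and cds[-3:] in ("TAA", "TAG"):
        return cds[:-3]
    if rem == 2 and cds[-2:] == "TA":
        return cds[:-2]
    if rem == 1 and cds[-1] == "T":
        return cds[:-1]
    return cds


def translate_mito(cds: str) -> str:
    """Invertebrate mitochondrial translation (table 5) of whole codons."""
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate(table=INVERTEBRATE_MITO_TABLE))


def retroalign(aa_alignment: SiteMatrix, cds: dict[str, str]) -> SiteMatrix:
    """Expand an amino-acid alignment back to codons using each taxon's CDS.

    Terminal (complete or incomplete) stop codons are excluded first; the
    remaining CDS must translate exactly to the taxon's ungapped amino-acid
    row under the invertebrate mitochondrial code.
    """
    gene = aa_alignment.labels[0].gene
    ncol = aa_alignment.n_columns
    out_rows = []
    for ti, taxon in enumerate(aa_alignment.taxa):
        if taxon not in cds:
            raise ValueError(f"no CDS provided for taxon {taxon!r}")
        coding = _strip_terminal_stop(cds[taxon])
        if len(coding) % 3:
            raise ValueError(
                f"{gene}/{taxon}: CDS length {len(coding)} not a codon multiple"
            )
        aa_row = "".join(aa_alignment.data[ti])
        ungapped = aa_row.replace("-", "").replace("?", "")
        translated = translate_mito(coding)
        if translated != ungapped:
            for pos, (a, b) in enumerate(zip(translated, ungapped)):
                if a != b:
                    raise ValueError(
                        f"translation mismatch for {taxon} at amino-acid "
                        f"position {pos + 1}: {a!r} != {b!r}"
                    )
            raise ValueError(
                f"translation length mismatch for {taxon}: "
                f"{len(translated)} vs {len(ungapped)}"
            )
        codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
        row, k = [], 0
        for ch in aa_row:
            if ch in GAP_CHARS:
                row.append(ch * 3)
            else:
                row.append(codons[k])
                k += 1
        out_rows.append("".join(row))
    labels = [
        ColumnLabel(gene, str(i % 3 + 1), i) for i in range(3 * ncol)
    ]
    data = np.array([list(r) for r in out_rows], dtype="<U1")
    return SiteMatrix(list(aa_alignment.taxa), data, labels, ["nt"] * 3 * ncol)


# --- conserved-block trimming ------------------------------------------------


@dataclass(frozen=True)
class TrimParams:
    """Codon-aware conserved-block filter in the Gblocks spirit.

    ``t1``: fraction of taxa that must share the majority state for a column
    to count as conserved (default just over half); ``t2``: the stricter
    flank threshold; ``min_block``: minimum run length (codons in codon mode,
    columns otherwise); ``gmax``: maximum tolerated gap fraction.
    """

    t1: float | None = None   # default floor(n/2)+1 taxa
    t2: float = 0.85
    min_block: int = 10
    gmax: float = 0.0


def _conservation(matrix: SiteMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(majority-state fraction, gap fraction) per column."""
    n = matrix.n_taxa
    cons = np.zeros(matrix.n_columns)
    gaps = np.zeros(matrix.n_columns)
    for i in range(matrix.n_columns):
        col = matrix.data[:, i]
        is_gap = np.isin(col, GAP_CHARS)
        gaps[i] = is_gap.mean()
        states = col[~is_gap]
        if states.size:
            _, counts = np.unique(states, return_counts=True)
            cons[i] = counts.max() / n
    return cons, gaps


def trim_blocks(matrix: SiteMatrix, params: TrimParams = TrimParams(),
                codon_aware: bool | None = None) -> SiteMatrix:
    """Keep maximal runs of conserved columns, flanked by highly conserved
    ones; in codon mode units are whole codon triples."""
    n = matrix.n_taxa
    t1 = params.t1 if params.t1 is not None else (n // 2 + 1) / n
    if codon_aware is None:
        codon_aware = all(l.codon_position in "123" for l in matrix.labels)
    cons, gaps = _conservation(matrix)
    ok = (cons >= t1) & (gaps <= params.gmax)
    flank = (cons >= params.t2) & (gaps <= params.gmax)

    if codon_aware:
        if matrix.n_columns % 3:
            raise ValueError("codon-aware trimming needs a codon-multiple width")
        ok = ok.reshape(-1, 3).all(axis=1)
        flank = flank.reshape(-1, 3).all(axis=1)
    units = len(ok)

    keep = np.zeros(units, dtype=bool)
    i = 0
    while i < units:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < units and ok[j]:
            j += 1
        lo, hi = i, j  # run [lo, hi)
        while lo < hi and not flank[lo]:
            lo += 1
        while hi > lo and not flank[hi - 1]:
            hi -= 1
        if hi - lo >= params.min_block:
            keep[lo:hi] = True
        i = j

    if codon_aware:
        col_keep = np.repeat(keep, 3)
    else:
        col_keep = keep
    return matrix.select_columns(np.nonzero(col_keep)[0])


# --- concatenation -----------------------------------------------------------


def concatenate(matrices: list[SiteMatrix],
                fill_missing_taxa: bool = True) -> tuple[SiteMatrix, list[DataBlock]]:
    """Concatenate gene matrices over the union of taxa; rows absent from a
    matrix are filled with '?'.  Returns one DataBlock per source matrix."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    taxa: list[str] = []
    for m in matrices:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    chunks, labels, alphabets, blocks = [], [], [], []
    offset = 0
    for m in matrices:
        if len(set(m.taxa)) != len(m.taxa):
            dup = sorted({t for t in m.taxa if m.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa in {m.labels[0].gene}: {dup}")
        missing = [t for t in taxa if t not in m.taxa]
        if missing and not fill_missing_taxa:
            raise ValueError(f"taxa missing from {m.labels[0].gene}: {missing}")
        block = np.full((len(taxa), m.n_columns), "?", dtype="<U1")
        for ti, t in enumerate(m.taxa):
            block[taxa.index(t)] = m.data[ti]
        chunks.append(block)
        labels.extend(m.labels)
        alphabets.extend(m.alphabets)
        name = m.labels[0].gene
        blocks.append(DataBlock(name, tuple(range(offset, offset + m.n_columns))))
        offset += m.n_columns
    data = np.concatenate(chunks, axis=1)
    return SiteMatrix(taxa, data, labels, alphabets), blocks


def split_codon_blocks(matrix: SiteMatrix, blocks: list[DataBlock],
                       positions: tuple = (1, 2),
                       drop_other_positions: bool = False) -> list[DataBlock]:
    """Refine per-gene blocks into per-codon-position blocks.

    rRNA blocks pass through unchanged.  Codon positions not listed are kept
    as their own ``gene_posK`` blocks unless ``drop_other_positions``.
    """
    out = []
    for block in blocks:
        pos_cols: dict[str, list[int]] = {}
        for col in block.columns:
            pos_cols.setdefault(matrix.labels[col].codon_position, []).append(col)
        if set(pos_cols) == {"rRNA"}:
            out.append(block)
            continue
        for pos in sorted(pos_cols):
            if pos == "rRNA":
                out.append(DataBlock(f"{block.name}_rRNA", tuple(pos_cols[pos])))
            elif int(pos) in positions or not drop_other_positions:
                out.append(DataBlock(f"{block.name}_pos{pos}", tuple(pos_cols[pos])))
    return out


# --- RY recoding -------------------------------------------------------------


def ry_recode(matrix: SiteMatrix, positions: set) -> SiteMatrix:
    """Recode purines to R and pyrimidines to Y at the given codon positions.

    ``positions`` is a subset of {1, 2, 3} (nt3 coding = {3}, nt13 = {1, 3});
    rRNA-labeled columns are never recoded and may not be requested.
    """
    positions = {str(p) for p in positions}
    if not positions <= {"1", "2", "3"}:
        raise ValueError("RY recoding applies to codon positions 1-3 only")
    data = matrix.data.copy()
    alphabets = list(matrix.alphabets)
    for i, label in enumerate(matrix.labels):
        if label.codon_position not in positions:
            continue
        if label.codon_position == "rRNA":  # pragma: no cover - guarded above
            raise ValueError("cannot RY-recode rRNA columns")
        if alphabets[i] == "ry":
            data[:, i] = [_RY_MAP.get(c, "?") for c in data[:, i]]
        else:
            data[:, i] = [_RY_MAP.get(c, "?") for c in data[:, i]]
        alphabets[i] = "ry"
    return SiteMatrix(list(matrix.taxa), data, list(matrix.labels), alphabets)


# --- partition files ---------------------------------------------------------


def write_raxml_partitions(blocks: list[DataBlock], matrix: SiteMatrix,
                           path: str | Path) -> None:
    """RAxML-style partition file; contiguous codon-strided blocks use the
    ``start-end\\3`` dialect, others an explicit column list."""
    lines = []
    for block in blocks:
        cols = list(block.columns)
        model = "BIN" if matrix.alphabets[cols[0]] == "ry" else "DNA"
        step = cols[1] - cols[0] if len(cols) > 1 else 1
        contiguous = all(b - a == step for a, b in zip(cols, cols[1:]))
        if contiguous and step in (1, 3):
            span = f"{cols[0] + 1}-{cols[-1] + 1}"
            if step == 3:
                span += "\\3"
        else:
            span = ", ".join(str(c + 1) for c in cols)
        lines.append(f"{model}, {block.name} = {span}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_nexus_charsets(blocks: list[DataBlock], path: str | Path) -> None:
    """NEXUS sets block with one charset per data block."""
    lines = ["#NEXUS", "begin sets;"]
    for block in blocks:
        cols = list(block.columns)
        step = cols[1] - cols[0] if len(cols) > 1 else 1
        contiguous = all(b - a == step for a, b in zip(cols, cols[1:]))
        if contiguous and step == 1:
            span = f"{cols[0] + 1}-{cols[-1] + 1}"
        elif contiguous and step == 3:
            span = f"{cols[0] + 1}-{cols[-1] + 1}\\3"
        else:
            span = " ".join(str(c + 1) for c in cols)
        lines.append(f"    charset {block.name} = {span};")
    lines.append("end;")
    Path(path).write_text("\n".join(lines) + "\n")


def read_raxml_partitions(path: str | Path) -> list[DataBlock]:
    blocks = []
    for line in Path(path).read_text().strip().split("\n"):
        head, spans = line.split("=", 1)
        name = head.split(",", 1)[1].strip()
        cols: list[int] = []
        for span in spans.split(","):
            span = span.strip()
            step = 1
            if "\\" in span:
                span, step_s = span.split("\\")
                step = int(step_s)
            if "-" in span:
                lo, hi = map(int, span.split("-"))
                cols.extend(range(lo - 1, hi, step))
            else:
                cols.append(int(span) - 1)
        blocks.append(DataBlock(name, tuple(cols)))
    return blocks
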