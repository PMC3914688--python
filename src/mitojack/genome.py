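"""Annotated circular mitochondrial genomes: data model, I/O, gene order.

Internal coordinates are 0-based half-open on the deposited strand, which is
taken to be the majority (J) strand.  All file I/O (GenBank, feature-table
TSV) uses the 1-based inclusive convention.  Origin-spanning features are
stored with ``end < start`` and handled by modular arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

from . import pancrustacea

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "AT_rich_region")


class AnnotationError(ValueError):
    """Malformed or out-of-range annotation."""


class CodonClassificationError(ValueError):
    """Terminal residue of a CDS matches no start/stop class."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene on a circular genome, on the deposited-strand coordinates.

    ``strand`` is "J" (deposited strand) or "N" (its complement).  ``end`` may
    be smaller than ``start`` for a feature that spans the origin.
    """

    name: str
    strand: str
    start: int
    end: int
    feature_class: str

    def __post_init__(self):
        if self.strand not in ("J", "N"):
            raise AnnotationError(f"strand must be J or N, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(f"unknown feature class {self.feature_class!r}")

    def length(self, genome_length: int) -> int:
        return (self.end - self.start - 1) % genome_length + 1


@dataclass(frozen=True)
class JunctionRecord:
    """Spacer between two genes adjacent in J-strand order (negative = overlap)."""

    upstream_gene: str
    downstream_gene: str
    spacer: int


@dataclass(frozen=True)
class CodonCall:
    """Classified start or stop codon of a protein-coding gene."""

    codon: str
    role: str            # "start" | "stop"
    classification: str  # start: canonical_ATN | noncanonical
                         # stop: complete_TAA | complete_TAG | incomplete_TA | incomplete_T


@dataclass
class CircularGenome:
    id: str
    seq: str
    circular: bool = True
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if not self.seq:
            raise AnnotationError("empty genome sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise AnnotationError(f"non-ACGTN symbols in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def annotation(self, name: str) -> GeneAnnotation:
        for a in self.annotations:
            if a.name == name:
                return a
        raise KeyError(f"gene {name!r} not annotated on {self.id}")

    def has_gene(self, name: str) -> bool:
        return any(a.name == name for a in self.annotations)

    def slice(self, start: int, end: int) -> str:
        """Deposited-strand slice, wrap-aware (end may be <= start)."""
        L = len(self.seq)
        start %= L
        if end > start:
            return self.seq[start:end]
        if not self.circular:
            raise AnnotationError("origin-spanning slice on a linear genome")
        return (self.seq + self.seq)[start : start + (end - start) % L]


def gene_sequence(genome: CircularGenome, gene: str) -> str:
    """Coding-sense sequence of an annotated gene (reverse complement for N)."""
    ann = genome.annotation(gene)
    raw = genome.slice(ann.start, ann.end)
    return reverse_complement(raw) if ann.strand == "N" else raw


def strand_counts(genome: CircularGenome) -> tuple[int, int]:
    """(J, N) gene counts, ignoring an annotated A+T-rich region."""
    genes = [a for a in genome.annotations if a.feature_class != "AT_rich_region"]
    j = sum(1 for a in genes if a.strand == "J")
    return j, len(genes) - j


def linearize_gene_order(
    genome: CircularGenome, anchor: str = "trnI-gau"
) -> tuple[list[tuple[str, str]], bool]:
    """Gene order rotated to start at ``anchor``, following the J strand 5'->3'.

    Returns ``(order, anchor_found)``; if the anchor is missing (cf. the
    L. weberi contig that lacks trnI) the rotation starts at the first
    annotated gene and ``anchor_found`` is False.
    """
    genes = sorted(
        (a for a in genome.annotations if a.feature_class != "AT_rich_region"),
        key=lambda a: a.start,
    )
    if not genes:
        return [], False
    names = [a.name for a in genes]
    found = anchor in names
    k = names.index(anchor) if found else 0
    rotated = genes[k:] + genes[:k]
    return [(a.name, a.strand) for a in rotated], found


def junction_table(genome: CircularGenome) -> list[JunctionRecord]:
    """Signed spacer between each adjacent gene pair, including the wrap junction."""
    genes = sorted(
        (a for a in genome.annotations if a.feature_class != "AT_rich_region"),
        key=lambda a: a.start,
    )
    if len(genes) < 2:
        raise AnnotationError("need at least two annotations for a junction table")
    L = len(genome)
    records = []
    for up, down in zip(genes, genes[1:] + genes[:1]):
        raw = (down.start - up.end) % L
        # choose the representative nearest zero: large positive wrap-arounds
        # are spacers, values just below L are overlaps
        spacer = raw if raw <= L // 2 else raw - L
        records.append(JunctionRecord(up.name, down.name, spacer))
    return records


def at_rich_region(genome: CircularGenome) -> tuple[str, str, int]:
    """(upstream gene, downstream gene, length) of the A+T-rich region.

    Uses the explicit annotation when present, else the largest junction
    spacer (conventionally the rrnS -> trnI span).
    """
    for a in genome.annotations:
        if a.feature_class == "AT_rich_region":
            recs = junction_table(genome)
            return ("", a.name, a.length(len(genome)))
    best = max(junction_table(genome), key=lambda r: r.spacer)
    return (best.upstream_gene, best.downstream_gene, best.spacer)


# --- codon classification ---------------------------------------------------

_START_ATN = re.compile(r"^AT[ACGT]$")


def classify_codons(cds: str) -> tuple[CodonCall, CodonCall]:
    """Classify the start codon and the (possibly incomplete) stop of a CDS.

    The terminal remainder after whole codons decides the stop class: length 0
    with TAA/TAG -> complete, a trailing "TA" -> incomplete_TA, a trailing
    "T" -> incomplete_T (completed to TAA by polyadenylation in vivo).
    """
    cds = cds.upper()
    if len(cds) < 4:
        raise CodonClassificationError("CDS shorter than 4 nt")
    start = cds[:3]
    if "N" in start:
        raise CodonClassificationError(f"ambiguity code in start codon {start!r}")
    start_call = CodonCall(
        start, "start", "canonical_ATN" if _START_ATN.match(start) else "noncanonical"
    )
    rem = len(cds) % 3
    if rem == 0:
        tail = cds[-3:]
        if "N" in tail:
            raise CodonClassificationError(f"ambiguity code in stop codon {tail!r}")
        if tail == "TAA":
            stop_call = CodonCall(tail, "stop", "complete_TAA")
        elif tail == "TAG":
            stop_call = CodonCall(tail, "stop", "complete_TAG")
        else:
            raise CodonClassificationError(f"terminal codon {tail!r} is not a stop")
    elif rem == 2:
        tail = cds[-2:]
        if tail != "TA":
            raise CodonClassificationError(f"2-nt remainder {tail!r} is not 'TA'")
        stop_call = CodonCall(tail, "stop", "incomplete_TA")
    else:
        tail = cds[-1:]
        if tail != "T":
            raise CodonClassificationError(f"1-nt remainder {tail!r} is not 'T'")
        stop_call = CodonCall(tail, "stop", "incomplete_T")
    return start_call, stop_call


# --- GenBank I/O ------------------------------------------------------------

_TRNA_BY_AA = {
    "Ala": "trnA-ugc", "Arg": "trnR-ucg", "Asn": "trnN-guu", "Asp": "trnD-guc",
    "Cys": "trnC-gca", "Gln": "trnQ-uug", "Glu": "trnE-uuc", "Gly": "trnG-ucc",
    "His": "trnH-gug", "Ile": "trnI-gau", "Lys": "trnK-cuu", "Met": "trnM-cau",
    "Phe": "trnF-gaa", "Pro": "trnP-ugg", "Thr": "trnT-ugu", "Trp": "trnW-uca",
    "Tyr": "trnY-gua", "Val": "trnV-uac",
}

_PCG_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4", "nd4l": "nad4l",
    "nd5": "nad5", "nd6": "nad6", "cox1": "cox1", "coi": "cox1", "co1": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "cox3": "cox3",
    "coiii": "cox3", "co3": "cox3", "cytb": "cob", "cob": "cob", "atp6": "atp6",
    "atp8": "atp8", "nad1": "nad1", "nad2": "nad2", "nad3": "nad3",
    "nad4": "nad4", "nad4l": "nad4l", "nad5": "nad5", "nad6": "nad6",
}


def _canonical_pcg(label: str) -> str | None:
    key = _PCG_ALIASES.get(label.replace("-", "").replace("_", "").lower())
    if key == "nad4l":
        return "nad4L"
    return key


def _trna_symbol(feature: SeqFeature) -> str | None:
    product = (feature.qualifiers.get("product", [""])[0] or "").strip()
    gene_q = (feature.qualifiers.get("gene", [""])[0] or "").strip()
    if gene_q.startswith("trn"):
        return gene_q
    m = re.match(r"tRNA[- ]([A-Za-z]{3})", product)
    if not m:
        return None
    aa = m.group(1).capitalize()
    anticodon = None
    for q in ("anticodon", "note"):
        for val in feature.qualifiers.get(q, []):
            am = re.search(r"(?:seq:|anticodon[:=]?\s*)([acgtu]{3})", val, re.I)
            if am:
                anticodon = am.group(1).lower().replace("t", "u")
    if aa == "Leu":
        return f"trnL-{anticodon}" if anticodon in ("uaa", "uag") else "trnL-uaa"
    if aa == "Ser":
        return f"trnS-{anticodon}" if anticodon in ("gcu", "uga") else "trnS-gcu"
    return _TRNA_BY_AA.get(aa)


def _rrna_symbol(feature: SeqFeature) -> str | None:
    text = " ".join(
        feature.qualifiers.get("product", []) + feature.qualifiers.get("gene", [])
    ).lower()
    if "12s" in text or "small" in text or "rrns" in text or "s-rrna" in text:
        return "rrnS"
    if "16s" in text or "large" in text or "rrnl" in text or "l-rrna" in text:
        return "rrnL"
    return None


def _location_bounds(feature: SeqFeature, length: int) -> tuple[int, int]:
    loc = feature.location
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    start = int(parts[0].start)
    end = int(parts[-1].end)
    if start >= length or end > length:
        raise AnnotationError(
            f"feature {feature.type} at {loc} exceeds sequence length {length}"
        )
    return start, end


def read_genbank(path: str | Path) -> CircularGenome:
    """Read a GenBank flatfile into a :class:`CircularGenome`.

    CDS/tRNA/rRNA features are mapped to controlled gene symbols; minus-strand
    features are stored with strand "N" on deposited-strand coordinates.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise AnnotationError(f"malformed GenBank record in {path}: {exc}") from exc
    circular = record.annotations.get("topology", "circular") != "linear"
    genome = CircularGenome(record.id or path.stem, str(record.seq), circular)
    for feat in record.features:
        if feat.type == "CDS":
            label = feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
            name = _canonical_pcg(label)
            fclass = "PCG"
        elif feat.type == "tRNA":
            name = _trna_symbol(feat)
            fclass = "tRNA"
        elif feat.type == "rRNA":
            name = _rrna_symbol(feat)
            fclass = "rRNA"
        elif feat.type in ("misc_feature", "D-loop"):
            text = " ".join(sum(feat.qualifiers.values(), [])).lower()
            if "a+t" not in text and "control region" not in text and feat.type != "D-loop":
                continue
            name, fclass = "AT_rich_region", "AT_rich_region"
        else:
            continue
        if name is None:
            continue
        start, end = _location_bounds(feat, len(genome))
        strand = "N" if feat.location.strand == -1 else "J"
        genome.annotations.append(GeneAnnotation(name, strand, start, end, fclass))
    return genome


def write_genbank(genome: CircularGenome, path: str | Path) -> None:
    """Write a minimal GenBank flatfile (round-trips through read_genbank)."""
    record = SeqRecord(Seq(genome.seq), id=genome.id, name=genome.id[:16],
                       description="mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    for a in genome.annotations:
        strand = -1 if a.strand == "N" else 1
        if a.end > a.start:
            loc = SimpleLocation(a.start, a.end, strand=strand)
        else:  # origin-spanning
            loc = CompoundLocation(
                [SimpleLocation(a.start, len(genome), strand=strand),
                 SimpleLocation(0, a.end, strand=strand)]
            )
        if a.feature_class == "PCG":
            ftype, quals = "CDS", {"gene": [a.name]}
        elif a.feature_class == "tRNA":
            ftype, quals = "tRNA", {"gene": [a.name], "product": [a.name]}
        elif a.feature_class == "rRNA":
            ftype = "rRNA"
            quals = {"gene": [a.name],
                     "product": ["12S ribosomal RNA" if a.name == "rrnS"
                                 else "16S ribosomal RNA"]}
        else:
            ftype, quals = "misc_feature", {"note": ["A+T-rich region"]}
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


# --- feature-table TSV ------------------------------------------------------

_TSV_HEADER = "genome_id\tgene\tstrand\tstart\tend\tclass"


def write_feature_table(genome: CircularGenome, path: str | Path) -> None:
    """Companion TSV dialect: 1-based inclusive coordinates, strand +/-."""
    lines = [_TSV_HEADER]
    for a in genome.annotations:
        strand = "+" if a.strand == "J" else "-"
        lines.append(
            f"{genome.id}\t{a.name}\t{strand}\t{a.start + 1}\t{a.end}\t{a.feature_class}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path, seq: str, genome_id: str | None = None) -> CircularGenome:
    """Read the companion TSV back (requires the sequence separately)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    if lines[0] != _TSV_HEADER:
        raise AnnotationError(f"bad feature-table header: {lines[0]!r}")
    annotations, gid = [], genome_id
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 6:
            raise AnnotationError(f"line {i}: expected 6 columns, got {len(parts)}")
        row_id, gene, strand, start, end, fclass = parts
        gid = gid or row_id
        annotations.append(
            GeneAnnotation(gene, "J" if strand == "+" else "N",
                           int(start) - 1, int(end), fclass)
        )
    genome = CircularGenome(gid or "genome", seq, True, annotations)
    for a in annotations:
        if not 0 <= a.start < len(genome) or a.end > len(genome):
            raise AnnotationError(f"annotation {a.name} out of range")
    return genome


def is_pancrustacean_order(genome: CircularGenome) -> bool:
    order, _ = linearize_gene_order(genome)
    return [g for g, _ in order] == [g for g, _ in pancrustacea.GENE_ORDER]
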