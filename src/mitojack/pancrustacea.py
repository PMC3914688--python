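"""Reference table for the pancrustacean mitochondrial gene arrangement.

The 37-gene order shared by most crustaceans and hexapods (and by all seven
dipluran mitogenomes compared here), together with per-species start/stop
codons, gene sizes and intergenic spacers for the seven diplurans:

    cf  Campodea fragilis      (NC_008233)
    cl  Campodea lubbocki      (NC_008234)
    lw  Lepidocampa weberi     (JN990601; circular contig, trnI not found)
    os  Octostigma sinensis    (JN990598)
    pe  Parajapyx emeryanus    (JN990599)
    oj  Occasjapyx japonicus   (JN990600)
    js  Japyx solifugus        (NC_007214)

Coordinates of the table are sizes in bp and signed spacers in bp (negative =
overlap with the next gene in J-strand order).  ``None`` marks a value that is
unknown (the missing trnI of L. weberi).  Strand "J" is the majority strand,
"N" the minority strand; 23 genes lie on J and 14 on N.
"""

from __future__ import annotations

from typing import NamedTuple

SPECIES = ("cf", "cl", "lw", "os", "pe", "oj", "js")

ACCESSIONS = {
    "cf": "NC_008233",
    "cl": "NC_008234",
    "lw": "JN990601",
    "os": "JN990598",
    "pe": "JN990599",
    "oj": "JN990600",
    "js": "NC_007214",
}

GENOME_LENGTHS = {
    "cf": 14965,
    "cl": 14974,
    "lw": 14360,  # incomplete contig; ~500 bp of the A+T-rich region missing
    "os": 15122,
    "pe": 15268,
    "oj": 15746,
    "js": 15785,
}


class GeneRow(NamedTuple):
    gene: str
    strand: str            # "J" or "N"
    feature_class: str     # "PCG", "tRNA", "rRNA"
    sizes: tuple           # per species, bp; None = unknown
    spacers: tuple         # to the NEXT gene in J-strand order; None = unknown
    starts: tuple | None   # PCGs only
    stops: tuple | None    # PCGs only; "TA-"/"T-" are incomplete stops


# fmt: off
TABLE = (
    GeneRow("trnI-gau", "J", "tRNA", (62, 61, None, 66, 64, 63, 63), (-3, 7, None, -3, -3, 1, 6), None, None),
    GeneRow("trnQ-uug", "N", "tRNA", (65, 64, 66, 67, 69, 69, 60), (2, 2, 0, 3, -14, 2, -1), None, None),
    GeneRow("trnM-cau", "J", "tRNA", (64, 64, 63, 65, 65, 64, 64), (0, 0, 0, 0, 0, 0, 0), None, None),
    GeneRow("nad2", "J", "PCG", (1005, 1005, 996, 1011, 1014, 1008, 1008), (111, 3, -2, -2, 6, -2, -2),
            ("ATA", "ATT", "ATA", "ATG", "ATG", "ATG", "ATG"),
            ("TAA", "TAA", "TAA", "TAA", "TAA", "TAA", "TAA")),
    GeneRow("trnW-uca", "J", "tRNA", (64, 66, 63, 68, 68, 67, 67), (3, 0, -1, -8, 0, -1, -1), None, None),
    GeneRow("trnC-gca", "N", "tRNA", (62, 53, 62, 61, 61, 61, 62), (-1, 0, 4, 0, 1, -1, -2), None, None),
    GeneRow("trnY-gua", "N", "tRNA", (63, 62, 63, 64, 66, 62, 65), (-8, -5, -5, -3, -5, -5, -9), None, None),
    GeneRow("cox1", "J", "PCG", (1540, 1542, 1542, 1534, 1539, 1539, 1545), (0, -4, -5, 0, 3, 0, 0),
            ("ATT", "ATA", "ATA", "ATT", "TTA", "TTA", "ATC"),
            ("T-", "TAA", "TAA", "T-", "TAA", "TAA", "TAA")),
    GeneRow("trnL-uaa", "J", "tRNA", (64, 63, 61, 62, 63, 65, 62), (0, 1, 0, 0, 0, -1, 0), None, None),
    GeneRow("cox2", "J", "PCG", (679, 684, 682, 682, 679, 679, 679), (0, -6, 0, 0, 0, 0, 0),
            ("ATA", "ATA", "ATT", "ATG", "ATG", "ATG", "ATA"),
            ("T-", "TAA", "T-", "T-", "T-", "T-", "T-")),
    GeneRow("trnK-cuu", "J", "tRNA", (57, 68, 64, 68, 68, 69, 70), (8, -3, -2, -2, 0, -1, -1), None, None),
    GeneRow("trnD-guc", "J", "tRNA", (63, 61, 64, 65, 65, 63, 63), (0, 0, 0, 0, 0, 1, 0), None, None),
    GeneRow("atp8", "J", "PCG", (156, 156, 156, 159, 159, 159, 156), (-7, -7, -7, -7, -4, -7, -4),
            ("ATT", "ATC", "ATC", "ATC", "ATT", "ATT", "ATA"),
            ("TAA", "TAA", "TAA", "TAA", "TAA", "TAA", "TAA")),
    GeneRow("atp6", "J", "PCG", (675, 675, 675, 672, 675, 678, 672), (4, 3, 3, -1, -1, 3, 4),
            ("ATG", "ATG", "ATG", "ATG", "ATA", "ATG", "ATA"),
            ("TAA", "TAA", "TAA", "TAA", "TAA", "TAA", "TAA")),
    GeneRow("cox3", "J", "PCG", (792, 787, 787, 789, 789, 787, 787), (-5, 0, 0, -1, -1, 0, 0),
            ("ATG", "ATG", "ATG", "ATG", "ATG", "ATG", "ATG"),
            ("TAA", "T-", "T-", "TAA", "TAA", "T-", "T-")),
    GeneRow("trnG-ucc", "J", "tRNA", (59, 60, 60, 65, 63, 61, 62), (-3, 0, 1, 0, 0, 0, -3), None, None),
    GeneRow("nad3", "J", "PCG", (357, 347, 354, 354, 354, 352, 355), (-2, 2, -2, -2, -2, 0, 0),
            ("ATA", "ATC", "ATG", "ATC", "ATC", "ATT", "ATA"),
            ("TAA", "TA-", "TAG", "TAG", "TAG", "T-", "T-")),
    GeneRow("trnA-ugc", "J", "tRNA", (62, 60, 60, 64, 61, 62, 62), (0, 0, -1, 5, 0, 2, 1), None, None),
    GeneRow("trnR-ucg", "J", "tRNA", (52, 53, 53, 62, 69, 60, 62), (-3, -3, -1, 6, 4, -1, -3), None, None),
    GeneRow("trnN-guu", "J", "tRNA", (62, 61, 64, 64, 66, 62, 64), (-2, -1, -3, 0, 0, 0, -5), None, None),
    GeneRow("trnS-gcu", "J", "tRNA", (54, 55, 54, 68, 67, 66, 62), (-1, -1, -1, 0, 4, -1, 3), None, None),
    GeneRow("trnE-uuc", "J", "tRNA", (64, 61, 62, 65, 63, 64, 65), (-2, 0, 0, -1, 15, 0, -1), None, None),
    GeneRow("trnF-gaa", "N", "tRNA", (61, 60, 61, 65, 66, 62, 63), (0, 0, 0, -8, -1, 0, 0), None, None),
    GeneRow("nad5", "N", "PCG", (1707, 1710, 1708, 1713, 1734, 1732, 1726), (-1, 0, 0, 0, 1, 0, 7),
            ("ATA", "ATC", "ATT", "TTG", "TTG", "GTG", "ATA"),
            ("TAA", "TAG", "T-", "TAA", "TAA", "T-", "T-")),
    GeneRow("trnH-gug", "N", "tRNA", (64, 60, 62, 64, 64, 62, 60), (-15, -1, 0, 0, 1, 1, 0), None, None),
    GeneRow("nad4", "N", "PCG", (1338, 1328, 1333, 1330, 1344, 1344, 1345), (-7, -7, -7, -7, -7, -7, -7),
            ("ATG", "ATG", "ATG", "ATG", "ATG", "ATG", "ATG"),
            ("TAA", "TA-", "T-", "T-", "TAA", "TAA", "T-")),
    GeneRow("nad4L", "N", "PCG", (285, 285, 288, 288, 288, 294, 294), (8, 5, 5, 2, 5, 2, 2),
            ("ATG", "ATG", "ATG", "ATT", "ATG", "ATG", "ATG"),
            ("TAA", "TAG", "TAA", "TAA", "TAA", "TAA", "TAA")),
    GeneRow("trnT-ugu", "J", "tRNA", (60, 61, 60, 66, 61, 63, 63), (0, 0, -1, 0, 0, 0, -1), None, None),
    GeneRow("trnP-ugg", "N", "tRNA", (67, 63, 61, 65, 63, 63, 62), (2, 2, 1, 2, 2, 2, 2), None, None),
    GeneRow("nad6", "J", "PCG", (510, 525, 507, 504, 510, 510, 510), (-1, -1, -1, -1, -1, -1, -1),
            ("ATT", "ATT", "ATT", "ATA", "ATA", "ATC", "ATC"),
            ("TAA", "TAA", "TAA", "TAA", "TAA", "TAA", "TAA")),
    GeneRow("cob", "J", "PCG", (1143, 1140, 1137, 1132, 1132, 1134, 1132), (-2, -2, -2, 0, 0, -2, 0),
            ("ATG", "ATG", "ATG", "ATG", "ATG", "ATG", "ATG"),
            ("TAA", "TAA", "TAA", "T-", "T-", "TAA", "T-")),
    GeneRow("trnS-uga", "J", "tRNA", (56, 55, 54, 63, 65, 66, 66), (5, 6, 79, 29, 4, 21, 23), None, None),
    GeneRow("nad1", "N", "PCG", (924, 921, 921, 952, 933, 936, 936), (0, 0, 1, 23, 15, 2, 139),
            ("ATT", "ATA", "ATT", "ATT", "ATT", "ATG", "ATG"),
            ("TAA", "TAA", "TAA", "T-", "TAG", "TAG", "TAG")),
    GeneRow("trnL-uag", "N", "tRNA", (63, 59, 62, 65, 62, 66, 64), (0, 0, 0, 0, 0, 0, 0), None, None),
    GeneRow("rrnL", "N", "rRNA", (1092, 1096, 1066, 1169, 1289, 1249, 1417), (1, 0, 0, 0, 0, 0, 0), None, None),
    GeneRow("trnV-uac", "N", "tRNA", (62, 61, 60, 65, 71, 65, 69), (0, 0, 0, 0, 0, 0, 0), None, None),
    # the spacer after rrnS (back to trnI) is the A+T-rich region
    GeneRow("rrnS", "N", "rRNA", (722, 740, 700, 773, 764, 755, 742), (558, 621, 212, 668, 578, 1178, 1052), None, None),
)
# fmt: on

#: 37 (gene, strand) pairs in J-strand order starting at trnI-gau.
GENE_ORDER = tuple((row.gene, row.strand) for row in TABLE)

PCG_NAMES = tuple(r.gene for r in TABLE if r.feature_class == "PCG")
TRNA_NAMES = tuple(r.gene for r in TABLE if r.feature_class == "tRNA")
RRNA_NAMES = tuple(r.gene for r in TABLE if r.feature_class == "rRNA")

#: tRNAs whose D-arm is lost in at least one dipluran, with the 0/1 state per
#: species (1 = D-arm absent).  trnS-gcu (S1) lacks the D-arm in all seven;
#: trnR and trnS-uga (S2) lost it in the three campodeids; trnC only in
#: C. lubbocki.
D_ARM_LOSS = {
    "trnR-ucg": {"cf": 1, "cl": 1, "lw": 1, "os": 0, "pe": 0, "oj": 0, "js": 0},
    "trnC-gca": {"cf": 0, "cl": 1, "lw": 0, "os": 0, "pe": 0, "oj": 0, "js": 0},
    "trnS-gcu": {"cf": 1, "cl": 1, "lw": 1, "os": 1, "pe": 1, "oj": 1, "js": 1},
    "trnS-uga": {"cf": 1, "cl": 1, "lw": 1, "os": 0, "pe": 0, "oj": 0, "js": 0},
}

#: Dipluran subtree recovered by every analysis herein: Rhabdura =
#: (Campodeidae + Octostigma), Dicellurata = Japygoidea.
DIPLURAN_TREE = "((((cf,cl),lw),os),((oj,js),pe));"


def strand_counts() -> tuple[int, int]:
    """Number of (J, N) genes in the pancrustacean arrangement."""
    j = sum(1 for _, s in GENE_ORDER if s == "J")
    return j, len(GENE_ORDER) - j


def junction_spacers(upstream: str, downstream: str) -> tuple:
    """Per-species spacer between two genes adjacent in the template order."""
    genes = [r.gene for r in TABLE]
    i = genes.index(upstream)
    j = genes.index(downstream)
    if (i + 1) % len(genes) != j:
        raise ValueError(f"{upstream} and {downstream} are not adjacent")
    return TABLE[i].spacers
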