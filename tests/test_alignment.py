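"""Supermatrix preparation: retro-alignment, trimming, concatenation, RY."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitojack.alignment import (ColumnLabel, DataBlock, SiteMatrix, TrimParams,
                                concatenate, read_raxml_partitions, retroalign,
                                ry_recode, split_codon_blocks, translate_mito,
                                trim_blocks, write_raxml_partitions)


def aa_matrix(taxa, rows, gene="cox1"):
    labels = [ColumnLabel(gene, "1", i) for i in range(len(rows[0]))]
    data = np.array([list(r) for r in rows], dtype="<U1")
    return SiteMatrix(list(taxa), data, labels, ["aa"] * len(rows[0]))


class TestRetroalign:
    def test_gap_expansion(self):
        aa = aa_matrix(["t1", "t2"], ["MK", "M-"])
        out = retroalign(aa, {"t1": "ATGAAA", "t2": "ATG"})
        assert out.row("t1") == "ATGAAA"
        assert out.row("t2") == "ATG---"
        assert [l.codon_position for l in out.labels] == ["1", "2", "3"] * 2

    def test_terminal_stops_excluded(self):
        aa = aa_matrix(["t1"], ["MK"])
        for stop in ("TAA", "TAG", "TA", "T"):
            out = retroalign(aa, {"t1": "ATGAAA" + stop})
            assert out.row("t1") == "ATGAAA"

    def test_degap_round_trip_and_translation(self, rng):
        # random CDSs, trivially aligned (no gaps)
        from mitojack.simulate import GenomeRecipe, _pcg_sequence, base_probabilities
        probs = base_probabilities(0.6, 0.0, 0.0)
        recipe = GenomeRecipe()
        cds = {}
        rows = []
        for t in ("a", "b", "c"):
            s, _, _ = _pcg_sequence(rng, 120, probs, recipe, force_stop="TAA")
            cds[t] = s
            rows.append(translate_mito(s[:-3]))
        aa = aa_matrix(["a", "b", "c"], rows)
        out = retroalign(aa, cds)
        for t in ("a", "b", "c"):
            assert out.row(t).replace("-", "") == cds[t][:-3]
        # every codon column triple translates back to the aa column
        for i in range(aa.n_columns):
            for ti, t in enumerate(out.taxa):
                codon = "".join(out.data[ti, 3 * i : 3 * i + 3])
                assert translate_mito(codon) == aa.data[ti, i]

    def test_translation_mismatch_names_taxon_and_position(self):
        aa = aa_matrix(["t1"], ["MM"])
        with pytest.raises(ValueError, match="t1.*position 2"):
            retroalign(aa, {"t1": "ATGAAA"})  # AAA is K, not M

    def test_missing_cds(self):
        aa = aa_matrix(["t1"], ["M"])
        with pytest.raises(ValueError, match="no CDS"):
            retroalign(aa, {})


def reference_trim(matrix, t1, t2, min_block, gmax, codon):
    """Independent straightforward rescan of the trimming rules."""
    n = matrix.n_taxa
    ncol = matrix.n_columns
    def col_stats(i):
        col = list(matrix.data[:, i])
        gaps = sum(c in "-?" for c in col) / n
        states = [c for c in col if c not in "-?"]
        maj = max((states.count(s) for s in set(states)), default=0) / n
        return maj, gaps
    unit = 3 if codon else 1
    units = ncol // unit
    ok, flank = [], []
    for u in range(units):
        stats = [col_stats(u * unit + j) for j in range(unit)]
        ok.append(all(m >= t1 and g <= gmax for m, g in stats))
        flank.append(all(m >= t2 and g <= gmax for m, g in stats))
    keep = [False] * units
    u = 0
    while u < units:
        if not ok[u]:
            u += 1
            continue
        v = u
        while v < units and ok[v]:
            v += 1
        lo, hi = u, v
        while lo < hi and not flank[lo]:
            lo += 1
        while hi > lo and not flank[hi - 1]:
            hi -= 1
        if hi - lo >= min_block:
            for w in range(lo, hi):
                keep[w] = True
        u = v
    cols = [u * unit + j for u in range(units) if keep[u] for j in range(unit)]
    return cols


class TestTrimBlocks:
    def test_conserved_gapless_matrix_unchanged(self):
        m = SiteMatrix.from_sequences(["a", "b", "c"], ["ACGTAC" * 6] * 3, "g")
        out = trim_blocks(m, TrimParams(min_block=2))
        assert out.n_columns == m.n_columns
        assert out.labels == m.labels

    def test_all_gap_codon_removed(self):
        rows = ["ACGTTT" * 10 + "---", "ACGTTT" * 10 + "---",
                "ACGTTT" * 10 + "---"]
        m = SiteMatrix.from_sequences(["a", "b", "c"], rows, "g")
        out = trim_blocks(m, TrimParams(min_block=2, gmax=0.0))
        assert out.n_columns == 60

    def test_labels_are_a_subsequence(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), size=90)) for _ in range(6)]
        m = SiteMatrix.from_sequences(list("abcdef"), rows, "g")
        out = trim_blocks(m, TrimParams(min_block=1, gmax=0.5))
        it = iter(m.labels)
        assert all(l in it for l in out.labels)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_rescan(self, seed):
        rng = np.random.default_rng(seed)
        # mix of conserved and noisy codon stretches
        ncod = 40
        base = rng.choice(list("ACGT"), size=3 * ncod)
        rows = []
        for _ in range(10):
            row = base.copy()
            noisy = rng.random(3 * ncod) < 0.4
            row[noisy] = rng.choice(list("ACGT-"), size=noisy.sum())
            rows.append("".join(row))
        m = SiteMatrix.from_sequences([f"t{i}" for i in range(10)], rows, "g")
        params = TrimParams(t1=0.6, t2=0.85, min_block=3, gmax=0.1)
        out = trim_blocks(m, params)
        expected = reference_trim(m, 0.6, 0.85, 3, 0.1, codon=True)
        assert [l.coordinate for l in out.labels] == expected


class TestConcatenate:
    def test_widths_additive_and_blocks_partition(self):
        m1 = SiteMatrix.from_sequences(["a", "b"], ["ACG", "ACG"], "g1")
        m2 = SiteMatrix.from_sequences(["a", "b"], ["TTTTTT", "TTTTTT"], "g2")
        cat, blocks = concatenate([m1, m2])
        assert cat.n_columns == 9
        cols = sorted(c for b in blocks for c in b.columns)
        assert cols == list(range(9))

    def test_missing_taxon_filled(self):
        m1 = SiteMatrix.from_sequences(["a", "b"], ["ACG", "ACG"], "g1")
        m2 = SiteMatrix.from_sequences(["a"], ["TTT"], "g2")
        cat, _ = concatenate([m1, m2])
        assert cat.row("b") == "ACG???"

    def test_duplicate_taxon_rejected(self):
        m = SiteMatrix.from_sequences(["a", "a"], ["ACG", "ACG"], "g1")
        with pytest.raises(ValueError, match="duplicate"):
            concatenate([m])

    @given(st.integers(2, 5), st.integers(1, 4), st.integers(0, 6))
    @settings(max_examples=25, deadline=None)
    def test_block_bookkeeping_fuzz(self, n_taxa, n_genes, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(n_taxa)]
        mats = []
        for g in range(n_genes):
            width = int(rng.integers(1, 5)) * 3
            present = [t for t in taxa if rng.random() < 0.8] or taxa[:1]
            rows = ["".join(rng.choice(list("ACGT"), size=width))
                    for _ in present]
            mats.append(SiteMatrix.from_sequences(present, rows, f"g{g}"))
        cat, blocks = concatenate(mats)
        cols = sorted(c for b in blocks for c in b.columns)
        assert cols == list(range(cat.n_columns))
        assert len({c for b in blocks for c in b.columns}) == cat.n_columns

    def test_pcg_rrna_split_gives_28_blocks(self):
        pcgs = ["atp6", "atp8", "cox1", "cox2", "cox3", "cob", "nad1", "nad2",
                "nad3", "nad4", "nad4L", "nad5", "nad6"]
        mats = [SiteMatrix.from_sequences(["a", "b"], ["ATGAAA"] * 2, g)
                for g in pcgs]
        mats += [SiteMatrix.from_sequences(["a", "b"], ["ACGT"] * 2, g, "rRNA")
                 for g in ("rrnS", "rrnL")]
        cat, blocks = concatenate(mats)
        split = split_codon_blocks(cat, blocks, positions=(1, 2),
                                   drop_other_positions=True)
        assert len(split) == 28

class TestRYRecode:
    def test_third_position_recode(self):
        m = SiteMatrix.from_sequences(["a"], ["ATG"], "g")
        out = ry_recode(m, {3})
        assert out.row("a") == "ATR"
        assert out.alphabets == ["nt", "nt", "ry"]

    def test_recode_all_positions(self):
        m = SiteMatrix.from_sequences(["a"], ["ACGT"], "g")
        out = ry_recode(m, {1, 2, 3})
        assert out.row("a") == "RYRY"

    def test_idempotent_and_shape_preserving(self, rng):
        rows = ["".join(rng.choice(list("ACGT-N"), size=30)) for _ in range(4)]
        m = SiteMatrix.from_sequences(list("abcd"), rows, "g")
        once = ry_recode(m, {1, 3})
        twice = ry_recode(once, {1, 3})
        assert (once.data == twice.data).all()
        assert once.data.shape == m.data.shape
        assert ((m.data == "-") == (once.data == "-")).all()

    def test_ambiguity_codes(self):
        m = SiteMatrix.from_sequences(["a"], ["RWN-"], "g")
        out = ry_recode(m, {1, 2, 3})
        # R stays R; W and N cross classes -> missing; gap preserved
        assert out.row("a")[:3] == "R??"
        assert out.row("a")[3] == "-"

    def test_rejects_rrna_positions(self):
        m = SiteMatrix.from_sequences(["a"], ["ACGT"], "g", codon_position="rRNA")
        with pytest.raises(ValueError):
            ry_recode(m, {"rRNA"})


class TestPartitionFiles:
    def test_round_trip(self, tmp_path, toy_matrix):
        blocks = [DataBlock("g_pos1", (0, 3)), DataBlock("g_pos2", (1, 4)),
                  DataBlock("g_rest", (2, 5))]
        path = tmp_path / "parts.txt"
        write_raxml_partitions(blocks, toy_matrix, path)
        back = read_raxml_partitions(path)
        assert [(b.name, tuple(b.columns)) for b in back] == \
               [(b.name, tuple(b.columns)) for b in blocks]

    def test_phylip_round_trip(self, tmp_path, toy_matrix):
        path = tmp_path / "m.phy"
        toy_matrix.write_phylip(path)
        back = SiteMatrix.read_phylip(path)
        assert back.taxa == toy_matrix.taxa
        assert (back.data == toy_matrix.data).all()
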