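"""Genomic-block karyotype algebra: parsing, WGD/NCI/inversion, detection."""

import numpy as np
import pytest

from ksphase.karyotype import (
    CANONICAL_BLOCKS,
    Karyotype,
    block_copy_numbers,
    invert_segment,
    load_preset,
    match_ancestral,
    nested_chromosome_insertion,
    parse_block,
    parse_karyotype,
    ploidy_call,
    serialize_karyotype,
    whole_genome_duplication,
)


class TestParsing:
    def test_round_trip_simple(self):
        text = "AK2: D | E .\n"
        k = parse_karyotype(text)
        assert serialize_karyotype(k) == text
        assert k.n == 1
        assert k["AK2"].centromere == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="malformed|unknown"):
            parse_karyotype("c1: Z9 | A .")
        with pytest.raises(ValueError):
            parse_block("K")  # bare K invalid: K-L is one block

    def test_signs_subblocks_comments(self):
        k = parse_karyotype("# comment\nc1: -Wa K-L | -M-N X . # trailing\n")
        blocks = k["c1"].blocks
        assert [str(b) for b in blocks] == ["-Wa", "K-L", "-M-N", "X"]

    def test_malformed_lines(self):
        for bad in ("c1: A B C .", "c1: A | B", "c1 A | B .", "c1: A | B | C ."):
            with pytest.raises(ValueError):
                parse_karyotype(bad)

    def test_presets_parse(self):
        ack = load_preset("ACK_Cardamineae_n8")
        ra = load_preset("R_aquatica_n15")
        assert ack.n == 8
        assert ra.n == 15

    def test_round_trip_random_karyotypes(self):
        rng = np.random.default_rng(77)
        labels = list(CANONICAL_BLOCKS)
        for trial in range(200):
            n_chrom = rng.integers(1, 5)
            chroms = []
            for i in range(n_chrom):
                n_blocks = int(rng.integers(1, 6))
                toks = []
                for _ in range(n_blocks):
                    lab = labels[rng.integers(len(labels))]
                    if lab == "W":
                        lab += ["", "a", "b"][rng.integers(3)]
                    sign = "-" if rng.random() < 0.5 else ""
                    toks.append(sign + lab)
                cent = int(rng.integers(0, n_blocks + 1))
                toks.insert(cent, "|")
                chroms.append(f"c{i}: " + " ".join(toks) + " .")
            text = "\n".join(chroms) + "\n"
            assert serialize_karyotype(parse_karyotype(text)) == text


class TestWGD:
    def test_doubles_chromosome_number(self):
        ack = load_preset("ACK_Cardamineae_n8")
        assert whole_genome_duplication(ack).n == 16

    def test_empty(self):
        assert whole_genome_duplication(Karyotype(())).n == 0

    def test_block_copy_numbers_double(self):
        ack = load_preset("ACK_Cardamineae_n8")
        before = block_copy_numbers(ack)
        after = block_copy_numbers(whole_genome_duplication(ack))
        assert after == {b: 2 * c for b, c in before.items()}


class TestNCI:
    def test_reproduces_fusion_chromosome(self):
        k = parse_karyotype("rec: O P | Wb X .\ndon: D | E .")
        fused = nested_chromosome_insertion(k, "rec", "don", "inverted")
        assert fused.n == 1
        assert [str(b) for b in fused["rec"].blocks] == ["O", "P", "-E", "-D", "Wb", "X"]

    def test_chromosome_number_drops_by_one(self):
        doubled = whole_genome_duplication(load_preset("ACK_Cardamineae_n8"))
        after = nested_chromosome_insertion(doubled, "AK8/6_1", "AK2_1")
        assert doubled.n == 16 and after.n == 15

    def test_block_content_conserved(self):
        doubled = whole_genome_duplication(load_preset("ACK_Cardamineae_n8"))
        after = nested_chromosome_insertion(doubled, "AK8/6_1", "AK2_1")
        assert block_copy_numbers(after) == block_copy_numbers(doubled)

    def test_errors(self):
        k = parse_karyotype("rec: O P | Wb X .\ndon: D | E .\nterm: | A B .")
        with pytest.raises(ValueError, match="different"):
            nested_chromosome_insertion(k, "rec", "rec")
        with pytest.raises(ValueError, match="terminal"):
            nested_chromosome_insertion(k, "term", "don")
        with pytest.raises(KeyError):
            nested_chromosome_insertion(k, "rec", "nope")


class TestInversion:
    def test_definition(self):
        k = parse_karyotype("c: O P E D | Wb X .")
        inv = invert_segment(k["c"], 2, 3)
        assert [str(b) for b in inv.blocks] == ["O", "P", "-D", "-E", "Wb", "X"]

    def test_involution(self):
        k = parse_karyotype("c: O -P E | D .")
        twice = invert_segment(invert_segment(k["c"], 1, 2), 1, 2)
        assert twice == k["c"]

    def test_paracentric_guard(self):
        k = parse_karyotype("c: O P | Wb X .")
        with pytest.raises(ValueError, match="centromere"):
            invert_segment(k["c"], 1, 2, paracentric=True)
        # same span allowed in unrestricted mode
        invert_segment(k["c"], 1, 2)

    def test_index_validation(self):
        k = parse_karyotype("c: O P | Wb X .")
        with pytest.raises(ValueError):
            invert_segment(k["c"], 2, 9)


class TestCopyNumbers:
    def test_ack_all_single(self):
        counts = block_copy_numbers(load_preset("ACK_Cardamineae_n8"))
        assert set(counts) == set(CANONICAL_BLOCKS)
        assert all(v == 1 for v in counts.values())

    def test_r_aquatica_all_duplicated(self):
        counts = block_copy_numbers(load_preset("R_aquatica_n15"))
        assert set(counts) == set(CANONICAL_BLOCKS)
        assert all(v == 2 for v in counts.values())
        assert ploidy_call(load_preset("R_aquatica_n15")) == "tetraploid-origin"

    def test_w_halves_combine(self):
        k = parse_karyotype("c1: Wa | A .\nc2: Wb | B .")
        assert block_copy_numbers(k)["W"] == 1.0


class TestMatchAncestral:
    def test_self_match_all_shared(self):
        ack = load_preset("ACK_Cardamineae_n8")
        res = match_ancestral(ack, ack)
        assert res.n_shared == 8 and res.n_derived == 0
        assert res.events == []

    def test_r_aquatica_vs_cardamineae(self):
        res = match_ancestral(
            load_preset("R_aquatica_n15"), load_preset("ACK_Cardamineae_n8")
        )
        assert res.n_shared == 14 and res.n_derived == 1
        assert res.classifications["RaChr15"] == "derived"
        assert len(res.events) == 1
        event = res.events[0]
        assert event.kind == "NCI"
        assert event.detail["donor"] == "AK2"
        assert event.detail["recipient"] == "AK8/6"

    def test_shared_call_ignores_inversions(self):
        ack = load_preset("ACK_Cardamineae_n8")
        k = Karyotype(
            tuple(
                invert_segment(c, 0, len(c.blocks) - 1) for c in ack.chromosomes
            )
        )
        res = match_ancestral(k, ack)
        assert res.n_shared == 8


def _random_disjoint_karyotype(rng):
    """Random karyotype whose chromosomes have disjoint block contents."""
    labels = [b for b in CANONICAL_BLOCKS if b != "W"]
    rng.shuffle(labels)
    chroms = []
    i = 0
    cid = 0
    while i + 2 <= len(labels) and cid < 5:
        take = int(rng.integers(2, 4))
        blocks = labels[i : i + take]
        i += take
        cent = int(rng.integers(1, len(blocks)))  # internal centromere
        toks = list(blocks)
        toks.insert(cent, "|")
        chroms.append(f"k{cid}: " + " ".join(toks) + " .")
        cid += 1
    return parse_karyotype("\n".join(chroms))


def test_wgd_then_nci_detector_duality():
    """Constructor/detector round trip on random karyotypes.

    After WGD plus one random valid NCI, matching against the original
    ancestor finds exactly one NCI event with the right donor/recipient,
    and n == 2 n0 - 1.
    """
    rng = np.random.default_rng(1234)
    for _ in range(25):
        k0 = _random_disjoint_karyotype(rng)
        if k0.n < 2:
            continue
        doubled = whole_genome_duplication(k0)
        ids = doubled.ids()
        internal = [c.id for c in doubled.chromosomes if c.centromere_is_internal]
        recipient = internal[rng.integers(len(internal))]
        donor = rng.choice([i for i in ids if i != recipient])
        orientation = ["forward", "inverted"][rng.integers(2)]
        after = nested_chromosome_insertion(doubled, recipient, donor, orientation)
        assert after.n == 2 * k0.n - 1
        res = match_ancestral(after, k0)
        assert res.n_derived == 1
        assert len(res.events) == 1
        ev = res.events[0]
        assert ev.detail["donor"] == donor.rsplit("_", 1)[0]
        assert ev.detail["recipient"] == recipient.rsplit("_", 1)[0]
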