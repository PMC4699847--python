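"""In-silico PCR, digestion, decoding and colony classification."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddt_assay._dna import revcomp
from ddt_assay.construct_model import LAYOUT_NAMES
from ddt_assay.molecular_readout import (
    ENZYMES,
    DecodingError,
    DigestPattern,
    DiscordantColonyError,
    Enzyme,
    EventClass,
    PCRError,
    classify_colony,
    decode_fasta,
    decode_genotype,
    digest,
    find_sites,
    genotype_pattern_map,
    pcr_amplify,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


@pytest.mark.parametrize(
    "seq,enzyme,expected",
    [
        ("GCAAGTTAACACG", "HincII", [5]),   # TT-lesion context
        ("ATCACCGGCGCCACA", "NarI", [7]),   # G-AAF context
        ("AAAA", "PvuII", []),
        ("AATATTAATATT", "SspI", [1, 7]),
        ("AATATATT", "SspI", []),
    ],
)
def test_find_sites_examples(seq, enzyme, expected):
    assert find_sites(seq, ENZYMES[enzyme]) == expected


def test_find_sites_rejects_bad_characters():
    with pytest.raises(ValueError, match="invalid DNA"):
        find_sites("ACGTN", ENZYMES["SspI"])


@settings(derandomize=True, max_examples=100)
@given(seq=dna, enzyme=st.sampled_from(sorted(ENZYMES)))
def test_find_sites_matches_bruteforce_scan(seq, enzyme):
    """Overlap-aware motif scan agrees with an all-positions brute force."""
    from ddt_assay._dna import IUPAC

    motif = ENZYMES[enzyme].recognition_motif
    brute = [
        i + 1
        for i in range(len(seq) - len(motif) + 1)
        if all(seq[i + j] in IUPAC[m] for j, m in enumerate(motif))
    ]
    assert find_sites(seq, ENZYMES[enzyme]) == brute


def test_enzyme_validation():
    with pytest.raises(ValueError):
        Enzyme("tiny", "ACG", 1)
    with pytest.raises(ValueError):
        Enzyme("off", "ACGTAC", 7)


def test_digest_single_cut_arithmetic():
    # one PvuII site cutting after position 40 of a 100-mer
    seq = "A" * 37 + "CAGCTG" + "A" * 57
    assert digest(seq, ["PvuII"]).key == (40, 60)


def test_digest_no_sites_returns_whole_molecule():
    seq = "ACGT" * 25
    assert digest(seq, ["SspI", "PvuII"]).key == (100,)


def test_digest_pattern_requires_conservation():
    with pytest.raises(ValueError):
        DigestPattern((10, 20), 100)


@settings(derandomize=True, max_examples=100)
@given(seq=st.text(alphabet="ACGT", min_size=1, max_size=300),
       names=st.lists(st.sampled_from(sorted(ENZYMES)), min_size=1, max_size=3))
def test_digest_conserves_length(seq, names):
    pattern = digest(seq, names)
    assert sum(pattern.fragment_lengths) == len(seq) == pattern.total_length
    assert all(f > 0 for f in pattern.fragment_lengths)


@pytest.mark.parametrize("layout,length", [("pLL1_2c", 506), ("pLL1_7", 506),
                                           ("pLL4_5", 1100), ("pLL9_2c", 2283)])
def test_pcr_product_lengths(constructs, layout, length):
    c = constructs[layout]
    product = pcr_amplify(c.daughter_sequence(c.undamaged_genotype), *c.primers)
    assert len(product) == length
    assert product.startswith(c.primers[0])
    assert product.endswith(revcomp(c.primers[1]))


def test_pcr_amplify_works_from_either_strand(pll1_2c):
    daughter = pll1_2c.daughter_sequence(("A", "B"))
    fwd, rev = pll1_2c.primers
    assert pcr_amplify(revcomp(daughter), fwd, rev) == pcr_amplify(daughter, fwd, rev)


def test_pcr_errors(pll1_2c):
    daughter = pll1_2c.daughter_sequence(("A", "B"))
    fwd, rev = pll1_2c.primers
    with pytest.raises(PCRError, match="exactly once"):
        pcr_amplify(daughter, "ACGTACGTACGTACGT", rev)  # absent primer
    with pytest.raises(PCRError, match="exactly once"):
        pcr_amplify(daughter + daughter, fwd, rev)      # two binding sites
    with pytest.raises(PCRError, match="divergent"):
        pcr_amplify(daughter, revcomp(rev), revcomp(fwd))


def test_digest_patterns_distinguish_hdgr_from_loss(pll1_2c):
    """The C+B (blue) and A+B (white) daughters give different gel patterns."""
    fwd, rev = pll1_2c.primers
    patterns = {
        g: digest(pcr_amplify(pll1_2c.daughter_sequence(g), fwd, rev),
                  pll1_2c.digest_enzymes)
        for g in (("C", "B"), ("A", "B"))
    }
    assert patterns[("C", "B")] != patterns[("A", "B")]


@pytest.mark.parametrize("layout", LAYOUT_NAMES)
def test_decoder_roundtrip_exhaustive(constructs, layout):
    """Every transmitted allele combination is recovered from its digest."""
    c = constructs[layout]
    fwd, rev = c.primers
    for genotype in c.genotypes():
        amplicon = pcr_amplify(c.daughter_sequence(genotype), fwd, rev)
        pattern = digest(amplicon, c.digest_enzymes)
        assert decode_genotype(pattern, c) == genotype


def test_decode_rejects_unknown_pattern(pll1_2c):
    with pytest.raises(DecodingError, match="no genotype"):
        decode_genotype(DigestPattern((1, 505), 506), pll1_2c)


def test_pattern_map_is_injective(constructs):
    for c in constructs.values():
        mapping = genotype_pattern_map(c)
        assert len(mapping) == 2 ** len(c.markers)


@pytest.mark.parametrize(
    "phenotype,genotypes,expected",
    [
        ("sectored-blue-white", [("C", "B"), ("A", "B")], EventClass.HDGR),
        ("white", [("A", "B")], EventClass.CHROMATID_LOSS),
        ("pale-blue", [("C", "D")], EventClass.TLS),
        ("pure-blue", [("C", "B")], EventClass.HDGR),
        ("sectored-blue-white", None, EventClass.HDGR),
        ("white", None, EventClass.CHROMATID_LOSS),
        ("dead", None, EventClass.DEAD),
        (None, [("A", "D")], EventClass.CHROMATID_LOSS),
        (None, [("C", "B", "F"), ("A", "B", "E")], EventClass.HDGR),
    ],
)
def test_classify_colony(phenotype, genotypes, expected):
    assert classify_colony(phenotype, genotypes) is expected


def test_classify_discordant_pair_is_flagged():
    with pytest.raises(DiscordantColonyError):
        classify_colony("white", [("C", "B")])
    with pytest.raises(DiscordantColonyError):
        classify_colony("pale-blue", [("C", "B"), ("A", "B")])


def test_classify_requires_some_evidence():
    with pytest.raises(ValueError):
        classify_colony(None, None)
    with pytest.raises(ValueError, match="unknown phenotype"):
        classify_colony("chartreuse", None)


def test_decode_fasta(tmp_path, pll1_2c):
    from ddt_assay.construct_model import write_construct_fasta

    path = tmp_path / "daughters.fasta"
    write_construct_fasta(pll1_2c, path)
    rows = decode_fasta(path, pll1_2c)
    decoded = {r["id"]: r["alleles"] for r in rows}
    # the four homoduplex daughters decode; heteroduplex parents are skipped
    assert decoded["pLL1_2c|daughter|C-B"] == ("C", "B")
    assert decoded["pLL1_2c|daughter|A-D"] == ("A", "D")
    assert len(rows) >= 4
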