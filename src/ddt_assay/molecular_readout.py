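"""In-silico molecular analysis of assay colonies.

The wet protocol amplifies the marker-bearing region from each colony sector,
digests the product with two diagnostic restriction enzymes and reads the
fragment pattern off an agarose gel; the pattern identifies which marker
alleles the sector inherited, and the allele combination identifies the
tolerance event (HDGR, TLS or damaged chromatid loss). This module performs
the same steps on sequences: exact-match PCR, IUPAC-aware site finding,
linear-molecule digestion, pattern -> genotype inversion and colony
classification.

Gel resolution is treated as perfect (any fragment-length difference is
distinguishable) and enzymes as blunt double-strand cutters; both are
adequate because the assay reads patterns qualitatively.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from ._dna import find_motif, revcomp, validate_dna
from .construct_model import ConstructSpec

__all__ = [
    "Enzyme",
    "ENZYMES",
    "DigestPattern",
    "EventClass",
    "PCRError",
    "DecodingError",
    "ConstructDesignError",
    "DiscordantColonyError",
    "find_sites",
    "pcr_amplify",
    "digest",
    "genotype_pattern_map",
    "decode_genotype",
    "classify_colony",
    "decode_fasta",
    "write_colony_calls",
]


class PCRError(ValueError):
    """Primer pair does not define a unique convergent amplicon."""


class DecodingError(ValueError):
    """Digest pattern matches no genotype of the layout."""


class ConstructDesignError(ValueError):
    """Layout is not decodable: two genotypes share a digest pattern."""


class DiscordantColonyError(ValueError):
    """Colony phenotype and decoded genotypes disagree."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease modelled as a blunt double-strand cutter.

    ``cut_offset`` is the number of motif bases left of the cut, so an enzyme
    cuts between positions ``site_start + cut_offset - 1`` and the next base.
    """

    name: str
    recognition_motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition_motif) < 4:
            raise ValueError("recognition motif must be at least 4 bases")
        if not 0 <= self.cut_offset <= len(self.recognition_motif):
            raise ValueError("cut offset must lie within the motif")


ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        Enzyme("SspI", "AATATT", 3),
        Enzyme("PvuII", "CAGCTG", 3),
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("NheI", "GCTAGC", 1),
        Enzyme("BglII", "AGATCT", 1),
        Enzyme("HincII", "GTYRAC", 3),
        Enzyme("NarI", "GGCGCC", 2),
    )
}


@dataclass(frozen=True)
class DigestPattern:
    """Multiset of restriction-fragment lengths from one linear molecule.

    Fragment order on the molecule is not retained: a gel only reports the
    multiset, so lengths are stored sorted and compared as such.
    """

    fragment_lengths: tuple[int, ...]
    total_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_lengths",
                           tuple(sorted(self.fragment_lengths)))
        if sum(self.fragment_lengths) != self.total_length:
            raise ValueError("fragment lengths must sum to the molecule length")

    @property
    def key(self) -> tuple[int, ...]:
        return self.fragment_lengths


class EventClass(enum.Enum):
    """Tolerance-event classes a colony can report."""

    HDGR = "HDGR"
    TLS = "TLS"
    CHROMATID_LOSS = "CHROMATID_LOSS"
    DEAD = "DEAD"


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """1-based start positions of the recognition motif on the given strand.

    Overlapping matches are all reported; the motif may be IUPAC-degenerate.
    """
    validate_dna(seq)
    return find_motif(seq, enzyme.recognition_motif)


def _cut_positions(seq: str, enzyme: Enzyme) -> set[int]:
    """Double-strand cut positions (cut after this 1-based base).

    The primer-bearing strand is scanned with the motif and with its reverse
    complement so sites in either orientation are cut.
    """
    cuts: set[int] = set()
    motif = enzyme.recognition_motif
    for start in find_motif(seq, motif):
        cuts.add(start + enzyme.cut_offset - 1)
    rc = revcomp(motif)
    rc_offset = len(motif) - enzyme.cut_offset
    if rc != motif:
        for start in find_motif(seq, rc):
            cuts.add(start + rc_offset - 1)
    return {c for c in cuts if 0 < c < len(seq)}


def digest(seq: str, enzymes: Iterable[Enzyme | str]) -> DigestPattern:
    """Fragment-length pattern of a complete digest of a linear molecule."""
    validate_dna(seq)
    cuts: set[int] = set()
    for e in enzymes:
        enzyme = ENZYMES[e] if isinstance(e, str) else e
        cuts |= _cut_positions(seq, enzyme)
    bounds = [0, *sorted(cuts), len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestPattern(fragments, len(seq))


def pcr_amplify(template: str, fwd: str, rev: str) -> str:
    """Exact-match PCR product of a convergent primer pair on a duplex.

    *template* is one strand of the duplex, 5'->3'. Each primer must bind the
    duplex exactly once and the pair must converge; the primer-inclusive
    product is returned in the forward primer's orientation.
    """
    validate_dna(template)
    for strand in (template, revcomp(template)):
        n_fwd = strand.count(fwd) + strand.count(revcomp(fwd))
        n_rev = strand.count(rev) + strand.count(revcomp(rev))
        if n_fwd != 1 or n_rev != 1:
            raise PCRError(
                f"primers must each bind exactly once (forward: {n_fwd}, reverse: {n_rev})"
            )
        i = strand.find(fwd)
        j = strand.find(revcomp(rev))
        if i >= 0 and j >= 0:
            if j <= i:
                raise PCRError("primers bind in divergent orientation")
            return strand[i:j + len(rev)]
    raise PCRError("primers bind opposite strands in divergent orientation")


@lru_cache(maxsize=16)
def genotype_pattern_map(construct: ConstructSpec) -> dict[DigestPattern, tuple[str, ...]]:
    """Forward-simulated digest pattern for every daughter genotype, inverted.

    Raises :class:`ConstructDesignError` if two genotypes are indistinguishable
    (the layout would not be decodable on a gel).
    """
    fwd, rev = construct.primers
    mapping: dict[DigestPattern, tuple[str, ...]] = {}
    for genotype in construct.genotypes():
        amplicon = pcr_amplify(construct.daughter_sequence(genotype), fwd, rev)
        pattern = digest(amplicon, construct.digest_enzymes)
        if pattern in mapping:
            raise ConstructDesignError(
                f"{construct.name}: genotypes {mapping[pattern]} and {genotype} "
                f"share digest pattern {pattern.key}"
            )
        mapping[pattern] = genotype
    return mapping


def decode_genotype(pattern: DigestPattern, layout: ConstructSpec) -> tuple[str, ...]:
    """Invert a digest pattern to the unique transmitted allele combination."""
    mapping = genotype_pattern_map(layout)
    try:
        return mapping[pattern]
    except KeyError:
        raise DecodingError(
            f"pattern {pattern.key} matches no genotype of {layout.name}"
        ) from None


PHENOTYPES = ("sectored-blue-white", "pale-blue", "white", "pure-blue", "dead")

_PHENOTYPE_CLASS = {
    "sectored-blue-white": EventClass.HDGR,
    # pure blue: only the gap-repaired daughter formed a colony; still HDGR
    # (tracked as a separate sub-count by the simulator)
    "pure-blue": EventClass.HDGR,
    "pale-blue": EventClass.TLS,
    "white": EventClass.CHROMATID_LOSS,
    "dead": EventClass.DEAD,
}


def _genotype_class(genotypes: Iterable[Sequence[str]]) -> EventClass:
    gts = [tuple(g) for g in genotypes]
    if not gts:
        raise ValueError("no decoded genotypes supplied")
    has = lambda *letters: any(all(l in g for l in letters) for g in gts)
    if has("C", "B"):
        return EventClass.HDGR
    if has("C", "D"):
        return EventClass.TLS
    return EventClass.CHROMATID_LOSS


def classify_colony(phenotype: str | None,
                    genotypes: Iterable[Sequence[str]] | None = None) -> EventClass:
    """Classify a colony into its tolerance-event class.

    Either the plate phenotype, the decoded sector genotypes, or both may be
    given. A sectored blue/white colony (or any colony with a C+B sector) is
    an HDGR event; pale blue (or C+D) is TLS; pure white with only undamaged-
    strand markers is damaged chromatid loss. Inconsistent phenotype/genotype
    pairs raise :class:`DiscordantColonyError` rather than being silently
    classified.
    """
    if phenotype is None and genotypes is None:
        raise ValueError("phenotype or genotypes required")
    pheno_class = None
    if phenotype is not None:
        try:
            pheno_class = _PHENOTYPE_CLASS[phenotype]
        except KeyError:
            raise ValueError(f"unknown phenotype {phenotype!r}") from None
    if genotypes is None:
        return pheno_class
    geno_class = _genotype_class(genotypes)
    if pheno_class is not None and pheno_class is not geno_class:
        raise DiscordantColonyError(
            f"phenotype {phenotype!r} implies {pheno_class.value} but decoded "
            f"genotypes imply {geno_class.value}"
        )
    return geno_class


# ---------------------------------------------------------------------------
# external interfaces

def decode_fasta(path, layout: ConstructSpec) -> list[dict]:
    """Decode every daughter sequence in a FASTA file against a layout.

    Returns one record per sequence with the digest pattern and the decoded
    alleles; parental (heteroduplex) strands that fail to decode are skipped.
    """
    out = []
    fwd, rev = layout.primers
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            amplicon = pcr_amplify(seq, fwd, rev)
            pattern = digest(amplicon, layout.digest_enzymes)
            genotype = decode_genotype(pattern, layout)
        except (PCRError, DecodingError):
            continue
        out.append({
            "id": rec.id,
            "fragments": pattern.key,
            "alleles": genotype,
        })
    return out


def write_colony_calls(rows: Iterable[Mapping], path) -> None:
    """Write per-colony molecular calls as TSV.

    Expected row keys: ``colony_id``, ``phenotype``, ``fragments`` (iterable
    of iterables, one per sector), ``alleles`` (iterable of genotype tuples),
    ``event_class``.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["colony_id", "phenotype", "fragment_lengths",
                         "decoded_alleles", "event_class"])
        for row in rows:
            frags = "/".join(
                ";".join(str(x) for x in sector) for sector in row["fragments"]
            )
            alleles = "/".join("+".join(g) for g in row["alleles"])
            writer.writerow([row["colony_id"], row["phenotype"], frags,
                             alleles, row["event_class"]])
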