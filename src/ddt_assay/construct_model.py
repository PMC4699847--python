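"""Heteroduplex marker-bearing construct model.

The assay introduces a single replication-blocking lesion into the *E. coli*
chromosome on a heteroduplex vector whose two strands are distinguishable by
short genetic markers. Each heteroduplex site is one :class:`MarkerLocus`
carrying two lettered alleles: the undamaged (bottom) strand carries A and B
(and E on the long construct), the damaged (top) strand carries C and D (and
F). The B/D locus sits at the lesion; A/C lies upstream of it. Marker D is a
+2 frameshift allele, B a +4 loop opposite it; with the vector backbone at
frame baseline -4 relative to a functional *lacZ*, only the C+B combination
is in frame (blue colonies), C+D gives a leaky frameshifted gene (pale blue)
and any A-containing combination is inactivated by a stop codon (white).

Four reference layouts are generated as synthetic fixtures: the published
construct sequences are not available, so backbone filler is drawn
pseudo-randomly from a fixed per-layout seed and then constrained so that

* the primer pair amplifies the documented product length (506, 1100 or
  2283 bp on a B-carrying daughter),
* each diagnostic restriction site occurs exactly where an allele puts it
  (no stray sites anywhere on any daughter duplex), and
* the digest-pattern -> genotype map is decodable.

Only amplicon lengths and decodability are asserted by the assay itself; the
filler is explicitly synthetic.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import find_motif, random_dna, revcomp

__all__ = [
    "MarkerLocus",
    "LesionSpec",
    "ConstructSpec",
    "LAYOUT_NAMES",
    "build_reference_construct",
    "validate_construct",
    "write_construct_fasta",
    "write_construct_sidecar",
]

#: recognition motifs used when checking the "exactly one allele carries the
#: diagnostic site" invariant (duplicated from molecular_readout on purpose:
#: this module must stay importable without it).
_SITE_MOTIFS = {
    "SspI": "AATATT",
    "PvuII": "CAGCTG",
    "EcoRI": "GAATTC",
    "NheI": "GCTAGC",
    "BglII": "AGATCT",
    "HincII": "GTYRAC",
    "NarI": "GGCGCC",
}

#: lesion-context oligonucleotides (inserted into the damaged strand).
UV_CONTEXT = "GCAAGTTAACACG"       # TT dimer in the HincII site
AAF_CONTEXT = "ATCACCGGCGCCACA"    # G-AAF adduct in the NarI site

LESION_KINDS = ("TT64", "CPD", "G-AAF", "none")


@dataclass(frozen=True)
class MarkerLocus:
    """One heteroduplex site carrying two lettered marker alleles.

    ``position`` is the 1-based start of the allele slot on the top-strand
    assembly (the strand that carries the lesion and the C/D/F alleles).
    ``*_frame`` record each allele's reading-frame shift in nucleotides.
    """

    name: str
    position: int
    top_name: str
    bottom_name: str
    top_allele: str
    bottom_allele: str
    top_kind: str
    bottom_kind: str
    top_frame: int
    bottom_frame: int
    diagnostic_enzyme: str

    @property
    def letters(self) -> tuple[str, str]:
        return (self.bottom_name, self.top_name)

    def allele(self, letter: str) -> str:
        if letter == self.top_name:
            return self.top_allele
        if letter == self.bottom_name:
            return self.bottom_allele
        raise KeyError(f"locus {self.name} has no allele {letter!r}")

    def frame_shift(self, letter: str) -> int:
        return self.top_frame if letter == self.top_name else self.bottom_frame


@dataclass(frozen=True)
class LesionSpec:
    """A single replication-blocking lesion on the top (damaged) strand."""

    kind: str                  # TT64 | CPD | G-AAF | none
    strand: str = "leading"    # replication-fork orientation, metadata only
    position: int = 0          # 1-based on the top-strand assembly; 0 if none
    context_oligo: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.strand not in ("leading", "lagging"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class ConstructSpec:
    """A heteroduplex integration vector and its molecular annotations.

    ``segments`` alternates fixed backbone sequence with marker-locus slots:
    each item is ``("seq", <str>)`` or ``("locus", <index into markers>)``.
    Daughter homoduplexes are obtained by substituting one allele per locus.
    """

    name: str
    segments: tuple[tuple[str, object], ...]
    markers: tuple[MarkerLocus, ...]
    lesion: LesionSpec
    primers: tuple[str, str]
    expected_amplicon_length: int
    digest_enzymes: tuple[str, ...]
    frame_baseline: int = -4

    # -- assembly -----------------------------------------------------------

    def assemble(self, choice: Mapping[str, str]) -> str:
        """Top-strand sequence with the allele *choice* (locus name -> letter)."""
        parts = []
        for kind, payload in self.segments:
            if kind == "seq":
                parts.append(payload)
            else:
                locus = self.markers[payload]
                parts.append(locus.allele(choice[locus.name]))
        return "".join(parts)

    @property
    def top_strand(self) -> str:
        return self.assemble({m.name: m.top_name for m in self.markers})

    @property
    def bottom_strand(self) -> str:
        """Bottom strand, 5'->3' (reverse complement of the A/B/E assembly)."""
        return revcomp(self.assemble({m.name: m.bottom_name for m in self.markers}))

    def daughter_sequence(self, genotype: Sequence[str]) -> str:
        """Homoduplex daughter (top-strand orientation) for a genotype tuple.

        *genotype* gives one allele letter per locus, in locus order, e.g.
        ``("C", "B")`` for the blue HDGR daughter of a four-marker layout.
        """
        if len(genotype) != len(self.markers):
            raise ValueError(
                f"genotype {genotype!r} has {len(genotype)} alleles; "
                f"{self.name} has {len(self.markers)} marker loci"
            )
        choice = {m.name: g for m, g in zip(self.markers, genotype)}
        return self.assemble(choice)

    def genotypes(self) -> Iterator[tuple[str, ...]]:
        """All allele combinations (2^n_loci daughter homoduplexes)."""
        return itertools.product(*(m.letters for m in self.markers))

    # -- semantics ----------------------------------------------------------

    @property
    def marker_count(self) -> int:
        """Number of individual lettered markers (two per heteroduplex site)."""
        return 2 * len(self.markers)

    @property
    def lesion_locus_index(self) -> int:
        """Index of the locus at the lesion (the B/D site)."""
        for i, m in enumerate(self.markers):
            if "B" in m.letters:
                return i
        raise ValueError(f"{self.name} has no B/D locus")

    @property
    def undamaged_genotype(self) -> tuple[str, ...]:
        return tuple(m.bottom_name for m in self.markers)

    @property
    def tls_genotype(self) -> tuple[str, ...]:
        return tuple(m.top_name for m in self.markers)

    @property
    def hdgr_genotype(self) -> tuple[str, ...]:
        """Damaged-strand daughter after a sister-strand exchange at the gap.

        Replication initiated on the damaged strand (top alleles) with a local
        template switch at the lesion locus (bottom allele there).
        """
        i = self.lesion_locus_index
        return tuple(
            m.bottom_name if j == i else m.top_name
            for j, m in enumerate(self.markers)
        )

    def frame_offset(self, genotype: Sequence[str]) -> int:
        """Net reading-frame offset of a daughter relative to functional lacZ."""
        return self.frame_baseline + sum(
            m.frame_shift(g) for m, g in zip(self.markers, genotype)
        )

    def sector_color(self, genotype: Sequence[str]) -> str:
        """Colony-sector colour of a daughter: blue, pale-blue or white.

        C+B is the only in-frame, stop-free combination (lacZ+, blue); C+D is
        frameshifted but leaky (pale blue); anything carrying the stop-codon
        allele A is white.
        """
        i = self.lesion_locus_index
        by_locus = dict(zip((m.name for m in self.markers), genotype))
        ac = by_locus.get("A/C")
        bd = genotype[i]
        if ac == "C" and self.frame_offset(genotype) % 3 == 0:
            return "blue"
        if ac == "C" and bd == "D":
            return "pale-blue"
        return "white"


LAYOUT_NAMES = ("pLL1_2c", "pLL1_7", "pLL4_5", "pLL9_2c")

# Primers as printed in the assay protocol.
VP56 = "TAAATGTGAGCGAGTAACAACC"
VP215 = "CTTGGGCTGCAGGTCGACT"
VP210 = "TCGGGTTTTCGACGTTCAGA"
GM1 = "GCGCTAATGCTCTGTTACAGG"

# Allele pairs, written in top-strand orientation: (bottom allele, top allele).
# Bottom alleles carry the diagnostic sites; which allele carries which site
# is not documented and is a free design choice of this fixture.
_AC_UV = ("TAATATTG", "CAGTATTG")            # A: SspI + TAA stop | C
_AC_AAF = ("TGAATTCTAA", "TGACTTCTAA")       # A: EcoRI + stop | C
_EF = ("GAATATTC", "GAACATTC")               # E: SspI | F (C/T point mismatch)
_BD_PVUII = ("ATCAGCTGTCACTGA", UV_CONTEXT)      # B (+4, PvuII) | D (+2, lesion 13-mer)
_BD_NHEI = ("ATGCTAGCTCACTGA", UV_CONTEXT)       # B (+4, NheI)  | D
_BD_BGLII = ("ATAGATCTTCACTGA", UV_CONTEXT)      # B (+4, BglII) | D
_BD_AAF = ("AATCAGCTGTCACTGAT", AAF_CONTEXT)     # B (+4, PvuII) | D (+2, 15-mer)

_FLANK = 80  # random backbone outside the amplicon, both sides


def _locus_plan(name, letters, alleles, kinds, frames, enzyme, lesion_offset=None):
    return {
        "name": name, "letters": letters, "alleles": alleles, "kinds": kinds,
        "frames": frames, "enzyme": enzyme, "lesion_offset": lesion_offset,
    }


_LAYOUTS: dict[str, dict] = {
    # four markers spanning 506 bp, UV lesions, SspI/PvuII digest
    "pLL1_2c": {
        "primers": (VP56, VP215),
        "amplicon": 506,
        "default_lesion": "TT64",
        "enzymes": ("SspI", "PvuII"),
        "fillers": (99, 100, 243),
        "seed": 151229,
        "loci": (
            _locus_plan("A/C", ("A", "C"), _AC_UV,
                        ("stop-codon", "point-mismatch"), (0, 0), "SspI"),
            _locus_plan("B/D", ("B", "D"), _BD_PVUII,
                        ("+4-loop", "+2-frameshift"), (4, 2), "PvuII",
                        lesion_offset=5),
        ),
    },
    # same geometry, G-AAF lesion, EcoRI/PvuII digest
    "pLL1_7": {
        "primers": (VP56, VP215),
        "amplicon": 506,
        "default_lesion": "G-AAF",
        "enzymes": ("EcoRI", "PvuII"),
        "fillers": (97, 100, 241),
        "seed": 151230,
        "loci": (
            _locus_plan("A/C", ("A", "C"), _AC_AAF,
                        ("stop-codon", "point-mismatch"), (0, 0), "EcoRI"),
            _locus_plan("B/D", ("B", "D"), _BD_AAF,
                        ("+4-loop", "+2-frameshift"), (4, 2), "PvuII",
                        lesion_offset=8),
        ),
    },
    # A/C moved 800 bp upstream of the lesion, 1100 bp amplicon, SspI/NheI
    "pLL4_5": {
        "primers": (VP210, VP215),
        "amplicon": 1100,
        "default_lesion": "TT64",
        "enzymes": ("SspI", "NheI"),
        "fillers": (100, 800, 138),
        "seed": 151231,
        "loci": (
            _locus_plan("A/C", ("A", "C"), _AC_UV,
                        ("stop-codon", "point-mismatch"), (0, 0), "SspI"),
            _locus_plan("B/D", ("B", "D"), _BD_NHEI,
                        ("+4-loop", "+2-frameshift"), (4, 2), "NheI",
                        lesion_offset=5),
        ),
    },
    # six markers with E/F 1.6 kb downstream of the lesion, 2283 bp, BglII/SspI
    "pLL9_2c": {
        "primers": (VP56, GM1),
        "amplicon": 2283,
        "default_lesion": "TT64",
        "enzymes": ("BglII", "SspI"),
        "fillers": (99, 100, 1600, 410),
        "seed": 151232,
        "loci": (
            _locus_plan("A/C", ("A", "C"), _AC_UV,
                        ("stop-codon", "point-mismatch"), (0, 0), "SspI"),
            _locus_plan("B/D", ("B", "D"), _BD_BGLII,
                        ("+4-loop", "+2-frameshift"), (4, 2), "BglII",
                        lesion_offset=5),
            _locus_plan("E/F", ("E", "F"), _EF,
                        ("point-mismatch", "point-mismatch"), (0, 0), "SspI"),
        ),
    },
}


def _assemble_layout(layout_name: str, plan: dict, lesion_kind: str,
                     orientation: str, seed: int) -> ConstructSpec:
    rng = np.random.default_rng(seed)
    fwd, rev = plan["primers"]
    fillers = [random_dna(rng, n) for n in plan["fillers"]]
    flank_l = random_dna(rng, _FLANK)
    flank_r = random_dna(rng, _FLANK)

    segments: list[tuple[str, object]] = [("seq", flank_l + fwd + fillers[0])]
    markers: list[MarkerLocus] = []
    pos = len(flank_l) + len(fwd) + len(fillers[0]) + 1  # 1-based slot start
    lesion_pos = 0
    for i, lp in enumerate(plan["loci"]):
        bottom, top = lp["alleles"]
        markers.append(MarkerLocus(
            name=lp["name"], position=pos,
            top_name=lp["letters"][1], bottom_name=lp["letters"][0],
            top_allele=top, bottom_allele=bottom,
            top_kind=lp["kinds"][1], bottom_kind=lp["kinds"][0],
            top_frame=lp["frames"][1], bottom_frame=lp["frames"][0],
            diagnostic_enzyme=lp["enzyme"],
        ))
        segments.append(("locus", i))
        if lp["lesion_offset"] is not None and lesion_kind != "none":
            lesion_pos = pos + lp["lesion_offset"] - 1
        pos += len(top)  # top-strand coordinate frame
        tail = fillers[i + 1]
        segments.append(("seq", tail))
        pos += len(tail)
    # final filler already appended; terminate with the reverse-primer site
    last_kind, last_seq = segments[-1]
    segments[-1] = ("seq", last_seq + revcomp(rev) + flank_r)

    context = ""
    if lesion_kind in ("TT64", "CPD"):
        context = UV_CONTEXT
    elif lesion_kind == "G-AAF":
        context = AAF_CONTEXT
    lesion = LesionSpec(kind=lesion_kind, strand=orientation,
                        position=lesion_pos, context_oligo=context)
    return ConstructSpec(
        name=layout_name,
        segments=tuple(segments),
        markers=tuple(markers),
        lesion=lesion,
        primers=(fwd, rev),
        expected_amplicon_length=plan["amplicon"],
        digest_enzymes=plan["enzymes"],
    )


def _template_is_clean(c: ConstructSpec) -> bool:
    """No stray primer or diagnostic-enzyme sites on any daughter duplex."""
    fwd, rev = c.primers
    motifs = {e: _SITE_MOTIFS[e] for e in c.digest_enzymes}
    for genotype in c.genotypes():
        t = c.daughter_sequence(genotype)
        if t.count(fwd) != 1 or revcomp(fwd) in t:
            return False
        if t.count(revcomp(rev)) != 1 or rev in t:
            return False
        for enzyme, motif in motifs.items():
            expect = sum(
                 len(find_motif(m.allele(g), motif))
                 + len(find_motif(revcomp(m.allele(g)), motif))
                 for m, g in zip(c.markers, genotype)
            )
            # all digest motifs here are palindromic, so each designed site is
            # counted twice in `expect`
            if len(find_motif(t, motif)) + len(find_motif(revcomp(t), motif)) != expect:
                return False
    return True


def build_reference_construct(layout_name: str, lesion_kind: str | None = None,
                              orientation: str = "leading") -> ConstructSpec:
    """Build one of the four reference heteroduplex layouts.

    Parameters
    ----------
    layout_name
        One of ``pLL1_2c``, ``pLL1_7``, ``pLL4_5``, ``pLL9_2c``.
    lesion_kind
        ``TT64``, ``CPD``, ``G-AAF`` or ``none`` (lesion-free control vector,
        same sequence, no adduct). Defaults to the layout's canonical lesion.
    orientation
        ``leading`` or ``lagging``; carried as metadata only.
    """
    try:
        plan = _LAYOUTS[layout_name]
    except KeyError:
        raise ValueError(
            f"unknown layout {layout_name!r}; expected one of {LAYOUT_NAMES}"
        ) from None
    kind = plan["default_lesion"] if lesion_kind is None else lesion_kind
    if kind not in LESION_KINDS:
        raise ValueError(f"unknown lesion kind {kind!r}")
    if kind == "G-AAF" and plan["default_lesion"] != "G-AAF":
        raise ValueError(f"{layout_name} does not carry a NarI lesion site")
    if kind in ("TT64", "CPD") and plan["default_lesion"] == "G-AAF":
        raise ValueError(f"{layout_name} does not carry a HincII lesion site")

    for attempt in range(64):
        c = _assemble_layout(layout_name, plan, kind, orientation,
                             plan["seed"] + 7919 * attempt)
        if _template_is_clean(c):
            expected = (len(plan["primers"][0]) + sum(plan["fillers"])
                        + sum(len(lp["alleles"][0]) for lp in plan["loci"])
                        + len(plan["primers"][1]))
            assert expected == plan["amplicon"], "layout geometry inconsistent"
            return c
    raise RuntimeError(f"could not generate a clean backbone for {layout_name}")


# ---------------------------------------------------------------------------
# validation

def _amplicon_span(c: ConstructSpec, genotype: Sequence[str]) -> tuple[int, int] | None:
    seq = c.daughter_sequence(genotype)
    fwd, rev = c.primers
    i = seq.find(fwd)
    j = seq.find(revcomp(rev))
    if i < 0 or j < 0 or seq.find(fwd, i + 1) >= 0 or seq.find(revcomp(rev), j + 1) >= 0:
        return None
    return (i + 1, j + len(rev))  # 1-based inclusive


def validate_construct(c: ConstructSpec) -> list[str]:
    """Check all construct invariants; returns human-readable violations.

    An empty list means the construct is valid. Violations name the offending
    locus and the rule broken; the function never raises on bad geometry.
    """
    violations: list[str] = []

    for m in c.markers:
        if m.top_allele == m.bottom_allele:
            violations.append(f"{m.name}: top and bottom alleles are identical")
        motif = _SITE_MOTIFS.get(m.diagnostic_enzyme)
        if motif is None:
            violations.append(f"{m.name}: unknown diagnostic enzyme {m.diagnostic_enzyme}")
        else:
            def has_site(a: str) -> bool:
                return bool(find_motif(a, motif) or find_motif(revcomp(a), motif))
            n = has_site(m.top_allele) + has_site(m.bottom_allele)
            if n != 1:
                violations.append(
                    f"{m.name}: {n} alleles carry the {m.diagnostic_enzyme} site "
                    f"(exactly one required)"
                )

    # markers inside the primer-delimited amplicon (top-strand coordinates)
    span = _amplicon_span(c, c.tls_genotype)
    if span is None:
        violations.append("primers: do not delimit a unique amplicon")
    else:
        start, end = span
        for m in c.markers:
            if m.position < start or m.position + len(m.top_allele) - 1 > end:
                violations.append(f"{m.name}: locus outside the amplicon [{start},{end}]")

    # reverse-complement symmetry away from marker loci, base by base
    top = c.assemble({m.name: m.top_name for m in c.markers})
    bot = c.assemble({m.name: m.bottom_name for m in c.markers})
    ti = bi = 0
    for kind, payload in c.segments:
        if kind == "seq":
            n = len(payload)
            if top[ti:ti + n] != bot[bi:bi + n]:
                violations.append("backbone: strands not reverse-complementary outside marker loci")
            ti += n
            bi += n
        else:
            m = c.markers[payload]
            ti += len(m.top_allele)
            bi += len(m.bottom_allele)

    # lesion context
    les = c.lesion
    if les.kind in ("TT64", "CPD"):
        if les.context_oligo != UV_CONTEXT:
            violations.append("lesion: UV context oligo is not the 13-mer GCAAGTTAACACG")
        elif not find_motif(les.context_oligo, _SITE_MOTIFS["HincII"]):
            violations.append("lesion: UV context lacks the HincII motif")
    elif les.kind == "G-AAF":
        if les.context_oligo != AAF_CONTEXT:
            violations.append("lesion: G-AAF context oligo is not the 15-mer ATCACCGGCGCCACA")
        elif len(find_motif(les.context_oligo, _SITE_MOTIFS["NarI"])) != 1:
            violations.append("lesion: G-AAF context must contain the NarI motif exactly once")
    if les.kind != "none" and les.position <= 0:
        violations.append("lesion: missing position for a lesion-carrying construct")

    return violations


# ---------------------------------------------------------------------------
# external interfaces

def write_construct_fasta(c: ConstructSpec, path, include_daughters: bool = True) -> None:
    """Write the two parental strands (and daughter homoduplexes) as FASTA."""
    records = [
        SeqRecord(Seq(c.top_strand), id=f"{c.name}|top", description="damaged strand 5'->3'"),
        SeqRecord(Seq(c.bottom_strand), id=f"{c.name}|bottom", description="undamaged strand 5'->3'"),
    ]
    if include_daughters:
        for g in c.genotypes():
            gid = "-".join(g)
            records.append(SeqRecord(
                Seq(c.daughter_sequence(g)),
                id=f"{c.name}|daughter|{gid}",
                description="homoduplex daughter (top-strand orientation)",
            ))
    SeqIO.write(records, str(path), "fasta")


def construct_description(c: ConstructSpec) -> dict:
    """Sidecar description (marker table, primers, lesion) for config files."""
    return {
        "name": c.name,
        "amplicon_length": c.expected_amplicon_length,
        "primers": {"forward": c.primers[0], "reverse": c.primers[1]},
        "digest_enzymes": list(c.digest_enzymes),
        "frame_baseline": c.frame_baseline,
        "lesion": {
            "kind": c.lesion.kind,
            "strand": c.lesion.strand,
            "position": c.lesion.position,
            "context_oligo": c.lesion.context_oligo,
        },
        "markers": [
            {
                "name": m.name,
                "position": m.position,
                "bottom": {"marker": m.bottom_name, "allele": m.bottom_allele,
                           "kind": m.bottom_kind, "frame_shift": m.bottom_frame},
                "top": {"marker": m.top_name, "allele": m.top_allele,
                        "kind": m.top_kind, "frame_shift": m.top_frame},
                "diagnostic_enzyme": m.diagnostic_enzyme,
            }
            for m in c.markers
        ],
    }


def write_construct_sidecar(c: ConstructSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(construct_description(c), fh, sort_keys=False)


def broken_copy(c: ConstructSpec, **marker_overrides) -> ConstructSpec:
    """Return a copy with one marker replaced (used to exercise validation)."""
    markers = list(c.markers)
    for idx, new in marker_overrides.items():
        markers[int(idx)] = new
    return dataclasses.replace(c, markers=tuple(markers))
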