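"""Low-level DNA string helpers shared by the construct and readout modules.

Sequences are plain upper-case ``str`` over A/C/G/T; motifs may use the full
IUPAC degenerate alphabet. Positions are 1-based throughout the package, to
match how restriction maps and primer coordinates are reported in the lab.
"""

from __future__ import annotations

import re

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC-degenerate characters."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str) -> None:
    """Raise ``ValueError`` if *seq* contains characters outside A/C/G/T."""
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)!r}")


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile a degenerate motif into a lookahead regex (overlapping hits)."""
    parts = []
    for ch in motif.upper():
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def find_motif(seq: str, motif: str) -> list[int]:
    """All 1-based start positions of *motif* on *seq*, overlapping included."""
    return [m.start() + 1 for m in iupac_regex(motif).finditer(seq)]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))
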