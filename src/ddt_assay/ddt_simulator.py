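"""Stochastic model of single-lesion tolerance outcomes.

One "integration" introduces a heteroduplex vector carrying a single
replication-blocking lesion into a cell. Replication re-primes downstream of
the lesion, leaving a daughter-strand gap opposite it; the gap is resolved by
homology-directed gap repair (HDGR, probability ``h``), translesion synthesis
(TLS, probability ``t``) or not at all. The daughter cell inheriting an
unresolved gap dies at the next division; the daughter replicated from the
undamaged strand survives unless that strand itself carries endogenous
blocking lesions, whose number is Poisson with mean ``lambda_opp`` (plus
``lambda_uv`` in the clustered-UV mode) and each of which is resolved
independently with probability ``h + t``.

With ``r = h + t`` and ``lam = lambda_opp + lambda_uv`` the closed-form class
probabilities (relative to a lesion-free control, which survives with
probability 1) are

    survival        S = r + (1 - r) * exp(-lam * (1 - r))
    HDGR tolerance      = h
    TLS tolerance       = t
    chromatid loss      = (1 - r) * exp(-lam * (1 - r))

Marker transmission follows the construct geometry: the gap-repaired daughter
carries C+B, a TLS daughter C+D, the undamaged daughter A+B; each surviving
daughter's B/D marker is then flipped with the conversion probability ``c``,
which is what confounds HDGR and TLS counts in the raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .construct_model import ConstructSpec, LesionSpec

__all__ = [
    "GenotypeParams",
    "CellOutcome",
    "COLONY_TABLE_COLUMNS",
    "CALIBRATIONS",
    "get_calibration",
    "simulate_integration",
    "simulate_experiment",
    "survival_closed_form",
    "CLUSTERED_UV_MEAN",
]

#: mean clustered-UV lesion load per strand; chosen so the Poisson zero class
#: is exp(-2.56) = 7.73%, within the stated 2-3 lesions per strand.
CLUSTERED_UV_MEAN = 2.56

#: default endogenous opposite-strand lesion burden (lesions per integration),
#: consistent with the ~50% recA-null survival the model must reproduce.
DEFAULT_LAMBDA_OPP = 0.8

#: default B/D marker conversion probability per heteroduplex locus.
DEFAULT_CONVERSION = 0.05


@dataclass(frozen=True)
class GenotypeParams:
    """Per (strain, lesion) parameters of the tolerance model."""

    strain: str
    lesion: str
    h: float                       # per-gap HDGR probability
    t: float                       # per-gap TLS probability
    lambda_opp: float = DEFAULT_LAMBDA_OPP
    lambda_uv: float = 0.0         # clustered-UV mode only
    conversion_rate: float = DEFAULT_CONVERSION

    def __post_init__(self) -> None:
        for name in ("h", "t", "conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.h + self.t > 1.0 + 1e-12:
            raise ValueError(f"h + t must not exceed 1, got {self.h + self.t}")
        if self.lambda_opp < 0 or self.lambda_uv < 0:
            raise ValueError("lesion means must be non-negative")

    @property
    def r(self) -> float:
        """Per-gap resolution probability."""
        return self.h + self.t

    @property
    def lam(self) -> float:
        """Total opposite-strand lesion mean."""
        return self.lambda_opp + self.lambda_uv


@dataclass
class CellOutcome:
    """Fate of a single integration event."""

    gap_resolution: str            # HDGR | TLS | unresolved | none (no lesion)
    n_opposite: int
    n_opposite_resolved: int
    daughter1_viable: bool         # lesion-strand daughter
    daughter2_viable: bool         # undamaged-strand daughter
    phenotype: str
    daughter1_alleles: tuple[str, ...] | None
    daughter2_alleles: tuple[str, ...] | None


COLONY_TABLE_COLUMNS = [
    "construct", "strain", "lesion", "orientation", "n_integrations",
    "n_sectored", "n_pale_blue", "n_white", "n_pure_blue", "n_dead",
    "n_control", "internal_standard_lesion", "internal_standard_free", "seed",
]

# ---------------------------------------------------------------------------
# calibration table: per-gap probabilities per strain x lesion. UV covers both
# photoproducts (TT64 and CPD behave alike in the figures); sulA equals the
# parental set. recF shows the four-fold G-AAF TLS rise; recB a ~20% HDGR drop.

_CAL = {
    ("parental", "UV"): dict(h=0.895, t=0.002),
    ("parental", "G-AAF"): dict(h=0.88, t=0.02),
    ("recA", "UV"): dict(h=0.05, t=0.01),
    ("recA", "G-AAF"): dict(h=0.05, t=0.01),
    ("recF", "UV"): dict(h=0.46, t=0.002),
    ("recF", "G-AAF"): dict(h=0.42, t=0.08),
    ("recB", "UV"): dict(h=0.72, t=0.002),
    ("sulA", "UV"): dict(h=0.895, t=0.002),
}

CALIBRATIONS: dict[tuple[str, str], GenotypeParams] = {}
for (_strain, _grp), _p in _CAL.items():
    _lesions = ("TT64", "CPD") if _grp == "UV" else ("G-AAF",)
    for _lesion in _lesions:
        CALIBRATIONS[(_strain, _lesion)] = GenotypeParams(
            strain=_strain, lesion=_lesion, **_p
        )


def get_calibration(strain: str, lesion: str, clustered: bool = False) -> GenotypeParams:
    """Calibrated parameters for a strain and lesion kind.

    ``clustered=True`` adds the clustered-UV opposite-strand load.
    """
    try:
        params = CALIBRATIONS[(strain, lesion)]
    except KeyError:
        raise KeyError(
            f"no calibration for strain={strain!r}, lesion={lesion!r}; "
            f"available: {sorted(CALIBRATIONS)}"
        ) from None
    if clustered:
        params = replace(params, lambda_uv=CLUSTERED_UV_MEAN)
    return params


# ---------------------------------------------------------------------------
# marker-transmission helpers

_DEFAULT_GENOTYPES = {
    "undamaged": ("A", "B"),
    "hdgr": ("C", "B"),
    "tls": ("C", "D"),
    "lesion_locus_index": 1,
}


def _genotype_table(construct: ConstructSpec | None) -> dict:
    if construct is None:
        return _DEFAULT_GENOTYPES
    return {
        "undamaged": construct.undamaged_genotype,
        "hdgr": construct.hdgr_genotype,
        "tls": construct.tls_genotype,
        "lesion_locus_index": construct.lesion_locus_index,
    }


def _flip_bd(genotype: tuple[str, ...], idx: int) -> tuple[str, ...]:
    g = list(genotype)
    g[idx] = "D" if g[idx] == "B" else "B"
    return tuple(g)


def _sector_color(genotype: tuple[str, ...], construct: ConstructSpec | None) -> str:
    if construct is not None:
        return construct.sector_color(genotype)
    if genotype[0] == "C" and genotype[1] == "B":
        return "blue"
    if genotype[0] == "C" and genotype[1] == "D":
        return "pale-blue"
    return "white"


def _colony_phenotype(colors: list[str]) -> str:
    if not colors:
        return "dead"
    if "blue" in colors:
        return "sectored-blue-white" if "white" in colors else "pure-blue"
    if "pale-blue" in colors:
        return "pale-blue"
    return "white"


# ---------------------------------------------------------------------------
# single-integration sampling (scalar reference implementation)

def simulate_integration(params: GenotypeParams, lesion: LesionSpec | str,
                         rng: np.random.Generator,
                         construct: ConstructSpec | None = None) -> CellOutcome:
    """Sample the fate of one integration event.

    The lesion-carrying daughter lives iff its gap is resolved (HDGR or TLS);
    the undamaged-strand daughter lives iff every endogenous opposite-strand
    gap is resolved. A lesion-free integration survives with probability 1.
    """
    kind = lesion.kind if isinstance(lesion, LesionSpec) else lesion
    gt = _genotype_table(construct)
    bd = gt["lesion_locus_index"]
    c = params.conversion_rate

    if kind == "none":
        d1, d2 = gt["tls"], gt["undamaged"]
        if c and rng.random() < c:
            d1 = _flip_bd(d1, bd)
        if c and rng.random() < c:
            d2 = _flip_bd(d2, bd)
        colors = [_sector_color(d1, construct), _sector_color(d2, construct)]
        return CellOutcome("none", 0, 0, True, True,
                           _colony_phenotype(colors), d1, d2)

    u = rng.random()
    if u < params.h:
        resolution, d1 = "HDGR", gt["hdgr"]
    elif u < params.r:
        resolution, d1 = "TLS", gt["tls"]
    else:
        resolution, d1 = "unresolved", None
    d1_viable = d1 is not None

    n_opp = int(rng.poisson(params.lam))
    n_resolved = int(rng.binomial(n_opp, params.r)) if n_opp else 0
    d2_viable = n_resolved == n_opp
    d2 = gt["undamaged"] if d2_viable else None

    if d1_viable and c and rng.random() < c:
        d1 = _flip_bd(d1, bd)
    if d2_viable and c and rng.random() < c:
        d2 = _flip_bd(d2, bd)

    colors = [_sector_color(g, construct) for g in (d1, d2) if g is not None]
    return CellOutcome(resolution, n_opp, n_resolved, d1_viable, d2_viable,
                       _colony_phenotype(colors), d1, d2)


# ---------------------------------------------------------------------------
# experiment-scale sampling (vectorized, same law)

def simulate_experiment(params: GenotypeParams,
                        lesion: LesionSpec | str | None = None,
                        n_integrations: int = 20000,
                        seed: int | np.random.Generator = 0,
                        construct: ConstructSpec | None = None,
                        orientation: str = "leading",
                        internal_standard_mean: float = 30000.0,
                        collect_outcomes: bool = False):
    """Simulate a full integration experiment plus its lesion-free control arm.

    Returns a one-row colony table (:data:`COLONY_TABLE_COLUMNS`); with
    ``collect_outcomes=True`` also the list of per-integration
    :class:`CellOutcome` records (needed for the molecular-readout pipeline).

    The control arm integrates the lesion-free homologue: by the model's
    accounting it survives with probability 1, so it contributes
    ``n_integrations`` colonies; internal-standard plates are Poisson counts
    around ``internal_standard_mean`` in both arms.
    """
    if n_integrations < 1:
        raise ValueError("n_integrations must be >= 1")
    if isinstance(lesion, LesionSpec):
        kind = lesion.kind
        orientation = lesion.strand
    else:
        kind = params.lesion if lesion is None else lesion
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = "" if isinstance(seed, np.random.Generator) else str(seed)

    gt = _genotype_table(construct)
    bd = gt["lesion_locus_index"]
    n = int(n_integrations)
    c = params.conversion_rate

    if kind == "none":
        res = np.full(n, 3)            # 3 = no introduced gap
        d1_viable = np.ones(n, dtype=bool)
        d2_viable = np.ones(n, dtype=bool)
        n_opp = np.zeros(n, dtype=int)
        n_res = np.zeros(n, dtype=int)
        d1_base = np.full(n, 1)        # tls genotype (undamaged replication of top strand)
    else:
        u = rng.random(n)
        res = np.where(u < params.h, 0, np.where(u < params.r, 1, 2))
        d1_viable = res < 2
        n_opp = rng.poisson(params.lam, size=n)
        n_res = rng.binomial(n_opp, params.r)
        d2_viable = n_res == n_opp
        d1_base = res.copy()           # 0 = hdgr genotype, 1 = tls genotype

    flip1 = rng.random(n) < c
    flip2 = rng.random(n) < c

    genotype_codes = {
        0: gt["hdgr"], 1: gt["tls"],
        2: _flip_bd(gt["hdgr"], bd), 3: _flip_bd(gt["tls"], bd),
    }
    # d1 genotype code with conversion applied (only meaningful where viable)
    d1_code = np.where(flip1, d1_base + 2, d1_base)

    colors = {code: _sector_color(g, construct) for code, g in genotype_codes.items()}
    d1_blue = np.isin(d1_code, [code for code, col in colors.items() if col == "blue"])
    d1_pale = np.isin(d1_code, [code for code, col in colors.items() if col == "pale-blue"])

    both = d1_viable & d2_viable
    n_sectored = int(np.sum(both & d1_blue))
    n_pale = int(np.sum(d1_viable & d1_pale))          # sectored-pale or pure-pale
    n_pure_blue = int(np.sum(d1_viable & ~d2_viable & d1_blue))
    n_white = int(np.sum(~d1_viable & d2_viable))
    n_dead = int(np.sum(~d1_viable & ~d2_viable))
    assert n_sectored + n_pale + n_pure_blue + n_white + n_dead == n

    table = pd.DataFrame([{
        "construct": construct.name if construct is not None else "pLL1_2c",
        "strain": params.strain,
        "lesion": kind,
        "orientation": orientation,
        "n_integrations": n,
        "n_sectored": n_sectored,
        "n_pale_blue": n_pale,
        "n_white": n_white,
        "n_pure_blue": n_pure_blue,
        "n_dead": n_dead,
        "n_control": n,
        "internal_standard_lesion": int(rng.poisson(internal_standard_mean)),
        "internal_standard_free": int(rng.poisson(internal_standard_mean)),
        "seed": seed_label,
    }], columns=COLONY_TABLE_COLUMNS)

    if not collect_outcomes:
        return table

    undam = gt["undamaged"]
    undam_flipped = _flip_bd(undam, bd)
    res_names = {0: "HDGR", 1: "TLS", 2: "unresolved", 3: "none"}
    outcomes = []
    for i in range(n):
        v1, v2 = bool(d1_viable[i]), bool(d2_viable[i])
        g1 = genotype_codes[int(d1_code[i])] if v1 else None
        g2 = (undam_flipped if flip2[i] else undam) if v2 else None
        cols = [colors[int(d1_code[i])]] if v1 else []
        if v2:
            cols.append(_sector_color(g2, construct))
        outcomes.append(CellOutcome(
            res_names[int(res[i])], int(n_opp[i]), int(n_res[i]),
            v1, v2, _colony_phenotype(cols), g1, g2,
        ))
    return table, outcomes


class ClosedFormPartition(NamedTuple):
    survival: float
    hdgr: float
    tls: float
    chromatid_loss: float


def survival_closed_form(params: GenotypeParams) -> ClosedFormPartition:
    """Exact class probabilities of the model, as fractions of integrations.

    The lesion-free control is the unit: survival is relative survival, and
    the three tolerance classes sum to it.
    """
    r = params.r
    lam = params.lam
    loss = (1.0 - r) * math.exp(-lam * (1.0 - r))
    return ClosedFormPartition(
        survival=r + loss,
        hdgr=params.h,
        tls=params.t,
        chromatid_loss=loss,
    )
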