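"""Estimators over colony data.

Covers the statistical side of the assay: multinomial event fractions among
survivors, the B/D marker-conversion rate from lesion-free control colonies,
the endogenous opposite-strand lesion burden implied by a measured relative
survival, and calibration of per-gap model parameters against target
percentages via a deterministic grid search on the closed-form model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .ddt_simulator import CellOutcome, GenotypeParams

__all__ = [
    "EventFraction",
    "ConversionEstimate",
    "CalibrationResult",
    "estimate_event_fractions",
    "estimate_conversion_rate",
    "estimate_opposite_burden",
    "calibrate_params",
]


@dataclass(frozen=True)
class EventFraction:
    fraction: float
    ci_low: float
    ci_high: float
    count: int


@dataclass(frozen=True)
class ConversionEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_discordant: int
    n_sectors: int


def estimate_event_fractions(counts: Mapping[str, int],
                             control_count: int | None = None,
                             std_lesion: int = 1, std_free: int = 1,
                             alpha: float = 0.05) -> dict[str, EventFraction]:
    """Maximum-likelihood multinomial fractions among surviving colonies.

    *counts* maps event class (``HDGR``/``TLS``/``CHROMATID_LOSS``) to colony
    count. Wilson intervals per class. If *control_count* is given the result
    also contains ``<class>_tolerance`` entries expressed relative to the
    lesion-free control (in percent / 100, i.e. still fractions).
    """
    counts = {k: int(v) for k, v in counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no surviving colonies")
    out: dict[str, EventFraction] = {}
    for name, k in counts.items():
        lo, hi = proportion_confint(k, total, alpha=alpha, method="wilson")
        out[name] = EventFraction(k / total, float(lo), float(hi), k)
    if control_count is not None:
        if control_count <= 0:
            raise ValueError("control colony count must be positive")
        scale = (std_free / std_lesion) / control_count
        for name, k in counts.items():
            est = out[name]
            out[name + "_tolerance"] = EventFraction(
                k * scale, est.ci_low * total * scale, est.ci_high * total * scale, k
            )
    return out


def estimate_conversion_rate(
    decoded: Iterable[Sequence[str] | CellOutcome],
    lesion_locus_index: int = 1,
    alpha: float = 0.05,
) -> ConversionEstimate:
    """B/D marker-conversion rate from decoded lesion-free control colonies.

    Each item is either a decoded sector genotype (allele tuple) or a
    :class:`~ddt_assay.ddt_simulator.CellOutcome` whose viable daughters are
    used as sectors. In the lesion-free arm the parental strand of a sector is
    identified by its A/C marker, which fixes the B/D allele it should carry
    (C goes with D, A with B); a sector whose decoded B/D allele differs was
    converted.
    """
    n_sectors = 0
    n_disc = 0
    for item in decoded:
        if isinstance(item, CellOutcome):
            sectors = [g for g in (item.daughter1_alleles, item.daughter2_alleles)
                       if g is not None]
        else:
            sectors = [item]
        for g in sectors:
            expected_bd = "D" if g[0] == "C" else "B"
            n_sectors += 1
            if g[lesion_locus_index] != expected_bd:
                n_disc += 1
    if n_sectors == 0:
        raise ValueError("no decoded genotypes supplied")
    lo, hi = proportion_confint(n_disc, n_sectors, alpha=alpha, method="wilson")
    return ConversionEstimate(n_disc / n_sectors, float(lo), float(hi),
                              n_disc, n_sectors)


def estimate_opposite_burden(s_rel: float, r: float) -> float:
    """Invert the survival law for the endogenous opposite-strand mean.

    Solves ``S = r + (1 - r) * exp(-lam * (1 - r))`` for ``lam``:
    ``lam = -ln((S - r) / (1 - r)) / (1 - r)``. Requires ``r < S <= 1``
    (model admissibility: survival can never drop below the per-gap
    resolution probability).
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("per-gap resolution r must be in [0, 1)")
    if s_rel > 1.0 + 1e-12:
        raise ValueError(f"relative survival {s_rel} exceeds 1")
    if s_rel <= r:
        raise ValueError(
            f"relative survival {s_rel} is not admissible: the model bounds "
            f"survival below by r = {r}"
        )
    return -math.log((min(s_rel, 1.0) - r) / (1.0 - r)) / (1.0 - r)


@dataclass(frozen=True)
class CalibrationResult:
    name: str
    params: GenotypeParams
    residuals: dict[str, float]
    max_residual: float
    converged: bool


_TARGET_CLASSES = ("HDGR", "TLS", "CHROMATID_LOSS", "survival")


def _fit_one(name: str, targets: Sequence[tuple[str, float, float]],
             h_step: float, t_step: float,
             lam_step: float, lam_max: float) -> CalibrationResult:
    hs = np.round(np.arange(0.0, 1.0 + 1e-9, h_step), 10)
    ts = np.round(np.arange(0.0, 1.0 + 1e-9, t_step), 10)
    lams = np.round(np.arange(0.0, lam_max + 1e-9, lam_step), 10)
    H, T, L = np.meshgrid(hs, ts, lams, indexing="ij")
    feasible = (H + T) <= 1.0 + 1e-12
    R = H + T
    loss = (1.0 - R) * np.exp(-L * (1.0 - R))
    model = {
        "HDGR": 100.0 * H,
        "TLS": 100.0 * T,
        "CHROMATID_LOSS": 100.0 * loss,
        "survival": 100.0 * (R + loss),
    }
    worst = np.zeros_like(H)
    l2 = np.zeros_like(H)
    for cls, pct, tol in targets:
        if cls not in _TARGET_CLASSES:
            raise ValueError(f"unknown target class {cls!r}")
        if tol <= 0:
            raise ValueError("target tolerance must be positive")
        rel = np.abs(model[cls] - pct) / tol
        worst = np.maximum(worst, rel)
        l2 += rel ** 2
    worst = np.where(feasible, worst, np.inf)
    best = worst.min()
    tie = np.flatnonzero((worst <= best + 1e-12).ravel())
    idx = tie[np.argmin(l2.ravel()[tie])]
    i, j, k = np.unravel_index(idx, worst.shape)
    h, t, lam = float(hs[i]), float(ts[j]), float(lams[k])
    params = GenotypeParams(strain=name, lesion="calibrated", h=h, t=t,
                            lambda_opp=lam)
    residuals = {
        cls: float(model[cls][i, j, k] - pct) for cls, pct, _ in targets
    }
    return CalibrationResult(
        name=name, params=params, residuals=residuals,
        max_residual=float(max(abs(v) for v in residuals.values())),
        converged=bool(best <= 1.0 + 1e-12),
    )


def calibrate_params(targets: Mapping[str, Sequence[tuple[str, float, float]]],
                     h_step: float = 0.005, t_step: float = 0.005,
                     lam_step: float = 0.05,
                     lam_max: float = 2.0) -> list[CalibrationResult]:
    """Fit (h, t, lambda_opp) per strain against target percentages.

    *targets* maps a strain label to ``(class, percent, tolerance)`` triples,
    where class is ``HDGR``, ``TLS``, ``CHROMATID_LOSS`` or ``survival`` in
    percent of integrations (lesion-free control = 100). The search is an
    exhaustive deterministic grid; the objective is the worst
    tolerance-normalized residual (minimax), tie-broken by the L2 norm. A
    result is ``converged`` when every residual lies within its tolerance;
    otherwise the best-found table is returned flagged non-convergent.
    """
    return [
        _fit_one(name, list(t), h_step, t_step, lam_step, lam_max)
        for name, t in targets.items()
    ]


def calibration_to_frame(results: Iterable[CalibrationResult]) -> pd.DataFrame:
    rows = [
        {"strain": r.name, "h": r.params.h, "t": r.params.t,
         "lambda_opp": r.params.lambda_opp,
         "max_residual": r.max_residual, "converged": r.converged}
        for r in results
    ]
    return pd.DataFrame(rows)
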