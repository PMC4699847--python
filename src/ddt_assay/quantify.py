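"""Turn colony counts into tolerance percentages.

The assay reports every class as a percentage of cells able to survive with
the integrated lesion relative to the lesion-free control, with both arms
normalized by an internal-standard plasmid co-electroporated to absorb
transformation-efficiency differences:

    class % = 100 * (class_count / std_lesion) / (control_count / std_free)

Two corrections are applied to raw counts. First, B/D heteroduplex markers
convert at a small rate ``c`` even without mismatch repair, which swaps HDGR
and TLS calls symmetrically; the inverse of the implied 2x2 confusion matrix
undoes it. Second, constructs carrying clustered UV lesions include a Poisson
zero class of molecules that received no lesion at all; their contribution is
removed from measured survival.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ClassEstimate",
    "TolerancePartition",
    "tolerance_partition",
    "partition_from_table",
    "partition_to_frame",
    "marker_conversion_correct",
    "poisson_zero_fraction",
    "clustered_survival_correct",
    "bootstrap_partition",
]

CLASS_NAMES = ("HDGR", "TLS", "CHROMATID_LOSS")


@dataclass(frozen=True)
class ClassEstimate:
    percent: float
    ci_low: float
    ci_high: float
    count: int


@dataclass(frozen=True)
class TolerancePartition:
    """Normalized tolerance percentages with confidence intervals.

    Class percentages sum to ``survival.percent`` exactly; CIs are Wilson
    intervals on the lesion-arm multinomial scaled by the normalization
    ratio (class CIs) and a log-normal delta-method interval (survival).
    """

    classes: dict[str, ClassEstimate]
    survival: ClassEstimate
    denominators: dict[str, int]

    def percent(self, name: str) -> float:
        return self.classes[name].percent


def tolerance_partition(lesion_counts: Mapping[str, int],
                        control_count: int,
                        std_lesion: int,
                        std_free: int,
                        alpha: float = 0.05) -> TolerancePartition:
    """Internal-standard-normalized tolerance partition.

    Parameters
    ----------
    lesion_counts
        Colony counts per event class from the lesion arm, keyed by
        ``HDGR`` / ``TLS`` / ``CHROMATID_LOSS`` (missing classes count 0).
    control_count
        Colonies from the lesion-free arm.
    std_lesion, std_free
        Internal-standard colony counts of the two arms.
    """
    counts = {k: int(lesion_counts.get(k, 0)) for k in CLASS_NAMES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be non-negative")
    if control_count <= 0:
        raise ValueError("control colony count must be positive")
    if std_lesion <= 0 or std_free <= 0:
        raise ValueError("internal-standard counts must be positive")

    n_col = sum(counts.values())
    survival_pct = 100.0 * (n_col / std_lesion) / (control_count / std_free)

    classes: dict[str, ClassEstimate] = {}
    for name, k in counts.items():
        pct = 100.0 * (k / std_lesion) / (control_count / std_free)
        if n_col > 0:
            lo, hi = proportion_confint(k, n_col, alpha=alpha, method="wilson")
        else:
            lo = hi = 0.0
        classes[name] = ClassEstimate(pct, lo * survival_pct, hi * survival_pct, k)

    # survival CI: log-normal delta method over four independent counts
    if n_col > 0:
        se_log = math.sqrt(1 / n_col + 1 / std_lesion + 1 / control_count + 1 / std_free)
        z = float(stats.norm.ppf(1 - alpha / 2))
        s_lo = survival_pct * math.exp(-z * se_log)
        s_hi = survival_pct * math.exp(z * se_log)
    else:
        s_lo = s_hi = 0.0
    survival = ClassEstimate(survival_pct, s_lo, s_hi, n_col)

    return TolerancePartition(
        classes=classes,
        survival=survival,
        denominators={
            "lesion_colonies": n_col,
            "control_colonies": int(control_count),
            "std_lesion": int(std_lesion),
            "std_free": int(std_free),
        },
    )


def partition_from_table(row: Mapping, conversion_rate: float = 0.0,
                         alpha: float = 0.05) -> TolerancePartition:
    """Partition one colony-table row, optionally conversion-corrected.

    Pure-blue colonies are counted as HDGR (only the gap-repaired daughter
    formed the colony).
    """
    counts = {
        "HDGR": int(row["n_sectored"]) + int(row["n_pure_blue"]),
        "TLS": int(row["n_pale_blue"]),
        "CHROMATID_LOSS": int(row["n_white"]),
    }
    if conversion_rate:
        counts = marker_conversion_correct(counts, conversion_rate)
        counts = {k: int(round(v)) for k, v in counts.items()}
    return tolerance_partition(
        counts,
        control_count=int(row["n_control"]),
        std_lesion=int(row["internal_standard_lesion"]),
        std_free=int(row["internal_standard_free"]),
        alpha=alpha,
    )


def partition_to_frame(p: TolerancePartition) -> pd.DataFrame:
    """Partition as a tidy table (class, percent, ci_low, ci_high, denominator)."""
    rows = [
        {"class": name, "percent": est.percent, "ci_low": est.ci_low,
         "ci_high": est.ci_high, "count": est.count,
         "denominator": p.denominators["lesion_colonies"]}
        for name, est in p.classes.items()
    ]
    rows.append({
        "class": "survival", "percent": p.survival.percent,
        "ci_low": p.survival.ci_low, "ci_high": p.survival.ci_high,
        "count": p.survival.count,
        "denominator": p.denominators["control_colonies"],
    })
    return pd.DataFrame(rows)


def marker_conversion_correct(class_counts: Mapping[str, float],
                              c: float) -> dict[str, float]:
    """Undo B/D marker conversion in HDGR/TLS counts.

    A converted B/D locus turns an HDGR daughter's C+B into C+D and a TLS
    daughter's C+D into C+B, so observed counts are ``M @ true`` with
    ``M = [[1-c, c], [c, 1-c]]``. This applies ``M^-1``; negative corrected
    counts are clipped to zero with a warning. Other classes pass through.
    """
    if not 0.0 <= c < 0.5:
        raise ValueError("conversion rate must satisfy 0 <= c < 0.5")
    out = dict(class_counts)
    hd = float(class_counts.get("HDGR", 0))
    tl = float(class_counts.get("TLS", 0))
    det = 1.0 - 2.0 * c
    hd_true = ((1 - c) * hd - c * tl) / det
    tl_true = ((1 - c) * tl - c * hd) / det
    if hd_true < 0 or tl_true < 0:
        warnings.warn("conversion correction produced a negative count; clipped to 0",
                      stacklevel=2)
    out["HDGR"] = max(hd_true, 0.0)
    out["TLS"] = max(tl_true, 0.0)
    return out


def poisson_zero_fraction(lam: float) -> float:
    """Percentage of molecules with zero lesions under a Poisson(lam) load."""
    if lam < 0:
        raise ValueError("lesion mean must be non-negative")
    return 100.0 * math.exp(-lam)


def clustered_survival_correct(s_obs: float, f0: float, s_single: float) -> float:
    """Remove the lesion-free zero class from clustered-mode survival.

    Measured survival is the mixture ``S_obs = f0*S_single + (1-f0)*S_clustered``
    where ``f0`` is the Poisson zero-class fraction and ``S_single`` the
    survival of the single-lesion (no clustered load) construct; this returns
    ``S_clustered``, clipped to [0, 1] with a warning if the inversion falls
    outside.
    """
    if not 0.0 <= f0 < 1.0:
        raise ValueError("zero-class fraction must satisfy 0 <= f0 < 1")
    for name, s in (("S_obs", s_obs), ("S_single", s_single)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    s_corr = (s_obs - f0 * s_single) / (1.0 - f0)
    if not 0.0 <= s_corr <= 1.0:
        warnings.warn("corrected survival outside [0, 1]; clipped", stacklevel=2)
        s_corr = min(max(s_corr, 0.0), 1.0)
    return s_corr


def bootstrap_partition(lesion_counts: Mapping[str, int], control_count: int,
                        std_lesion: int, std_free: int,
                        n_boot: int = 2000, seed: int = 0,
                        alpha: float = 0.05) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap CIs for the ratio-of-ratios percentages.

    All counts are resampled as Poisson (plating statistics); returns
    ``{class or 'survival': (lo, hi)}`` percentage bounds.
    """
    rng = np.random.default_rng(seed)
    counts = np.array([int(lesion_counts.get(k, 0)) for k in CLASS_NAMES], float)
    k = rng.poisson(counts, size=(n_boot, len(CLASS_NAMES)))
    ctrl = np.maximum(rng.poisson(control_count, size=n_boot), 1)
    sl = np.maximum(rng.poisson(std_lesion, size=n_boot), 1)
    sf = np.maximum(rng.poisson(std_free, size=n_boot), 1)
    pct = 100.0 * (k / sl[:, None]) / (ctrl / sf)[:, None]
    out = {}
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    for i, name in enumerate(CLASS_NAMES):
        lo, hi = np.percentile(pct[:, i], qs)
        out[name] = (float(lo), float(hi))
    surv = pct.sum(axis=1)
    lo, hi = np.percentile(surv, qs)
    out["survival"] = (float(lo), float(hi))
    return out
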