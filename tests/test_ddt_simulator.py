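"""Stochastic outcome model: sampling law, closed form and round-trips."""

import dataclasses
import math

import numpy as np
import pytest

from ddt_assay.ddt_simulator import (
    CALIBRATIONS,
    COLONY_TABLE_COLUMNS,
    CLUSTERED_UV_MEAN,
    GenotypeParams,
    get_calibration,
    simulate_experiment,
    simulate_integration,
    survival_closed_form,
)
from ddt_assay.molecular_readout import decode_genotype, digest, pcr_amplify


def params(h, t, lam=0.8, c=0.0, lam_uv=0.0, strain="test", lesion="TT64"):
    return GenotypeParams(strain=strain, lesion=lesion, h=h, t=t,
                          lambda_opp=lam, lambda_uv=lam_uv, conversion_rate=c)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        params(0.7, 0.4)          # h + t > 1
    with pytest.raises(ValueError):
        params(-0.1, 0.0)
    with pytest.raises(ValueError):
        params(0.5, 0.0, lam=-1.0)


def test_degenerate_always_hdgr():
    rng = np.random.default_rng(0)
    for _ in range(50):
        oc = simulate_integration(params(1.0, 0.0, lam=0.0), "TT64", rng)
        assert oc.phenotype == "sectored-blue-white"
        assert oc.daughter1_viable and oc.daughter2_viable
        assert oc.daughter1_alleles == ("C", "B")
        assert oc.daughter2_alleles == ("A", "B")


def test_degenerate_always_chromatid_loss():
    rng = np.random.default_rng(0)
    for _ in range(50):
        oc = simulate_integration(params(0.0, 0.0, lam=0.0), "TT64", rng)
        assert oc.phenotype == "white"
        assert not oc.daughter1_viable and oc.daughter2_viable


def test_large_burden_kills_everything():
    rng = np.random.default_rng(0)
    outcomes = [simulate_integration(params(0.0, 0.0, lam=50.0), "TT64", rng)
                for _ in range(200)]
    assert all(oc.phenotype == "dead" for oc in outcomes)


def test_viability_invariants_scalar():
    """daughter1 lives iff the gap resolved; daughter2 iff all opposite gaps."""
    rng = np.random.default_rng(42)
    for _ in range(500):
        oc = simulate_integration(params(0.4, 0.1, lam=1.5), "TT64", rng)
        assert oc.daughter1_viable == (oc.gap_resolution in ("HDGR", "TLS"))
        assert oc.daughter2_viable == (oc.n_opposite_resolved == oc.n_opposite)
        if not (oc.daughter1_viable or oc.daughter2_viable):
            assert oc.phenotype == "dead"


def test_experiment_determinism_and_schema():
    p = params(0.5, 0.05, c=0.05)
    t1 = simulate_experiment(p, n_integrations=1000, seed=123)
    t2 = simulate_experiment(p, n_integrations=1000, seed=123)
    assert t1.equals(t2)
    assert list(t1.columns) == COLONY_TABLE_COLUMNS
    t3 = simulate_experiment(p, n_integrations=1000, seed=124)
    assert not t3.equals(t1)


def test_class_counts_conserve_integrations():
    for seed, p in enumerate([params(0.9, 0.0), params(0.05, 0.01),
                              params(0.4, 0.2, lam=2.0, c=0.05)]):
        row = simulate_experiment(p, n_integrations=5000, seed=seed).iloc[0]
        total = (row.n_sectored + row.n_pale_blue + row.n_white
                 + row.n_pure_blue + row.n_dead)
        assert total == row.n_integrations == 5000


def test_closed_form_degenerate_cases():
    assert survival_closed_form(params(1.0, 0.0, lam=3.0)).survival == pytest.approx(1.0)
    cf = survival_closed_form(params(0.3, 0.1, lam=0.0))
    assert cf.survival == pytest.approx(1.0)
    assert cf.chromatid_loss == pytest.approx(0.6)


def test_closed_form_reca_value():
    """h=0.05, t=0.01, lam=0.8 puts relative survival near one half."""
    cf = survival_closed_form(params(0.05, 0.01, lam=0.8))
    expected = 0.06 + 0.94 * math.exp(-0.8 * 0.94)
    assert cf.survival == pytest.approx(expected, abs=1e-12)
    assert cf.survival == pytest.approx(0.503, abs=0.001)


def test_monte_carlo_matches_closed_form_grid():
    """Simulated class frequencies track the closed form within 3 SE."""
    rng = np.random.default_rng(7)
    n = 20000
    for i in range(20):
        h, t = sorted(rng.uniform(0, 1, size=2))
        t = (t - h) * 0.2
        lam = rng.uniform(0, 2)
        p = params(round(h, 3), round(t, 3), lam=round(lam, 3))
        cf = survival_closed_form(p)
        row = simulate_experiment(p, n_integrations=n, seed=1000 + i).iloc[0]
        surv_hat = 1 - row.n_dead / n
        se = math.sqrt(cf.survival * (1 - cf.survival) / n) + 1e-9
        assert abs(surv_hat - cf.survival) <= 3 * se + 1e-6
        loss_hat = row.n_white / n
        se_l = math.sqrt(cf.chromatid_loss * (1 - cf.chromatid_loss) / n) + 1e-9
        assert abs(loss_hat - cf.chromatid_loss) <= 3 * se_l + 1e-6


def test_survival_monotonicity():
    """S is non-decreasing in h and t, non-increasing in the burden."""
    hs = np.linspace(0, 0.9, 10)
    lams = np.linspace(0, 3, 13)
    for lam in lams:
        s = [survival_closed_form(params(h, 0.05, lam=lam)).survival for h in hs]
        assert np.all(np.diff(s) >= -1e-12)
        s_t = [survival_closed_form(params(0.3, t, lam=lam)).survival
               for t in np.linspace(0, 0.5, 8)]
        assert np.all(np.diff(s_t) >= -1e-12)
    for h in hs:
        s = [survival_closed_form(params(h, 0.02, lam=lam)).survival for lam in lams]
        assert np.all(np.diff(s) <= 1e-12)


def test_pipeline_roundtrip_decoding(pll1_2c):
    """With no marker conversion, decoding recovers every transmitted allele."""
    p = params(0.6, 0.1, lam=0.8, c=0.0)
    _, outcomes = simulate_experiment(
        p, n_integrations=300, seed=5, construct=pll1_2c, collect_outcomes=True)
    fwd, rev = pll1_2c.primers
    checked = 0
    for oc in outcomes:
        for alleles in (oc.daughter1_alleles, oc.daughter2_alleles):
            if alleles is None:
                continue
            amplicon = pcr_amplify(pll1_2c.daughter_sequence(alleles), fwd, rev)
            assert decode_genotype(digest(amplicon, pll1_2c.digest_enzymes),
                                   pll1_2c) == alleles
            checked += 1
    assert checked > 100


def test_conversion_flips_only_bd():
    p = params(1.0, 0.0, lam=0.0, c=1.0)  # every B/D locus converts
    rng = np.random.default_rng(0)
    oc = simulate_integration(p, "TT64", rng)
    assert oc.daughter1_alleles == ("C", "D")  # HDGR daughter reads as TLS
    assert oc.daughter2_alleles == ("A", "D")
    assert oc.phenotype == "pale-blue"


def test_lesion_free_arm_survives_completely():
    p = params(0.895, 0.002, c=0.05)
    row = simulate_experiment(p, lesion="none", n_integrations=2000, seed=9).iloc[0]
    assert row.n_dead == 0
    assert row.n_white == 0  # both strands replicate; no pure-white colonies


def test_calibration_table_contents():
    assert get_calibration("parental", "TT64").h == pytest.approx(0.895)
    assert get_calibration("recA", "CPD").h == pytest.approx(0.05)
    # sulA behaves as the parental strain
    par, sul = get_calibration("parental", "TT64"), get_calibration("sulA", "TT64")
    assert (par.h, par.t) == (sul.h, sul.t)
    # recF shows the G-AAF TLS rise (four-fold over parental)
    assert get_calibration("recF", "G-AAF").t == pytest.approx(
        4 * get_calibration("parental", "G-AAF").t)
    clustered = get_calibration("recA", "TT64", clustered=True)
    assert clustered.lambda_uv == pytest.approx(CLUSTERED_UV_MEAN)
    with pytest.raises(KeyError):
        get_calibration("recQ", "TT64")
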