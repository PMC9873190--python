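"""Two-cohort delta R^2, RRHO and peak-time population classification."""

import math

import numpy as np
import pandas as pd
import pytest

from ultradian.differential import (
    classify_gain_loss,
    classify_phase_population,
    delta_r2_table,
    delta_r2_test,
    peak_times,
    phase_population_table,
    rrho,
)
from ultradian.nlr import RhythmFit


def _mat(Y, prefix):
    return pd.DataFrame(
        Y, index=[f"g{i}" for i in range(len(Y))],
        columns=[f"{prefix}{j}" for j in range(Y.shape[1])],
    )


def test_identical_cohorts_have_zero_delta(uneven_zt, rng):
    Y = rng.normal(0, 1, (4, 46))
    tab = delta_r2_table(_mat(Y, "a"), uneven_zt, _mat(Y, "b"), uneven_zt, n_perm=100, seed=0)
    assert np.allclose(tab["delta_r2"], 0.0, atol=1e-12)


def test_overlapping_subject_ids_rejected(uneven_zt, rng):
    Y = rng.normal(0, 1, (2, 46))
    with pytest.raises(ValueError, match="share subject ids"):
        delta_r2_table(_mat(Y, "s"), uneven_zt, _mat(Y, "s"), uneven_zt, n_perm=100)


def test_planted_loss_is_detected(uneven_zt, rng):
    ya = 1.5 * np.cos(2 * np.pi * (uneven_zt - 3) / 12.0) + rng.normal(0, 0.7, 46)
    yb = rng.normal(0, 0.7, 46)
    delta, p = delta_r2_test(ya, uneven_zt, yb, uneven_zt, n_perm=500, seed=1)
    assert delta > 0.2 and p < 0.05


def test_delta_p_calibrated_under_null(uneven_zt, rng):
    """Random split of one pool: p_delta should be ~uniform."""
    G = 300
    Ya = rng.normal(0, 1, (G, 46))
    Yb = rng.normal(0, 1, (G, 46))
    tab = delta_r2_table(_mat(Ya, "a"), uneven_zt, _mat(Yb, "b"), uneven_zt, n_perm=200, seed=5)
    frac = (tab["p_delta"] < 0.05).mean()
    # one-sided-by-observed-sign doubles the nominal rate at alpha/...: the
    # sign is data-chosen, so the null rate target is ~0.10 here
    assert abs(frac - 0.10) < 3 * math.sqrt(0.10 * 0.90 / G) + 0.01


def _fits(ps):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(ps))], "p": ps})


def test_classification_rules_and_counts():
    fits_a = _fits([0.001, 0.001, 0.2, 0.01])
    fits_b = _fits([0.2, 0.001, 0.001, 0.01])
    deltas = pd.DataFrame(
        {
            "gene_id": ["g0", "g1", "g2", "g3"],
            "r2_a": [0.5, 0.4, 0.05, 0.3],
            "r2_b": [0.05, 0.4, 0.5, 0.3],
            "delta_r2": [0.45, 0.0, -0.45, 0.0],
            "p_delta": [0.001, 0.9, 0.001, 0.9],
        }
    )
    out, counts = classify_gain_loss(fits_a, fits_b, deltas, alpha=0.05)
    klass = out.set_index("gene_id")["class"]
    assert klass["g0"] == "lost"
    assert klass["g1"] == "shared"  # significant in both, no delta
    assert klass["g2"] == "gained"
    assert klass["g3"] == "shared"
    assert counts == {"rhythmic_a": 3, "rhythmic_b": 3, "rhythmic_both": 2, "lost": 1, "gained": 1}


def test_cohort_swap_antisymmetry(uneven_zt, rng):
    """Swapping cohorts maps lost <-> gained exactly."""
    G = 40
    Ya = rng.normal(0, 1, (G, 46))
    Ya[:10] += 1.5 * np.cos(2 * np.pi * (uneven_zt - 2) / 12.0)
    Yb = rng.normal(0, 1, (G, 46))
    Yb[10:18] += 1.5 * np.cos(2 * np.pi * (uneven_zt - 7) / 12.0)
    ma, mb = _mat(Ya, "a"), _mat(Yb, "b")
    from ultradian.nlr import fit_transcriptome

    fa = fit_transcriptome(ma, uneven_zt, 12.0, n_perm=200, seed=1)
    fb = fit_transcriptome(mb, uneven_zt, 12.0, n_perm=200, seed=2)
    d = delta_r2_table(ma, uneven_zt, mb, uneven_zt, n_perm=200, seed=3)
    out, _ = classify_gain_loss(fa, fb, d, alpha=0.05)

    d_swapped = d.assign(
        r2_a=d["r2_b"], r2_b=d["r2_a"], delta_r2=-d["delta_r2"]
    )
    out_sw, _ = classify_gain_loss(fb, fa, d_swapped, alpha=0.05)
    swap = {"lost": "gained", "gained": "lost", "shared": "shared", "neither": "neither"}
    expected = out.set_index("gene_id")["class"].map(swap)
    assert (out_sw.set_index("gene_id")["class"] == expected).all()


def test_alpha_validation():
    with pytest.raises(ValueError, match="alpha"):
        classify_gain_loss(_fits([0.5]), _fits([0.5]),
                           pd.DataFrame({"gene_id": ["g0"], "r2_a": [0], "r2_b": [0],
                                         "delta_r2": [0], "p_delta": [1]}), alpha=0.6)


# ---------------------------------------------------------------------------
# RRHO


def exact_hyper_tail(k, n, i, j):
    """P(overlap >= k) by direct enumeration with exact rationals."""
    total = math.comb(n, j)
    acc = 0
    for m in range(k, min(i, j) + 1):
        acc += math.comb(i, m) * math.comb(n - i, j - m)
    return acc / total


def test_rrho_matches_exact_enumeration(rng):
    n = 20
    genes = [f"g{i}" for i in range(n)]
    pa = pd.Series(rng.uniform(0, 1, n), index=genes)
    pb = pd.Series(rng.uniform(0, 1, n), index=genes)
    grid = rrho(pa, pb, step=1)
    ra = pa.sort_values().index
    rb = pb.sort_values().index
    for i in (1, 3, 7, 12, 20):
        for j in (2, 5, 11, 20):
            k = len(set(ra[:i]) & set(rb[:j]))
            expected = -math.log10(exact_hyper_tail(k, n, i, j))
            assert grid.loc[i, j] == pytest.approx(expected, abs=1e-9)


def test_rrho_self_comparison_is_symmetric_and_diagonal_maximal(rng):
    n = 20
    genes = [f"g{i}" for i in range(n)]
    p = pd.Series(rng.uniform(0, 1, n), index=genes)
    grid = rrho(p, p.copy(), step=1)
    assert np.allclose(grid.to_numpy(), grid.to_numpy().T)
    g = grid.to_numpy()
    for row in range(n - 1):  # last row is the degenerate all-genes cutoff
        assert g[row, row] == max(g[row, : n - 1])


def test_rrho_input_validation(rng):
    genes = ["a", "b", "c"]
    p = pd.Series([0.1, 0.2, 0.3], index=genes)
    with pytest.raises(ValueError, match="universes"):
        rrho(p, pd.Series([0.1, 0.2, 0.3], index=["a", "b", "d"]))
    dup = pd.Series([0.1, 0.2, 0.3], index=["a", "a", "b"])
    with pytest.raises(ValueError):
        rrho(dup, dup)
    with pytest.raises(ValueError, match="missing"):
        rrho(p, pd.Series([0.1, np.nan, 0.3], index=genes))


def test_rrho_grid_dimensions(rng):
    genes = [f"g{i}" for i in range(25)]
    p = pd.Series(rng.uniform(0, 1, 25), index=genes)
    grid = rrho(p, p.copy(), step=10)
    assert grid.shape == (3, 3)
    assert list(grid.index) == [10, 20, 25]


# ---------------------------------------------------------------------------
# Peak times and phase populations


@pytest.mark.parametrize("acro,peaks", [(2.5, (2.5, 14.5)), (11.9, (11.9, 23.9))])
def test_peak_times(acro, peaks):
    call = peak_times(RhythmFit("g", 12.0, 0.0, 1.0, acro, 0.9))
    assert (call.peak1, call.peak2) == pytest.approx(peaks)
    assert call.peak2 - call.peak1 == pytest.approx(12.0, abs=1e-12)


def test_peak_times_rejects_non_12h_fit():
    with pytest.raises(ValueError, match="12 h"):
        peak_times(RhythmFit("g", 24.0, 0.0, 1.0, 3.0, 0.9))


@pytest.mark.parametrize(
    "peak1,pop",
    [(2.5, "ME"), (8.5, "AN"), (5.5, "AN"), (11.5, "ME"), (0.0, "ME"), (11.49, "AN")],
)
def test_phase_population_boundaries(peak1, pop):
    assert classify_phase_population(peak1) == pop


def test_phase_population_requires_window():
    with pytest.raises(ValueError):
        classify_phase_population(12.0)


def test_phase_population_table_filters_significant():
    fits = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "period": [12.0, 12.0, 12.0],
            "acrophase": [2.5, 8.5, 1.0],
            "p": [0.001, 0.005, 0.5],
        }
    )
    tab = phase_population_table(fits, alpha=0.01)
    assert tab["gene_id"].tolist() == ["a", "b"]
    assert tab["population"].tolist() == ["ME", "AN"]
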