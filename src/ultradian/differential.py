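"""Two-cohort comparison of 12 h rhythmicity.

A gene can *lose* or *gain* rhythmicity between cohorts (e.g. controls vs
cases). For each gene the difference in goodness of fit, delta R^2 = R^2_A -
R^2_B, is tested against a null built by randomly reassigning subjects to
cohorts (preserving group sizes); the p-value is one-sided for the observed
sign with the usual pseudo-count. Classification:

* ``lost``   — rhythmic in A (p < alpha), delta R^2 > 0 and significant;
* ``gained`` — rhythmic in B, delta R^2 < 0 and significant;
* ``shared`` — rhythmic in both, no significant difference;
* ``neither`` otherwise.

Threshold-free concordance between cohorts uses the rank-rank hypergeometric
overlap (RRHO): genes are ranked by -log10(p) in each cohort and, for every
pair of rank cutoffs, the hypergeometric tail probability of the observed
overlap is mapped on a grid.

Peak-time analysis splits 12 h rhythmic genes into the two phase
populations: morning/evening (ME; peaks near ZT 2-3 and 14-15) and
afternoon/night (AN; peaks near ZT 8-9 and 20-21), with the boundary at the
midpoints ZT 5.5 / 11.5 of the two cluster centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .nlr import ALPHA_TWO_COHORT, _as_frame, _centered_orthobasis, _r2_matrix

__all__ = [
    "DifferentialResult",
    "PhaseCall",
    "delta_r2_test",
    "delta_r2_table",
    "classify_gain_loss",
    "rrho",
    "peak_times",
    "classify_phase_population",
    "ME_AN_BOUNDS",
]

#: Half-open boundaries splitting peak1 in [0, 12) into ME and AN; midpoints
#: between the observed cluster centers ZT 2.5 and ZT 8.5.
ME_AN_BOUNDS = (5.5, 11.5)


@dataclass
class DifferentialResult:
    gene_id: str
    r2_a: float
    r2_b: float
    delta_r2: float
    p_delta: float
    klass: str


@dataclass
class PhaseCall:
    gene_id: str
    peak1: float
    peak2: float
    population: str = ""


def _pooled_r2(
    Z: np.ndarray, zt: np.ndarray, na: int, perm: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = perm[:na], perm[na:]
    return (
        _r2_matrix(Z[:, ia], zt[ia], period),
        _r2_matrix(Z[:, ib], zt[ib], period),
    )


def delta_r2_table(
    Ya,
    zt_a: Sequence[float],
    Yb,
    zt_b: Sequence[float],
    period: float = 12.0,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """delta R^2 and its permutation p-value for every shared gene.

    ``Ya``/``Yb`` are ExpressionMatrix or DataFrame with identical gene
    indices. The null reassigns the pooled subjects to two groups of the
    original sizes; p is one-sided for the observed sign of delta R^2.
    """
    A, B = _as_frame(Ya), _as_frame(Yb)
    if not A.index.equals(B.index):
        raise ValueError("cohort matrices must share an identical gene index")
    shared = set(A.columns) & set(B.columns)
    if shared:
        raise ValueError(f"cohorts share subject ids: {sorted(shared)[:5]}")
    zt_a = np.asarray(zt_a, dtype=float)
    zt_b = np.asarray(zt_b, dtype=float)
    Za, Zb = A.to_numpy(dtype=float), B.to_numpy(dtype=float)
    na, nb = Za.shape[1], Zb.shape[1]
    r2a = _r2_matrix(Za, zt_a, period)
    r2b = _r2_matrix(Zb, zt_b, period)
    delta = r2a - r2b

    Z = np.concatenate([Za, Zb], axis=1)
    zt = np.concatenate([zt_a, zt_b])
    rng = np.random.default_rng(seed)
    ge = np.zeros(delta.size, dtype=int)  # null >= obs (for delta >= 0)
    le = np.zeros(delta.size, dtype=int)  # null <= obs (for delta < 0)
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        r2a_n, r2b_n = _pooled_r2(Z, zt, na, perm, period)
        dn = r2a_n - r2b_n
        ge += dn >= delta - 1e-12
        le += dn <= delta + 1e-12
    k = np.where(delta >= 0, ge, le)
    p = (1 + k) / (n_perm + 1)
    return pd.DataFrame(
        {
            "gene_id": A.index.astype(str),
            "r2_a": r2a,
            "r2_b": r2b,
            "delta_r2": delta,
            "p_delta": p,
        }
    )


def delta_r2_test(
    y_a: Sequence[float],
    zt_a: Sequence[float],
    y_b: Sequence[float],
    zt_b: Sequence[float],
    period: float = 12.0,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Single-gene convenience wrapper: returns (delta_r2, p_delta)."""
    ya = pd.DataFrame([np.asarray(y_a, float)], index=["g"], columns=[f"a{i}" for i in range(len(y_a))])
    yb = pd.DataFrame([np.asarray(y_b, float)], index=["g"], columns=[f"b{i}" for i in range(len(y_b))])
    row = delta_r2_table(ya, zt_a, yb, zt_b, period, n_perm, seed).iloc[0]
    return float(row["delta_r2"]), float(row["p_delta"])


def classify_gain_loss(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    deltas: pd.DataFrame,
    alpha: float = ALPHA_TWO_COHORT,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene loss/gain/shared/neither labels plus summary counts.

    ``fits_a``/``fits_b`` are fixed-period fit tables (gene_id, p, ...);
    ``deltas`` is the delta R^2 table. All three must cover the same genes.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")
    genes = set(fits_a["gene_id"])
    if genes != set(fits_b["gene_id"]) or genes != set(deltas["gene_id"]):
        raise ValueError("gene universes differ between inputs")

    pa = fits_a.set_index("gene_id")["p"]
    pb = fits_b.set_index("gene_id")["p"]
    d = deltas.set_index("gene_id")
    order = d.index
    rhythmic_a = pa.loc[order] < alpha
    rhythmic_b = pb.loc[order] < alpha
    sig_delta = d["p_delta"] < alpha

    lost = rhythmic_a & sig_delta & (d["delta_r2"] > 0)
    gained = rhythmic_b & sig_delta & (d["delta_r2"] < 0)
    shared = rhythmic_a & rhythmic_b & ~lost & ~gained
    klass = np.select([lost, gained, shared], ["lost", "gained", "shared"], "neither")

    out = d.reset_index()[["gene_id", "r2_a", "r2_b", "delta_r2", "p_delta"]]
    out["p_a"] = pa.loc[order].to_numpy()
    out["p_b"] = pb.loc[order].to_numpy()
    out["class"] = klass
    counts = {
        "rhythmic_a": int(rhythmic_a.sum()),
        "rhythmic_b": int(rhythmic_b.sum()),
        "rhythmic_both": int((rhythmic_a & rhythmic_b).sum()),
        "lost": int(lost.sum()),
        "gained": int(gained.sum()),
    }
    return out, counts


def rrho(p_a: pd.Series, p_b: pd.Series, step: int | None = None) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap grid of two per-gene p-value lists.

    Genes are ranked by -log10(p), most significant first (ties broken by
    gene id for determinism). Entry (i, j) of the returned DataFrame is
    -log10 of the hypergeometric tail probability of observing at least the
    actual overlap between the top i*step genes of list A and the top
    j*step genes of list B. Index/columns are the rank cutoffs.
    """
    if not p_a.index.sort_values().equals(p_b.index.sort_values()):
        raise ValueError("gene universes of the two lists differ")
    if p_a.index.has_duplicates or p_b.index.has_duplicates:
        raise ValueError("duplicated gene ids")
    if p_a.isna().any() or p_b.isna().any():
        raise ValueError("missing p-values")
    n = p_a.size
    if step is None:
        step = max(1, n // 100)

    def _ranks(p: pd.Series) -> pd.Series:
        ordered = p.to_frame("p").assign(g=p.index.astype(str)).sort_values(["p", "g"])
        return pd.Series(np.arange(1, n + 1), index=ordered.index)

    ra = _ranks(p_a)
    rb = _ranks(p_b).loc[ra.index]

    n_cells = -(-n // step)  # ceil(n / step)
    cutoffs = np.minimum(np.arange(1, n_cells + 1) * step, n)
    # overlap counts via a cumulative 2-D histogram of the rank pairs
    H, _, _ = np.histogram2d(
        ra.to_numpy(), rb.to_numpy(), bins=[np.r_[0, cutoffs] + 0.5, np.r_[0, cutoffs] + 0.5]
    )
    K = H.cumsum(axis=0).cumsum(axis=1)  # K[i, j] = |top_i(A) & top_j(B)|
    ii = cutoffs[:, None].astype(int)
    jj = cutoffs[None, :].astype(int)
    tail = hypergeom.sf(K - 1, n, ii, jj)
    grid = -np.log10(np.clip(tail, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(grid, index=cutoffs, columns=cutoffs)


def peak_times(fit) -> PhaseCall:
    """Both daily peaks of a 12 h fit: peak1 in [0, 12), peak2 = peak1 + 12."""
    if fit.period != 12.0:
        raise ValueError(f"peak-time split requires a 12 h fit, got period {fit.period}")
    peak1 = float(fit.acrophase % 12.0)
    return PhaseCall(fit.gene_id, peak1, peak1 + 12.0)


def classify_phase_population(peak1: float) -> str:
    """ME (morning/evening) or AN (afternoon/night) from the first peak time."""
    if not (0.0 <= peak1 < 12.0):
        raise ValueError(f"peak1 must be in [0, 12), got {peak1}")
    lo, hi = ME_AN_BOUNDS
    return "AN" if lo <= peak1 < hi else "ME"


def phase_population_table(fits: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Peak times and ME/AN labels for significant 12 h fits."""
    sig = fits[(fits["p"] < alpha) & (fits["period"] == 12.0)]
    peak1 = sig["acrophase"].to_numpy() % 12.0
    pop = [classify_phase_population(p1) for p1 in peak1]
    return pd.DataFrame(
        {
            "gene_id": sig["gene_id"].to_numpy(),
            "peak1": peak1,
            "peak2": peak1 + 12.0,
            "population": pop,
        }
    )
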