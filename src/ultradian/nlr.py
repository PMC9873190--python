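"""Fixed-period sinusoidal regression with permutation p-values.

Per gene, expression across subjects ordered by Zeitgeber time (ZT) is fit to

    y = mesor + A * cos(2*pi*(t - acrophase)/period)

at a *fixed* period (12 h or 24 h). On the cos/sin basis the problem is
ordinary least squares, so the fit is closed-form; amplitude A and acrophase
follow from the cos/sin coefficients. Significance is an empirical p-value
against a null built by re-fitting after randomizing the time-of-death
labels, with the standard pseudo-count p = (1 + k) / (n_perm + 1).

Bootstrap stability resamples subjects with replacement and reports, per
gene, the fraction of resamples in which the gene stays significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RhythmFit",
    "FitError",
    "fit_sinusoid",
    "empirical_p",
    "fit_transcriptome",
    "bootstrap_stability",
    "MIN_SUBJECTS",
    "DEFAULT_N_PERM",
    "ALPHA_SINGLE_COHORT",
    "ALPHA_TWO_COHORT",
]

MIN_SUBJECTS = 6
DEFAULT_N_PERM = 1000
#: Significance cutoffs: stringent for the full single-cohort scan, relaxed
#: for the smaller two-cohort comparisons.
ALPHA_SINGLE_COHORT = 0.01
ALPHA_TWO_COHORT = 0.05


class FitError(ValueError):
    """Raised when a sinusoid fit is ill-posed (too few or degenerate data)."""


@dataclass
class RhythmFit:
    """Result of one fixed-period sinusoid fit.

    amplitude is half the peak-to-trough height on the log2 scale; acrophase
    is the ZT (hours in [0, period)) of the first fitted maximum.
    """

    gene_id: str
    period: float
    mesor: float
    amplitude: float
    acrophase: float
    r2: float
    p_emp: Optional[float] = None


def _check_inputs(y: np.ndarray, zt: np.ndarray, period: float) -> None:
    if period <= 0:
        raise FitError(f"period must be positive, got {period}")
    if y.shape != zt.shape or y.ndim != 1:
        raise FitError("y and zt must be 1-D arrays of equal length")
    if y.size < MIN_SUBJECTS:
        raise FitError(f"need at least {MIN_SUBJECTS} observations, got {y.size}")
    if not np.all(np.isfinite(zt)):
        raise FitError("zt contains non-finite values")
    if np.unique(zt).size < 3:
        raise FitError("need at least 3 distinct zt values")


def _basis(zt: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(zt), np.cos(w * zt), np.sin(w * zt)])


def fit_sinusoid(
    y: Sequence[float], zt: Sequence[float], period: float, gene_id: str = ""
) -> RhythmFit:
    """Least-squares fixed-period sinusoid fit for one gene.

    Returns mesor, amplitude = sqrt(a^2 + b^2), acrophase in [0, period),
    and R^2 = 1 - SSE/SST. A constant gene gets amplitude 0 and R^2 = 0 by
    convention.
    """
    y = np.asarray(y, dtype=float)
    zt = np.asarray(zt, dtype=float)
    _check_inputs(y, zt, period)

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0 or np.all(y == y[0]):
        return RhythmFit(gene_id, period, float(y[0]), 0.0, 0.0, 0.0)

    X = _basis(zt, period)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, a, b = (float(v) for v in beta)
    resid = y - X @ beta
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    r2 = float(min(max(r2, 0.0), 1.0))
    amplitude = float(np.hypot(a, b))
    # a*cos(wt) + b*sin(wt) = A*cos(w*(t - acrophase)) with w*acrophase = atan2(b, a)
    acrophase = float(np.arctan2(b, a) / (2.0 * np.pi) * period % period)
    if acrophase >= period:  # guard the float wrap at exactly `period`
        acrophase = 0.0
    if amplitude == 0.0:
        acrophase = 0.0
    return RhythmFit(gene_id, period, mesor, amplitude, acrophase, r2)


def _r2_matrix(Y: np.ndarray, zt: np.ndarray, period: float) -> np.ndarray:
    """Vectorized R^2 of the fixed-period fit for every row of Y.

    Uses an orthonormal basis Q of the centered cos/sin columns, so that
    R^2_g = ||Q^T yc_g||^2 / ||yc_g||^2.
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sst = np.sum(Yc**2, axis=1)
    Q = _centered_orthobasis(zt, period)
    proj = Yc @ Q  # (G, 2)
    ssr = np.sum(proj**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssr / np.where(sst > 0, sst, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0)


def _centered_orthobasis(zt: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    C = np.column_stack([np.cos(w * zt), np.sin(w * zt)])
    C -= C.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(C)
    return Q


def _null_r2(
    Y: np.ndarray, zt: np.ndarray, period: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null R^2 matrix (genes x permutations) from TOD-label randomization.

    Shuffling zt labels is equivalent to permuting each expression vector
    relative to a fixed time basis; one shared permutation set serves all
    genes, which keeps the null exchangeable and the run deterministic.
    """
    G, N = Y.shape
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sst = np.sum(Yc**2, axis=1)
    Q = _centered_orthobasis(zt, period)
    null = np.empty((G, n_perm))
    for j in range(n_perm):
        perm = rng.permutation(N)
        proj = Yc[:, perm] @ Q
        with np.errstate(invalid="ignore", divide="ignore"):
            null[:, j] = np.where(sst > 0, np.sum(proj**2, axis=1) / np.where(sst > 0, sst, 1.0), 0.0)
    return null


def empirical_p(
    y: Sequence[float],
    zt: Sequence[float],
    period: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> float:
    """Permutation p-value for one gene: p = (1 + #{null R^2 >= obs}) / (n_perm + 1).

    Ties between null and observed R^2 count against significance.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    y = np.asarray(y, dtype=float)
    zt = np.asarray(zt, dtype=float)
    _check_inputs(y, zt, period)
    obs = fit_sinusoid(y, zt, period).r2
    rng = np.random.default_rng(seed)
    null = _null_r2(y[None, :], zt, period, n_perm, rng)[0]
    k = int(np.sum(null >= obs - 1e-12))
    return (1 + k) / (n_perm + 1)


def fit_transcriptome(
    matrix,
    zt: Sequence[float],
    period: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fit every gene of an expression matrix at a fixed period.

    Parameters
    ----------
    matrix : ExpressionMatrix or pandas.DataFrame
        Genes as rows, subjects as columns; log2 or batch-adjusted stage.
    zt : sequence of float
        One ZT value per subject, aligned with the matrix columns.
    period : float
        Fixed period in hours (12 or 24 in practice).
    n_perm, seed :
        Size and seed of the shared permutation null.

    Returns
    -------
    pandas.DataFrame
        Columns gene_id, period, mesor, amplitude, acrophase, peak1_zt,
        peak2_zt, r2, p, q — sorted by p then gene_id. q is a
        Benjamini-Hochberg column emitted for convenience only.
    """
    df = _as_frame(matrix)
    zt = np.asarray(zt, dtype=float)
    if zt.size != df.shape[1]:
        raise ValueError(
            f"zt has {zt.size} entries but matrix has {df.shape[1]} subjects"
        )
    Y = df.to_numpy(dtype=float)
    G, N = Y.shape
    if N < MIN_SUBJECTS:
        raise FitError(f"need at least {MIN_SUBJECTS} subjects, got {N}")

    X = _basis(zt, period)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (3, G)
    mesor, a, b = beta
    amplitude = np.hypot(a, b)
    acrophase = (np.arctan2(b, a) / (2.0 * np.pi) * period) % period
    acrophase = np.where(acrophase >= period, 0.0, acrophase)
    r2 = _r2_matrix(Y, zt, period)

    rng = np.random.default_rng(seed)
    null = _null_r2(Y, zt, period, n_perm, rng)
    k = np.sum(null >= r2[:, None] - 1e-12, axis=1)
    p = (1 + k) / (n_perm + 1)

    constant = np.ptp(Y, axis=1) == 0
    amplitude = np.where(constant, 0.0, amplitude)
    acrophase = np.where(constant | (amplitude == 0), 0.0, acrophase)
    r2 = np.where(constant, 0.0, r2)
    p = np.where(constant, 1.0, p)

    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene_id": df.index.astype(str),
            "period": period,
            "mesor": mesor,
            "amplitude": amplitude,
            "acrophase": acrophase,
            "peak1_zt": acrophase % period,
            # an ultradian fit peaks twice per day: second peak one period later
            "peak2_zt": (acrophase % period) + period if period < 24.0 else np.nan,
            "r2": r2,
            "p": p,
            "q": q,
        }
    )
    out = out.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out


def bootstrap_stability(
    matrix,
    zt: Sequence[float],
    period: float,
    n_boot: int = 100,
    alpha: float = ALPHA_SINGLE_COHORT,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fraction of subject-resamples in which each gene stays significant.

    Subjects are resampled with replacement ``n_boot`` times; each resample
    is re-fit (including its permutation null) and a gene counts as stable
    in that resample when p < alpha. Resamples with fewer than
    ``MIN_SUBJECTS`` distinct subjects are redrawn.
    """
    if n_boot < 10:
        raise ValueError(f"n_boot must be >= 10, got {n_boot}")
    df = _as_frame(matrix)
    zt = np.asarray(zt, dtype=float)
    Y = df.to_numpy(dtype=float)
    G, N = Y.shape
    rng = np.random.default_rng(seed)
    hits = np.zeros(G)
    redrawn = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, N, size=N)
            if np.unique(idx).size >= MIN_SUBJECTS and np.unique(zt[idx]).size >= 3:
                break
            redrawn += 1
        Yb, ztb = Y[:, idx], zt[idx]
        r2 = _r2_matrix(Yb, ztb, period)
        null = _null_r2(Yb, ztb, period, n_perm, rng)
        p = (1 + np.sum(null >= r2[:, None] - 1e-12, axis=1)) / (n_perm + 1)
        hits += p < alpha
    out = pd.DataFrame(
        {"gene_id": df.index.astype(str), "stability": hits / n_boot}
    )
    out.attrs["redrawn_resamples"] = redrawn
    return out


def _as_frame(matrix) -> pd.DataFrame:
    """Accept an ExpressionMatrix or a bare genes-by-subjects DataFrame."""
    data = getattr(matrix, "data", matrix)
    if not isinstance(data, pd.DataFrame):
        raise TypeError("matrix must be an ExpressionMatrix or DataFrame")
    stage = getattr(matrix, "stage", None)
    if stage is not None and stage not in ("log2", "adjusted"):
        raise ValueError(f"rhythm fitting expects log2 or adjusted data, got stage {stage!r}")
    return data
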