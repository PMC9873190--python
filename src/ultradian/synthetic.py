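"""Synthetic study generator with known planted truth.

Real postmortem cohorts of this design are controlled-access, so every
downstream stage is exercised on simulated data that emulates the study:
~13,914 genes after filtering, cohorts of 104 / 46 / 46 subjects whose
times of death spread over the full 24 h cycle, two collection sites in
equal proportions, and genes carrying superimposed 12 h and/or 24 h
sinusoids on the log2 scale:

    value(g, s) = baseline_g
                  + sum_c A_c * cos(2*pi*(zt_s - acrophase_c)/period_c)
                  + Normal(0, noise_sd_g)

Two-cohort studies plant differential effects — loss of the 12 h component,
gain of it, or a phase shift — and return the truth table so sensitivity
and specificity of the detection stages can be measured exactly.

Times of death are drawn from a configurable law (a two-mode von Mises
mixture by default, mimicking the uneven spread of real death times; a
uniform law is available for calibration work) and converted to concrete
local death datetimes anchored to the actual computed sunrise of a real
site, so the Zeitgeber conversion round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta, timezone
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .zeitgeber import sunrise_utc

__all__ = [
    "RhythmSpec",
    "CohortEffect",
    "TruthTable",
    "StudyDesign",
    "ConfigurationError",
    "generate_subjects",
    "generate_expression",
    "generate_two_cohort_study",
    "single_cohort_preset",
    "SITES",
    "EFFECT_KINDS",
]

EFFECT_KINDS = ("none", "loss_12h", "gain_12h", "phase_shift_12h")

#: The two collection sites of the emulated design (name, lat, lon east+, elev m, tz).
SITES = {
    "Pittsburgh": dict(lat=40.4406, lon=-79.9959, elev_m=300.0, tz="America/New_York"),
    "MtSinai": dict(lat=40.7900, lon=-73.9526, elev_m=30.0, tz="America/New_York"),
}


class ConfigurationError(ValueError):
    """Invalid generator configuration (law descriptor, fractions, sizes)."""


@dataclass
class RhythmSpec:
    """Planted rhythm for one gene: components are (period, amplitude, acrophase)."""

    gene_id: str
    components: list = field(default_factory=list)
    baseline: float = 5.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        seen = set()
        for period, amp, acro in self.components:
            if period <= 0 or amp < 0 or self.noise_sd < 0:
                raise ConfigurationError(f"{self.gene_id}: invalid component parameters")
            if not (0 <= acro < period):
                raise ConfigurationError(
                    f"{self.gene_id}: acrophase {acro} outside [0, {period})"
                )
            if period in seen:
                raise ConfigurationError(f"{self.gene_id}: duplicate period {period}")
            seen.add(period)

    def evaluate(self, zt: np.ndarray) -> np.ndarray:
        out = np.full_like(zt, self.baseline, dtype=float)
        for period, amp, acro in self.components:
            out += amp * np.cos(2.0 * np.pi * (zt - acro) / period)
        return out


@dataclass
class CohortEffect:
    kind: str = "none"
    shift_h: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "phase_shift_12h" and not (0 < self.shift_h < 12):
            raise ConfigurationError(f"shift_h must be in (0, 12), got {self.shift_h}")


@dataclass
class TruthTable:
    """Planted specs per cohort plus the effect label, one row per gene."""

    specs: dict  # cohort -> {gene_id -> RhythmSpec}
    effects: dict  # gene_id -> effect kind

    def to_frame(self) -> pd.DataFrame:
        cohorts = sorted(self.specs)
        rows = []
        for g in sorted(self.effects):
            row = {"gene_id": g, "effect": self.effects[g]}
            for c in cohorts:
                spec = self.specs[c][g]
                amp12 = acro12 = amp24 = acro24 = 0.0
                for period, amp, acro in spec.components:
                    if period == 12.0:
                        amp12, acro12 = amp, acro
                    elif period == 24.0:
                        amp24, acro24 = amp, acro
                row.update(
                    {
                        f"{c}_amp12": amp12,
                        f"{c}_acro12": acro12,
                        f"{c}_amp24": amp24,
                        f"{c}_acro24": acro24,
                        f"{c}_baseline": spec.baseline,
                        f"{c}_noise_sd": spec.noise_sd,
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-of-death laws


def sample_tod(law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n ZT values in [-6, 18) from a law descriptor.

    Descriptors: ``"uniform"``; ``"point:<zt>"``; ``"bimodal"`` (the default
    two-mode von Mises mixture); or a dict ``{"kind": "vonmises_mixture",
    "modes": [(mu_zt, kappa, weight), ...]}``.
    """
    if law == "uniform":
        return rng.uniform(-6.0, 18.0, size=n)
    if isinstance(law, str) and law.startswith("point:"):
        try:
            v = float(law.split(":", 1)[1])
        except ValueError as exc:
            raise ConfigurationError(f"bad point law {law!r}") from exc
        if not (-6.0 <= v < 18.0):
            raise ConfigurationError(f"point mass {v} outside [-6, 18)")
        return np.full(n, v)
    if law == "bimodal":
        law = {"kind": "vonmises_mixture", "modes": [(4.0, 1.5, 0.5), (14.0, 1.5, 0.5)]}
    if isinstance(law, dict) and law.get("kind") == "vonmises_mixture":
        modes = law.get("modes", [])
        if not modes or not math.isclose(sum(w for *_t, w in modes), 1.0, abs_tol=1e-9):
            raise ConfigurationError("von Mises mixture weights must sum to 1")
        weights = np.array([w for *_t, w in modes])
        comp = rng.choice(len(modes), size=n, p=weights)
        out = np.empty(n)
        for i, (mu, kappa, _w) in enumerate(modes):
            m = comp == i
            theta = rng.vonmises(mu * 2 * np.pi / 24.0, kappa, size=int(m.sum()))
            hours = theta * 24.0 / (2 * np.pi)
            out[m] = ((hours + 6.0) % 24.0) - 6.0  # wrap into [-6, 18)
        return out
    raise ConfigurationError(f"unknown TOD law descriptor: {law!r}")


# ---------------------------------------------------------------------------
# Subjects


def generate_subjects(
    n: int,
    tod_law="bimodal",
    site_fractions: Optional[dict] = None,
    seed: int | None = 0,
    cohort: str = "A",
    id_prefix: str = "S",
) -> pd.DataFrame:
    """Simulate a subject metadata table with ZT-consistent death times.

    Each subject gets a site (equal proportions by default), a random death
    date in 2015, and a death datetime placed exactly ``zt`` hours after the
    computed local sunrise of that site/date, so downstream ZT conversion
    recovers the sampled value. Returns the subject TSV schema plus ``zt``.
    """
    if n < 4:
        raise ConfigurationError(f"need at least 4 subjects, got {n}")
    site_fractions = site_fractions or {name: 1.0 / len(SITES) for name in SITES}
    if not math.isclose(sum(site_fractions.values()), 1.0, abs_tol=1e-9):
        raise ConfigurationError("site fractions must sum to 1")
    for name in site_fractions:
        if name not in SITES:
            raise ConfigurationError(f"unknown site {name!r}")

    rng = np.random.default_rng(seed)
    zts = sample_tod(tod_law, n, rng)

    names = sorted(site_fractions)
    counts = [int(round(site_fractions[s] * n)) for s in names]
    counts[-1] = n - sum(counts[:-1])
    sites = np.array([s for s, c in zip(names, counts) for _ in range(c)])
    rng.shuffle(sites)

    rows = []
    for i in range(n):
        site = SITES[str(sites[i])]
        d = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        rise = sunrise_utc(d, site["lat"], site["lon"], site["elev_m"])
        death_utc = rise + timedelta(hours=float(zts[i]))
        local = death_utc.astimezone(ZoneInfo(site["tz"])).replace(tzinfo=None)
        rows.append(
            {
                "subject_id": f"{id_prefix}{i:04d}",
                "cohort": cohort,
                "death_datetime": local.isoformat(),
                "tz": site["tz"],
                "lat": site["lat"],
                "lon": site["lon"],
                "elev_m": site["elev_m"],
                "site": str(sites[i]),
                "age": float(np.round(rng.uniform(20, 65), 1)),
                "sex": str(rng.choice(["F", "M"])),
                "ph": float(np.round(rng.normal(6.7, 0.25), 2)),
                "pmi": float(np.round(rng.uniform(4, 30), 1)),
                "zt": float(zts[i]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    subjects: pd.DataFrame,
    truth: TruthTable,
    seed: int | None = 0,
    cohort: Optional[str] = None,
) -> ExpressionMatrix:
    """Realize a log2 expression matrix from planted specs plus Gaussian noise."""
    if "zt" not in subjects.columns or subjects["zt"].isna().any():
        raise ValueError("subjects must carry a complete zt column")
    cohort = cohort if cohort is not None else str(subjects["cohort"].iloc[0])
    if cohort not in truth.specs:
        raise ValueError(f"truth table has no specs for cohort {cohort!r}")
    specs = truth.specs[cohort]
    missing = [g for g in truth.effects if g not in specs]
    if missing:
        raise ValueError(f"genes without a spec for cohort {cohort!r}: {missing[:5]}")

    zt = subjects["zt"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    gene_ids = sorted(specs)
    values = np.empty((len(gene_ids), zt.size))
    for i, g in enumerate(gene_ids):
        spec = specs[g]
        values[i] = spec.evaluate(zt)
        if spec.noise_sd > 0:
            values[i] += rng.normal(0.0, spec.noise_sd, size=zt.size)
    df = pd.DataFrame(values, index=gene_ids, columns=subjects["subject_id"].tolist())
    return ExpressionMatrix(df, "log2", ["synthetic"])


# ---------------------------------------------------------------------------
# Study designs


@dataclass
class StudyDesign:
    """Parameters of a planted two-cohort study (defaults: study-like SNR).

    Fractions are of the gene universe; amplitudes and noise are log2-scale.
    The default planting is deliberately high-SNR (amplitude 1.25x the noise
    sd, expected R^2 ~ 0.44 for a planted 12 h gene): differential effects
    are meant to be clearly present, so that loss/gain classification
    measures the method rather than borderline power at n = 46.
    """

    n_genes: int = 1000
    n_a: int = 46
    n_b: int = 46
    frac_loss: float = 0.10
    frac_gain: float = 0.05
    frac_shift: float = 0.05
    shift_h: float = 6.0
    amplitude: float = 1.25
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    tod_law: object = "bimodal"

    def __post_init__(self) -> None:
        if self.n_a < 4 or self.n_b < 4:
            raise ConfigurationError("cohort sizes must be >= 4")
        total = self.frac_loss + self.frac_gain + self.frac_shift
        if total > 1.0 + 1e-9:
            raise ConfigurationError(f"effect fractions sum to {total} > 1")


def _draw_acrophase12(rng: np.random.Generator) -> float:
    """Bimodal acrophases: two 12 h phase clusters near ZT 2.5 and 8.5."""
    center = 2.5 if rng.random() < 0.5 else 8.5
    return float((rng.normal(center, 0.75)) % 12.0)


def generate_two_cohort_study(
    design: StudyDesign, seed: int | None = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Two cohorts with planted loss / gain / phase-shift effects.

    Genes labelled ``loss_12h`` are 12 h rhythmic only in cohort A,
    ``gain_12h`` only in B, ``phase_shift_12h`` in both with acrophases
    offset by ``shift_h``; the rest are flat. Returns (matrix_a, matrix_b,
    subjects_a, subjects_b, truth).
    """
    rng = np.random.default_rng(seed)
    n = design.n_genes
    n_loss = int(round(design.frac_loss * n))
    n_gain = int(round(design.frac_gain * n))
    n_shift = int(round(design.frac_shift * n))
    labels = (
        ["loss_12h"] * n_loss
        + ["gain_12h"] * n_gain
        + ["phase_shift_12h"] * n_shift
        + ["none"] * (n - n_loss - n_gain - n_shift)
    )

    specs_a, specs_b, effects = {}, {}, {}
    width = len(str(n - 1))
    for i, label in enumerate(labels):
        g = f"G{i:0{width}d}"
        base = float(rng.normal(design.baseline_mean, design.baseline_sd))
        acro = _draw_acrophase12(rng)
        comp = (12.0, design.amplitude, acro)
        if label == "loss_12h":
            ca, cb = [comp], []
        elif label == "gain_12h":
            ca, cb = [], [comp]
        elif label == "phase_shift_12h":
            ca = [comp]
            cb = [(12.0, design.amplitude, float((acro + design.shift_h) % 12.0))]
        else:
            ca, cb = [], []
        specs_a[g] = RhythmSpec(g, ca, base, design.noise_sd)
        specs_b[g] = RhythmSpec(g, cb, base, design.noise_sd)
        effects[g] = label

    truth = TruthTable({"A": specs_a, "B": specs_b}, effects)
    sa, sb = rng.spawn(2) if hasattr(rng, "spawn") else (rng, rng)
    subjects_a = generate_subjects(
        design.n_a, design.tod_law, seed=sa, cohort="A", id_prefix="A"
    )
    subjects_b = generate_subjects(
        design.n_b, design.tod_law, seed=sb, cohort="B", id_prefix="B"
    )
    ea, eb = rng.spawn(2) if hasattr(rng, "spawn") else (rng, rng)
    mat_a = generate_expression(subjects_a, truth, seed=ea, cohort="A")
    mat_b = generate_expression(subjects_b, truth, seed=eb, cohort="B")
    return mat_a, mat_b, subjects_a, subjects_b, truth


def single_cohort_preset(
    n_genes: int = 13914,
    n_subjects: int = 104,
    frac_12: float = 0.06,
    frac_24: float = 0.06,
    frac_both: float = 0.02,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    tod_law="bimodal",
    seed: int | None = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthTable]:
    """Single-cohort study: planted 12 h, 24 h and dual-rhythm genes.

    Defaults emulate the full design (13,914 genes x 104 subjects, ~6% of
    genes with a 12 h rhythm). Returns (matrix, subjects, truth).
    """
    rng = np.random.default_rng(seed)
    n12 = int(round(frac_12 * n_genes))
    n24 = int(round(frac_24 * n_genes))
    nboth = int(round(frac_both * n_genes))
    if n12 + n24 + nboth > n_genes:
        raise ConfigurationError("rhythmic fractions exceed the gene universe")
    labels = (
        ["12h"] * n12 + ["24h"] * n24 + ["both"] * nboth + ["none"] * (n_genes - n12 - n24 - nboth)
    )
    specs, effects = {}, {}
    width = len(str(n_genes - 1))
    for i, label in enumerate(labels):
        g = f"G{i:0{width}d}"
        base = float(rng.normal(5.0, 1.5))
        comps = []
        if label in ("12h", "both"):
            comps.append((12.0, amplitude, _draw_acrophase12(rng)))
        if label in ("24h", "both"):
            comps.append((24.0, amplitude, float(rng.uniform(0.0, 24.0))))
        specs[g] = RhythmSpec(g, comps, base, noise_sd)
        effects[g] = label
    truth = TruthTable({"A": specs}, effects)
    (s_seed,) = rng.spawn(1)
    subjects = generate_subjects(n_subjects, tod_law, seed=s_seed, cohort="A")
    (e_seed,) = rng.spawn(1)
    matrix = generate_expression(subjects, truth, seed=e_seed, cohort="A")
    return matrix, subjects, truth
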