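"""Synthetic aging transcriptomes and lifespan cohorts with known truth.

The generator emulates the statistical structure drift analysis assumes:
each gene g carries a direction s_g in {-1, +1} (balanced by default, so
genes move in opposing directions with age) and a nonnegative rate r_g, and
its true drift at age t in the untreated arm is

    td_g(t) = s_g * r_g * u(t) + Normal(0, noise_sd),   u(t) = (t - t_ref)**gamma,

i.e. a deterministic trend away from the young profile plus replicate-level
noise, anchored so td is exactly 0 at the young-reference age t_ref (the
youngest configured age) as the drift definition requires.  A treatment
started at age t_s scales all drift accrued after t_s by (1 - a), with
attenuation factor a in [0, 1]: a = 1 freezes the transcriptome at its state
when treatment began, a = 0 is no treatment.  Expected expression is baseline_g * 2**td, and observed counts
are negative-binomial around the expected cpm at a log-normally distributed
library size — the count-noise model standard for bulk RNA-seq.

Under this model the drift-variance of the untreated arm at age t has the
closed form Var(s*r) * u(t)**2 + noise_sd**2 (plus a count-noise term that
shrinks with sequencing depth), which recovery tests exploit.

A ``random_walk`` mode replaces the deterministic trend with accumulating
per-age increments of the same scale, for analyses that should not depend on
whether drift is a program or a stochastic walk.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import ExpressionMatrix, GeneSet, LifeTable, SampleAnnotation
from .mortality import GompertzModel


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror a worm cohort-style design:
    ~19,196 detected transcripts, reference age day 1 and harvests at days
    3/5/10 in triplicate, sequencing depth 20-30 million reads."""

    n_genes: int = 19196
    ages: Sequence[float] = (1.0, 3.0, 5.0, 10.0)
    n_replicates: int = 3
    baseline_log2_cpm_mean: float = 4.0
    baseline_log2_cpm_sd: float = 2.0
    p_up: float = 0.5
    drift_rate_mean: float = 0.10  # log2 units per day at gamma=1
    drift_rate_sd: float = 0.05
    age_exponent: float = 1.0  # gamma: td grows proportional to t**gamma
    attenuation: float = 0.0  # a: treated-arm rates scaled by (1 - a)
    treatment_start_age: float | None = None  # attenuation active from this age on
    noise_sd: float = 0.10
    nb_dispersion: float = 0.05  # NB variance = m + disp * m^2; 0 = Poisson
    library_size: float = 25e6
    library_size_log_sd: float = 0.15
    drift_mode: Literal["trend", "random_walk"] = "trend"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation must lie in [0, 1]")
        if list(self.ages) != sorted(self.ages):
            raise ValueError("ages must be sorted ascending")
        if not 0 <= self.p_up <= 1:
            raise ValueError("p_up must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    gene_ids: list[str]
    direction: np.ndarray  # s_g in {-1, +1}
    rate: np.ndarray  # r_g >= 0
    attenuation: float
    age_exponent: float
    noise_sd: float
    ref_age: float = 0.0
    treatment_start_age: float = 0.0
    true_td: dict[str, np.ndarray] = field(default_factory=dict)  # sample -> per-gene td
    hazard: dict = field(default_factory=dict)

    def drift_clock(self, age: float) -> float:
        """u(t) = (t - t_ref)**gamma, the systematic drift scale at an age."""
        return max(age - self.ref_age, 0.0) ** self.age_exponent

    def expected_drift_variance(self, age: float, treated: bool = False) -> float:
        """Closed-form Var(td) at an age, excluding count noise."""
        u = self.drift_clock(age)
        if treated:
            u_pre = self.drift_clock(min(age, self.treatment_start_age))
            u = u_pre + (1 - self.attenuation) * (u - u_pre)
        sr = self.direction * self.rate
        return float(np.var(sr, ddof=0)) * u**2 + self.noise_sd**2


def _split(seed: int, *streams: str) -> np.random.Generator:
    # every sub-result draws from its own named child stream of one root seed;
    # crc32 keys are stable across processes (unlike the builtin str hash)
    keys = tuple(zlib.crc32(s.encode()) % (2**31) for s in streams)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


def generate_transcriptome(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Simulate a two-arm aging RNA-seq experiment with known drift truth.

    Returns raw counts (genes x samples), annotations, and the truth record.
    The control ("water") arm spans every configured age; the treated arm
    spans every age after the youngest (treatment is added at the reference
    age, so no separate treated reference exists, matching the usual design).
    Reproducible: the same config (including seed) yields identical output.
    """
    rng = _split(cfg.seed, "transcriptome")
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_cpm_mean, cfg.baseline_log2_cpm_sd, cfg.n_genes)
    baseline *= 1e6 / baseline.sum()  # cpm-scale young profile
    direction = np.where(rng.uniform(size=cfg.n_genes) < cfg.p_up, 1.0, -1.0)
    rate = np.abs(rng.normal(cfg.drift_rate_mean, cfg.drift_rate_sd, cfg.n_genes))

    ref_age = cfg.ages[0]
    t0 = cfg.treatment_start_age if cfg.treatment_start_age is not None else ref_age
    truth = SyntheticTruth(
        gene_ids=genes,
        direction=direction,
        rate=rate,
        attenuation=cfg.attenuation,
        age_exponent=cfg.age_exponent,
        noise_sd=cfg.noise_sd,
        ref_age=ref_age,
        treatment_start_age=t0,
    )

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    arms = [("water", 0.0, list(cfg.ages))]
    if cfg.attenuation > 0 or cfg.treatment_start_age is not None:
        treated_ages = [a for a in cfg.ages if a > ref_age]
        arms.append(("treated", cfg.attenuation, treated_ages))

    for arm, atten, arm_ages in arms:
        # trend per age; random_walk accumulates increments across the age grid
        walk = np.zeros(cfg.n_genes)
        prev_u = 0.0
        for age in cfg.ages:
            # drift clock u(t) anchors td at 0 for the young-reference age;
            # attenuation damps only the drift accrued after treatment start
            u = truth.drift_clock(age)
            u_pre = truth.drift_clock(min(age, t0))
            u_eff = u if (arm == "water" or atten == 0) else u_pre + (1 - atten) * (u - u_pre)
            if cfg.drift_mode == "trend":
                systematic = direction * rate * u_eff
            else:  # random_walk: same mean path, diffusing increments
                du = max(u_eff - prev_u, 0.0)
                walk = walk + direction * rate * du + rng.normal(0, 1, cfg.n_genes) * (
                    0.25 * rate * math.sqrt(du)
                )
                systematic = walk
                prev_u = u_eff
            if age not in arm_ages:
                continue
            for rep in range(1, cfg.n_replicates + 1):
                td_true = systematic + rng.normal(0, cfg.noise_sd, cfg.n_genes)
                expected_cpm = baseline * 2.0**td_true
                lib = cfg.library_size * np.exp(rng.normal(0, cfg.library_size_log_sd))
                mean_counts = expected_cpm / 1e6 * lib
                if cfg.nb_dispersion > 0:
                    shape = 1.0 / cfg.nb_dispersion
                    counts = rng.poisson(rng.gamma(shape, mean_counts / shape))
                else:
                    counts = rng.poisson(mean_counts)
                sid = f"{arm}_d{age:g}_r{rep}"
                sample_ids.append(sid)
                columns.append(counts.astype(float))
                annotations.append(
                    SampleAnnotation(
                        sample_id=sid, age=age, age_unit="days",
                        treatment=arm, replicate=rep,
                    )
                )
                truth.true_td[sid] = td_true
    matrix = ExpressionMatrix(genes, sample_ids, np.column_stack(columns), unit="raw_count")
    return matrix, annotations, truth


def generate_gene_sets(
    truth: SyntheticTruth, n_sets: int, set_size: int, seed: int
) -> list[GeneSet]:
    """Random gene sets plus two designed contrast sets.

    ``coherent``: genes all drifting the same direction (pathway-level shift,
    low within-set drift-variance growth relative to its mean drift);
    ``opposing``: balanced up/down membership (maximal drift-variance at
    matched rate magnitude).  Random sets mirror transcriptome-wide behavior.
    """
    if set_size > len(truth.gene_ids):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.gene_ids)
    sets = []
    for i in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets.append(GeneSet(f"random_{i+1}", list(members), source="synthetic"))
    up = genes[truth.direction > 0]
    down = genes[truth.direction < 0]
    k = min(set_size, len(up))
    sets.append(GeneSet("coherent", list(rng.choice(up, size=k, replace=False)), source="synthetic"))
    half = min(set_size // 2, len(up), len(down))
    opposing = list(rng.choice(up, size=half, replace=False)) + list(
        rng.choice(down, size=half, replace=False)
    )
    sets.append(GeneSet("opposing", opposing, source="synthetic"))
    return sets


def generate_lifespans(
    model: GompertzModel,
    n_per_arm: int,
    effect_days: float,
    seed: int,
) -> tuple[LifeTable, LifeTable, dict]:
    """Two-arm lifespan experiment: control from the model, treated shifted
    additively by ``effect_days`` (a parallel log-mortality displacement)."""
    from .mortality import simulate_cohort

    rng = _split(seed, "lifespans")
    control = simulate_cohort(model, n_per_arm, 0.0, rng, "control")
    treated = simulate_cohort(model, n_per_arm, effect_days, rng, "treated")
    truth = {"A": model.A, "G": model.G, "effect_days": effect_days, "n_per_arm": n_per_arm}
    return control, treated, truth
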