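"""Synthetic gonadal time-course expression data and ground-truth networks.

The simulator reproduces the temperature-shift study design: eggs are
incubated at the female-producing temperature (FPT) until Day 0, when a
subset is shifted to the male-producing temperature (MPT).  Gonads are
sampled in triplicate at Days 0, 3, 6 and 12 (Day 0 exists only in the
FPT arm — it is the shared pre-shift baseline) and as single samples at
Days 18, 24, 30 and 36 (Day 36 FPT only).

Expression values are FPKM-like continuous positives generated as
``2 ** (log2 baseline + planted effects + Gaussian noise)``; the noise is
therefore multiplicative on the linear scale.  Gene classes plant
development-dependent, sex-dependent, immediate temperature-responsive
and combined effects, with the remainder null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import GRNModel, InputSignal, TimeSeriesSet, step_response

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "PlantedEffect",
    "GroundTruth",
    "ExpressionMatrix",
    "standard_design",
    "generate_expression_dataset",
    "generate_grn_system",
    "simulate_trajectories",
    "TESTED_DAYS",
    "DESCRIPTIVE_DAYS",
]

TESTED_DAYS = (0, 3, 6, 12)          # triplicate, statistically testable
DESCRIPTIVE_DAYS = (18, 24, 30, 36)  # singletons, descriptive only

GENE_CLASSES = (
    "null",
    "development_dependent",
    "sex_dependent",
    "temperature_responsive",
    "candidate_both",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic dataset.

    Class fractions must sum to ≤ 1; the remainder of genes are null.
    ``effect_size_log2`` is the planted shift on the log2 scale and
    ``noise_sd`` the log2-scale Gaussian replicate noise (multiplicative
    on the FPKM scale). ``baseline_range`` is the FPKM interval baselines
    are drawn from (log-uniformly).
    """

    n_genes: int = 1000
    frac_development: float = 0.05
    frac_sex: float = 0.05
    frac_temperature: float = 0.05
    frac_candidate_both: float = 0.05
    effect_size_log2: float = 2.0
    noise_sd: float = 0.25
    baseline_range: tuple = (1.0, 256.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.effect_size_log2 <= 0:
            raise ConfigurationError("effect_size_log2 must be positive")
        fracs = (
            self.frac_development,
            self.frac_sex,
            self.frac_temperature,
            self.frac_candidate_both,
        )
        if any(f < 0 for f in fracs):
            raise ConfigurationError("class fractions must be nonnegative")
        if sum(fracs) > 1 + 1e-12:
            raise ConfigurationError("class fractions sum to more than 1")
        lo, hi = self.baseline_range
        if not (0 < lo < hi):
            raise ConfigurationError("baseline_range must be a positive interval")


@dataclass(frozen=True)
class PlantedEffect:
    """A log2-scale step applied to one arm (or both) from a day onward."""

    condition: str       # "MPT", "FPT" or "both"
    start_day: int
    delta_log2: float


@dataclass
class GroundTruth:
    """Planted truth for a synthetic dataset: labels partition the genes."""

    labels: dict = field(default_factory=dict)           # gene -> class
    effects: dict = field(default_factory=dict)          # gene -> [PlantedEffect]
    grn: GRNModel | None = None

    def genes_of_class(self, cls: str) -> set:
        return {g for g, c in self.labels.items() if c == cls}


@dataclass
class ExpressionMatrix:
    """Genes × samples nonnegative expression with its sample design."""

    values: pd.DataFrame                 # index gene_id, columns sample_id
    samples: pd.DataFrame                # sample_id, condition, day, replicate

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix columns must match sample sheet order")

    def select(self, condition: str, day: int) -> pd.DataFrame:
        ids = self.samples.loc[
            (self.samples["condition"] == condition)
            & (self.samples["day"] == day),
            "sample_id",
        ]
        return self.values[list(ids)]

    def group_size(self, condition: str, day: int) -> int:
        return self.select(condition, day).shape[1]


def standard_design() -> pd.DataFrame:
    """The temperature-shift design's sample sheet: which (condition, day, replicate) exist.

    Day 0 is FPT only (pre-shift baseline); Days 0–12 are triplicate,
    Days 18–36 singletons, Day 36 FPT only.
    """
    rows = []
    for cond in ("FPT", "MPT"):
        tested = TESTED_DAYS if cond == "FPT" else TESTED_DAYS[1:]
        for day in tested:
            for rep in (1, 2, 3):
                rows.append((f"{cond}_d{day}_r{rep}", cond, day, rep))
        desc = DESCRIPTIVE_DAYS if cond == "FPT" else DESCRIPTIVE_DAYS[:-1]
        for day in desc:
            rows.append((f"{cond}_d{day}_r1", cond, day, 1))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "day", "replicate"])


def _assign_classes(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_genes
    counts = {
        "development_dependent": int(round(config.frac_development * n)),
        "sex_dependent": int(round(config.frac_sex * n)),
        "temperature_responsive": int(round(config.frac_temperature * n)),
        "candidate_both": int(round(config.frac_candidate_both * n)),
    }
    order = rng.permutation(n)
    labels = {}
    pos = 0
    for cls, k in counts.items():
        for idx in order[pos : pos + k]:
            labels[idx] = cls
        pos += k
    for idx in order[pos:]:
        labels[idx] = "null"
    return labels


def _plant_effect(cls, effect, rng: np.random.Generator):
    sign = float(rng.choice([-1.0, 1.0]))
    if cls == "development_dependent":
        # same shift in both arms from a tested-day boundary: changes with
        # development but never between temperatures
        start = int(rng.choice([3, 6, 12]))
        return [PlantedEffect("both", start, sign * effect)]
    if cls == "sex_dependent":
        # whole-arm offset: dimorphic at every matched day
        arm = str(rng.choice(["MPT", "FPT"]))
        return [PlantedEffect(arm, 3, sign * effect)]
    if cls == "temperature_responsive":
        # step only in the shifted (MPT) arm from Day 3 onward
        return [PlantedEffect("MPT", 3, sign * effect)]
    if cls == "candidate_both":
        # later-onset single-arm step: development-dependent and dimorphic
        arm = str(rng.choice(["MPT", "FPT"]))
        start = int(rng.choice([6, 12]))
        return [PlantedEffect(arm, start, sign * effect)]
    return []


def generate_expression_dataset(config: SimulationConfig):
    """Simulate one dataset under the temperature-shift design.

    Returns ``(ExpressionMatrix, GroundTruth)``; identical configs
    (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    design = standard_design()
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n)]

    idx_labels = _assign_classes(config, rng)
    labels = {gene_ids[i]: idx_labels[i] for i in range(n)}
    effects = {
        gene_ids[i]: _plant_effect(idx_labels[i], config.effect_size_log2, rng)
        for i in range(n)
    }

    lo, hi = config.baseline_range
    base_log2 = rng.uniform(np.log2(lo), np.log2(hi), size=n)

    log2_expr = np.tile(base_log2[:, None], (1, len(design)))
    for col, (cond, day) in enumerate(zip(design["condition"], design["day"])):
        for i in range(n):
            for eff in effects[gene_ids[i]]:
                applies = eff.condition in ("both", cond) and day >= eff.start_day
                if applies:
                    log2_expr[i, col] += eff.delta_log2
    log2_expr += rng.normal(0.0, config.noise_sd, size=log2_expr.shape)

    values = pd.DataFrame(
        np.exp2(log2_expr), index=pd.Index(gene_ids, name="gene_id"),
        columns=list(design["sample_id"]),
    )
    matrix = ExpressionMatrix(values=values, samples=design)
    truth = GroundTruth(labels=labels, effects=effects)
    return matrix, truth


def generate_grn_system(
    n_genes: int,
    density: float,
    seed: int,
    weight_range: tuple = (0.4, 1.0),
    decay_range: tuple = (0.5, 1.5),
    input_prob: float = 0.5,
) -> GRNModel:
    """Random sparse stable linear ODE system with a step input.

    Off-diagonal entries of A are nonzero independently with probability
    ``density`` and magnitudes in ``weight_range``; self-decay terms are
    negative. If the draw is unstable the diagonal is deepened until all
    eigenvalues have negative real part. At least one gene receives a
    nonzero input weight. ``density=0`` yields a decay-only system.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_genes
    A = np.zeros((n, n))
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    mags = rng.uniform(*weight_range, size=(n, n))
    A[mask] = (signs * mags)[mask]
    np.fill_diagonal(A, -rng.uniform(*decay_range, size=n))

    # enforce stability by deepening self-decay
    margin = 0.1
    top = np.max(np.linalg.eigvals(A).real)
    if top >= -margin / 2:
        A -= (top + margin) * np.eye(n)

    b = np.where(rng.random(n) < input_prob, rng.uniform(*weight_range, size=n), 0.0)
    b *= rng.choice([-1.0, 1.0], size=n)
    if not np.any(b):
        b[int(rng.integers(n))] = rng.uniform(*weight_range) * float(
            rng.choice([-1.0, 1.0])
        )

    # every gene must be excited by the input (directly or through the
    # network), otherwise its trajectory is identically zero and any edge
    # touching it is unobservable
    while True:
        reached = set(np.flatnonzero(b))
        frontier = set(reached)
        while frontier:
            nxt = {
                i
                for i in range(n)
                if i not in reached and any(A[i, j] != 0 for j in frontier)
            }
            reached |= nxt
            frontier = nxt
        silent = sorted(set(range(n)) - reached)
        if not silent:
            break
        k = silent[int(rng.integers(len(silent)))]
        b[k] = rng.uniform(*weight_range) * float(rng.choice([-1.0, 1.0]))

    genes = [f"g{i}" for i in range(n)]
    return GRNModel(genes=genes, A=A, b=b)


def simulate_trajectories(
    model: GRNModel,
    input_signal: InputSignal,
    timepoints,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeriesSet:
    """Sample dx/dt = A·x + b·u(t), x(0)=0, at ``timepoints`` with noise.

    Additive Gaussian observation noise of sd ``noise_sd`` is applied to
    the sampled points; ``noise_sd=0`` is deterministic.  Unsorted
    timepoints are an error; an unstable model only warns.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(timepoints) <= 0):
        raise ValueError("timepoints must be sorted strictly ascending")
    if not model.is_stable():
        warnings.warn("simulating an unstable ground-truth model", stacklevel=2)
    traj = step_response(model.A, model.b, timepoints)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        traj = traj + rng.normal(0.0, noise_sd, size=traj.shape)
    elif noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    return TimeSeriesSet(model.genes, timepoints, traj)
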