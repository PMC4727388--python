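"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (brute-force
loops, exhaustive enumeration, fine-step integration) and independent of
the library code paths they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tsdnet.diffexpr import ComparisonSpec, DEGTable, Thresholds
from tsdnet.grn import GRNModel, InputSignal, TimeSeriesSet


# ---------------------------------------------------------------- oracles


def bh_stepup_bruteforce(pvalues):
    """Literal BH step-up: find largest k with p_(k) <= k/m * q via scan.

    Computes adjusted q-values by the textbook definition
    q_i = min over thresholds t >= p_i of m * t / rank(t), evaluated by
    looping over every (i, j) pair.
    """
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos in range(m):
        best = float("inf")
        for later in range(rank_pos, m):
            candidate = m * p[order[later]] / (later + 1)
            best = min(best, candidate)
        q[order[rank_pos]] = min(best, 1.0)
    return q


def step_response_rk4(A, b, t_end, n_steps, x0=None):
    """Fine-step classic RK4 integration of dx/dt = A x + b (u == 1)."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    x = np.zeros(A.shape[0]) if x0 is None else np.asarray(x0, float)
    h = t_end / n_steps
    f = lambda y: A @ y + b  # noqa: E731
    for _ in range(n_steps):
        k1 = f(x)
        k2 = f(x + h / 2 * k1)
        k3 = f(x + h / 2 * k2)
        k4 = f(x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def _scalar_traj(a_self, coefs, regressors, x0, grid):
    """RK4 integration of one target ODE with exogenous regulator signals."""
    f = coefs @ regressors if len(coefs) else np.zeros(grid.size)
    z = np.empty(grid.size)
    z[0] = x0
    for k in range(grid.size - 1):
        h = grid[k + 1] - grid[k]
        fm = 0.5 * (f[k] + f[k + 1])
        k1 = a_self * z[k] + f[k]
        k2 = a_self * (z[k] + h / 2 * k1) + fm
        k3 = a_self * (z[k] + h / 2 * k2) + fm
        k4 = a_self * (z[k] + h * k3) + f[k + 1]
        z[k + 1] = z[k] + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return z


def enumerate_support(series: TimeSeriesSet, allowed_error: float,
                      max_in_degree: int, input_name: str = "input",
                      grid_step: float = 0.1):
    """Exhaustive structure search oracle.

    For every target gene, fit every regulator subset within the
    in-degree cap (with and without the step input) by least squares on
    the estimated derivative, and return the edge support of the
    smallest structure whose simulated target trajectory reaches
    ``allowed_error`` (ties: lower MSE, then lexicographic).  If no
    structure reaches the threshold the minimum-MSE structure wins.
    """
    grid, dense = series.interpolated(grid_step)
    deriv = np.gradient(dense, grid, axis=1)
    u = np.ones(grid.size)
    genes = series.genes
    n = len(genes)
    edges = set()
    for i in range(n):
        others = [j for j in range(n) if j != i]
        scored = []
        for r in range(0, max_in_degree + 1):
            for sub in combinations(others, r):
                for use_input in (False, True):
                    cols = [dense[i]] + [dense[j] for j in sub]
                    regs = [dense[j] for j in sub]
                    if use_input:
                        cols.append(u)
                        regs.append(u)
                    X = np.column_stack(cols)
                    coef, *_ = np.linalg.lstsq(X, deriv[i], rcond=None)
                    regs = np.array(regs) if regs else np.zeros((0, grid.size))
                    with np.errstate(over="ignore", invalid="ignore"):
                        z = _scalar_traj(coef[0], coef[1:], regs, dense[i, 0], grid)
                        mse = (
                            float(np.mean((z - dense[i]) ** 2))
                            if np.all(np.isfinite(z))
                            else float("inf")
                        )
                    if not np.isfinite(mse):
                        mse = float("inf")
                    size = r + (1 if use_input else 0)
                    names = tuple(
                        sorted([genes[j] for j in sub])
                        + (["~input"] if use_input else [])
                    )
                    scored.append((size, mse, names))
        reaching = [s for s in scored if s[1] <= allowed_error]
        best = min(reaching) if reaching else min(scored, key=lambda s: (s[1], s[0], s[2]))
        for name in best[2]:
            if name == "~input":
                edges.add((input_name, genes[i], "input"))
            else:
                edges.add((name, genes[i], "gene"))
    return edges


def make_cascade(seed: int, n_genes: int = 3) -> GRNModel:
    """Identifiable chain system: input → g0 → g1 → … with strong weights."""
    rng = np.random.default_rng(seed)
    decay = rng.uniform(0.5, 1.2, n_genes)
    A = np.diag(-decay)
    for i in range(1, n_genes):
        A[i, i - 1] = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
    b = np.zeros(n_genes)
    b[0] = rng.uniform(0.5, 1.0)
    return GRNModel(
        genes=[f"g{i}" for i in range(n_genes)], A=A, b=b, input_name="input"
    )


# ---------------------------------------------------------- DEG helpers


def deg_table_from_dict(label: str, sig: dict, universe=None,
                        group_a=("FPT", 0), group_b=("MPT", 3)) -> DEGTable:
    """Build a DEGTable directly from {gene: direction} significance calls."""
    universe = sorted(universe if universe is not None else sig)
    records = pd.DataFrame(
        {
            "gene_id": universe,
            "log2fc": [
                (1.0 if sig.get(g) == "up" else -1.0 if sig.get(g) == "down" else 0.0)
                for g in universe
            ],
            "p_raw": [0.0001 if g in sig else 0.9 for g in universe],
            "q_bh": [0.001 if g in sig else 0.95 for g in universe],
            "significant": [g in sig for g in universe],
            "direction": [sig.get(g, "none") for g in universe],
        }
    )
    return DEGTable(
        comparison=ComparisonSpec(label, group_a, group_b),
        records=records,
        thresholds=Thresholds(),
    )


def random_deg_tables(rng: np.random.Generator, n_genes: int = 30):
    """Random small DEG tables for all comparisons of the temperature-shift design."""
    universe = [f"G{i:03d}" for i in range(n_genes)]

    def one(label, ga, gb):
        k = int(rng.integers(0, n_genes // 2))
        chosen = rng.choice(universe, size=k, replace=False)
        sig = {g: ("up" if rng.random() < 0.5 else "down") for g in chosen}
        return deg_table_from_dict(label, sig, universe, ga, gb)

    dev = {
        cond: {
            (d0, d1): one(
                f"{cond}_{d0}_{d1}",
                ("FPT" if d0 == 0 else cond, d0),
                (cond, d1),
            )
            for d0, d1 in ((0, 3), (3, 6), (6, 12))
        }
        for cond in ("MPT", "FPT")
    }
    sex = {
        day: one(f"sex_{day}", ("FPT", day), ("MPT", day)) for day in (3, 6, 12)
    }
    return universe, dev, sex


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene synthetic dataset with all planted classes (seed 11)."""
    from tsdnet.simulate import SimulationConfig, generate_expression_dataset

    config = SimulationConfig(
        n_genes=300,
        frac_development=0.05,
        frac_sex=0.05,
        frac_temperature=0.05,
        frac_candidate_both=0.05,
        seed=11,
    )
    return generate_expression_dataset(config)


@pytest.fixture
def step_input():
    return InputSignal("input")
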