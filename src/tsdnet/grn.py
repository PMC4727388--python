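"""Linear-ODE gene regulatory network inference from time-course fold changes.

The model class is the one used for temperature-shift gonadal time courses:
each gene's log2 fold change x_i(t) relative to the pre-shift baseline obeys

    dx_i/dt = a_ii x_i + sum_j a_ij x_j + b_i u(t),      x(0) = 0,

where u(t) is a stepwise external input (the incubation temperature, 0
before the shift and 1 after) and a_ii is a self-decay term.  Structure is
found per target gene by greedy forward selection of regulators, guided by
optional prior-knowledge gene pairs, stopping once the simulated trajectory
matches the interpolated data to within ``allowed_error`` (mean squared
error) or the in-degree cap is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import expm

__all__ = [
    "InputSignal",
    "TimeSeriesSet",
    "PriorKnowledge",
    "GRNModel",
    "interpolate",
    "step_response",
    "infer_network",
    "simulate_model",
    "model_fit_error",
]

INPUT_NODE = "__input__"


@dataclass(frozen=True)
class InputSignal:
    """Stepwise external input: 0 before the shift at t=0, 1 afterwards."""

    name: str = "MPT"

    def __call__(self, t):
        return np.where(np.asarray(t, dtype=float) >= 0.0, 1.0, 0.0)


class TimeSeriesSet:
    """Per-gene log2 fold-change observations on a shared day grid.

    Parameters
    ----------
    genes
        Gene identifiers, one per row of ``values``.
    days
        Strictly increasing observation days.
    values
        Array of shape (n_genes, n_days); fold changes relative to day 0.
    """

    def __init__(self, genes, days, values):
        self.genes = list(genes)
        self.days = np.asarray(days, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.days.ndim != 1 or len(self.days) < 2:
            raise ValueError("need at least two observation days")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("observation days must be strictly increasing")
        if self.values.shape != (len(self.genes), len(self.days)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)}, {len(self.days)})"
            )

    def interpolated(self, grid_step: float = 0.1):
        """Dense monotone piecewise-cubic interpolation of every gene.

        Returns ``(grid, dense)`` where dense has shape (n_genes, n_grid).
        The interpolant passes exactly through every observation and does
        not overshoot between points (PCHIP).
        """
        if grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        grid = np.arange(self.days[0], self.days[-1] + grid_step / 2, grid_step)
        grid[-1] = min(grid[-1], self.days[-1])
        dense = np.empty((len(self.genes), grid.size))
        for i in range(len(self.genes)):
            dense[i] = interpolate(self.days, self.values[i], grid)
        return grid, dense

    def perturbed(self, noise_sd: float, rng: np.random.Generator) -> "TimeSeriesSet":
        """Copy with i.i.d. Gaussian noise added to every observed value."""
        noisy = self.values + rng.normal(0.0, noise_sd, size=self.values.shape)
        return TimeSeriesSet(self.genes, self.days, noisy)


def interpolate(days, values, grid):
    """Monotone piecewise-cubic (PCHIP) interpolation of one trajectory.

    Exact at the observed days; monotone segments stay monotone (no
    overshoot). Duplicate days raise a ValueError.
    """
    days = np.asarray(days, dtype=float)
    if np.unique(days).size != days.size:
        raise ValueError("duplicate observation days")
    return PchipInterpolator(days, np.asarray(values, dtype=float))(grid)


@dataclass
class PriorKnowledge:
    """Gene-pair co-expression evidence guiding regulator selection.

    Pairs are undirected unless ``directed=True``; confidence defaults to
    0.25 (the mouse co-expression confidence used for this analysis).
    """

    pairs: list = field(default_factory=list)  # (gene_a, gene_b, confidence)
    directed: bool = False

    def __post_init__(self):
        cleaned = []
        for entry in self.pairs:
            a, b = entry[0], entry[1]
            conf = float(entry[2]) if len(entry) > 2 else 0.25
            if a == b:
                raise ValueError(f"prior contains self-pair {a!r}")
            if not 0 < conf <= 1:
                raise ValueError(f"prior confidence {conf} outside (0, 1]")
            cleaned.append((a, b, conf))
        self.pairs = cleaned

    def __len__(self):
        return len(self.pairs)

    def confidence(self, source: str, target: str) -> float:
        """Confidence of a source→target edge; 0.0 if the pair is absent."""
        best = 0.0
        for a, b, conf in self.pairs:
            if (a, b) == (source, target) or (not self.directed and (b, a) == (source, target)):
                best = max(best, conf)
        return best

    def subset(self, keep_indices) -> "PriorKnowledge":
        keep = sorted(keep_indices)
        return PriorKnowledge([self.pairs[i] for i in keep], directed=self.directed)


@dataclass
class GRNModel:
    """Linear ODE system dx/dt = A·x + b·u(t) over an ordered gene list."""

    genes: list
    A: np.ndarray
    b: np.ndarray
    fit_error: float = 0.0
    allowed_error: float = 0.01
    max_in_degree: int = 3
    input_name: str = "input"

    def edges(self, weight_tol: float = 0.0):
        """Edge support as a set of (source, target, kind) triples.

        ``kind`` is "gene" for regulator→target entries of A (self-decay
        excluded) and "input" for nonzero input weights.
        """
        out = set()
        n = len(self.genes)
        for i in range(n):
            for j in range(n):
                if i != j and abs(self.A[i, j]) > weight_tol:
                    out.add((self.genes[j], self.genes[i], "gene"))
            if abs(self.b[i]) > weight_tol:
                out.add((self.input_name, self.genes[i], "input"))
        return out

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.A).real < 0))

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "A": self.A.tolist(),
            "b": self.b.tolist(),
            "fit_error": float(self.fit_error),
            "allowed_error": float(self.allowed_error),
            "max_in_degree": int(self.max_in_degree),
            "input_name": self.input_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRNModel":
        return cls(
            genes=list(d["genes"]),
            A=np.asarray(d["A"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            fit_error=float(d["fit_error"]),
            allowed_error=float(d["allowed_error"]),
            max_in_degree=int(d["max_in_degree"]),
            input_name=d.get("input_name", "input"),
        )


def step_response(A, b, times, x0=None):
    """Trajectories of dx/dt = A·x + b·u, u ≡ 1 for t ≥ 0, sampled at ``times``.

    Uses the matrix-exponential closed form
    ``x(t) = e^{At} x0 + A^{-1}(e^{At} − I) b`` (solved, not inverted).
    Returns an array of shape (n_genes, n_times).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[0]
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    out = np.empty((n, times.size))
    # particular solution: A y = b  (fall back to lstsq if A is singular)
    try:
        y = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        y = np.linalg.lstsq(A, b, rcond=None)[0]
    for k, t in enumerate(times):
        if t <= 0:
            out[:, k] = x0
            continue
        E = expm(A * t)
        out[:, k] = E @ x0 + E @ y - y
    return out


def model_fit_error(predicted, interpolated) -> float:
    """Mean squared deviation over all genes and grid points."""
    predicted = np.asarray(predicted, dtype=float)
    interpolated = np.asarray(interpolated, dtype=float)
    if predicted.shape != interpolated.shape:
        raise ValueError(
            f"grid mismatch: {predicted.shape} vs {interpolated.shape}"
        )
    return float(np.mean((predicted - interpolated) ** 2))


def simulate_model(model: GRNModel, input_signal: InputSignal, grid):
    """Forward-simulate an inferred model on ``grid`` from x(0)=0."""
    if not model.is_stable():
        warnings.warn("simulating an unstable model", stacklevel=2)
    return step_response(model.A, model.b, grid)


def _target_trajectory(a_self, coefs, regressors, x0, grid):
    """Integrate one target's ODE with fixed regulator signals (RK4).

    dz/dt = a_self·z + f(t) with f given on the (uniform) dense grid.
    """
    f = coefs @ regressors if len(coefs) else np.zeros(grid.size)
    z = np.empty(grid.size)
    z[0] = x0
    for k in range(grid.size - 1):
        h = grid[k + 1] - grid[k]
        fm = 0.5 * (f[k] + f[k + 1])
        zk = z[k]
        k1 = a_self * zk + f[k]
        k2 = a_self * (zk + h / 2 * k1) + fm
        k3 = a_self * (zk + h / 2 * k2) + fm
        k4 = a_self * (zk + h * k3) + f[k + 1]
        z[k + 1] = zk + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return z


def _fit_coefficients(dxi, columns):
    """Least-squares fit of the derivative on the given design columns."""
    X = np.column_stack(columns)
    coef, _, rank, _ = np.linalg.lstsq(X, dxi, rcond=None)
    resid = dxi - X @ coef
    return coef, float(resid @ resid), rank


def infer_network(
    series: TimeSeriesSet,
    input_signal: InputSignal | None = None,
    prior: PriorKnowledge | None = None,
    allowed_error: float = 0.01,
    max_in_degree: int = 3,
    grid_step: float = 0.1,
) -> GRNModel:
    """Infer a linear ODE network from interpolated fold-change series.

    Per target gene, regulators are added one at a time by greedy forward
    selection: coefficients for each candidate set come from a least-squares
    fit of the estimated derivative (central differences on the dense PCHIP
    grid), and the candidate whose simulated target trajectory best matches
    the interpolated data is selected.  Candidates listed in the prior are
    favoured — their trajectory error is discounted by (1 + confidence) and
    they win ties — but the prior never forces inclusion.  Selection stops
    once the target's trajectory MSE is ≤ ``allowed_error``, the in-degree
    cap is reached, or no candidate improves the fit.  The self-decay term
    is always present and the stepwise input competes as an ordinary
    candidate (not counted against the gene in-degree cap).
    """
    if allowed_error <= 0:
        raise ValueError("allowed_error must be > 0")
    if len(series.genes) < 2:
        raise ValueError("need at least two genes")
    input_signal = input_signal or InputSignal()
    genes = series.genes
    n = len(genes)
    grid, dense = series.interpolated(grid_step)
    deriv = np.gradient(dense, grid, axis=1)
    u = input_signal(grid)

    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        target = genes[i]
        dxi = deriv[i]
        selected: list[str] = []  # gene names and/or INPUT_NODE, in order

        def columns_for(sel):
            cols = [dense[i]]
            for name in sel:
                cols.append(u if name == INPUT_NODE else dense[genes.index(name)])
            return cols

        def target_mse(coef, sel):
            regs = (
                np.array([u if s == INPUT_NODE else dense[genes.index(s)] for s in sel])
                if sel
                else np.zeros((0, grid.size))
            )
            with np.errstate(over="ignore", invalid="ignore"):
                z = _target_trajectory(coef[0], coef[1:], regs, dense[i, 0], grid)
                if not np.all(np.isfinite(z)):
                    return float("inf")
                mse = float(np.mean((z - dense[i]) ** 2))
            return mse if np.isfinite(mse) else float("inf")

        coef, _, _ = _fit_coefficients(dxi, columns_for(selected))
        current = target_mse(coef, selected)
        while current > allowed_error:
            gene_count = sum(1 for s in selected if s != INPUT_NODE)
            candidates = []
            if gene_count < max_in_degree:
                candidates.extend(
                    g for g in genes if g != target and g not in selected
                )
            if INPUT_NODE not in selected:
                candidates.append(INPUT_NODE)
            if not candidates:
                break
            best = None  # (key, mse, name, coef); minimize key
            for cand in candidates:
                cand_coef, _, rank = _fit_coefficients(
                    dxi, columns_for(selected + [cand])
                )
                if rank < len(selected) + 2:
                    continue  # collinear candidate: drop
                mse = target_mse(cand_coef, selected + [cand])
                conf = (
                    prior.confidence(cand, target)
                    if prior is not None and cand != INPUT_NODE
                    else 0.0
                )
                # prior confidence discounts the error; deterministic
                # tie-break: prior-listed first, genes before the input,
                # then lexicographic name
                key = (mse / (1.0 + conf), conf == 0, cand == INPUT_NODE, cand)
                if best is None or key < best[0]:
                    best = (key, mse, cand, cand_coef)
            if best is None or best[1] >= current * (1 - 1e-9):
                break
            _, current, chosen, coef = best
            selected.append(chosen)

        for name, w in zip(selected, coef[1:]):
            if name == INPUT_NODE:
                b[i] = w
            else:
                A[i, genes.index(name)] = w
        A[i, i] = coef[0]

    model = GRNModel(
        genes=list(genes),
        A=A,
        b=b,
        allowed_error=allowed_error,
        max_in_degree=max_in_degree,
        input_name=input_signal.name,
    )
    with np.errstate(over="ignore", invalid="ignore"):
        predicted = step_response(A, b, grid, x0=dense[:, 0])
        model.fit_error = (
            float(np.mean((predicted - dense) ** 2))
            if np.all(np.isfinite(predicted))
            else float("inf")
        )
    return model
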