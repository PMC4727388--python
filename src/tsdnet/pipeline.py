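"""End-to-end orchestration: simulate/load → DE → screens → GRN → robustness.

The pipeline mirrors the temperature-shift study flow.  Day 0 (the
pre-shift FPT-incubated bipotential gonad) is the baseline group for
the Day 0→3 comparison in *both* arms; development-dependent tables are
computed per arm over intervals (0,3), (3,6), (6,12) and sex-dependent
tables at Days 3, 6 and 12.  Singleton samples (Days 18–36) are never
tested, only used descriptively for the dimorphism-timespan labels.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tsdio
from .diffexpr import ComparisonSpec, Thresholds, test_differential_expression
from .fixtures import load_table1_fixture, load_table2_fixture
from .grn import InputSignal, PriorKnowledge, TimeSeriesSet, infer_network
from .robustness import consensus, noise_perturbation_test, prior_omission_test
from .screens import (
    DEV_INTERVALS,
    SEX_DAYS,
    candidate_sexdev_screen,
    classify_timespan,
    development_dependent_degs,
    dimorphism_zscore_matrix,
    hierarchical_cluster,
    persistent_dimorphic,
    sex_dependent_degs,
    summarize_table1,
    summarize_table2,
    temperature_responsive_screen,
)
from .simulate import (
    DESCRIPTIVE_DAYS,
    ExpressionMatrix,
    SimulationConfig,
    generate_expression_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline", "fixture_report", "adjacent_comparisons"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and sizes for one pipeline run.

    Defaults are the analysis defaults: FDR screen 0.01, allowedError
    0.01, perturbation noise sd 0.05, prior omission 10 %, robustness
    consensus at >50 % with the high-robustness mark at ≥80 %, and a
    |M−F log2FC| ≥ 1 descriptive dimorphism threshold for the
    no-replicate days.
    """

    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    prior_path: str | None = None
    out_dir: str = "tsdnet_out"
    fdr_screen: float = 0.01
    allowed_error: float = 0.01
    noise_sd: float = 0.05
    omit_fraction: float = 0.10
    robust_threshold: float = 0.5
    high_threshold: float = 0.8
    dimorphism_log2fc: float = 1.0
    n_reps: int = 200
    max_in_degree: int = 3
    n_grn_genes: int = 6
    seed: int = 0
    simulation: SimulationConfig | None = None

    def __post_init__(self):
        for name, value, lo, hi in (
            ("fdr_screen", self.fdr_screen, 0, 1),
            ("allowed_error", self.allowed_error, 0, np.inf),
            ("omit_fraction", self.omit_fraction, -1e-12, 1),
            ("robust_threshold", self.robust_threshold, 0, 1),
            ("high_threshold", self.high_threshold, 0, 1),
        ):
            if not (lo < value < hi or (name == "omit_fraction" and value == 0)):
                raise ValueError(f"{name}={value} outside its documented range")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        if self.simulation is not None:
            d["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.simulation.__dict__.items()
            }
        return d


def adjacent_comparisons(condition: str):
    """The arm's adjacent-day comparisons; Day 0 always comes from FPT."""
    specs = []
    for d0, d1 in DEV_INTERVALS:
        ga = ("FPT", d0) if d0 == 0 else (condition, d0)
        specs.append(
            ComparisonSpec(f"{condition}_day{d0}_vs_day{d1}", ga, (condition, d1))
        )
    return specs


def _log_mean(matrix: ExpressionMatrix, condition: str, day: int) -> pd.Series:
    sub = matrix.select(condition, day)
    return np.log2(sub + 1.0).mean(axis=1)


def _mf_log2fc(matrix: ExpressionMatrix, days) -> pd.DataFrame:
    """M−F difference of mean log2(FPKM+1) per gene at each day."""
    cols = {}
    for day in days:
        cols[day] = _log_mean(matrix, "MPT", day) - _log_mean(matrix, "FPT", day)
    return pd.DataFrame(cols)


def _fold_change_series(matrix: ExpressionMatrix, condition: str, genes, days):
    """Per-gene log2 fold change vs the Day 0 (FPT) baseline."""
    base = _log_mean(matrix, "FPT", 0)[genes]
    values = np.empty((len(genes), len(days)))
    for k, day in enumerate(days):
        if day == 0:
            values[:, k] = 0.0
        else:
            values[:, k] = (_log_mean(matrix, condition, day)[genes] - base).to_numpy()
    return TimeSeriesSet(genes, days, values)


def fixture_report() -> dict:
    """Summaries of the packaged in-print tables (fixture-only mode)."""
    return {
        "temperature_responsive_table": summarize_table1(load_table1_fixture()),
        "candidate_regulator_table": summarize_table2(load_table2_fixture()),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Returns the JSON-serializable run report (also written to
    ``report.json``): per-screen totals, timespan label counts, inferred
    edge counts and robust-edge counts per condition, plus the echoed
    configuration.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    child_seed = lambda: int(rng.integers(2**31 - 1))  # noqa: E731

    # ---- input data -------------------------------------------------
    if config.matrix_path is not None:
        log.info("reading expression matrix from %s", config.matrix_path)
        matrix = tsdio.read_expression_matrix(config.matrix_path, config.sample_sheet_path)
        truth = None
    else:
        sim = config.simulation or SimulationConfig(seed=child_seed())
        log.info("simulating dataset: %d genes, seed %d", sim.n_genes, sim.seed)
        matrix, truth = generate_expression_dataset(sim)
        tsdio.write_expression_matrix(
            matrix, out / "expression.tsv", out / "samples.tsv"
        )
    prior = PriorKnowledge([])
    if config.prior_path:
        rows = pd.read_csv(config.prior_path, sep="\t")
        prior = PriorKnowledge(
            [tuple(r) for r in rows.itertuples(index=False)]
        )

    thresholds = Thresholds(fdr_screen=config.fdr_screen)

    # ---- differential expression ------------------------------------
    log.info("stage DE: adjacent-interval and intergroup comparisons")
    dev_tables = {}
    for cond in ("MPT", "FPT"):
        dev_tables[cond] = {}
        for spec, iv in zip(adjacent_comparisons(cond), DEV_INTERVALS):
            table = test_differential_expression(matrix, spec, thresholds)
            dev_tables[cond][iv] = table
            tsdio.write_deg_table(table, out / f"deg_{spec.label}.tsv")
    sex_tables = {}
    for day in SEX_DAYS:
        spec = ComparisonSpec(f"MPT_vs_FPT_day{day}", ("FPT", day), ("MPT", day))
        sex_tables[day] = test_differential_expression(matrix, spec, thresholds)
        tsdio.write_deg_table(sex_tables[day], out / f"deg_{spec.label}.tsv")

    # ---- screens ----------------------------------------------------
    log.info("stage screens")
    dev_screens = {c: development_dependent_degs(t) for c, t in dev_tables.items()}
    sex_screens = sex_dependent_degs(sex_tables)
    persistent, persistent_consistent = persistent_dimorphic(sex_screens)
    temp = temperature_responsive_screen(
        dev_tables["MPT"][(0, 3)], dev_tables["FPT"][(0, 3)], sex_screens[3]
    )
    cand = candidate_sexdev_screen(dev_screens, sex_screens)
    for res in (temp.mpt_specific, temp.responsive, cand.candidates):
        tsdio.write_screen_result(res, out / f"screen_{res.name}.tsv")

    # dimorphism flags: tested days from the DE screens, no-replicate days
    # from the descriptive |M−F| >= dimorphism_log2fc rule
    genes = list(matrix.values.index)
    flag_days, flags = [], []
    for day in SEX_DAYS:
        flag_days.append(day)
        flags.append([g in sex_screens[day] for g in genes])
    desc_days = [d for d in DESCRIPTIVE_DAYS if
                 matrix.group_size("MPT", d) >= 1 and matrix.group_size("FPT", d) >= 1]
    mf_desc = _mf_log2fc(matrix, desc_days)
    for day in desc_days:
        flag_days.append(day)
        flags.append((mf_desc[day].abs() >= config.dimorphism_log2fc).tolist())
    flag_frame = pd.DataFrame(
        dict(zip(flag_days, flags)), index=pd.Index(genes, name="gene_id")
    )
    timespans = classify_timespan(flag_frame.loc[sorted(cand.candidates.genes)]) \
        if len(cand.candidates) else pd.Series(dtype=object)

    # z-scored dimorphism profiles of the candidates, clustered
    newick = None
    if len(cand.candidates) >= 2:
        mf = _mf_log2fc(matrix, SEX_DAYS).loc[sorted(cand.candidates.genes)]
        z = dimorphism_zscore_matrix(mf)
        if z.shape[0] >= 2:
            _, _, newick = hierarchical_cluster(z)
            (out / "candidate_cluster.nwk").write_text(newick + "\n")

    # ---- network inference + robustness -----------------------------
    log.info("stage GRN inference")
    grn_report = {}
    mf12 = _mf_log2fc(matrix, [12])[12].abs()
    ranked = sorted(
        cand.candidates.genes, key=lambda g: (-float(mf12.get(g, 0.0)), g)
    )
    grn_genes = ranked[: config.n_grn_genes]
    for cond in ("MPT", "FPT"):
        if len(grn_genes) < 2:
            log.warning("fewer than 2 candidate genes; skipping %s network", cond)
            continue
        days = sorted({0} | {d for d in (3, 6, 12, 18, 24, 30)
                             if matrix.group_size(cond, d) >= 1})
        series = _fold_change_series(matrix, cond, grn_genes, days)
        signal = InputSignal(cond)
        settings = dict(
            allowed_error=config.allowed_error, max_in_degree=config.max_in_degree
        )
        model = infer_network(series, signal, prior or None, **settings)
        tsdio.write_model(model, out / f"model_{cond}.json")
        tsdio.write_edge_list(model, out / f"edges_{cond}.tsv")
        entry = {
            "genes": grn_genes,
            "n_edges": len(model.edges()),
            "fit_error": model.fit_error,
        }
        fn = noise_perturbation_test(
            series, signal, prior if len(prior) else None,
            n_reps=config.n_reps, noise_sd=config.noise_sd,
            seed=child_seed(), **settings,
        )
        if len(prior):
            fp = prior_omission_test(
                series, prior, signal, n_reps=config.n_reps,
                omit_fraction=config.omit_fraction, seed=child_seed(), **settings,
            )
            report = consensus(fn, fp, config.robust_threshold, config.high_threshold)
            tsdio.write_robustness_report(
                report, out / f"robustness_{cond}.tsv",
                out / f"robustness_{cond}.json",
                {"n_reps": config.n_reps, "noise_sd": config.noise_sd,
                 "omit_fraction": config.omit_fraction},
            )
            entry["n_robust"] = len(report.robust_edges)
            entry["n_high_robust"] = len(report.high_robust_edges)
        else:
            entry["n_noise_stable"] = sum(
                1 for e in fn.baseline_edges if fn.frequency(e) > config.robust_threshold
            )
        grn_report[cond] = entry

    # ---- report -----------------------------------------------------
    report = {
        "config": config.to_dict(),
        "n_genes": len(genes),
        "screens": {
            "development_dependent": {
                cond: {
                    "union": len(dev_screens[cond].union),
                    "multi_occasion": len(dev_screens[cond].multi_occasion),
                    "per_interval": {
                        f"{iv[0]}-{iv[1]}": len(dev_screens[cond].per_interval[iv])
                        for iv in DEV_INTERVALS
                    },
                }
                for cond in ("MPT", "FPT")
            },
            "sex_dependent": {str(d): len(sex_screens[d]) for d in SEX_DAYS},
            "persistent_dimorphic": len(persistent),
            "persistent_direction_consistent": len(persistent_consistent),
            "mpt_specific": len(temp.mpt_specific),
            "temperature_responsive": len(temp.responsive),
            "temperature_responsive_up": sum(
                1 for d in temp.responsive.directions.values() if d == "up"
            ),
            "temperature_responsive_down": sum(
                1 for d in temp.responsive.directions.values() if d == "down"
            ),
            "candidates": len(cand.candidates),
        },
        "timespan_labels": timespans.value_counts().to_dict() if len(timespans) else {},
        "grn": grn_report,
    }
    if truth is not None:
        planted = {}
        for cls in ("development_dependent", "sex_dependent",
                    "temperature_responsive", "candidate_both"):
            planted[cls] = len(truth.genes_of_class(cls))
        report["planted_classes"] = planted
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report
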