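"""Set-algebra gene screens over differential-expression tables.

These are the cross-comparison procedures of the temperature-shift
analysis: development-dependent DEGs (adjacent time points within one
temperature arm), sex-dependent DEGs (MPT vs FPT at matched days),
persistent dimorphism, the immediate temperature-responsive screen
(change after the Day-0 shift in the MPT arm only, and dimorphic at
Day 3), the candidate sexual-development screen (development-dependent
AND dimorphic), the Long/Short/Ambiguous dimorphism-timespan
classification, and z-scored hierarchical clustering of the M−F log2
fold-change profile.

Every screen is a pure function of its input tables; all tie-breaking
is lexicographic in gene_id.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .diffexpr import DEGTable
from .fixtures import Table1Record, Table2Record

__all__ = [
    "ScreenResult",
    "DevelopmentScreen",
    "TemperatureScreen",
    "CandidateScreen",
    "development_dependent_degs",
    "sex_dependent_degs",
    "persistent_dimorphic",
    "temperature_responsive_screen",
    "candidate_sexdev_screen",
    "classify_timespan",
    "dimorphism_zscore_matrix",
    "hierarchical_cluster",
    "summarize_table1",
    "summarize_table2",
    "DEV_INTERVALS",
    "SEX_DAYS",
]

DEV_INTERVALS = ((0, 3), (3, 6), (6, 12))
SEX_DAYS = (3, 6, 12)


@dataclass
class ScreenResult:
    """A named gene set with per-gene direction and provenance labels."""

    name: str
    directions: dict = field(default_factory=dict)   # gene -> direction
    provenance: dict = field(default_factory=dict)   # gene -> [comparison labels]

    @property
    def genes(self) -> set:
        return set(self.directions)

    def __contains__(self, gene) -> bool:
        return gene in self.directions

    def __len__(self) -> int:
        return len(self.directions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, self.name, self.directions[g], ";".join(self.provenance.get(g, [])))
            for g in sorted(self.directions)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "screen", "direction", "provenance"])


def _significant(table: DEGTable) -> dict:
    """gene -> direction for the genes passing the FDR screen."""
    recs = table.records
    sig = recs[recs["significant"]]
    return dict(zip(sig["gene_id"], sig["direction"]))


@dataclass
class DevelopmentScreen:
    per_interval: dict          # (d0, d1) -> ScreenResult
    union: ScreenResult
    multi_occasion: set         # significant in >= 2 intervals


def development_dependent_degs(deg_tables: dict) -> DevelopmentScreen:
    """Screen DEGs between temporally adjacent days within one arm.

    ``deg_tables`` maps intervals (0,3), (3,6), (6,12) to DEGTables.
    Returns per-interval sets, their union, and the "multiple occasion"
    genes significant in at least two intervals.
    """
    missing = [iv for iv in DEV_INTERVALS if iv not in deg_tables]
    if missing:
        raise ValueError(f"missing interval tables: {missing}")
    per_interval = {}
    counts: dict = {}
    union = ScreenResult(name="development_dependent")
    for iv in DEV_INTERVALS:
        table = deg_tables[iv]
        sig = _significant(table)
        res = ScreenResult(name=f"development_{iv[0]}_{iv[1]}")
        for gene, direction in sig.items():
            res.directions[gene] = direction
            res.provenance[gene] = [table.comparison.label]
            counts[gene] = counts.get(gene, 0) + 1
            union.directions[gene] = direction  # last interval wins for direction
            union.provenance.setdefault(gene, []).append(table.comparison.label)
        per_interval[iv] = res
    multi = {g for g, c in counts.items() if c >= 2}
    return DevelopmentScreen(per_interval=per_interval, union=union, multi_occasion=multi)


def sex_dependent_degs(deg_tables: dict) -> dict:
    """Screen MPT-vs-FPT DEGs per day; directions MPT-/FPT-biased.

    ``deg_tables`` maps day -> DEGTable where group A is FPT and group B
    is MPT, so positive fold change means higher at MPT.  Day 0 has no
    MPT arm and is refused.
    """
    out = {}
    for day, table in sorted(deg_tables.items()):
        if day == 0:
            raise ValueError("Day 0 has no MPT arm; sex-dependent screen undefined")
        conds = (table.comparison.group_a[0], table.comparison.group_b[0])
        if conds != ("FPT", "MPT"):
            raise ValueError(
                f"day {day}: expected FPT-vs-MPT orientation, got {conds}"
            )
        res = ScreenResult(name=f"sex_dependent_day{day}")
        for gene, direction in _significant(table).items():
            res.directions[gene] = "MPT-biased" if direction == "up" else "FPT-biased"
            res.provenance[gene] = [table.comparison.label]
        out[day] = res
    return out


def persistent_dimorphic(day_sets: dict) -> tuple:
    """Genes dimorphic at all of Days 3, 6 and 12.

    Returns ``(always_dimorphic, direction_consistent)`` — the plain
    intersection regardless of direction, and the subset biased toward
    the same temperature at every day.
    """
    for day in SEX_DAYS:
        if day not in day_sets:
            raise ValueError(f"missing Day {day} sex-dependent set")
    sets = [day_sets[d].genes for d in SEX_DAYS]
    inter = sets[0] & sets[1] & sets[2]
    consistent = {
        g
        for g in inter
        if len({day_sets[d].directions[g] for d in SEX_DAYS}) == 1
    }
    return inter, consistent


@dataclass
class TemperatureScreen:
    mpt_specific: ScreenResult
    responsive: ScreenResult     # mpt_specific ∩ dimorphic at Day 3, split up/down


def temperature_responsive_screen(
    mpt_d0_d3: DEGTable, fpt_d0_d3: DEGTable, dimorphic_d3: ScreenResult
) -> TemperatureScreen:
    """The immediate temperature-response screen.

    A gene responds to the Day-0 temperature shift if it changes between
    Day 0 (pre-shift, FPT) and Day 3 in the shifted (MPT) arm but not in
    the arm kept at FPT; the responsive candidates are those that are
    additionally sexually dimorphic at Day 3, split by direction of the
    MPT change.
    """
    if mpt_d0_d3.gene_universe != fpt_d0_d3.gene_universe:
        raise ValueError("comparisons cover different gene universes")
    sig_mpt = _significant(mpt_d0_d3)
    sig_fpt = _significant(fpt_d0_d3)
    mpt_specific = ScreenResult(name="mpt_specific")
    for gene in sorted(set(sig_mpt) - set(sig_fpt)):
        mpt_specific.directions[gene] = sig_mpt[gene]
        mpt_specific.provenance[gene] = [mpt_d0_d3.comparison.label]
    responsive = ScreenResult(name="temperature_responsive")
    for gene in sorted(mpt_specific.genes & dimorphic_d3.genes):
        responsive.directions[gene] = mpt_specific.directions[gene]
        responsive.provenance[gene] = (
            mpt_specific.provenance[gene] + dimorphic_d3.provenance.get(gene, [])
        )
    return TemperatureScreen(mpt_specific=mpt_specific, responsive=responsive)


@dataclass
class CandidateScreen:
    candidates: ScreenResult
    per_cell: dict   # (condition, interval) -> ScreenResult with up/down


def candidate_sexdev_screen(dev_screens: dict, sex_days: dict) -> CandidateScreen:
    """Development-dependent DEGs that are also sexually dimorphic.

    ``dev_screens`` maps condition -> DevelopmentScreen; ``sex_days``
    maps day -> sex-dependent ScreenResult.  A change over an interval
    (t_i, t_{i+1}) counts when the gene is dimorphic at the interval's
    right endpoint t_{i+1}; the candidate set is the union over
    conditions and intervals, annotated up/down per cell.
    """
    candidates = ScreenResult(name="candidate_sexdev")
    per_cell = {}
    for cond in sorted(dev_screens):
        screen = dev_screens[cond]
        for iv in DEV_INTERVALS:
            right = iv[1]
            if right not in sex_days:
                continue
            dev_set = screen.per_interval[iv]
            dim = sex_days[right].genes
            cell = ScreenResult(name=f"candidate_{cond}_{iv[0]}_{iv[1]}")
            for gene in sorted(dev_set.genes & dim):
                cell.directions[gene] = dev_set.directions[gene]
                cell.provenance[gene] = (
                    dev_set.provenance[gene] + sex_days[right].provenance[gene]
                )
                candidates.directions[gene] = dev_set.directions[gene]
                candidates.provenance.setdefault(gene, []).extend(
                    cell.provenance[gene]
                )
            per_cell[(cond, iv)] = cell
    return CandidateScreen(candidates=candidates, per_cell=per_cell)


def classify_timespan(dimorphism_flags: pd.DataFrame) -> pd.Series:
    """Label each gene's dimorphism duration Long / Short / Ambiguous.

    ``dimorphism_flags`` is a boolean genes × days frame (columns sorted
    ascending, e.g. Days 3,6,12,18,24,30).  From the first dimorphic day:
    a contiguous run through the final observed day is "Long"; a
    contiguous run ending earlier is "Short"; any gap makes the pattern
    "Ambiguous".  Genes never dimorphic get "none".
    """
    days = sorted(dimorphism_flags.columns)
    flags = dimorphism_flags[days].to_numpy(dtype=bool)
    labels = []
    for row in flags:
        idx = np.flatnonzero(row)
        if idx.size == 0:
            labels.append("none")
        elif idx[-1] - idx[0] + 1 != idx.size:
            labels.append("Ambiguous")
        elif idx[-1] == len(days) - 1:
            labels.append("Long")
        else:
            labels.append("Short")
    return pd.Series(labels, index=dimorphism_flags.index, name="timespan")


def dimorphism_zscore_matrix(mf_log2fc: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score of an M−F log2FC matrix.

    Rows with non-finite entries (infinite fold changes) or zero
    variance are excluded with a warning — capping an infinite fold
    change would invent a magnitude.
    """
    finite = np.isfinite(mf_log2fc.to_numpy(dtype=float)).all(axis=1)
    with np.errstate(invalid="ignore"):
        sd = mf_log2fc.where(pd.DataFrame(
            np.isfinite(mf_log2fc.to_numpy(dtype=float)),
            index=mf_log2fc.index, columns=mf_log2fc.columns,
        )).std(axis=1, ddof=1)
    keep = finite & (sd.to_numpy() > 0)
    dropped = mf_log2fc.index[~keep]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} constant or non-finite rows from z-scoring",
            stacklevel=2,
        )
    sub = mf_log2fc.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)


def hierarchical_cluster(matrix: pd.DataFrame):
    """Average-linkage clustering on Euclidean distances between gene rows.

    Rows are pre-sorted lexicographically by gene_id so ties resolve
    deterministically.  Returns ``(leaf_order, linkage, newick)`` where
    ``leaf_order`` is the list of gene ids in dendrogram order and
    ``newick`` a branch-length-annotated tree string.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two genes to cluster")
    matrix = matrix.sort_index()
    Z = hierarchy.linkage(pdist(matrix.to_numpy(dtype=float)), method="average")
    leaves = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)
    names = list(matrix.index)

    def newick(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return leaves, Z, newick(tree, tree.dist) + ";"


def summarize_table1(records: list[Table1Record]) -> dict:
    """Exact tallies of the temperature-responsive gene table."""
    up = [r for r in records if r.direction == "up"]
    down = [r for r in records if r.direction == "down"]
    finite_up = [r.log2fc for r in up if not math.isinf(r.log2fc)]
    finite_down = [r.log2fc for r in down if not math.isinf(r.log2fc)]
    return {
        "total": len(records),
        "up": len(up),
        "down": len(down),
        "n_infinite": sum(1 for r in records if r.is_infinite),
        "max_finite_up_log2fc": max(finite_up) if finite_up else None,
        "min_finite_down_log2fc": min(finite_down) if finite_down else None,
    }


def summarize_table2(records: list[Table2Record]) -> dict:
    """Exact tallies of the candidate-regulator table."""
    symbols = {r.gene_symbol for r in records}
    tf_symbols = {
        r.gene_symbol for r in records if r.molecule_type == "Transcription factor"
    }
    by_type: dict = {}
    for r in records:
        by_type[r.molecule_type] = by_type.get(r.molecule_type, 0) + 1
    return {
        "n_records": len(records),
        "unique_genes": len(symbols),
        "transcription_factors": len(tf_symbols),
        "records_per_molecule_type": dict(sorted(by_type.items())),
        "comparisons": sorted({r.comparison for r in records}),
    }


def counts_report(named_sets: dict) -> str:
    """Venn-style JSON summary: set name -> member count."""
    return json.dumps({k: len(v) for k, v in sorted(named_sets.items())}, indent=2)
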