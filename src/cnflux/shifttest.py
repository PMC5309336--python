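"""Permutation histogram-distance test for shifted flux distributions.

For each reaction the two conditions contribute equal-length flux sample
vectors.  Per repeat, both vectors are independently permuted and subtracted
elementwise, giving a distance vector; the statistic is the minority sign
count ``min(#positive, #negative)`` averaged over repeats and scaled by the
vector length, and the two-sided p-value is twice that fraction (capped at
1).  Identical distributions give balanced signs and p near 1; disjoint
supports give a zero minority count and p = 0.  Exact zero differences count
toward neither sign, and a pair of elementwise-identical vectors is assigned
p = 1 (no evidence of a difference) rather than the degenerate p = 0.

The test responds to *separation* of the two distributions: the expected
minority fraction for two unit normals a distance d apart is Phi(-d/sqrt(2)),
so p falls below 0.05 only once the overlap drops under 2.5% (d around
2.8 sd).  Moderate mean shifts that leave substantial overlap are therefore
not flagged — the test is deliberately conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel
from .sampling import FluxSampleSet

__all__ = [
    "ShiftTestResult",
    "GroupSummary",
    "shift_statistic",
    "bh_adjust",
    "test_all",
    "summarize_groups",
    "compare_hit_sets",
]

DEFAULT_REPEATS = 100
DEFAULT_ALPHA = 0.05


@dataclass
class ShiftTestResult:
    reaction_id: str
    stat: float  # mean minority-sign fraction, in [0, 0.5]
    p_value: float
    q_value: float | None = None
    direction: str = "none"  # up | down | none (high minus low median sign)
    significant: bool = False


@dataclass
class GroupSummary:
    group: str
    n_reactions_in_group: int
    n_up: int
    n_down: int

    @property
    def pct_up(self) -> float:
        return 100.0 * self.n_up / self.n_reactions_in_group

    @property
    def pct_down(self) -> float:
        return 100.0 * self.n_down / self.n_reactions_in_group


def shift_statistic(
    v_low: np.ndarray,
    v_high: np.ndarray,
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> tuple[float, float]:
    """Minority-sign permutation statistic and its two-sided p-value."""
    v_low = np.asarray(v_low, float)
    v_high = np.asarray(v_high, float)
    if v_low.shape != v_high.shape or v_low.ndim != 1:
        raise ValueError("flux vectors must be 1-D and of equal length")
    n = v_low.size
    if n < 2:
        raise ValueError("need at least 2 samples per condition")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if np.array_equal(v_low, v_high):
        return 0.5, 1.0
    rng = np.random.default_rng(seed)
    # one argsort-of-uniforms per repeat gives an independent permutation
    perms_low = np.argsort(rng.random((n_repeats, n)), axis=1)
    perms_high = np.argsort(rng.random((n_repeats, n)), axis=1)
    d = v_low[perms_low] - v_high[perms_high]
    pos = (d > 0).sum(axis=1)
    neg = (d < 0).sum(axis=1)
    stat = float(np.minimum(pos, neg).mean() / n)
    return stat, min(1.0, 2.0 * stat)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_all(
    low: FluxSampleSet,
    high: FluxSampleSet,
    n_repeats: int = DEFAULT_REPEATS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    subsample: int | None = None,
) -> tuple[list[ShiftTestResult], list[str]]:
    """Shift test per shared reaction with BH-FDR across all tested reactions.

    Returns the result list (shared-reaction order of the low-condition set)
    and the reaction ids skipped because they appear in only one set.
    ``subsample`` caps the number of sample rows used per condition (seeded),
    for tractability on very large sampling runs.
    """
    shared = [rid for rid in low.reaction_ids if rid in set(high.reaction_ids)]
    if not shared:
        raise ValueError("the two sample sets share no reactions")
    skipped = sorted(
        (set(low.reaction_ids) | set(high.reaction_ids)) - set(shared)
    )
    rng = np.random.default_rng(seed)
    vl_all, vh_all = low.samples, high.samples
    if subsample is not None:
        n = min(subsample, vl_all.shape[0], vh_all.shape[0])
        vl_all = vl_all[rng.choice(vl_all.shape[0], n, replace=False)]
        vh_all = vh_all[rng.choice(vh_all.shape[0], n, replace=False)]
    else:
        n = min(vl_all.shape[0], vh_all.shape[0])
        vl_all, vh_all = vl_all[:n], vh_all[:n]

    child_seeds = rng.integers(0, 2**31 - 1, size=len(shared))
    results = []
    for rid, child in zip(shared, child_seeds):
        vl = vl_all[:, low.reaction_ids.index(rid)]
        vh = vh_all[:, high.reaction_ids.index(rid)]
        stat, p = shift_statistic(vl, vh, n_repeats=n_repeats, seed=int(child))
        diff = float(np.median(vh) - np.median(vl))
        direction = "up" if diff > 0 else ("down" if diff < 0 else "none")
        results.append(ShiftTestResult(rid, stat, p, direction=direction))
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < alpha and r.direction != "none")
    return results, skipped


def summarize_groups(
    results: list[ShiftTestResult],
    model: MetabolicModel,
    cmap,
    gene_associated_only: bool = True,
) -> list[GroupSummary]:
    """Count significant up/down reactions per display group.

    Reactions without a GPR are dropped from the counts when
    ``gene_associated_only`` (the convention used for the group figures);
    percentages are over *all* model reactions in the group.  Subsystems
    missing from the category map land in an "unmapped" bucket.
    """
    group_of = {}
    totals: dict[str, int] = {}
    for r in model.reactions:
        g = cmap.display_group(r.subsystem)
        group_of[r.id] = g
        totals[g] = totals.get(g, 0) + 1
    ups: dict[str, int] = {}
    downs: dict[str, int] = {}
    for res in results:
        if not res.significant:
            continue
        rxn = model.reaction(res.reaction_id)
        if gene_associated_only and not rxn.genes:
            continue
        g = group_of[res.reaction_id]
        if res.direction == "up":
            ups[g] = ups.get(g, 0) + 1
        elif res.direction == "down":
            downs[g] = downs.get(g, 0) + 1
    return [
        GroupSummary(g, totals[g], ups.get(g, 0), downs.get(g, 0))
        for g in sorted(totals)
    ]


def compare_hit_sets(
    sampling_hits: set[str],
    de_genes: set[str],
    model: MetabolicModel,
):
    """Per-subsystem overlap of sampling hits and DE-gene-mapped reactions.

    Differentially-expressed genes are mapped to reactions through the GPRs;
    the table reports, per subsystem, how many reactions are unique to the
    sampling analysis, unique to the DE mapping, and shared.
    """
    import pandas as pd

    from .model import map_genes_to_reactions

    de_rxns: set[str] = set()
    for rxns in map_genes_to_reactions(model, set(de_genes)).values():
        de_rxns |= rxns
    subsystems = sorted({model.reaction(r).subsystem for r in sampling_hits | de_rxns})
    rows = []
    for sub in subsystems:
        in_sub = {r.id for r in model.reactions if r.subsystem == sub}
        s = sampling_hits & in_sub
        d = de_rxns & in_sub
        rows.append(
            {
                "subsystem": sub,
                "sampling_only": len(s - d),
                "de_only": len(d - s),
                "shared": len(s & d),
            }
        )
    return pd.DataFrame(rows, columns=["subsystem", "sampling_only", "de_only", "shared"])


def write_results_tsv(results: list[ShiftTestResult], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (r.reaction_id, r.stat, r.p_value, r.q_value, r.direction, r.significant)
            for r in results
        ],
        columns=["reaction_id", "stat", "p", "q", "direction", "significant"],
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_group_summary_tsv(summaries: list[GroupSummary], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (s.group, s.n_reactions_in_group, s.n_up, s.n_down, s.pct_up, s.pct_down)
            for s in summaries
        ],
        columns=["group", "n_reactions", "n_up", "n_down", "pct_up", "pct_down"],
    ).to_csv(path, sep="\t", index=False, float_format="%.4g")
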