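"""Group statistics, relative qPCR quantification, and report generation.

The comparison workflow mirrors standard biomechanics practice: every group
is first screened with the Shapiro-Wilk normality test at alpha; if all
groups pass, a one-way ANOVA is used with Dunnett's correction (when a
control group is named) or Tukey's HSD (all pairs); if any group fails, the
whole endpoint switches to the Kruskal-Wallis test with Dunn's multiple-
comparison correction (Šidák-adjusted over the compared pairs).  Two
non-normal groups are compared with the Wilcoxon-Mann-Whitney test.

Relative expression uses the ΔΔCt method: ΔCt = Ct_target - Ct_reference
per replicate, ΔΔCt = mean ΔCt(group) - mean ΔCt(control), and fold change
2^(-ΔΔCt).  Group summarization averages ΔCt (not folds); per-replicate
fold changes are returned for downstream group tests.

The miR-target suppression statistic counts targets with negative log2 fold
change and tests the fraction against 0.5 with an exact two-sided binomial
sign test (zeros excluded).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError


@dataclass
class GroupComparison:
    test_name: str  # anova_dunnett | anova_tukey | kruskal_dunn | mann_whitney
    global_p: float
    pairwise: list[tuple[str, str, float]]
    descriptives: dict[str, dict[str, float]]
    normality_p: dict[str, float]


@dataclass
class ExpressionResult:
    gene: str
    group: str
    fold_change: float
    delta_delta_ct: float
    replicate_fold_changes: list[float]


@dataclass
class SuppressionResult:
    n_targets: int
    n_down: int
    p_value: float

    @property
    def fraction_down(self) -> float:
        return self.n_down / self.n_targets


def _descriptives(values: np.ndarray) -> dict[str, float]:
    # linear-interpolation quantiles so descriptives are bit-reproducible
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
        "q25": float(np.quantile(values, 0.25)),
        "q75": float(np.quantile(values, 0.75)),
    }


def dunn_test(
    values_by_group: Mapping[str, np.ndarray],
    control_group: Optional[str] = None,
    adjust: str = "sidak",
) -> list[tuple[str, str, float]]:
    """Dunn's post-hoc rank test after Kruskal-Wallis.

    z statistic on mean ranks with tie correction; pairwise p values are
    Šidák-adjusted over the compared pairs (all pairs, or all-vs-control
    when a control group is given).
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    all_vals = np.concatenate(arrays)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    mean_ranks = {}
    start = 0
    for g, arr in zip(names, arrays):
        mean_ranks[g] = ranks[start : start + arr.size].mean()
        start += arr.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    if control_group is not None:
        if control_group not in values_by_group:
            raise InvalidParameterError(f"unknown control group {control_group!r}")
        pairs = [(control_group, g) for g in names if g != control_group]
    else:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    k = len(pairs)
    out = []
    for a, b in pairs:
        na, nb = values_by_group[a].size, values_by_group[b].size
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "sidak":
            p_adj = 1.0 - (1.0 - min(p, 1.0)) ** k
        elif adjust == "bonferroni":
            p_adj = min(p * k, 1.0)
        else:
            p_adj = p
        out.append((a, b, float(min(p_adj, 1.0))))
    return out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    control_group: Optional[str] = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated multi-group comparison with post-hoc correction.

    See the module docstring for the decision rule.  Each group needs at
    least three observations (Shapiro-Wilk minimum).
    """
    if len(values_by_group) < 2:
        raise InvalidParameterError("need at least two groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, arr in groups.items():
        if arr.size < 3:
            raise InvalidParameterError(f"group {g!r} has n = {arr.size} < 3")
    if control_group is not None and control_group not in groups:
        raise InvalidParameterError(f"unknown control group {control_group!r}")
    normality = {g: float(sps.shapiro(arr).pvalue) for g, arr in groups.items()}
    desc = {g: _descriptives(arr) for g, arr in groups.items()}
    names = list(groups)
    arrays = [groups[g] for g in names]
    all_normal = all(p > alpha for p in normality.values())

    if all_normal:
        global_p = float(sps.f_oneway(*arrays).pvalue)
        if control_group is not None:
            others = [g for g in names if g != control_group]
            res = sps.dunnett(
                *[groups[g] for g in others], control=groups[control_group]
            )
            pairwise = [
                (control_group, g, float(p)) for g, p in zip(others, res.pvalue)
            ]
            test_name = "anova_dunnett"
        else:
            res = sps.tukey_hsd(*arrays)
            pairwise = [
                (names[i], names[j], float(res.pvalue[i, j]))
                for i in range(len(names))
                for j in range(i + 1, len(names))
            ]
            test_name = "anova_tukey"
    elif len(names) == 2 and control_group is None:
        # plain two-group comparison; a named control routes to the
        # multi-group family (Kruskal-Wallis + Dunn) even at two groups
        global_p = float(sps.mannwhitneyu(arrays[0], arrays[1]).pvalue)
        pairwise = [(names[0], names[1], global_p)]
        test_name = "mann_whitney"
    else:
        global_p = float(sps.kruskal(*arrays).pvalue)
        pairwise = dunn_test(groups, control_group)
        test_name = "kruskal_dunn"
    return GroupComparison(
        test_name=test_name,
        global_p=global_p,
        pairwise=pairwise,
        descriptives=desc,
        normality_p=normality,
    )


# ---------------------------------------------------------------------------
# ΔΔCt expression


def ddct_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
) -> dict[str, ExpressionResult]:
    """Relative expression of ``target_gene`` per group by the ΔΔCt method.

    ``ct_table`` is long-format with columns ``group``, ``replicate``,
    ``gene``, ``ct``.  Every (group, replicate) must have a Ct for both the
    target and the reference gene.
    """
    for col in ("group", "replicate", "gene", "ct"):
        if col not in ct_table.columns:
            raise InvalidParameterError(f"ct_table lacks column {col!r}")
    wide = ct_table.pivot_table(
        index=["group", "replicate"], columns="gene", values="ct"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            raise InvalidParameterError(f"missing Ct values for gene {gene!r}")
    delta_ct = wide[target_gene] - wide[reference_gene]
    if control_group not in delta_ct.index.get_level_values("group"):
        raise InvalidParameterError(f"unknown control group {control_group!r}")
    control_mean = float(delta_ct.xs(control_group, level="group").mean())
    results = {}
    for group, vals in delta_ct.groupby(level="group"):
        ddct = float(vals.mean()) - control_mean
        results[str(group)] = ExpressionResult(
            gene=target_gene,
            group=str(group),
            fold_change=float(2.0 ** (-ddct)),
            delta_delta_ct=ddct,
            replicate_fold_changes=[
                float(2.0 ** (-(v - control_mean))) for v in vals
            ],
        )
    return results


def target_suppression(
    deg_table: pd.DataFrame,
    target_flag_column: str = "is_target",
    log2fc_column: str = "log2_fold_change",
) -> SuppressionResult:
    """Fraction of flagged targets with reduced expression, with sign test.

    Counts targets with negative log2 fold change (zeros excluded from both
    counts) and tests the fraction against 0.5 with an exact two-sided
    binomial test.
    """
    for col in (target_flag_column, log2fc_column):
        if col not in deg_table.columns:
            raise InvalidParameterError(f"deg_table lacks column {col!r}")
    targets = deg_table.loc[deg_table[target_flag_column].astype(bool), log2fc_column]
    targets = targets[targets != 0]
    n = int(targets.size)
    if n == 0:
        raise InvalidParameterError("no (nonzero) flagged targets in table")
    n_down = int((targets < 0).sum())
    p = float(sps.binomtest(n_down, n, 0.5, alternative="two-sided").pvalue)
    return SuppressionResult(n_targets=n, n_down=n_down, p_value=p)


# ---------------------------------------------------------------------------
# Reporting


def comparison_to_dict(comp: GroupComparison) -> dict:
    return {
        "test_name": comp.test_name,
        "global_p": comp.global_p,
        "pairwise": [list(p) for p in comp.pairwise],
        "descriptives": comp.descriptives,
        "normality_p": comp.normality_p,
    }


def comparison_from_dict(d: dict) -> GroupComparison:
    return GroupComparison(
        test_name=d["test_name"],
        global_p=d["global_p"],
        pairwise=[tuple(p) for p in d["pairwise"]],
        descriptives=d["descriptives"],
        normality_p=d["normality_p"],
    )


def build_report(
    cell_summaries: pd.DataFrame,
    comparisons: Mapping[str, GroupComparison],
    out_dir: str | Path,
    endpoints: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Emit descriptives CSV, a JSON of all tests, and scatter-dot plots.

    ``cell_summaries`` needs a ``group`` column (or ``group_label``) plus
    one numeric column per endpoint; ``comparisons`` maps endpoint name to
    its :class:`GroupComparison`.  Plots show each cell as a dot with the
    group mean, median, and +/- SD marked.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cell_summaries.empty:
        raise InvalidParameterError("cell_summaries is empty")
    df = cell_summaries.rename(columns={"group_label": "group"})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    desc_rows = []
    for endpoint, comp in comparisons.items():
        for group, d in comp.descriptives.items():
            desc_rows.append({"endpoint": endpoint, "group": group, **d})
    desc_path = out / "descriptives.csv"
    pd.DataFrame(desc_rows).to_csv(desc_path, index=False)
    written["descriptives"] = desc_path

    json_path = out / "tests.json"
    json_path.write_text(
        json.dumps(
            {name: comparison_to_dict(c) for name, c in comparisons.items()},
            indent=2,
        )
    )
    written["tests"] = json_path

    plot_endpoints = list(endpoints) if endpoints is not None else list(comparisons)
    for endpoint in plot_endpoints:
        if endpoint not in df.columns:
            continue
        fig, ax = plt.subplots(figsize=(4, 3.2))
        groups = list(df["group"].unique())
        rng = np.random.default_rng(0)
        for i, g in enumerate(groups):
            vals = df.loc[df["group"] == g, endpoint].to_numpy(dtype=float)
            x = i + 0.08 * rng.standard_normal(vals.size)
            ax.plot(x, vals, "o", ms=3, alpha=0.6)
            ax.errorbar(
                [i], [vals.mean()], yerr=[vals.std(ddof=1) if vals.size > 1 else 0],
                fmt="_", color="k", capsize=4, ms=16, zorder=3,
            )
            ax.plot([i - 0.18, i + 0.18], [np.median(vals)] * 2, "-", color="r", lw=1)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups, rotation=30, ha="right")
        ax.set_ylabel(endpoint)
        fig.tight_layout()
        p = out / f"{endpoint}_dotplot.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written[f"plot_{endpoint}"] = p
    return written
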