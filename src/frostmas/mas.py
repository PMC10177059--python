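"""Multi-marker genotype strings, combination classes, and the MAS rule.

Each progeny's validated-marker codes are concatenated, in a fixed marker
order, into a 0/1 genotype string (e.g. "111111" over chr05V42, chr05V92,
chr05V158, chr09V26, chr09V212, chr09V222).  Individuals are classified by
chromosome-group combination -- chr05(i)+chr09(j) where an indicator is 1
when any marker of that chromosome codes 1 -- and the classes are compared on
injury score with a Tukey(-Kramer) HSD test plus a compact letter display.
The final selection rule keeps an individual when every required marker
(default chr05V158, chr09V26, chr09V212) codes 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GenotypeString",
    "SelectionRule",
    "DEFAULT_MARKER_ORDER",
    "DEFAULT_RULE",
    "build_genotype_strings",
    "combination_class",
    "classify_population",
    "class_phenotype_comparison",
    "apply_selection_rule",
    "select_individuals",
    "allele_effect_report",
]

DEFAULT_MARKER_ORDER: tuple[str, ...] = (
    "chr05V42", "chr05V92", "chr05V158", "chr09V26", "chr09V212", "chr09V222",
)


@dataclass(frozen=True)
class GenotypeString:
    individual_id: str
    marker_order: tuple[str, ...]
    code_string: str

    def __post_init__(self) -> None:
        if len(self.code_string) != len(self.marker_order):
            raise ValueError("code string length must match marker order")
        if set(self.code_string) - {"0", "1"}:
            raise ValueError("code string may contain only 0/1")

    def code_of(self, marker: str) -> int:
        return int(self.code_string[self.marker_order.index(marker)])


@dataclass(frozen=True)
class SelectionRule:
    """Markers that must all code 1 for an individual to be selected."""

    required_markers: frozenset[str]


DEFAULT_RULE = SelectionRule(frozenset({"chr05V158", "chr09V26", "chr09V212"}))


def build_genotype_strings(
    codes: pd.DataFrame, marker_order: Sequence[str] = DEFAULT_MARKER_ORDER
) -> tuple[list[GenotypeString], list[str]]:
    """Concatenate per-marker codes into one string per individual.

    ``codes`` is tidy (marker, individual_id, code).  Individuals with any
    missing code over ``marker_order`` are excluded and returned separately.
    """
    order = tuple(marker_order)
    if not order:
        raise ValueError("marker_order must be non-empty")
    known = set(codes["marker"])
    unknown = [m for m in order if m not in known]
    if unknown:
        raise ValueError(f"markers absent from code table: {unknown}")
    wide = codes.pivot_table(
        index="individual_id", columns="marker", values="code", aggfunc="first"
    ).reindex(columns=list(order))
    complete = wide.dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    strings = [
        GenotypeString(ind, order, "".join(str(int(v)) for v in row))
        for ind, row in complete.iterrows()
    ]
    return strings, excluded


def combination_class(
    gs: GenotypeString, chrom_of_marker: Mapping[str, str]
) -> str:
    """Label like "chr05(1)+chr09(0)": 1 when any group marker codes 1."""
    groups: dict[str, int] = {}
    for marker in gs.marker_order:
        group = chrom_of_marker.get(marker)
        if group is None:
            raise ValueError(f"marker {marker!r} has no chromosome group")
        groups.setdefault(group, 0)
        if gs.code_of(marker) == 1:
            groups[group] = 1
    if not groups:
        raise ValueError("empty chromosome grouping")
    return "+".join(f"{g}({groups[g]})" for g in sorted(groups))


def classify_population(
    strings: Sequence[GenotypeString], chrom_of_marker: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Genotype string and combination class per individual."""
    if chrom_of_marker is None:
        chrom_of_marker = {
            m: m.split("V")[0] for gs in strings[:1] for m in gs.marker_order
        }
    return pd.DataFrame(
        {
            "individual_id": [g.individual_id for g in strings],
            "code_string": [g.code_string for g in strings],
            "combination_class": [
                combination_class(g, chrom_of_marker) for g in strings
            ],
        }
    )


def _compact_letter_display(
    groups: Sequence[str], means: Mapping[str, float], not_different: set[frozenset]
) -> dict[str, str]:
    """Letters such that two groups share a letter iff one maximal clique of
    the not-significantly-different graph contains both."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(
        (a, b) for pair in not_different for a, b in [tuple(pair)]
    )
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: min(means[m] for m in c))
    letters: dict[str, str] = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for member in clique:
            letters[member] += letter
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def class_phenotype_comparison(
    class_of: Mapping[str, str],
    as_by_environment: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-class AS summary with Tukey HSD compact letters per environment.

    Classes with fewer than ``min_n`` members are summarised but excluded
    from the test and flagged with an empty letter.  Unequal class sizes are
    handled by the Tukey-Kramer adjustment of the studentized-range test.
    """
    assign = pd.Series(dict(class_of))
    common = assign.index.intersection(as_by_environment.index)
    assign = assign.loc[common]
    rows = []
    for env in as_by_environment.columns:
        vals = as_by_environment.loc[common, env].astype(float)
        counts = assign.value_counts()
        tested = counts[counts >= max(min_n, 2)].index
        letters: dict[str, str] = {}
        if len(tested) >= 2:
            mask = assign.isin(tested)
            tk = pairwise_tukeyhsd(vals[mask].to_numpy(), assign[mask].to_numpy(),
                                   alpha=alpha)
            pairs = list(combinations(sorted(tested), 2))
            nd = {frozenset(p) for p, rej in zip(pairs, tk.reject) if not rej}
            group_means = {
                g: float(vals[assign == g].mean()) for g in tested
            }
            letters = _compact_letter_display(list(tested), group_means, nd)
        for cls in counts.index:
            sub = vals[assign == cls]
            rows.append(
                {
                    "environment": env,
                    "combination_class": cls,
                    "n": int(counts[cls]),
                    "mean": float(sub.mean()),
                    "sd": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
                    "letters": letters.get(cls, ""),
                }
            )
    return pd.DataFrame(rows)


def apply_selection_rule(gs: GenotypeString, rule: SelectionRule = DEFAULT_RULE) -> bool:
    """True when every required marker of the rule codes 1."""
    missing = rule.required_markers - set(gs.marker_order)
    if missing:
        raise ValueError(f"rule markers absent from marker order: {sorted(missing)}")
    return all(gs.code_of(m) == 1 for m in rule.required_markers)


def select_individuals(
    strings: Sequence[GenotypeString], rule: SelectionRule = DEFAULT_RULE
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [g.individual_id for g in strings],
            "code_string": [g.code_string for g in strings],
            "selected": [apply_selection_rule(g, rule) for g in strings],
        }
    )


def allele_effect_report(
    codes: pd.DataFrame, as_by_environment: pd.DataFrame
) -> pd.DataFrame:
    """Per-marker comparison of AS between code-1 and code-0 carriers.

    Two-sample Student's t per marker and environment; markers with an empty
    code group are skipped with a reason column instead of a test.
    """
    rows = []
    for marker, grp in codes.groupby("marker", sort=True):
        g = grp.dropna(subset=["code"]).set_index("individual_id")["code"]
        common = g.index.intersection(as_by_environment.index)
        g = g.loc[common]
        ones = g[g == 1].index
        zeros = g[g == 0].index
        for env in as_by_environment.columns:
            if len(ones) == 0 or len(zeros) == 0:
                rows.append(
                    {"marker": marker, "environment": env, "n1": len(ones),
                     "n0": len(zeros), "mean1": np.nan, "mean0": np.nan,
                     "mean_diff": np.nan, "t": np.nan, "p_value": np.nan,
                     "note": "one-sided group empty"}
                )
                continue
            a = as_by_environment.loc[ones, env].to_numpy(dtype=float)
            b = as_by_environment.loc[zeros, env].to_numpy(dtype=float)
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {"marker": marker, "environment": env, "n1": len(ones),
                 "n0": len(zeros), "mean1": float(a.mean()),
                 "mean0": float(b.mean()), "mean_diff": float(a.mean() - b.mean()),
                 "t": float(t), "p_value": float(p), "note": ""}
            )
    return pd.DataFrame(rows)
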