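"""One-command reproduction of the fixture-based headline analysis.

Runs, for each STR category (mono, di, tri): column totals checked against
the published Sum rows, the k=3 cut of the default clustering compared
with the phylogenetic reference partition, the two-way ANOVA and Friedman
confirmation for the species-cluster effect, per-species boxplot
summaries, and the descriptive great-ape outlier distances.  Fixed inputs,
no randomness: running twice yields identical reports.
"""

from __future__ import annotations

from typing import Any

from . import __version__
from .abundance import column_totals, load_fixture
from .cluster_stats import (
    abundance_summaries,
    cluster_species,
    cut,
    great_ape_outlier,
    partitions_equal,
    reference_partition,
    species_effect_anova,
    species_effect_nonparametric,
)

#: Published genome-wide Sum-row totals per category and species.
PUBLISHED_TOTALS = {
    "mono": {
        "rat": 549_053, "mouse": 650_864, "gelada": 1_084_599,
        "baboon": 1_036_675, "macaque": 1_004_054, "gorilla": 925_406,
        "chimpanzee": 946_356, "bonobo": 946_792, "human": 990_970,
    },
    "di": {
        "rat": 845_568, "mouse": 775_351, "gelada": 311_972,
        "baboon": 300_994, "macaque": 312_946, "gorilla": 304_120,
        "chimpanzee": 309_042, "bonobo": 304_215, "human": 321_054,
    },
    "tri": {
        "rat": 258_478, "mouse": 258_360, "gelada": 198_875,
        "baboon": 189_725, "macaque": 186_787, "gorilla": 176_152,
        "chimpanzee": 183_317, "bonobo": 179_714, "human": 202_461,
    },
}


def reproduce_paper() -> dict[str, Any]:
    """Recompute the headline fixture analysis; see module docstring.

    The returned report carries ``all_totals_match``; the CLI exits
    nonzero when any exact-total check fails.
    """
    ref = reference_partition()
    report: dict[str, Any] = {"version": __version__, "categories": {}}
    all_match = True
    for category in ("mono", "di", "tri"):
        m = load_fixture(category)
        totals = column_totals(m)
        matches = {
            sp: totals[sp] == PUBLISHED_TOTALS[category][sp] for sp in totals
        }
        all_match = all_match and all(matches.values())
        tree = cluster_species(m)
        part = cut(tree, 3)
        anova = species_effect_anova(m, design="two_way", factor="cluster")
        friedman = species_effect_nonparametric(m, factor="cluster")
        entry: dict[str, Any] = {
            "column_totals": totals,
            "published_totals": PUBLISHED_TOTALS[category],
            "totals_match": matches,
            "k3_partition": dict(part.assignments),
            "matches_reference_partition": partitions_equal(part, ref),
            "anova": {
                "design": anova.design,
                "factor": anova.factor,
                "F": anova.statistic,
                "df_effect": anova.df_effect,
                "df_resid": anova.df_resid,
                "p_value": anova.p_value,
            },
            "friedman": {
                "statistic": friedman.statistic,
                "df": friedman.df_effect,
                "p_value": friedman.p_value,
            },
            "boxplot_summaries": {
                sp: row.to_dict()
                for sp, row in abundance_summaries(m).iterrows()
            },
            "newick": tree.to_newick(),
        }
        if category == "tri":
            entry["great_ape_outlier"] = great_ape_outlier(m)[
                "mean_distance_to_other_great_apes"
            ].to_dict()
        report["categories"][category] = entry
    report["all_totals_match"] = all_match
    return report


def format_report(report: dict[str, Any]) -> str:
    """Human-readable rendering of :func:`reproduce_paper` output."""
    lines = [f"strscape {report['version']} — fixture reproduction", ""]
    for category, entry in report["categories"].items():
        lines.append(f"[{category}]")
        n_ok = sum(entry["totals_match"].values())
        lines.append(f"  column totals matching published sums: {n_ok}/9")
        lines.append(
            "  k=3 cut matches rodents|Old World monkeys|great apes: "
            f"{entry['matches_reference_partition']}"
        )
        a, f = entry["anova"], entry["friedman"]
        lines.append(
            f"  two-way ANOVA cluster effect: F={a['F']:.1f} "
            f"(df {a['df_effect']:.0f}, {a['df_resid']:.0f}), p={a['p_value']:.3g}"
        )
        lines.append(
            f"  Friedman confirmation: chi2={f['statistic']:.1f} "
            f"(df {f['df']:.0f}), p={f['p_value']:.3g}"
        )
        if "great_ape_outlier" in entry:
            dists = ", ".join(
                f"{sp}={d:,.0f}" for sp, d in entry["great_ape_outlier"].items()
            )
            lines.append(f"  great-ape mean profile distances: {dists}")
        lines.append("")
    lines.append(f"all exact-total checks passed: {report['all_totals_match']}")
    return "\n".join(lines)
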