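"""Canonical variate analysis of the Ward-MLM groups.

Uses the assignment written by 03_divergence_grouping.py (or recomputes
it) and writes coefficients, scores, group means and variance
proportions under results/canonical/. Reports which traits drive the
first axis — the axis-1 contribution of a trait is 100 x its absolute
standardized coefficient.
"""

import pandas as pd

from common import RESULTS, load_or_simulate
from seedpheno.canonical import canonical_analysis
from seedpheno.divergence import cluster_criteria, gower_matrix, select_group_count, ward_linkage


def main() -> None:
    out = RESULTS / "canonical"
    out.mkdir(parents=True, exist_ok=True)
    table, _ = load_or_simulate()
    profiles = table.genotype_means()

    assignments_path = RESULTS / "divergence" / "assignments.csv"
    if assignments_path.exists():
        groups = pd.read_csv(assignments_path).set_index("genotype")["group"]
        groups.index = groups.index.astype(str)
    else:
        criteria = cluster_criteria(profiles, ward_linkage(gower_matrix(profiles)))
        groups = criteria.solutions[select_group_count(criteria)].assignments

    result = canonical_analysis(profiles, groups)
    result.coefficients.rename_axis("trait").to_csv(out / "coefficients.csv")
    result.scores.rename_axis("genotype").to_csv(out / "scores.csv")
    result.group_means.to_csv(out / "group_means.csv")
    pd.DataFrame(
        {
            "axis": result.coefficients.columns,
            "eigenvalue": result.eigenvalues,
            "proportion": result.proportions,
            "cumulative": result.cumulative,
        }
    ).to_csv(out / "proportions.csv", index=False)

    first_two = 100.0 * result.cumulative[min(1, result.n_axes - 1)]
    print(f"{result.n_axes} canonical axes; first two carry {first_two:.2f}% "
          "of the between-group variance")
    top = result.contributions.sort_values(ascending=False).head(3)
    tops = ", ".join(f"{t} ({v:.0f}%)" for t, v in top.items())
    print(f"largest axis-1 contributions: {tops}")


if __name__ == "__main__":
    main()
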