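"""Pearson correlations among the ten selected geometric traits.

Computes the genotype-mean correlation matrix over the conventional
five-bean + five-cherry trait subset, flags significance at the 1%
level, classifies magnitudes, and writes matrices plus a per-pair
table under results/correlation/.
"""

import json

from common import RESULTS, load_or_simulate
from seedpheno.correlation import correlation_matrix
from seedpheno.traits import DEFAULT_CORRELATION_TRAITS


def main() -> None:
    out = RESULTS / "correlation"
    out.mkdir(parents=True, exist_ok=True)
    table, _ = load_or_simulate()
    profiles = table.genotype_means()[DEFAULT_CORRELATION_TRAITS]

    result = correlation_matrix(profiles, alpha=0.01)
    result.r.to_csv(out / "r_matrix.csv")
    result.p.to_csv(out / "p_matrix.csv")
    result.classes.to_csv(out / "class_matrix.csv")
    pairs = result.pair_table()
    pairs.to_csv(out / "pairs.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "n_pairs": result.n_pairs,
                "alpha": result.alpha,
                "class_counts": result.counts,
                "class_percentages": result.percentages,
            },
            indent=2,
        )
    )

    n_sig = int(pairs["significant"].sum())
    n_pos = int((pairs["significant"] & (pairs["r"] > 0)).sum())
    print(f"{result.n_pairs} trait pairs; {n_sig} significant at 1% ({n_pos} positive)")
    print(f"magnitude classes: { {c: n for c, n in result.counts.items() if n} }")
    strongest = pairs.loc[pairs["r"].abs().idxmax()]
    print(f"strongest pair: {strongest.trait_a} x {strongest.trait_b} "
          f"(r = {strongest.r:.2f}, {strongest.magnitude})")


if __name__ == "__main__":
    main()
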