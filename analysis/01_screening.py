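"""Screening stage: which carbon and nitrogen sources matter.

Rebuilds replicate sets from the published group means and error sums of
squares, runs the one-way ANOVA and Duncan's multiple range test for both
selection steps, and writes the tables under results/.  Expected outcome:
cellulose and fructose form the top carbon group, urea and L-glutamic acid
the top nitrogen group — the basis for carrying cellulose and urea into the
designed experiment.
"""

from pathlib import Path

from medopt import duncan_mrt, make_screening_groups, one_way_anova
from medopt import reference as ref

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for step, summary in (("carbon", ref.CARBON_SCREEN), ("nitrogen", ref.NITROGEN_SCREEN)):
        groups = make_screening_groups(
            summary["means"], summary["within_ss"], summary["n_per_group"]
        )
        aov = one_way_anova(groups)
        duncan = duncan_mrt(
            summary["means"],
            summary["n_per_group"],
            summary["ms_error"],
            summary["df_error"],
            alpha=0.05,
        )
        aov.frame.to_csv(RESULTS / f"screening_{step}_anova.csv", index=False)
        duncan.to_frame().to_csv(RESULTS / f"screening_{step}_duncan.csv", index=False)
        between = aov.row("between")
        print(f"{step}: between-group SS={between['SS']:.2f}, F={between['F']:.2f}")
        print(duncan.to_frame().to_string(index=False))
        print()


if __name__ == "__main__":
    main()
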