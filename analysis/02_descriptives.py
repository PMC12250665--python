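"""Population characteristics of the full synthetic corpus.

Per-drug stratified counts (year, age group, role code, indication,
country, sex, outcome) with the cross-drug comparison p-values, written to
results/descriptives/.
"""

from pathlib import Path

import pandas as pd

from gnrha_pv import descriptives as desc
from gnrha_pv import io as gio
from gnrha_pv.dedup import deduplicate

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixtures" / "full"
OUT = ROOT / "results" / "descriptives"


def main() -> None:
    corpus = gio.read_reports(FIXTURE / "reports.csv", "simple_table")
    kept, removed = deduplicate(corpus)
    print(f"corpus: {len(corpus)} cases, {removed} duplicates removed")
    OUT.mkdir(parents=True, exist_ok=True)
    pvals = []
    for strat in desc.STRATIFIERS:
        counts = desc.summarize(kept, strat)
        counts.to_frame().to_csv(OUT / f"{strat}.csv", index=False)
        if strat == "age_group":
            method, p = "anova", desc.compare_strata(counts, "anova", reports=kept)
        elif strat in ("role_code", "outcome"):
            method, p = "fisher_mc", desc.compare_strata(counts, "fisher_mc", n_permutations=2_000)
        else:
            method, p = "chi_square", desc.compare_strata(counts, "chi_square")
        pvals.append({"stratifier": strat, "method": method, "p": p})
        print(f"  {strat:>10}: p = {p:.3g} ({method})")
    pd.DataFrame(pvals).to_csv(OUT / "p_values.csv", index=False)
    print(f"wrote {len(desc.STRATIFIERS)} tables -> {OUT}")


if __name__ == "__main__":
    main()
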