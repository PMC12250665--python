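"""SOC-level profile of the passed signals per drug.

Aggregates the screened signal table to system-organ-class level, writes
the long-format profile to results/soc_profile.csv, and compares each SOC's
share of signals across drugs with the r x 2 chi-square (Monte-Carlo
fallback at small cells).
"""

from pathlib import Path

import pandas as pd

from gnrha_pv import io as gio
from gnrha_pv.dedup import deduplicate
from gnrha_pv.signal_pipeline import detect_signals
from gnrha_pv.soc_profile import compare_soc_proportions, profiles_to_frame, soc_summary
from gnrha_pv.types import STUDY_DRUGS

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixtures" / "full"
OUT = ROOT / "results"


def main() -> None:
    corpus = gio.read_reports(FIXTURE / "reports.csv", "simple_table")
    kept, _ = deduplicate(corpus)
    pt_map = gio.load_pt_soc_map(FIXTURE / "pt_soc_map.csv")
    roles = {"primary_suspect", "secondary_suspect"}
    drugs = [d for d in STUDY_DRUGS if any(r.has_drug(d, roles) for r in kept)]
    records = detect_signals(kept, drugs, pt_map)
    profiles = soc_summary(records)

    OUT.mkdir(parents=True, exist_ok=True)
    long = profiles_to_frame(profiles)
    long.to_csv(OUT / "soc_profile.csv", index=False)
    for p in profiles:
        head = ", ".join(f"{soc} ({k})" for soc, k, _ in p.rows[:3])
        print(f"  {p.drug:>12}: {p.total_signals} signals; top SOCs: {head}")

    rows = []
    for soc in sorted(long["soc"].unique()):
        try:
            chi2, df, p = compare_soc_proportions(profiles, soc, seed=0)
        except ValueError:
            continue
        rows.append({"soc": soc, "chi2": chi2, "df": df, "p": p})
        print(f"  {soc}: chi2={chi2:.2f} (df={df}), p={p:.3g}")
    pd.DataFrame(rows).to_csv(OUT / "soc_comparisons.csv", index=False)


if __name__ == "__main__":
    main()
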