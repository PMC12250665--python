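"""Generate the synthetic study corpora.

Writes every named corpus profile (tiny / null / signals / ime / full) under
scratch/fixtures/, each with the corpus in both dialects, the PT->SOC map,
the IME list, the generative config and the planted ground truth. The
downstream analysis scripts (02-05) read the `full` corpus.
"""

from pathlib import Path

from gnrha_pv import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "fixtures"
SEED = 20240901


def main() -> None:
    for profile in syn.PROFILES:
        path = syn.make_fixture(profile, OUT / profile, seed=SEED)
        cfg = syn.profile_config(profile, seed=SEED)
        print(f"[{profile}] {cfg.n_reports} reports -> {path}")
        if profile == "full":
            _, truth = syn.generate(cfg)
            print(f"  planted duplicates: {truth.n_duplicates}")
            for t in truth.injected:
                print(
                    f"  injected {t.drug} / {t.pt}: true ROR {t.true_ror}, "
                    f"realized cells a={t.realized_cells[0]}"
                )
            print(f"  mean planted IME rate: {truth.mean_ime_rate:.3f}")


if __name__ == "__main__":
    main()
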