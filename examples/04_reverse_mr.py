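"""Reverse MR: does the disease change the abundance of a hit taxon?

Simulates the mirrored design — the binary trait has genome-wide instruments
and truly raises one taxon's abundance (+0.3 SD per log-odds) — then runs
the reverse screen, which forces the genome-wide threshold (p < 5e-8) for
the disease instruments.  A Steiger check on the naive forward analysis of
the same data shows why directionality testing matters.
"""

from pathlib import Path

from mrlink import AnalysisConfig, TruthConfig, run_forward, run_reverse, simulate_pair, write_summary_table

truth = TruthConfig(
    seed=92, n_taxa=1, n_snps_per_taxon=12, n_null_snps_per_taxon=0,
    causal_taxa={"genus.Taxon001": 0.3}, gamma_range=(0.15, 0.40),
)
disease, taxon, _, _ = simulate_pair(truth, "genus.Taxon001")
taxon.trait_id = "genus.Taxon001"

d = Path("scratch/example_reverse")
d.mkdir(parents=True, exist_ok=True)
write_summary_table(disease, d / "disease.tsv")
write_summary_table(taxon, d / "genus.Taxon001.tsv")

config = AnalysisConfig(
    exposure_paths=[str(d / "genus.Taxon001.tsv")],
    outcome_path=str(d / "disease.tsv"),
    seed=4,
)
rev = run_reverse(config, hits=["genus.Taxon001"])[0]
e = rev.primary
print(f"reverse MR (disease -> {rev.exposure_id}): {e.method}, "
      f"n_snp={rev.n_snp}, beta={e.beta:+.3f}, "
      f"OR={e.or_:.3f} [{e.ci_low:.3f}, {e.ci_high:.3f}], p={e.pval:.2e}")

fwd = run_forward(config)[0]
if fwd.status == "ok" and fwd.diagnostics is not None:
    print(f"naive forward analysis Steiger direction: "
          f"{fwd.diagnostics.steiger_direction}")

print("\nThe reverse estimate recovers the simulated effect of 0.3 SD per")
print("log-odds. Running the same files forward would look significant too —")
print("but Steiger attributes the signal to the outcome side, exposing the")
print("reverse-causal structure.")
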