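"""Run the complete analysis on a simulated transcriptome-like paranome.

Sequences in, dated WGD out: homology search, family construction, per-pair
ML Ks, node-weighted age distribution, mixture fit, clock dating.  Takes a
minute or two for 150 families.
"""

from paleoks import PipelineConfig, SimulationConfig, run_pipeline, simulate_population

seqs, truth = simulate_population(SimulationConfig(n_families=150, seed=5))
config = PipelineConfig(out_dir="pipeline_demo", seed=5, k_range=(1, 6), bootstrap=50)
report = run_pipeline(config, seqs=seqs)

a = report["a"]
print(f"\nsequences {a['n_sequences']}  families {a['n_families']}  "
      f"retained pairs {a['n_pairs_retained']}")
for d in a["dating"]:
    lo, hi = d["age_mya_ci95"]
    print(
        f"candidate WGD: Ks peak {d['ks_peak']:.3f} "
        f"(proportion {d['proportion']:.2f}) -> {d['age_mya']} mya "
        f"(CI {min(lo, hi)}-{max(lo, hi)}) under the plant rate"
    )
print(
    "\nThe generating WGD burst sits at Ks 1.2, i.e. ~98 mya under the "
    "plant average rate; intermediate tables and the distribution plot are "
    "in pipeline_demo/."
)
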