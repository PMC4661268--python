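"""Run the end-to-end pipeline from a config and compare two variants.

Executes plan -> sample -> WHAM -> project -> states for two constructed
opening surfaces (5.3 and 4.1 kcal/mol) and prints the aligned comparison —
the way one would compare a native channel against a destabilized mutant.
"""
from porepmf import RunConfig, compare_runs, run_pipeline

manifests = []
for tag, dg in (("native", 5.3), ("mutant", 4.1)):
    config = RunConfig.from_dict(
        {
            "surface": {"kind": "opening_profile", "delta_g_open": dg},
            "plan": {"mode": "diagonal", "spacing": 0.5, "k": 3.0},
            "sampler": {"n_steps": 20_000, "seed": 2, "step_size": 0.5},
            "states": {"open_zeta": 11.5},
            "out_dir": f"pipeline_{tag}",
        }
    )
    manifest = run_pipeline(config)
    print(f"{tag:>7s}: stages {list(manifest['stages'].values())}, "
          f"WHAM iterations {manifest['wham_iterations']}")
    manifests.append(manifest)

table = compare_runs(*manifests)
print("\naligned state analysis (a = native, b = mutant):")
for key, row in table.items():
    print(f"  {key:28s} a={row['a']:.3f}  b={row['b']:.3f}  diff={row['difference']:+.3f}")
print("\nThe delta-G difference recovers the constructed 1.2 kcal/mol gap between")
print("the two surfaces; every artifact of each run sits under its out_dir.")
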