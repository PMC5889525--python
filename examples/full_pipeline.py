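"""End-to-end run: simulate -> cost estimator -> survival -> ledger -> policy.

Writes curves.csv, ledger.json, policy.json, a cumulative-effect figure and
a reproducibility log (config hash, stage timings) under scratch/run/.
"""

from pathlib import Path

from reroutecost import RunConfig, run_pipeline, site_preset

out = Path(__file__).resolve().parent.parent / "scratch" / "run"
cfg = RunConfig(out_dir=str(out), site="colorectal",
                sim=site_preset("colorectal", n_patients=2000, seed=3),
                seed=3)
bundle = run_pipeline(cfg)

print("artifacts in", out)
print("stage timings:", bundle["log"]["stages"])
print("ledger:", {k: v for k, v in bundle["ledger"].report().items()
                  if k in ("total_1yr", "total_h", "cost_per_yls")})
print("policy:", {k: v for k, v in bundle["policy"].report().items()
                  if k in ("rerouted", "total_cost_horizon", "yls_total")})
# Rerunning with the same RunConfig reproduces every numeric output
# byte for byte; the config hash stamped into each file proves provenance.
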