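"""Growth response to gas availability.

Sweeps the community H2 and CO2 uptake upper bounds over nine thresholds
from 0 to 160 mmol/gDW/h (medium-constrained community, no fixed reactor
gas bounds) and reports where community growth saturates.

Outputs under results/sweep/: per-threshold growth table and plateau report.
"""

from syntroflux.workflow import RunConfig, run_sweep

config = RunConfig(out_dir="results/sweep")
result = run_sweep(config)

print("threshold  mu_c")
for t, mu in zip(result.thresholds, result.mu_c):
    print(f"  {t:7.1f}  {mu:.4f}")
print(f"\nplateau mu_c = {result.plateau_value:.4f} 1/h "
      f"(onset at grid index {result.plateau_onset_index})")
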