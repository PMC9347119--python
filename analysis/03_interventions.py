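"""Elasticity of exports to feedstock and abundance interventions.

Doubles, one at a time, each medium component's availability and each
species' abundance (renormalized), re-solves the cooperative tradeoff, and
reports the log-log elasticity of the gas and amino-acid export fluxes.

Output under results/interventions/: effectors x responses elasticity TSV.
"""

from syntroflux.workflow import RunConfig, run_interventions

config = RunConfig(out_dir="results/interventions")
matrix = run_interventions(config)

nonzero = matrix.loc[(matrix.abs() > 1e-4).any(axis=1)]
print("interventions with a nonzero effect on at least one export:")
print(nonzero.round(3).to_string())
print(f"\n({len(matrix) - len(nonzero)} further interventions had no "
      "effect on any tracked export)")
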