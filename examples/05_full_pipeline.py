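"""One-call pipeline run: simulate -> fit -> validate -> optimize.

Writes the full report bundle (CSV tables, markdown dose table, JSON
report) into ./pipeline_demo; rerunning with the same seed reproduces
every file byte for byte.
"""

import json

from siropk import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir="pipeline_demo", seed=1, n_subjects=40,
                        n_bootstrap=20, n_vpc_sim=300, n_virtual=5000,
                        weight_step=2.5, band_n_virtual=5000)
report = run_pipeline(config)

print(json.dumps({k: report[k] for k in ("config_hash", "cohort", "validation")},
                 indent=2, default=float))
print("\nrecommended initial doses:")
for row in report["recommendations"]:
    print(f"  oxc={row['oxc']} {row['regimen']}: "
          f"{row['weight_lo_kg']:g}-{row['weight_hi_kg']:g} kg -> "
          f"{row['dose_mg_kg_day']:.2f} mg/kg/day")
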