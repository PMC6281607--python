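"""Simulate a small case-control exome cohort and run the burden scan.

Plants one gene with a strong carrier enrichment (odds ratio 8) among
background genes with no effect, runs QC + classification + the per-gene
collapsing Fisher tests, and prints the top of the results table.
"""

import tempfile

import pandas as pd

from rvburden import (
    GeneSpec,
    PipelineConfig,
    SimulationConfig,
    run_all,
    simulate_cohort,
)

config = SimulationConfig(
    seed=11,
    n_case=92,
    n_control=1051,
    genes=[GeneSpec("RISK1", {"Mis3": 3}, carrier_freq=0.005, odds_ratio=8.0)]
    + [
        GeneSpec(f"NULL{i}", {"Mis2": 2, "Mis1": 1}, carrier_freq=0.006, odds_ratio=1.0)
        for i in range(30)
    ],
)

with tempfile.TemporaryDirectory() as tmp:
    paths = simulate_cohort(config, tmp)
    outputs = run_all(
        PipelineConfig(
            vcf=paths["vcf"],
            sample_sheet=paths["sample_sheet"],
            annotation=paths["annotation"],
            masks=[paths["masks"]],
            outdir=f"{tmp}/out",
            log_level="WARNING",
        )
    )
    burden = pd.read_csv(outputs["burden"], sep="\t", comment="#")

top = burden[burden["is_min_p_class"]].head(5)
cols = ["gene", "collapse_class", "case_carriers", "control_carriers", "or_point", "p", "q"]
print(top[cols].to_string(index=False))
print()
print(
    "Each row collapses a gene's rare qualifying variants to carrier counts\n"
    "(92 cases vs 1051 controls) and tests them with a two-sided Fisher exact\n"
    "test; the planted risk gene should head the table with an odds ratio far\n"
    "from 1, while null genes drift around p ~ uniform."
)
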