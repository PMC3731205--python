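"""Call SUMO targets from two label-swap replicate purifications.

A protein is called when both replicates quantify it from >= 3 unique
peptides with a tagged/mock ratio of at least 10.  Contaminants co-purify
equally from both arms and fail the cutoff.
"""

import sumoquant as sq

config = sq.GeneratorConfig(seed=11, n_proteins=300)
params = sq.AnalysisParams()

truth = sq.generate_ground_truth(config)
rep1, rep2 = sq.enrichment_replicates()  # isotope labels swapped between them
tables = []
for design in (rep1, rep2):
    peptides = sq.simulate_silac_experiment(truth, design, config)
    ratios = sq.peptide_ratio_table(peptides, params)
    tables.append(sq.orient_to_reference(sq.protein_table(ratios, params), [design]))

report = sq.replicate_concordance(*tables)
targets = sq.call_targets(*tables, params)
called = targets.loc[targets["called"]]

is_target = {g.protein_id: g.is_sumo_target for g in truth}
true_positive = sum(is_target[p] for p in called["protein_id"])
print(f"replicate 1: {report.n_rep1} proteins, replicate 2: {report.n_rep2}, "
      f"shared: {report.n_both}")
print(f"called at >= {params.fold_cutoff:.0f}-fold in both replicates: {len(called)}")
print(f"of which true synthetic SUMO targets: {true_positive} "
      f"({sum(is_target.values())} in the ground truth)")
# The dual-replicate cutoff recovers nearly every target with >= 3 peptides
# while ratio-1 contaminants and weakly enriched bystanders are excluded.
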