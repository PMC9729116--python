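"""Selecting state-specific transcription factors and per-gene core TFs.

A TF is selected for a cell state when it is expressed (mean TPM > 4), its
binding motif is over-represented in the state's linked CREs, and its
regulon-activity specificity ranks in the state's top 30.  For each gene with
predictive chromatin (GPC), a core TF must both list the gene among its
regulon targets and show motif enrichment in the gene's own linked CREs.
"""

from statescape.analysis import run_tf_analysis, simulate_and_link
from statescape.expression import assign_state, score_signatures
from statescape.simulate import gen_motifs_regulons, tf_config

cfg = tf_config(seed=3)
out = simulate_and_link(cfg, pseudobulk_seed=3)
truth = out["truth"]
regulons, motifs = gen_motifs_regulons(cfg, truth)
labels = assign_state(score_signatures(out["Er"], truth.signatures))

res = run_tf_analysis(out["rna"], out["Er"], labels, regulons, motifs,
                      out["links"], truth.signatures)

print("state-specific TFs (expressed + motif-enriched + top-30 specificity):")
for state, tfs in res["selected"].items():
    planted = truth.state_tfs[state]
    mark = "<- planted TF" if planted in tfs else ""
    print(f"  {state:10s} {tfs} {mark}")

print("\ncore TFs per GPC gene (regulon membership AND motif enrichment):")
for gene, tfs in sorted(res["core"].items()):
    print(f"  {gene}: {tfs}")
print("\nEach planted hub gene should list its own state's TF as core.")
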