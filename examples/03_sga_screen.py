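"""Score a yeast deletion screen and project hits onto human genes.

Generates replicated colony-growth curves for 300 deletion strains under
query-factor-inducing and non-inducing conditions, calls suppressor and
enhancer hits from area-under-curve fitness, augments library-absent
essential genes through the protein-interaction network, and maps the hits
to human orthologs.
"""

import oncohub as oh

cfg = oh.SimConfig(seed=1)
comp, traits, truth = oh.generate_compendium(cfg)
oh.generate_perturbation(truth, cfg)
sga = oh.generate_sga(truth, cfg)
network, orthologs = oh.generate_ppi_and_orthologs(truth, cfg)

hits = oh.call_hits(sga, alpha=0.05)
n_sup = (hits["category"] == "suppressor").sum()
n_enh = (hits["category"] == "enhancer").sum()
print(f"strains screened: {hits.shape[0]}; "
      f"suppressors (red): {n_sup}, enhancers (green): {n_enh} "
      f"(planted interactors: {len(truth.interaction_genes)})")

library = set(sga["strain"].unique())
hits = oh.augment_essential(hits, network, library, min_conf=0.7, min_neighbors=2)
n_ess = (hits["category"] == "essential").sum()
print(f"essential genes added via >=2 high-confidence hit neighbours "
      f"(white): {n_ess} (planted: {len(truth.essential_interactors)})")

humans = oh.map_orthologs(hits, orthologs)
print(f"\nhuman interactome: {len(humans)} genes "
      f"({humans.attrs['n_unmapped']} yeast hits had no ortholog)")
print(humans.groupby("category").size().to_string())
print("\n'mixed' (pink) genes are supported by both an essential and a"
      "\nnon-essential yeast hit identifying the same human protein.")
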