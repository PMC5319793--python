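"""Predict an editing stem and score the ADAR motif around a site.

Folds the window around a planted editing site, applies the published
stem filters (>= 20 paired bases, max bulge 8), extracts the 8
structural features, and scores the site's nucleotide triplet with a
motif matrix built from highly edited sites.
"""

from editevol import motif, simulate, structure

cfg = simulate.SimConfig(n_sites=100, rng_seed=2, structure_effect=1.5,
                         motif_effect=1.0)
_, truth = simulate.simulate_levels(cfg)
seqs, _ = simulate.simulate_sequences(truth, cfg)

site = simulate.SITE_OFFSET
row = truth.sites[truth.sites["stem_np"] > 0].iloc[0]
seq = seqs[truth.anchor][row["site_id"]]

candidates = structure.fold_window(seq, site)
best = structure.find_proximal_ecs(candidates, site, sequence=seq)
features = structure.extract_features(best, site, seq)
print(f"site {row['site_id']}: planted stem of {row['stem_np']} pairs")
print(f"  recovered {features.paired_total} pairs, stem length "
      f"{features.stem_length}, max bulge {features.max_bulge}")
print(f"  free energy {features.free_energy:.1f} kcal/mol "
      f"(more negative = more stable duplex)")
print(f"  site sits {features.dist_to_edge} nt from the nearest stem edge")

# motif: build the weight matrix from triplets of sites edited >= 50%
high = truth.levels[truth.anchor] >= 0.5
triplets = [seqs[truth.anchor][s][site - 1:site + 2]
            for s, h in zip(truth.sites["site_id"], high) if h]
matrix = motif.build_motif_matrix(triplets)
scores = motif.score_triplets(matrix)
table = dict(zip(scores["triplet"], scores["scaled_score"]))
trip = seq[site - 1:site + 2]
print(f"\nmotif triplet at the site: {trip}, scaled score "
      f"{table[trip]:.1f} / 10")
print("top triplets:",
      scores.nlargest(3, "scaled_score")["triplet"].tolist())
# A U at -1 and G at +1 are ADAR's preferred context, so UAG scores highest.
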