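"""Screens: rarefaction, core genera, candidate comammox taxa, dominance, MCN.

Rarefies the count table, screens genus-level core taxa (ubiquitous +
abundant + frequently top-ranked), identifies candidate comammox taxa by
correlation with the guild qPCR marker, classifies the dominant ammonia
oxidizer per sample, and computes the community mean rrn copy number (MCN,
low = slow-growing K-strategists).
"""

import pandas as pd

import acidonet as an

spec = an.CommunitySpec(seed=42)
bundle = an.generate_all(spec)
table, truth, meta = bundle["table"], bundle["truth"], bundle["metadata"]

rar = an.rarefy(table, depth=14_527, seed=0)
print(f"rarefied to {int(rar.counts.sum(axis=0).iloc[0])} reads/sample")

core, flags = an.screen_core_genera(rar.aggregate_by("genus"))
print(f"core genera ({len(core)}): {sorted(core)[:6]} ...")
print("  Nitrospira is core:", "Nitrospira" in core)

marker = bundle["guild_amoa_log10"]["comammox"]
lineage = [truth.keystone_id] + list(truth.coop_block_ids)[:3]
sel, stats_frame, group_ab = an.screen_pc_taxa(rar, lineage, marker.to_numpy())
print(f"marker-correlated candidate taxa: {sel}")
r_ph = an.correlate(group_ab.to_numpy(), meta["pH"].to_numpy())
print(f"their summed abundance vs pH: r={r_ph['r']:.2f} (p={r_ph['p']:.1e})")

dom = an.classify_dominant_oxidizer(an.linear_copies(bundle["guild_amoa_log10"]))
print("dominant oxidizer counts:", dom["label"].value_counts().to_dict())

rrn = an.assign_rrn(rar, bundle["rrn_lookup"])
mcn = an.compute_mcn(rar, rrn["copies"])
r_mcn = an.correlate(mcn.to_numpy(), meta["pH"].to_numpy())
print(f"MCN range {mcn.min():.2f}-{mcn.max():.2f}; MCN vs pH r={r_mcn['r']:.2f}"
      " -> acid soils favour slow growers")
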