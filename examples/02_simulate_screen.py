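"""Simulate a small multi-clone screen with two spiked resistance genes.

One sensitive and one resistant clone share a pool under escalating doses
(days 0/1/4); samples are drawn at days 0/4/9/14 in both arms.
"""

from clonepool import ScreenDesign, demo_clones, demo_manifest, run_screen, spike_effects

manifest = demo_manifest(n_genes=50, sgrnas_per_gene=4, bcs_per_sgrna=8,
                         ntc_sgrnas=40, systems=("crisprwt",), seed=1)
clones = demo_clones(("crisprwt",))
effects = spike_effects(["G00001", "G00002"], resistance=0.9)
design = ScreenDesign(read_depth=300_000)

result = run_screen(manifest, clones, effects, design, seed=2)
print("samples:", result.counts.samples)
print(f"lineages seeded: {len(result.lineages)} "
      f"({design.coverage} cells per sgRNA at seeding)")
print(result.counts.df.head(4).to_string(index=False))

truth14 = result.truth[(result.truth.day == 14)]
by = truth14.groupby(["arm", "clone_id"])["cells"].sum().unstack()
print("\nground-truth cells at day 14 (rows = arm):")
print(by.to_string())
# Under treatment the sensitive clone collapses while spiked-gene lineages
# and the resistant clone take over the read pool.
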