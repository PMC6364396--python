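"""Select sgRNAs with the seed off-target rule and barcode them.

Builds a toy promoter background, filters candidate sites of the (N)20-NGG
form by the 11-nt seed / >=7-mismatch rule, caps selections per transcript,
and attaches random 20-nt barcodes under a library ID.
"""

import numpy as np

from clonepool import (
    CandidateSite, SeedIndex, assign_barcodes, check_pam, design_library,
    passes_offtarget,
)

rng = np.random.default_rng(0)
bases = list("ACGT")

# toy background: 5 promoter sequences of 300 nt
background = {f"prom{i}": "".join(rng.choice(bases, 300)) for i in range(5)}

# candidate sites for two transcripts; one site is planted into a promoter so
# its seed has an exact off-target match
sites = {
    "TX1": [CandidateSite("".join(rng.choice(bases, 20)), "AGG", "TX1", p)
            for p in range(60, 360, 20)],
    "TX2": [CandidateSite("".join(rng.choice(bases, 20)), "TGG", "TX2", p)
            for p in range(60, 360, 20)],
}
planted = sites["TX1"][0]
background["prom0"] = background["prom0"][:100] + planted.protospacer[-11:] + background["prom0"][111:]

index = SeedIndex.build(background)
print(f"indexed {len(index)} distinct 11-nt seeds from {len(background)} promoters")
print(f"planted site passes off-target rule: {passes_offtarget(planted, index)}")
print(f"planted site has NGG PAM: {check_pam(planted)}")

manifest = design_library(
    sites, {"TX1": "GENE1", "TX2": "GENE2"}, background,
    library_id="GCCTAA", mode="crispri", cap=12,
    ntc_sequences=["".join(rng.choice(bases, 20)) for _ in range(3)],
)
manifest = assign_barcodes(manifest, bcs_per_sgrna=5, seed=1)
print(manifest.entries.groupby(["gene", "is_ntc"]).size())
some_entry = next(iter(manifest.bc_pools))
print(f"barcode pool of {some_entry}: {manifest.bc_pools[some_entry]}")
# Selected guides sit in the CRISPRi TSS window [50, 500) and each carries a
# pool of distinct random barcodes marking future integration events.
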