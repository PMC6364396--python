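"""sgRNA library design rules and the multi-level barcode manifest.

Candidate target sites of the form (N)20-NGG are filtered by a seed-based
off-target rule: the 11-nt PAM-proximal seed of a guide must not match any
background (promoter) sequence exactly, unless the remaining 9 PAM-distal
nucleotides carry at least 7 mismatches against the aligned background bases
at every such seed hit. Accepted guides are capped per transcript and then
tagged with a 6-nt library identifier (ID, one per clonal line) and a pool
of random 20-nt barcodes (BC, one per lentiviral integration event).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The four library identifiers used in the screens: two CRISPRwt lines and
#: two CRISPRi lines. Minimum pairwise Hamming distance is 4, so single
#: sequencing errors cannot flip one ID into another.
DEFAULT_ID_WHITELIST = ("GCCTAA", "TGGTCA", "CGTGAT", "ACATCG")

SEED_LENGTH = 11
DISTAL_LENGTH = 9
MIN_DISTAL_MISMATCHES = 7


def revcomp(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, what: str) -> None:
    if not set(seq) <= DNA_ALPHABET:
        raise ValidationError(f"invalid alphabet in {what}: {seq!r}")


@dataclass(frozen=True)
class CandidateSite:
    """A genomic target site: 20-nt protospacer followed by a 3-nt PAM.

    ``position`` is the 0-based offset of the site relative to the feature
    anchor (TSS for CRISPRi, exon start for CRISPRwt).
    """

    protospacer: str
    pam: str
    transcript_id: str
    position: int
    strand: str = "+"

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ValidationError(
                f"protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        _check_alphabet(self.protospacer, "protospacer")


def check_pam(site: CandidateSite) -> bool:
    """True iff the site's PAM is of the NGG form."""
    if len(site.pam) != 3:
        raise ValidationError(f"PAM must be 3 nt, got {site.pam!r}")
    _check_alphabet(site.pam, "PAM")
    return site.pam[1:3] == "GG"


class SeedIndex:
    """Index of all 11-mers in a background sequence collection.

    For every seed occurrence the 9 bases on either side are stored (padded
    with ``-`` at sequence boundaries, which always count as mismatches), so
    the off-target rule can be evaluated without re-scanning the background.
    Both strands are indexed.
    """

    def __init__(
        self,
        hits: Mapping[str, list[tuple[str, str, str]]],
        seed_length: int = SEED_LENGTH,
    ):
        for seed in hits:
            if len(seed) != seed_length:
                raise ValidationError(f"seed {seed!r} is not {seed_length} nt")
        self.hits = dict(hits)
        self.seed_length = seed_length

    def __len__(self) -> int:
        return len(self.hits)

    @classmethod
    def build(
        cls,
        background: Mapping[str, str],
        seed_length: int = SEED_LENGTH,
        context_length: int = DISTAL_LENGTH,
        both_strands: bool = True,
    ) -> "SeedIndex":
        hits: dict[str, list[tuple[str, str, str]]] = {}
        for seq_id, seq in background.items():
            seq = seq.upper()
            strands = [seq, revcomp(seq)] if both_strands else [seq]
            for s in strands:
                n = len(s)
                for i in range(n - seed_length + 1):
                    seed = s[i : i + seed_length]
                    up = s[max(0, i - context_length) : i].rjust(context_length, "-")
                    down = s[i + seed_length : i + seed_length + context_length].ljust(
                        context_length, "-"
                    )
                    hits.setdefault(seed, []).append((seq_id, up, down))
        return cls(hits, seed_length)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def passes_offtarget(
    site: CandidateSite,
    index: SeedIndex,
    exclude_ids: Iterable[str] = (),
    seed_end: str = "pam_proximal",
) -> bool:
    """Apply the seed off-target rule to one candidate site.

    The seed is the 11 PAM-proximal nucleotides of the protospacer by
    default (``seed_end="pam_distal"`` flips the convention). A site passes
    if its seed is absent from the index, or if at every seed hit the
    remaining 9 nt of the guide mismatch the aligned background bases at
    >= 7 positions. Hits on the site's own locus (``exclude_ids``) are
    ignored.
    """
    if len(index) == 0:
        logger.warning("off-target check against an empty seed index; passing %s",
                       site.protospacer)
        return True
    proto = site.protospacer
    if seed_end == "pam_proximal":
        seed, distal, context_slot = proto[-SEED_LENGTH:], proto[:DISTAL_LENGTH], 1
    elif seed_end == "pam_distal":
        seed, distal, context_slot = proto[:SEED_LENGTH], proto[-DISTAL_LENGTH:], 2
    else:
        raise ValidationError(f"unknown seed_end {seed_end!r}")
    exclude = set(exclude_ids)
    hits = index.hits.get(seed)
    if not hits:
        return True
    for hit in hits:
        if hit[0] in exclude:
            continue
        if _mismatches(distal, hit[context_slot]) < MIN_DISTAL_MISMATCHES:
            return False
    return True


def select_per_transcript(
    sites: Sequence[CandidateSite],
    cap: int = 12,
    mode: str = "crisprwt",
    tss_window: tuple[int, int] = (50, 500),
) -> list[CandidateSite]:
    """Select up to ``cap`` sites for one transcript.

    In CRISPRi mode only sites whose position falls in the half-open window
    ``[tss_window[0], tss_window[1])`` downstream of the TSS are eligible.
    Sites are ordered by position ascending (ties by protospacer) so the
    earliest usable sites are preferred.
    """
    if not sites:
        return []
    tids = {s.transcript_id for s in sites}
    if len(tids) > 1:
        raise ValidationError(f"sites span multiple transcripts: {sorted(tids)}")
    if mode == "crispri":
        lo, hi = tss_window
        eligible = [s for s in sites if lo <= s.position < hi]
    elif mode == "crisprwt":
        eligible = list(sites)
    else:
        raise ValidationError(f"unknown selection mode {mode!r}")
    eligible.sort(key=lambda s: (s.position, s.protospacer))
    return eligible[: max(cap, 0)]


@dataclass
class LibraryManifest:
    """The sgRNA universe of one or more barcoded libraries.

    ``entries`` holds one row per (sgrna, library_id) with the target gene
    and the NTC flag; ``bc_pools`` maps (library_id, sgrna) to the random
    barcode pool assigned to that library entry.
    """

    entries: pd.DataFrame
    bc_pools: dict[tuple[str, str], list[str]] | None = None
    id_whitelist: tuple[str, ...] = DEFAULT_ID_WHITELIST

    def __post_init__(self):
        required = ["sgrna", "gene", "library_id", "is_ntc"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise DataError(f"manifest is missing columns: {missing}")
        self.entries = self.entries[required].reset_index(drop=True)
        dup = self.entries.duplicated(subset=["sgrna", "library_id"])
        if dup.any():
            raise ValidationError("duplicate (sgrna, library_id) pairs in manifest")
        bad = set(self.entries["library_id"]) - set(self.id_whitelist)
        if bad:
            raise ValidationError(f"library IDs not in whitelist: {sorted(bad)}")

    # -- lookups ---------------------------------------------------------
    def gene_lookup(self) -> dict[tuple[str, str], str]:
        return {
            (lib, sg): gene
            for lib, sg, gene in zip(
                self.entries["library_id"], self.entries["sgrna"], self.entries["gene"]
            )
        }

    def ntc_genes(self) -> set[str]:
        return set(self.entries.loc[self.entries["is_ntc"], "gene"])

    def library_ids(self) -> list[str]:
        return sorted(set(self.entries["library_id"]))

    def sgrnas(self, library_id: str | None = None) -> set[str]:
        df = self.entries
        if library_id is not None:
            df = df[df["library_id"] == library_id]
        return set(df["sgrna"])

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def write_oligo_tsv(self, path) -> None:
        """One row per (entry, barcode); requires assigned BC pools."""
        if self.bc_pools is None:
            raise DataError("no barcode pools assigned; run assign_barcodes first")
        rows = []
        for _, e in self.entries.iterrows():
            for bc in self.bc_pools[(e["library_id"], e["sgrna"])]:
                rows.append((e["library_id"], e["sgrna"], e["gene"], e["is_ntc"], bc))
        pd.DataFrame(
            rows, columns=["library_id", "sgrna", "gene", "is_ntc", "barcode"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, id_whitelist=DEFAULT_ID_WHITELIST) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", dtype={"sgrna": str, "gene": str,
                                                "library_id": str})
        df["is_ntc"] = df["is_ntc"].astype(bool)
        return cls(df, id_whitelist=tuple(id_whitelist))

    @classmethod
    def read_oligo_tsv(cls, path, id_whitelist=DEFAULT_ID_WHITELIST) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", dtype={"sgrna": str, "gene": str,
                                                "library_id": str, "barcode": str})
        df["is_ntc"] = df["is_ntc"].astype(bool)
        entries = df[["sgrna", "gene", "library_id", "is_ntc"]].drop_duplicates()
        pools: dict[tuple[str, str], list[str]] = {}
        for lib, sg, bc in zip(df["library_id"], df["sgrna"], df["barcode"]):
            pools.setdefault((lib, sg), []).append(bc)
        return cls(entries, bc_pools=pools, id_whitelist=tuple(id_whitelist))


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """``n`` distinct random DNA ``length``-mers."""
    space = 4 ** length
    if space < n:
        raise ValidationError(
            f"cannot draw {n} distinct barcodes of length {length} (only {space} exist)"
        )
    bases = np.array(list("ACGT"))
    if space <= 4 ** 12:  # small spaces: sample integers without replacement
        codes = rng.choice(space, size=n, replace=False)
        out = []
        for c in codes:
            s = []
            for _ in range(length):
                s.append("ACGT"[c % 4])
                c //= 4
            out.append("".join(s))
        return out
    # large spaces: collisions are vanishingly rare; draw and de-duplicate
    seen: set[str] = set()
    out = []
    while len(out) < n:
        draw = bases[rng.integers(0, 4, size=(n - len(out), length))]
        for row in draw:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def assign_barcodes(
    manifest: LibraryManifest,
    bcs_per_sgrna: int,
    bc_length: int = 20,
    seed: int = 0,
) -> LibraryManifest:
    """Attach a pool of distinct random barcodes to every manifest entry.

    Reproducible under a fixed seed; barcodes are unique within an entry
    (cross-entry collisions are allowed, as in the physical library).
    """
    if bcs_per_sgrna < 1:
        raise ValidationError("bcs_per_sgrna must be >= 1")
    if 4 ** bc_length < bcs_per_sgrna:
        raise ValidationError(
            f"barcode space 4^{bc_length} cannot hold {bcs_per_sgrna} distinct barcodes"
        )
    rng = np.random.default_rng(seed)
    pools: dict[tuple[str, str], list[str]] = {}
    order = manifest.entries.sort_values(["library_id", "sgrna"], kind="mergesort")
    for lib, sg in zip(order["library_id"], order["sgrna"]):
        pools[(lib, sg)] = _random_kmers(rng, bcs_per_sgrna, bc_length)
    return LibraryManifest(
        manifest.entries.copy(), bc_pools=pools, id_whitelist=manifest.id_whitelist
    )


# -- site table / FASTA I/O -------------------------------------------------

def read_sites_tsv(path) -> list[CandidateSite]:
    """Candidate sites from a TSV with columns transcript_id, protospacer,
    pam, position, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "protospacer": str,
                                            "pam": str, "strand": str})
    return [
        CandidateSite(r.protospacer, r.pam, r.transcript_id, int(r.position), r.strand)
        for r in df.itertuples()
    ]


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA reader for background/promoter collections."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise DataError(f"FASTA {path} does not start with a header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def design_library(
    sites_by_transcript: Mapping[str, Sequence[CandidateSite]],
    gene_of_transcript: Mapping[str, str],
    background: Mapping[str, str],
    library_id: str,
    mode: str = "crisprwt",
    cap: int = 12,
    ntc_sequences: Sequence[str] = (),
    seed_end: str = "pam_proximal",
) -> LibraryManifest:
    """Run the full selection over candidate sites and emit a manifest.

    NTC sequences bypass the PAM and off-target filters (they have no
    genomic target by construction).
    """
    index = SeedIndex.build(background)
    rows = []
    for tid, sites in sites_by_transcript.items():
        passing = [
            s
            for s in sites
            if check_pam(s)
            and passes_offtarget(s, index, exclude_ids={tid}, seed_end=seed_end)
        ]
        for s in select_per_transcript(passing, cap=cap, mode=mode):
            rows.append((s.protospacer, gene_of_transcript[tid], library_id, False))
    for i, seq in enumerate(ntc_sequences):
        _check_alphabet(seq, "NTC sequence")
        rows.append((seq, f"NTC_{i + 1:05d}", library_id, True))
    df = pd.DataFrame(rows, columns=["sgrna", "gene", "library_id", "is_ntc"])
    df = df.drop_duplicates(subset=["sgrna", "library_id"])
    return LibraryManifest(df)
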