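"""Paired-end read deconvolution into (library ID, sgRNA, barcode) counts.

Read 1 carries the 20-nt sgRNA protospacer, read 2 carries the 20-nt random
barcode and the 6-nt library ID at fixed offsets. Field positions are
configuration (``ReadLayout``), not constants, because they depend on the
sequencing primers used. Base qualities are ignored; reads containing N in
any field are rejected and all rejections are tallied by reason.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping

import pysam
import yaml

from .errors import DataError
from .libdesign import LibraryManifest, revcomp
from .tables import BarcodeCountTable

logger = logging.getLogger(__name__)

# rejection reasons
TOO_SHORT = "too_short"
AMBIGUOUS_BASE = "ambiguous_base"
ANCHOR_MISMATCH = "anchor_mismatch"
SGRNA_UNMATCHED = "sgrna_unmatched"
SGRNA_AMBIGUOUS = "sgrna_ambiguous"
ID_UNMATCHED = "id_unmatched"
ID_AMBIGUOUS = "id_ambiguous"
PAIR_UNMATCHED = "pair_unmatched"

REASONS = (
    TOO_SHORT,
    AMBIGUOUS_BASE,
    ANCHOR_MISMATCH,
    SGRNA_UNMATCHED,
    SGRNA_AMBIGUOUS,
    ID_UNMATCHED,
    ID_AMBIGUOUS,
    PAIR_UNMATCHED,
)


@dataclass
class ReadLayout:
    """Where the sgRNA, barcode, and library ID sit in the read pair."""

    sgrna_offset: int = 0
    sgrna_length: int = 20
    bc_offset: int = 0
    bc_length: int = 20
    id_offset: int = 30
    id_length: int = 6
    r1_anchor: str | None = None  # expected constant sequence after the sgRNA
    r1_anchor_offset: int = 20
    revcomp_read2: bool = False  # flip read 2 for dialects sequenced in reverse

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReadLayout":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def extract_fields(
    read1: str, read2: str, layout: ReadLayout
) -> tuple[tuple[str, str, str] | None, str | None]:
    """Pull (sgrna, bc, id) out of one read pair.

    Returns ``(fields, None)`` on success or ``(None, reason)`` when the
    pair is rejected (too short, anchor mismatch, or N in any field).
    """
    if layout.revcomp_read2:
        read2 = revcomp(read2)
    if len(read1) < layout.sgrna_offset + layout.sgrna_length:
        return None, TOO_SHORT
    need2 = max(layout.bc_offset + layout.bc_length, layout.id_offset + layout.id_length)
    if len(read2) < need2:
        return None, TOO_SHORT
    if layout.r1_anchor is not None:
        got = read1[layout.r1_anchor_offset : layout.r1_anchor_offset + len(layout.r1_anchor)]
        if got != layout.r1_anchor:
            return None, ANCHOR_MISMATCH
    sgrna = read1[layout.sgrna_offset : layout.sgrna_offset + layout.sgrna_length]
    bc = read2[layout.bc_offset : layout.bc_offset + layout.bc_length]
    ident = read2[layout.id_offset : layout.id_offset + layout.id_length]
    if "N" in sgrna or "N" in bc or "N" in ident:
        return None, AMBIGUOUS_BASE
    return (sgrna, bc, ident), None


def _neighbors1(seq: str) -> Iterable[str]:
    for i, base in enumerate(seq):
        for b in "ACGT":
            if b != base:
                yield seq[:i] + b + seq[i + 1 :]


class WhitelistMatcher:
    """Match observed sgRNA and ID sequences to the manifest whitelists.

    sgRNAs are matched exactly by default (``sgrna_mm=1`` allows a unique
    single-mismatch match); IDs are matched within ``id_mm`` mismatches to a
    unique whitelist ID. A matched (ID, sgRNA) pair must also exist in the
    manifest.
    """

    _AMBIG = object()

    def __init__(self, manifest: LibraryManifest, sgrna_mm: int = 0, id_mm: int = 1):
        if sgrna_mm not in (0, 1):
            raise DataError("sgrna_mm must be 0 or 1")
        if id_mm < 0:
            raise DataError("id_mm must be >= 0")
        self.sgrna_mm = sgrna_mm
        self.id_mm = id_mm
        self.sgrnas = manifest.sgrnas()
        self.ids = list(manifest.id_whitelist)
        self.pairs = set(
            zip(manifest.entries["library_id"], manifest.entries["sgrna"])
        )
        self._sg_neighbors: dict[str, object] | None = None
        if sgrna_mm == 1:
            nb: dict[str, object] = {}
            for sg in self.sgrnas:
                for n in _neighbors1(sg):
                    nb[n] = self._AMBIG if n in nb else sg
            self._sg_neighbors = nb

    def match(self, sgrna: str, ident: str) -> tuple[tuple[str, str] | None, str | None]:
        if sgrna in self.sgrnas:
            sg = sgrna
        elif self.sgrna_mm == 1:
            hit = self._sg_neighbors.get(sgrna)
            if hit is None:
                return None, SGRNA_UNMATCHED
            if hit is self._AMBIG:
                return None, SGRNA_AMBIGUOUS
            sg = hit
        else:
            return None, SGRNA_UNMATCHED
        cands = [
            wl
            for wl in self.ids
            if len(wl) == len(ident)
            and sum(a != b for a, b in zip(wl, ident)) <= self.id_mm
        ]
        if not cands:
            return None, ID_UNMATCHED
        if len(cands) > 1:
            return None, ID_AMBIGUOUS
        lib = cands[0]
        if (lib, sg) not in self.pairs:
            return None, PAIR_UNMATCHED
        return (sg, lib), None


def match_whitelists(
    sgrna: str,
    ident: str,
    manifest: LibraryManifest,
    sgrna_mm: int = 0,
    id_mm: int = 1,
) -> tuple[tuple[str, str] | None, str | None]:
    """One-shot whitelist matching; use :class:`WhitelistMatcher` in loops."""
    return WhitelistMatcher(manifest, sgrna_mm, id_mm).match(sgrna, ident)


def count_sample(
    fastq1,
    fastq2,
    layout: ReadLayout,
    manifest: LibraryManifest,
    sample_id: str | None = None,
    sgrna_mm: int = 0,
    id_mm: int = 1,
) -> tuple[dict[tuple[str, str, str], int], dict]:
    """Tally accepted read pairs of one sample by (library_id, sgrna, bc).

    Returns the counter plus a QC report: total / accepted counts, per-reason
    rejections, and the per-ID fraction of accepted reads.
    """
    matcher = WhitelistMatcher(manifest, sgrna_mm, id_mm)
    counts: dict[tuple[str, str, str], int] = {}
    rejected = {r: 0 for r in REASONS}
    total = 0
    accepted = 0
    id_totals: dict[str, int] = {}
    with pysam.FastxFile(str(fastq1)) as fh1, pysam.FastxFile(str(fastq2)) as fh2:
        for rec1, rec2 in zip(fh1, fh2):
            total += 1
            fields, reason = extract_fields(rec1.sequence, rec2.sequence, layout)
            if fields is None:
                rejected[reason] += 1
                continue
            sgrna, bc, ident = fields
            matched, reason = matcher.match(sgrna, ident)
            if matched is None:
                rejected[reason] += 1
                continue
            sg, lib = matched
            key = (lib, sg, bc)
            counts[key] = counts.get(key, 0) + 1
            id_totals[lib] = id_totals.get(lib, 0) + 1
            accepted += 1
    if total == 0:
        logger.warning("sample %s: empty FASTQ input", sample_id)
    qc = {
        "sample": sample_id,
        "total": total,
        "accepted": accepted,
        "rejected": {r: n for r, n in rejected.items() if n},
        "id_fractions": {
            lib: n / accepted for lib, n in sorted(id_totals.items())
        }
        if accepted
        else {},
    }
    return counts, qc


def build_count_table(
    sample_counts: Mapping[str, Mapping[tuple[str, str, str], int]],
    manifest: LibraryManifest,
    samples: Iterable[str] | None = None,
) -> BarcodeCountTable:
    """Assemble per-sample counters into a :class:`BarcodeCountTable`."""
    return BarcodeCountTable.from_sample_counts(
        sample_counts, manifest.gene_lookup(), samples
    )
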