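"""Generative model for multi-clone pooled CRISPR screens.

Four clonal Cas9 lines, each carrying one ID-tagged sgRNA library, are
pooled and split into a treated arm (escalating doses of a selective agent
on days 0, 1 and 4) and an untreated arm, with samples drawn on days 0
(baseline), 4, 9 and 14. Every (clone, sgRNA, barcode) triple is one
lentiviral integration event, i.e. one sub-clonal lineage.

Lineage dynamics per day d::

    cells <- cells * 2 ** (growth_c + fitness_shift_g + eta_l)

and on dose-event days (treated arm only)::

    cells <- cells * (1 - s_l * (1 - resistance_g) * (dose / max_dose) ** kill_exponent)

Sub-clonal heterogeneity has two per-lineage components, both drawn once at
seeding and both governed by the clone's ``sigma_sub``: a growth jitter
``eta_l ~ Normal(0, sigma_sub)`` shared by both arms, and a sensitivity
jitter giving the lineage its own kill fraction
``s_l = clip(sensitivity_c + Normal(0, sigma_sub), 0, 1)``. The growth
jitter cancels in treated-vs-untreated fold changes; the sensitivity jitter
is what makes barcode-level fold-change dispersion grow with ``sigma_sub``.

Sequencing is a multinomial draw of reads over lineages proportional to
cell counts, with optional independent per-base substitution errors on the
sgRNA/BC/ID fields, and optional paired-end FASTQ output in the fixed
layout that :mod:`clonepool.readproc` inverts.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .libdesign import DEFAULT_ID_WHITELIST, LibraryManifest, assign_barcodes, _random_kmers
from .readproc import ReadLayout
from .tables import BarcodeCountTable, sample_name

logger = logging.getLogger(__name__)

# -- read layout constants ----------------------------------------------------
READ_LENGTH = 50
SCAFFOLD = "GTTTAAGAGCTATGCTGGAAAC"
R1_PAD = (SCAFFOLD + "A" * 30)[:30]  # constant 30-nt scaffold pad after the sgRNA
R2_SPACER = "CTGCAGGTCA"  # constant 10-nt spacer between BC and ID
R2_PAD = "A" * 14
_FIELD_LENGTH = 6 + 20 + 20  # id + sgrna + bc


def default_layout() -> ReadLayout:
    """The layout written by the simulator (and its YAML sidecar)."""
    return ReadLayout(
        sgrna_offset=0,
        sgrna_length=20,
        bc_offset=0,
        bc_length=20,
        id_offset=30,
        id_length=6,
    )


# -- model parameters ---------------------------------------------------------
@dataclass(frozen=True)
class CloneProfile:
    """One clonal Cas9 line carrying one ID-tagged library.

    growth_rate is in doublings/day; sensitivity is the fraction of cells
    killed by a full-dose event absent any rescue; sigma_sub scales both
    per-lineage jitters (growth, in doublings/day, and sensitivity, as a
    fraction).
    """

    clone_id: str
    library_id: str
    growth_rate: float = 1.0
    sensitivity: float = 0.5
    sigma_sub: float = 0.1

    def __post_init__(self):
        if self.growth_rate <= 0:
            raise ValidationError(f"growth_rate must be > 0 ({self.clone_id})")
        if not 0 <= self.sensitivity <= 1:
            raise ValidationError(f"sensitivity must be in [0,1] ({self.clone_id})")
        if self.sigma_sub < 0:
            raise ValidationError(f"sigma_sub must be >= 0 ({self.clone_id})")


@dataclass(frozen=True)
class GeneEffect:
    """Ground-truth effect of perturbing one gene.

    resistance=1 fully rescues treatment killing; fitness_shift is an
    additive growth term in doublings/day.
    """

    gene: str
    resistance: float = 0.0
    fitness_shift: float = 0.0

    def __post_init__(self):
        if not 0 <= self.resistance <= 1:
            raise ValidationError(f"resistance must be in [0,1] ({self.gene})")


@dataclass(frozen=True)
class DoseSchedule:
    """Dose events (day, dose in ng/ml) applied to the treated arm."""

    events: tuple[tuple[int, float], ...] = ((0, 10.0), (1, 20.0), (4, 25.0))
    max_dose: float = 25.0

    def __post_init__(self):
        days = [d for d, _ in self.events]
        if any(d < 0 for d in days):
            raise ValidationError("dose days must be non-negative")
        if sorted(days) != days or len(set(days)) != len(days):
            raise ValidationError("dose days must be strictly increasing")
        if self.max_dose <= 0:
            raise ValidationError("max_dose must be > 0")

    def dose_on(self, day: int) -> float | None:
        for d, dose in self.events:
            if d == day:
                return dose
        return None


@dataclass(frozen=True)
class ScreenDesign:
    """Arms, sampling days, coverage and sequencing depth of the screen.

    moi is recorded for documentation: infections are Poisson at low MOI and
    only single-integration cells are modeled (one sgRNA-BC per cell).
    """

    arms: tuple[str, ...] = ("treated", "untreated")
    sample_days: tuple[int, ...] = (0, 4, 9, 14)
    coverage: int = 1000
    moi: float = 0.3
    read_depth: int = 2_000_000

    def __post_init__(self):
        if not 0 < self.moi <= 1:
            raise ValidationError("moi must be in (0, 1]")
        if self.coverage < 0:
            raise ValidationError("coverage must be >= 0")
        if self.read_depth <= 0:
            raise ValidationError("read_depth must be > 0")
        if list(self.sample_days) != sorted(set(self.sample_days)):
            raise ValidationError("sample_days must be strictly increasing")

    def samples(self) -> list[str]:
        return [sample_name(a, d) for a in self.arms for d in self.sample_days]


LINEAGE_COLS = ["clone_id", "library_id", "sgrna", "gene", "barcode", "eta", "sens", "cells"]


# -- seeding ------------------------------------------------------------------
def seed_lineages(
    manifest: LibraryManifest,
    clones: Sequence[CloneProfile],
    design: ScreenDesign,
    seed: int | np.random.Generator = 0,
    lineages_per_sgrna: int | None = None,
) -> pd.DataFrame:
    """Transduce each clone with its library and return the lineage table.

    Per clone and sgRNA, ``design.coverage`` cells each draw one barcode
    from the entry's BC pool (a multinomial split), so the cell total per
    sgRNA is exactly the coverage. ``lineages_per_sgrna`` instead forces a
    fixed number of distinct-barcode lineages (error if the pool is too
    small). Per-lineage growth (eta) and sensitivity jitters are drawn here.
    """
    if manifest.bc_pools is None:
        raise DataError("manifest has no barcode pools; run assign_barcodes first")
    libs = [c.library_id for c in clones]
    if len(set(libs)) != len(libs):
        raise ValidationError("each clone must carry a distinct library_id")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: dict[str, list] = {c: [] for c in LINEAGE_COLS}
    for clone in clones:
        entries = manifest.entries[manifest.entries["library_id"] == clone.library_id]
        if entries.empty:
            raise DataError(f"no manifest entries for library {clone.library_id!r}")
        for sg, gene in zip(entries["sgrna"], entries["gene"]):
            pool = manifest.bc_pools[(clone.library_id, sg)]
            if lineages_per_sgrna is not None:
                if lineages_per_sgrna > len(pool):
                    raise DataError(
                        f"barcode pool exhausted for sgRNA {sg!r}: "
                        f"{lineages_per_sgrna} lineages requested, pool {len(pool)}"
                    )
                chosen = rng.choice(len(pool), size=lineages_per_sgrna, replace=False)
                counts = np.zeros(len(pool), dtype=np.int64)
                split = rng.multinomial(design.coverage, np.ones(lineages_per_sgrna) / lineages_per_sgrna)
                counts[chosen] = np.maximum(split, 0)
            else:
                if design.coverage == 0:
                    continue
                counts = rng.multinomial(design.coverage, np.ones(len(pool)) / len(pool))
            nz = np.nonzero(counts)[0]
            if nz.size == 0:
                continue
            etas = rng.normal(0.0, clone.sigma_sub, size=nz.size)
            sens = np.clip(
                rng.normal(clone.sensitivity, clone.sigma_sub, size=nz.size), 0.0, 1.0
            )
            rows["clone_id"].extend([clone.clone_id] * nz.size)
            rows["library_id"].extend([clone.library_id] * nz.size)
            rows["sgrna"].extend([sg] * nz.size)
            rows["gene"].extend([gene] * nz.size)
            rows["barcode"].extend(pool[i] for i in nz)
            rows["eta"].extend(etas)
            rows["sens"].extend(sens)
            rows["cells"].extend(counts[nz])
    df = pd.DataFrame(rows)
    df["cells"] = df["cells"].astype(float)
    return df


# -- propagation --------------------------------------------------------------
def _effect_arrays(
    lineages: pd.DataFrame,
    clones: Sequence[CloneProfile],
    effects: Mapping[str, GeneEffect],
) -> tuple[np.ndarray, np.ndarray]:
    growth = {c.clone_id: c.growth_rate for c in clones}
    shift = np.array([
        effects[g].fitness_shift if g in effects else 0.0 for g in lineages["gene"]
    ])
    res = np.array([
        effects[g].resistance if g in effects else 0.0 for g in lineages["gene"]
    ])
    rate = (
        lineages["clone_id"].map(growth).to_numpy(dtype=float)
        + shift
        + lineages["eta"].to_numpy(dtype=float)
    )
    kill = lineages["sens"].to_numpy(dtype=float) * (1.0 - res)
    return rate, kill


def propagate(
    lineages: pd.DataFrame,
    clones: Sequence[CloneProfile],
    effects: Mapping[str, GeneEffect],
    schedule: DoseSchedule,
    day_from: int,
    day_to: int,
    arm: str = "untreated",
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    kill_exponent: float = 1.0,
) -> pd.DataFrame:
    """Advance the lineage table from ``day_from`` to ``day_to``.

    Sampling semantics: the state at day ``d`` reflects all growth up to day
    ``d`` and all dose events on days < ``d`` (a sample taken on a dose day
    precedes that day's dose). Expected mode evolves real-valued expected
    cell counts; stochastic mode applies binomial survival and Poisson
    growth to integer counts.
    """
    if day_from >= day_to:
        raise ValidationError("day_from must be < day_to")
    if mode not in ("expected", "stochastic"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "stochastic" and rng is None:
        raise ValidationError("stochastic mode requires an rng")
    rate, kill = _effect_arrays(lineages, clones, effects)
    growth_factor = 2.0 ** rate
    cells = lineages["cells"].to_numpy(dtype=float).copy()
    for day in range(day_from, day_to):
        if arm == "treated":
            dose = schedule.dose_on(day)
            if dose is not None:
                if dose > schedule.max_dose:
                    logger.warning(
                        "dose %.3g on day %d exceeds max_dose %.3g; clipping",
                        dose, day, schedule.max_dose,
                    )
                    dose = schedule.max_dose
                surv = 1.0 - kill * (dose / schedule.max_dose) ** kill_exponent
                if mode == "expected":
                    cells = cells * surv
                else:
                    cells = rng.binomial(cells.astype(np.int64), surv).astype(float)
        if mode == "expected":
            cells = cells * growth_factor
        else:
            cells = rng.poisson(cells * growth_factor).astype(float)
    out = lineages.copy()
    out["cells"] = cells
    return out


# -- sequencing ---------------------------------------------------------------
_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class _ReadMatcher:
    """Mirror of readproc's default acceptance rules, used so the
    simulator's internal count table equals what deconvolution of its own
    FASTQ produces (exact sgRNA match, <=1-mismatch ID, manifest pair)."""

    def __init__(self, manifest: LibraryManifest):
        self.sgrnas = manifest.sgrnas()
        self.id_map: dict[str, str] = {}
        for wl in manifest.id_whitelist:
            self.id_map[wl] = wl
            for i in range(len(wl)):
                for b in "ACGT":
                    if b != wl[i]:
                        self.id_map[wl[:i] + b + wl[i + 1:]] = wl
        self.pairs = set(zip(manifest.entries["library_id"], manifest.entries["sgrna"]))

    def match(self, ident: str, sgrna: str) -> str | None:
        lib = self.id_map.get(ident)
        if lib is None or sgrna not in self.sgrnas:
            return None
        if (lib, sgrna) not in self.pairs:
            return None
        return lib


def sample_reads(
    lineages: pd.DataFrame,
    read_depth: int,
    error_rate: float,
    rng: np.random.Generator,
    matcher: _ReadMatcher | None = None,
) -> tuple[dict[tuple[str, str, str], int], dict[tuple[str, str, str], int], int]:
    """Draw reads over lineages proportional to cell counts.

    Returns ``(accepted, raw, n_unmatched)``: ``raw`` counts every read by
    its observed (library_id, sgrna, barcode) triple after sequencing
    errors; ``accepted`` applies the deconvolution acceptance rules
    (identity when error_rate is 0).
    """
    cells = lineages["cells"].to_numpy(dtype=float)
    total = cells.sum()
    if total <= 0:
        raise DataError("cannot sequence a sample with zero cells")
    reads = rng.multinomial(read_depth, cells / total)
    nz = np.nonzero(reads)[0]
    keys = list(
        zip(lineages["library_id"], lineages["sgrna"], lineages["barcode"])
    )
    raw: dict[tuple[str, str, str], int] = {}
    accepted: dict[tuple[str, str, str], int] = {}
    unmatched = 0
    if error_rate == 0:
        for i in nz:
            k = keys[i]
            raw[k] = raw.get(k, 0) + int(reads[i])
        return dict(raw), dict(raw), 0

    p_clean = (1.0 - error_rate) ** _FIELD_LENGTH
    n_err = rng.binomial(reads[nz], 1.0 - p_clean)
    clean = reads[nz] - n_err
    for i, c in zip(nz, clean):
        if c > 0:
            k = keys[i]
            raw[k] = raw.get(k, 0) + int(c)
            accepted[k] = accepted.get(k, 0) + int(c)
    err_lineages = np.repeat(nz, n_err)
    n = err_lineages.size
    if n:
        fields = np.frombuffer(
            "".join(f"{k[0]}{k[1]}{k[2]}" for k in keys).encode(), dtype="S1"
        ).reshape(len(keys), _FIELD_LENGTH)
        seqs = fields[err_lineages].copy()
        mask = rng.random((n, _FIELD_LENGTH)) < error_rate
        empty = ~mask.any(axis=1)
        if empty.any():  # condition on >= 1 substitution
            mask[np.nonzero(empty)[0], rng.integers(0, _FIELD_LENGTH, int(empty.sum()))] = True
        idx = _BASE_LUT[seqs.view(np.uint8)]
        offs = rng.integers(1, 4, size=(n, _FIELD_LENGTH))
        idx = np.where(mask, (idx + offs) % 4, idx)
        mut = _BASES[idx]
        if matcher is None:
            raise ValidationError("error_rate > 0 requires a read matcher")
        for r in range(n):
            s = mut[r].tobytes().decode()
            ident, sg, bc = s[:6], s[6:26], s[26:46]
            lib = matcher.match(ident, sg)
            obs_key = (lib if lib is not None else ident, sg, bc)
            raw_key = (ident, sg, bc)
            raw[raw_key] = raw.get(raw_key, 0) + 1
            if lib is None:
                unmatched += 1
            else:
                k = (lib, sg, bc)
                accepted[k] = accepted.get(k, 0) + 1
    return accepted, raw, unmatched


def write_fastq_pair(
    path1,
    path2,
    read_counts: Mapping[tuple[str, str, str], int],
    sample: str,
    compress: bool = False,
) -> None:
    """Write a read pair per counted read: read1 = sgRNA + scaffold pad,
    read2 = BC + spacer + ID + pad (Phred-33 qualities, all 'I')."""
    qual = "I" * READ_LENGTH
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))
    serial = 0
    with opener(str(path1)) as f1, opener(str(path2)) as f2:
        for (ident, sg, bc), count in read_counts.items():
            r1 = sg + R1_PAD
            r2 = bc + R2_SPACER + ident + R2_PAD
            names = [f"@{sample}:{i}" for i in range(serial, serial + count)]
            serial += count
            f1.write("".join(f"{nm}\n{r1}\n+\n{qual}\n" for nm in names))
            f2.write("".join(f"{nm}\n{r2}\n+\n{qual}\n" for nm in names))


# -- full screen --------------------------------------------------------------
@dataclass
class ScreenResult:
    manifest: LibraryManifest
    design: ScreenDesign
    schedule: DoseSchedule
    lineages: pd.DataFrame
    truth: pd.DataFrame
    counts: BarcodeCountTable
    unmatched_reads: dict[str, int]
    layout: ReadLayout
    fastq: dict[str, tuple[str, str]]
    seed: int
    mode: str
    error_rate: float

    def write_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def run_screen(
    manifest: LibraryManifest,
    clones: Sequence[CloneProfile],
    effects: Mapping[str, GeneEffect],
    design: ScreenDesign,
    schedule: DoseSchedule = DoseSchedule(),
    seed: int = 0,
    mode: str = "expected",
    error_rate: float = 0.0,
    kill_exponent: float = 1.0,
    fastq_dir=None,
    fastq_gzip: bool = False,
    lineages_per_sgrna: int | None = None,
) -> ScreenResult:
    """Simulate the whole screen: seeding, both arms, all sample days.

    All randomness derives from ``seed``. When ``fastq_dir`` is given,
    paired FASTQ files are written per sample containing exactly the reads
    that were counted (including reads the count table rejects as
    unmatched, so deconvolution of the FASTQ reproduces ``counts``).
    """
    ntc = manifest.ntc_genes()
    for g, e in effects.items():
        if g != e.gene:
            raise ValidationError(f"effects key {g!r} != effect gene {e.gene!r}")
        if g in ntc and (e.resistance != 0 or e.fitness_shift != 0):
            raise ValidationError(f"NTC gene {g!r} cannot carry an effect")
    ss = np.random.SeedSequence(seed)
    seed_ss, prop_ss, reads_ss = ss.spawn(3)
    lineages = seed_lineages(
        manifest, clones, design, np.random.default_rng(seed_ss),
        lineages_per_sgrna=lineages_per_sgrna,
    )
    matcher = _ReadMatcher(manifest) if error_rate > 0 else None
    prop_rngs = {a: np.random.default_rng(s) for a, s in zip(design.arms, prop_ss.spawn(len(design.arms)))}
    samples = design.samples()
    read_rngs = {
        s: np.random.default_rng(c) for s, c in zip(samples, reads_ss.spawn(len(samples)))
    }
    truth_frames = []
    sample_counts: dict[str, dict] = {}
    raw_counts: dict[str, dict] = {}
    unmatched: dict[str, int] = {}
    for arm in design.arms:
        state = lineages
        prev_day = 0
        for day in design.sample_days:
            if day > prev_day:
                state = propagate(
                    state, clones, effects, schedule, prev_day, day, arm, mode,
                    prop_rngs[arm], kill_exponent,
                )
                prev_day = day
            t = state[["clone_id", "library_id", "sgrna", "gene", "barcode", "cells"]].copy()
            t["arm"] = arm
            t["day"] = day
            truth_frames.append(t)
            sname = sample_name(arm, day)
            acc, raw, unm = sample_reads(
                state, design.read_depth, error_rate, read_rngs[sname], matcher
            )
            sample_counts[sname] = acc
            raw_counts[sname] = raw
            unmatched[sname] = unm
    truth = pd.concat(truth_frames, ignore_index=True)
    counts = BarcodeCountTable.from_sample_counts(
        sample_counts, manifest.gene_lookup(), samples
    )
    layout = default_layout()
    fastq: dict[str, tuple[str, str]] = {}
    if fastq_dir is not None:
        fastq_dir = Path(fastq_dir)
        fastq_dir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if fastq_gzip else ".fastq"
        for sname in samples:
            p1 = fastq_dir / f"{sname}_R1{ext}"
            p2 = fastq_dir / f"{sname}_R2{ext}"
            write_fastq_pair(p1, p2, raw_counts[sname], sname, compress=fastq_gzip)
            fastq[sname] = (str(p1), str(p2))
        layout.to_yaml(fastq_dir / "layout.yaml")
    return ScreenResult(
        manifest, design, schedule, lineages, truth, counts, unmatched,
        layout, fastq, seed, mode, error_rate,
    )


# -- demo design ---------------------------------------------------------------
SYSTEM_IDS = {
    "crisprwt": ("GCCTAA", "TGGTCA"),
    "crispri": ("CGTGAT", "ACATCG"),
}


def demo_manifest(
    n_genes: int = 500,
    sgrnas_per_gene: int = 4,
    bcs_per_sgrna: int = 20,
    ntc_sgrnas: int = 200,
    systems: Sequence[str] = ("crisprwt", "crispri"),
    seed: int = 0,
) -> LibraryManifest:
    """A small synthetic library: shared gene set, one random sgRNA set per
    CRISPR system tagged with that system's two library IDs, plus NTCs."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    ntc_genes = [f"NTC{i // sgrnas_per_gene + 1:05d}" for i in range(ntc_sgrnas)]
    rows = []
    for system in systems:
        ids = SYSTEM_IDS[system]
        n_total = n_genes * sgrnas_per_gene + ntc_sgrnas
        seqs = _random_kmers(rng, n_total, 20)
        gene_of = [g for g in genes for _ in range(sgrnas_per_gene)] + ntc_genes
        is_ntc = [False] * (n_genes * sgrnas_per_gene) + [True] * ntc_sgrnas
        for lib in ids:
            for sg, g, flag in zip(seqs, gene_of, is_ntc):
                rows.append((sg, g, lib, flag))
    entries = pd.DataFrame(rows, columns=["sgrna", "gene", "library_id", "is_ntc"])
    manifest = LibraryManifest(entries)
    return assign_barcodes(manifest, bcs_per_sgrna, seed=int(rng.integers(2 ** 31)))


def demo_clones(systems: Sequence[str] = ("crisprwt", "crispri"), sigma_sub: float = 0.1) -> list[CloneProfile]:
    """One sensitive and one resistant clone per CRISPR system, with mild
    proliferation heterogeneity."""
    params = {
        "crisprwt": [("CloneS_wt", "GCCTAA", 0.95, 0.9), ("CloneR_wt", "TGGTCA", 1.0, 0.1)],
        "crispri": [("CloneS_i", "CGTGAT", 0.9, 0.85), ("CloneR_i", "ACATCG", 1.0, 0.15)],
    }
    out = []
    for system in systems:
        for cid, lib, g, s in params[system]:
            out.append(CloneProfile(cid, lib, growth_rate=g, sensitivity=s, sigma_sub=sigma_sub))
    return out


def spike_effects(genes: Sequence[str], resistance: float = 0.9, fitness_shift: float = 0.0) -> dict[str, GeneEffect]:
    return {g: GeneEffect(g, resistance=resistance, fitness_shift=fitness_shift) for g in genes}


def clone_totals(truth: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth cell totals per (library_id, arm, day)."""
    return (
        truth.groupby(["library_id", "arm", "day"], as_index=False)["cells"].sum()
    )
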