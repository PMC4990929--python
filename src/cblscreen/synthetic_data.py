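"""Labeled synthetic proteins and proteomes with machine-readable ground truth.

Every architecture the screen must recognize is embodied by a canonical
family blueprint: CaM-like and CNB/NCS-like sensors (canonical 12-residue
first loop, D at X, L or F after the -Z anchor), plant and non-plant CBLs
(14-residue first loop with S at X; plants add the invariant 23-residue
EF1-EF2 spacer, an N-terminal lipid-modification motif and a C-terminal
FPSF), stramenopile CBLs (15-residue loop, L at X, inserted G, Q-H/N-E
motif), extended-loop CBLs (19-residue loop), degenerate CBLs (A at X with a
single-residue insertion), CIPK kinases (HRD/DFG catalytic core plus a
21-residue NAF domain) and NAF-less kinases, plus unrelated decoys.

Blueprints are fixed: the structural anchors are hand-placed and the filler
positions are drawn once from a fixed internal seed, so members of a family
are genuine homologs of one another.  The per-record seed drives everything
record-specific: the non-plant spacer-length draw, decoy composition and the
substitution-noise process, which touches unconstrained positions only --
the six coordinating residues, the post-loop residue, motif anchors and the
N-A-F tripeptide are never mutated.  Scaffold filler is restricted to
motif-inert residues (no D/E/G/N/Q/S/T, no C/F/M/P, no H/R) so that at zero
noise the ground truth is exact by construction; substitution noise draws
from all nineteen alternative residues and reintroduces full composition.
"""

from __future__ import annotations

import dataclasses
import functools
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import EFScanConfig
from .efhand import TEMPLATES, score_loop
from .seq_io import AMINO_ACIDS, ProteinRecord, write_fasta

#: residues that participate in no motif and no scoring set of the pipeline
INERT = "IKLVWY"

_BLUEPRINT_SEED = 97531

SENSOR_FAMILIES = (
    "CAM_LIKE", "CNB_NCS_LIKE", "CBL_PLANT", "CBL_NONPLANT",
    "CBL_STRAMENOPILE", "CBL_EXTENDED", "CBL_DEGENERATE",
)
KINASE_FAMILIES = ("CIPK", "KINASE_NO_NAF")
ALL_FAMILIES = SENSOR_FAMILIES + KINASE_FAMILIES + ("DECOY",)

#: first-EF-hand loop per family: (template, loop string, family anchor offsets)
_EF1 = {
    "CAM_LIKE": ("L12", "DKDGDGTITTKE", ()),
    "CNB_NCS_LIKE": ("L12", "DKDGDGTITTKE", ()),
    "CBL_PLANT": ("L14", "SKIKDKDKTKTKKE", ()),
    "CBL_NONPLANT": ("L14", "SKIKDKDKTKTKKE", ()),
    "CBL_STRAMENOPILE": ("L15", "LKGIKDKDQHETKKE", (2, 8, 10)),  # G + Q.E anchors
    "CBL_EXTENDED": ("L19", "SKGIKKIKKDKDKTKTKKE", ()),
    "CBL_DEGENERATE": ("L15", "AKKIKDKDKTKTKKE", ()),
}

_CANONICAL_L12 = "DKDGDGTITTKE"

#: 21-residue NAF-domain window; the N-A-F tripeptide sits at offsets 8-10
_NAF_WINDOW = "ELSRKWQVNAFDLISKMWEHG"
_NAF_OFFSET = 8
#: the same window with the tripeptide replaced, for the NAF-less kinase
_NONAF_WINDOW = "ELSRKWQVKLIDLISKMWEHG"

DEFAULT_SPACER12 = 23
NONPLANT_SPACER_RANGE = (19, 24)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeSpec:
    family: str
    substitution_rate: float = 0.0
    seed: int = 0
    species: str = "unknown"
    record_id: Optional[str] = None
    spacer12: Optional[int] = None  # non-plant CBLs draw from 19-24 when None
    decoy_length_range: tuple[int, int] = (200, 400)

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SpecError("substitution_rate must be in [0, 1)")
        if self.spacer12 is not None and self.spacer12 < 1:
            raise SpecError("spacer12 must be positive")


@dataclass(frozen=True)
class GroundTruth:
    record_id: str
    family: str
    species: str
    ef_hands: tuple[tuple[int, int, str], ...]  # (start, end, template), 0-based half-open
    spacers: tuple[int, ...]
    myristoylation: bool
    cys3: bool
    fpsf_position: Optional[int]  # 1-based
    naf_window: Optional[tuple[int, int]]
    kinase_core: Optional[tuple[int, int]]  # (HRD start, DFG start)
    constrained_mask: tuple[bool, ...]


def _fill(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(INERT), size=n))


@functools.lru_cache(maxsize=None)
def _scaffold_fills() -> dict[str, str]:
    """Shared filler segments, drawn once so all families are homologous."""
    rng = np.random.default_rng(_BLUEPRINT_SEED)
    return {
        "nterm_mid2": _fill(rng, 2),
        "nterm_plant24": _fill(rng, 24),
        "nterm_plain30": _fill(rng, 30),
        "sp12": _fill(rng, 23),
        "sp23": _fill(rng, 24),
        "sp34": _fill(rng, 24),
        "ct_plant_a": _fill(rng, 20),
        "ct_plant_b": _fill(rng, 8),
        "ct_plain": _fill(rng, 12),
        "kin_nterm": _fill(rng, 20),
        "kin_hrd_dfg": _fill(rng, 25),
        "kin_mid": _fill(rng, 50),
        "kin_cterm": _fill(rng, 40),
    }


class _Builder:
    def __init__(self) -> None:
        self.chars: list[str] = []
        self.mask: list[bool] = []

    def add(self, text: str, constrained: Sequence[int] = (), all_constrained: bool = False
            ) -> int:
        start = len(self.chars)
        cset = set(constrained)
        for i, c in enumerate(text):
            self.chars.append(c)
            self.mask.append(all_constrained or i in cset)
        return start


def _build_sensor(family: str, spacer12_len: int):
    fills = _scaffold_fills()
    b = _Builder()
    if family == "CBL_PLANT":
        # MGC..S satisfies both the MGXXXS/T myristoylation pattern and Cys-3
        b.add("MGC", all_constrained=True)
        b.add(fills["nterm_mid2"])
        b.add("S", all_constrained=True)
        b.add(fills["nterm_plant24"])
        myr, cys3 = True, True
    else:
        b.add(fills["nterm_plain30"])
        myr, cys3 = False, False

    template_name, ef1_loop, extra = _EF1[family]
    template = TEMPLATES[template_name]
    coords = []
    post_char = "L" if family == "CAM_LIKE" else "F"

    start = b.add(ef1_loop, constrained=tuple(template.coord_offsets) + tuple(extra))
    coords.append((start, start + len(ef1_loop), template_name))
    b.add(post_char, all_constrained=True)
    b.add(fills["sp12"][: spacer12_len - 1])

    for fill_key in ("sp23", "sp34", None):
        start = b.add(_CANONICAL_L12, constrained=TEMPLATES["L12"].coord_offsets)
        coords.append((start, start + 12, "L12"))
        b.add(post_char, all_constrained=True)
        if fill_key is not None:
            b.add(fills[fill_key])

    fpsf_position = None
    if family == "CBL_PLANT":
        b.add(fills["ct_plant_a"])
        fpsf_position = b.add("FPSF", all_constrained=True) + 1
        b.add(fills["ct_plant_b"])
    else:
        b.add(fills["ct_plain"])

    spacers = tuple(coords[i + 1][0] - coords[i][1] for i in range(3))
    return b, dict(ef_hands=tuple(coords), spacers=spacers, myristoylation=myr,
                   cys3=cys3, fpsf_position=fpsf_position, naf_window=None,
                   kinase_core=None)


def _build_kinase(family: str):
    fills = _scaffold_fills()
    b = _Builder()
    b.add(fills["kin_nterm"])
    hrd = b.add("HRD", all_constrained=True)
    b.add(fills["kin_hrd_dfg"])
    dfg = b.add("DFG", all_constrained=True)
    b.add(fills["kin_mid"])
    if family == "CIPK":
        start = b.add(_NAF_WINDOW,
                      constrained=range(_NAF_OFFSET, _NAF_OFFSET + 3))
        naf_window = (start, start + len(_NAF_WINDOW))
    else:
        b.add(_NONAF_WINDOW)
        naf_window = None
    b.add(fills["kin_cterm"])
    return b, dict(ef_hands=(), spacers=(), myristoylation=False, cys3=False,
                   fpsf_position=None, naf_window=naf_window, kinase_core=(hrd, dfg))


def _apply_noise(chars: list[str], mask: list[bool], rate: float,
                 rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    for i, constrained in enumerate(mask):
        if constrained:
            continue
        if rng.random() < rate:
            alternatives = AMINO_ACIDS.replace(chars[i], "")
            chars[i] = alternatives[int(rng.integers(len(alternatives)))]


def _default_id(spec: ArchetypeSpec) -> str:
    digest = hashlib.sha1(
        f"{spec.seed}:{spec.family}:{spec.species}".encode()).hexdigest()
    return "sq" + digest[:10]


def generate_archetype(spec: ArchetypeSpec,
                       scan_config: EFScanConfig | None = None
                       ) -> tuple[ProteinRecord, GroundTruth]:
    """Generate one labeled protein from its family blueprint.

    The emitted sequence is self-checked: every planted EF-hand, rescored
    with the scanner's own configuration at its ground-truth coordinates,
    must clear the acceptance threshold (the constrained anchors guarantee
    this at any substitution rate).
    """
    scan_config = scan_config or EFScanConfig()
    rng = np.random.default_rng([spec.seed, 20_0819])
    if spec.family == "DECOY":
        lo, hi = spec.decoy_length_range
        if lo < 1 or hi < lo:
            raise SpecError(f"bad decoy length range {spec.decoy_length_range}")
        length = int(rng.integers(lo, hi + 1))
        chars = list(rng.choice(list(AMINO_ACIDS), size=length))
        mask = [False] * length
        truth_fields = dict(ef_hands=(), spacers=(), myristoylation=False,
                            cys3=False, fpsf_position=None, naf_window=None,
                            kinase_core=None)
    else:
        if spec.family in SENSOR_FAMILIES:
            if spec.spacer12 is not None:
                spacer12 = spec.spacer12
            elif spec.family == "CBL_NONPLANT":
                lo, hi = NONPLANT_SPACER_RANGE
                spacer12 = int(rng.integers(lo, hi + 1))
            else:
                spacer12 = DEFAULT_SPACER12
            if spacer12 > len(_scaffold_fills()["sp12"]) + 1:
                raise SpecError(f"spacer12={spacer12} exceeds the scaffold spacer")
            builder, truth_fields = _build_sensor(spec.family, spacer12)
        else:
            builder, truth_fields = _build_kinase(spec.family)
        chars, mask = builder.chars, builder.mask
        _apply_noise(chars, mask, spec.substitution_rate, rng)

    sequence = "".join(chars)
    record_id = spec.record_id or _default_id(spec)
    record = ProteinRecord(id=record_id, sequence=sequence, species=spec.species)
    truth = GroundTruth(record_id=record_id, family=spec.family,
                        species=spec.species, constrained_mask=tuple(mask),
                        **truth_fields)
    for start, end, template in truth.ef_hands:
        planted = score_loop(sequence[start:end], template, scan_config)
        if planted < scan_config.threshold:
            raise AssertionError(
                f"emit-time self-check failed: planted {template} loop at "
                f"{start}..{end} scores {planted} < {scan_config.threshold}")
    return record, truth


def generate_proteome(
    specs: Sequence[tuple[ArchetypeSpec, int]],
    n_decoys: int = 0,
    decoy_length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
    decoy_species: str = "unknown",
    fasta_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[ProteinRecord], list[GroundTruth]]:
    """Concatenate archetype copies and random decoys into one proteome.

    Record ids are sequential hashes of (proteome seed, running index) and
    carry no family information; labels live only in the ground truth.
    Deterministic given (specs, seed).
    """
    records: list[ProteinRecord] = []
    truths: list[GroundTruth] = []
    index = 0

    def child(spec: ArchetypeSpec) -> tuple[ProteinRecord, GroundTruth]:
        nonlocal index
        child_seed = (seed * 1_000_003 + index) % (2**31 - 1)
        rid = "sq" + hashlib.sha1(f"{seed}:{index}".encode()).hexdigest()[:10]
        index += 1
        return generate_archetype(
            dataclasses.replace(spec, seed=child_seed, record_id=rid))

    for spec, count in specs:
        if count < 0:
            raise SpecError("archetype count must be >= 0")
        for _ in range(count):
            record, truth = child(spec)
            records.append(record)
            truths.append(truth)
    decoy_spec = ArchetypeSpec(family="DECOY", species=decoy_species,
                               decoy_length_range=decoy_length_range)
    for _ in range(n_decoys):
        record, truth = child(decoy_spec)
        records.append(record)
        truths.append(truth)

    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if truth_path is not None:
        write_truth_table(truths, truth_path)
    return records, truths


TRUTH_COLUMNS = ("record_id", "species", "family", "ef_hands", "spacers",
                 "myristoylation", "cys3", "fpsf_position", "naf_window",
                 "kinase_core")


def write_truth_table(truths: Sequence[GroundTruth], path: str | Path) -> Path:
    """Ground truth as TSV (coordinates serialized 1-based inclusive)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            hands = ";".join(f"{s + 1}-{e}:{tpl}" for s, e, tpl in t.ef_hands)
            naf = f"{t.naf_window[0] + 1}-{t.naf_window[1]}" if t.naf_window else "NA"
            core = (f"{t.kinase_core[0] + 1},{t.kinase_core[1] + 1}"
                    if t.kinase_core else "NA")
            fh.write("\t".join([
                t.record_id, t.species, t.family, hands or "NA",
                ",".join(map(str, t.spacers)) or "NA",
                str(t.myristoylation).lower(), str(t.cys3).lower(),
                str(t.fpsf_position) if t.fpsf_position else "NA", naf, core,
            ]) + "\n")
    return path


def two_species_bundle(out_dir: str | Path, seed: int = 0
                       ) -> tuple[dict[str, Path], list[GroundTruth]]:
    """The reference two-species screening fixture.

    Species A: one plant-type CBL, one CIPK and decoys; species B: four
    non-plant CBL paralogs, one CIPK, one NAF-less kinase and decoys --
    mirroring a genome with an intraspecific CBL amplification next to a
    CIPK/NAF-less-kinase pair.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteomes: dict[str, Path] = {}
    truths: list[GroundTruth] = []

    spec_a = [
        (ArchetypeSpec(family="CBL_PLANT", species="speciesA"), 1),
        (ArchetypeSpec(family="CIPK", species="speciesA"), 1),
    ]
    path_a = out_dir / "speciesA.fasta"
    recs, tr = generate_proteome(spec_a, n_decoys=8, seed=seed * 2 + 1,
                                 decoy_species="speciesA", fasta_path=path_a)
    proteomes["speciesA"] = path_a
    truths.extend(tr)

    spec_b = [
        (ArchetypeSpec(family="CBL_NONPLANT", species="speciesB"), 4),
        (ArchetypeSpec(family="CIPK", species="speciesB"), 1),
        (ArchetypeSpec(family="KINASE_NO_NAF", species="speciesB"), 1),
    ]
    path_b = out_dir / "speciesB.fasta"
    recs, tr = generate_proteome(spec_b, n_decoys=8, seed=seed * 2 + 2,
                                 decoy_species="speciesB", fasta_path=path_b)
    proteomes["speciesB"] = path_b
    truths.extend(tr)
    return proteomes, truths
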