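"""CIPK candidate identification: kinase-core check plus NAF-domain detection.

CIPK-type kinases are Ser/Thr kinases defined by the 21-residue NAF domain,
named after its invariant Asn-Ala-Phe tripeptide, which is necessary and
sufficient for binding CBL-type calcium sensors.  Detection combines a crude
catalytic-core heuristic (the HRD and DFG anchors of the catalytic loop and
activation segment at plausible spacing) with a position-specific scoring
matrix over 21-residue windows, gated by the hard invariant-tripeptide
constraint: a window without a contiguous N-A-F can never be a hit,
regardless of its profile score.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import NAFConfig
from .seq_io import AMINO_ACIDS, ProteinRecord

NAF_WINDOW = 21

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class NAFHit:
    start: int
    end: int
    naf_tripeptide_start: int  # 0-based offset of N-A-F within the window
    pssm_score: float
    invariants_satisfied: bool


@dataclass(frozen=True)
class KinaseCall:
    has_kinase_core: bool
    naf_hits: tuple[NAFHit, ...]
    verdict: str  # CIPK | KINASE_NO_NAF | NOT_KINASE


class PSSM:
    """21 x 20 log-odds matrix against a uniform residue background."""

    def __init__(self, matrix: np.ndarray):
        if matrix.shape != (NAF_WINDOW, 20):
            raise ValueError(f"PSSM must be {NAF_WINDOW} x 20, got {matrix.shape}")
        self.matrix = matrix

    def score(self, window: str) -> float:
        """Sum of per-position log-odds, in bits; the ambiguity code X scores 0."""
        if len(window) != NAF_WINDOW:
            raise ValueError(f"window must have length {NAF_WINDOW}")
        total = 0.0
        for pos, aa in enumerate(window):
            if aa == "X":
                continue
            total += self.matrix[pos, _CODE[aa]]
        return float(total)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[int(i)] for i in np.argmax(self.matrix, axis=1))


def build_naf_pssm(seed_alignment: Sequence[str], pseudocount: float = 0.1) -> PSSM:
    """Build the NAF profile from an ungapped alignment of 21-mers.

    entry(p, a) = log2((count(p, a) + pc) / (n_rows + 20 pc)) - log2(1/20).
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    for row in seed_alignment:
        if len(row) != NAF_WINDOW:
            raise ValueError(f"ragged seed alignment row {row!r} (need length {NAF_WINDOW})")
        bad = set(row) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"seed alignment row contains non-standard residues {bad}")
    counts = np.zeros((NAF_WINDOW, 20))
    for row in seed_alignment:
        for pos, aa in enumerate(row):
            counts[pos, _CODE[aa]] += 1
    n = len(seed_alignment)
    freq = (counts + pseudocount) / (n + 20 * pseudocount)
    with np.errstate(divide="ignore"):  # pseudocount 0: unseen residues -> -inf
        matrix = np.log2(freq) - math.log2(1 / 20)
    return PSSM(matrix)


def read_seed_alignment(path: str | Path) -> list[str]:
    """Read a seed alignment: one 21-mer per line, or aligned FASTA."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        rows, current = [], []
        for line in text.splitlines():
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                    current = []
            else:
                current.append(line.strip())
        if current:
            rows.append("".join(current))
    else:
        rows = [line.strip() for line in text.splitlines() if line.strip()]
    return [row.upper() for row in rows]


@functools.lru_cache(maxsize=1)
def default_seed_alignment() -> tuple[str, ...]:
    """NAF-window 21-mers from the packaged synthetic CIPK archetype family.

    Generated at runtime from twelve CIPK archetypes at substitution rate 0.1
    (fixed internal seeds); users may supply their own alignment instead.
    """
    from .synthetic_data import ArchetypeSpec, generate_archetype

    rows = []
    for seed in range(101, 113):
        record, truth = generate_archetype(
            ArchetypeSpec(family="CIPK", substitution_rate=0.1, seed=seed))
        start, end = truth.naf_window
        rows.append(record.sequence[start:end])
    return tuple(rows)


@functools.lru_cache(maxsize=1)
def default_pssm(pseudocount: float = 0.1) -> PSSM:
    return build_naf_pssm(default_seed_alignment(), pseudocount=pseudocount)


def detect_kinase_core(record: ProteinRecord) -> bool:
    """Crude Ser/Thr kinase-core proxy: HRD then DFG separated by 10-60 residues.

    This only gates NAF calls; it is not a kinase annotator.
    """
    s = record.sequence
    hrd_positions = []
    i = s.find("HRD")
    while i >= 0:
        hrd_positions.append(i)
        i = s.find("HRD", i + 1)
    j = s.find("DFG")
    while j >= 0:
        for i in hrd_positions:
            gap = j - (i + 3)
            if 10 <= gap <= 60:
                return True
        j = s.find("DFG", j + 1)
    return False


def detect_naf(record: ProteinRecord, pssm: PSSM | None = None,
               config: NAFConfig | None = None) -> list[NAFHit]:
    """Detect 21-residue NAF-domain windows.

    Hard constraint first: a window is a candidate only if it contains the
    contiguous N-A-F tripeptide at a window offset inside the configured
    range.  Candidates are then PSSM-scored; windows at or above the bit
    threshold become hits, with overlaps resolved greedily by score.
    """
    config = config or NAFConfig()
    pssm = pssm or default_pssm(config.pseudocount)
    s = record.sequence
    if len(s) < NAF_WINDOW:
        return []
    candidates: list[tuple[float, int, int]] = []
    p = s.find("NAF")
    while p >= 0:
        lo = max(0, p - config.offset_max)
        hi = min(len(s) - NAF_WINDOW, p - config.offset_min)
        for start in range(lo, hi + 1):
            score = pssm.score(s[start:start + NAF_WINDOW])
            if score >= config.threshold:
                candidates.append((score, start, p - start))
        p = s.find("NAF", p + 1)
    candidates.sort(key=lambda c: (-c[0], c[1]))
    hits: list[NAFHit] = []
    occupied: list[tuple[int, int]] = []
    for score, start, rel in candidates:
        end = start + NAF_WINDOW
        if any(start < e and b < end for b, e in occupied):
            continue
        occupied.append((start, end))
        hits.append(NAFHit(start=start, end=end, naf_tripeptide_start=rel,
                           pssm_score=score, invariants_satisfied=True))
    hits.sort(key=lambda h: h.start)
    return hits


def call_kinase(record: ProteinRecord, pssm: PSSM | None = None,
                config: NAFConfig | None = None) -> KinaseCall:
    """Per-protein CIPK verdict: kinase core plus at least one NAF hit."""
    has_core = detect_kinase_core(record)
    naf_hits = tuple(detect_naf(record, pssm, config))
    if has_core and naf_hits:
        verdict = "CIPK"
    elif has_core:
        verdict = "KINASE_NO_NAF"
    else:
        verdict = "NOT_KINASE"
    return KinaseCall(has_kinase_core=has_core, naf_hits=naf_hits, verdict=verdict)
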