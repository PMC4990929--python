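"""EF-hand Ca2+-binding loop detection.

A canonical EF-hand loop spans 12 residues with six Ca2+-coordinating
positions conventionally labelled X, Y, Z, -Y, -X, -Z (X at the first loop
residue, -Z the terminal, usually bidentate, glutamate).  CBL-type sensors
carry an extended first loop produced by insertions between the X and Y
coordinates: 14 residues in plants and their closest relatives, 15 in
stramenopiles (an extra glycine plus a Q-H/N-E motif in the loop middle) and
19 in the Aphanomyces/Saprolegnia clade.  The scanner scores every window of
every enabled loop template with a simple additive scheme over the
coordinating positions and resolves overlaps greedily by score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import EFScanConfig, EFWeights
from .seq_io import AMINO_ACIDS, ProteinRecord

#: residue order used by all integer encodings; index 20 is the ambiguity code X
_ALPHABET = AMINO_ACIDS + "X"
_CODE = {aa: i for i, aa in enumerate(_ALPHABET)}

_Y_Z_SET = set("DNSTEGQ")
_MINUS_X_SET = set("DNSTEG")

#: sentinel reported as the post-loop residue when the loop ends the sequence
NO_RESIDUE = "-"


@dataclass(frozen=True)
class LoopTemplate:
    """Geometry of one EF-hand loop variant.

    ``insert_length`` counts the residues inserted between the X and Y
    coordinates relative to the canonical 12-residue loop; the remaining
    inter-coordinate spacing is canonical.
    """

    name: str
    loop_length: int
    insert_length: int

    @property
    def coord_offsets(self) -> tuple[int, int, int, int, int, int]:
        """0-based offsets of X, Y, Z, -Y, -X, -Z within the loop window."""
        ins = self.insert_length
        return (0, 2 + ins, 4 + ins, 6 + ins, 8 + ins, self.loop_length - 1)

    def __post_init__(self) -> None:
        offs = self.coord_offsets
        assert offs[0] == 0 and offs[-1] == self.loop_length - 1
        assert all(a < b for a, b in zip(offs, offs[1:])), "offsets must increase"


TEMPLATES: dict[str, LoopTemplate] = {
    "L12": LoopTemplate("L12", 12, 0),
    "L14": LoopTemplate("L14", 14, 2),
    "L15": LoopTemplate("L15", 15, 3),
    "L19": LoopTemplate("L19", 19, 7),
}

#: window offsets (start..start+2 of the triplet) searched for Q-[HN]-E in
#: the middle part of an L15 loop
QHE_OFFSET_RANGE = (4, 8)


@dataclass(frozen=True)
class EFHandHit:
    """One detected Ca2+-binding loop with its coordinating-residue report."""

    loop_start: int
    loop_end: int
    template: str
    x_res: str
    y_res: str
    z_res: str
    minus_y_res: str
    minus_x_res: str
    minus_z_res: str
    post_minus_z_res: str
    qhe_motif: bool
    insert_has_g: bool
    score: float


def _term_tables(weights: EFWeights, template: LoopTemplate) -> dict[str, np.ndarray]:
    """Per-residue lookup tables (length 21; X scores 0 at every position)."""
    n = len(_ALPHABET)
    anchor = np.full(n, weights.anchor_other)
    anchor[_CODE["E"]] = weights.anchor_e
    anchor[_CODE["D"]] = weights.anchor_d

    x_term = np.full(n, weights.x_other)
    x_term[_CODE["D"]] = weights.x_strong
    x_term[_CODE["S"]] = weights.x_strong
    x_term[_CODE["N"]] = weights.x_n
    if template.name == "L15":
        x_term[_CODE["A"]] = weights.x_a_l15
        x_term[_CODE["L"]] = weights.x_l_l15

    y_term = np.zeros(n)
    z_term = np.zeros(n)
    for aa in _Y_Z_SET:
        y_term[_CODE[aa]] = weights.y_coord
        z_term[_CODE[aa]] = weights.z_coord
    mx_term = np.zeros(n)
    for aa in _MINUS_X_SET:
        mx_term[_CODE[aa]] = weights.minus_x

    for table in (anchor, x_term, y_term, z_term, mx_term):
        table[_CODE["X"]] = 0.0
    return {"anchor": anchor, "x": x_term, "y": y_term, "z": z_term, "mx": mx_term}


def encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in sequence), dtype=np.int64, count=len(sequence))


def _l15_flags(codes: np.ndarray, starts: np.ndarray, template: LoopTemplate
               ) -> tuple[np.ndarray, np.ndarray]:
    """(insert_has_g, qhe_motif) booleans for each candidate L15 window start."""
    y_off = template.coord_offsets[1]
    is_g = codes == _CODE["G"]
    has_g = np.zeros(len(starts), dtype=bool)
    for off in range(1, y_off):
        has_g |= is_g[starts + off]

    is_q = codes == _CODE["Q"]
    is_hn = (codes == _CODE["H"]) | (codes == _CODE["N"])
    is_e = codes == _CODE["E"]
    qhe_at = np.zeros(len(codes), dtype=bool)
    if len(codes) >= 3:
        qhe_at[: len(codes) - 2] = is_q[:-2] & is_hn[1:-1] & is_e[2:]
    qhe = np.zeros(len(starts), dtype=bool)
    lo, hi = QHE_OFFSET_RANGE
    for off in range(lo, hi + 1):
        qhe |= qhe_at[starts + off]
    return has_g, qhe


def _window_scores(codes: np.ndarray, template: LoopTemplate, weights: EFWeights
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scores for every window start of one template.

    Returns (starts, scores, insert_has_g, qhe) arrays; the two flag arrays
    are all-False except for L15 windows.
    """
    n_starts = len(codes) - template.loop_length + 1
    if n_starts <= 0:
        empty = np.empty(0)
        return np.empty(0, dtype=np.int64), empty, empty.astype(bool), empty.astype(bool)
    starts = np.arange(n_starts)
    t = _term_tables(weights, template)
    x_off, y_off, z_off, _, mx_off, mz_off = template.coord_offsets
    scores = (
        t["anchor"][codes[starts + mz_off]]
        + t["x"][codes[starts + x_off]]
        + t["y"][codes[starts + y_off]]
        + t["z"][codes[starts + z_off]]
        + t["mx"][codes[starts + mx_off]]
    )
    if template.name == "L15":
        has_g, qhe = _l15_flags(codes, starts, template)
        scores = scores + weights.l15_g_bonus * has_g + weights.l15_qhe_bonus * qhe
    else:
        has_g = np.zeros(n_starts, dtype=bool)
        qhe = np.zeros(n_starts, dtype=bool)
    return starts, scores, has_g, qhe


def score_loop(window: str, template: LoopTemplate | str, config: EFScanConfig | None = None
               ) -> float:
    """Score one loop-length window under the additive scheme."""
    if isinstance(template, str):
        template = TEMPLATES[template]
    if len(window) != template.loop_length:
        raise ValueError(
            f"window length {len(window)} != template {template.name} "
            f"loop length {template.loop_length}"
        )
    config = config or EFScanConfig()
    _, scores, _, _ = _window_scores(encode(window), template, config.weights)
    return float(scores[0])


def _build_hit(sequence: str, start: int, template: LoopTemplate, score: float,
               has_g: bool, qhe: bool) -> EFHandHit:
    offs = template.coord_offsets
    end = start + template.loop_length
    res = [sequence[start + o] for o in offs]
    post = sequence[end] if end < len(sequence) else NO_RESIDUE
    return EFHandHit(
        loop_start=start, loop_end=end, template=template.name,
        x_res=res[0], y_res=res[1], z_res=res[2], minus_y_res=res[3],
        minus_x_res=res[4], minus_z_res=res[5], post_minus_z_res=post,
        qhe_motif=qhe, insert_has_g=has_g, score=score,
    )


def scan_ef_hands(record: ProteinRecord, config: EFScanConfig | None = None
                  ) -> list[EFHandHit]:
    """Scan one protein for EF-hand loops over all enabled templates.

    Every window of every enabled template is scored; windows at or above the
    threshold are resolved to a non-overlapping set greedily by
    (score descending, start ascending, loop length ascending), capped at
    ``max_hits``, and returned sorted by loop start.
    """
    config = config or EFScanConfig()
    codes = encode(record.sequence)
    candidates: list[tuple[float, int, int, LoopTemplate, bool, bool]] = []
    for name in config.templates:
        template = TEMPLATES[name]
        starts, scores, has_g, qhe = _window_scores(codes, template, config.weights)
        keep = np.nonzero(scores >= config.threshold)[0]
        for i in keep:
            candidates.append((float(scores[i]), int(starts[i]),
                               template.loop_length, template, bool(has_g[i]), bool(qhe[i])))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[tuple[float, int, LoopTemplate, bool, bool]] = []
    occupied: list[tuple[int, int]] = []
    for score, start, loop_len, template, g, q in candidates:
        if len(accepted) >= config.max_hits:
            break
        end = start + loop_len
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        accepted.append((score, start, template, g, q))
    accepted.sort(key=lambda a: a[1])
    return [_build_hit(record.sequence, start, template, score, g, q)
            for score, start, template, g, q in accepted]


def check_hits_sorted(hits: Sequence[EFHandHit]) -> None:
    """Contract check: hits sorted by start and non-overlapping."""
    for prev, cur in zip(hits, hits[1:]):
        if cur.loop_start < prev.loop_end:
            raise ValueError(
                f"hits overlap or are unsorted at positions {prev.loop_start}..{prev.loop_end} "
                f"and {cur.loop_start}..{cur.loop_end}"
            )


def compute_spacers(hits: Sequence[EFHandHit]) -> list[int]:
    """Residue counts strictly between consecutive loops."""
    check_hits_sorted(hits)
    return [nxt.loop_start - cur.loop_end for cur, nxt in zip(hits, hits[1:])]
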