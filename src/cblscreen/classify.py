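"""Family classification of EF-hand-bearing Ca2+ sensors.

The decision logic mirrors the structural hallmarks that separate the
calcium-sensor families: CaM-type and CNB/NCS-type proteins keep the
canonical 12-residue first loop with aspartate at X (distinguished by the
residue following the -Z anchor: leucine in CaMs, phenylalanine otherwise),
while genuine CBL-type sensors carry an extended first loop -- 14 residues
with serine at X in plants and their relatives, 15 residues with leucine at
X (plus an inserted glycine and a Q-H/N-E motif) in stramenopiles, 19
residues in the Aphanomyces/Saprolegnia clade, and a degenerate 14/15-residue
variant with alanine at X.  Plant CBLs are additionally distinguished by the
invariant 23-residue EF1-EF2 spacer and an N-terminal membrane-targeting
motif (MGXXXS/T N-myristoylation or a palmitoylated cysteine at position 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import ClassifyConfig
from .efhand import EFHandHit, check_hits_sorted, compute_spacers
from .seq_io import ProteinRecord

FAMILIES = (
    "CAM_LIKE", "CNB_NCS_LIKE", "CBL_PLANT", "CBL_NONPLANT",
    "CBL_STRAMENOPILE", "CBL_EXTENDED", "CBL_DEGENERATE", "UNCLASSIFIED",
)

#: plant EF1-EF2 spacer length, invariant in land plants
PLANT_SPACER = 23


@dataclass(frozen=True)
class LipidMotifAnnotation:
    myristoylation: bool
    cys3: bool
    n_cys_nterm: int


@dataclass(frozen=True)
class SensorClassification:
    family: str
    n_ef_hands: int
    ef1_template: Optional[str]
    x_residue: Optional[str]
    post_minus_z: Optional[str]
    spacer12: Optional[int]
    lipid: LipidMotifAnnotation
    fpsf_position: Optional[int]
    evidence: tuple[str, ...] = ()


def detect_lipid_motifs(record: ProteinRecord, nterm_window: int = 30) -> LipidMotifAnnotation:
    """N-terminal lipid-modification motifs.

    Myristoylation requires the MGXXXS/T pattern anchored at residue 1;
    ``cys3`` reports the conserved palmitoylatable cysteine at position 3;
    ``n_cys_nterm`` counts cysteines in the first ``nterm_window`` residues.
    """
    if nterm_window < 6:
        raise ValueError("nterm_window must be at least 6")
    s = record.sequence
    myr = len(s) >= 6 and s[0] == "M" and s[1] == "G" and s[5] in "ST"
    cys3 = len(s) >= 3 and s[2] == "C"
    return LipidMotifAnnotation(myristoylation=myr, cys3=cys3,
                                n_cys_nterm=s[:nterm_window].count("C"))


def detect_fpsf(record: ProteinRecord, cterm_window: int = 40) -> Optional[int]:
    """1-based start of the last FPSF motif within the C-terminal window."""
    if cterm_window < 4:
        raise ValueError("cterm_window must be at least 4")
    s = record.sequence
    tail_start = max(0, len(s) - cterm_window)
    idx = s.rfind("FPSF", tail_start)
    return idx + 1 if idx >= 0 else None


def classify_sensor(record: ProteinRecord, hits: Sequence[EFHandHit],
                    config: ClassifyConfig | None = None) -> SensorClassification:
    """Assign a Ca2+-sensor family from the detected EF-hands.

    Only the first four hits participate in the rules (the families in
    question have exactly four EF-hands; later hits are reported in
    ``n_ef_hands`` but otherwise ignored).  The rules fire in order; the
    evidence list records every rule consulted.
    """
    config = config or ClassifyConfig()
    check_hits_sorted(hits)
    lipid = detect_lipid_motifs(record, config.nterm_window)
    fpsf = detect_fpsf(record, config.cterm_window)
    considered = list(hits[:4])
    n = len(hits)
    ef1 = considered[0] if considered else None
    spacers = compute_spacers(considered) if len(considered) >= 2 else []
    spacer12 = spacers[0] if spacers else None
    evidence: list[str] = []

    def result(family: str) -> SensorClassification:
        return SensorClassification(
            family=family, n_ef_hands=n,
            ef1_template=ef1.template if ef1 else None,
            x_residue=ef1.x_res if ef1 else None,
            post_minus_z=ef1.post_minus_z_res if ef1 else None,
            spacer12=spacer12, lipid=lipid, fpsf_position=fpsf,
            evidence=tuple(evidence),
        )

    # rule 1: fewer than two EF-hands cannot be a four-hand sensor
    if n < 2:
        evidence.append(f"rule1: {n} EF-hand(s) detected, need >= 2 -> UNCLASSIFIED")
        return result("UNCLASSIFIED")
    evidence.append(f"rule1: {n} EF-hand(s) detected")

    # rule 2: canonical first loop with D at X -> CaM vs CNB/NCS by post--Z residue
    if ef1.template == "L12" and ef1.x_res == "D":
        if ef1.post_minus_z_res == "L":
            evidence.append("rule2: EF1=L12, X=D, post-Z=L (CaM hallmark)")
            return result("CAM_LIKE")
        if ef1.post_minus_z_res == "F":
            evidence.append("rule2: EF1=L12, X=D, post-Z=F (CNB/NCS hallmark)")
            return result("CNB_NCS_LIKE")
        evidence.append(
            f"rule2: EF1=L12, X=D, post-Z={ef1.post_minus_z_res} "
            "(neither L nor F; low-confidence CNB/NCS call)"
        )
        return result("CNB_NCS_LIKE")
    evidence.append("rule2: not a canonical D-at-X L12 first loop")

    # rule 3: 14-residue first loop with S at X -> genuine CBL; plant when the
    # invariant spacer and a membrane-targeting motif are both present
    if ef1.template == "L14" and ef1.x_res == "S":
        if spacer12 == PLANT_SPACER and (lipid.myristoylation or lipid.cys3):
            evidence.append(
                f"rule3: EF1=L14, X=S, spacer12={spacer12}, lipid motif present -> plant CBL"
            )
            return result("CBL_PLANT")
        evidence.append(
            f"rule3: EF1=L14, X=S, spacer12={spacer12}, "
            f"myristoylation={lipid.myristoylation}, cys3={lipid.cys3} -> non-plant CBL"
        )
        return result("CBL_NONPLANT")
    evidence.append("rule3: not an S-at-X L14 first loop")

    # rule 4: stramenopile 15-residue loop: S->L exchange with inserted G / QHE motif
    if ef1.template == "L15" and ef1.x_res == "L" and (ef1.qhe_motif or ef1.insert_has_g):
        evidence.append(
            f"rule4: EF1=L15, X=L, insert_has_g={ef1.insert_has_g}, "
            f"qhe={ef1.qhe_motif} -> stramenopile CBL"
        )
        return result("CBL_STRAMENOPILE")
    evidence.append("rule4: not a stramenopile L15 first loop")

    # rule 5: 19-residue loop (Aphanomyces/Saprolegnia clade)
    if ef1.template == "L19":
        evidence.append("rule5: EF1=L19 -> extended-loop CBL")
        return result("CBL_EXTENDED")
    evidence.append("rule5: EF1 not L19")

    # rule 6: degenerate S->A exchange at X (TvCBL3/4-like)
    if ef1.template in ("L14", "L15") and ef1.x_res == "A":
        evidence.append(f"rule6: EF1={ef1.template}, X=A -> degenerate CBL")
        return result("CBL_DEGENERATE")
    evidence.append("rule6: not an A-at-X extended loop")

    # rule 7: divergent four-hand protein with the invariant post--Z F
    if ef1.post_minus_z_res == "F" and n >= 4:
        evidence.append(
            "rule7: post-Z=F with >= 4 EF-hands; low-confidence non-plant CBL call"
        )
        return result("CBL_NONPLANT")
    evidence.append("rule7: no fallback applies -> UNCLASSIFIED")
    return result("UNCLASSIFIED")
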