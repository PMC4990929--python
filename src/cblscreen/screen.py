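"""The multilevel screen over one or many proteomes.

Per proteome, the sensor arm runs a local-alignment prefilter against a
CBL query (the in-repo replacement for a BLASTp prescreen), then the
EF-hand scanner and the family classifier on the survivors; the kinase arm
runs the kinase-core check and NAF detection on the full proteome (kinases
do not resemble the sensor query, so they skip the prefilter).  All
CBL-classified sequences are pooled across species into a distance matrix,
a neighbor-joining tree and an intraspecific-amplification report, and a
per-species family census is assembled.  Identical inputs and configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy

from . import seq_io
from .classify import SensorClassification, classify_sensor
from .config import ScreenConfig
from .efhand import scan_ef_hands
from .kinase import KinaseCall, call_kinase, default_pssm
from .phylo import detect_amplification, distance_matrix, nj_tree
from .seq_io import ProteinRecord, to_one_based
from .synthetic_data import ArchetypeSpec, generate_archetype

CBL_FAMILIES = ("CBL_PLANT", "CBL_NONPLANT", "CBL_STRAMENOPILE",
                "CBL_EXTENDED", "CBL_DEGENERATE")
SENSOR_COUNT_FAMILIES = ("CAM_LIKE", "CNB_NCS_LIKE") + CBL_FAMILIES

#: annotation value for proteins that did not survive the sensor prefilter
NOT_SCREENED = "NOT_SCREENED"


@functools.lru_cache(maxsize=1)
def default_query() -> ProteinRecord:
    """Default prefilter query: the zero-noise plant-CBL archetype."""
    record, _ = generate_archetype(
        ArchetypeSpec(family="CBL_PLANT", substitution_rate=0.0, seed=0,
                      record_id="query"))
    return record


def prefilter_candidates(query: ProteinRecord, proteome: Sequence[ProteinRecord],
                         config: ScreenConfig | None = None) -> list[ProteinRecord]:
    """Retain proteins whose best Smith-Waterman score against the query
    reaches the configured fraction of the query self-score; order preserved."""
    from .phylo import local_align_score

    config = config or ScreenConfig()
    self_score = local_align_score(query.sequence, query.sequence, config.align)
    threshold = config.prefilter.score_fraction * self_score
    return [rec for rec in proteome
            if local_align_score(query.sequence, rec.sequence, config.align) >= threshold]


@dataclass
class ScreenResult:
    annotations: list[dict]
    inventory: list[dict]
    tree: Optional[dendropy.Tree]
    amplified: list[tuple[str, tuple[str, ...]]]
    log: list[str]
    output_paths: dict[str, Path] = field(default_factory=dict)


def _annotation_row(record: ProteinRecord,
                    classification: Optional[SensorClassification],
                    hits, kinase_call: KinaseCall) -> dict:
    row: dict = {"id": record.id, "species": record.species}
    if classification is None:
        row.update({"family": NOT_SCREENED, "n_ef_hands": None,
                    "ef1_template": None, "ef1_start": None, "ef1_end": None,
                    "ef1_score": None, "x_residue": None, "post_minus_z": None,
                    "spacer12": None, "myristoylation": None, "cys3": None,
                    "n_cys_nterm": None, "fpsf_position": None})
    else:
        ef1 = hits[0] if hits else None
        start, end = to_one_based(ef1.loop_start, ef1.loop_end) if ef1 else (None, None)
        row.update({
            "family": classification.family,
            "n_ef_hands": classification.n_ef_hands,
            "ef1_template": classification.ef1_template,
            "ef1_start": start, "ef1_end": end,
            "ef1_score": ef1.score if ef1 else None,
            "x_residue": classification.x_residue,
            "post_minus_z": classification.post_minus_z,
            "spacer12": classification.spacer12,
            "myristoylation": classification.lipid.myristoylation,
            "cys3": classification.lipid.cys3,
            "n_cys_nterm": classification.lipid.n_cys_nterm,
            "fpsf_position": classification.fpsf_position,
        })
    best_naf = max((h.pssm_score for h in kinase_call.naf_hits), default=None)
    row.update({
        "naf_present": bool(kinase_call.naf_hits),
        "naf_score": best_naf,
        "kinase_verdict": kinase_call.verdict,
    })
    return row


INVENTORY_COLUMNS = (
    ("species",)
    + tuple(f"n_{fam}" for fam in SENSOR_COUNT_FAMILIES)
    + ("n_CBL_total", "n_CIPK", "n_KINASE_NO_NAF", "amplification")
)


def run_screen(proteomes: Mapping[str, str | Path],
               config: ScreenConfig | None = None,
               out_dir: str | Path | None = None,
               query: ProteinRecord | None = None) -> ScreenResult:
    """Run the full multilevel screen and assemble the per-species census."""
    config = config or ScreenConfig()
    query = query or default_query()
    pssm = default_pssm(config.naf.pseudocount)
    log: list[str] = [f"seed={config.seed} config={config.config_hash()}"]
    annotations: list[dict] = []
    species_records: dict[str, list[ProteinRecord]] = {}
    species_rows: dict[str, list[dict]] = {}
    cbl_records: list[ProteinRecord] = []
    species_of: dict[str, str] = {}

    for species in sorted(proteomes):
        path = proteomes[species]
        try:
            records = seq_io.read_fasta(path, species_hint=species)
        except (OSError, seq_io.FastaError) as exc:
            log.append(f"ERROR species={species}: {exc}")
            continue
        log.append(f"species={species} n_records={len(records)}")
        survivors = {r.id for r in prefilter_candidates(query, records, config)}
        log.append(f"species={species} prefilter_survivors={len(survivors)}")
        rows = []
        for record in records:
            kin = call_kinase(record, pssm, config.naf)
            if record.id in survivors:
                hits = scan_ef_hands(record, config.efscan)
                cls = classify_sensor(record, hits, config.classify)
                if cls.family in CBL_FAMILIES:
                    cbl_records.append(record)
                    species_of[record.id] = species
            else:
                hits, cls = [], None
            rows.append(_annotation_row(record, cls, hits, kin))
        species_records[species] = records
        species_rows[species] = rows
        annotations.extend(rows)

    tree = None
    amplified: list[tuple[str, tuple[str, ...]]] = []
    if len(cbl_records) >= 3:
        dm = distance_matrix(cbl_records, config.align)
        tree = nj_tree(dm)
        amplified = detect_amplification(tree, species_of)
    elif cbl_records:
        log.append(f"tree skipped: only {len(cbl_records)} CBL sequence(s)")
    amplified_species = {s for s, _ in amplified}

    inventory: list[dict] = []
    for species in sorted(species_rows):
        rows = species_rows[species]
        row: dict = {"species": species}
        for fam in SENSOR_COUNT_FAMILIES:
            row[f"n_{fam}"] = sum(1 for r in rows if r["family"] == fam)
        row["n_CBL_total"] = sum(row[f"n_{fam}"] for fam in CBL_FAMILIES)
        row["n_CIPK"] = sum(1 for r in rows if r["kinase_verdict"] == "CIPK")
        row["n_KINASE_NO_NAF"] = sum(
            1 for r in rows if r["kinase_verdict"] == "KINASE_NO_NAF")
        row["amplification"] = species in amplified_species
        inventory.append(row)

    result = ScreenResult(annotations=annotations, inventory=inventory,
                          tree=tree, amplified=amplified, log=log)
    if out_dir is not None:
        result.output_paths = _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: ScreenResult, config: ScreenConfig, out_dir: Path
                   ) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = [f"seed={config.seed} config={config.config_hash()}"]
    paths: dict[str, Path] = {}
    fmt = config.output_format
    ext = "json" if fmt == "json" else "tsv"
    paths["annotations"] = seq_io.write_annotations(
        result.annotations, out_dir / f"annotations.{ext}", format=fmt,
        header_comments=stamp)
    paths["inventory"] = seq_io.write_annotations(
        result.inventory, out_dir / "inventory.tsv", format="tsv",
        columns=INVENTORY_COLUMNS, header_comments=stamp)
    amp_rows = [{"species": s, "n_genes": len(leaves),
                 "clade_members": ",".join(leaves)}
                for s, leaves in result.amplified]
    paths["amplification"] = seq_io.write_annotations(
        amp_rows, out_dir / "amplification.tsv", format="tsv",
        columns=("species", "n_genes", "clade_members"), header_comments=stamp)
    if result.tree is not None:
        paths["tree"] = seq_io.write_newick(result.tree, out_dir / "cbl_tree.nwk")
    log_path = out_dir / "run_log.txt"
    log_path.write_text("".join(line + "\n" for line in result.log))
    paths["log"] = log_path
    return paths
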