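"""End-to-end orchestration: run config → stage execution → reports.

A run config (YAML) lists the structures to analyze (path, id, taxon,
species, chain, experimental/predicted), the triad-annotation config,
the reference structure for superposition, core cutoffs, and optional
alignment/sequence inputs.  Stages are independently skippable: a run
without an alignment simply omits the conservation report and logs the
skip.  Every report is written as a TSV/JSON twin with a provenance
block (config hash, seed, package version), and re-running an unchanged
config reproduces all numeric content exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .backbone import (
    assign_secondary_structure,
    backbone_dihedrals,
    count_ss_elements,
    ramachandran_report,
    write_ramachandran_report,
)
from .composition import (
    composition_profile,
    flag_outliers,
    read_fasta_sequences,
    write_composition_report,
)
from .conservation import (
    conservation_table,
    progressive_align,
    read_alignment,
    write_conservation_report,
)
from .structure_io import (
    extract_ca_trace,
    load_triad_annotations,
    read_pdb,
    sequence_from_structure,
)
from .superpose import (
    CUTOFF_PREDICTED,
    CUTOFF_XRAY,
    CoreNotConvergedError,
    align_sequences_pairwise,
    detect_conserved_core,
    write_superposition_report,
)
from .triad import (
    round_half_away,
    summarize_triads,
    triad_ca_distances,
    write_triad_report,
)

logger = logging.getLogger("triadcore")

__all__ = ["StructureEntry", "RunConfig", "load_run_config", "run_pipeline"]


@dataclass
class StructureEntry:
    path: Path
    id: str
    taxa: str = ""
    species: str = ""
    chain: str | None = None    # None -> first chain in file order
    source: str = "experimental"


@dataclass
class RunConfig:
    structures: list[StructureEntry]
    report_dir: Path
    reference: str | None = None
    triad_config: Path | None = None
    alignment: Path | None = None
    alignment_format: str = "fasta"
    build_alignment: bool = False
    reference_sequence_id: str | None = None
    first_number: int = 1
    sequences: Path | None = None
    core_cutoff_experimental: float = CUTOFF_XRAY
    core_cutoff_predicted: float = CUTOFF_PREDICTED
    medium_threshold: float = 60.0
    ndigits: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not self.structures:
            raise ValueError("run config lists no structures")
        ids = [e.id for e in self.structures]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate structure ids in run config")
        if self.reference is not None and self.reference not in ids:
            raise ValueError(f"reference {self.reference!r} is not a listed structure")
        for entry in self.structures:
            if not entry.path.exists():
                raise FileNotFoundError(entry.path)
            if entry.source not in ("experimental", "predicted", "synthetic"):
                raise ValueError(f"{entry.id}: unknown source {entry.source!r}")
        for path in (self.triad_config, self.alignment, self.sequences):
            if path is not None and not path.exists():
                raise FileNotFoundError(path)
        if min(self.core_cutoff_experimental, self.core_cutoff_predicted) <= 0:
            raise ValueError("core cutoffs must be positive")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    entries = [
        StructureEntry(
            path=resolve(e["path"]),
            id=str(e["id"]),
            taxa=e.get("taxa", ""),
            species=e.get("species", ""),
            chain=e.get("chain"),
            source=e.get("source", "experimental"),
        )
        for e in doc.get("structures", [])
    ]
    cfg = RunConfig(
        structures=entries,
        report_dir=resolve(doc.get("report_dir", "reports")),
        reference=doc.get("reference"),
        triad_config=resolve(doc.get("triad_config")),
        alignment=resolve(doc.get("alignment")),
        alignment_format=doc.get("alignment_format", "fasta"),
        build_alignment=bool(doc.get("build_alignment", False)),
        reference_sequence_id=doc.get("reference_sequence_id"),
        first_number=int(doc.get("first_number", 1)),
        sequences=resolve(doc.get("sequences")),
        core_cutoff_experimental=float(doc.get("core_cutoff_experimental", CUTOFF_XRAY)),
        core_cutoff_predicted=float(doc.get("core_cutoff_predicted", CUTOFF_PREDICTED)),
        medium_threshold=float(doc.get("medium_threshold", 60.0)),
        ndigits=int(doc.get("ndigits", 1)),
        seed=int(doc.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "structures": [[str(e.path), e.id, e.chain, e.source] for e in config.structures],
            "reference": config.reference,
            "cutoffs": [config.core_cutoff_experimental, config.core_cutoff_predicted],
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"provenance": _provenance(config), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the file manifest + summary."""
    config.validate()
    outdir = config.report_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {}

    # --- stage: structure loading -----------------------------------------
    loaded = {}
    for entry in config.structures:
        st = read_pdb(entry.path, structure_id=entry.id, source=entry.source)
        chain_id = entry.chain or st.default_chain.chain_id
        trace = extract_ca_trace(st, chain_id)
        seq = sequence_from_structure(st, chain_id)
        loaded[entry.id] = (entry, st, chain_id, trace, seq)
        logger.info("load %s: chain %s, %d residues (%d without CA)",
                    entry.id, chain_id, len(trace) + trace.n_skipped, trace.n_skipped)

    # --- stage: superposition vs reference --------------------------------
    if config.reference is not None:
        ref_entry, ref_st, ref_chain, ref_trace, ref_seq = loaded[config.reference]
        rows = []
        for sid, (entry, st, chain_id, trace, seq) in loaded.items():
            cutoff = (config.core_cutoff_predicted if entry.source == "predicted"
                      else config.core_cutoff_experimental)
            corr = align_sequences_pairwise(seq, ref_seq)
            try:
                result = detect_conserved_core(trace, ref_trace, corr, cutoff=cutoff)
                rows.append({
                    "id": sid, "taxa": entry.taxa, "species": entry.species,
                    "superposed_percent": round_half_away(result.superposed_percent, 2),
                    "rmsd": round_half_away(result.rmsd, 3),
                    "n_core": result.n_pairs, "cutoff": cutoff,
                })
                logger.info("superpose %s -> %s: %.1f%% core, rmsd %.3f",
                            sid, config.reference, result.superposed_percent, result.rmsd)
            except CoreNotConvergedError as exc:
                rows.append({"id": sid, "taxa": entry.taxa, "species": entry.species,
                             "superposed_percent": float("nan"), "rmsd": float("nan"),
                             "error": str(exc)})
                logger.warning("superpose %s: %s", sid, exc)
        path = write_superposition_report(rows, outdir / "superposition.tsv")
        manifest["superposition_tsv"] = str(path)
        jpath = outdir / "superposition.json"
        _write_json(jpath, {"reference": config.reference, "rows": rows}, config)
        manifest["superposition_json"] = str(jpath)
        summary["superposition"] = rows
    else:
        logger.info("superposition skipped: no reference structure configured")

    # --- stage: triad geometry --------------------------------------------
    if config.triad_config is not None:
        annotations = load_triad_annotations(config.triad_config)
        triad_rows = []
        by_source: dict[str, list] = {}
        for sid, (entry, st, chain_id, trace, seq) in loaded.items():
            if sid not in annotations:
                logger.info("triad %s: no annotation, skipped", sid)
                continue
            geom = triad_ca_distances(st, annotations[sid])
            triad_rows.append({"id": sid, "taxa": entry.taxa,
                               "species": entry.species, "source": entry.source,
                               "geometry": geom})
            by_source.setdefault(entry.source, []).append(geom)
            logger.info("triad %s: D-H %.1f, H-S %.1f, S-D %.1f",
                        sid, *geom.rounded(config.ndigits))
        summaries = {src: summarize_triads(geoms) for src, geoms in by_source.items()}
        path = write_triad_report(triad_rows, summaries,
                                  outdir / "triads.tsv", ndigits=config.ndigits)
        manifest["triads_tsv"] = str(path)
        jpath = outdir / "triads.json"
        _write_json(jpath, {
            "rows": [
                {"id": r["id"], "taxa": r["taxa"], "species": r["species"],
                 "source": r["source"],
                 "d_dh": r["geometry"].d_dh, "d_hs": r["geometry"].d_hs,
                 "d_sd": r["geometry"].d_sd}
                for r in triad_rows
            ],
            "summaries": {
                src: {"n": s.n,
                      "mean_dh": s.mean_dh, "mean_hs": s.mean_hs, "mean_sd": s.mean_sd,
                      "sd_dh": s.sd_dh, "sd_hs": s.sd_hs, "sd_sd": s.sd_sd,
                      "sd_convention": "sample (n-1)"}
                for src, s in summaries.items()
            },
        }, config)
        manifest["triads_json"] = str(jpath)
        summary["triads"] = {src: s.rounded_means(config.ndigits)
                             for src, s in summaries.items()}
    else:
        logger.info("triad stage skipped: no triad config")

    # --- stage: conservation ----------------------------------------------
    aln = None
    if config.alignment is not None:
        aln = read_alignment(config.alignment, config.alignment_format)
    elif config.build_alignment:
        seqs = {sid: tup[4] for sid, tup in loaded.items()}
        if len(seqs) >= 2:
            aln = progressive_align(seqs)
    if aln is not None:
        ref_id = config.reference_sequence_id
        if ref_id is not None and ref_id not in aln.ids:
            raise ValueError(f"reference sequence {ref_id!r} not in alignment")
        profiles = conservation_table(
            aln, reference_id=ref_id, first_number=config.first_number,
            medium_threshold=config.medium_threshold,
        )
        path = write_conservation_report(profiles, outdir / "conservation.tsv")
        manifest["conservation_tsv"] = str(path)
        jpath = outdir / "conservation.json"
        _write_json(jpath, {
            "n_rows": aln.n_rows,
            "medium_threshold": config.medium_threshold,
            "columns": [
                {"column": p.column, "ref_number": p.ref_number,
                 "ref_residue": p.ref_residue, "modal_residue": p.modal_residue,
                 "occupancy_pct": p.occupancy_pct, "category": p.category}
                for p in profiles
            ],
        }, config)
        manifest["conservation_json"] = str(jpath)
        summary["conservation"] = {"n_columns": aln.length, "n_rows": aln.n_rows}
        logger.info("conservation: %d columns over %d rows", aln.length, aln.n_rows)
    else:
        logger.info("conservation skipped: no alignment supplied or built")

    # --- stage: composition -------------------------------------------------
    if config.sequences is not None:
        seqs = read_fasta_sequences(config.sequences)
    else:
        seqs = {sid: tup[4] for sid, tup in loaded.items()}
    profiles = [composition_profile(seq, sid) for sid, seq in seqs.items()]
    if len(profiles) >= 3:
        outliers = flag_outliers(profiles)
        path = write_composition_report(profiles, outliers,
                                        outdir / "composition.tsv")
        manifest["composition_tsv"] = str(path)
        jpath = outdir / "composition.json"
        _write_json(jpath, {
            "profiles": [
                {"sequence_id": p.sequence_id, "length": p.length,
                 "class_pct": p.class_pct}
                for p in profiles
            ],
            "outliers": {
                cls: [{"sequence_id": sid, "value": v, "mean": m, "sd": s}
                      for sid, v, m, s in hits]
                for cls, hits in outliers.flags.items()
            },
        }, config)
        manifest["composition_json"] = str(jpath)
        summary["composition_outliers"] = {
            cls: outliers.flagged_ids(cls) for cls in outliers.flags
        }
        logger.info("composition: %d profiles, %d classes flagged",
                    len(profiles), len(outliers.flags))
    else:
        logger.info("composition outlier stage skipped: fewer than 3 sequences")

    # --- stage: backbone QC --------------------------------------------------
    rama_reports = {}
    ss_rows = []
    for sid, (entry, st, chain_id, trace, seq) in loaded.items():
        has_backbone = any(
            all(a in r.atoms for a in ("N", "CA", "C"))
            for r in st.chain(chain_id).residues
        )
        if has_backbone:
            try:
                records, skipped = backbone_dihedrals(st, chain_id)
                rama_reports[sid] = ramachandran_report(records)
            except ValueError as exc:
                logger.warning("ramachandran %s: %s", sid, exc)
        else:
            logger.info("ramachandran %s: Cα-only model, skipped", sid)
        if len(trace) >= 5:
            states = assign_secondary_structure(trace.coords)
            counts = count_ss_elements(states)
            ss_rows.append({"id": sid, "n_helices": counts.n_helices,
                            "n_strands": counts.n_strands, "states": counts.states})
            logger.info("secondary structure %s: %d helices, %d strands",
                        sid, counts.n_helices, counts.n_strands)
    if rama_reports:
        path = write_ramachandran_report(rama_reports, outdir / "ramachandran.tsv")
        manifest["ramachandran_tsv"] = str(path)
        jpath = outdir / "ramachandran.json"
        _write_json(jpath, {
            "reports": {
                sid: {"counts": rep.counts, "percentages": rep.percentages,
                      "n_assessed": rep.n_assessed, "n_excluded": rep.n_excluded}
                for sid, rep in rama_reports.items()
            },
        }, config)
        manifest["ramachandran_json"] = str(jpath)
        summary["ramachandran"] = {sid: rep.counts for sid, rep in rama_reports.items()}
    if ss_rows:
        path = outdir / "secondary_structure.tsv"
        with path.open("w") as fh:
            fh.write("id\tn_helices\tn_strands\tstates\n")
            for row in ss_rows:
                fh.write(f"{row['id']}\t{row['n_helices']}\t{row['n_strands']}\t{row['states']}\n")
        manifest["secondary_structure_tsv"] = str(path)
        jpath = outdir / "secondary_structure.json"
        _write_json(jpath, {"rows": ss_rows}, config)
        manifest["secondary_structure_json"] = str(jpath)
        summary["secondary_structure"] = {
            row["id"]: (row["n_helices"], row["n_strands"]) for row in ss_rows
        }

    mpath = outdir / "manifest.json"
    _write_json(mpath, {"files": manifest}, config)
    return {"manifest": manifest, "summary": summary}
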