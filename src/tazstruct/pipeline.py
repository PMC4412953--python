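"""End-to-end orchestration: structure + sequence + tables → annotated report.

``annotate`` runs the full chain — accessibility → core → cleft → patches
→ charge/segments → mutation classification (→ ligand geometry when
ligands are supplied) — and ``write_report`` emits the two report tables
(per-mutation annotations; cleft residues per exon) plus a JSON run
summary.  In *table-only* mode the mutation table's own location labels
are used directly, so variant flags and effects can be reproduced without
any structure file.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .access_align import GapProfile  # noqa: F401  (re-exported stage surface)
from .cleft_map import (
    ExonTabulation,
    cleft_residues,
    count_mouths,
    detect_pockets,
    tabulate_by_exon,
)
from .core_io import (
    ExonMap,
    MutationRecord,
    SequenceRecord,
    Structure,
    read_exon_map,
    read_fasta,
    read_mutation_table,
    read_structure,
)
from .ligand_geom import aggregate_spacing, match_basic_pairs
from .membrane_charge import (
    basic_patch,
    disorder_segments,
    net_formal_charge,
    tm_segments,
)
from .mut_classify import (
    MutationAnnotation,
    annotate_mutation,
    classify_location,
    find_hx4d,
    normalize_location,
)
from .surface_core import (
    compute_sasa,
    core_hydrophobic_stats,
    relative_accessibility,
    residue_contacts,
    structural_core,
)

__all__ = ["PipelineConfig", "AnnotationReport", "PipelineError", "annotate", "write_report"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the name of the stage that raised."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs plus every tunable default of the pipeline stages."""

    structure_path: Optional[str] = None
    sequence_path: Optional[str] = None
    exon_map_path: Optional[str] = None
    mutations_path: Optional[str] = None
    ligands_path: Optional[str] = None
    table_only: bool = False
    seed: int = 0
    # surface / core
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    burial_threshold: float = 0.1
    contact_cutoff: float = 4.5
    # cleft detection
    grid_spacing: float = 1.0
    psp_threshold: int = 4
    min_pocket_points: int = 30
    lining_distance: float = 4.0
    # patches / segments
    patch_link_distance: float = 15.0
    patch_min_size: int = 3
    patch_distance: float = 10.0
    tm_window: int = 19
    tm_threshold: float = 1.6
    disorder_window: int = 21
    # mutation flags
    dv_threshold: float = 20.0
    # ligand geometry
    spacing_tolerance: float = 3.0


@dataclass
class AnnotationReport:
    """Aggregated results of one pipeline run."""

    config: PipelineConfig
    n_residues: int = 0
    n_buried: int = 0
    core_component_sizes: list[int] = field(default_factory=list)
    core_hydrophobic_total: int = 0
    net_charge: Optional[float] = None
    pockets: list[dict] = field(default_factory=list)
    cleft_tabulation: Optional[ExonTabulation] = None
    patches: list[list[str]] = field(default_factory=list)
    tm: list[tuple[int, int, str]] = field(default_factory=list)
    disorder: list[tuple[int, int, str]] = field(default_factory=list)
    hx4d: list[tuple[int, int]] = field(default_factory=list)
    mutation_annotations: list[MutationAnnotation] = field(default_factory=list)
    ligand_spacing: Optional[dict] = None
    pair_matches: list[dict] = field(default_factory=list)
    rejected_rows: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)


def _log(verbose: bool, msg: str) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def annotate(config: PipelineConfig, verbose: bool = False) -> AnnotationReport:
    """Run every applicable stage and return the aggregated report.

    Stages that lack their required inputs are skipped (e.g. all
    structural stages in table-only mode); any exception inside a stage
    is re-raised as :class:`PipelineError` naming the stage.
    """
    report = AnnotationReport(config=config)
    t0 = time.perf_counter()

    def stage(name: str):
        def deco(fn):
            start = time.perf_counter()
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            report.timings[name] = round(time.perf_counter() - start, 4)
            _log(verbose, f"[{name}] done in {report.timings[name]:.2f}s")
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        if config.structure_path:
            state["structure"] = read_structure(config.structure_path)
        if config.sequence_path:
            records = read_fasta(config.sequence_path)
            if not records:
                raise ValueError("sequence file has no records")
            state["sequence"] = records[0]
        if config.exon_map_path:
            state["exon_map"] = read_exon_map(config.exon_map_path)
        if config.mutations_path:
            df = pd.read_csv(config.mutations_path, sep="\t", comment="#",
                             dtype=str).fillna("")
            state["mutation_df"] = df
            state["mutations"] = read_mutation_table(config.mutations_path)

    structure: Optional[Structure] = state.get("structure")
    sequence: Optional[SequenceRecord] = state.get("sequence")
    exon_map: Optional[ExonMap] = state.get("exon_map")

    if structure is not None:
        @stage("surface_core")
        def _surface():
            areas = compute_sasa(structure, config.probe_radius, config.n_sphere_points)
            profile = relative_accessibility(
                structure, areas, threshold=config.burial_threshold
            )
            contacts = residue_contacts(structure, config.contact_cutoff)
            core = structural_core(profile, contacts)
            _, hydro_total = core_hydrophobic_stats(core, structure)
            state["profile"], state["core"] = profile, core
            report.n_residues = len(structure)
            report.n_buried = int(profile.buried.sum())
            report.core_component_sizes = [len(c) for c in core.components]
            report.core_hydrophobic_total = hydro_total

        @stage("cleft")
        def _cleft():
            pockets = detect_pockets(
                structure, config.grid_spacing, config.psp_threshold,
                config.min_pocket_points, config.probe_radius,
            )
            state["pockets"] = pockets
            for p in pockets:
                count_mouths(p)
                cleft_residues(p, structure, config.lining_distance)
            report.pockets = [
                {"volume": p.volume, "mouths": p.mouth_count,
                 "n_lining": len(p.lining_residues)}
                for p in pockets
            ]
            if pockets and exon_map is not None:
                state["cleft_set"] = {k[1] for k in pockets[0].lining_residues}
                report.cleft_tabulation = tabulate_by_exon(
                    pockets[0].lining_residues, exon_map
                )

        @stage("membrane")
        def _membrane():
            patches = basic_patch(
                structure, state["profile"],
                config.patch_link_distance, config.patch_min_size,
            )
            state["patches"] = patches
            report.patches = [
                sorted(f"{k[0]}:{k[1]}" for k in members)
                for members, _ in patches.patches
            ]
            report.net_charge = net_formal_charge(structure)

    if sequence is not None:
        @stage("segments")
        def _segments():
            if len(sequence) >= config.tm_window:
                report.tm = tm_segments(
                    sequence, config.tm_window, config.tm_threshold
                ).segments
            if len(sequence) >= config.disorder_window:
                report.disorder = disorder_segments(
                    sequence, config.disorder_window
                ).segments
            report.hx4d = [tuple(h) for h in find_hx4d(sequence)]

    if state.get("mutations") is not None:
        @stage("classify")
        def _classify():
            df = state["mutation_df"]
            has_locations = "location" in df.columns
            if config.table_only and not has_locations:
                raise ValueError("table-only mode needs a 'location' column")
            if structure is None and not has_locations:
                raise ValueError(
                    "mutation classification needs a structure or a 'location' column"
                )
            catalytic = {p for hit in report.hx4d for p in hit}
            annotations = []
            for idx, rec in enumerate(state["mutations"]):
                try:
                    if config.table_only or (has_locations and structure is None):
                        loc = normalize_location(df.iloc[idx]["location"])
                        distal = False
                    else:
                        call = classify_location(
                            rec, catalytic, state.get("cleft_set", set()),
                            state.get("patches"), state["profile"], structure,
                            config.patch_distance,
                        )
                        loc, distal = call.location, call.distal
                    annotations.append(
                        annotate_mutation(rec, loc, distal=distal,
                                          dv_threshold=config.dv_threshold)
                    )
                except (KeyError, ValueError) as exc:
                    report.rejected_rows.append(f"row {idx}: {exc}")
            report.mutation_annotations = annotations

    if structure is not None and structure.ligands:
        @stage("ligand_geometry")
        def _ligands():
            stats = aggregate_spacing(structure.ligands)
            report.ligand_spacing = {"mean": stats.mean, "sd": stats.sd, "n": stats.n}
            basics = [r.number for r in structure.residues if r.aa in "KR"]
            match = match_basic_pairs(basics, structure, stats,
                                      config.spacing_tolerance)
            report.pair_matches = [
                {"pair": (str(a), str(b)), "distance": round(d, 2), "compatible": ok}
                for a, b, d, ok in match.pairs
            ]

    report.timings["total"] = round(time.perf_counter() - t0, 4)
    return report


def write_report(report: AnnotationReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the mutation and cleft tables plus a JSON run summary.

    Returns the paths written.  Re-running with identical inputs and
    config produces byte-identical table bodies (timings live only in the
    JSON summary).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    mut_path = out / "report_mutations.tsv"
    rows = []
    for ann in report.mutation_annotations:
        rows.append({
            "hgvs_p": ann.record.hgvs_p,
            "exon": ann.record.exon_id or "",
            "location": ann.location + (" (distal)" if ann.distal else ""),
            "electrostatic": "X" if ann.electrostatic else "",
            "stability": "X" if ann.stability else "",
            "effect": ann.effect,
            "rules": ";".join(ann.rules),
        })
    pd.DataFrame(rows).to_csv(mut_path, sep="\t", index=False)
    written["mutations"] = mut_path

    cleft_path = out / "report_cleft_by_exon.tsv"
    if report.cleft_tabulation is not None:
        tab = report.cleft_tabulation
        df = pd.DataFrame(tab.rows, columns=["exon_id", "count", "fraction_pct"])
        df.loc[len(df)] = ["total", tab.total, 100.0 if tab.total else 0.0]
        df.to_csv(cleft_path, sep="\t", index=False)
        written["cleft"] = cleft_path

    summary = {
        "package_version": __version__,
        "config": asdict(report.config),
        "n_residues": report.n_residues,
        "n_buried": report.n_buried,
        "core_component_sizes": report.core_component_sizes,
        "core_hydrophobic_total": report.core_hydrophobic_total,
        "net_charge": report.net_charge,
        "pockets": report.pockets,
        "patches": report.patches,
        "tm_segments": report.tm,
        "disorder_segments": report.disorder,
        "hx4d": report.hx4d,
        "n_mutations": len(report.mutation_annotations),
        "rejected_rows": report.rejected_rows,
        "ligand_spacing": report.ligand_spacing,
        "timings": report.timings,
    }
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    written["summary"] = summary_path
    return written
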