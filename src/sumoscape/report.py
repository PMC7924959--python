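"""Per-protein site-map diagrams and the end-to-end pipeline orchestrator.

A :class:`ProteinDiagram` assembles, for one protein, the tracks of the
per-target site maps: all lysines and the detected SUMO sites (with
cumulative intensities) on top, SUMO-interacting-motif (SIM) and domain
intervals in the middle, and structural context (globular / coiled-coil /
transmembrane intervals plus the continuous short-disorder score) at the
bottom.  Rendering to SVG via matplotlib is a thin layer over the assembled
data.

:func:`run_pipeline` chains filter → motifs → topology → structure →
dynamics over a set of input tables and writes every result table, a run
log, and a headline summary.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sumoscape import dynamics as dyn
from sumoscape import motifs as mot
from sumoscape import structure as struc
from sumoscape import topology as topo
from sumoscape.tables_io import (
    ProteinRecord,
    SampleDesign,
    SiteRecord,
    filter_sites,
    read_annotations,
    read_fasta,
    read_protein_table,
    read_sites_table,
)

log = logging.getLogger("sumoscape")


@dataclass
class Interval:
    """Half-open 1-based interval [start, end) with an optional label/tier."""

    start: int
    end: int
    label: str = ""
    tier: str = ""


@dataclass
class ProteinDiagram:
    protein_id: str
    length: int
    lysines: list[int] = field(default_factory=list)
    sumo_sites: list[tuple[int, str, float]] = field(default_factory=list)
    sims: list[Interval] = field(default_factory=list)
    domains: list[Interval] = field(default_factory=list)
    structure_intervals: dict[str, list[Interval]] = field(default_factory=dict)
    disorder_score: list[float] = field(default_factory=list)


def build_protein_diagram(
    protein: ProteinRecord,
    sites: Sequence[SiteRecord],
    ann: "struc.ResidueAnnotation | None" = None,
    sims: Sequence[Interval] = (),
    domains: Sequence[Interval] = (),
) -> ProteinDiagram:
    """Assemble the diagram tracks for one protein.

    All positions and intervals must lie within [1, length]; SIM/domain
    intervals are half-open [start, end).
    """
    L = protein.length
    own = [s for s in sites if s.protein_id == protein.protein_id]
    for s in own:
        if not 1 <= s.position <= L:
            raise ValueError(
                f"{protein.protein_id}: site position {s.position} outside [1, {L}]"
            )
    for iv in list(sims) + list(domains):
        if not (1 <= iv.start < iv.end <= L + 1):
            raise ValueError(
                f"{protein.protein_id}: interval [{iv.start}, {iv.end}) outside [1, {L + 1})"
            )
    totals, _ = dyn.cumulative_site_intensity(own)
    structure_intervals: dict[str, list[Interval]] = {}
    score: list[float] = []
    if ann is not None:
        if ann.length != L:
            raise ValueError(f"{protein.protein_id}: annotation length mismatch")
        for name, track in (
            ("globular", ann.globular),
            ("coiled_coil", ann.coiled_coil),
            ("transmembrane", ann.transmembrane),
        ):
            structure_intervals[name] = [
                Interval(a + 1, b + 1) for a, b in struc._runs(track)
            ]
        score = [float(v) for v in ann.short_disorder_score]
    return ProteinDiagram(
        protein_id=protein.protein_id,
        length=L,
        lysines=list(protein.lysine_positions),
        sumo_sites=sorted(
            (s.position, s.site_id, totals[s.site_id]) for s in own
        ),
        sims=list(sims),
        domains=list(domains),
        structure_intervals=structure_intervals,
        disorder_score=score,
    )


_TIER_GRAY = {"high": "0.25", "medium": "0.5", "low": "0.75", "": "0.5"}


def render_diagram(diagram: ProteinDiagram, path: str | Path) -> None:
    """Render the assembled tracks to a simple vector-graphics (SVG) file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.4))
    ax.set_xlim(0, diagram.length + 1)
    ax.set_ylim(0, 3.2)
    ax.set_yticks([0.5, 1.5, 2.5], ["structure", "domains", "sites"])
    ax.hlines([1.0, 2.0], 0, diagram.length + 1, color="0.9", lw=0.5)
    for k in diagram.lysines:
        ax.vlines(k, 2.2, 2.5, color="black", lw=0.6)
    for pos, sid, _tot in diagram.sumo_sites:
        ax.vlines(pos, 2.2, 2.9, color="red", lw=1.2)
        ax.text(pos, 2.92, str(pos), fontsize=5, ha="center", color="red")
    for iv in diagram.sims:
        ax.axvspan(iv.start, iv.end, ymin=2.0 / 3.2, ymax=2.18 / 3.2,
                   color=_TIER_GRAY.get(iv.tier, "0.5"))
    for iv in diagram.domains:
        ax.axvspan(iv.start, iv.end, ymin=1.1 / 3.2, ymax=1.9 / 3.2, color="tab:green", alpha=0.5)
        ax.text((iv.start + iv.end) / 2, 1.5, iv.label, fontsize=6, ha="center")
    colors = {"globular": "tab:blue", "coiled_coil": "tab:red", "transmembrane": "black"}
    for name, ivs in diagram.structure_intervals.items():
        for iv in ivs:
            ax.axvspan(iv.start, iv.end, ymin=0.1 / 3.2, ymax=0.9 / 3.2,
                       color=colors.get(name, "gray"), alpha=0.6)
    if diagram.disorder_score:
        x = np.arange(1, diagram.length + 1)
        y = 0.1 + 0.8 * np.asarray(diagram.disorder_score)
        ax.fill_between(x, 0.1, y, color="lightcoral", alpha=0.3, lw=0)
    ax.set_title(diagram.protein_id, fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline

class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


DEFAULT_PIPELINE_CONFIG: dict[str, object] = {
    "min_loc_prob": None,
    "hydrophobic_set": "ILVMF",
    "disorder_threshold": 0.5,
    "impute_width": 0.3,
    "impute_downshift": 1.8,
    "linkage": "average",
    "rounding": "half_away",
    "spacing_threshold": 5,
    "seed": 0,
}


def run_pipeline(
    sites_path: str | Path,
    design_path: str | Path,
    outdir: str | Path,
    fasta_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
    protein_groups_path: str | Path | None = None,
    config: Mapping[str, object] | None = None,
) -> Path:
    """Execute filter → motifs → topology → structure → dynamics; write a
    report directory with all result tables, a run log and a summary."""
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}

    design = SampleDesign.from_yaml(design_path)

    # -- filter
    try:
        raw_sites = read_sites_table(sites_path, design)
        sites = filter_sites(raw_sites, cfg["min_loc_prob"])
        if not sites:
            raise ValueError("no sites remain after filtering")
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc
    summary["n_sites_raw"] = len(raw_sites)
    summary["n_sites_filtered"] = len(sites)
    summary["n_proteins"] = len({s.protein_id for s in sites})

    # -- motifs
    try:
        hydro = frozenset(str(cfg["hydrophobic_set"]))
        comp = mot.motif_composition(sites, hydro)
        counts = mot.motif_counts(sites, hydro)
        pd.DataFrame(
            {
                "category": [c.value for c in comp],
                "count": [counts[c] for c in comp],
                "fraction": [comp[c] for c in comp],
            }
        ).to_csv(out / "motif_composition.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("motifs", str(exc)) from exc
    summary["motif_composition"] = {c.value: comp[c] for c in comp}

    # -- topology
    proteins: list[ProteinRecord] | None = None
    try:
        dist = topo.site_count_distribution(sites)
        pd.DataFrame(
            {"sites_per_protein": list(dist.histogram),
             "n_proteins": list(dist.histogram.values())}
        ).to_csv(out / "site_count_histogram.tsv", sep="\t", index=False)
        summary["proteins_ge2_sites"] = dist.n_ge2
        summary["proteins_ge5_sites"] = dist.n_ge5
        try:
            spacings = topo.adjacent_spacing(sites)
            pd.DataFrame({"spacing": spacings}).to_csv(
                out / "adjacent_spacings.tsv", sep="\t", index=False
            )
            summary["spacing_fraction_below_5"] = topo.fraction_below(
                spacings, int(cfg["spacing_threshold"])
            )
        except ValueError:
            summary["spacing_fraction_below_5"] = None
        if fasta_path is not None:
            proteins = read_fasta(fasta_path)
            for ref in ("FROM_SUMO_K", "FROM_ANY_K"):
                curve = topo.distance_curve(
                    sites, proteins, ref, rounding=str(cfg["rounding"])
                )
                pd.DataFrame(
                    {"bin_center": curve.bin_centers,
                     "fraction_sumo": curve.fraction_sumo,
                     "n_pairs": curve.n_pairs}
                ).to_csv(out / f"distance_curve_{ref.lower()}.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("topology", str(exc)) from exc

    # -- structure
    if proteins is not None and annotations_path is not None:
        try:
            annotations = read_annotations(annotations_path)
            classes = {
                pid: struc.derive_classes(a, float(cfg["disorder_threshold"]))
                for pid, a in annotations.items()
            }
            enr = struc.fold_enrichment(sites, proteins, classes)
            pd.DataFrame(
                {
                    "class": [c.value for c in struc.StructureClass],
                    "enrichment": [enr[c].enrichment for c in struc.StructureClass],
                    "n_sumo_k": [enr[c].n_sumo_k for c in struc.StructureClass],
                    "n_all_k": [enr[c].n_all_k for c in struc.StructureClass],
                }
            ).to_csv(out / "structure_enrichment.tsv", sep="\t", index=False)
            summary["fold_enrichment"] = {
                c.value: enr[c].enrichment for c in struc.StructureClass
            }
        except Exception as exc:
            raise StageError("structure", str(exc)) from exc

    # -- dynamics
    try:
        matrix = dyn.matrix_from_sites(sites, design)
        counts_tp = dyn.count_identified(matrix, design)
        summary["sites_identified_per_timepoint"] = counts_tp
        averaged = dyn.average_replicates(matrix, design)
        averaged.data.to_csv(out / "site_profiles_averaged.tsv", sep="\t")
        complete = averaged.data.dropna(how="any")
        complete = complete[complete.std(axis=1, ddof=1) > 0]
        if len(complete) >= 2:
            sub = dyn.ProfileMatrix(complete, dyn.MatrixState.AVERAGED)
            z = dyn.zscore_rows(
                dyn.impute_downshift(
                    dyn.log2_transform(sub),
                    width=float(cfg["impute_width"]),
                    downshift=float(cfg["impute_downshift"]),
                    seed=int(cfg["seed"]),
                )
            )
            keep = [r for r in z.row_ids if r not in z.flagged_rows]
            z = dyn.ProfileMatrix(z.data.loc[keep], dyn.MatrixState.ZSCORED)
            z.data.to_csv(out / "site_profiles_zscored.tsv", sep="\t")
            clust = dyn.hierarchical_cluster(z, str(cfg["linkage"]))
            (out / "site_clustering.nwk").write_text(clust.to_newick() + "\n")
            dyn.similarity_matrix(z).to_csv(out / "site_similarity.tsv", sep="\t")
        totals, flagged = dyn.cumulative_site_intensity(sites)
        pd.DataFrame(
            {"site_id": list(totals), "cumulative_intensity": list(totals.values())}
        ).to_csv(out / "cumulative_site_intensity.tsv", sep="\t", index=False)
        if protein_groups_path is not None:
            seqs = {p.protein_id: p.sequence for p in proteins} if proteins else None
            prot_records = read_protein_table(protein_groups_path, design, seqs)
            pmat = dyn.matrix_from_proteins(prot_records, design)
            summary["proteins_identified_per_timepoint"] = dyn.count_identified(
                pmat, design
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("dynamics", str(exc)) from exc

    import sumoscape

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "sumoscape_version": sumoscape.__version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "seed": cfg["seed"],
                "config": {k: (list(v) if isinstance(v, (set, frozenset)) else v)
                           for k, v in cfg.items()},
                "inputs": {
                    "sites": str(sites_path),
                    "design": str(design_path),
                    "fasta": str(fasta_path) if fasta_path else None,
                    "annotations": str(annotations_path) if annotations_path else None,
                    "protein_groups": str(protein_groups_path) if protein_groups_path else None,
                },
            },
            indent=2,
        )
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
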