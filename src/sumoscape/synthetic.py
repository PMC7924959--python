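"""Synthetic proteome and SUMO-site generator.

Emits a proteome, planted conjugation sites, per-residue structure tracks and
per-sample intensities with the statistical structure the downstream analyses
assume, in the same table dialects the I/O layer reads, plus a ground-truth
record for parameter-recovery tests.

Defaults emulate the study conditions: 775 site-bearing proteins with 2700 ±
sites, yeast-like lysine frequency 0.073, ~40% of residues in disordered
segments, sites enriched in disorder and clustered along the sequence, seven
motif categories mixed in the observed proportions, a 6-timepoint ×
3-replicate design with five temporal profile shapes, multiplicative
replicate noise, and intensity-dependent (MNAR) missingness following a
logistic law on the latent log2 intensity.

All randomness flows from one integer seed through two named
``numpy.random.Generator`` streams (children of ``SeedSequence(seed)``):
stream 0 drives the proteome/sites/annotations, stream 1 the intensities.
Within stream 0 the draw order is, per protein: length, disorder blocks,
sequence, site count, site placement, motif assignment and stamping, then
annotation tracks; decoy rows and localization probabilities follow after
all proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from sumoscape.motifs import MotifCategory, classify_site, DEFAULT_HYDROPHOBIC
from sumoscape.structure import ResidueAnnotation
from sumoscape.tables_io import (
    AMINO_ACIDS,
    DEFAULT_TIMEPOINTS,
    ProteinRecord,
    SampleDesign,
    SiteRecord,
    write_annotations,
    write_fasta,
    write_protein_table,
    write_sites_table,
)

PROFILE_SHAPES = ("rising", "falling", "U", "peak-mid", "flat")

#: motif-category mix matching the observed site-composition proportions
DEFAULT_MOTIF_MIX = {
    MotifCategory.CONSENSUS: 0.1426,
    MotifCategory.HYDROPHOBIC_VARIANT: 0.0050,
    MotifCategory.REVERSE_CONSENSUS: 0.0323,
    MotifCategory.ACIDIC: 0.1157,
    MotifCategory.REVERSE_ACIDIC: 0.1032,
    MotifCategory.DILYSINE: 0.0755,
    MotifCategory.NONE: 0.5257,
}

_ACIDIC = "ED"
# stamp filler: never hydrophobic (ILVMF), acidic (ED) or lysine, so a
# position set to one of these can satisfy no pattern clause
_NEUTRAL = "SGTAPNQ"


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator (see module docstring)."""

    n_proteins: int = 775
    length_range: tuple[int, int] = (150, 1000)
    lysine_freq: float = 0.073
    site_rate: float = 9.5            # expected sites per 100 lysines
    disorder_enrichment: float = 2.0  # relative odds of a disordered K being a site
    cluster_prob: float = 0.45
    cluster_window: int = 5
    motif_mix: dict[MotifCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_MIX)
    )
    n_timepoints: int = 6
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    profile_classes: tuple[tuple[str, float], ...] = tuple(
        (s, 0.2) for s in PROFILE_SHAPES
    )
    profile_amplitude: float = 2.0    # log2 units peak-to-trough of a shaped profile
    base_mean: float = 25.0           # latent log2 intensity, N(base_mean, base_sd)
    base_sd: float = 2.0
    noise_cv: float = 0.02            # replicate SD = noise_cv * |base|
    mnar_steepness: float = 1.0
    mnar_midpoint: float = 23.0
    loc_prob_high_fraction: float = 0.77   # share of sites with loc prob >= 0.96
    decoy_rate: float = 0.02          # reverse and contaminant rows, each
    disorder_run_mean: float = 30.0   # geometric mean lengths of alternating blocks
    ordered_run_mean: float = 45.0
    window_halfwidth: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif_mix = {MotifCategory(k): float(v) for k, v in self.motif_mix.items()}
        total = sum(self.motif_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"motif_mix fractions sum to {total}, not 1")
        for name in ("lysine_freq", "cluster_prob", "loc_prob_high_fraction",
                     "decoy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for cat, frac in self.motif_mix.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"motif_mix[{cat}]={frac} outside [0, 1]")
        wsum = sum(w for _, w in self.profile_classes)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"profile_classes weights sum to {wsum}, not 1")
        if self.timepoints and len(self.timepoints) != self.n_timepoints:
            raise ValueError("timepoints length disagrees with n_timepoints")
        if self.disorder_enrichment < 0:
            raise ValueError("disorder_enrichment must be >= 0")

    def design(self) -> SampleDesign:
        return SampleDesign.from_layout(self.timepoints, self.n_replicates)


@dataclass
class GroundTruth:
    """Planted values recorded for parameter-recovery tests."""

    true_sites: dict[str, list[int]]            # protein -> sorted positions
    true_motif_of: dict[str, str]               # site_id -> category
    true_profile_class_of: dict[str, str]       # site_id -> shape label
    true_disorder_mask: dict[str, list[bool]]   # protein -> per-residue flags

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_sites={k: list(map(int, v)) for k, v in d["true_sites"].items()},
            true_motif_of=dict(d["true_motif_of"]),
            true_profile_class_of=dict(d["true_profile_class_of"]),
            true_disorder_mask={k: list(map(bool, v)) for k, v in d["true_disorder_mask"].items()},
        )


# ---------------------------------------------------------------------------
# proteome simulation

def _disorder_mask(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> np.ndarray:
    """Alternating disordered/ordered blocks with geometric lengths."""
    p_start_dis = cfg.disorder_run_mean / (cfg.disorder_run_mean + cfg.ordered_run_mean)
    state = bool(rng.random() < p_start_dis)
    mask = np.zeros(length, dtype=bool)
    i = 0
    while i < length:
        mean = cfg.disorder_run_mean if state else cfg.ordered_run_mean
        run = int(rng.geometric(1.0 / mean))
        mask[i : i + run] = state
        i += run
        state = not state
    return mask


def _draw_sequence(rng: np.random.Generator, length: int, lysine_freq: float) -> np.ndarray:
    others = np.array([aa for aa in AMINO_ACIDS if aa != "K"])
    seq = others[rng.integers(0, len(others), size=length)]
    seq[rng.random(length) < lysine_freq] = "K"
    return seq


def _place_sites(
    rng: np.random.Generator,
    seq: np.ndarray,
    dis: np.ndarray,
    cfg: SimulationConfig,
) -> list[int]:
    """Plant site positions (1-based).

    Seed sites: each eligible lysine becomes a site independently with
    probability proportional to 1 + (disorder_enrichment − 1)·disordered(k),
    scaled so the expected seed count is (1 − cluster_prob)·site_rate per
    100 lysines (Bernoulli thinning keeps inclusion exactly proportional to
    the planted odds, which fixed-count weighted sampling without
    replacement would attenuate).  Cluster sites: an additional
    Binomial(nK, cluster_prob·site_rate/100) sites are each placed at a
    free offset 1..cluster_window from a randomly chosen existing site, the
    residue being converted to lysine when necessary (SUMO-site clusters
    sit in K-rich patches).  Only positions far enough from the termini to
    carry a full −3..+2 motif context are eligible.
    """
    L = len(seq)
    lys0 = np.flatnonzero(seq == "K")
    lys0 = lys0[(lys0 >= 3) & (lys0 <= L - 3)]  # room for the -3..+2 stamp
    if lys0.size == 0:
        return []
    rate = min(cfg.site_rate / 100.0, 1.0)

    w = 1.0 + (cfg.disorder_enrichment - 1.0) * dis[lys0].astype(float)
    # normalize by the EXPECTED weight (global disorder fraction), not the
    # per-protein mean: per-protein normalization couples a lysine's site
    # probability to its protein's disorder fraction and attenuates the
    # pooled planted odds ratio
    f_dis = cfg.disorder_run_mean / (cfg.disorder_run_mean + cfg.ordered_run_mean)
    mean_w = 1.0 + (cfg.disorder_enrichment - 1.0) * f_dis
    p_seed = np.clip((1.0 - cfg.cluster_prob) * rate * w / mean_w, 0.0, 1.0)
    seed_mask = rng.random(lys0.size) < p_seed
    sites: list[int] = [int(i) for i in lys0[seed_mask]]
    taken: set[int] = set(sites)

    n_cluster = int(rng.binomial(lys0.size, cfg.cluster_prob * rate))
    for _ in range(n_cluster):
        if not sites:
            break
        anchor = int(rng.choice(np.array(sites)))
        offsets = rng.permutation(
            [d * s for d in range(1, cfg.cluster_window + 1) for s in (1, -1)]
        )
        for off in offsets:
            pos = anchor + int(off)
            if 3 <= pos <= L - 3 and pos not in taken:
                seq[pos] = "K"
                sites.append(pos)
                taken.add(pos)
                break
    return sorted(p + 1 for p in sites)   # back to 1-based


def _stamp_motifs(
    rng: np.random.Generator,
    seq: np.ndarray,
    sites: Sequence[int],
    cfg: SimulationConfig,
    max_retries: int = 50,
) -> dict[int, MotifCategory]:
    """Overwrite the −3..+2 context of each site to realize its assigned
    category; return the category each site actually carries.

    Collisions between nearby stamps resolve later-site-wins, except that a
    stamp never overwrites another site's central lysine (the planted-site
    invariant).  For the NONE category the context is rejection-sampled from
    the background residue distribution until no pattern class matches.
    Because a protected neighbouring lysine or a later overlapping stamp can
    alter a realized context, the returned ground-truth category is the
    classification of the *final* emitted window, not the drawn assignment;
    with well-separated sites the two coincide.
    """
    cats = list(cfg.motif_mix)
    probs = np.array([cfg.motif_mix[c] for c in cats])
    protected = {p - 1 for p in sites}
    hydro = sorted(DEFAULT_HYDROPHOBIC)
    assigned: dict[int, MotifCategory] = {}

    def put(idx0: int, char: str) -> None:
        if idx0 not in protected:
            seq[idx0] = char

    def rand(chars: str | Sequence[str]) -> str:
        return str(rng.choice(list(chars)))

    for pos in sites:           # ascending order: later (downstream) site wins
        c = pos - 1             # 0-based center
        cat = cats[int(rng.choice(len(cats), p=probs))]
        assigned[pos] = cat
        m3, m2, m1, p1, p2 = c - 3, c - 2, c - 1, c + 1, c + 2
        if cat is MotifCategory.HYDROPHOBIC_VARIANT:
            put(m3, rand(hydro)); put(m2, rand(hydro)); put(m1, rand(hydro))
            put(p2, rand(_ACIDIC))
        elif cat is MotifCategory.CONSENSUS:
            put(m2, rand(_NEUTRAL))          # blocks the triple-hydrophobic variant
            put(m1, rand(hydro)); put(p2, rand(_ACIDIC))
        elif cat is MotifCategory.REVERSE_CONSENSUS:
            put(m2, rand(_ACIDIC)); put(p1, rand(hydro)); put(p2, rand(_NEUTRAL))
        elif cat is MotifCategory.ACIDIC:
            put(m2, rand(_NEUTRAL)); put(m1, rand(_NEUTRAL)); put(p2, rand(_ACIDIC))
        elif cat is MotifCategory.REVERSE_ACIDIC:
            put(m2, rand(_ACIDIC)); put(p1, rand(_NEUTRAL)); put(p2, rand(_NEUTRAL))
        elif cat is MotifCategory.DILYSINE:
            flank = p1 if rng.random() < 0.5 else m1
            other = m1 if flank == p1 else p1
            put(flank, "K"); put(other, rand(_NEUTRAL))
            put(m2, rand(_NEUTRAL)); put(p2, rand(_NEUTRAL))
        else:  # NONE: rejection-sample a pattern-free context
            idxs = [m3, m2, m1, p1, p2]
            ok = False
            for _ in range(max_retries):
                for i in idxs:
                    put(i, _draw_sequence(rng, 1, cfg.lysine_freq)[0])
                if classify_site(_window(seq, pos, 3)).category is MotifCategory.NONE:
                    ok = True
                    break
            if not ok:
                # a protected neighbouring site-K can force a pattern (e.g.
                # di-lysine); settle for neutral context and let the final
                # classification below define the truth
                for i in idxs:
                    put(i, rand(_NEUTRAL))
    # ground truth = category actually realized in the emitted sequence
    for pos in sites:
        assigned[pos] = classify_site(_window(seq, pos, 3)).category
    return assigned


def _window(seq: np.ndarray, pos: int, halfwidth: int) -> str:
    """1-based centered window, "_"-padded beyond the termini."""
    c = pos - 1
    L = len(seq)
    lo, hi = c - halfwidth, c + halfwidth + 1
    left = "_" * max(0, -lo)
    right = "_" * max(0, hi - L)
    return left + "".join(seq[max(lo, 0) : min(hi, L)]) + right


def _annotate(
    rng: np.random.Generator, pid: str, dis: np.ndarray
) -> ResidueAnnotation:
    """Synthesize predictor-style tracks consistent with the disorder mask."""
    L = dis.size
    score = np.where(dis, rng.uniform(0.55, 0.95, L), rng.uniform(0.05, 0.45, L))
    exposed = rng.random(L) < 0.55
    coiled = np.zeros(L, dtype=bool)
    if rng.random() < 0.2 and L > 60:
        start = int(rng.integers(0, L - 40))
        coiled[start : start + int(rng.integers(20, 40))] = True
    tm = np.zeros(L, dtype=bool)
    if rng.random() < 0.05 and L > 30:
        start = int(rng.integers(0, L - 21))
        tm[start : start + 21] = True
    return ResidueAnnotation(
        protein_id=pid,
        length=L,
        globular=~dis,
        long_disorder=dis.copy(),
        short_disorder_score=score,
        exposed=exposed,
        buried=~exposed,
        coiled_coil=np.zeros(L, dtype=bool) | coiled,
        transmembrane=tm,
    )


def simulate_proteome(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], dict[str, ResidueAnnotation], GroundTruth]:
    """Generate sequences, disorder architecture, planted sites and tracks."""
    rng, _ = _streams(config.seed)
    return _simulate_proteome_with_rng(rng, config)


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


# ---------------------------------------------------------------------------
# intensities

def _shape_offsets(shape: str, n_timepoints: int, amplitude: float) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n_timepoints)
    half = amplitude / 2.0
    if shape == "flat":
        return np.zeros(n_timepoints)
    if shape == "rising":
        return t * half
    if shape == "falling":
        return -t * half
    if shape == "U":
        return (2.0 * np.abs(t) - 1.0) * half
    if shape == "peak-mid":
        return (1.0 - 2.0 * np.abs(t)) * half
    raise ValueError(f"unknown profile shape {shape!r}")


def simulate_intensities(
    site_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, float | None]], dict[str, str]]:
    """Per-sample intensities for each site, plus the planted profile class.

    The latent log2 intensity of a replicate cell is
    base + shape_offset(timepoint) + N(0, (noise_cv·|base|)²) with
    base ~ N(base_mean, base_sd²); the cell is missing with probability
    logistic(mnar_steepness · (mnar_midpoint − latent)).  Observed values
    are reported on the raw (2**latent) scale.
    """
    if rng is None:
        _, rng = _streams(config.seed)
    design = config.design()
    shapes = [s for s, _ in config.profile_classes]
    weights = np.array([w for _, w in config.profile_classes])
    intensities: dict[str, dict[str, float | None]] = {}
    class_of: dict[str, str] = {}
    offsets = {s: _shape_offsets(s, config.n_timepoints, config.profile_amplitude)
               for s in shapes}
    tp_index = {tp: i for i, tp in enumerate(design.timepoints)}
    for sid in site_ids:
        shape = shapes[int(rng.choice(len(shapes), p=weights))]
        class_of[sid] = shape
        base = rng.normal(config.base_mean, config.base_sd)
        row: dict[str, float | None] = {}
        for sample in design.samples:
            latent = (
                base
                + offsets[shape][tp_index[design.timepoint_of[sample]]]
                + rng.normal(0.0, config.noise_cv * abs(base))
            )
            p_missing = expit(config.mnar_steepness * (config.mnar_midpoint - latent))
            row[sample] = None if rng.random() < p_missing else float(2.0 ** latent)
        intensities[sid] = row
    return intensities, class_of


# ---------------------------------------------------------------------------
# full study

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    design: SampleDesign
    sites: list[SiteRecord]              # true sites followed by decoy rows
    proteins: list[ProteinRecord]
    annotations: dict[str, ResidueAnnotation]
    truth: GroundTruth

    @property
    def true_site_records(self) -> list[SiteRecord]:
        return [s for s in self.sites if not (s.is_reverse or s.is_contaminant)]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Full generator: proteome, sites, intensities, decoys, protein LFQ."""
    rng0, rng1 = _streams(config.seed)
    proteins, annotations, truth = _simulate_proteome_with_rng(rng0, config)
    design = config.design()

    site_ids = [
        f"{pid}_K{pos}" for pid, positions in truth.true_sites.items() for pos in positions
    ]
    intensities, class_of = simulate_intensities(site_ids, config, rng=rng1)
    truth.true_profile_class_of = class_of

    seq_of = {p.protein_id: p.sequence for p in proteins}
    sites: list[SiteRecord] = []
    for pid, positions in truth.true_sites.items():
        seq = np.array(list(seq_of[pid]))
        for pos in positions:
            sid = f"{pid}_K{pos}"
            high = rng1.random() < config.loc_prob_high_fraction
            loc = rng1.uniform(0.96, 1.0) if high else rng1.uniform(0.30, 0.96)
            sites.append(
                SiteRecord(
                    site_id=sid,
                    protein_id=pid,
                    position=pos,
                    localization_prob=float(loc),
                    sequence_window=_window(seq, pos, config.window_halfwidth),
                    intensities=intensities[sid],
                )
            )

    # decoy rows: reverse-database hits and potential contaminants
    n_decoy = int(round(config.decoy_rate * len(sites)))
    w = 2 * config.window_halfwidth + 1
    for i in range(n_decoy):
        seq = _draw_sequence(rng1, w, config.lysine_freq)
        seq[w // 2] = "K"
        sites.append(
            SiteRecord(
                site_id=f"REV__{i + 1}_K1",
                protein_id=f"REV__{i + 1}",
                position=int(rng1.integers(1, 500)),
                localization_prob=float(rng1.uniform(0, 1)),
                sequence_window="".join(seq),
                intensities={s: None for s in design.samples},
                is_reverse=True,
            )
        )
    for i in range(n_decoy):
        seq = _draw_sequence(rng1, w, config.lysine_freq)
        seq[w // 2] = "K"
        sites.append(
            SiteRecord(
                site_id=f"CON__{i + 1}_K1",
                protein_id=f"CON__{i + 1}",
                position=int(rng1.integers(1, 500)),
                localization_prob=float(rng1.uniform(0, 1)),
                sequence_window="".join(seq),
                intensities={s: None for s in design.samples},
                is_contaminant=True,
            )
        )

    # per-protein LFQ: sum of the raw intensities of the protein's sites
    by_protein: dict[str, list[SiteRecord]] = {}
    for s in sites:
        if not (s.is_reverse or s.is_contaminant):
            by_protein.setdefault(s.protein_id, []).append(s)
    for p in proteins:
        lfq: dict[str, float | None] = {}
        group = by_protein.get(p.protein_id, [])
        for sample in design.samples:
            vals = [s.intensities[sample] for s in group if s.intensities[sample] is not None]
            lfq[sample] = float(sum(vals)) if vals else None
        p.lfq = lfq

    return SyntheticStudy(
        config=config,
        design=design,
        sites=sites,
        proteins=proteins,
        annotations=annotations,
        truth=truth,
    )


def _simulate_proteome_with_rng(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[ProteinRecord], dict[str, ResidueAnnotation], GroundTruth]:
    proteins: list[ProteinRecord] = []
    annotations: dict[str, ResidueAnnotation] = {}
    true_sites: dict[str, list[int]] = {}
    true_motif: dict[str, str] = {}
    true_dis: dict[str, list[bool]] = {}
    for k in range(config.n_proteins):
        pid = f"SYP{k + 1:05d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        dis = _disorder_mask(rng, length, config)
        seq = _draw_sequence(rng, length, config.lysine_freq)
        sites = _place_sites(rng, seq, dis, config)
        assigned = _stamp_motifs(rng, seq, sites, config)
        annotations[pid] = _annotate(rng, pid, dis)
        proteins.append(ProteinRecord(protein_id=pid, sequence="".join(seq)))
        true_sites[pid] = sites
        true_dis[pid] = [bool(v) for v in dis]
        for pos in sites:
            true_motif[f"{pid}_K{pos}"] = assigned[pos].value
    truth = GroundTruth(
        true_sites=true_sites,
        true_motif_of=true_motif,
        true_profile_class_of={},
        true_disorder_mask=true_dis,
    )
    return proteins, annotations, truth


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study files in the I/O-layer formats; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.tsv",
        "protein_groups": out / "protein_groups.tsv",
        "fasta": out / "proteins.fasta",
        "annotations": out / "annotations.tsv",
        "design": out / "design.yaml",
        "ground_truth": out / "ground_truth.json",
    }
    write_sites_table(study.sites, paths["sites"], study.design)
    write_protein_table(study.proteins, paths["protein_groups"], study.design)
    write_fasta(study.proteins, paths["fasta"])
    write_annotations(study.annotations, paths["annotations"])
    study.design.to_yaml(paths["design"])
    study.truth.to_json(paths["ground_truth"])
    return paths
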