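"""Synthetic-data generator for the whole pipeline.

Generates every input the analysis consumes -- gene annotation with
CAGE-supported TSSs, an open-chromatin region universe split across two
sources, negative-binomial CUT&RUN-style fragment sets with
class-specific enrichment over an IgG baseline, spike-in counts,
stranded RNA-seq flank reads, stage-wise expression tables, gamete and
embryo methylation, motif-hit counts, and crispant Ct tables -- with
the statistical structure the analysis assumes planted and recorded as
ground truth.

Element classes and their default chromatin profiles encode the
empirical patterns the classifier exploits: promoters carry H3K4me2/3,
H3K4me1-only enhancers carry H3K4me1 + H3K27ac with background
H3K4me2, and H3K4me2 enhancers are deliberately promoter-like in the
dominant coverage features (high H3K4me2 and H3K27ac, background
H3K4me3) so that they land inside the promoter cloud in PC space --
the discordance the SVM step is built to detect.

Fragment counts are negative-binomial (mean/dispersion); every sample's
library is padded to the configured depth with genome-wide background
fragments placed outside region territory, so that per-region
mark-over-IgG enrichment ratios estimate the planted folds directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SEED = 20250710
MARKS = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K9ac", "H4K16ac",
         "H2BK16ac")
CONTROL_MARK = "IgG"
ELEMENT_CLASSES = ("active-promoter", "weak-promoter", "H3K4me1-enhancer",
                   "H3K4me2-enhancer", "poised-enhancer", "unmarked")

# genome layout: one placement slot every SLOT_PITCH bp; a slot hosts
# either a gene TSS or one distal region, so every distal region is
# several kb from every TSS by construction
SLOT_PITCH = 6_000
REGION_WIDTH = (700, 1_100)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    exons: list[tuple[int, int]]
    cage_tags: int
    expression_group: str       # "NPS-down" | "unaffected"
    contribution: str           # "maternal-zygotic" | "strictly-zygotic"
    annotation_source: str = "primary-annotation"


@dataclass
class SyntheticGenomeSpec:
    chromosomes: list[tuple[str, int]]
    genes: list[Gene]

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.cage_tags < 0 or int(g.cage_tags) != g.cage_tags:
                raise ValueError(f"{g.gene_id}: tag count must be a "
                                 "non-negative integer")
            for s, e in g.exons:
                if not (0 <= s < e <= lengths[g.chrom]):
                    raise ValueError(f"{g.gene_id}: exon outside chromosome")
            fs, fe = g.exons[0]
            if not (fs <= g.tss < fe):
                raise ValueError(f"{g.gene_id}: TSS not inside first exon")

    def genes_per_chrom(self) -> dict[str, int]:
        counts = {name: 0 for name, _ in self.chromosomes}
        for g in self.genes:
            counts[g.chrom] += 1
        return counts


@dataclass
class ClassProfile:
    """Per-class generative profile.

    ``folds`` are dome-stage mean fold enrichments over the IgG
    baseline per mark; other stages scale the enrichment component by
    ``stage_progress`` (fold_stage = 1 + (fold - 1) * progress), so
    marks are acquired over developmental time. ``methylation`` holds
    mean proportions for embryo, egg, and sperm; ``motif_density`` is
    the mean planted pluripotency-factor motif hit count per region.

    ``activity_scatter`` is the log-sd of a per-region activity latent
    that scales the enrichment component of all marks jointly, and
    ``activity_shift`` its log-mean: regulatory elements of one class
    form a continuum of activity rather than a point mass, which is
    what makes less active promoters and promoter-like enhancers
    overlap in principal-component space. ``fold_scatter`` optionally
    overrides the per-(region, mark) scatter of the simulation config.
    """

    name: str
    folds: dict[str, float]
    methylation: dict[str, float]
    motif_density: float = 0.0
    activity_scatter: float = 0.35
    activity_shift: float = 0.0
    fold_scatter: float | None = None
    stage_progress: dict[str, float] = field(
        default_factory=lambda: {"1K-cell": 0.35, "dome": 1.0, "shield": 1.1})

    def fold(self, mark: str, stage: str = "dome") -> float:
        base = self.folds.get(mark, 1.0)
        return 1.0 + (base - 1.0) * self.stage_progress.get(stage, 1.0)


def default_profiles() -> dict[str, ClassProfile]:
    """Default strong-signal class profiles (fold >= 3 defining marks).

    Active promoters and H3K4me2 enhancers share the same
    H3K4me2-high / acetylation-high chromatin signature (differing only
    in H3K4me3, whose modest contrast stays out of the leading
    principal components), and weak promoters sit lower on the same
    activity continuum -- the planted structure that makes H3K4me2
    enhancers land inside the promoter point cloud.
    """
    _m = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K9ac", "H4K16ac",
          "H2BK16ac")

    def folds(*values):
        return dict(zip(_m, values))

    profiles = {
        "active-promoter": ClassProfile(
            "active-promoter",
            folds(1.5, 5.0, 1.3, 3.0, 3.0, 3.0, 2.5),
            {"embryo": 0.06, "egg": 0.30, "sperm": 0.10},
            motif_density=0.4, activity_scatter=0.45, fold_scatter=0.26),
        "weak-promoter": ClassProfile(
            "weak-promoter",
            folds(1.44, 4.8, 1.25, 2.77, 2.77, 2.77, 2.26),
            {"embryo": 0.35, "egg": 0.50, "sperm": 0.40},
            motif_density=0.2, activity_scatter=0.55, activity_shift=-0.35),
        "H3K4me1-enhancer": ClassProfile(
            "H3K4me1-enhancer",
            folds(4.5, 1.0, 1.0, 3.5, 2.8, 1.8, 2.2),
            {"embryo": 0.88, "egg": 0.90, "sperm": 0.90},
            motif_density=2.5, activity_scatter=0.22, fold_scatter=0.22),
        "H3K4me2-enhancer": ClassProfile(
            "H3K4me2-enhancer",
            folds(1.5, 5.0, 1.1, 3.0, 3.0, 3.0, 2.5),
            {"embryo": 0.08, "egg": 0.50, "sperm": 0.50},
            motif_density=0.5, activity_scatter=0.40, activity_shift=-0.20,
            fold_scatter=0.22),
        "poised-enhancer": ClassProfile(
            "poised-enhancer",
            folds(3.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
            {"embryo": 0.50, "egg": 0.60, "sperm": 0.55},
            activity_scatter=0.25),
        "unmarked": ClassProfile(
            "unmarked",
            {m: 1.0 for m in _m},
            {"embryo": 0.50, "egg": 0.55, "sperm": 0.50},
            activity_scatter=0.0),
    }
    validate_profiles(profiles)
    return profiles


def validate_profiles(profiles: dict[str, ClassProfile]) -> None:
    me2 = profiles.get("H3K4me2-enhancer")
    if me2 is not None:
        assert me2.folds["H3K4me2"] >= 2 and me2.folds["H3K4me3"] < 1.25
    me1 = profiles.get("H3K4me1-enhancer")
    if me1 is not None:
        assert me1.folds["H3K4me2"] < 1.25
    un = profiles.get("unmarked")
    if un is not None:
        assert all(abs(f - 1.0) < 0.05 for f in un.folds.values())


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    ``depth`` is the raw fragment count per sample (library size);
    ``dispersion`` is the negative-binomial dispersion phi in
    var = mu + phi * mu^2; ``in_region_fraction`` is the share of an
    IgG library falling on region territory (the rest is genome-wide
    background, as in real chromatin-profiling libraries where open
    regions capture a small minority of fragments).
    """

    regions_per_class: int | dict[str, int] = 200
    depth: int = 1_500_000
    dispersion: float = 0.002
    spike_pairs: int = 500_000
    seed: int = DEFAULT_SEED
    stages: tuple[str, ...] = ("dome",)
    replicates: int = 2
    in_region_fraction: float = 0.12
    fold_scatter: float = 0.30
    baseline_scatter: float = 0.15
    secondary_source_fraction: float = 0.15
    region_width: tuple[int, int] = REGION_WIDTH
    cryptic_tss_fraction: float = 0.07
    shared_gamete_fraction: float = 0.69
    methylation_concentration: float = 80.0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def class_counts(self) -> dict[str, int]:
        if isinstance(self.regions_per_class, dict):
            return dict(self.regions_per_class)
        return {c: int(self.regions_per_class) for c in ELEMENT_CLASSES}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# annotation

RNA_STAGES = ("2-cell", "1K-cell", "dome", "shield")


def default_genome_spec(n_genes: int = 500,
                        n_chromosomes: int = 4,
                        chrom_length: int = 2_500_000,
                        seed: int = DEFAULT_SEED) -> SyntheticGenomeSpec:
    """A deterministic genome with genes laid out on a slot grid."""
    rng = _rng(seed, 0)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)]
    n_slots = (chrom_length - SLOT_PITCH) // SLOT_PITCH
    genes = []
    for i in range(n_genes):
        chrom = f"chr{i % n_chromosomes + 1}"
        slot = i // n_chromosomes
        if slot >= n_slots:
            raise ValueError("chromosomes too short for requested genes")
        tss = SLOT_PITCH // 2 + slot * SLOT_PITCH
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            exons = [(tss, tss + 300), (tss + 800, tss + 1200)]
        else:
            exons = [(tss - 299, tss + 1), (tss - 1199, tss - 799)]
            exons = [exons[0], exons[1]]
        # 85% of genes have strong CAGE support; the rest at or below
        # the >20-tag promoter cutoff
        tags = int(rng.integers(25, 200)) if rng.random() < 0.85 \
            else int(rng.integers(0, 21))
        genes.append(Gene(
            gene_id=f"gene{i + 1:04d}", chrom=chrom, tss=tss, strand=strand,
            exons=exons, cage_tags=tags,
            expression_group="NPS-down" if i % 2 == 0 else "unaffected",
            contribution="maternal-zygotic" if (i // 2) % 2 == 0
            else "strictly-zygotic",
            annotation_source="primary-annotation" if rng.random() < 0.95
            else "secondary-annotation"))
    return SyntheticGenomeSpec(chroms, genes)


def generate_annotation(spec: SyntheticGenomeSpec, seed: int
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TSS table, exon intervals, and stage-wise expression table.

    Expression plants the qualitative activation structure: unaffected
    genes activate earlier at lower amplitude; NPS-down genes activate
    later and overtake. Maternal-zygotic genes start with 2-cell
    expression above the 0.5 RPKM cutoff; strictly zygotic genes below.
    """
    seen = set()
    for g in spec.genes:
        key = (g.chrom, g.tss, g.strand)
        if key in seen:
            raise ValueError(f"overlapping genes at {key}")
        seen.add(key)

    tss = pd.DataFrame(
        [{"gene_id": g.gene_id, "chrom": g.chrom, "pos": g.tss,
          "strand": g.strand, "tag_count": g.cage_tags,
          "source": g.annotation_source} for g in spec.genes])
    exons = pd.DataFrame(
        [{"gene_id": g.gene_id, "chrom": g.chrom, "start": s, "end": e}
         for g in spec.genes for s, e in g.exons])

    rng = _rng(seed, 1)
    # zygotic ramp per group: fraction of full amplitude reached per stage
    ramp = {"unaffected": {"2-cell": 0.0, "1K-cell": 0.5, "dome": 0.8,
                           "shield": 1.0},
            "NPS-down": {"2-cell": 0.0, "1K-cell": 0.02, "dome": 0.5,
                         "shield": 1.0}}
    amplitude = {"unaffected": 6.0, "NPS-down": 30.0}
    decay = {"2-cell": 1.0, "1K-cell": 0.9, "dome": 0.5, "shield": 0.3}

    rows = []
    for g in spec.genes:
        maternal = rng.uniform(1.0, 10.0) if \
            g.contribution == "maternal-zygotic" else rng.uniform(0.0, 0.3)
        amp = amplitude[g.expression_group] * rng.lognormal(0.0, 0.3)
        row = {"gene_id": g.gene_id,
               "expression_group": g.expression_group,
               "contribution": g.contribution}
        for stage in RNA_STAGES:
            mean = maternal * decay[stage] + \
                amp * ramp[g.expression_group][stage]
            noise = rng.lognormal(0.0, 0.2) if stage != "2-cell" else 1.0
            row[stage] = mean * noise
        rows.append(row)
    expression = pd.DataFrame(rows).set_index("gene_id")
    return tss, exons, expression


# ---------------------------------------------------------------------------
# regions

def generate_regions(spec: SyntheticGenomeSpec,
                     config: SimulationConfig) -> pd.DataFrame:
    """Labeled region universe with planted truth.

    Promoter-class regions are centered on a CAGE-supported gene TSS;
    all other classes occupy gene-free slots, hence sit >= 2 kb from
    every TSS. Regions are split across two sources (L / P) and ids
    follow the merged-universe naming convention. A configurable
    fraction of H3K4me2 enhancers is flagged as cryptic gene TSSs
    (directional-transcription contaminants).
    """
    rng = _rng(config.seed, 2)
    counts = config.class_counts()
    promoter_classes = [c for c in counts if c.endswith("promoter")]
    distal_classes = [c for c in counts if not c.endswith("promoter")]

    # promoter hosts: genes with > 20 CAGE tags
    hosts = [g for g in spec.genes if g.cage_tags > 20]
    n_prom = sum(counts[c] for c in promoter_classes)
    if n_prom > len(hosts):
        raise ValueError(
            f"need {n_prom} CAGE-supported genes for promoter regions, "
            f"have {len(hosts)}")
    host_iter = iter(hosts)

    # distal slots: grid slots not occupied by any gene
    lengths = dict(spec.chromosomes)
    occupied = {(g.chrom, (g.tss - SLOT_PITCH // 2) // SLOT_PITCH)
                for g in spec.genes}
    free_slots = []
    for chrom, length in spec.chromosomes:
        for slot in range((length - SLOT_PITCH) // SLOT_PITCH):
            if (chrom, slot) not in occupied:
                free_slots.append((chrom, slot))
    n_distal = sum(counts[c] for c in distal_classes)
    if n_distal > len(free_slots):
        shortest = min(spec.chromosomes, key=lambda c: c[1])[0]
        raise ValueError(
            f"not enough gene-free territory for {n_distal} distal "
            f"regions (shortest chromosome: {shortest})")
    slot_order = rng.permutation(len(free_slots))
    slot_iter = iter(slot_order)

    rows = []
    for cls in ELEMENT_CLASSES:
        if cls not in counts:
            continue
        for _ in range(counts[cls]):
            width = int(rng.integers(*config.region_width))
            if cls in promoter_classes:
                g = next(host_iter)
                center = g.tss + int(rng.integers(-width // 4, width // 4))
                chrom = g.chrom
            else:
                chrom, slot = free_slots[next(slot_iter)]
                center = SLOT_PITCH // 2 + slot * SLOT_PITCH + \
                    int(rng.integers(-500, 500))
            start = max(600, center - width // 2)
            end = min(lengths[chrom] - 600, start + width)
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "true_class": cls,
                         "true_downstream_right": bool(rng.random() < 0.5),
                         "is_cryptic_tss": False})
    truth = pd.DataFrame(rows)

    # source split and merged-universe ids
    secondary = rng.random(len(truth)) < config.secondary_source_fraction
    truth["source"] = np.where(secondary, "P", "L")
    ids = np.empty(len(truth), dtype=object)
    ids[~secondary] = [f"atac_L{i + 1:05d}"
                       for i in range(int((~secondary).sum()))]
    ids[secondary] = [f"atac_P{i + 1:05d}"
                      for i in range(int(secondary.sum()))]
    truth.insert(0, "region_id", ids)

    # cryptic-TSS contaminants among H3K4me2 enhancers
    me2 = np.flatnonzero((truth["true_class"] == "H3K4me2-enhancer").to_numpy())
    n_cryptic = int(round(config.cryptic_tss_fraction * len(me2)))
    if n_cryptic:
        chosen = rng.choice(me2, size=n_cryptic, replace=False)
        truth.loc[truth.index[chosen], "is_cryptic_tss"] = True
    return truth


# ---------------------------------------------------------------------------
# coverage

FRAG_LEN_MEAN = 185.0
FRAG_LEN_SD = 30.0
FRAG_LEN_RANGE = (100, 400)
SUBINTERVAL_PROBS = {"center": 0.70, "downstream": 0.20, "upstream": 0.10}


def _per_region_latents(truth: pd.DataFrame,
                        profiles: dict[str, ClassProfile],
                        config: SimulationConfig
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Region baselines and per-(region, mark) biological fold scatter,
    shared across samples, stages and replicates.

    Scatter is the product of a per-region activity latent (lognormal,
    class-specific log-sd/shift, shared by all marks of the region) and
    an independent per-(region, mark) lognormal."""
    rng = _rng(config.seed, 3)
    n = len(truth)
    baseline = rng.lognormal(0.0, config.baseline_scatter, n)
    act_sd = np.array([profiles[c].activity_scatter
                       for c in truth["true_class"]])
    act_mu = np.array([profiles[c].activity_shift
                       for c in truth["true_class"]])
    activity = np.exp(act_mu + rng.normal(0.0, 1.0, n) * act_sd)
    mark_sd = np.array([
        profiles[c].fold_scatter if profiles[c].fold_scatter is not None
        else config.fold_scatter for c in truth["true_class"]])
    scatter = {m: np.exp(rng.normal(0.0, 1.0, n) * mark_sd) * activity
               for m in MARKS}
    return baseline, scatter


def _fold_matrix(truth: pd.DataFrame, profiles: dict[str, ClassProfile],
                 scatter: dict[str, np.ndarray], mark: str,
                 stage: str) -> np.ndarray:
    """Planted per-region fold for one mark: the enrichment component
    scales with biological scatter, background stays at 1."""
    missing = set(truth["true_class"]) - set(profiles)
    if missing:
        raise ValueError(f"missing profile for class {sorted(missing)[0]!r}")
    base = np.array([profiles[c].fold(mark, stage)
                     for c in truth["true_class"]])
    if mark == CONTROL_MARK:
        return np.ones(len(truth))
    return 1.0 + (base - 1.0) * scatter[mark]


def simulate_coverage(truth: pd.DataFrame,
                      profiles: dict[str, ClassProfile],
                      config: SimulationConfig,
                      chromosome_lengths: dict[str, int] | None = None
                      ) -> tuple[dict, dict]:
    """Per-(stage, mark, replicate) fragment sets plus spike-in counts.

    Counts per region are negative-binomial with mean = baseline x
    class fold enrichment; an IgG track (fold 1 everywhere) is always
    emitted. Fragment spans are drawn from a clipped normal in
    100-400 bp, so the mononucleosome filter removes a tail. Each
    library is padded to ``config.depth`` with background fragments
    placed outside region territory.
    """
    missing = set(truth["true_class"]) - set(profiles)
    if missing:
        raise ValueError(f"missing profile for class {sorted(missing)[0]!r}")
    baseline, scatter = _per_region_latents(truth, profiles, config)
    n_regions = len(truth)
    base_rate = config.in_region_fraction * config.depth / n_regions
    mu0 = base_rate * baseline

    chroms = truth["chrom"].to_numpy()
    starts = truth["start"].to_numpy()
    ends = truth["end"].to_numpy()
    down_right = truth["true_downstream_right"].to_numpy()
    windows = {
        "center": (starts, ends),
        "downstream": (np.where(down_right, ends, starts - 500),
                       np.where(down_right, ends + 500, starts)),
        "upstream": (np.where(down_right, starts - 500, ends),
                     np.where(down_right, starts, ends + 500)),
    }
    if chromosome_lengths is None:
        chromosome_lengths = {c: int(ends[chroms == c].max()) + 10_000
                              for c in np.unique(chroms)}
    blocked = _blocked_intervals(truth, chromosome_lengths)

    marks = list(MARKS) + [CONTROL_MARK]
    fragments, spikes = {}, {}
    r = 1.0 / config.dispersion
    for si, stage in enumerate(config.stages):
        for mi, mark in enumerate(marks):
            fold = _fold_matrix(truth, profiles, scatter, mark, stage)
            mu = mu0 * fold
            for rep in range(1, config.replicates + 1):
                rng = _rng(config.seed, 4, si, mi, rep)
                counts = rng.negative_binomial(r, r / (r + mu))
                frame = _place_fragments(rng, counts, windows, chroms,
                                         config, blocked,
                                         chromosome_lengths)
                key = (stage, mark, f"rep{rep}")
                fragments[key] = frame
                spikes[key] = config.spike_pairs
    return fragments, spikes


def _blocked_intervals(truth: pd.DataFrame,
                       chromosome_lengths: dict[str, int]) -> dict:
    """Per-chromosome sorted region+flank territory closed to
    background fragments."""
    blocked = {}
    pad = 700
    for chrom, grp in truth.groupby("chrom"):
        s = np.sort(grp["start"].to_numpy() - pad)
        e = np.sort(grp["end"].to_numpy() + pad)
        blocked[chrom] = (s, e)
    return blocked


def _place_fragments(rng, counts, windows, chroms, config, blocked,
                     chromosome_lengths) -> pd.DataFrame:
    # fragments model unique library molecules: midpoints are sampled
    # without replacement within each region subwindow (capped at the
    # window size), so downstream duplicate removal is a near no-op
    names = ["upstream", "downstream", "center"]
    probs = np.array([SUBINTERVAL_PROBS[n] for n in names])
    mids_parts, region_parts = [], []
    for r, n_r in enumerate(counts):
        if n_r == 0:
            continue
        per_window = rng.multinomial(n_r, probs)
        for k, name in enumerate(names):
            n_w = int(per_window[k])
            if n_w == 0:
                continue
            ws = int(windows[name][0][r])
            m = int(windows[name][1][r]) - ws
            n_w = min(n_w, m)
            mids_parts.append(ws + rng.choice(m, size=n_w, replace=False))
            region_parts.append(np.full(n_w, r, dtype=np.int64))
    if mids_parts:
        mid = np.concatenate(mids_parts)
        region_idx = np.concatenate(region_parts)
    else:
        mid = np.empty(0, dtype=np.int64)
        region_idx = np.empty(0, dtype=np.int64)
    total = len(mid)
    length = np.clip(np.rint(rng.normal(FRAG_LEN_MEAN, FRAG_LEN_SD, total)),
                     *FRAG_LEN_RANGE).astype(np.int64)
    start = mid - length // 2
    frag_chrom = chroms[region_idx]

    n_bg = config.depth - total
    if n_bg < 0:
        warnings.warn("in-region fragments exceed configured depth; "
                      "no background emitted", stacklevel=2)
        n_bg = 0
    bg_chrom, bg_start, bg_len = _background_fragments(
        rng, n_bg, blocked, chromosome_lengths)

    frame = pd.DataFrame({
        "chrom": np.concatenate([frag_chrom, bg_chrom]),
        "start": np.concatenate([start, bg_start]),
        "end": np.concatenate([start + length, bg_start + bg_len]),
    })
    frame["chrom"] = frame["chrom"].astype("category")
    return frame


def _background_fragments(rng, n_bg, blocked, chromosome_lengths):
    chrom_names = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chrom_names],
                       dtype=float)
    alloc = rng.multinomial(n_bg, lengths / lengths.sum())
    out_chrom, out_start, out_len = [], [], []
    for chrom, n in zip(chrom_names, alloc):
        if n == 0:
            continue
        s_block, e_block = blocked.get(chrom, (np.array([]), np.array([])))
        mids = np.empty(0, dtype=np.int64)
        while len(mids) < n:
            draw = rng.integers(500, chromosome_lengths[chrom] - 500,
                                size=int((n - len(mids)) * 1.4) + 16)
            if len(s_block):
                inside = np.searchsorted(s_block, draw, side="right") > \
                    np.searchsorted(e_block, draw, side="right")
                draw = draw[~inside]
            mids = np.concatenate([mids, draw])
        mids = mids[:n]
        length = np.clip(np.rint(rng.normal(FRAG_LEN_MEAN, FRAG_LEN_SD, n)),
                         *FRAG_LEN_RANGE).astype(np.int64)
        out_chrom.append(np.full(n, chrom, dtype=object))
        out_start.append(mids - length // 2)
        out_len.append(length)
    if not out_chrom:
        empty = np.array([], dtype=np.int64)
        return np.array([], dtype=object), empty, empty
    return (np.concatenate(out_chrom), np.concatenate(out_start),
            np.concatenate(out_len))


# ---------------------------------------------------------------------------
# methylation, motifs, RNA flanks, Ct tables

def simulate_methylation(truth: pd.DataFrame,
                         profiles: dict[str, ClassProfile],
                         config: SimulationConfig) -> pd.DataFrame:
    """Embryo / egg / sperm methylation proportions per region.

    Proportions are Beta-distributed around the class means
    (concentration ``config.methylation_concentration``; infinite
    concentration gives the exact means). For the hypomethylated
    H3K4me2-enhancer class, a configurable fraction of regions is
    hypomethylated in both gametes; the remainder is hypermethylated in
    both.
    """
    rng = _rng(config.seed, 5)
    kappa = config.methylation_concentration

    def draw(mean, size=None):
        mean = np.broadcast_to(np.asarray(mean, dtype=float),
                               (size,) if size else np.shape(mean)).copy()
        if not np.isfinite(kappa):
            return mean
        out = np.empty_like(mean)
        interior = (mean > 0) & (mean < 1)
        out[~interior] = mean[~interior]
        m = mean[interior]
        out[interior] = rng.beta(m * kappa, (1 - m) * kappa)
        return np.clip(out, 0.0, 1.0)

    rows = []
    for cls, grp in truth.groupby("true_class", sort=False):
        prof = profiles[cls]
        n = len(grp)
        embryo = draw(prof.methylation["embryo"], n)
        if cls == "H3K4me2-enhancer":
            shared = rng.random(n) < config.shared_gamete_fraction
            egg = np.where(shared, draw(0.08, n), draw(0.85, n))
            sperm = np.where(shared, draw(0.08, n), draw(0.85, n))
        else:
            egg = draw(prof.methylation["egg"], n)
            sperm = draw(prof.methylation["sperm"], n)
        rows.append(pd.DataFrame({"region_id": grp["region_id"].to_numpy(),
                                  "embryo": embryo, "egg": egg,
                                  "sperm": sperm}))
    out = pd.concat(rows, ignore_index=True).set_index("region_id")
    return out.loc[truth["region_id"]]


def simulate_motif_counts(truth: pd.DataFrame,
                          profiles: dict[str, ClassProfile],
                          config: SimulationConfig) -> pd.Series:
    """Planted motif hit counts per region (Poisson around the class
    mean density), emitted directly as a density table."""
    rng = _rng(config.seed, 6)
    means = np.array([profiles[c].motif_density
                      for c in truth["true_class"]])
    counts = rng.poisson(means)
    return pd.Series(counts, index=pd.Index(truth["region_id"],
                                            name="region_id"),
                     name="motif_hits")


RNA_FLANK_STAGES = ("dome", "50pct-epiboly", "shield", "75pct-epiboly")
RNA_LIBRARY_SIZE = 10_000_000
CRYPTIC_SIGNAL_MEAN = 8.0
CRYPTIC_OPPOSITE_MEAN = 0.5
# sparse ambient signal: spurious reproducible directional calls are
# rare, so the removed fraction tracks the planted cryptic-TSS rate
RNA_BACKGROUND_MEAN = 0.02


def simulate_rna_flanks(truth: pd.DataFrame,
                        config: SimulationConfig,
                        stages: tuple[str, ...] = RNA_FLANK_STAGES
                        ) -> tuple[dict, dict]:
    """Stranded RNA-seq reads in the 100-bp flanks of each region.

    Cryptic-TSS regions receive strong strand-biased coverage in the
    flank downstream of their (random) transcription direction across
    all stages; other regions receive sparse background. Library sizes
    are nominal full-library totals so flank counts translate directly
    to RPKM.
    """
    rng = _rng(config.seed, 7)
    plus_strand = rng.random(len(truth)) < 0.5  # cryptic direction
    reads = {(stage, strand): [] for stage in stages for strand in "+-"}
    libs = {(stage, strand): float(RNA_LIBRARY_SIZE)
            for stage in stages for strand in "+-"}

    chroms = truth["chrom"].to_numpy()
    left = (truth["start"].to_numpy() - 100, truth["start"].to_numpy())
    right = (truth["end"].to_numpy(), truth["end"].to_numpy() + 100)
    cryptic = truth["is_cryptic_tss"].to_numpy()

    for stage in stages:
        for strand_idx, strand in enumerate("+-"):
            for side, (ws, we) in (("left", left), ("right", right)):
                mean = np.full(len(truth), RNA_BACKGROUND_MEAN)
                if strand == "+":
                    mean[cryptic & plus_strand &
                         (side == "right")] = CRYPTIC_SIGNAL_MEAN
                    mean[cryptic & plus_strand &
                         (side == "left")] = CRYPTIC_OPPOSITE_MEAN
                else:
                    mean[cryptic & ~plus_strand &
                         (side == "left")] = CRYPTIC_SIGNAL_MEAN
                    mean[cryptic & ~plus_strand &
                         (side == "right")] = CRYPTIC_OPPOSITE_MEAN
                counts = rng.poisson(mean)
                idx = np.repeat(np.arange(len(truth)), counts)
                if not len(idx):
                    continue
                mid = ws[idx] + (rng.random(len(idx)) *
                                 (we[idx] - ws[idx])).astype(np.int64)
                reads[(stage, strand)].append(pd.DataFrame(
                    {"chrom": chroms[idx], "start": mid - 40,
                     "end": mid + 40}))
    frames = {}
    for key, parts in reads.items():
        frames[key] = pd.concat(parts, ignore_index=True) if parts else \
            pd.DataFrame({"chrom": pd.Series(dtype=object),
                          "start": pd.Series(dtype=np.int64),
                          "end": pd.Series(dtype=np.int64)})
    return frames, libs


CT_REFERENCE_MEAN = 18.0
CT_BASE_DELTA = 2.0
MOSAIC_BETA = (8.0, 2.0)  # edited-fraction distribution, mean 0.8


def simulate_ct_table(config: SimulationConfig,
                      planted_fold: float,
                      n_embryos_per_group: int = 10,
                      n_technical: int = 3,
                      noise_scale: float = 1.0,
                      salt: int = 0) -> pd.DataFrame:
    """Per-embryo qRT-PCR Ct table with a planted knockdown.

    Crispant embryos' target delta-Ct is shifted by log2(planted_fold)
    on average; per-embryo heterogeneity follows a Beta-distributed
    edited fraction (mosaicism), normalized to mean 1 so the planted
    fold is the mean effect. ``noise_scale`` scales all noise sources;
    0 gives the exact closed-form table.
    """
    if planted_fold <= 0:
        raise ValueError("planted fold must be positive")
    rng = _rng(config.seed, 8, salt)
    tech_sd = 0.08 * noise_scale
    embryo_sd = 0.15 * noise_scale
    a, b = MOSAIC_BETA
    mosaic_mean = a / (a + b)

    rows = []
    for group, n in (("control", n_embryos_per_group),
                     ("crispant", n_embryos_per_group)):
        for i in range(n):
            embryo = f"{group}_{i + 1:02d}"
            ct_ref = CT_REFERENCE_MEAN + rng.normal(0.0, embryo_sd) \
                if noise_scale else CT_REFERENCE_MEAN
            delta = CT_BASE_DELTA
            if group == "crispant":
                frac = rng.beta(a, b) if noise_scale else mosaic_mean
                delta = delta + np.log2(planted_fold) * frac / mosaic_mean
            ct_target = ct_ref + delta
            for primer, ct in (("reference", ct_ref), ("target", ct_target)):
                for rep in range(1, n_technical + 1):
                    noise = rng.normal(0.0, tech_sd) if noise_scale else 0.0
                    rows.append({"embryo_id": embryo, "group": group,
                                 "primer": primer, "rep": rep,
                                 "ct": ct + noise})
    return pd.DataFrame(rows)
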