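"""Seeded synthetic-data generators for every stage of the pipeline.

Each generator is a pure function of its arguments (seed included) and
returns the planted ground truth alongside the data, so downstream
operations can be tested by recounting rather than inference.

The regulome generator emulates a dose-resolved induction experiment: an
uninduced baseline, low- and high-dose induced fractions at two time
points (two replicates each), and ESC/TSC reference states.  Responsive
regions carry one of four planted classes:

* ``TE-GRE``  - opens on induction, open in TSCs, closed in ESCs;
* ``ESC-GRE`` - closes on induction, open in ESCs, closed in TSCs;
* ``SC-GRE``  - closes on induction, open in both references;
* ``DIND``    - opens equally at low and high dose, closed in both.

Dose dependence (``dose_ratio``) scales the high-fraction effect of the
dose-dependent classes, mirroring the stronger chromatin responses seen in
high-dose cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import AccessibilityMatrix, ConditionDesign, SampleInfo
from .intervals import GenomicInterval, RegionSet
from .nuclei import ImageStack
from .states import EmbryoTrackSet, STATES, STATE_ACTIVATED, STATE_STANDBY

CLASS_TE = "TE-GRE"
CLASS_ESC = "ESC-GRE"
CLASS_SC = "SC-GRE"
CLASS_DIND = "DIND"
CLASS_BACKGROUND = "nonresponsive"
GRE_CLASSES = (CLASS_TE, CLASS_ESC, CLASS_SC, CLASS_DIND)

# (open in ESC reference, open in TSC reference)
REF_PATTERN = {
    CLASS_TE: (False, True),
    CLASS_ESC: (True, False),
    CLASS_SC: (True, True),
    CLASS_DIND: (False, False),
}
OPENING_CLASSES = {CLASS_TE, CLASS_DIND}

OPEN_LEVEL = 200.0    # mean counts per replicate for an open region
CLOSED_LEVEL = 20.0   # and for a closed one


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    return np.random.default_rng(int(seed))


def _tile_regions(
    n: int, width: int = 500, gap: int = 1500, chroms: Sequence[str] = ("chr1", "chr2", "chr3", "chr4", "chr5"),
    prefix: str = "r",
) -> RegionSet:
    """Lay out n non-overlapping regions round-robin across chromosomes."""
    per_chrom = math.ceil(n / len(chroms))
    ivs = []
    k = 0
    for slot in range(per_chrom):
        for chrom in chroms:
            if k >= n:
                break
            start = 10_000 + slot * (width + gap)
            ivs.append(GenomicInterval(chrom, start, start + width, name=f"{prefix}{k:05d}"))
            k += 1
    return RegionSet(ivs, label="synthetic_regions")


def default_design(replicates: int = 2) -> ConditionDesign:
    """The study design emulated by the regulome generator."""
    conditions = [
        ("0h", "baseline", None),
        ("48h_low", "induced_low", "48h"),
        ("48h_high", "induced_high", "48h"),
        ("72h_low", "induced_low", "72h"),
        ("72h_high", "induced_high", "72h"),
        ("ESC", "esc_ref", None),
        ("TSC", "tsc_ref", None),
    ]
    samples = [
        SampleInfo(f"{cond}_r{r}", cond, role, time, r)
        for cond, role, time in conditions
        for r in range(1, replicates + 1)
    ]
    return ConditionDesign(samples)


@dataclass
class RegulomeSimulation:
    regions: RegionSet
    matrix: AccessibilityMatrix
    design: ConditionDesign
    chip_peaks: RegionSet
    truth: pd.DataFrame   # index: region id; class, bound, effects, openness


def simulate_regulome_dataset(
    n_per_class: Mapping[str, int] | None = None,
    n_background: int = 400,
    noise_sd: float = 0.25,
    dose_ratio: float = 1.3,
    effect_size: float = 1.5,
    bound_fraction: Mapping[str, float] | None = None,
    replicates: int = 2,
    *,
    seed: int,
) -> RegulomeSimulation:
    """Simulate a region x sample count matrix with planted GRE classes.

    Counts follow a log-normal signal model: each region has a baseline
    mean (open ~200 or closed ~20 counts per replicate, jittered), class
    effects (log2 units, ``effect_size`` at low dose, scaled by
    ``dose_ratio`` at high dose for dose-dependent classes) are added to
    the induced columns, Gaussian noise of sd ``noise_sd`` is applied on
    the log2 scale, and integer counts are drawn by Poisson sampling.
    With ``noise_sd=0`` the exact means are emitted (no log-noise, no
    Poisson draw), so planted effects are recoverable exactly.

    CEBPa ChIP peaks are placed on a class-dependent fraction of TE-GRE
    and DIND regions (defaults 0.6 / 0.8, binding being concentrated on
    the opening classes), plus decoy peaks away from all regions.
    """
    rng = _require_seed(seed)
    if n_per_class is None:
        n_per_class = {cls: 200 for cls in GRE_CLASSES}
    if bound_fraction is None:
        bound_fraction = {CLASS_TE: 0.6, CLASS_DIND: 0.8}
    for cls, n in n_per_class.items():
        if cls not in GRE_CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        if n < 0:
            raise ValueError("class counts must be >= 0")
    if n_background < 0 or noise_sd < 0:
        raise ValueError("n_background and noise_sd must be >= 0")
    if dose_ratio < 1:
        raise ValueError("dose_ratio must be >= 1")

    classes = [cls for cls in GRE_CLASSES for _ in range(n_per_class.get(cls, 0))]
    classes += [CLASS_BACKGROUND] * n_background
    n_total = len(classes)
    order = rng.permutation(n_total)
    classes = [classes[i] for i in order]

    regions = _tile_regions(n_total)
    design = default_design(replicates=replicates)
    ids = regions.ids

    # per-region baseline jitter (log2), shared across all columns
    region_jitter = 2.0 ** rng.uniform(-0.5, 0.5, size=n_total)
    bg_open = rng.random(n_total) < 0.5   # used for background regions only

    effect_low = np.zeros(n_total)
    effect_high = np.zeros(n_total)
    base_open = np.zeros(n_total, dtype=bool)
    esc_open = np.zeros(n_total, dtype=bool)
    tsc_open = np.zeros(n_total, dtype=bool)
    for i, cls in enumerate(classes):
        if cls == CLASS_BACKGROUND:
            base_open[i] = esc_open[i] = tsc_open[i] = bg_open[i]
            continue
        opening = cls in OPENING_CLASSES
        sign = 1.0 if opening else -1.0
        base_open[i] = not opening
        esc_open[i], tsc_open[i] = REF_PATTERN[cls]
        if cls == CLASS_DIND:
            effect_low[i] = effect_high[i] = effect_size
        else:
            effect_low[i] = sign * effect_size
            effect_high[i] = sign * effect_size * dose_ratio

    base_level = np.where(base_open, OPEN_LEVEL, CLOSED_LEVEL) * region_jitter

    means = {}
    for s in design.samples:
        if s.role == "baseline":
            mu = base_level
        elif s.role == "induced_low":
            mu = base_level * 2.0**effect_low
        elif s.role == "induced_high":
            mu = base_level * 2.0**effect_high
        elif s.role == "esc_ref":
            mu = np.where(esc_open, OPEN_LEVEL, CLOSED_LEVEL) * region_jitter
        else:  # tsc_ref
            mu = np.where(tsc_open, OPEN_LEVEL, CLOSED_LEVEL) * region_jitter
        means[s.sample] = mu

    values = {}
    for sample, mu in means.items():
        if noise_sd > 0:
            noisy = mu * 2.0 ** rng.normal(0.0, noise_sd, size=n_total)
            values[sample] = rng.poisson(noisy).astype(float)
        else:
            values[sample] = mu.copy()
    matrix = AccessibilityMatrix(pd.DataFrame(values, index=ids))

    bound = np.zeros(n_total, dtype=bool)
    for cls, frac in bound_fraction.items():
        idx = [i for i, c in enumerate(classes) if c == cls]
        n_bound = int(round(frac * len(idx)))
        chosen = rng.choice(len(idx), size=n_bound, replace=False) if idx else []
        for j in chosen:
            bound[idx[j]] = True
    peaks = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"p{k:05d}")
        for k, iv in enumerate(regions)
        if bound[regions.ids.index(iv.id)]
    ]
    # decoy ChIP peaks on a spare chromosome, away from every region
    n_decoys = 50
    for k in range(n_decoys):
        start = 10_000 + k * 2_000
        peaks.append(GenomicInterval("chr9", start, start + 400, name=f"decoy{k:04d}"))
    chip = RegionSet(peaks, label="cebpa_chip_peaks")

    truth = pd.DataFrame(
        {
            "gre_class": classes,
            "cebpa_bound": bound,
            "effect_low": effect_low,
            "effect_high": effect_high,
            "baseline_open": base_open,
            "esc_open": esc_open,
            "tsc_open": tsc_open,
        },
        index=pd.Index(ids, name="region"),
    )
    return RegulomeSimulation(regions, matrix, design, chip, truth)


@dataclass
class EmbryoSimulation:
    tracks: EmbryoTrackSet
    truth: pd.DataFrame   # index region id; state, accessible_stages


def simulate_embryo_epigenome(
    te_gres: RegionSet,
    states: Mapping[str, str],
    jitter_bp: int = 100,
    peak_width: int = 400,
    n_decoys: int = 40,
    *,
    seed: int,
) -> EmbryoSimulation:
    """Plant embryo-stage ATAC and H3K27ac peaks realizing requested states.

    Non-standby regions receive an ATAC peak (center jittered by at most
    ``jitter_bp``, overlap guaranteed) in *both* replicates of at least one
    of the 4C/8C stages; activated regions additionally receive an H3K27ac
    peak.  Some non-standby regions also get a single-replicate peak at the
    other stage, which the default all-replicates rule must ignore.  Decoy
    peaks (including the whole 2C stage) are placed away from every region.
    """
    rng = _require_seed(seed)
    for rid, st in states.items():
        if st not in STATES:
            raise ValueError(f"unknown state {st!r} for region {rid!r}")
        if rid not in te_gres:
            raise KeyError(f"region {rid!r} not in the given set")
    min_width = min(iv.length for iv in te_gres) if len(te_gres) else peak_width
    max_jitter = (min_width + peak_width) // 2 - 1
    if jitter_bp > max_jitter:
        raise ValueError(
            f"jitter_bp={jitter_bp} cannot guarantee overlap (max {max_jitter})"
        )

    stages = ("2C", "4C", "8C")
    atac: dict[str, list[list[GenomicInterval]]] = {s: [[], []] for s in stages}
    k27: list[GenomicInterval] = []
    counter = 0

    def jittered_peak(iv: GenomicInterval, tag: str) -> GenomicInterval:
        nonlocal counter
        shift = int(rng.integers(-jitter_bp, jitter_bp + 1))
        center = int(iv.center) + shift
        start = max(0, center - peak_width // 2)
        counter += 1
        return GenomicInterval(iv.chrom, start, start + peak_width, name=f"{tag}{counter:05d}")

    rows = []
    for iv in te_gres:
        st = states[iv.id]
        if st == STATE_STANDBY:
            rows.append((iv.id, st, ""))
            continue
        which = ["4C"], ["8C"], ["4C", "8C"]
        chosen = list(which[int(rng.integers(0, 3))])
        for stage in chosen:
            for rep in (0, 1):
                atac[stage][rep].append(jittered_peak(iv, f"{stage}r{rep}_"))
        other = [s for s in ("4C", "8C") if s not in chosen]
        if other and rng.random() < 0.3:
            # one-replicate-only peak: must not count under the "all" rule
            atac[other[0]][0].append(jittered_peak(iv, f"{other[0]}solo_"))
        if st == STATE_ACTIVATED:
            k27.append(jittered_peak(iv, "k27_"))
        rows.append((iv.id, st, ",".join(chosen)))

    # decoys on a spare chromosome absent from te_gres
    for k in range(n_decoys):
        start = 10_000 + k * 3_000
        for stage in stages:
            for rep in (0, 1):
                if rng.random() < 0.8:
                    atac[stage][rep].append(
                        GenomicInterval("chrZ", start, start + peak_width, name=f"d{stage}{rep}_{k:04d}")
                    )
        if rng.random() < 0.5:
            k27.append(GenomicInterval("chrZ", start, start + peak_width, name=f"dk27_{k:04d}"))

    tracks = EmbryoTrackSet(
        atac={
            s: [RegionSet(reps, label=f"{s}_rep{r+1}") for r, reps in enumerate(atac[s])]
            for s in stages
        },
        k27ac=[RegionSet(k27, label="H3K27ac")],
    )
    truth = pd.DataFrame(rows, columns=["region", "state", "accessible_stages"]).set_index("region")
    return EmbryoSimulation(tracks, truth)


def default_cluster_spec() -> tuple[dict[str, int], dict[str, int], dict[str, str]]:
    """Default cluster ecosystem for the similarity statistic.

    Reference (embryo-stage) clusters are small — real preimplantation
    datasets contribute only tens of cells per stage — while induced query
    clusters are larger and get subsampled by the resampling procedure.
    Each stage has one transcriptionally matched induced cluster.
    """
    clusters_ref = {"ICM": 25, "Epiblast": 25, "TE": 25}
    clusters_query = {"ES1": 80, "ES3": 80, "TE3": 80}
    match = {"ES1": "ICM", "ES3": "Epiblast", "TE3": "TE"}
    return clusters_ref, clusters_query, match


@dataclass
class ClusterExpressionSim:
    expr_query: pd.DataFrame    # cells x genes
    expr_ref: pd.DataFrame
    labels: pd.DataFrame        # index cell; columns dataset, cluster
    centroids: pd.DataFrame     # log-space cluster centroids (cluster x gene)


def simulate_cluster_expression(
    clusters_ref: Mapping[str, int],
    clusters_query: Mapping[str, int],
    n_genes: int = 200,
    separation: float = 10.0,
    match: Mapping[str, str] | None = None,
    *,
    seed: int,
) -> ClusterExpressionSim:
    """Simulate two clustered expression datasets with planted matching.

    Cells are log-normal: ``expr = exp(centroid + N(0, 1))`` per gene.
    Each distinct cluster identity carries a signature block of
    ``n_signature`` genes, with the amplitude chosen so unmatched centroids
    are exactly ``separation`` apart (in units of the per-gene log-sd,
    sigma=1); spreading the signature over several genes keeps the planted
    separation meaningful after per-gene standardization.  A query cluster
    matched to a reference cluster shares that centroid exactly;
    ``separation=0`` collapses all centroids to the origin.
    """
    rng = _require_seed(seed)
    match = dict(match or {})
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if n_genes < 20:
        raise ValueError("n_genes must be >= 20")
    for name, size in {**clusters_ref, **clusters_query}.items():
        if size < 1:
            raise ValueError(f"cluster {name!r} is empty")
    for q, r in match.items():
        if q not in clusters_query or r not in clusters_ref:
            raise KeyError(f"match {q!r}->{r!r} names unknown clusters")

    identities = list(clusters_ref) + [q for q in clusters_query if q not in match]
    n_signature = 20
    if len(identities) * n_signature > n_genes:
        raise ValueError(
            f"need n_genes >= {n_signature} x number of distinct cluster identities"
        )
    genes = [f"g{j:04d}" for j in range(n_genes)]
    centroids = pd.DataFrame(0.0, index=identities, columns=genes)
    # Target a centroid distance of `separation` after the per-gene
    # standardization downstream embeddings apply: standardizing a
    # signature gene divides by sqrt(1 + f(1-f) a^2) where f is the
    # fraction of cells carrying the signature, so the raw amplitude is
    # inflated to compensate.
    sizes = dict(clusters_ref)
    for q, n in clusters_query.items():
        ident = match.get(q, q)
        sizes[ident] = sizes.get(ident, 0) + n
    n_cells_total = sum(sizes.values())
    b = separation / math.sqrt(2 * n_signature)
    for axis, ident in enumerate(identities):
        f = sizes[ident] / n_cells_total
        shrink = 1 - f * (1 - f) * b**2
        if shrink <= 0.05:
            raise ValueError("separation too large for the signature size")
        amplitude = b / math.sqrt(shrink)
        block = slice(axis * n_signature, (axis + 1) * n_signature)
        centroids.iloc[axis, block] = amplitude

    def centroid_of(dataset: str, cluster: str) -> np.ndarray:
        ident = match.get(cluster, cluster) if dataset == "query" else cluster
        return centroids.loc[ident].to_numpy()

    def build(dataset: str, clusters: Mapping[str, int]) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
        rows, meta = [], []
        for cluster, size in clusters.items():
            mu = centroid_of(dataset, cluster)
            logs = mu + rng.normal(0.0, 1.0, size=(size, n_genes))
            rows.append(np.exp(logs))
            meta.extend((f"{dataset}_{cluster}_{k:04d}", dataset, cluster) for k in range(size))
        cells = [m[0] for m in meta]
        return pd.DataFrame(np.vstack(rows), index=cells, columns=genes), meta

    expr_ref, meta_r = build("reference", clusters_ref)
    expr_query, meta_q = build("query", clusters_query)
    labels = pd.DataFrame(
        [(m[1], m[2]) for m in meta_r + meta_q],
        index=[m[0] for m in meta_r + meta_q],
        columns=["dataset", "cluster"],
    )
    labels.index.name = "cell"
    return ClusterExpressionSim(expr_query, expr_ref, labels, centroids)


@dataclass
class NucleiSimulation:
    stack: ImageStack
    truth: pd.DataFrame    # per nucleus: center, radius, planted channel means
    planted_corr: float


def simulate_nuclei_stack(
    n_nuclei: int = 12,
    shape: tuple[int, int, int] = (36, 110, 110),
    radius_range: tuple[int, int] = (6, 9),
    margin: int = 10,
    corr: float = 0.8,
    noise_sd: float = 2.0,
    dna_value: float = 200.0,
    cha_mean: float = 150.0,
    cha_sd: float = 25.0,
    chb_base: float = 100.0,
    chb_scale: float = 25.0,
    *,
    seed: int,
    max_tries: int = 5000,
) -> NucleiSimulation:
    """Simulate a 3-channel stack of spherical nuclei with correlated
    channel intensities.

    Nuclei are spheres of uniform interior intensity (DNA channel constant,
    channels A and B per-nucleus) placed with pairwise center separation of
    at least ``r_i + r_j + margin``; the per-nucleus (A, B) means are built
    from exactly standardized variates so their *sample* Pearson
    correlation equals ``corr`` (for n >= 3).  Background is zero plus
    Gaussian noise of sd ``noise_sd``, clipped at zero.
    """
    rng = _require_seed(seed)
    if not 0 <= corr <= 1:
        raise ValueError("corr must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    nz, ny, nx = shape
    r_lo, r_hi = radius_range
    if 2 * r_hi + 2 >= min(shape):
        raise ValueError("nuclei do not fit in the volume")

    centers: list[tuple[int, int, int]] = []
    radii: list[int] = []
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not pack nuclei with the requested margins")
        r = int(rng.integers(r_lo, r_hi + 1))
        c = (
            int(rng.integers(r + 1, nz - r - 1)),
            int(rng.integers(r + 1, ny - r - 1)),
            int(rng.integers(r + 1, nx - r - 1)),
        )
        ok = all(
            math.dist(c, c2) >= r + r2 + margin for c2, r2 in zip(centers, radii)
        )
        if ok:
            centers.append(c)
            radii.append(r)

    if n_nuclei >= 3:
        for _ in range(100):
            z1 = rng.normal(size=n_nuclei)
            z2 = rng.normal(size=n_nuclei)
            u = (z1 - z1.mean()) / z1.std()
            z2c = z2 - z2.mean()
            resid = z2c - (z2c @ u) / (u @ u) * u
            if resid.std() == 0:
                continue
            w = resid / resid.std()
            v = corr * u + math.sqrt(1 - corr**2) * w
            mean_a = cha_mean + cha_sd * u
            mean_b = chb_base + chb_scale * v
            if (mean_a > 1).all() and (mean_b > 1).all():
                break
        else:
            raise RuntimeError("could not draw positive channel intensities")
    elif n_nuclei > 0:
        mean_a = cha_mean + cha_sd * rng.normal(size=n_nuclei)
        mean_b = chb_base + chb_scale * rng.normal(size=n_nuclei)
        mean_a = np.maximum(mean_a, 1.0)
        mean_b = np.maximum(mean_b, 1.0)
    else:
        mean_a = np.array([])
        mean_b = np.array([])

    channels = ("dapi", "chA", "chB")
    data = rng.normal(0.0, noise_sd, size=(nz, ny, nx, len(channels))) if noise_sd > 0 else np.zeros(
        (nz, ny, nx, len(channels))
    )
    data = np.maximum(data, 0.0)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    for i, ((cz, cy, cx), r) in enumerate(zip(centers, radii)):
        sphere = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        data[sphere, 0] = dna_value
        data[sphere, 1] = mean_a[i]
        data[sphere, 2] = mean_b[i]

    stack = ImageStack(data, channels, dna_channel="dapi")
    truth = pd.DataFrame(
        {
            "z": [c[0] for c in centers],
            "y": [c[1] for c in centers],
            "x": [c[2] for c in centers],
            "radius": radii,
            "mean_dapi": dna_value if n_nuclei else [],
            "mean_chA": mean_a,
            "mean_chB": mean_b,
        },
        index=pd.RangeIndex(n_nuclei, name="nucleus"),
    )
    return NucleiSimulation(stack, truth, corr)
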