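"""Synthetic DamID data with planted ground truth.

Emulates the structure of a whole-genome tiling-array DamID study in a
small worm-like genome: ~50-bp probes at 50-bp spacing, nuclear-envelope
domains enriched on chromosome arms and depleted in centers, two highly
correlated factor tracks (sharing one latent domain architecture) with
planted factor-exclusive elements, genotype-dependent "detached"
intervals, replicate structure with a linear GC bias and AR(1)
autocorrelated Gaussian probe noise, a freely-diffusing-control null
track, and exon-level expression with planted de-repression in mutant
genotypes.

Every generator is a pure function of its seed.  The generated truth is
what downstream callers are scored against in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nedomains.annotate import GeneModel
from nedomains.tracks import ProbeTrack, merge_intervals, overlap_bp

FACTORS = ("A", "B")


@dataclass
class GenomeLayout:
    """Probe tiling of a synthetic genome."""

    chrom_lengths: dict[str, int]
    probe_length: int
    spacing: int
    probes: pd.DataFrame  # chrom, start, end, gc_count

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass
class ElementPlan:
    """How many exclusive elements to plant and at what signal levels."""

    count_per_factor: dict[str, int] = field(default_factory=lambda: {"A": 8, "B": 4})
    length_bp: int = 750  # short regions, sub-kilobase median
    own_level: float = 1.5
    other_level: float = -0.5
    min_probes: int = 10  # used only to validate plantability


@dataclass
class DetachedPlan:
    """Intervals associated in wild type but released in the mutant."""

    count: int = 6
    length_bp: int = 5_000
    factor: str = "A"


@dataclass
class LatentArchitecture:
    """Ground-truth nuclear-envelope association of the synthetic genome."""

    domains: dict[str, pd.DataFrame]  # factor -> (chrom, start, end, level)
    elements: dict[str, pd.DataFrame]  # factor -> (chrom, start, end, own_level, other_level)
    detached: pd.DataFrame  # chrom, start, end (subset of the WT factor's domains)
    arms: pd.DataFrame  # chrom, start, end
    centers: pd.DataFrame  # chrom, start, end


@dataclass
class NoiseModel:
    """Probe-level noise: AR(1) Gaussian plus a linear GC bias.

    sd
        Marginal standard deviation of the probe noise (score units).
    rho
        Lag-1 autocorrelation along the probe order, in [0, 1).
    gc_coeff
        Linear bias in score units per GC count, applied as
        ``gc_coeff * (gc - probe_length / 2)`` so it is centered.
    n_replicates
        Biological replicates per strain.
    seed
        Fixes every draw.
    """

    sd: float = 1.0
    rho: float = 0.5
    gc_coeff: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 <= self.rho < 1):
            raise ValueError("autocorrelation must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def make_genome(
    chrom_lengths: dict[str, int],
    probe_length: int = 50,
    spacing: int = 50,
    gc_model: str | tuple[int, int] = "uniform",
    seed: int = 0,
) -> GenomeLayout:
    """Tile each chromosome with fixed-length probes at a fixed spacing.

    Probe count per chromosome is ``floor((L - probe_length)/spacing) + 1``.
    ``gc_model`` is "uniform" (GC count uniform on 0..probe_length) or an
    inclusive (low, high) range.
    """
    if probe_length <= 0 or spacing <= 0:
        raise ValueError("probe length and spacing must be positive")
    for chrom, length in chrom_lengths.items():
        if length < probe_length:
            raise ValueError(f"chromosome {chrom} shorter than one probe")
    if gc_model == "uniform":
        gc_lo, gc_hi = 0, probe_length
    else:
        gc_lo, gc_hi = gc_model
        if not (0 <= gc_lo <= gc_hi <= probe_length):
            raise ValueError("GC range must lie within [0, probe_length]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    frames = []
    for chrom, length in chrom_lengths.items():
        n = (length - probe_length) // spacing + 1
        starts = np.arange(n, dtype=np.int64) * spacing
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + probe_length,
                    "gc_count": rng.integers(gc_lo, gc_hi + 1, size=n),
                }
            )
        )
    probes = pd.concat(frames, ignore_index=True)
    return GenomeLayout(dict(chrom_lengths), probe_length, spacing, probes)


def default_partition(
    chrom_lengths: dict[str, int], arm_fraction: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arm/center split: outer ``arm_fraction`` of each chromosome end is arm."""
    arms, centers = [], []
    for chrom, length in chrom_lengths.items():
        cut = int(round(length * arm_fraction))
        arms.append((chrom, 0, cut))
        arms.append((chrom, length - cut, length))
        centers.append((chrom, cut, length - cut))
    cols = ["chrom", "start", "end"]
    return pd.DataFrame(arms, columns=cols), pd.DataFrame(centers, columns=cols)


def _place_domains(
    region: tuple[str, int, int],
    density: float,
    rng: np.random.Generator,
    median_bp: float,
    sigma_log: float,
    min_bp: int,
) -> list[tuple[str, int, int]]:
    """Alternating gap/domain renewal process targeting a bp density.

    Domain lengths are lognormal around ``median_bp`` (clipped at
    ``min_bp`` so every domain exceeds one calling-window span); gap
    lengths are exponential with mean chosen so the expected bp fraction
    in domains equals ``density``.
    """
    chrom, lo, hi = region
    if density <= 0:
        return []
    mean_dom = median_bp * np.exp(sigma_log**2 / 2)
    mean_gap = max(mean_dom * (1 - density) / density, 1.0)
    out = []
    pos = lo + rng.exponential(mean_gap / 2)
    while pos < hi:
        size = max(min_bp, rng.lognormal(np.log(median_bp), sigma_log))
        end = min(hi, pos + size)
        if end - pos >= min_bp:
            out.append((chrom, int(pos), int(end)))
        pos = end + max(rng.exponential(mean_gap), 1.0)
    return out


def plant_architecture(
    layout: GenomeLayout,
    domain_density_by_region: dict[str, float] | None = None,
    element_params: ElementPlan | None = None,
    detached_params: DetachedPlan | None = None,
    seed: int = 0,
    domain_level: float = 1.5,
    domain_median_bp: float = 23_000,
    domain_sigma_log: float = 0.45,
    domain_min_bp: int = 15_000,
    arm_fraction: float = 0.25,
    partition: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> LatentArchitecture:
    """Plant an arm-enriched domain architecture shared by both factors.

    Both factors receive the same latent domains (their association
    profiles are strongly correlated in vivo); factor-exclusive elements
    are short intervals inside one factor's domains where the *other*
    factor's domain is locally interrupted, so each element lies inside
    its own factor's domains and outside the other's — with its own
    planted signal level on each track.  Detached intervals are segments
    of wild-type domains whose level drops to zero in the mutant
    genotype.
    """
    densities = domain_density_by_region or {"arm": 0.6, "center": 0.05}
    for name, rho in densities.items():
        if not (0 <= rho <= 1):
            raise ValueError(f"density for {name!r} must be in [0, 1]")
    elem = element_params or ElementPlan()
    if elem.length_bp < elem.min_probes * layout.spacing:
        raise ValueError(
            "element length below min_probes x spacing: elements would be unplantable"
        )
    det = detached_params or DetachedPlan()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    arms, centers = (
        partition
        if partition is not None
        else default_partition(layout.chrom_lengths, arm_fraction)
    )

    shared: list[tuple[str, int, int]] = []
    for frame, key in ((arms, "arm"), (centers, "center")):
        for chrom, lo, hi in zip(frame["chrom"], frame["start"], frame["end"]):
            shared.extend(
                _place_domains(
                    (chrom, lo, hi),
                    densities[key],
                    rng,
                    domain_median_bp,
                    domain_sigma_log,
                    domain_min_bp,
                )
            )
    shared_df = pd.DataFrame(shared, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    # carve exclusive elements: interval inside an own-factor domain where
    # the other factor's domain is interrupted (with a margin so the hole
    # is wider than the element, keeping containment strict)
    margin = 2 * layout.spacing
    holes: dict[str, list[tuple[str, int, int]]] = {f: [] for f in FACTORS}
    elements: dict[str, list[tuple[str, int, int]]] = {f: [] for f in FACTORS}
    eligible = shared_df[
        (shared_df["end"] - shared_df["start"]) >= elem.length_bp + 4 * margin
    ].reset_index(drop=True)
    order = rng.permutation(len(eligible))
    cursor = 0
    for factor, other in ((FACTORS[0], FACTORS[1]), (FACTORS[1], FACTORS[0])):
        for _ in range(elem.count_per_factor.get(factor, 0)):
            if cursor >= len(order):
                raise ValueError("not enough eligible domains to plant elements")
            row = eligible.iloc[order[cursor]]
            cursor += 1
            lo = int(row["start"]) + margin
            hi = int(row["end"]) - margin - elem.length_bp
            start = int(rng.integers(lo, hi + 1))
            elements[factor].append((row["chrom"], start, start + elem.length_bp))
            holes[other].append(
                (row["chrom"], start - margin, start + elem.length_bp + margin)
            )

    domains = {}
    for factor in FACTORS:
        doms = _subtract(shared_df, pd.DataFrame(holes[factor], columns=["chrom", "start", "end"]))
        doms["level"] = domain_level
        domains[factor] = doms

    elem_frames = {}
    for factor in FACTORS:
        frame = pd.DataFrame(elements[factor], columns=["chrom", "start", "end"])
        frame["own_level"] = elem.own_level
        frame["other_level"] = elem.other_level
        elem_frames[factor] = frame.sort_values(["chrom", "start"], ignore_index=True)

    # detached intervals: interior segments of the WT factor's domains
    det_rows = []
    wt_doms = domains[det.factor]
    big = wt_doms[(wt_doms["end"] - wt_doms["start"]) >= det.length_bp + 2 * margin]
    big = big.reset_index(drop=True)
    # avoid domains already hosting an element hole on either track
    used = pd.concat(
        [pd.DataFrame(elements[f], columns=["chrom", "start", "end"]) for f in FACTORS],
        ignore_index=True,
    )
    order = rng.permutation(len(big))
    taken = 0
    for idx in order:
        if taken >= det.count:
            break
        row = big.iloc[idx]
        cand = pd.DataFrame(
            [(row["chrom"], int(row["start"]), int(row["end"]))],
            columns=["chrom", "start", "end"],
        )
        if len(used) and overlap_bp(cand, used) > 0:
            continue
        lo = int(row["start"]) + margin
        hi = int(row["end"]) - margin - det.length_bp
        start = int(rng.integers(lo, hi + 1))
        det_rows.append((row["chrom"], start, start + det.length_bp))
        taken += 1
    detached = pd.DataFrame(det_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    return LatentArchitecture(domains, elem_frames, detached, arms, centers)


def _subtract(intervals: pd.DataFrame, holes: pd.DataFrame) -> pd.DataFrame:
    """Remove hole intervals from an interval table (both bp-level)."""
    if len(holes) == 0:
        return intervals.loc[:, ["chrom", "start", "end"]].copy()
    out = []
    for chrom, start, end in zip(intervals["chrom"], intervals["start"], intervals["end"]):
        segs = [(int(start), int(end))]
        sub = holes[holes["chrom"] == chrom]
        for h_lo, h_hi in zip(sub["start"], sub["end"]):
            new = []
            for lo, hi in segs:
                if h_hi <= lo or h_lo >= hi:
                    new.append((lo, hi))
                    continue
                if lo < h_lo:
                    new.append((lo, int(h_lo)))
                if h_hi < hi:
                    new.append((int(h_hi), hi))
            segs = new
        out.extend((chrom, lo, hi) for lo, hi in segs)
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def _latent_mean(
    layout: GenomeLayout,
    architecture: LatentArchitecture,
    factor: str,
    genotype: str,
) -> np.ndarray:
    """Per-probe latent signal for one factor track in one genotype."""
    mean = np.zeros(layout.n_probes)
    starts = layout.probes["start"].to_numpy()
    chroms = layout.probes["chrom"].to_numpy()
    offsets: dict[str, tuple[int, np.ndarray]] = {}
    pos = 0
    for chrom in dict.fromkeys(chroms):
        n = int(np.sum(chroms == chrom))
        offsets[chrom] = (pos, starts[pos : pos + n])
        pos += n

    def paint(frame: pd.DataFrame, levels: np.ndarray) -> None:
        for (chrom, lo, hi), level in zip(
            frame[["chrom", "start", "end"]].itertuples(index=False), levels
        ):
            if chrom not in offsets:
                continue
            off, s = offsets[chrom]
            i = np.searchsorted(s, lo, "left")
            j = np.searchsorted(s, hi, "left")
            mean[off + i : off + j] = level

    doms = architecture.domains[factor]
    paint(doms, doms["level"].to_numpy())
    if genotype == "mutant" and len(architecture.detached):
        paint(architecture.detached, np.zeros(len(architecture.detached)))
    # elements override: own level on the factor's own track, the planted
    # (typically negative) other level on the opposite track
    own = architecture.elements[factor]
    paint(own, own["own_level"].to_numpy())
    other_factor = FACTORS[1] if factor == FACTORS[0] else FACTORS[0]
    other = architecture.elements[other_factor]
    paint(other, other["other_level"].to_numpy())
    return mean


def _ar1_noise(
    layout: GenomeLayout, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) Gaussian noise with marginal sd ``noise.sd``, per chromosome."""
    from scipy.signal import lfilter

    out = np.empty(layout.n_probes)
    chroms = layout.probes["chrom"].to_numpy()
    scale = np.sqrt(1 - noise.rho**2)
    pos = 0
    for chrom in dict.fromkeys(chroms):
        n = int(np.sum(chroms == chrom))
        z = rng.standard_normal(n)
        x = scale * z
        x[0] = z[0]  # stationary start: e_0 ~ N(0, 1)
        e = lfilter([1.0], [1.0, -noise.rho], x)
        out[pos : pos + n] = noise.sd * e
        pos += n
    return out


def simulate_damid(
    layout: GenomeLayout,
    architecture: LatentArchitecture,
    noise: NoiseModel,
    factor: str,
    genotype: str = "wt",
) -> tuple[ProbeTrack, ProbeTrack]:
    """Simulate raw log-ratio replicates for one factor plus a null control.

    Each replicate is latent mean + centered linear GC bias + AR(1)
    Gaussian noise; the null control (freely diffusing Dam over itself)
    has latent mean zero everywhere with the same bias and noise
    structure.  All draws are fixed by ``noise.seed`` together with the
    factor/genotype identity.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}")
    mean = _latent_mean(layout, architecture, factor, genotype)
    gc = layout.probes["gc_count"].to_numpy()
    bias = noise.gc_coeff * (gc - layout.probe_length / 2)
    factor_code = FACTORS.index(factor)
    genotype_code = {"wt": 0, "mutant": 1}[genotype]

    def replicates(latent: np.ndarray, control: int) -> np.ndarray:
        cols = []
        for r in range(noise.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([noise.seed, factor_code, genotype_code, control, r])
            )
            cols.append(latent + bias + _ar1_noise(layout, noise, rng))
        return np.column_stack(cols)

    signal = ProbeTrack(
        layout.probes.copy(), replicates(mean, 0), sample=f"{factor}:{genotype}"
    )
    null = ProbeTrack(
        layout.probes.copy(),
        replicates(np.zeros_like(mean), 1),
        sample="control",
    )
    return signal, null


def make_genes(
    layout: GenomeLayout,
    architecture: LatentArchitecture,
    n_genes: int = 1000,
    gene_bp: int = 2000,
    n_exons: int = 3,
    seed: int = 0,
) -> list[GeneModel]:
    """Random gene models, guaranteeing coverage of detached intervals.

    Genes are uniform over the genome; one gene is centered in each
    detached interval so that planted de-repression always has a target.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    chrom_names = list(layout.chrom_lengths)
    lengths = np.array([layout.chrom_lengths[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    genes: list[GeneModel] = []

    def build(gene_id: str, chrom: str, start: int) -> GeneModel:
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, start + gene_bp) if strand == "+" else (start + gene_bp, start)
        bounds = np.sort(
            rng.choice(np.arange(1, gene_bp), size=2 * n_exons - 2, replace=False)
        )
        edges = np.concatenate(([0], bounds, [gene_bp]))
        exons = [
            (start + int(edges[2 * i]), start + int(edges[2 * i + 1]))
            for i in range(n_exons)
        ]
        return GeneModel(gene_id, chrom, strand, tss, tes, exons)

    for i, (chrom, lo, hi) in enumerate(
        zip(
            architecture.detached["chrom"],
            architecture.detached["start"],
            architecture.detached["end"],
        )
    ):
        center = (int(lo) + int(hi)) // 2
        genes.append(build(f"det{i:04d}", chrom, max(0, center - gene_bp // 2)))
    for i in range(n_genes - len(genes)):
        ci = rng.choice(len(chrom_names), p=probs)
        chrom = chrom_names[ci]
        start = int(rng.integers(0, layout.chrom_lengths[chrom] - gene_bp))
        genes.append(build(f"g{i:05d}", chrom, start))
    return genes


def simulate_expression(
    gene_models: list[GeneModel],
    architecture: LatentArchitecture,
    baseline: float = 20.0,
    derepression_fold: float = 4.0,
    dispersion: float = 0.05,
    groups: dict[str, int] | None = None,
    seed: int = 0,
    control_group: str = "wt",
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Per-exon coverage values per sample with planted de-repression.

    Genes overlapping a detached (released) interval have mean coverage
    ``baseline * derepression_fold`` in every non-control group, and
    ``baseline`` otherwise.  Exon values carry multiplicative
    gamma-distributed noise with squared coefficient of variation
    ``dispersion`` (the overdispersion of a gamma-Poisson count model in
    its coverage limit); ``dispersion = 0`` is the noise-free limit.

    Returns (exon table [exon x sample], exon-to-locus map, sample-to-group map).
    """
    if derepression_fold <= 0:
        raise ValueError("fold must be positive")
    groups = groups or {"wt": 3, "double": 2}
    for g, n in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    if control_group not in groups:
        raise ValueError("control group missing from groups")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    det = architecture.detached
    released = set()
    for gene in gene_models:
        if len(gene.exons) == 0:
            raise ValueError(f"gene {gene.gene_id} has no exons")
        lo, hi = gene.span()
        sub = det[det["chrom"] == gene.chrom]
        if len(sub) and np.any((sub["start"] < hi) & (sub["end"] > lo)):
            released.add(gene.gene_id)

    sample_groups: dict[str, str] = {}
    for g, n in groups.items():
        for r in range(n):
            sample_groups[f"{g}_{r + 1}"] = g

    exon_ids, exon_to_locus = [], {}
    for gene in gene_models:
        for k in range(len(gene.exons)):
            eid = f"{gene.gene_id}.e{k}"
            exon_ids.append(eid)
            exon_to_locus[eid] = gene.gene_id

    data = {}
    for sample, group in sample_groups.items():
        col = np.empty(len(exon_ids))
        i = 0
        for gene in gene_models:
            mean = baseline
            if gene.gene_id in released and group != control_group:
                mean = baseline * derepression_fold
            for _ in gene.exons:
                if dispersion > 0:
                    col[i] = mean * rng.gamma(1.0 / dispersion, dispersion)
                else:
                    col[i] = mean
                i += 1
        data[sample] = col
    table = pd.DataFrame(data, index=exon_ids)
    return table, exon_to_locus, sample_groups


def true_positive_probe_windows(
    layout: GenomeLayout, architecture: LatentArchitecture, factor: str, window: int
) -> np.ndarray:
    """Boolean per-window truth: does the window overlap a true domain?

    Helper for false-discovery-proportion checks; windows are anchored at
    every probe index with ``window`` successors on the same chromosome,
    matching the caller's geometry.
    """
    starts = layout.probes["start"].to_numpy()
    ends = layout.probes["end"].to_numpy()
    chroms = layout.probes["chrom"].to_numpy()
    truth = merge_intervals(architecture.domains[factor])
    flags = []
    pos = 0
    for chrom in dict.fromkeys(chroms):
        n = int(np.sum(chroms == chrom))
        if n >= window:
            sub = truth[truth["chrom"] == chrom]
            t_starts = sub["start"].to_numpy()
            t_ends = sub["end"].to_numpy()
            idx = np.arange(pos, pos + n - window + 1)
            w_lo = starts[idx]
            w_hi = ends[idx + window - 1]
            if len(t_starts):
                j = np.searchsorted(t_ends, w_lo, "right")
                ok = j < len(t_starts)
                hit = ok & (t_starts[np.minimum(j, len(t_starts) - 1)] < w_hi)
                flags.append(hit)
            else:
                flags.append(np.zeros(len(idx), dtype=bool))
        pos += n
    if not flags:
        return np.zeros(0, dtype=bool)
    return np.concatenate(flags)
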