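"""File formats, run configuration and the end-to-end pipeline driver.

Tracks travel as bedGraph (chrom, start, end, score — one file per
sample/replicate) with a tabular GC sidecar (chrom, start, end,
gc_count); interval sets as BED; configuration as a flat YAML file whose
keys mirror the per-stage parameter dataclasses.  All coordinates are
0-based half-open on disk and in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nedomains import annotate, elements as elements_mod, expression as expr_mod
from nedomains import domains as domains_mod
from nedomains import normalize as norm_mod
from nedomains import synth as synth_mod
from nedomains.tracks import DomainSet, ElementSet, ProbeTrack

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file."""


def read_probe_track(path: str | Path, sidecar: str | Path, sample: str = "") -> ProbeTrack:
    """Read a bedGraph track and join its GC sidecar into a ProbeTrack.

    The sidecar is a TSV with header ``chrom start end gc_count`` keyed by
    (chrom, start).  Unsorted input is sorted with a logged warning; a
    probe missing from the sidecar raises a join error naming the first
    offender.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, start, end, score = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            rows.append((chrom, start, end, score))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if not frame[["chrom", "start"]].equals(
        frame.sort_values(["chrom", "start"], kind="mergesort")[["chrom", "start"]].reset_index(drop=True)
    ):
        logger.warning("%s: input not sorted; sorting", path)
        frame = frame.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    gc = pd.read_csv(sidecar, sep="\t")
    merged = frame.merge(gc[["chrom", "start", "gc_count"]], on=["chrom", "start"], how="left")
    if merged["gc_count"].isna().any():
        bad = merged[merged["gc_count"].isna()].iloc[0]
        raise ParseError(
            f"sidecar {sidecar} lacks GC for probe {bad['chrom']}:{bad['start']}"
        )
    probes = merged[["chrom", "start", "end"]].copy()
    probes["gc_count"] = merged["gc_count"].astype(int)
    return ProbeTrack(probes, merged["score"].to_numpy(), sample=sample)


def write_probe_track(track: ProbeTrack, path: str | Path, replicate: int = 0) -> None:
    """Write one replicate column of a track as bedGraph."""
    frame = track.probes[["chrom", "start", "end"]].copy()
    frame["score"] = track.scores[:, replicate]
    frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_gc_sidecar(track: ProbeTrack, path: str | Path) -> None:
    track.probes[["chrom", "start", "end", "gc_count"]].to_csv(path, sep="\t", index=False)


def write_intervals(
    interval_set: DomainSet | ElementSet, path: str | Path, score_scale: float = 1000.0
) -> None:
    """Write an interval set as BED with a parameter-recording header.

    The name column holds the set label; the score column the mean window
    value (domains) or probe count (elements), clamped to BED's 0-1000.
    """
    iv = interval_set.intervals
    with open(path, "w") as fh:
        fh.write(f"# label={interval_set.label} params={json.dumps(interval_set.params, sort_keys=True)}\n")
        for _, row in iv.iterrows():
            if "score" in iv.columns:
                score = int(np.clip(round(float(row["score"]) * score_scale), 0, 1000))
            elif "n_probes" in iv.columns:
                score = int(np.clip(int(row["n_probes"]), 0, 1000))
            else:
                score = 0
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{interval_set.label}\t{score}\n"
            )


def read_intervals(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


#: Arm/center coordinates of the C. elegans chromosomes (0-based
#: half-open, converted from the 1-based inclusive reference ranges) used
#: when analyzing real data at full scale.  The X right arm is not part
#: of the reference partition.
CELEGANS_ARMS: dict[str, list[tuple[int, int]]] = {
    "chrI": [(0, 3_745_632), (10_809_937, 15_072_421)],
    "chrII": [(0, 4_708_341), (11_877_167, 15_279_323)],
    "chrIII": [(0, 3_508_994), (9_947_267, 13_783_681)],
    "chrIV": [(0, 7_317_812), (12_176_624, 17_493_785)],
    "chrX": [(0, 4_191_936)],
}


@dataclass
class RunConfig:
    """All parameters of an end-to-end synthetic run.

    Defaults mirror the published analysis: 200-probe windows at
    one-probe offset with binary threshold 0.8 and FDR ceiling 5%,
    300-bp median smoothing, exclusive elements at own >= 1 / other < 0
    with >= 10 probes separated <= 500 bp, 3-kb promoters, SAM Delta 4.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_400_000}
    )
    probe_length: int = 50
    spacing: int = 50
    noise_sd: float = 1.0
    noise_rho: float = 0.5
    gc_coeff: float = 0.02
    n_replicates: int = 3
    domain_density_arm: float = 0.6
    domain_density_center: float = 0.05
    domain_level: float = 1.5
    normalization: norm_mod.NormalizationParams = field(
        default_factory=norm_mod.NormalizationParams
    )
    calling: domains_mod.DomainCallingParams = field(
        default_factory=domains_mod.DomainCallingParams
    )
    elements: elements_mod.ElementParams = field(default_factory=elements_mod.ElementParams)
    sam: expr_mod.SamParams = field(default_factory=expr_mod.SamParams)
    n_genes: int = 600
    baseline: float = 20.0
    derepression_fold: float = 4.0
    dispersion: float = 0.05

    def to_dict(self) -> dict:
        # JSON round-trip turns tuples into lists for clean YAML/JSON output
        return json.loads(json.dumps(asdict(self)))


def prepare_tracks(config: RunConfig):
    """Simulate and normalize both factor tracks plus the null control.

    Returns a dict with the layout, architecture, normalized averaged
    tracks for factors A and B and the control, the replicate-level
    normalized tracks, and the replicate correlation matrices.

    Normalization order mirrors the published chain: per-replicate GC
    standardization and median smoothing, quantile normalization jointly
    over all replicates and backgrounds, then replicate averaging.
    """
    layout = synth_mod.make_genome(
        config.chrom_lengths, config.probe_length, config.spacing, seed=config.seed
    )
    arch = synth_mod.plant_architecture(
        layout,
        {"arm": config.domain_density_arm, "center": config.domain_density_center},
        seed=config.seed,
        domain_level=config.domain_level,
    )
    noise = synth_mod.NoiseModel(
        sd=config.noise_sd,
        rho=config.noise_rho,
        gc_coeff=config.gc_coeff,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )
    raw_a, raw_null = synth_mod.simulate_damid(layout, arch, noise, "A")
    raw_b, _ = synth_mod.simulate_damid(layout, arch, noise, "B")

    norm = {
        name: norm_mod.normalize_track(track, config.normalization)
        for name, track in (("A", raw_a), ("B", raw_b), ("control", raw_null))
    }
    # quantile normalization across the strains being compared; the control
    # self-comparison runs through the identical per-track chain but stays
    # out of the cross-strain pool (its role is sign-based null calibration,
    # which is invariant to any monotone per-column map)
    stacked = np.hstack([norm["A"].scores, norm["B"].scores])
    qn = norm_mod.quantile_normalize(stacked)
    r = config.n_replicates
    out = {}
    correlations = {}
    for i, name in enumerate(("A", "B")):
        track = norm[name].with_scores(qn[:, i * r : (i + 1) * r], sample=name)
        correlations[name] = norm_mod.replicate_correlations(track)
        out[name] = norm_mod.average_replicates(track)
    correlations["control"] = norm_mod.replicate_correlations(norm["control"])
    out["control"] = norm_mod.average_replicates(
        norm["control"].with_scores(norm["control"].scores, sample="control")
    )
    return {
        "layout": layout,
        "architecture": arch,
        "tracks": out,
        "replicate_correlations": correlations,
        "noise": noise,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Full synthetic run: simulate, normalize, call, annotate, test expression.

    Writes tracks, domain/element BED files, FDR and expression tables
    and a manifest with parameters and output checksums into ``out_dir``;
    returns a summary dict.  Outputs are bit-reproducible from the
    configuration and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prep = prepare_tracks(config)
    layout, arch = prep["layout"], prep["architecture"]
    tracks = prep["tracks"]

    domain_sets = {}
    fdr_tables = {}
    for name, label in (("A", "LAD"), ("B", "EAD")):
        domain_sets[name], fdr_tables[name] = domains_mod.call_domains_pipeline(
            tracks[name], tracks["control"], config.calling, label=label
        )
    gaps_a, stats_a = domains_mod.gaps_and_stats(domain_sets["A"], layout.chrom_lengths)
    occupancy, regression = domains_mod.chromosome_occupancy(
        domain_sets["A"], layout.chrom_lengths
    )

    exclusive = {
        "A": elements_mod.call_exclusive_elements(
            tracks["A"], tracks["B"], config.elements, label="A-only"
        ),
        "B": elements_mod.call_exclusive_elements(
            tracks["B"], tracks["A"], config.elements, label="B-only"
        ),
    }
    corr_ab = annotate.track_correlation(tracks["A"], tracks["B"])

    genes = synth_mod.make_genes(layout, arch, n_genes=config.n_genes, seed=config.seed)
    exon_table, exon_to_locus, sample_groups = synth_mod.simulate_expression(
        genes,
        arch,
        baseline=config.baseline,
        derepression_fold=config.derepression_fold,
        dispersion=config.dispersion,
        seed=config.seed,
    )
    matrix = expr_mod.locus_matrix_from_exons(exon_table, exon_to_locus, sample_groups)
    sam = expr_mod.sam_select(matrix, "wt", "double", config.sam)

    # persist outputs
    for name in ("A", "B", "control"):
        write_probe_track(tracks[name], out_dir / f"track_{name}.bedgraph")
    write_gc_sidecar(tracks["A"], out_dir / "probes_gc.tsv")
    for name in ("A", "B"):
        write_intervals(domain_sets[name], out_dir / f"domains_{name}.bed")
        write_intervals(exclusive[name], out_dir / f"elements_{name}_only.bed")
        fdr_tables[name].table.to_csv(out_dir / f"fdr_{name}.tsv", sep="\t", index=False)
    sam.table.to_csv(out_dir / "sam.tsv", sep="\t")
    occupancy.to_csv(out_dir / "occupancy.tsv", sep="\t", index=False)

    summary = {
        "config": config.to_dict(),
        "selected_theta": {n: fdr_tables[n].selected_theta for n in ("A", "B")},
        "n_domains": {n: len(domain_sets[n]) for n in ("A", "B")},
        "coverage_fraction": stats_a["coverage_fraction"],
        "n_exclusive_elements": {n: len(exclusive[n]) for n in ("A", "B")},
        "track_correlation_AB": corr_ab,
        "n_significant_loci": int(sam.table["significant"].sum()),
        "occupancy_regression": regression,
        "replicate_correlations": {
            n: np.round(prep["replicate_correlations"][n], 4).tolist()
            for n in ("A", "B", "control")
        },
    }
    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"summary_keys": sorted(summary), "checksums": checksums, "config": config.to_dict()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from flat YAML; missing keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, value in raw.items():
        if key in ("normalization", "calling", "elements", "sam"):
            block = getattr(cfg, key)
            for k, v in value.items():
                if not hasattr(block, k):
                    raise KeyError(f"unknown {key} parameter {k!r}")
                setattr(block, k, v)
            block.__post_init__()
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise KeyError(f"unknown config key {key!r}")
    return cfg


def print_defaults() -> str:
    """YAML rendering of the default configuration."""
    return yaml.safe_dump(RunConfig().to_dict(), sort_keys=False)
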