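"""One-command orchestration: tracks → peaks → binding matrix → classes →
class annotation → boundary analysis, with a machine-readable report.

``run_analysis`` is the in-memory engine; ``run_pipeline`` wraps it with
manifest-driven file I/O.  All randomness (RGR draws) flows from one root
seed via named substreams, and the JSON report is byte-identical across
runs of the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, features, peaks as peakmod
from .classify import ClassModel, classify as classify_matrix
from .core_io import (GeneAnnotation, GenomeModel, RegionSet, SignalTrack, dump_yaml,
                      load_gene_annotation, load_regions, load_signal_track, load_yaml,
                      read_tsv, write_bed, write_bedgraph, write_gene_annotation,
                      write_tsv)
from .synthetic import SimulatedDataset, TruthTable

logger = logging.getLogger("crmclass")


@dataclass(frozen=True)
class AnalysisParams:
    """All tunable parameters of the classification pipeline."""

    alpha: float = 0.5
    smoothing_window: int = 100
    percentile: float = 95.0
    min_peak_length: int = 200
    protein_half_window: int = 150
    histone_half_window: int = 250
    n_consecutive: int = 3
    floor: bool = True
    n_classes: int = 9
    selection: str = "fixed"
    n_components: int = 4
    promoter_window: tuple[int, int] = (500, 100)
    flank: int = 10_000
    out_bin: int = 100
    max_domain_distance: int = 10_000
    rgr_draws: int = 50
    seed: int = 0


def paper_preset(**overrides) -> AnalysisParams:
    """The published parameterization: 10 bp bins (set at simulation/IO
    time), 100 bp median smoothing, 95th percentile, 200 bp minimum,
    ±150 bp protein / ±250 bp histone windows, four fixed components, nine
    classes."""
    return replace(AnalysisParams(), **overrides)


def synthetic_preset(n_archetypes: int = 6, **overrides) -> AnalysisParams:
    """Data-driven preset for the synthetic bundle: classes match the
    planted archetype count and components are chosen by broken stick."""
    return replace(AnalysisParams(n_classes=n_archetypes, selection="broken_stick"),
                   **overrides)


@dataclass
class AnalysisResult:
    params: AnalysisParams
    enrichment: SignalTrack
    smoothed: SignalTrack
    peaks: list
    matrix: features.BindingMatrix
    model: ClassModel
    labels: np.ndarray
    summary: pd.DataFrame
    report: dict


def match_peaks_to_truth(peaks: list, truth: TruthTable) -> list[str | None]:
    """Per peak, the label of any overlapping planted element (None if the
    peak lies outside every truth element)."""
    out: list[str | None] = []
    by_chrom = {}
    for chrom, sub in truth.df.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                           sub["label"].to_numpy())
    for p in peaks:
        label = None
        if p.chrom in by_chrom:
            s, e, lab = by_chrom[p.chrom]
            j = np.searchsorted(s, p.end, side="left")
            if j > 0 and e[j - 1] > p.start:
                label = str(lab[j - 1])
        out.append(label)
    return out


def run_analysis(ip: SignalTrack, input_track: SignalTrack,
                 tracks: dict[str, SignalTrack], histone_names: set[str],
                 genes: GeneAnnotation | None = None,
                 expression: pd.Series | None = None,
                 domains: RegionSet | None = None,
                 truth: TruthTable | None = None,
                 params: AnalysisParams | None = None) -> AnalysisResult:
    """Execute the full classification pipeline in memory."""
    params = params or AnalysisParams()
    enr = peakmod.log2_enrichment(ip, input_track, params.alpha)
    sm = peakmod.median_smooth(enr, params.smoothing_window)
    called = peakmod.call_peaks(sm, params.percentile, params.min_peak_length)
    logger.info("called %d peaks", len(called))
    if not called:
        raise ValueError("pipeline aborted at peak calling: no peaks called")

    matrix = features.build_matrix(
        called, tracks, histone_datasets=histone_names,
        protein_half_window=params.protein_half_window,
        histone_half_window=params.histone_half_window,
        n_consecutive=params.n_consecutive, floor=params.floor, alpha=params.alpha)
    model = classify_matrix(matrix.protein_view(), n_classes=params.n_classes,
                            selection=params.selection, k=params.n_components)
    labels = model.labels

    summary = pd.DataFrame()
    if genes is not None and expression is not None:
        summary = annotate.class_summary(called, labels, matrix, genes, expression,
                                         params.promoter_window)

    report: dict = {
        "parameters": {**asdict(params),
                       "promoter_window": list(params.promoter_window)},
        "n_peaks": len(called),
        "peak_threshold": peakmod.peak_threshold(sm, params.percentile),
        "n_significant_components": model.n_significant,
        "class_sizes": {int(c): int((labels == c).sum())
                        for c in sorted(set(labels.tolist()))},
    }
    if not summary.empty:
        report["class_summary"] = json.loads(summary.to_json(orient="index"))
    if truth is not None:
        matched = match_peaks_to_truth(called, truth)
        hit = [m is not None for m in matched]
        truth_regions = truth.regions()
        from .core_io import overlaps_any
        rec_flags = overlaps_any(truth_regions, peakmod.peaks_to_regions(called))
        report["truth_evaluation"] = {
            "sensitivity": float(rec_flags.mean()),
            "false_discovery_rate": float(1.0 - np.mean(hit)),
            "n_truth_elements": len(truth),
        }
        idx = [i for i, m in enumerate(matched) if m is not None]
        if idx:
            from sklearn.metrics import adjusted_rand_score
            report["truth_evaluation"]["adjusted_rand_index"] = float(
                adjusted_rand_score([matched[i] for i in idx], labels[idx]))
    return AnalysisResult(params, enr, sm, called, matrix, model, labels,
                          summary, report)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(ds: SimulatedDataset, outdir) -> Path:
    """Write the full synthetic input bundle plus a manifest consumable by
    ``run_pipeline``; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.genome.to_file(out / "genome.tsv")
    write_bedgraph(ds.ip, out / "ip.bedgraph")
    write_bedgraph(ds.input_track, out / "input.bedgraph")
    track_entries = {}
    for name, tr in ds.tracks.items():
        p = out / f"track_{name}.bedgraph"
        write_bedgraph(tr, p)
        track_entries[name] = {"path": p.name, "is_histone": name in ds.histone_names}
    write_gene_annotation(ds.genes, out / "genes.gff3")
    write_tsv(ds.expression.to_frame(), out / "expression.tsv", index_label="gene_id")
    write_tsv(ds.timecourse, out / "timecourse.tsv", index_label="gene_id")
    write_bed(ds.domains, out / "h3k27me3_domains.bed")
    write_bed(ds.truth.regions(), out / "truth.bed")
    manifest = {
        "genome_file": "genome.tsv",
        "bin_size": ds.genome.bin_size,
        "ip": "ip.bedgraph",
        "input": "input.bedgraph",
        "tracks": track_entries,
        "genes": "genes.gff3",
        "expression": "expression.tsv",
        "timecourse": "timecourse.tsv",
        "domains": "h3k27me3_domains.bed",
        "truth": "truth.bed",
    }
    dump_yaml(manifest, out / "manifest.yaml")
    return out / "manifest.yaml"


@dataclass
class InputBundle:
    genome: GenomeModel
    ip: SignalTrack
    input_track: SignalTrack
    tracks: dict[str, SignalTrack]
    histone_names: set[str]
    genes: GeneAnnotation | None
    expression: pd.Series | None
    timecourse: pd.DataFrame | None
    domains: RegionSet | None
    truth: TruthTable | None


def load_bundle(manifest_path) -> InputBundle:
    mpath = Path(manifest_path)
    m = load_yaml(mpath)
    base = mpath.parent
    for key in ("genome_file", "ip", "input"):
        if not (base / m[key]).exists():
            raise FileNotFoundError(f"manifest entry {key!r}: missing file {m[key]}")
    for name, entry in m.get("tracks", {}).items():
        if not (base / entry["path"]).exists():
            raise FileNotFoundError(f"track {name!r}: missing file {entry['path']}")
    genome = GenomeModel.from_file(base / m["genome_file"], int(m["bin_size"]))
    ip = load_signal_track(base / m["ip"], genome)
    inp = load_signal_track(base / m["input"], genome)
    tracks, histones = {}, set()
    for name, entry in m.get("tracks", {}).items():
        tracks[name] = load_signal_track(base / entry["path"], genome)
        if entry.get("is_histone"):
            histones.add(name)
    genes = load_gene_annotation(base / m["genes"]) if m.get("genes") else None
    expr = (read_tsv(base / m["expression"]).iloc[:, 0]
            if m.get("expression") else None)
    tc = read_tsv(base / m["timecourse"]) if m.get("timecourse") else None
    domains = load_regions(base / m["domains"], genome) if m.get("domains") else None
    truth = None
    if m.get("truth"):
        t = load_regions(base / m["truth"], genome)
        truth = TruthTable(pd.DataFrame({
            "chrom": t.df["chrom"], "start": t.df["start"], "end": t.df["end"],
            "label": t.df["name"], "gene_id": ""}))
    return InputBundle(genome, ip, inp, tracks, histones, genes, expr, tc,
                       domains, truth)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(manifest_path, outdir, params: AnalysisParams | None = None) -> dict:
    """File-based pipeline: load the manifest bundle, run the analysis, and
    write peaks (BED6), matrices/summaries (TSV), the smoothed enrichment
    track (bedGraph) and a deterministic JSON report."""
    params = params or AnalysisParams()
    mpath = Path(manifest_path)
    bundle = load_bundle(mpath)
    result = run_analysis(bundle.ip, bundle.input_track, bundle.tracks,
                          bundle.histone_names, bundle.genes, bundle.expression,
                          bundle.domains, bundle.truth, params)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(peakmod.peaks_to_regions(result.peaks, result.labels), out / "peaks.bed")
    write_tsv(result.matrix.df, out / "binding_matrix.tsv", index_label="peak")
    write_tsv(result.matrix.meta, out / "matrix_metadata.tsv", index_label="dataset")
    labels_df = pd.DataFrame({"peak": [p.id for p in result.peaks],
                              "class": result.labels}).set_index("peak")
    write_tsv(labels_df, out / "classes.tsv", index_label="peak")
    if not result.summary.empty:
        write_tsv(result.summary, out / "class_summary.tsv", index_label="class")
    write_bedgraph(result.smoothed, out / "smoothed_enrichment.bedgraph")

    m = load_yaml(mpath)
    inputs = {"manifest": _hash_file(mpath)}
    for key in ("ip", "input"):
        inputs[key] = _hash_file(mpath.parent / m[key])
    report = dict(result.report)
    report["input_hashes"] = inputs
    report["outputs"] = sorted(p.name for p in out.iterdir())
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
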