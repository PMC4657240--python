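"""Genome model, binned signal tracks, interval sets and standard-format I/O.

All internal coordinates are 0-based half-open; conversions to/from 1-based
conventions (GFF3) happen only at the I/O boundary.  Signal tracks are
rasterized onto a uniform bin grid shared by every track of an analysis:
chromosome ``c`` has ``ceil(len(c) / bin_size)`` bins and the last, possibly
partial, bin is kept and weighted as a full bin in genomic statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crmclass")

REGION_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes, their lengths, and the shared bin width."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    bin_size: int

    def __post_init__(self):
        if not self.chrom_names:
            raise ValueError("genome needs at least one chromosome")
        for c in self.chrom_names:
            if self.chrom_lengths[c] <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.bin_size > min(self.chrom_lengths.values()):
            raise ValueError("bin_size exceeds the shortest chromosome")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @classmethod
    def from_file(cls, path, bin_size: int) -> "GenomeModel":
        """Read a two-column ``chrom<TAB>length`` file."""
        tab = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                          comment="#", dtype={"chrom": str})
        names = tuple(tab["chrom"])
        lengths = dict(zip(tab["chrom"], tab["length"].astype(int)))
        return cls(names, lengths, bin_size)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chrom_names:
                fh.write(f"{c}\t{self.chrom_lengths[c]}\n")


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Genome-wide binned numeric signal.

    ``semantics`` is one of ``raw_density``, ``log2_enrichment`` or
    ``scaled``; ``meta`` records provenance (pseudocount, smoothing window,
    source ids) where applicable.
    """

    genome: GenomeModel
    values: dict[str, np.ndarray]
    semantics: str = "raw_density"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for c in self.genome.chrom_names:
            v = np.asarray(self.values[c], dtype=float)
            if v.shape != (self.genome.n_bins(c),):
                raise ValueError(
                    f"chromosome {c!r}: expected {self.genome.n_bins(c)} bins, "
                    f"got {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values on chromosome {c!r}")
            self.values[c] = v

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.chrom_names])

    def copy(self, semantics: str | None = None, **meta) -> "SignalTrack":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return SignalTrack(self.genome,
                           {c: v.copy() for c, v in self.values.items()},
                           semantics or self.semantics, new_meta)

    @classmethod
    def zeros(cls, genome: GenomeModel, semantics: str = "raw_density") -> "SignalTrack":
        return cls(genome, {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names},
                   semantics)


def genomic_stats(track: SignalTrack) -> tuple[float, float]:
    """Genome-wide (mean, max) over every bin of every chromosome.

    The partial last bin of each chromosome counts as one full bin.  A
    constant track (mean == max) is legal here but degenerate for
    mean/max scaling downstream.
    """
    v = track.all_values()
    if v.size == 0:
        raise ValueError("empty track")
    return float(v.mean()), float(v.max())


def load_signal_track(path, genome: GenomeModel) -> SignalTrack:
    """Rasterize a bedGraph file onto the genome's uniform bin grid.

    Each bin takes the value of the interval covering its midpoint;
    uncovered bins are 0.  Overlapping intervals on a chromosome are a
    format error (the first offending line is named).
    """
    per_chrom: dict[str, list[tuple[int, int, float, int]]] = {c: [] for c in genome.chrom_names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in genome.chrom_lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome.chrom_lengths[chrom]):
                raise ValueError(f"{path}:{lineno}: bad interval {start}-{end}")
            per_chrom[chrom].append((start, end, value, lineno))

    values = {}
    bs = genome.bin_size
    for chrom in genome.chrom_names:
        ivals = sorted(per_chrom[chrom])
        for (s0, e0, _, l0), (s1, e1, _, l1) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom} "
                    f"(line {min(l0, l1)} overlaps line {max(l0, l1)})")
        n = genome.n_bins(chrom)
        v = np.zeros(n)
        if ivals:
            starts = np.array([iv[0] for iv in ivals])
            ends = np.array([iv[1] for iv in ivals])
            vals = np.array([iv[2] for iv in ivals])
            mids = np.arange(n) * bs + bs / 2.0
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(ends) - 1)])
            v[ok] = vals[idx[ok]]
        values[chrom] = v
    return SignalTrack(genome, values, "raw_density", {"source": str(path)})


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write one line per bin (zero bins included, runs not merged)."""
    bs = track.genome.bin_size
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            L = track.genome.chrom_lengths[chrom]
            v = track.values[chrom]
            for i, x in enumerate(v):
                fh.write(f"{chrom}\t{i * bs}\t{min((i + 1) * bs, L)}\t{x:g}\n")


# ---------------------------------------------------------------------------
# Region sets
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Genomic intervals (0-based half-open) with optional name/score/strand."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[REGION_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"region with end <= start: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def validate(self, genome: GenomeModel, lenient: bool = False) -> "RegionSet":
        keep = []
        for i, r in self.df.iterrows():
            ok = (r["chrom"] in genome.chrom_lengths
                  and 0 <= r["start"] < r["end"] <= genome.chrom_lengths.get(r["chrom"], -1))
            if not ok:
                if lenient:
                    logger.warning("skipping out-of-genome region %s:%s-%s",
                                   r["chrom"], r["start"], r["end"])
                    continue
                raise ValueError(f"region outside genome: {r['chrom']}:{r['start']}-{r['end']}")
            keep.append(i)
        return RegionSet(self.df.loc[keep])

    @classmethod
    def from_records(cls, records, names=None) -> "RegionSet":
        """Build from an iterable of (chrom, start, end[, name[, score[, strand]]])."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            rows.append(rec + (".", 0.0, ".")[len(rec) - 3:])
        df = pd.DataFrame(rows, columns=REGION_COLUMNS)
        if names is not None:
            df["name"] = list(names)
        return cls(df)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        return int(self.lengths().sum())


def load_regions(path, genome: GenomeModel | None = None, *,
                 dialect: str | None = None, lenient: bool = False) -> RegionSet:
    """Read BED (as-is) or GFF3 (converted 1-based inclusive → 0-based half-open).

    The dialect is inferred from the file extension unless given.
    """
    path = str(path)
    if dialect is None:
        dialect = "gff3" if path.endswith((".gff", ".gff3", ".gtf")) else "bed"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if dialect == "bed":
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
                strand = parts[5] if len(parts) > 5 else "."
            else:
                if len(parts) < 8:
                    raise ValueError(f"{path}:{lineno}: short GFF3 line")
                chrom = parts[0]
                start, end = int(parts[3]) - 1, int(parts[4])
                name = parts[2]
                score = float(parts[5]) if parts[5] != "." else 0.0
                strand = parts[6]
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start after conversion")
            rows.append((chrom, start, end, name, score, strand))
    rs = RegionSet(pd.DataFrame(rows, columns=REGION_COLUMNS))
    if genome is not None:
        rs = rs.validate(genome, lenient=lenient)
    return rs


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n")


def overlaps_any(query: RegionSet, reference: RegionSet, slop: int = 0) -> np.ndarray:
    """Boolean flag per query region: ≥1 bp intersection with the reference.

    ``slop`` widens both query and reference records on both sides.
    Invariant to reference record order and to merging adjacent reference
    intervals (half-open arithmetic: touching intervals do not overlap).
    """
    flags = np.zeros(len(query), dtype=bool)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ref = reference.df
    for chrom, sub in ref.groupby("chrom"):
        starts = np.maximum(sub["start"].to_numpy() - slop, 0)
        ends = sub["end"].to_numpy() + slop
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # cumulative max of ends handles nested intervals
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    for i, r in enumerate(query):
        if r.chrom not in by_chrom:
            continue
        starts, cummax_ends = by_chrom[r.chrom]
        qs, qe = r.start - slop, r.end + slop
        j = np.searchsorted(starts, qe, side="left")  # refs starting before query end
        if j > 0 and cummax_ends[j - 1] > qs:
            flags[i] = True
    return flags


def distance_to_nearest(positions: np.ndarray, chroms: list[str],
                        reference: RegionSet) -> np.ndarray:
    """bp distance from each point to the nearest reference interval edge
    (0 if the point lies inside an interval); inf when the chromosome holds
    no reference record."""
    out = np.full(len(positions), np.inf)
    by_chrom = {}
    for chrom, sub in reference.df.groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="stable")
        by_chrom[chrom] = (s[order], e[order])
    for i, (p, c) in enumerate(zip(positions, chroms)):
        if c not in by_chrom:
            continue
        s, e = by_chrom[c]
        inside = (s <= p) & (p < e)
        if inside.any():
            out[i] = 0.0
            continue
        d = np.minimum(np.abs(s - p), np.abs(e - 1 - p))
        out[i] = float(d.min())
    return out


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene records with strand-aware TSS positions plus exon intervals.

    ``genes``: DataFrame(gene_id, chrom, strand, start, end, tss);
    ``exons``: DataFrame(gene_id, chrom, start, end).  The TSS is the 5'
    end of the gene span on its strand.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self):
        g = self.genes.reset_index(drop=True).copy()
        if "tss" not in g.columns:
            g["tss"] = np.where(g["strand"] == "-", g["end"] - 1, g["start"])
        spans = g.set_index("gene_id")
        for r in self.exons.itertuples(index=False):
            gs, ge = spans.loc[r.gene_id, "start"], spans.loc[r.gene_id, "end"]
            if not (gs <= r.start < r.end <= ge):
                raise ValueError(f"exon outside gene span for {r.gene_id}")
        self.genes = g
        self.exons = self.exons.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)


def load_gene_annotation(path) -> GeneAnnotation:
    """Read gene and exon features from a GFF3 file (ID=/Parent= attributes)."""
    genes, exons = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand = parts[:7]
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            start, end = int(start) - 1, int(end)
            if ftype == "gene":
                genes.append((attrs.get("ID", attrs.get("gene_id", ".")),
                              chrom, strand, start, end))
            elif ftype == "exon":
                exons.append((attrs.get("Parent", "."), chrom, start, end))
    gdf = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "start", "end"])
    edf = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(gdf, edf)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\tcrmclass\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for e in ann.exons[ann.exons["gene_id"] == g.gene_id].itertuples(index=False):
                fh.write(f"{e.chrom}\tcrmclass\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# FASTA / TSV / YAML helpers
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index_label="id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def configure_logging(verbose: int = 0) -> None:
    """Route package logs to stderr; -v = INFO, -vv = DEBUG."""
    level = logging.WARNING - 10 * min(int(verbose), 2)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
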