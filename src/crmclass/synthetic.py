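"""Synthetic multi-factor ChIP dataset with planted regulatory-element
archetypes and known ground truth.

The generator emulates the statistical structure of a co-activator ChIP
compendium over one desk-scale chromosome: Poisson (optionally
negative-binomial) read-density tracks for an IP/input pair and a panel of
protein and histone-modification datasets; planted elements of six
archetypes (promoter, active enhancer, inactive enhancer, PRE embedded in a
repressive H3K27me3 domain, and insulators that do or do not block domain
spreading); gene models placed so promoter elements straddle TSSs and
enhancers sit in introns; expression and developmental-timecourse tables
correlated with the archetypes; plus sequence sets with planted words and a
qPCR Cq table generator for the boundary assay arithmetic.

Every draw flows from one seed, so a fixed configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, GenomeModel, RegionSet, SignalTrack

PROTEIN_FACTORS = ["CBP", "PolII", "GAF", "Pho", "dSfmbt", "CP190", "SuHw",
                   "SMC1", "NippedB"]
HISTONE_FACTORS = ["H3K4me1", "H3K27ac", "H3K18ac", "H3K23ac", "H3K27me3"]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Emission profile and context of one planted element archetype.

    ``amplitudes`` are expected fold-over-background at the element peak;
    ``domain`` is the H3K27me3-domain behaviour (none | embedded |
    one-sided-stops | one-sided-crosses); ``expression`` the expression
    class of the element's nearest gene; ``placement`` where the element
    sits relative to gene models (tss | intron | intergenic).
    """

    label: str
    amplitudes: dict[str, float]
    width: int = 500
    domain: str = "none"
    expression: str = "mid"
    placement: str = "intergenic"
    count: int = 40

    def __post_init__(self):
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.width < 1:
            raise ValueError("width must be at least 1 bp")


def default_archetypes() -> list[ArchetypeSpec]:
    """The six planted archetypes mirroring promoter / active-enhancer /
    inactive-enhancer / PRE / blocking- and non-blocking-insulator
    signatures."""
    A = ArchetypeSpec
    return [
        A("PROMOTER", {"CBP": 6, "PolII": 10, "GAF": 2, "SMC1": 3, "NippedB": 3,
                       "H3K4me1": 3, "H3K27ac": 4, "H3K18ac": 3, "H3K23ac": 1.5},
          expression="high", placement="tss"),
        A("ENH_ACTIVE", {"CBP": 6, "GAF": 4, "SMC1": 3, "NippedB": 3,
                         "H3K4me1": 8, "H3K27ac": 8, "H3K18ac": 8, "H3K23ac": 2},
          expression="high", placement="intron"),
        A("ENH_INACTIVE", {"CBP": 5, "GAF": 1.5, "H3K4me1": 6, "H3K23ac": 2.5},
          expression="low", placement="intron"),
        A("PRE", {"CBP": 12, "Pho": 10, "dSfmbt": 8, "GAF": 3, "H3K4me1": 2},
          domain="embedded", expression="low", placement="intergenic"),
        A("INS_BLOCKING", {"CBP": 5, "CP190": 8, "SuHw": 6, "SMC1": 6, "NippedB": 6,
                           "H3K27ac": 4, "H3K18ac": 4, "H3K23ac": 2},
          domain="one-sided-stops", expression="mid", placement="intergenic"),
        A("INS_NONBLOCKING", {"CBP": 5, "CP190": 8, "SuHw": 6, "H3K23ac": 1.2},
          domain="one-sided-crosses", expression="mid", placement="intergenic"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the default synthetic dataset: one 5 Mb
    chromosome binned at 10 bp, Poisson background of 20 reads/bin, 40
    elements of 500 bp per archetype, Gaussian element kernel with
    σ = width/4 truncated at the element boundary."""

    chrom_name: str = "chrS"
    chrom_length: int = 5_000_000
    bin_size: int = 10
    lambda_bg: float = 20.0
    archetypes: tuple[ArchetypeSpec, ...] = field(
        default_factory=lambda: tuple(default_archetypes()))
    margin: int = 30_000
    jitter: int = 500
    kernel: str = "gaussian"          # or "flat"
    noise: str = "poisson"            # or "nb"
    nb_dispersion: float = 0.1
    domain_amplitude: float = 4.0
    pre_domain_halfwidth: int = 8_000
    ins_domain_extent: int = 9_000    # bp of domain beyond the element edge
    strength_sigma: float = 0.2       # per-element log-normal intensity jitter
    strength_clip: tuple[float, float] = (0.8, 1.5)

    def scaled_down(self, factor: int) -> "SimConfig":
        """Same conditions on a genome shrunk by ``factor`` (element counts
        shrink with it); used for fast file-round-trip checks."""
        arch = tuple(replace(a, count=max(a.count // factor, 2)) for a in self.archetypes)
        return replace(self, chrom_length=self.chrom_length // factor, archetypes=arch)


@dataclass
class TruthTable:
    """Planted-element ground truth: positions, archetype labels, genes."""

    df: pd.DataFrame  # chrom, start, end, label, gene_id

    def __len__(self) -> int:
        return len(self.df)

    def regions(self, label: str | None = None) -> RegionSet:
        sub = self.df if label is None else self.df[self.df["label"] == label]
        return RegionSet.from_records(
            [(r.chrom, r.start, r.end, r.label) for r in sub.itertuples(index=False)])

    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()


@dataclass
class SimulatedDataset:
    genome: GenomeModel
    ip: SignalTrack
    input_track: SignalTrack
    tracks: dict[str, SignalTrack]
    histone_names: set[str]
    genes: GeneAnnotation
    expression: pd.Series
    timecourse: pd.DataFrame
    domains: RegionSet
    truth: TruthTable
    config: SimConfig


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place_elements(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    total = sum(a.count for a in cfg.archetypes)
    usable = cfg.chrom_length - 2 * cfg.margin
    step = usable / total
    max_w = max(a.width for a in cfg.archetypes)
    if step < max_w + 2 * cfg.jitter + 1000:
        raise ValueError(
            f"genome too small: {total} elements of ≤{max_w} bp need more than "
            f"{cfg.chrom_length} bp at this spacing")
    labels = np.concatenate([[a.label] * a.count for a in cfg.archetypes])
    labels = labels[rng.permutation(total)]
    rows = []
    for i, label in enumerate(labels):
        spec = next(a for a in cfg.archetypes if a.label == label)
        c = int(cfg.margin + step * (i + 0.5)) + int(rng.integers(-cfg.jitter, cfg.jitter + 1))
        rows.append({"chrom": cfg.chrom_name, "start": c - spec.width // 2,
                     "end": c - spec.width // 2 + spec.width, "centre": c,
                     "label": label})
    return pd.DataFrame(rows)


def _gene_for_element(centre: int, label: str, placement: str, idx: int,
                      chrom: str) -> tuple[dict, list[dict]]:
    gid = f"g{idx:04d}"
    if placement == "tss":
        if idx % 2 == 0:
            gene = {"gene_id": gid, "chrom": chrom, "strand": "+",
                    "start": centre, "end": centre + 5000}
            exons = [(centre, centre + 200), (centre + 4800, centre + 5000)]
        else:  # '-' strand: TSS = end - 1 = centre
            gene = {"gene_id": gid, "chrom": chrom, "strand": "-",
                    "start": centre - 5000, "end": centre + 1}
            exons = [(centre - 5000, centre - 4800), (centre - 199, centre + 1)]
    elif placement == "intron":
        gene = {"gene_id": gid, "chrom": chrom, "strand": "+",
                "start": centre - 2000, "end": centre + 3000}
        exons = [(centre - 2000, centre - 1800), (centre + 2800, centre + 3000)]
    else:  # intergenic element with a nearby dedicated gene
        gene = {"gene_id": gid, "chrom": chrom, "strand": "+",
                "start": centre + 3000, "end": centre + 6000}
        exons = [(centre + 3000, centre + 3200), (centre + 5800, centre + 6000)]
    exon_rows = [{"gene_id": gid, "chrom": chrom, "start": s, "end": e} for s, e in exons]
    return gene, exon_rows


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def _element_kernel(centres_bp: np.ndarray, c: int, width: int, kind: str) -> np.ndarray:
    if kind == "flat":
        return np.ones_like(centres_bp, dtype=float)
    sigma = width / 4.0
    return np.exp(-((centres_bp - c) ** 2) / (2.0 * sigma ** 2))


def _draw_counts(rate: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise == "nb":
        shape = 1.0 / cfg.nb_dispersion
        lam = rate * rng.gamma(shape, 1.0 / shape, size=rate.size)
        return rng.poisson(lam).astype(float)
    return rng.poisson(rate).astype(float)


def simulate_dataset(config: SimConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate the full input bundle with ground truth.

    Background bins are Poisson(λ_bg); element bins Poisson(λ_bg × fold)
    with the fold shaped by a kernel truncated at the element boundary and
    jittered per element by a clipped log-normal intensity shared across
    factors (co-bound factors therefore co-vary within an archetype).
    H3K27me3 domains follow each archetype's declared behaviour: embedded
    domains surround the element, blocking-insulator domains end at the
    element edge, non-blocking domains continue past it.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    genome = GenomeModel((cfg.chrom_name,), {cfg.chrom_name: cfg.chrom_length},
                         cfg.bin_size)
    elements = _place_elements(cfg, rng)
    spec_by_label = {a.label: a for a in cfg.archetypes}
    n_bins = genome.n_bins(cfg.chrom_name)
    bin_centres = np.arange(n_bins) * cfg.bin_size + cfg.bin_size / 2.0

    lo, hi = cfg.strength_clip
    strengths = np.clip(rng.lognormal(0.0, cfg.strength_sigma, size=len(elements)), lo, hi)

    # per-factor fold-over-background multiplier tracks
    factors = PROTEIN_FACTORS + HISTONE_FACTORS
    mult = {f: np.ones(n_bins) for f in factors}
    for i, el in enumerate(elements.itertuples(index=False)):
        spec = spec_by_label[el.label]
        b0, b1 = el.start // cfg.bin_size, -(-el.end // cfg.bin_size)
        kern = _element_kernel(bin_centres[b0:b1], el.centre, spec.width, cfg.kernel)
        for f, amp in spec.amplitudes.items():
            if amp != 1.0:
                mult[f][b0:b1] += (amp - 1.0) * strengths[i] * kern

    # H3K27me3 domains per archetype behaviour
    domain_records = []
    for el in elements.itertuples(index=False):
        behaviour = spec_by_label[el.label].domain
        if behaviour == "embedded":
            domain_records.append((el.chrom, el.centre - cfg.pre_domain_halfwidth,
                                   el.centre + cfg.pre_domain_halfwidth, el.label))
        elif behaviour == "one-sided-stops":
            domain_records.append((el.chrom, el.end, el.end + cfg.ins_domain_extent,
                                   el.label))
        elif behaviour == "one-sided-crosses":
            domain_records.append((el.chrom, el.start - cfg.ins_domain_extent,
                                   el.end + cfg.ins_domain_extent, el.label))
    domains = RegionSet.from_records(domain_records).validate(genome)
    for d in domains:
        b0, b1 = d.start // cfg.bin_size, -(-d.end // cfg.bin_size)
        mult["H3K27me3"][b0:b1] += cfg.domain_amplitude - 1.0

    tracks = {}
    for f in factors:
        tracks[f] = SignalTrack(genome,
                                {cfg.chrom_name: _draw_counts(cfg.lambda_bg * mult[f], cfg, rng)},
                                "raw_density", {"factor": f})
    ip = SignalTrack(genome,
                     {cfg.chrom_name: _draw_counts(cfg.lambda_bg * mult["CBP"], cfg, rng)},
                     "raw_density", {"factor": "CBP_IP"})
    input_track = SignalTrack(genome,
                              {cfg.chrom_name: _draw_counts(np.full(n_bins, cfg.lambda_bg), cfg, rng)},
                              "raw_density", {"factor": "input"})

    # gene models and expression
    gene_rows, exon_rows, gene_ids = [], [], []
    for idx, el in enumerate(elements.itertuples(index=False)):
        spec = spec_by_label[el.label]
        gene, exons = _gene_for_element(el.centre, el.label, spec.placement, idx, el.chrom)
        gene_rows.append(gene)
        exon_rows.extend(exons)
        gene_ids.append(gene["gene_id"])
    genes = GeneAnnotation(pd.DataFrame(gene_rows), pd.DataFrame(exon_rows))

    expr_centre = {"low": 2.0, "mid": 5.0, "high": 8.0}
    expr_values = np.array([
        expr_centre[spec_by_label[el.label].expression] + rng.normal(0, 0.4)
        for el in elements.itertuples(index=False)])
    expression = pd.Series(expr_values, index=pd.Index(gene_ids, name="gene_id"),
                           name="expression")

    # developmental timecourse: inactive-enhancer genes rise late
    n_t = 12
    tc = np.tile(expr_values[:, None], (1, n_t)) + rng.normal(0, 0.1, size=(len(gene_ids), n_t))
    late = np.array([spec_by_label[el.label].label == "ENH_INACTIVE"
                     for el in elements.itertuples(index=False)])
    ramp = np.clip(np.arange(n_t) - 5, 0, None) * 0.7
    tc[late] += ramp
    timecourse = pd.DataFrame(tc, index=pd.Index(gene_ids, name="gene_id"),
                              columns=[f"t{j:02d}" for j in range(n_t)])

    truth = TruthTable(pd.DataFrame({
        "chrom": elements["chrom"], "start": elements["start"], "end": elements["end"],
        "label": elements["label"], "gene_id": gene_ids}))
    return SimulatedDataset(genome=genome, ip=ip, input_track=input_track,
                            tracks=tracks, histone_names=set(HISTONE_FACTORS),
                            genes=genes, expression=expression, timecourse=timecourse,
                            domains=domains, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceConfig:
    n_foreground: int = 100
    n_controls: int = 200
    length: int = 500
    at: float = 0.55
    words: tuple[tuple[str, float], ...] = (("GAGAG", 3.0), ("GATAA", 2.0),
                                            ("GTGTGT", 1.0))
    at_outlier_fraction: float = 0.2
    outlier_at: float = 0.75

    def __post_init__(self):
        if not (0 < self.at < 1):
            raise ValueError("AT fraction must be in (0, 1)")
        for w, _ in self.words:
            if len(w) > self.length:
                raise ValueError(f"word {w!r} longer than sequence length")


def _draw_seq(rng: np.random.Generator, length: int, at: float) -> list[str]:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return list(rng.choice(list("ACGT"), size=length, p=p))


def _scrub_words(seq: list[str], words: list[str], rng: np.random.Generator,
                 at: float, max_rounds: int = 50) -> list[str]:
    from .motifs import revcomp
    targets = {w for word in words for w in (word, revcomp(word))}
    for _ in range(max_rounds):
        s = "".join(seq)
        hit = None
        for w in targets:
            j = s.find(w)
            if j >= 0:
                hit = (j, len(w))
                break
        if hit is None:
            return seq
        j, L = hit
        seq[j:j + L] = _draw_seq(rng, L, at)
    return seq


def simulate_sequences(config: SequenceConfig | None = None, seed: int = 0
                       ) -> tuple[dict[str, str], dict[str, str]]:
    """Foreground sequences with planted words at configured per-sequence
    rates, and word-free control draws from the same base composition, a
    configurable fraction of which has its A/T content pushed outside the
    foreground range (to exercise the control filter)."""
    cfg = config or SequenceConfig()
    rng = np.random.default_rng(seed)
    word_list = [w for w, _ in cfg.words]

    fg = {}
    for i in range(cfg.n_foreground):
        seq = _draw_seq(rng, cfg.length, cfg.at)
        for word, rate in cfg.words:
            n_plant = int(rate) + (1 if rng.random() < rate - int(rate) else 0)
            used: list[tuple[int, int]] = []
            for _ in range(n_plant):
                for _try in range(100):
                    j = int(rng.integers(0, cfg.length - len(word) + 1))
                    if all(j + len(word) <= a or j >= b for a, b in used):
                        seq[j:j + len(word)] = list(word)
                        used.append((j, j + len(word)))
                        break
        fg[f"fg{i:03d}"] = "".join(seq)

    ctrl = {}
    n_out = math.ceil(cfg.at_outlier_fraction * cfg.n_controls)
    for i in range(cfg.n_controls):
        at = cfg.outlier_at if i < n_out else cfg.at
        seq = _scrub_words(_draw_seq(rng, cfg.length, at), word_list, rng, at)
        ctrl[f"ctrl{i:03d}"] = "".join(seq)
    return fg, ctrl


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def simulate_qpcr(true_fold: float = 2.4, sigma: float = 0.1, replicates: int = 4,
                  seed: int = 0, base_enrichment: float = 4.0,
                  h3_enrichment: float = 8.0, input_cq: float = 24.0) -> pd.DataFrame:
    """Cq table for one test site and two intergenic control sites.

    The target antibody's true enrichment at the test site is multiplied by
    ``true_fold`` under treatment; control sites sit at parity and total H3
    is constant.  Every measured Cq carries independent N(0, σ) noise; the
    input Cq of a sample is shared by its target and H3 measurements, as in
    a real ChIP where one chromatin input serves all antibodies.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for site in ("site1", "ctrlA", "ctrlB"):
        for condition in ("treated", "control"):
            for rep in range(1, replicates + 1):
                if site == "site1":
                    enr_t = base_enrichment * (true_fold if condition == "treated" else 1.0)
                else:
                    enr_t = 1.0
                q = input_cq  # true input quantity in Cq units
                for antibody, true_cq in (("input", q),
                                          ("target", q - np.log2(enr_t)),
                                          ("H3", q - np.log2(h3_enrichment))):
                    rows.append({"site": site, "primer": f"{site}.p1",
                                 "antibody": antibody, "condition": condition,
                                 "replicate": rep,
                                 "cq": float(true_cq + rng.normal(0, sigma))})
    return pd.DataFrame(rows)
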