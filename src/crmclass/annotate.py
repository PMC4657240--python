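"""Class characterization: gene-feature assignment, expression binning,
reference-set overlaps with a random-genomic-region control, inter-class
gene sharing, factor correlations, developmental profiles, enrichment
fractions and distance-to-domain statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneAnnotation, GenomeModel, RegionSet, distance_to_nearest, overlaps_any
from .features import BindingMatrix
from .peaks import Peak

logger = logging.getLogger("crmclass")

FEATURES = ("promoter", "exon", "intron", "intergenic")


def _promoter_interval(tss: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    # '-' strand: upstream lies at larger coordinates
    if strand == "-":
        return tss - downstream, tss + upstream
    return tss - upstream, tss + downstream


def assign_feature(peak: Peak, genes: GeneAnnotation,
                   promoter_window: tuple[int, int] = (500, 100)) -> str:
    """Classify a peak by its centre with precedence
    promoter > exon > intron > intergenic.

    The promoter is the strand-aware window [TSS − upstream, TSS +
    downstream) of any gene.
    """
    up, down = promoter_window
    c = peak.centre
    g = genes.genes
    on_chrom = g[g["chrom"] == peak.chrom]
    for r in on_chrom.itertuples(index=False):
        lo, hi = _promoter_interval(r.tss, r.strand, up, down)
        if lo <= c < hi:
            return "promoter"
    e = genes.exons
    ex = e[(e["chrom"] == peak.chrom) & (e["start"] <= c) & (c < e["end"])]
    if len(ex):
        return "exon"
    inside = on_chrom[(on_chrom["start"] <= c) & (c < on_chrom["end"])]
    if len(inside):
        return "intron"
    return "intergenic"


def feature_fractions(peaks: list[Peak], labels: np.ndarray, genes: GeneAnnotation,
                      promoter_window: tuple[int, int] = (500, 100)) -> pd.DataFrame:
    """Per class, the fraction of peaks in each gene feature (rows sum to 1)."""
    feats = [assign_feature(p, genes, promoter_window) for p in peaks]
    df = pd.DataFrame({"class": labels, "feature": feats})
    out = (df.groupby("class")["feature"].value_counts(normalize=True)
             .unstack(fill_value=0.0))
    for f in FEATURES:
        if f not in out.columns:
            out[f] = 0.0
    return out[list(FEATURES)]


def expression_bins(expr: pd.Series) -> pd.Series:
    """Rank genes by expression and split them into three equally sized
    bins (low / mid / high; sizes differ by at most 1, the lower bins take
    any remainder; ties broken by gene id)."""
    if len(expr) < 3:
        raise ValueError("need at least 3 genes to form three bins")
    order = expr.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="stable")
    n = len(order)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = (["low"] * sizes[0] + ["mid"] * sizes[1] + ["high"] * sizes[2])
    return pd.Series(labels, index=order["gene_id"].to_numpy(), name="expression_bin")


def nearest_gene(peak: Peak, genes: GeneAnnotation) -> str:
    """Gene whose TSS is closest to the peak centre (same chromosome
    preferred; ties broken by lexicographically smaller gene id)."""
    g = genes.genes
    if len(g) == 0:
        raise ValueError("empty gene annotation")
    cand = g[g["chrom"] == peak.chrom]
    if len(cand) == 0:
        cand = g
    d = (cand["tss"] - peak.centre).abs()
    best = cand.assign(_d=d).sort_values(["_d", "gene_id"], kind="stable")
    return str(best.iloc[0]["gene_id"])


def random_regions(genome: GenomeModel, lengths: np.ndarray,
                   rng: np.random.Generator) -> RegionSet:
    """Uniformly placed regions matching a length distribution (no mask)."""
    chrom_names = list(genome.chrom_names)
    sizes = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    records = []
    for L in lengths:
        ci = rng.choice(len(chrom_names), p=probs)
        chrom = chrom_names[ci]
        max_start = max(genome.chrom_lengths[chrom] - int(L), 1)
        s = int(rng.integers(0, max_start))
        records.append((chrom, s, s + int(L)))
    return RegionSet.from_records(records)


def overlap_fraction(class_regions: RegionSet, reference: RegionSet,
                     genome: GenomeModel, n_draws: int = 100,
                     rng: np.random.Generator | None = None,
                     slop: int = 0) -> tuple[float, float, tuple[float, float]]:
    """Fraction of class regions with ≥1 bp overlap with the reference,
    plus a random-genomic-region (RGR) control: the mean fraction over
    ``n_draws`` seeded draws of count- and length-matched uniform regions,
    with a 2.5–97.5 percentile interval."""
    if len(class_regions) == 0:
        raise ValueError("empty class region set")
    rng = rng or np.random.default_rng(0)
    frac = float(overlaps_any(class_regions, reference, slop=slop).mean())
    lengths = class_regions.lengths()
    draws = np.array([
        overlaps_any(random_regions(genome, lengths, rng), reference, slop=slop).mean()
        for _ in range(n_draws)])
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return frac, float(draws.mean()), ci


def gene_overlap_matrix(class_gene_sets: list[set]) -> np.ndarray:
    """M[i][j] = 100 × |G_i ∩ G_j| / |G_i| (row-normalized, asymmetric)."""
    for i, g in enumerate(class_gene_sets):
        if not g:
            raise ValueError(f"class {i + 1} has an empty gene set")
    k = len(class_gene_sets)
    M = np.zeros((k, k))
    for i, gi in enumerate(class_gene_sets):
        for j, gj in enumerate(class_gene_sets):
            M[i, j] = 100.0 * len(gi & gj) / len(gi)
    return M


def factor_correlation(matrix: BindingMatrix | pd.DataFrame, labels: np.ndarray,
                       anchor: str, adjust: bool = False,
                       min_members: int = 4) -> pd.DataFrame:
    """Within each class, Spearman ρ (and asymptotic p) between the anchor
    dataset and every other dataset; optional Benjamini–Hochberg adjustment
    across factors within a class.  Constant columns give NaN with a
    warning."""
    df = matrix.df if isinstance(matrix, BindingMatrix) else matrix
    if anchor not in df.columns:
        raise ValueError(f"anchor column {anchor!r} not in matrix")
    rows = []
    labels = np.asarray(labels)
    for cls in sorted(set(labels.tolist())):
        sub = df.iloc[labels == cls]
        if len(sub) < min_members:
            logger.warning("class %s has <%d members, skipped", cls, min_members)
            continue
        a = sub[anchor].to_numpy()
        pvals, keys = [], []
        for col in df.columns:
            if col == anchor:
                continue
            b = sub[col].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                logger.warning("constant column in class %s (%s): rho undefined", cls, col)
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(a, b)
            rows.append({"class": cls, "factor": col, "rho": rho, "p": p})
            pvals.append(p)
            keys.append(len(rows) - 1)
        if adjust:
            from statsmodels.stats.multitest import multipletests
            arr = np.asarray(pvals, dtype=float)
            ok = ~np.isnan(arr)
            adj = np.full(arr.shape, np.nan)
            if ok.any():
                adj[ok] = multipletests(arr[ok], method="fdr_bh")[1]
            for idx, q in zip(keys, adj):
                rows[idx]["p_adj"] = q
    return pd.DataFrame(rows)


def dev_expression_profile(timecourse: pd.DataFrame, gene_set) -> pd.Series:
    """Mean-centred profile of per-timepoint expression changes.

    Per gene, Δ_t = expr_t − expr_{t−1} on log2 values; Δ_t is averaged
    over the gene set, then the global mean is subtracted so the profile
    means exactly zero.  Genes missing a value are skipped at the affected
    transitions with a warning.
    """
    if timecourse.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    genes = [g for g in gene_set if g in timecourse.index]
    sub = timecourse.loc[genes]
    deltas = sub.diff(axis=1).iloc[:, 1:]
    if deltas.isna().any().any():
        logger.warning("missing expression values: %d transitions skipped",
                       int(deltas.isna().sum().sum()))
    profile = deltas.mean(axis=0, skipna=True)
    return profile - profile.mean()


def fraction_enriched(regions: RegionSet, track, fold: float = 2.0) -> float:
    """Fraction of regions whose maximum log2 enrichment over their bins
    reaches log2(fold)."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    thr = np.log2(fold)
    bs = track.genome.bin_size
    hits = 0
    for r in regions:
        v = track.values[r.chrom]
        i0 = r.start // bs
        i1 = min(-(-r.end // bs), v.size)  # ceil
        if v[i0:i1].size and v[i0:i1].max() >= thr:
            hits += 1
    return hits / len(regions)


def distance_to_domains(peaks: list[Peak], domains: RegionSet,
                        other_peaks: list[Peak]) -> tuple[np.ndarray, np.ndarray, float]:
    """Distances from peak centres to the nearest domain edge (0 inside),
    for two peak sets, with a two-sided Mann–Whitney U p-value comparing
    them."""
    if len(domains) == 0:
        raise ValueError("empty domain set")
    d1 = distance_to_nearest(np.array([p.centre for p in peaks]),
                             [p.chrom for p in peaks], domains)
    d2 = distance_to_nearest(np.array([p.centre for p in other_peaks]),
                             [p.chrom for p in other_peaks], domains)
    p = float(stats.mannwhitneyu(d1, d2, alternative="two-sided").pvalue)
    return d1, d2, p


def class_summary(peaks: list[Peak], labels: np.ndarray, matrix: BindingMatrix,
                  genes: GeneAnnotation, expr: pd.Series,
                  promoter_window: tuple[int, int] = (500, 100)) -> pd.DataFrame:
    """Per-class table: size, feature fractions, expression-bin fractions,
    and the class gene list size."""
    bins = expression_bins(expr)
    feats = feature_fractions(peaks, labels, genes, promoter_window)
    near = [nearest_gene(p, genes) for p in peaks]
    rows = []
    for cls in sorted(set(labels.tolist())):
        mask = labels == cls
        cls_genes = {near[i] for i in np.flatnonzero(mask)}
        with_expr = [g for g in cls_genes if g in bins.index]
        bc = pd.Series([bins.loc[g] for g in with_expr]).value_counts(normalize=True)
        row = {"class": cls, "n_peaks": int(mask.sum()), "n_genes": len(cls_genes)}
        for f in FEATURES:
            row[f"frac_{f}"] = float(feats.loc[cls, f]) if cls in feats.index else 0.0
        for b in ("low", "mid", "high"):
            row[f"expr_{b}"] = float(bc.get(b, 0.0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def class_mean_ci(matrix: BindingMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per class × dataset mean of mean/max-scaled values with a normal
    95 % CI on the mean (mean ± 1.96 SE)."""
    scaled = matrix.scaled()
    rows = []
    for cls in sorted(set(np.asarray(labels).tolist())):
        sub = scaled.iloc[np.asarray(labels) == cls]
        m = sub.mean()
        se = sub.std(ddof=1) / np.sqrt(len(sub))
        for col in scaled.columns:
            rows.append({"class": cls, "dataset": col, "mean": float(m[col]),
                         "ci_lo": float(m[col] - 1.96 * se[col]),
                         "ci_hi": float(m[col] + 1.96 * se[col])})
    return pd.DataFrame(rows)
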