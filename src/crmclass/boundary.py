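"""Insulator-class analyses: acetylation subclassing, oriented H3K27me3
boundary-spreading metaprofiles, and ChIP-qPCR fold evaluation.

The metaprofile asks whether repressive H3K27me3 spreads past an element:
flanking signal is extracted ±flank bp around each eligible element, each
region is flipped so its stronger flank (by summed signal) lies to the
right, and the oriented regions are averaged.  An element that blocks
spreading shows a near-background left flank; one that does not shows
similar levels on both sides.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RegionSet, SignalTrack, distance_to_nearest
from .features import BindingMatrix, scale_genomic

logger = logging.getLogger("crmclass")

ACETYL_RE = re.compile(r"(?i)k\d+ac")


@dataclass
class OrientedProfile:
    """Averaged, orientation-normalized flanking signal."""

    positions: np.ndarray       # oriented bp offsets (bin centres) from the element centre
    mean: np.ndarray            # mean scaled signal per output bin
    n: int
    flipped: np.ndarray         # per region: was the window reversed
    left_sum: np.ndarray        # per region, after orientation
    right_sum: np.ndarray

    def flank_means(self) -> tuple[float, float]:
        half = len(self.positions) // 2
        return float(self.mean[:half].mean()), float(self.mean[half:].mean())


def subclassify_histone(histone_matrix: BindingMatrix, k: int = 2,
                        acetyl_columns: list[str] | None = None,
                        selection: str = "broken_stick"):
    """Split a peak subset into k subclasses by PCA + Ward on histone
    columns; the subclass with the higher mean scaled value across
    acetylation-named columns is flagged high-acetylation.

    Returns (labels 1..k, high_acetyl_label or None).
    """
    from .classify import cluster_classes, fit_pca, select_components

    df = histone_matrix.df
    if k > len(df):
        raise ValueError(f"k={k} exceeds {len(df)} observations")
    if (df.to_numpy().std(axis=0, ddof=0) == 0).all():
        logger.warning("degenerate histone matrix: zero variance everywhere, "
                       "single effective cluster")
        return np.ones(len(df), dtype=int), None
    model = fit_pca(histone_matrix)
    n_sig = select_components(model, selection, k=min(4, len(model.explained_variance)))
    labels = cluster_classes(model, n_classes=k, n_components=max(n_sig, 1))

    if acetyl_columns is None:
        acetyl_columns = [c for c in df.columns if ACETYL_RE.search(c)
                          and "me" not in c.lower()]
    if not acetyl_columns:
        logger.warning("no acetylation-named columns found; high-acetyl flag unset")
        return labels, None
    scaled = histone_matrix.scaled()[acetyl_columns]
    means = {cls: float(scaled.iloc[labels == cls].mean().mean())
             for cls in sorted(set(labels.tolist()))}
    high = max(means, key=means.get)
    return labels, high


def _extract_window(track: SignalTrack, chrom: str, centre: int, flank: int) -> np.ndarray | None:
    bs = track.genome.bin_size
    i0, i1 = (centre - flank) // bs, (centre + flank) // bs
    v = track.values[chrom]
    if i0 < 0 or i1 > v.size:
        return None
    return v[i0:i1]


def oriented_profile(regions: RegionSet, track: SignalTrack, flank: int = 10_000,
                     out_bin: int = 100, domains: RegionSet | None = None,
                     max_domain_distance: int = 10_000,
                     intergenic_only: bool = False, genes=None,
                     orient: bool = True) -> OrientedProfile:
    """Oriented mean signal in [centre − flank, centre + flank).

    Eligibility: optionally intergenic elements only (by centre, against
    ``genes``), and elements whose centre lies within
    ``max_domain_distance`` bp of a domain (overlap counts as distance 0).
    Windows truncated by a chromosome end are excluded.  Each region is
    flipped so the flank with the larger summed signal is on the right
    (exact tie → no flip); re-orienting an oriented set is a no-op.
    """
    bs = track.genome.bin_size
    if flank < out_bin or out_bin % bs != 0 or flank % out_bin != 0:
        raise ValueError("need flank ≥ out_bin, out_bin a multiple of the track "
                         "bin and flank a multiple of out_bin")
    counts = {"input": len(regions), "not_intergenic": 0, "far_from_domain": 0,
              "truncated_window": 0, "eligible": 0}
    centres, chroms_ = [], []
    for r in regions:
        centres.append((r.start + r.end) // 2)
        chroms_.append(r.chrom)
    keep = np.ones(len(regions), dtype=bool)
    if intergenic_only and genes is not None:
        from .annotate import assign_feature
        from .peaks import Peak
        for i, r in enumerate(regions):
            pk = Peak(r.chrom, r.start, r.end, centres[i], 0.0, 0.0)
            if assign_feature(pk, genes) != "intergenic":
                keep[i] = False
                counts["not_intergenic"] += 1
    if domains is not None:
        d = distance_to_nearest(np.array(centres), chroms_, domains)
        far = keep & (d > max_domain_distance)
        counts["far_from_domain"] = int(far.sum())
        keep &= ~far

    rows, flipped, lsum, rsum = [], [], [], []
    for i in np.flatnonzero(keep):
        w = _extract_window(track, chroms_[i], centres[i], flank)
        if w is None:
            counts["truncated_window"] += 1
            continue
        half = w.size // 2
        flip = orient and (w[:half].sum() > w[half:].sum())
        if flip:
            w = w[::-1]
        rows.append(w)
        flipped.append(flip)
        lsum.append(float(w[:half].sum()))
        rsum.append(float(w[half:].sum()))
    if not rows:
        raise ValueError(f"no eligible regions (filter counts: {counts})")
    counts["eligible"] = len(rows)
    logger.info("oriented_profile eligibility: %s", counts)
    M = np.vstack(rows)
    # aggregate track bins into output bins
    per = out_bin // bs
    M = M.reshape(M.shape[0], -1, per).mean(axis=2)
    positions = np.arange(-flank, flank, out_bin) + out_bin / 2
    return OrientedProfile(positions=positions, mean=M.mean(axis=0), n=M.shape[0],
                           flipped=np.array(flipped), left_sum=np.array(lsum),
                           right_sum=np.array(rsum))


# ---------------------------------------------------------------------------
# ChIP-qPCR
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["site", "antibody", "condition", "replicate", "cq"]


def qpcr_enrichment(table: pd.DataFrame, control_sites: tuple[str, str]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔΔCq evaluation of ChIP-qPCR with dual normalization.

    Per replicate and antibody, enrichment over input E = 2^(Cq_input −
    Cq_IP); E is divided by the geometric mean of E at the two intergenic
    control sites (same antibody, condition, replicate), and the resulting
    target value is divided by the matching total-H3 value.  Per site the
    treated/control fold of the final values is reported with a two-sided
    Welch t-test across replicates.

    Returns (per-replicate finals, per-site summary with fold and p).
    """
    t = table.copy()
    missing = [c for c in QPCR_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if (t["cq"] <= 0).any():
        raise ValueError("non-positive Cq value")
    for cs in control_sites:
        if cs not in set(t["site"]):
            raise ValueError(f"control site {cs!r} absent from table")

    key = ["site", "condition", "replicate"]
    inp = t[t["antibody"] == "input"].set_index(key)["cq"]
    rows = []
    for ab in ("target", "H3"):
        sub = t[t["antibody"] == ab]
        for r in sub.itertuples(index=False):
            k = (r.site, r.condition, r.replicate)
            if k not in inp.index:
                raise ValueError(f"missing input Cq for {k}")
            rows.append({"site": r.site, "antibody": ab, "condition": r.condition,
                         "replicate": r.replicate,
                         "E": 2.0 ** (float(inp.loc[k]) - r.cq)})
    e = pd.DataFrame(rows)

    # background normalization against the two control sites
    ctrl = e[e["site"].isin(control_sites)]
    geo = (ctrl.groupby(["antibody", "condition", "replicate"])["E"]
               .apply(lambda v: float(np.exp(np.log(v).mean()))))
    e["E_norm"] = [row.E / geo.loc[(row.antibody, row.condition, row.replicate)]
                   for row in e.itertuples(index=False)]

    piv = e.pivot_table(index=key, columns="antibody", values="E_norm")
    if "target" not in piv or "H3" not in piv:
        raise ValueError("table must contain both 'target' and 'H3' antibodies")
    finals = (piv["target"] / piv["H3"]).rename("value").reset_index()

    summaries = []
    for site, sub in finals.groupby("site"):
        if site in control_sites:
            continue
        tr = sub[sub["condition"] == "treated"]["value"].to_numpy()
        co = sub[sub["condition"] == "control"]["value"].to_numpy()
        fold = float(tr.mean() / co.mean()) if len(tr) and len(co) else np.nan
        if len(tr) >= 2 and len(co) >= 2:
            p = float(stats.ttest_ind(tr, co, equal_var=False).pvalue)
        else:
            p = np.nan
        summaries.append({"site": site, "fold": fold, "p": p,
                          "n_treated": len(tr), "n_control": len(co)})
    return finals, pd.DataFrame(summaries)
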