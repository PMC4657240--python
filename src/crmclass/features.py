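"""Per-peak binding summaries and the classification matrix.

Each dataset's binding at a peak is the maximum mean over ``n_consecutive``
adjacent bins lying fully inside a window around the peak centre, computed
in log2 scale.  When the window holds fewer than ``n_consecutive`` bins the
dataset's genomic mean stands in, and (with flooring on) any value below the
genomic mean is raised to it — absence of binding is "background", never
"depletion".  Mean/max scaling maps the genomic mean to 0 and the genomic
maximum to 1 for cross-dataset display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SignalTrack
from .peaks import Peak


def to_log2(track: SignalTrack, alpha: float = 0.5) -> SignalTrack:
    """log2(raw density + α); tracks already in log2 scale pass through."""
    if track.semantics == "log2_enrichment":
        return track
    values = {c: np.log2(v + alpha) for c, v in track.values.items()}
    return SignalTrack(track.genome, values, "log2_enrichment",
                       {**track.meta, "alpha": alpha})


def summarize_binding(track: SignalTrack, chrom: str, centre: int,
                      half_window: int, genomic_mean: float,
                      n_consecutive: int = 3, floor: bool = True) -> float:
    """Top-``n_consecutive``-consecutive summary of a log2 track at a peak.

    Only bins fully inside [centre − half_window, centre + half_window)
    count; with fewer than ``n_consecutive`` of them the genomic mean is
    returned.
    """
    genome = track.genome
    if chrom not in genome.chrom_lengths or not (0 <= centre < genome.chrom_lengths[chrom]):
        raise ValueError(f"centre {centre} outside chromosome {chrom!r}")
    bs = genome.bin_size
    lo, hi = centre - half_window, centre + half_window
    i0 = max(0, math.ceil(lo / bs))
    i1 = min(genome.n_bins(chrom), hi // bs)  # exclusive
    w = track.values[chrom][i0:i1]
    if w.size < n_consecutive:
        value = genomic_mean
    else:
        run_means = np.convolve(w, np.ones(n_consecutive) / n_consecutive, mode="valid")
        value = float(run_means.max())
    if floor and value < genomic_mean:
        value = genomic_mean
    return value


@dataclass
class BindingMatrix:
    """Peaks × datasets matrix of summarized log2 binding values.

    ``meta`` is a DataFrame indexed by dataset id with columns
    genomic_mean, genomic_max, half_window, is_histone.
    """

    df: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.df.isna().any().any():
            raise ValueError("binding matrix has missing values")

    def columns(self, histone: bool | None = None) -> list[str]:
        if histone is None:
            return list(self.df.columns)
        return list(self.meta.index[self.meta["is_histone"] == histone])

    def protein_view(self) -> "BindingMatrix":
        cols = self.columns(histone=False)
        return BindingMatrix(self.df[cols], self.meta.loc[cols])

    def histone_view(self) -> "BindingMatrix":
        cols = self.columns(histone=True)
        return BindingMatrix(self.df[cols], self.meta.loc[cols])

    def scaled(self) -> pd.DataFrame:
        """Mean/max-scaled copy (0 = genomic mean, 1 = genomic max)."""
        out = {}
        for col in self.df.columns:
            m = self.meta.loc[col]
            out[col] = scale_genomic(self.df[col].to_numpy(),
                                     m["genomic_mean"], m["genomic_max"])
        return pd.DataFrame(out, index=self.df.index)


def build_matrix(peaks: list[Peak], tracks: dict[str, SignalTrack],
                 histone_datasets: set[str] | None = None,
                 protein_half_window: int = 150, histone_half_window: int = 250,
                 n_consecutive: int = 3, floor: bool = True,
                 alpha: float = 0.5) -> BindingMatrix:
    """Summarize every dataset at every peak centre.

    Protein datasets use ±``protein_half_window`` bp around the centre,
    datasets named in ``histone_datasets`` use ±``histone_half_window``.
    Raw-density tracks are log2-transformed (pseudocount α) first; genomic
    mean/max are computed on the same log2 track used for summarization.
    """
    if not peaks:
        raise ValueError("empty peak list")
    histone_datasets = histone_datasets or set()
    from .core_io import genomic_stats

    columns, meta_rows = {}, []
    for name, raw in tracks.items():
        track = to_log2(raw, alpha)
        gmean, gmax = genomic_stats(track)
        hw = histone_half_window if name in histone_datasets else protein_half_window
        columns[name] = [summarize_binding(track, p.chrom, p.centre, hw, gmean,
                                           n_consecutive, floor) for p in peaks]
        meta_rows.append((name, gmean, gmax, hw, name in histone_datasets))
    index = pd.Index([p.id for p in peaks], name="peak")
    meta = pd.DataFrame(meta_rows, columns=["dataset", "genomic_mean", "genomic_max",
                                            "half_window", "is_histone"]).set_index("dataset")
    return BindingMatrix(pd.DataFrame(columns, index=index), meta)


def scale_genomic(x, genomic_mean: float, genomic_max: float):
    """Affine map sending the genomic mean to 0 and the genomic maximum to 1.

    Order-preserving and deliberately not clipped; a constant track
    (max == mean) cannot be scaled.
    """
    if genomic_max <= genomic_mean:
        raise ValueError("degenerate track: genomic max does not exceed genomic mean")
    return (x - genomic_mean) / (genomic_max - genomic_mean)
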