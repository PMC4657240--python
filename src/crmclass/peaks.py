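"""Log2 IP/input enrichment, median smoothing, and percentile peak calling.

The calling rule: after library-size normalization of the input, compute the
per-bin log2 ratio with pseudocount α, median-smooth in windows of a fixed
bp width, take the genome-wide percentile of the smoothed track as the
threshold, and report maximal runs of bins strictly above it of at least a
minimum bp length as high-confidence binding sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import GenomeModel, RegionSet, SignalTrack

logger = logging.getLogger("crmclass")


@dataclass(frozen=True)
class Peak:
    """A called binding site: interval, summit, and enrichment summaries."""

    chrom: str
    start: int
    end: int
    centre: int
    max_enrichment: float
    mean_enrichment: float

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def log2_enrichment(ip: SignalTrack, inp: SignalTrack, alpha: float = 0.5) -> SignalTrack:
    """Per-bin log2((ip + α) / (input_scaled + α)).

    The input is first scaled so that its genome-wide total equals the IP
    total (library-size normalization); α > 0 stabilizes zero-input bins.
    """
    if ip.genome != inp.genome:
        raise ValueError("IP and input tracks are on different genome grids")
    if alpha <= 0:
        raise ValueError("pseudocount must be positive")
    ip_total = ip.all_values().sum()
    inp_total = inp.all_values().sum()
    scale = ip_total / inp_total if inp_total > 0 else 1.0
    values = {c: np.log2((ip.values[c] + alpha) / (inp.values[c] * scale + alpha))
              for c in ip.genome.chrom_names}
    return SignalTrack(ip.genome, values, "log2_enrichment",
                       {"alpha": alpha, "input_scale": scale})


def _sliding_median(v: np.ndarray, k: int) -> np.ndarray:
    """Median over the 2k+1 bins centred on each bin; edges truncated."""
    n = v.size
    if k == 0 or n == 0:
        return v.copy()
    out = np.empty_like(v)
    if n >= 2 * k + 1:
        win = np.lib.stride_tricks.sliding_window_view(v, 2 * k + 1)
        out[k:n - k] = np.median(win, axis=1)
        edge = k
    else:
        edge = n  # whole chromosome is edge territory
    for i in range(min(edge, n)):
        out[i] = np.median(v[max(0, i - k):i + k + 1])
    for i in range(max(n - edge, 0), n):
        out[i] = np.median(v[max(0, i - k):i + k + 1])
    return out


def median_smooth(track: SignalTrack, window: int = 100) -> SignalTrack:
    """Replace each bin by the median of the bins whose centres lie within
    ±window/2 of its centre (truncated at chromosome edges)."""
    bs = track.genome.bin_size
    if window < bs:
        raise ValueError("smoothing window must be at least one bin")
    k = int((window / 2) // bs)
    values = {c: _sliding_median(track.values[c], k) for c in track.genome.chrom_names}
    return SignalTrack(track.genome, values, track.semantics,
                       {**track.meta, "smoothing_window": window})


def call_peaks(track: SignalTrack, percentile: float = 95.0,
               min_length: int = 200) -> list[Peak]:
    """Maximal runs of bins strictly above the genome-wide percentile, kept
    if they span at least ``min_length`` bp; sorted by (chrom, start).

    The percentile is taken over every genome bin (zeros included).  The
    summit is the midpoint of the run's maximal bin (ties → leftmost).  A
    constant track has no bin strictly above its own percentile and yields
    an empty list with a warning.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    allv = track.all_values()
    if allv.max() == allv.min():
        logger.warning("constant track: no peaks can exceed the %sth percentile", percentile)
        return []
    threshold = float(np.percentile(allv, percentile))
    bs = track.genome.bin_size
    peaks: list[Peak] = []
    for chrom in track.genome.chrom_names:
        v = track.values[chrom]
        L = track.genome.chrom_lengths[chrom]
        above = v > threshold
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive bin index
        for b0, b1 in zip(run_starts, run_ends):
            start = int(b0 * bs)
            end = int(min(b1 * bs, L))
            if end - start < min_length:
                continue
            seg = v[b0:b1]
            imax = int(np.argmax(seg))  # leftmost maximal bin
            centre = int(min((b0 + imax) * bs + bs // 2, L - 1))
            peaks.append(Peak(chrom, start, end, centre,
                              float(seg.max()), float(seg.mean())))
    peaks.sort(key=lambda p: (track.genome.chrom_names.index(p.chrom), p.start))
    return peaks


def peak_threshold(track: SignalTrack, percentile: float = 95.0) -> float:
    return float(np.percentile(track.all_values(), percentile))


def peaks_to_regions(peaks: list[Peak], class_labels=None) -> RegionSet:
    """BED6 view: name carries the peak id (and class when given), score is
    the max smoothed enrichment ×100 rounded, strand '.'."""
    records = []
    for i, p in enumerate(peaks):
        name = p.id if class_labels is None else f"{p.id}|class{class_labels[i]}"
        records.append((p.chrom, p.start, p.end, name,
                        float(round(p.max_enrichment * 100)), "."))
    import pandas as pd
    from .core_io import REGION_COLUMNS
    return RegionSet(pd.DataFrame(records, columns=REGION_COLUMNS))
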