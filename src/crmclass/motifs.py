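"""Word-count motif enrichment of a foreground sequence set against
A/T-matched controls.

This module deliberately uses transparent overlapping k-mer counting and a
one-sided binomial test rather than multivariate word modeling: every number
it reports can be recomputed by hand from the counts.  Controls are first
filtered to the foreground's per-sequence A/T range so base-composition
differences cannot masquerade as motif enrichment.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

_COMP = str.maketrans("ACGT", "TGCA")
VALID = frozenset("ACGT")


def revcomp(word: str) -> str:
    return word.translate(_COMP)[::-1]


def at_fraction(seq: str) -> float:
    """A/T fraction ignoring ambiguous bases (N excluded from numerator
    and denominator)."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("A") + seq.count("T")) / acgt


def filter_controls(foreground: dict[str, str], controls: dict[str, str]
                    ) -> dict[str, str]:
    """Keep controls whose per-sequence A/T fraction lies within the
    [min, max] range of the foreground's A/T fractions."""
    if not foreground:
        raise ValueError("empty foreground set")
    fg_at = [at_fraction(s) for s in foreground.values()]
    lo, hi = min(fg_at), max(fg_at)
    kept = {name: s for name, s in controls.items() if lo <= at_fraction(s) <= hi}
    if not kept:
        raise ValueError(
            f"all {len(controls)} control sequences fall outside the foreground "
            f"A/T range [{lo:.3f}, {hi:.3f}]; sample controls with a broader "
            "composition")
    return kept


def count_words(seqs: dict[str, str], k: int) -> tuple[Counter, int]:
    """Overlapping k-mer counts and the number of counted positions.

    Windows containing a non-ACGT base are skipped in both the counts and
    the position total, so rates stay per-valid-position.
    """
    counts: Counter = Counter()
    positions = 0
    for seq in seqs.values():
        s = seq.upper()
        if len(s) < k:
            raise ValueError(f"sequence shorter than k={k}")
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if set(w) <= VALID:
                counts[w] += 1
                positions += 1
    return counts, positions


def _pool_revcomp(counts: Counter) -> Counter:
    pooled: Counter = Counter()
    for w, c in counts.items():
        pooled[min(w, revcomp(w))] += c
    return pooled


def is_dinucleotide_repeat(word: str) -> bool:
    """2-periodic words built from two distinct bases (GTGT…, GAGA…)."""
    return (len(word) >= 4 and word[0] != word[1]
            and all(word[i] == word[i % 2] for i in range(len(word))))


def word_enrichment(foreground: dict[str, str], controls: dict[str, str],
                    k: int = 5, both_strands: bool = True) -> pd.DataFrame:
    """Ranked k-mer enrichment of the foreground over the controls.

    Rates are per counted position; enrichment = log2((fg_rate + ε) /
    (bg_rate + ε)) with ε = 1 / (positions of the smaller set); p is the
    one-sided binomial tail for fg_count given the foreground position
    total and the background rate, with a Bonferroni column over the 4^k
    word space.  With ``both_strands`` each word is pooled with its reverse
    complement and reported as the lexicographically smaller of the pair.
    Ranking: descending enrichment, then ascending p, then word.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    fg_counts, fg_pos = count_words(foreground, k)
    bg_counts, bg_pos = count_words(controls, k)
    if both_strands:
        fg_counts = _pool_revcomp(fg_counts)
        bg_counts = _pool_revcomp(bg_counts)
    eps = 1.0 / min(fg_pos, bg_pos)
    words = sorted(set(fg_counts) | set(bg_counts))
    rows = []
    for w in words:
        fc, bc = fg_counts.get(w, 0), bg_counts.get(w, 0)
        fr, br = fc / fg_pos, bc / bg_pos
        enr = float(np.log2((fr + eps) / (br + eps)))
        p = float(stats.binom.sf(fc - 1, fg_pos, br)) if fc > 0 else 1.0
        rows.append({"word": w, "fg_count": fc, "bg_count": bc,
                     "fg_rate": fr, "bg_rate": br, "log2_enrichment": enr,
                     "p": p, "p_bonferroni": min(p * 4 ** k, 1.0),
                     "dinucleotide_repeat": is_dinucleotide_repeat(w)})
    out = pd.DataFrame(rows).sort_values(
        ["log2_enrichment", "p", "word"], ascending=[False, True, True],
        kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
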