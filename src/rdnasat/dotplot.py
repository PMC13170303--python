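"""Word-match dotplots and tandem sub-repeat reports.

A dotplot records every maximal run of consecutive matching words between
two sequences (self-comparison included), in forward and reverse sense.
Intergenic spacers of rDNA are sub-repeat rich, so their self-dotplots show
ladders of off-diagonal lines whose lag equals the tandem period; the
sub-repeat report aggregates those lags.

Mismatch tolerance (m <= 1) is implemented by wobble expansion: each query
word is looked up together with all of its one-substitution neighbours.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from rdnasat.align import _kmer_values, _wobble_values
from rdnasat.records import SequenceRecord, encode, reverse_complement
from rdnasat.satellite import SatMonomerHit

__all__ = [
    "DotplotMatch",
    "Dotplot",
    "dotplot",
    "highlight_hits",
    "subrepeat_report",
    "matches_to_tsv",
    "plot_dotplot",
]


@dataclass(frozen=True)
class DotplotMatch:
    """A maximal run of matching words; length is in bases (>= word size)."""

    x_start: int
    y_start: int
    length: int
    sense: str  # 'forward' or 'reverse'


@dataclass
class Dotplot:
    a_id: str
    b_id: str
    a_length: int
    b_length: int
    word_size: int
    matches: list[DotplotMatch]


def _word_matches(a_codes: np.ndarray, b_codes: np.ndarray, k: int, m: int) -> list[tuple[int, int]]:
    """All (x, y) word-start pairs matching with <= m mismatches (m <= 1)."""
    b_pos, b_vals = _kmer_values(b_codes, k)
    if len(b_vals) == 0:
        return []
    order = np.argsort(b_vals, kind="stable")
    sb_vals, sb_pos = b_vals[order], b_pos[order]
    a_pos, a_vals = _kmer_values(a_codes, k)
    if m >= 1:
        a_vals, a_pos = _wobble_values(a_vals, a_pos, k)
    lo = np.searchsorted(sb_vals, a_vals, side="left")
    hi = np.searchsorted(sb_vals, a_vals, side="right")
    out = set()
    for i in range(len(a_vals)):
        for j in range(lo[i], hi[i]):
            out.add((int(a_pos[i]), int(sb_pos[j])))
    return sorted(out)


def _merge_runs(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge word matches into maximal diagonal runs of (x, y, length)."""
    runs: list[tuple[int, int, int]] = []
    by_diag: dict[int, list[int]] = defaultdict(list)
    for x, y in pairs:
        by_diag[y - x].append(x)
    for diag, xs in sorted(by_diag.items()):
        xs.sort()
        start = prev = xs[0]
        for x in xs[1:]:
            if x == prev + 1:
                prev = x
                continue
            runs.append((start, start + diag, prev - start + k))
            start = prev = x
        runs.append((start, start + diag, prev - start + k))
    return runs


def dotplot(
    a: SequenceRecord,
    b: SequenceRecord,
    word_size: int = 10,
    allowed_mismatches: int = 0,
    both_senses: bool = True,
) -> Dotplot:
    """Word-match dotplot of ``a`` (x axis) vs ``b`` (y axis).

    Self-comparison (a is b) includes the main diagonal. Reverse-sense
    matches are reported with ``y_start`` on the forward strand of ``b``.
    Sequences shorter than the word size yield an empty plot.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if allowed_mismatches not in (0, 1):
        raise ValueError("allowed_mismatches must be 0 or 1 (wobble expansion)")
    matches: list[DotplotMatch] = []
    if len(a) >= word_size and len(b) >= word_size:
        ca = encode(a.seq)
        cb = encode(b.seq)
        for x, y, ln in _merge_runs(_word_matches(ca, cb, word_size, allowed_mismatches), word_size):
            matches.append(DotplotMatch(x, y, ln, "forward"))
        if both_senses:
            crc = encode(reverse_complement(b.seq))
            for x, yrc, ln in _merge_runs(_word_matches(ca, crc, word_size, allowed_mismatches), word_size):
                matches.append(DotplotMatch(x, len(b) - yrc - ln, ln, "reverse"))
    matches.sort(key=lambda m: (m.x_start, m.y_start, m.sense))
    return Dotplot(a.id, b.id, len(a), len(b), word_size, matches)


def highlight_hits(dp: Dotplot, sat_hits: Sequence[SatMonomerHit]) -> list[tuple[DotplotMatch, bool]]:
    """Tag every match overlapping a satellite hit on either axis.

    Hits must refer to the plotted sequences (by id); anything else is a
    coordinate mismatch and raises.
    """
    x_iv: list[tuple[int, int]] = []
    y_iv: list[tuple[int, int]] = []
    for h in sat_hits:
        known = False
        if h.target_id == dp.a_id:
            x_iv.append((h.start, h.end))
            known = True
        if h.target_id == dp.b_id:
            y_iv.append((h.start, h.end))
            known = True
        if not known:
            raise ValueError(f"satellite hit on {h.target_id!r} matches neither dotplot axis")

    def _overlaps(s: int, e: int, ivs: list[tuple[int, int]]) -> bool:
        return any(s < ie and iv_s < e for iv_s, ie in ivs)

    out = []
    for m in dp.matches:
        tagged = _overlaps(m.x_start, m.x_start + m.length, x_iv) or _overlaps(
            m.y_start, m.y_start + m.length, y_iv
        )
        out.append((m, tagged))
    return out


def subrepeat_report(
    dp: Dotplot,
    min_block: int = 50,
) -> list[tuple[int, int, int]]:
    """Tandem periods from a self-dotplot: (lag, span, n_repeats) rows.

    Forward off-diagonal matches are grouped by lag (tandem period
    candidate); ``span`` is the union length of their x-extents and
    ``n_repeats = span // lag``. Only lags with span >= ``min_block`` are
    reported, longest span first.
    """
    by_lag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for m in dp.matches:
        if m.sense != "forward":
            continue
        lag = m.y_start - m.x_start
        if lag <= 0:  # keep one of each symmetric pair
            continue
        by_lag[lag].append((m.x_start, m.x_start + m.length))
    report = []
    for lag, ivs in by_lag.items():
        ivs.sort()
        span = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                span += cur_e - cur_s
                cur_s, cur_e = s, e
        span += cur_e - cur_s
        if span >= min_block:
            report.append((lag, span, span // lag))
    report.sort(key=lambda r: (-r[1], r[0]))
    return report


def matches_to_tsv(dp: Dotplot, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#a={dp.a_id}\tb={dp.b_id}\tword_size={dp.word_size}\n")
        fh.write("x_start\ty_start\tlength\tsense\n")
        for m in dp.matches:
            fh.write(f"{m.x_start}\t{m.y_start}\t{m.length}\t{m.sense}\n")


def plot_dotplot(
    dp: Dotplot,
    path: str | Path,
    tagged: Sequence[tuple[DotplotMatch, bool]] | None = None,
) -> None:
    """Render the dotplot as SVG/PNG; tagged matches are drawn in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    items = tagged if tagged is not None else [(m, False) for m in dp.matches]
    fig, ax = plt.subplots(figsize=(6, 6))
    for sense, style in (("forward", "-"), ("reverse", "-")):
        for want_tag, color in ((False, "0.3"), (True, "red")):
            segs = []
            for m, is_tagged in items:
                if m.sense != sense or is_tagged != want_tag:
                    continue
                if sense == "forward":
                    segs.append([(m.x_start, m.y_start), (m.x_start + m.length, m.y_start + m.length)])
                else:
                    segs.append([(m.x_start, m.y_start + m.length), (m.x_start + m.length, m.y_start)])
            if segs:
                ax.add_collection(LineCollection(segs, colors=color, linewidths=1.0))
    ax.set_xlim(0, dp.a_length)
    ax.set_ylim(0, dp.b_length)
    ax.set_xlabel(f"{dp.a_id} (bp)")
    ax.set_ylabel(f"{dp.b_id} (bp)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
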