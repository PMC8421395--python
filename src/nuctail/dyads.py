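"""MNase-seq dyad-positioning protocol.

Nucleosome-protected fragments of exactly 147 bp are reduced to their
midpoints (putative dyads), the midpoint counts are smoothed with a
15-bp half-width tri-weight kernel, local maxima of the smoothed track
become candidate dyads, and within any 30-bp interval the candidate with
the highest raw midpoint count is kept as the representative dyad.

Coordinates are BED 0-based half-open throughout; the midpoint of a
147-bp fragment [start, start+147) is start + 73, exact for the odd
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CORE_FRAGMENT_LENGTH = 147
DEFAULT_KERNEL_HALF_WIDTH = 15
DEFAULT_DYAD_WINDOW = 30


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def filter_core_length(fragments: pd.DataFrame, length: int = CORE_FRAGMENT_LENGTH) -> pd.DataFrame:
    """Retain only fragments of exactly the nucleosome-core length."""
    keep = (fragments["end"] - fragments["start"]) == length
    return fragments.loc[keep].reset_index(drop=True)


@dataclass
class DyadCountTrack:
    """Midpoint counts on one chromosome; index 0 is genomic ``origin``."""

    chrom: str
    origin: int
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    kernel_half_width: int = DEFAULT_KERNEL_HALF_WIDTH

    def positions(self) -> np.ndarray:
        return self.origin + np.arange(len(self.raw))


def mid_fragment_counts(fragments: pd.DataFrame, pad: int = 0) -> dict[str, DyadCountTrack]:
    """Accumulate fragment midpoints into per-chromosome raw count tracks.

    All fragments must already be the 147-bp core length; anything else
    is an error (filter first with :func:`filter_core_length`).
    """
    lengths = fragments["end"] - fragments["start"]
    if (lengths != CORE_FRAGMENT_LENGTH).any():
        raise ValueError("non-147-bp fragment reached midpoint counting; filter first")
    out: dict[str, DyadCountTrack] = {}
    for chrom, grp in fragments.groupby("chrom", sort=True):
        mids = (grp["start"] + CORE_FRAGMENT_LENGTH // 2).to_numpy()
        origin = int(mids.min()) - pad
        raw = np.bincount(mids - origin, minlength=int(mids.max()) - origin + 1 + pad)
        out[str(chrom)] = DyadCountTrack(chrom=str(chrom), origin=origin, raw=raw.astype(int))
    return out


def triweight_kernel(half_width: int = DEFAULT_KERNEL_HALF_WIDTH) -> np.ndarray:
    """Normalized discrete tri-weight kernel w(d) ∝ (1 − (d/h)²)³, |d| ≤ h."""
    if half_width < 1:
        raise ValueError("kernel half-width must be at least 1 bp")
    d = np.arange(-half_width, half_width + 1)
    w = (1.0 - (d / half_width) ** 2) ** 3
    w[np.abs(d) >= half_width] = np.maximum(w[np.abs(d) >= half_width], 0.0)
    return w / w.sum()


def triweight_smooth(
    raw: np.ndarray, half_width: int = DEFAULT_KERNEL_HALF_WIDTH, full_width: bool = False
) -> np.ndarray:
    """Convolve a raw count track with the normalized tri-weight kernel.

    ``full_width=True`` reads the bandwidth parameter as the kernel's
    full support instead of its half-width.  Boundaries are zero-padded,
    so mass is conserved in the interior of the track.
    """
    h = max(1, half_width // 2) if full_width else half_width
    k = triweight_kernel(h)
    return np.convolve(np.asarray(raw, dtype=float), k, mode="same")


def call_local_maxima(smoothed: np.ndarray, min_height: float = 0.0) -> np.ndarray:
    """Indices that are strict local maxima of the smoothed track.

    A position qualifies when its value exceeds the nearest differing
    values on both sides; a flat plateau flanked by lower values yields
    its leftmost position.  ``min_height`` (default 0 = off) suppresses
    low candidates.
    """
    y = np.asarray(smoothed, dtype=float)
    n = len(y)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_lower = i == 0 or y[i - 1] < y[i]
        right_lower = j == n - 1 or y[j + 1] < y[i]
        interior = i > 0 and j < n - 1  # track-edge plateaus are not maxima
        if left_lower and right_lower and interior and y[i] > min_height:
            out.append(i)
        i = j + 1
    return np.asarray(out, dtype=int)


@dataclass
class DyadCalls:
    """Representative dyads of one chromosome track."""

    chrom: str
    candidates: np.ndarray         # genomic positions of all local maxima
    representative: pd.DataFrame   # position, raw_count, smoothed


def select_representative_dyad(
    candidates: np.ndarray,
    raw: np.ndarray,
    smoothed: np.ndarray,
    window: int = DEFAULT_DYAD_WINDOW,
) -> np.ndarray:
    """Keep, within any ``window``-bp interval, the best-supported candidate.

    Candidates closer than ``window`` bp compete; the one with the higher
    raw midpoint count wins, ties broken by higher smoothed value, then
    by the leftmost position.  Input/output are track indices.
    """
    if len(candidates) == 0:
        return np.asarray([], dtype=int)
    order = sorted(
        candidates, key=lambda p: (-raw[p], -smoothed[p], p)
    )
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= window for q in kept):
            kept.append(p)
    return np.asarray(sorted(kept), dtype=int)


def call_dyads(
    fragments: pd.DataFrame,
    half_width: int = DEFAULT_KERNEL_HALF_WIDTH,
    window: int = DEFAULT_DYAD_WINDOW,
    min_height: float = 0.0,
    full_width: bool = False,
) -> dict[str, DyadCalls]:
    """Full protocol: 147-bp filter → midpoints → smooth → maxima → select."""
    frags = filter_core_length(fragments)
    tracks = mid_fragment_counts(frags, pad=half_width)
    calls: dict[str, DyadCalls] = {}
    for chrom, track in tracks.items():
        track.smoothed = triweight_smooth(track.raw, half_width, full_width=full_width)
        track.kernel_half_width = half_width
        cand = call_local_maxima(track.smoothed, min_height=min_height)
        rep = select_representative_dyad(cand, track.raw, track.smoothed, window=window)
        calls[chrom] = DyadCalls(
            chrom=chrom,
            candidates=track.origin + cand,
            representative=pd.DataFrame(
                {
                    "position": track.origin + rep,
                    "raw_count": track.raw[rep],
                    "smoothed": track.smoothed[rep],
                }
            ),
        )
    return calls


def write_bedgraph(track: DyadCountTrack, path: str | Path, smoothed: bool = False) -> None:
    values = track.smoothed if smoothed else track.raw
    if values is None:
        raise ValueError("track has no smoothed values")
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if v != 0:
                fh.write(f"{track.chrom}\t{track.origin + i}\t{track.origin + i + 1}\t{v:.6g}\n")


def write_dyad_bed(calls: dict[str, DyadCalls], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(calls):
            for row in calls[chrom].representative.itertuples(index=False):
                fh.write(f"{chrom}\t{row.position}\t{row.position + 1}\tdyad\t{row.raw_count}\n")
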